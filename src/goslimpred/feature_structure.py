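"""Feature clustering and correlation-based feature selection.

Features are grouped by hierarchical Ward clustering on the absolute
Pearson correlation distance d = 1 - |r|, so strongly (anti-)correlated
features land in the same group. Per binary problem, a fast
correlation-based filter (FCBF) variant ranks features by |r(f, y)|
(relevance) and removes any feature predominated by a more relevant feature
it correlates with at least as strongly as with the labels (redundancy).
Both relevance and redundancy use linear correlation rather than
symmetrical uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("goslimpred")


def abs_correlation_distance(matrix) -> pd.DataFrame:
    """Symmetric distance matrix d_ij = 1 - |pearson(f_i, f_j)| in [0, 1].

    Zero-variance columns get distance 1 to everything (0 on the diagonal)
    and are logged.
    """
    df = getattr(matrix, "data", matrix)
    if len(df) < 2:
        raise ValueError("need at least two samples to correlate features")
    X = df.to_numpy(dtype=float)
    sd = X.std(axis=0)
    zero_var = sd == 0.0
    if zero_var.any():
        logger.warning("%d zero-variance features: distance set to 1", zero_var.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    d = 1.0 - np.abs(corr)
    d[np.isnan(d)] = 1.0
    d[zero_var, :] = 1.0
    d[:, zero_var] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, 1.0)
    return pd.DataFrame(d, index=df.columns, columns=df.columns)


@dataclass
class FeatureClustering:
    """A cut of the Ward merge tree into k feature groups.

    ``assignment`` maps feature name -> cluster id (0..k-1, ordered by the
    lexicographically smallest member). ``merges`` records (label_a,
    label_b, height, new_size) in merge order.
    """

    k: int
    assignment: dict[str, int]
    merges: list[tuple] = field(default_factory=list)

    def members(self, cluster_id: int) -> list[str]:
        return [f for f, c in self.assignment.items() if c == cluster_id]

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def main_feature(self, cluster_id: int, dist: Optional[pd.DataFrame] = None) -> str:
        """Medoid of the cluster under the supplied distance, else first name."""
        mem = sorted(self.members(cluster_id))
        if dist is None or len(mem) == 1:
            return mem[0]
        sub = dist.loc[mem, mem].to_numpy()
        return mem[int(sub.mean(axis=1).argmin())]

    def to_frame(self, dist: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        rows = []
        for cid in self.cluster_ids:
            main = self.main_feature(cid, dist)
            for f in sorted(self.members(cid)):
                rows.append((f, cid, main))
        return pd.DataFrame(rows, columns=["feature", "cluster", "main_feature"])


def ward_cluster(dist: pd.DataFrame, k: int, variant: str = "D") -> FeatureClustering:
    """Agglomerative Ward clustering cut to exactly k clusters.

    The Lance-Williams Ward recurrence is applied directly to the supplied
    dissimilarities: variant ``"D"`` (default) feeds the distances in as
    given, variant ``"D2"`` squares them first (heights reported on the
    original scale). Ties in merge cost break lexicographically on the pair
    of cluster labels, where a cluster's label is its smallest member name.
    """
    names = list(dist.columns)
    n = len(names)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if variant not in ("D", "D2"):
        raise ValueError(f"unknown Ward variant {variant!r}")
    D = dist.to_numpy(dtype=float).copy()
    if variant == "D2":
        D = D**2
    active = list(range(n))
    labels = {i: names[i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    members: dict[int, set] = {i: {names[i]} for i in range(n)}
    merges: list[tuple] = []

    while len(active) > k:
        # minimum-cost pair with lexicographic tie-break on (label_a, label_b)
        best = None
        m = len(active)
        sub = D[np.ix_(active, active)]
        iu = np.triu_indices(m, 1)
        costs = sub[iu]
        cmin = costs.min()
        tie_mask = costs <= cmin + 1e-12
        for flat in np.nonzero(tie_mask)[0]:
            i, j = active[iu[0][flat]], active[iu[1][flat]]
            la, lb = sorted((labels[i], labels[j]))
            key = (la, lb)
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        ni, nj = sizes[i], sizes[j]
        dij = D[i, j]
        height = dij if variant == "D" else float(np.sqrt(dij))
        merges.append((labels[i], labels[j], height, ni + nj))
        # Lance-Williams Ward update for every other active cluster
        for kk in active:
            if kk in (i, j):
                continue
            nk = sizes[kk]
            dnew = (
                (ni + nk) * D[i, kk] + (nj + nk) * D[j, kk] - nk * dij
            ) / (ni + nj + nk)
            D[i, kk] = D[kk, i] = dnew
        sizes[i] = ni + nj
        members[i] |= members[j]
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    groups = sorted((labels[i], members[i]) for i in active)
    assignment = {}
    for cid, (_, mem) in enumerate(groups):
        for f in mem:
            assignment[f] = cid
    return FeatureClustering(k=k, assignment=assignment, merges=merges)


@dataclass
class SelectionResult:
    """FCBF output: kept features in rank order plus the removal trace."""

    selected: list[str]
    relevance: dict[str, float]
    removal_log: list[tuple]  # (feature, removed_by, c_ij) — removed_by None = threshold

    def to_frame(self) -> pd.DataFrame:
        rows = [(f, self.relevance.get(f, np.nan), "kept", np.nan) for f in self.selected]
        for f, by, cij in self.removal_log:
            rows.append((f, self.relevance.get(f, np.nan), by or "below_delta", cij))
        return pd.DataFrame(rows, columns=["feature", "c_iy", "status", "c_ij"])


def _abs_pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def fcbf_select(matrix, y, delta: float = 0.0) -> SelectionResult:
    """Relevance/redundancy selection via the predominance rule.

    1. relevance c_iy = |pearson(f_i, y)| (point-biserial, y coded 0/1);
    2. drop features with c_iy < delta;
    3. rank the rest by c_iy descending (ties by name);
    4. walking down the ranking, each kept feature f_i removes every
       lower-ranked f_j with |pearson(f_i, f_j)| >= c_jy.
    """
    df = getattr(matrix, "data", matrix)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    X = df.to_numpy(dtype=float)
    relevance = {
        f: _abs_pearson(X[:, j], y) for j, f in enumerate(df.columns)
    }
    removal_log: list[tuple] = []
    surviving = []
    for f in df.columns:
        if relevance[f] >= delta:
            surviving.append(f)
        else:
            removal_log.append((f, None, np.nan))
    ranked = sorted(surviving, key=lambda f: (-relevance[f], f))
    col = {f: j for j, f in enumerate(df.columns)}
    selected: list[str] = []
    removed: set[str] = set()
    for i, fi in enumerate(ranked):
        if fi in removed:
            continue
        selected.append(fi)
        for fj in ranked[i + 1 :]:
            if fj in removed:
                continue
            cij = _abs_pearson(X[:, col[fi]], X[:, col[fj]])
            if cij >= relevance[fj]:
                removed.add(fj)
                removal_log.append((fj, fi, cij))
    return SelectionResult(selected=selected, relevance=relevance, removal_log=removal_log)
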