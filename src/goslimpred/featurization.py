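"""Map protein sequences to the 438-dimensional primary-structure feature set.

The vector concatenates, in fixed order:

* 6 physical-chemical features — sequence length, molecular weight (Da),
  % positively charged residues (K+R), % negatively charged residues (D+E),
  isoelectric point (pH units), GRAVY (mean Kyte-Doolittle hydropathy);
* 20 amino-acid frequencies;
* 400 overlapping dipeptide (dimer) frequencies;
* 3 secondary-structure state frequencies over {H, E, C};
* 9 secondary-structure dimer frequencies.

Ambiguous residues (B, Z, X, J, U, O) contribute their statistical expected
value: each ambiguity code is resolved to a probability vector over its
compatible residues, proportional to natural-abundance priors, and every
feature is computed as the expectation under independent resolution of each
position. Features are z-score normalized; the normalization state is fitted
on an explicit reference row set so cross-validation can fit on training
folds only.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io_formats import AA_CANONICAL, ProteinRecord, SequenceValidationError

logger = logging.getLogger("goslimpred")

SS_STATES = "HEC"

PHYSCHEM_NAMES = (
    "length",
    "molecular_weight",
    "pct_positive",
    "pct_negative",
    "isoelectric_point",
    "gravy",
)
MONOMER_NAMES = tuple(f"freq_{a}" for a in AA_CANONICAL)
DIMER_NAMES = tuple(f"freq_{a}{b}" for a in AA_CANONICAL for b in AA_CANONICAL)
SS_NAMES = tuple(f"ss_{s}" for s in SS_STATES)
SS_DIMER_NAMES = tuple(f"ss_{a}{b}" for a in SS_STATES for b in SS_STATES)

FEATURE_NAMES = PHYSCHEM_NAMES + MONOMER_NAMES + DIMER_NAMES + SS_NAMES + SS_DIMER_NAMES
FEATURE_BLOCKS = {
    "physchem": PHYSCHEM_NAMES,
    "monomer": MONOMER_NAMES,
    "dimer": DIMER_NAMES,
    "ss": SS_NAMES,
    "ss_dimer": SS_DIMER_NAMES,
}
N_FEATURES = len(FEATURE_NAMES)  # 438

_AA_INDEX = {a: i for i, a in enumerate(AA_CANONICAL)}
_SS_INDEX = {s: i for i, s in enumerate(SS_STATES)}

#: residue sets for the charge features; H excluded from positives by the
#: common protein-parameter convention (configurable via physchem kwargs)
POSITIVE_RESIDUES = ("K", "R")
NEGATIVE_RESIDUES = ("D", "E")


@dataclass(frozen=True)
class ResidueTables:
    """Physico-chemical constants and ambiguity priors.

    ``abundance`` is a length-20 probability vector (canonical residue
    order) of natural amino-acid abundances; ``ambiguity`` maps each
    ambiguity code to its renormalized prior vector over the 20 residues.
    """

    hydropathy: np.ndarray
    mass: np.ndarray
    water_mass: float
    pka_nterm: float
    pka_cterm: float
    pka_positive: dict[str, float]
    pka_negative: dict[str, float]
    abundance: np.ndarray
    ambiguity: dict[str, np.ndarray]
    ss_propensity: np.ndarray  # (20, 3) helix/sheet/coil

    def prob_vector(self, ch: str) -> np.ndarray:
        if ch in _AA_INDEX:
            v = np.zeros(20)
            v[_AA_INDEX[ch]] = 1.0
            return v
        if ch in self.ambiguity:
            return self.ambiguity[ch]
        raise SequenceValidationError(f"illegal residue {ch!r}")


@lru_cache(maxsize=1)
def default_tables() -> ResidueTables:
    ref = importlib.resources.files("goslimpred").joinpath("data/residue_tables.json")
    raw = json.loads(ref.read_text())
    abundance = np.array([raw["abundance_percent"][a] for a in AA_CANONICAL])
    abundance = abundance / abundance.sum()
    ambiguity = {}
    for code, residues in raw["ambiguity"].items():
        v = np.zeros(20)
        for r in residues:
            v[_AA_INDEX[r]] = abundance[_AA_INDEX[r]]
        total = v.sum()
        if total <= 0:
            raise ValueError(f"ambiguity code {code} maps to empty support")
        ambiguity[code] = v / total
    prop = np.column_stack(
        [
            np.array([raw["ss_propensity"][k][a] for a in AA_CANONICAL])
            for k in ("helix", "sheet", "coil")
        ]
    )
    return ResidueTables(
        hydropathy=np.array([raw["hydropathy"][a] for a in AA_CANONICAL]),
        mass=np.array([raw["mass"][a] for a in AA_CANONICAL]),
        water_mass=raw["water_mass"],
        pka_nterm=raw["pka"]["n_terminus"],
        pka_cterm=raw["pka"]["c_terminus"],
        pka_positive=dict(raw["pka"]["positive_side_chains"]),
        pka_negative=dict(raw["pka"]["negative_side_chains"]),
        abundance=abundance,
        ambiguity=ambiguity,
        ss_propensity=prop,
    )


def residue_probabilities(seq: str, tables: Optional[ResidueTables] = None) -> np.ndarray:
    """(L, 20) matrix of per-position residue probabilities.

    Canonical residues are one-hot; ambiguity codes carry their renormalized
    abundance priors. Illegal characters raise with the 1-based position.
    """
    tables = tables or default_tables()
    P = np.empty((len(seq), 20))
    for i, ch in enumerate(seq):
        try:
            P[i] = tables.prob_vector(ch)
        except SequenceValidationError:
            raise SequenceValidationError(
                f"illegal residue {ch!r} at position {i + 1}"
            ) from None
    return P


def monomer_frequencies(seq: str, tables: Optional[ResidueTables] = None) -> np.ndarray:
    """Expected relative frequencies of the 20 amino acids (sum to 1)."""
    if not seq:
        raise ValueError("empty sequence")
    P = residue_probabilities(seq, tables)
    return P.sum(axis=0) / len(seq)


def dimer_frequencies(seq: str, tables: Optional[ResidueTables] = None) -> np.ndarray:
    """Expected overlapping-dimer frequencies (400 values, sum to 1 for L>=2).

    Adjacent ambiguous positions are resolved independently, so a dimer's
    expected count is the product of the two marginal residue probabilities.
    """
    P = residue_probabilities(seq, tables)
    if len(seq) < 2:
        logger.warning("dimer frequencies of a length-%d sequence are all zero", len(seq))
        return np.zeros(400)
    D = np.einsum("ij,ik->jk", P[:-1], P[1:]) / (len(seq) - 1)
    return D.ravel()


def _net_charge(
    ph: float,
    n_pos: dict[str, float],
    n_neg: dict[str, float],
    tables: ResidueTables,
) -> float:
    charge = 1.0 / (1.0 + 10.0 ** (ph - tables.pka_nterm))
    for grp, n in n_pos.items():
        charge += n / (1.0 + 10.0 ** (ph - tables.pka_positive[grp]))
    charge -= 1.0 / (1.0 + 10.0 ** (tables.pka_cterm - ph))
    for grp, n in n_neg.items():
        charge -= n / (1.0 + 10.0 ** (tables.pka_negative[grp] - ph))
    return charge


def isoelectric_point(
    counts: np.ndarray, tables: Optional[ResidueTables] = None, tol: float = 1e-4
) -> float:
    """pH at which the Henderson-Hasselbalch net charge crosses zero.

    ``counts`` are (possibly fractional, expectation-valued) residue counts
    in canonical order; termini are included. Solved by bisection on
    [0, 14] to ``tol`` pH units.
    """
    tables = tables or default_tables()
    n_pos = {g: float(counts[_AA_INDEX[g]]) for g in tables.pka_positive}
    n_neg = {g: float(counts[_AA_INDEX[g]]) for g in tables.pka_negative}
    lo, hi = 0.0, 14.0
    f_lo = _net_charge(lo, n_pos, n_neg, tables)
    if f_lo < 0:
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _net_charge(mid, n_pos, n_neg, tables) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def physchem(seq: str, tables: Optional[ResidueTables] = None) -> np.ndarray:
    """The six physical-chemical features (see module docstring for order)."""
    tables = tables or default_tables()
    P = residue_probabilities(seq, tables)
    counts = P.sum(axis=0)
    length = float(len(seq))
    mw = float(counts @ tables.mass) + tables.water_mass
    pct_pos = 100.0 * sum(counts[_AA_INDEX[a]] for a in POSITIVE_RESIDUES) / length
    pct_neg = 100.0 * sum(counts[_AA_INDEX[a]] for a in NEGATIVE_RESIDUES) / length
    pi = isoelectric_point(counts, tables)
    gravy = float(counts @ tables.hydropathy) / length
    return np.array([length, mw, pct_pos, pct_neg, pi, gravy])


def ss_frequencies(ss: str) -> np.ndarray:
    """Relative frequencies of H/E/C states."""
    if not ss:
        raise ValueError("empty structure string")
    v = np.zeros(3)
    for ch in ss:
        v[_SS_INDEX[ch]] += 1.0
    return v / len(ss)


def ss_dimer_frequencies(ss: str) -> np.ndarray:
    """Overlapping structural dimer frequencies (9 values)."""
    if len(ss) < 2:
        logger.warning("structural dimers of a length-%d string are all zero", len(ss))
        return np.zeros(9)
    D = np.zeros((3, 3))
    for a, b in zip(ss[:-1], ss[1:]):
        D[_SS_INDEX[a], _SS_INDEX[b]] += 1.0
    return D.ravel() / (len(ss) - 1)


@dataclass
class FeatureMatrix:
    """Proteins × 438 named features, plus normalization bookkeeping."""

    data: pd.DataFrame
    normalized: bool = False
    missing_ss: frozenset = frozenset()

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    def block(self, name: str) -> pd.DataFrame:
        return self.data[list(FEATURE_BLOCKS[name])]


def feature_vector(
    record: ProteinRecord,
    tables: Optional[ResidueTables] = None,
    missing_ss_policy: str = "zero",
) -> np.ndarray:
    tables = tables or default_tables()
    parts = [
        physchem(record.seq, tables),
        monomer_frequencies(record.seq, tables),
        dimer_frequencies(record.seq, tables),
    ]
    if record.ss is not None:
        parts.append(ss_frequencies(record.ss))
        parts.append(ss_dimer_frequencies(record.ss))
    elif missing_ss_policy == "zero":
        parts.append(np.zeros(3))
        parts.append(np.zeros(9))
    else:
        raise ValueError(f"{record.id}: no secondary-structure string")
    return np.concatenate(parts)


def featurize(
    records: Iterable[ProteinRecord],
    tables: Optional[ResidueTables] = None,
    missing_ss_policy: str = "zero",
) -> FeatureMatrix:
    """Build the full feature matrix with stable column names.

    ``missing_ss_policy`` controls records without a structure string:
    ``"zero"`` (default) sets the 12 structural features to 0 and flags the
    protein; ``"error"`` raises.
    """
    tables = tables or default_tables()
    records = list(records)
    rows = np.empty((len(records), N_FEATURES))
    missing = set()
    for i, rec in enumerate(records):
        rows[i] = feature_vector(rec, tables, missing_ss_policy)
        if rec.ss is None:
            missing.add(rec.id)
    if missing:
        logger.warning("%d records lack secondary structure; features zeroed", len(missing))
    df = pd.DataFrame(rows, index=[r.id for r in records], columns=list(FEATURE_NAMES))
    return FeatureMatrix(data=df, normalized=False, missing_ss=frozenset(missing))


@dataclass
class NormalizationState:
    """Per-feature mean and sample standard deviation of a reference set."""

    mean: pd.Series
    sd: pd.Series
    zero_variance: tuple = ()

    def state_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.mean.to_numpy()).tobytes())
        h.update(np.ascontiguousarray(self.sd.to_numpy()).tobytes())
        return h.hexdigest()


def fit_zscore(matrix: FeatureMatrix, rows: Optional[Iterable[str]] = None) -> NormalizationState:
    """Fit z-score parameters on a stated reference row subset (sample sd)."""
    df = matrix.data if rows is None else matrix.data.loc[list(rows)]
    if len(df) == 0:
        raise ValueError("empty fitting subset")
    # materialize first: reductions are then independent of the frame's
    # internal block layout, so identical values give identical state
    X = np.ascontiguousarray(df.to_numpy(dtype=float))
    mean = pd.Series(X.mean(axis=0), index=df.columns)
    with np.errstate(invalid="ignore"):
        sd = pd.Series(X.std(axis=0, ddof=1), index=df.columns)
    sd = sd.fillna(0.0)
    zero_var = tuple(sd.index[sd == 0.0])
    if zero_var:
        logger.debug("%d zero-variance features flagged", len(zero_var))
    return NormalizationState(mean=mean, sd=sd, zero_variance=zero_var)


def apply_zscore(matrix: FeatureMatrix, state: NormalizationState) -> FeatureMatrix:
    """Transform to zero mean / unit sd; zero-variance columns map to 0."""
    sd = state.sd.replace(0.0, 1.0)
    df = (matrix.data - state.mean) / sd
    df[list(state.zero_variance)] = 0.0
    return FeatureMatrix(data=df, normalized=True, missing_ss=matrix.missing_ss)


def predict_ss_stub(seq: str, tables: Optional[ResidueTables] = None, window: int = 5) -> str:
    """Toy three-state structure predictor: windowed propensity argmax.

    A deterministic stand-in used only when no real secondary-structure
    source is available — it is *not* equivalent to a trained predictor and
    its output should be treated as synthetic.
    """
    tables = tables or default_tables()
    P = residue_probabilities(seq, tables)
    prop = P @ tables.ss_propensity  # (L, 3)
    window = min(window, len(seq))  # 'same'-mode kernels must not exceed L
    kernel = np.ones(window) / window
    smooth = np.column_stack(
        [np.convolve(prop[:, j], kernel, mode="same") for j in range(3)]
    )
    # edge windows average fewer than `window` positions; renormalize
    counts = np.convolve(np.ones(len(seq)), kernel, mode="same")
    smooth /= counts[:, None]
    idx = smooth.argmax(axis=1)
    return "".join(SS_STATES[i] for i in idx)
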