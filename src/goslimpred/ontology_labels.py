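"""GO-slim class construction under the annotation propagation principle.

An annotation to a term implies membership in all its ancestors (the
true-path rule). For every slim term T, positives are proteins annotated to
T or to a descendant of T that is not captured by a slim descendant of T:
slim descendants act as blockers, so a protein annotated below a slim child
counts toward the child, not the parent. Such parents are "incomplete" — the
asterisked classes of the published class table. The module also performs
the inverse direction at prediction time: a positive prediction for a child
term is propagated up to every slim ancestor.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .io_formats import AnnotationTable

logger = logging.getLogger("goslimpred")


@dataclass(frozen=True)
class GoDag:
    """Directed acyclic term graph with a marked slim subset.

    ``terms`` maps a GO id to a dict with keys name, namespace and
    parents (frozenset of ids). Edges point child -> parent (is_a).
    """

    terms: Mapping[str, dict]
    slim: frozenset = frozenset()

    def __post_init__(self):
        for tid, t in self.terms.items():
            for p in t["parents"]:
                if p not in self.terms:
                    raise ValueError(f"term {tid}: unknown parent {p}")
        missing = set(self.slim) - set(self.terms)
        if missing:
            raise ValueError(f"slim ids not in DAG: {sorted(missing)}")
        self._assert_acyclic()

    def _assert_acyclic(self):
        state: dict[str, int] = {}

        def visit(node, stack):
            state[node] = 1
            for p in self.terms[node]["parents"]:
                s = state.get(p, 0)
                if s == 1:
                    raise ValueError(f"cycle through {p}")
                if s == 0:
                    visit(p, stack)
            state[node] = 2

        for tid in self.terms:
            if state.get(tid, 0) == 0:
                visit(tid, [])

    @cached_property
    def children(self) -> dict[str, frozenset]:
        ch: dict[str, set] = {tid: set() for tid in self.terms}
        for tid, t in self.terms.items():
            for p in t["parents"]:
                ch[p].add(tid)
        return {tid: frozenset(s) for tid, s in ch.items()}

    def namespace(self, term: str) -> str:
        return self.terms[term]["namespace"]

    def with_slim(self, slim: Iterable[str]) -> "GoDag":
        return GoDag(terms=self.terms, slim=frozenset(slim))

    def roots(self) -> list[str]:
        return sorted(t for t, d in self.terms.items() if not d["parents"])


def ancestors(term: str, dag: GoDag) -> set[str]:
    """Transitive closure over parent edges, excluding the term itself."""
    if term not in dag.terms:
        raise KeyError(term)
    out: set[str] = set()
    stack = list(dag.terms[term]["parents"])
    while stack:
        t = stack.pop()
        if t not in out:
            out.add(t)
            stack.extend(dag.terms[t]["parents"])
    return out


def descendants(term: str, dag: GoDag) -> set[str]:
    if term not in dag.terms:
        raise KeyError(term)
    out: set[str] = set()
    stack = list(dag.children[term])
    while stack:
        t = stack.pop()
        if t not in out:
            out.add(t)
            stack.extend(dag.children[t])
    return out


def contributing_terms(slim_term: str, dag: GoDag) -> set[str]:
    """Terms whose annotations make a protein positive for ``slim_term``.

    Downward reachability from the slim term where every slim descendant
    blocks traversal: the blocker and anything reachable only through it are
    excluded, while a term also reachable by a slim-free path is kept
    (path-sensitive reading of the class-definition rule).
    """
    if slim_term not in dag.slim:
        raise ValueError(f"{slim_term} is not a slim term")
    out = {slim_term}
    stack = list(dag.children[slim_term])
    while stack:
        t = stack.pop()
        if t in out or t in dag.slim:
            continue
        out.add(t)
        stack.extend(dag.children[t])
    return out


@dataclass
class LabelMatrix:
    """Proteins × slim-terms binary membership.

    ``incomplete`` flags terms whose positive set excludes slim-descendant
    subtrees (the asterisked classes).
    """

    df: pd.DataFrame  # index: protein ids, columns: slim term ids, values {0,1}
    incomplete: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        self.df = self.df.astype(np.int8)
        bad = ~self.df.isin([0, 1]).all()
        if bad.any():
            raise ValueError(f"non-binary columns: {list(self.df.columns[bad])}")

    @property
    def proteins(self) -> list[str]:
        return list(self.df.index)

    @property
    def terms(self) -> list[str]:
        return list(self.df.columns)

    def positives(self, term: str) -> set[str]:
        col = self.df[term]
        return set(col.index[col == 1])

    def y(self, term: str) -> np.ndarray:
        return self.df[term].to_numpy()


def _incomplete_flags(dag: GoDag, terms: Iterable[str]) -> dict[str, bool]:
    return {t: bool(descendants(t, dag) & (dag.slim - {t})) for t in terms}


def build_label_matrix(
    ann: AnnotationTable,
    dag: GoDag,
    proteins: Optional[list[str]] = None,
) -> LabelMatrix:
    """Positive/negative membership per slim term.

    A protein is positive for slim term T iff it carries at least one
    annotation to a contributing term of T; every other protein in the table
    is a negative for T. Proteins with no annotation inside a namespace stay
    in the row set as universal negatives there. Annotations to unknown
    terms are logged and skipped.
    """
    if proteins is None:
        proteins = ann.proteins
    slim_terms = sorted(dag.slim)
    contrib = {t: contributing_terms(t, dag) for t in slim_terms}

    term_to_slims: dict[str, list[int]] = {}
    for j, t in enumerate(slim_terms):
        for c in contrib[t]:
            term_to_slims.setdefault(c, []).append(j)

    row_index = {p: i for i, p in enumerate(proteins)}
    values = np.zeros((len(proteins), len(slim_terms)), dtype=np.int8)
    n_unknown = 0
    for protein, go_id in zip(ann.df["protein_id"], ann.df["go_id"]):
        if go_id not in dag.terms:
            n_unknown += 1
            continue
        i = row_index.get(protein)
        if i is None:
            continue
        for j in term_to_slims.get(go_id, ()):
            values[i, j] = 1
    if n_unknown:
        logger.warning("skipped %d annotations to terms missing from the DAG", n_unknown)
    df = pd.DataFrame(values, index=proteins, columns=slim_terms)
    return LabelMatrix(df=df, incomplete=_incomplete_flags(dag, slim_terms))


def filter_min_size(m: LabelMatrix, min_size: int = 30) -> LabelMatrix:
    """Drop slim terms with fewer than ``min_size`` positive proteins."""
    counts = m.df.sum(axis=0)
    keep = [t for t in m.terms if counts[t] >= min_size]
    return LabelMatrix(
        df=m.df[keep].copy(),
        incomplete={t: m.incomplete.get(t, False) for t in keep},
    )


def propagate_predictions(pred: LabelMatrix, dag: GoDag) -> LabelMatrix:
    """OR a positive prediction for a term into every slim ancestor.

    Idempotent; after propagation each slim term includes all its slim
    descendants' positives (asterisks removed).
    """
    terms = pred.terms
    unknown = set(terms) - dag.slim
    if unknown:
        raise ValueError(f"prediction columns not in slim: {sorted(unknown)}")
    values = pred.df.to_numpy().copy()
    out = values.copy()
    for j, t in enumerate(terms):
        anc = ancestors(t, dag)
        for k, u in enumerate(terms):
            if u in anc:
                out[:, k] |= values[:, j]
    df = pd.DataFrame(out, index=pred.proteins, columns=terms)
    return LabelMatrix(df=df, incomplete={t: False for t in terms})


def annotation_closure(ann: AnnotationTable, dag: GoDag) -> AnnotationTable:
    """Close an annotation table upward over is_a (true-path rule)."""
    pairs = set()
    for protein, go_id, ev in zip(
        ann.df["protein_id"], ann.df["go_id"], ann.df["evidence"]
    ):
        if go_id not in dag.terms:
            continue
        pairs.add((protein, go_id, ev))
        for anc in ancestors(go_id, dag):
            pairs.add((protein, anc, ev))
    df = pd.DataFrame(sorted(pairs), columns=["protein_id", "go_id", "evidence"])
    df = df.drop_duplicates(subset=["protein_id", "go_id"]).reset_index(drop=True)
    return AnnotationTable(df=df)


def build_closure_labels(
    ann: AnnotationTable, dag: GoDag, proteins: Optional[list[str]] = None
) -> LabelMatrix:
    """Reference labels with every slim term including all its descendants.

    This is the asterisk-free target used when scoring propagated
    predictions: positive for T iff annotated to T or any descendant of T.
    """
    if proteins is None:
        proteins = ann.proteins
    slim_terms = sorted(dag.slim)
    full = {t: {t} | descendants(t, dag) for t in slim_terms}
    row_index = {p: i for i, p in enumerate(proteins)}
    values = np.zeros((len(proteins), len(slim_terms)), dtype=np.int8)
    for protein, go_id in zip(ann.df["protein_id"], ann.df["go_id"]):
        i = row_index.get(protein)
        if i is None or go_id not in dag.terms:
            continue
        for j, t in enumerate(slim_terms):
            if go_id in full[t]:
                values[i, j] = 1
    df = pd.DataFrame(values, index=proteins, columns=slim_terms)
    return LabelMatrix(df=df, incomplete={t: False for t in slim_terms})


def load_reference_classes() -> pd.DataFrame:
    """The packaged plant GO-slim class table (75 classes, three namespaces).

    Columns: namespace, class_name, acronym, incomplete, n_proteins. The
    sizes are the published class sizes at the 30% identity cutoff.
    """
    ref = importlib.resources.files("goslimpred").joinpath(
        "data/plant_goslim_classes.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
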