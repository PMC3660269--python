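"""Greedy identity-based sequence clustering to remove protein-family bias.

A direct, correctness-first analogue of greedy incremental clustering
(CD-HIT style): sequences are sorted longest-first and each one joins the
first existing cluster whose representative it matches at or above the
identity cutoff, otherwise it founds a new cluster. Identity is computed
from a global alignment (BLOSUM62, affine gaps open 11 / extend 1) with the
full alignment length — including gap columns — as denominator, a stricter
and order-independent convention than the shorter-sequence denominator used
by CD-HIT itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import ProteinRecord

# BLOSUM62 covers B/Z/X; map the remaining rare codes to nearest canonicals
_NONMATRIX = str.maketrans({"J": "L", "U": "C", "O": "K"})


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = mode
    return aligner


_GLOBAL_ALIGNER = _make_aligner("global")


@dataclass(frozen=True)
class IdentityCluster:
    """A representative and the members it absorbed at a given cutoff."""

    representative: ProteinRecord
    members: tuple
    cutoff: float


def pairwise_identity(a: ProteinRecord, b: ProteinRecord) -> float:
    """Global-alignment identity in [0, 1].

    Identical aligned positions divided by total alignment length (gap
    columns included). Symmetric in its arguments.
    """
    sa = a.seq.translate(_NONMATRIX)
    sb = b.seq.translate(_NONMATRIX)
    aln = _GLOBAL_ALIGNER.align(sa, sb)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def filter_by_identity(
    seqs: Iterable[ProteinRecord], cutoff: float
) -> tuple[list[ProteinRecord], list[IdentityCluster]]:
    """Greedy incremental clustering at an identity cutoff.

    Sequences are processed by descending length (ties broken by id); each
    joins the first cluster whose representative it matches at >= cutoff,
    else founds a new cluster. Returns representatives in founding order.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    ordered = sorted(seqs, key=lambda r: (-len(r.seq), r.id))
    reps: list[ProteinRecord] = []
    members: list[list[ProteinRecord]] = []
    for rec in ordered:
        placed = False
        for ci, rep in enumerate(reps):
            # cheap bound: identities <= min(len), alignment length >= max(len)
            if len(rec.seq) < cutoff * len(rep.seq):
                continue
            if pairwise_identity(rec, rep) >= cutoff:
                members[ci].append(rec)
                placed = True
                break
        if not placed:
            reps.append(rec)
            members.append([rec])
    clusters = [
        IdentityCluster(representative=rep, members=tuple(mem), cutoff=cutoff)
        for rep, mem in zip(reps, members)
    ]
    return reps, clusters


def clusters_to_tsv(clusters: list[IdentityCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("representative\tmember\n")
        for cl in clusters:
            for mem in cl.members:
                fh.write(f"{cl.representative.id}\t{mem.id}\n")
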