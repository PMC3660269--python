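"""Readers and writers for the external formats used by the pipeline.

Handles FASTA protein sequences, GAF-like annotation tables, OBO ontology
subsets, and feature/label CSV matrices in two dialects: the standard
comma/period dialect and the Western-European Excel dialect (semicolon
column separator, comma decimal mark) used by the published supplementary
matrices.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import obonet
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("goslimpred")

#: canonical 20-letter amino-acid alphabet, alphabetical by one-letter code
AA_CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
#: IUPAC ambiguity codes plus the rare translated residues U/O
AA_AMBIGUOUS = "BZXJUO"
AA_ALPHABET = frozenset(AA_CANONICAL + AA_AMBIGUOUS)
#: three-state secondary structure: helix, sheet (extended), coil
SS_ALPHABET = frozenset("HEC")

GO_ID_RE = re.compile(r"^GO:\d{7}$")

NAMESPACES = ("molecular_function", "cellular_component", "biological_process")


class FormatError(ValueError):
    """Raised when an input file violates its format."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside its alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an optional 3-state secondary-structure string."""

    id: str
    seq: str
    ss: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise FormatError("protein record requires a non-empty id")
        if not self.seq:
            raise SequenceValidationError(f"{self.id}: empty sequence")
        for pos, ch in enumerate(self.seq, start=1):
            if ch not in AA_ALPHABET:
                raise SequenceValidationError(
                    f"{self.id}: illegal character {ch!r} at position {pos}"
                )
        if self.ss is not None:
            if len(self.ss) != len(self.seq):
                raise SequenceValidationError(
                    f"{self.id}: secondary-structure length {len(self.ss)} "
                    f"!= sequence length {len(self.seq)}"
                )
            for pos, ch in enumerate(self.ss, start=1):
                if ch not in SS_ALPHABET:
                    raise SequenceValidationError(
                        f"{self.id}: illegal structure character {ch!r} at position {pos}"
                    )


@dataclass(frozen=True)
class CsvDialect:
    """Column separator plus decimal mark for matrix CSV files."""

    sep: str = ","
    decimal: str = "."

    def __post_init__(self):
        if self.sep == self.decimal:
            raise ValueError("separator must differ from the decimal mark")


STANDARD_DIALECT = CsvDialect(",", ".")
#: semicolon/comma convention of the published supplementary CSV files
PAPER_DIALECT = CsvDialect(";", ",")


@dataclass
class AnnotationTable:
    """Protein -> GO term annotations with evidence codes.

    ``df`` has columns protein_id, go_id, evidence; duplicate
    (protein, term) pairs are collapsed. ``n_skipped`` counts unparseable
    input rows.
    """

    df: pd.DataFrame
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def proteins(self) -> list[str]:
        return sorted(self.df["protein_id"].unique())

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.df["protein_id"], self.df["go_id"]))


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated records.

    The id is the header token before the first whitespace; sequences are
    uppercased. Raises :class:`SequenceValidationError` naming the offending
    position for illegal characters and :class:`FormatError` for empty
    headers.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA entry with empty header")
        records.append(ProteinRecord(id=rec.id, seq=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i : i + 60] + "\n")


def write_ss_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write secondary-structure strings as a FASTA-shaped companion file."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.ss is None:
                continue
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.ss), 60):
                fh.write(rec.ss[i : i + 60] + "\n")


def read_ss_fasta(path) -> dict[str, str]:
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def attach_ss(records: list[ProteinRecord], ss: dict[str, str]) -> list[ProteinRecord]:
    return [
        ProteinRecord(r.id, r.seq, ss.get(r.id)) if r.id in ss else r for r in records
    ]


DEFAULT_EXCLUDED_EVIDENCE = frozenset({"IEA"})


def read_annotations(path, excluded_evidence=DEFAULT_EXCLUDED_EVIDENCE) -> AnnotationTable:
    """Read a GAF-like TSV of (protein_id, go_id, evidence) rows.

    Rows whose evidence code is in ``excluded_evidence`` are dropped — by
    default the electronically inferred (IEA) annotations, i.e.
    automatically assigned ones. Unparseable rows are skipped with a logged
    warning and counted.
    """
    rows = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not parts[0] or not GO_ID_RE.match(parts[1]):
                logger.warning("%s:%d: skipping unparseable annotation row", path, lineno)
                n_skipped += 1
                continue
            protein, go_id, evidence = parts[0], parts[1], parts[2]
            if evidence in excluded_evidence:
                continue
            rows.append((protein, go_id, evidence))
    df = pd.DataFrame(rows, columns=["protein_id", "go_id", "evidence"])
    df = df.drop_duplicates(subset=["protein_id", "go_id"], keep="first").reset_index(
        drop=True
    )
    return AnnotationTable(df=df, n_skipped=n_skipped)


def write_annotations(table: AnnotationTable, path) -> None:
    table.df.to_csv(path, sep="\t", header=False, index=False)


def read_obo(path):
    """Parse an OBO term subset into a :class:`~goslimpred.ontology_labels.GoDag`.

    Only ``is_a`` edges are used; obsolete terms are dropped. A cycle or a
    dangling ``is_a`` target is a hard error.
    """
    from .ontology_labels import GoDag  # deferred: avoid import cycle

    graph = obonet.read_obo(str(path), ignore_obsolete=True)
    terms = {}
    for node, data in graph.nodes(data=True):
        if "name" not in data:
            # obonet materializes referenced-but-undefined targets as bare nodes
            raise FormatError(f"is_a target {node} has no term stanza")
        terms[node] = (
            data["name"],
            data.get("namespace", "molecular_function"),
            set(),
        )
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            continue
        if parent not in terms:
            raise FormatError(f"term {child}: dangling is_a target {parent}")
        terms[child][2].add(parent)
    is_a_graph = nx.DiGraph(
        (c, p) for c, p, k in graph.edges(keys=True) if k == "is_a"
    )
    if not nx.is_directed_acyclic_graph(is_a_graph):
        cycle = nx.find_cycle(is_a_graph)
        raise FormatError(f"cycle detected in is_a graph: {cycle}")
    return GoDag(
        terms={
            tid: {"name": name, "namespace": ns, "parents": frozenset(parents)}
            for tid, (name, ns, parents) in terms.items()
        },
        slim=frozenset(),
    )


def write_obo(dag, path) -> None:
    """Write a GoDag back to a minimal OBO term file."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for tid in sorted(dag.terms):
            t = dag.terms[tid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {tid}\n")
            fh.write(f"name: {t['name']}\n")
            fh.write(f"namespace: {t['namespace']}\n")
            for parent in sorted(t["parents"]):
                fh.write(f"is_a: {parent}\n")


def read_slim_list(path) -> frozenset[str]:
    """Read a plain-text list of slim GO ids (one per line, # comments)."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not GO_ID_RE.match(line):
                raise FormatError(f"invalid GO id in slim list: {line!r}")
            ids.add(line)
    return frozenset(ids)


def write_slim_list(slim: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(slim):
            fh.write(tid + "\n")


def _check_names(names: Iterable[str], dialect: CsvDialect, quote: bool) -> None:
    if quote:
        return
    for name in names:
        if dialect.sep in str(name):
            raise FormatError(
                f"name {name!r} contains the column separator {dialect.sep!r}; "
                "enable quoting or rename"
            )


def write_matrix_csv(
    df: pd.DataFrame,
    path,
    dialect: CsvDialect = STANDARD_DIALECT,
    float_format: Optional[str] = None,
    quote: bool = False,
) -> None:
    """Write a row-id × column-name matrix.

    First column holds the row ids, first row the column names and the
    top-left cell is empty. ``float_format`` of ``None`` keeps full float
    precision (lossless round trip with :func:`read_matrix_csv`).
    """
    _check_names(list(df.columns) + list(df.index), dialect, quote)
    df.to_csv(
        path,
        sep=dialect.sep,
        decimal=dialect.decimal,
        float_format=float_format,
        index_label="",
    )


def read_matrix_csv(path, dialect: CsvDialect = STANDARD_DIALECT) -> pd.DataFrame:
    df = pd.read_csv(path, sep=dialect.sep, decimal=dialect.decimal, index_col=0)
    df.index.name = None
    df.index = df.index.astype(str)
    return df


def write_feature_csv(matrix, path, dialect: CsvDialect = STANDARD_DIALECT, **kw) -> None:
    """Write a FeatureMatrix (or plain DataFrame) in the chosen dialect."""
    df = getattr(matrix, "data", matrix)
    write_matrix_csv(df, path, dialect=dialect, **kw)


def read_feature_csv(path, dialect: CsvDialect = STANDARD_DIALECT) -> pd.DataFrame:
    return read_matrix_csv(path, dialect=dialect)


def write_label_csv(labels, path, dialect: CsvDialect = STANDARD_DIALECT) -> None:
    """Write a binary label matrix; cells are rendered strictly as 0/1."""
    df = getattr(labels, "df", labels).astype(int)
    if not df.isin([0, 1]).all().all():
        raise ValueError("label matrix must be binary")
    write_matrix_csv(df, path, dialect=dialect)


def read_label_csv(path, dialect: CsvDialect = STANDARD_DIALECT) -> pd.DataFrame:
    df = read_matrix_csv(path, dialect=dialect)
    return df.astype(int)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def configure_logging(level=logging.INFO, seed: Optional[int] = None) -> None:
    """Structured logging for pipeline runs; the run seed is recorded once."""
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )
    if seed is not None:
        logger.info("run seed = %d", seed)
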