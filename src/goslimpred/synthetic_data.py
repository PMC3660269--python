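"""Synthetic ontologies, annotations and sequences with planted signal.

The generator emulates the statistical structure the pipeline assumes in
real annotation data: a rooted is_a DAG per namespace with a marked slim
subset, multi-label annotations that become slim memberships through the
propagation rule, class-conditional residue-composition signals (e.g.
K/R-enriched or hydrophobic-enriched classes), sequence families produced by
mutating founders at a controlled rate (hence controlled pairwise identity),
heavy class imbalance, and 3-state secondary-structure strings from a
first-order Markov chain. Everything is reproducible from a single seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .featurization import default_tables
from .io_formats import (
    AA_CANONICAL,
    AnnotationTable,
    ProteinRecord,
    write_annotations,
    write_fasta,
    write_obo,
    write_slim_list,
    write_ss_fasta,
)
from .ontology_labels import GoDag, ancestors, contributing_terms, descendants


class ConfigError(ValueError):
    """Raised for contradictory generator settings."""


@dataclass(frozen=True)
class ClassSpec:
    """One planted slim class.

    ``enriched`` multiplies the background abundance of the named residues
    before renormalization; an empty tuple means no compositional signal.
    Families are founder sequences copied ``family_copies`` times with
    point substitutions at ``mutation_rate`` per position.
    """

    name: str
    size: int
    enriched: tuple = ()  # ((residue, multiplier), ...)
    n_families: int = 0
    family_copies: int = 1
    mutation_rate: float = 0.0

    def __post_init__(self):
        if self.size < 1:
            raise ConfigError(f"class {self.name}: size must be >= 1")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ConfigError(f"class {self.name}: mutation rate must be in [0, 1)")
        if self.n_families * self.family_copies > self.size:
            raise ConfigError(
                f"class {self.name}: {self.n_families} families x "
                f"{self.family_copies} copies exceed class size {self.size}"
            )


_DEFAULT_SS_TRANSITION = (
    (0.90, 0.04, 0.06),
    (0.05, 0.85, 0.10),
    (0.10, 0.08, 0.82),
)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    namespaces: tuple = ("molecular_function",)
    depth: int = 3
    branching: int = 2
    slim_fraction: float = 0.6
    classes: tuple = ()
    n_background: int = 100
    length_meanlog: float = math.log(180.0)
    length_sdlog: float = 0.3
    min_length: int = 30
    ss_transition: tuple = _DEFAULT_SS_TRANSITION
    ss_init: tuple = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self):
        if self.depth < 2:
            raise ConfigError("DAG depth must be >= 2")
        if not 0.0 <= self.slim_fraction <= 1.0:
            raise ConfigError("slim fraction must be in [0, 1]")
        for row in self.ss_transition:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ConfigError("SS transition rows must sum to 1")


@dataclass
class SyntheticBundle:
    """Generated records, annotations, ontology and the planted-signal ledger."""

    records: list
    annotations: AnnotationTable
    dag: GoDag
    truth: dict  # protein id -> class name (or None for background)
    families: dict  # protein id -> family tag (or None)
    ledger: dict  # class name -> sorted enriched residues; {} when no signal
    config: GeneratorConfig

    def to_files(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.fasta",
            "ss": outdir / "ss.fasta",
            "annotations": outdir / "annotations.tsv",
            "obo": outdir / "ontology.obo",
            "slim": outdir / "slim.txt",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.records, paths["fasta"])
        write_ss_fasta(self.records, paths["ss"])
        write_annotations(self.annotations, paths["annotations"])
        write_obo(self.dag, paths["obo"])
        write_slim_list(self.dag.slim, paths["slim"])
        with open(paths["truth"], "w") as fh:
            json.dump(
                {"truth": self.truth, "families": self.families, "ledger": self.ledger},
                fh,
                indent=1,
                sort_keys=True,
            )
        return {k: str(v) for k, v in paths.items()}


def generate_dag(config: GeneratorConfig) -> GoDag:
    """Rooted complete tree per namespace with a seeded slim subset.

    The slim fraction is taken over non-root terms; every namespace gets at
    least one slim term.
    """
    rng = np.random.default_rng(config.seed)
    terms = {}
    slim: set[str] = set()
    counter = 1
    for ns in config.namespaces:
        level = [f"GO:{counter:07d}"]
        counter += 1
        terms[level[0]] = {"name": f"{ns} root", "namespace": ns, "parents": frozenset()}
        non_root = []
        for _ in range(config.depth - 1):
            nxt = []
            for parent in level:
                for _ in range(config.branching):
                    tid = f"GO:{counter:07d}"
                    counter += 1
                    terms[tid] = {
                        "name": f"synthetic term {tid}",
                        "namespace": ns,
                        "parents": frozenset({parent}),
                    }
                    nxt.append(tid)
                    non_root.append(tid)
            level = nxt
        n_slim = max(1, int(round(config.slim_fraction * len(non_root))))
        chosen = rng.choice(sorted(non_root), size=n_slim, replace=False)
        slim.update(chosen.tolist())
    return GoDag(terms=terms, slim=frozenset(slim))


def _class_distribution(spec: ClassSpec) -> np.ndarray:
    tables = default_tables()
    dist = tables.abundance.copy()
    idx = {a: i for i, a in enumerate(AA_CANONICAL)}
    for residue, mult in spec.enriched:
        dist[idx[residue]] *= mult
    return dist / dist.sum()


def _draw_sequence(rng: np.random.Generator, length: int, dist: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=dist)
    return "".join(AA_CANONICAL[i] for i in idx)


def _mutate(rng: np.random.Generator, seq: str, rate: float, dist: np.ndarray) -> str:
    out = list(seq)
    idx = {a: i for i, a in enumerate(AA_CANONICAL)}
    for i, ch in enumerate(out):
        if rng.uniform() < rate:
            # substitute with a *different* residue, class-distribution weighted
            d = dist.copy()
            d[idx[ch]] = 0.0
            d = d / d.sum()
            out[i] = AA_CANONICAL[rng.choice(20, p=d)]
    return "".join(out)


def _draw_ss(rng: np.random.Generator, length: int, config: GeneratorConfig) -> str:
    T = np.asarray(config.ss_transition)
    state = int(rng.choice(3, p=np.asarray(config.ss_init)))
    out = ["HEC"[state]]
    for _ in range(length - 1):
        state = int(rng.choice(3, p=T[state]))
        out.append("HEC"[state])
    return "".join(out)


def _draw_length(rng: np.random.Generator, config: GeneratorConfig) -> int:
    return max(
        config.min_length,
        int(round(rng.lognormal(config.length_meanlog, config.length_sdlog))),
    )


def _pick_class_terms(dag: GoDag, n: int, rng: np.random.Generator) -> list[str]:
    """Choose n pairwise-unrelated slim terms, preferring terms with
    non-slim descendants so annotations below them exercise the blocking
    rule of class construction."""

    def n_free_desc(t):
        return len(descendants(t, dag) - dag.slim)

    candidates = sorted(dag.slim, key=lambda t: (-n_free_desc(t), t))
    chosen: list[str] = []
    for t in candidates:
        related = any(
            t in ancestors(c, dag) or c in ancestors(t, dag) for c in chosen
        )
        if not related:
            chosen.append(t)
        if len(chosen) == n:
            return chosen
    raise ConfigError(
        f"DAG has only {len(chosen)} pairwise-unrelated slim terms; need {n}"
    )


def generate_sequences(
    config: GeneratorConfig, dag: Optional[GoDag] = None
) -> SyntheticBundle:
    """Draw the full bundle: sequences, structures, annotations, truth."""
    rng = np.random.default_rng(config.seed)
    if dag is None:
        dag = generate_dag(config)
    class_terms = _pick_class_terms(dag, len(config.classes), rng)

    records: list[ProteinRecord] = []
    ann_rows: list[tuple] = []
    truth: dict[str, Optional[str]] = {}
    families: dict[str, Optional[str]] = {}
    ledger: dict[str, list] = {}
    counter = 1

    def new_record(seq: str, class_name, family_tag, target_term):
        nonlocal counter
        pid = f"SYN{counter:05d}"
        counter += 1
        ss = _draw_ss(rng, len(seq), config)
        records.append(ProteinRecord(id=pid, seq=seq, ss=ss))
        truth[pid] = class_name
        families[pid] = family_tag
        ann_rows.append((pid, target_term, "EXP"))

    for spec, term in zip(config.classes, class_terms):
        if spec.enriched:
            ledger[spec.name] = sorted(r for r, _ in spec.enriched)
        dist = _class_distribution(spec)
        targets = sorted(contributing_terms(term, dag))
        n_family_members = spec.n_families * spec.family_copies
        for fam in range(spec.n_families):
            founder = _draw_sequence(rng, _draw_length(rng, config), dist)
            for _ in range(spec.family_copies):
                seq = _mutate(rng, founder, spec.mutation_rate, dist)
                new_record(
                    seq, spec.name, f"{spec.name}/fam{fam}",
                    targets[rng.integers(len(targets))],
                )
        for _ in range(spec.size - n_family_members):
            seq = _draw_sequence(rng, _draw_length(rng, config), dist)
            new_record(seq, spec.name, None, targets[rng.integers(len(targets))])

    background_dist = _class_distribution(ClassSpec(name="background", size=1))
    roots = dag.roots()
    for i in range(config.n_background):
        seq = _draw_sequence(rng, _draw_length(rng, config), background_dist)
        new_record(seq, None, None, roots[i % len(roots)])

    ann = AnnotationTable(
        df=pd.DataFrame(ann_rows, columns=["protein_id", "go_id", "evidence"])
    )
    return SyntheticBundle(
        records=records,
        annotations=ann,
        dag=dag,
        truth=truth,
        families=families,
        ledger=ledger,
        config=config,
    )


def reference_scenarios() -> dict[str, GeneratorConfig]:
    """Named study conditions exercised by the test suite and experiments.

    * ``planted-easy`` — two strongly composition-shifted classes (basic
      K/R-enriched and hydrophobic-enriched) among a larger background;
      recoverable at high G-mean.
    * ``imbalanced-30`` — a single signal class sitting exactly at the
      30-positive class-size floor.
    * ``null`` — class membership assigned with no compositional signal
      (empty ledger); any apparent predictability is overfitting.
    * ``family-bias`` — classes built from sequence families at ~65%
      within-family identity, so redundancy filtering at a 30% cutoff
      collapses each family while an 80% cutoff keeps it intact.
    """
    return {
        "planted-easy": GeneratorConfig(
            seed=2013,
            depth=3,
            branching=2,
            slim_fraction=0.7,
            classes=(
                ClassSpec(name="basic", size=100, enriched=(("K", 2.5), ("R", 2.5))),
                ClassSpec(
                    name="hydrophobic",
                    size=100,
                    enriched=(("L", 2.0), ("I", 2.0), ("V", 2.0), ("F", 2.0)),
                ),
            ),
            n_background=300,
            length_meanlog=math.log(180.0),
        ),
        "imbalanced-30": GeneratorConfig(
            seed=2013,
            slim_fraction=0.7,
            classes=(ClassSpec(name="rare", size=30, enriched=(("K", 2.5), ("R", 2.5))),),
            n_background=470,
            length_meanlog=math.log(180.0),
        ),
        "null": GeneratorConfig(
            seed=2013,
            slim_fraction=0.7,
            classes=(ClassSpec(name="nosignal", size=80),),
            n_background=220,
            length_meanlog=math.log(150.0),
        ),
        "family-bias": GeneratorConfig(
            seed=2013,
            slim_fraction=0.7,
            classes=(
                ClassSpec(
                    name="basic-fam",
                    size=48,
                    enriched=(("K", 2.0), ("R", 2.0)),
                    n_families=12,
                    family_copies=4,
                    mutation_rate=0.20,
                ),
                ClassSpec(
                    name="hydrophobic-fam",
                    size=48,
                    enriched=(("L", 1.8), ("I", 1.8), ("V", 1.8)),
                    n_families=12,
                    family_copies=4,
                    mutation_rate=0.20,
                ),
            ),
            n_background=104,
            length_meanlog=math.log(120.0),
            length_sdlog=0.2,
        ),
    }
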