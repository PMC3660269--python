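"""End-to-end experiment runners over the synthetic scenarios.

These compose the pipeline stages into the study's main designs: per-cluster
predictability grids, full-feature-set evaluation with selection, null
calibration with permuted labels, and the identity-cutoff sweep contrasting
the SVM pipeline with alignment-based annotation transfer.

Problem sizes here are desk-scale choices (hundreds of proteins, reduced
swarm budgets); they are stated in the methods note and exercised as-is by
the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment_baseline import transfer_evaluate
from .classification import (
    BinaryProblem,
    PipelineSettings,
    PsoConfig,
    SvmConfig,
    evaluate_term,
    fold_hash,
    make_folds,
    mean_gmean,
    run_grid,
)
from .feature_structure import FeatureClustering
from .featurization import FEATURE_BLOCKS, featurize
from .ontology_labels import LabelMatrix, build_label_matrix, filter_min_size
from .redundancy_filter import filter_by_identity
from .synthetic_data import GeneratorConfig, SyntheticBundle, generate_sequences, reference_scenarios

logger = logging.getLogger("goslimpred")


def desk_settings(seed: int, tune: bool = True) -> PipelineSettings:
    """Reduced-budget pipeline settings for desk-scale synthetic runs.

    The swarm budget (6 particles, 8 iterations) is far below the
    production default but ample for the 2-parameter log-space search on
    these problem sizes.
    """
    return PipelineSettings(
        n_folds=5,
        inner_folds=3,
        seed=seed,
        use_smote=True,
        tune=tune,
        svm=SvmConfig(pso=PsoConfig(swarm_size=6, iterations=8)),
    )


def scenario_bundle(name: str, seed: Optional[int] = None) -> SyntheticBundle:
    scenarios = reference_scenarios()
    if name not in scenarios:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(scenarios)}")
    config = scenarios[name]
    if seed is not None:
        config = replace(config, seed=seed)
    return generate_sequences(config)


def bundle_dataset(
    bundle: SyntheticBundle, min_size: int = 30
) -> tuple[pd.DataFrame, LabelMatrix]:
    """Featurize a bundle and build its size-filtered slim label matrix."""
    X = featurize(bundle.records).data
    labels = build_label_matrix(
        bundle.annotations, bundle.dag, proteins=[r.id for r in bundle.records]
    )
    labels = filter_min_size(labels, min_size=min_size)
    return X, labels


def run_planted_recovery(
    seed: int, scenario: str = "planted-easy", settings: Optional[PipelineSettings] = None
) -> dict[str, float]:
    """Mean G-mean per planted slim class on a signal scenario."""
    bundle = scenario_bundle(scenario, seed=seed)
    X, labels = bundle_dataset(bundle)
    settings = settings or replace(desk_settings(seed), use_fcbf=True)
    out = {}
    for term in labels.terms:
        problem = BinaryProblem(term=term, X=X, y=labels.y(term))
        out[term] = mean_gmean(evaluate_term(problem, settings))
    return out


def run_null_calibration(
    seed: int, n_permutations: int = 10, settings: Optional[PipelineSettings] = None
) -> list[float]:
    """Mean G-mean under label permutation on the no-signal scenario.

    Each permutation reshuffles the class column of the null scenario; a
    sound pipeline hovers around chance (G-mean ~ 0.5).
    """
    bundle = scenario_bundle("null", seed=seed)
    X, labels = bundle_dataset(bundle)
    term = labels.terms[0]
    y = labels.y(term)
    rng = np.random.default_rng(seed)
    settings = settings or replace(
        desk_settings(seed), use_fcbf=True,
        svm=SvmConfig(pso=PsoConfig(swarm_size=4, iterations=5)),
    )
    out = []
    for p in range(n_permutations):
        y_perm = rng.permutation(y)
        problem = BinaryProblem(term=term, X=X, y=y_perm)
        perm_settings = replace(settings, seed=int(rng.integers(2**31 - 1)))
        out.append(mean_gmean(evaluate_term(problem, perm_settings)))
    return out


def contrast_clustering() -> FeatureClustering:
    """Two handmade feature groups for the cluster-contrast design.

    Group 0 holds the amino-acid composition features (where the generator
    plants its signal); group 1 holds the secondary-structure features
    (generated independently of class, hence signal-free).
    """
    assignment = {f: 0 for f in FEATURE_BLOCKS["monomer"]}
    assignment.update({f: 1 for f in FEATURE_BLOCKS["ss"]})
    assignment.update({f: 1 for f in FEATURE_BLOCKS["ss_dimer"]})
    return FeatureClustering(k=2, assignment=assignment)


def run_cluster_contrast(
    seed: int, settings: Optional[PipelineSettings] = None
) -> pd.DataFrame:
    """Per-cluster grid on the planted scenario: signal vs signal-free group."""
    bundle = scenario_bundle("planted-easy", seed=seed)
    X, labels = bundle_dataset(bundle)
    clustering = contrast_clustering()
    cols = sorted(clustering.assignment)
    settings = settings or desk_settings(seed)
    grid = run_grid(
        X[cols], labels, clustering, settings=settings, include_full=False
    )
    return grid.matrix()


def run_identity_sweep(
    seed: int,
    cutoffs: Sequence[float] = (0.8, 0.3),
    min_size: int = 10,
    settings: Optional[PipelineSettings] = None,
    score_threshold: float = 50.0,
) -> pd.DataFrame:
    """SVM vs alignment-transfer G-mean across identity cutoffs.

    Runs the family-bias scenario, redundancy-filters at each cutoff, and
    evaluates both methods on identical fold assignments. Returns a long
    DataFrame (cutoff, term, method, gmean, n_proteins).
    """
    bundle = scenario_bundle("family-bias", seed=seed)
    rows = []
    for cutoff in cutoffs:
        reps, _ = filter_by_identity(bundle.records, cutoff)
        kept = sorted(reps, key=lambda r: r.id)
        ids = [r.id for r in kept]
        X = featurize(kept).data
        labels = build_label_matrix(bundle.annotations, bundle.dag, proteins=ids)
        labels = filter_min_size(labels, min_size=min_size)
        run_settings = settings or replace(desk_settings(seed), use_fcbf=True)
        for term in labels.terms:
            y = labels.y(term)
            folds = make_folds(y, run_settings.n_folds, run_settings.seed)
            problem = BinaryProblem(term=term, X=X, y=y)
            svm_metrics = evaluate_term(problem, run_settings, folds=folds)
            baseline_metrics = transfer_evaluate(
                kept, labels, folds, threshold=score_threshold
            )[term]
            rows.append((cutoff, term, "svm", mean_gmean(svm_metrics), len(ids),
                         fold_hash(folds)))
            rows.append((cutoff, term, "baseline", mean_gmean(baseline_metrics),
                         len(ids), fold_hash(folds)))
    return pd.DataFrame(
        rows, columns=["cutoff", "term", "method", "gmean", "n_proteins", "fold_hash"]
    )
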