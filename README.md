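# goslimpred

Machinery for asking how much of a plant protein's function — expressed as
Gene Ontology (GO) slim terms — is predictable from its primary structure
alone. The package implements the full analysis pipeline for land-plant
(*Embryophyta*) style annotation studies: sequence redundancy filtering,
slim-class construction under the GO propagation principle, a 438-dimensional
sequence featurization, feature clustering and correlation-based selection,
imbalance-corrected one-vs-all Gaussian-kernel SVM evaluation, an
alignment-transfer baseline, and ontology-aware propagation of predictions.
A synthetic-data generator with planted compositional signal makes every
stage testable end-to-end without any external downloads.

It is aimed at computational biologists studying sequence–function
relationships in non-model organisms, where curated training data are scarce
and heavily imbalanced.

## The method

**Classes.** For each slim term *T*, positives are proteins annotated to *T*
or to any descendant of *T* that is not captured by a slim descendant of *T*
(slim descendants act as blockers); every other protein is a negative. Terms
whose positive set excludes descendant-slim subtrees are flagged
*incomplete*. Classes with fewer than 30 positives are discarded. At
prediction time the inverse direction applies: a positive prediction for a
child term propagates to all slim ancestors (true-path rule).

**Features.** Each sequence maps to 438 named features:
6 physical-chemical (length, molecular weight, %K+R, %D+E, isoelectric
point, GRAVY), 20 amino-acid frequencies, 400 dipeptide frequencies, and
3 + 9 secondary-structure state/dimer frequencies over {H, E, C}. Ambiguous
residues (B, Z, X, J, U, O) contribute statistical expected values with
natural-abundance priors. Features are z-score normalized, fitted on
training folds only.

**Selection.** Features are Ward-clustered on the absolute Pearson
correlation distance *d* = 1 − |*r*|; per binary problem, a fast
correlation-based filter keeps features ranked by relevance
*c*<sub>iy</sub> = |cor(**f**<sub>i</sub>, **y**)| and removes any feature
predominated by a more relevant one (*c*<sub>ij</sub> ≥ *c*<sub>jy</sub>).

**Classification.** One-vs-all, stratified 5-fold CV. Inside each training
fold: SMOTE brings the minority class to parity, and the Gaussian-kernel SVM
hyperparameters (σ, C) are tuned by particle swarm optimization in log10
space against an inner 3-fold cross-validated G-mean,
G = √(sensitivity · specificity).

**Baseline.** BLASTP-style top-1 annotation transfer: each test protein
inherits the slim-label row of its best local-alignment hit (BLOSUM62,
affine gaps 11/1) in the training fold, on byte-identical fold assignments.

## Worked example

```python
from goslimpred.experiments import run_planted_recovery, run_identity_sweep

# two slim classes with planted compositional signal (K/R-enriched and
# hydrophobic-enriched) among 500 synthetic proteins
print(run_planted_recovery(seed=1))

# family-bias scenario: SVM vs alignment transfer at 80% / 30% cutoffs
sweep = run_identity_sweep(seed=1)
print(sweep.groupby(["method", "cutoff"])["gmean"].mean().unstack())
```

prints

```
{'GO:0000003': 0.9659518053146783, 'GO:0000004': 0.9205981908920224}
cutoff         0.3       0.8
method
baseline  0.128446  0.998319
svm       0.566438  0.874323
```

The first mapping is the cross-validated mean G-mean per planted slim term —
both classes are recovered well above chance (G ≈ 0.5). The sweep shows the
characteristic behavior of the two methods: with families intact (80%
cutoff) annotation transfer is nearly perfect, but once redundancy filtering
removes close homologs (30% cutoff) it collapses, while the feature-based
SVM, which keys on composition rather than homology, degrades far less.

A command-line interface covers the same stages
(`goslimpred simulate | filter-identity | build-labels | featurize |
cluster-features | select-features | train-eval | baseline | propagate-eval |
pipeline | identity-sweep`); `goslimpred pipeline --config run.yaml` chains
them and writes a run manifest with input digests and all seeds.

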