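# Methods

This note documents the models, parameter choices and numerical conventions
behind `goslimpred`, and what the synthetic experiments do and do not show.

## Class construction

GO annotation obeys the true-path rule: annotation to a term implies
membership in every ancestor. Slim vocabularies invert the problem — a small
curated term set must absorb annotations made anywhere below it. For a slim
term *T* the positive set is every protein with an annotation in the
*contributing set* of *T*: the terms reachable downward from *T* along paths
that never enter another slim term. A slim descendant therefore captures its
own subtree, and the parent class is *incomplete* (asterisked in the packaged
class table). The reading is path-sensitive: a multi-parent descendant kept
by at least one slim-free path from *T* still contributes to *T*. This is the
interpretation most consistent with standard slim-mapping semantics; the
purely set-based alternative (exclude every descendant of any slim child,
regardless of path) would silently drop multi-parent terms and is not
implemented.

Only `is_a` edges are used when parsing OBO input. `part_of` propagation is
a known open choice in slim mapping; restricting to `is_a` is the smallest
faithful reading and is trivial to revisit because the DAG type carries
arbitrary parent sets.

Each namespace is processed independently; a protein with no annotation in a
namespace remains in the row set as a universal negative there. Classes with
fewer than `min_size = 30` positives are discarded — below that a 5-fold
stratified split leaves too few positives per fold for a meaningful
sensitivity estimate. The packaged reference table
(`data/plant_goslim_classes.tsv`) lists the 75 plant GO-slim classes (14
molecular function, 20 cellular component, 41 biological process) with their
acronyms, incomplete flags and class sizes at the 30% identity cutoff.

## Redundancy filtering

Greedy incremental clustering, longest sequence first: a sequence joins the
first cluster whose representative it matches at ≥ cutoff identity, else
founds a new cluster. Identity is computed from a single global alignment
(BLOSUM62, affine gap open 11 / extend 1) as identical columns divided by
**total alignment length including gap columns**. This is deliberately
stricter and order-independent compared to the shorter-sequence denominator
used by CD-HIT; the package does not attempt to reproduce CD-HIT's k-mer
prefilter or its exact cluster boundaries, only the statistical effect of
removing family redundancy. A cheap length-ratio bound
(identity ≤ |shorter| / |longer|) skips most hopeless alignments.

## Featurization

438 features in fixed order: 6 physical-chemical, 20 monomer frequencies,
400 overlapping dimer frequencies, 3 secondary-structure state frequencies
and 9 structural dimer frequencies.

* **Molecular weight** — sum of average residue masses plus one water
  (18.015 Da).
* **Charge percentages** — positives are {K, R} and negatives {D, E}. H is
  excluded from the positive set by the common protein-parameter convention
  (it is mostly neutral at physiological pH); both sets are configurable
  constants.
* **Isoelectric point** — Henderson–Hasselbalch net charge over termini
  (pKa 7.5 / 3.55) and ionizable side chains (K 10.0, R 12.0, H 5.98,
  D 4.05, E 4.45, C 9.0, Y 10.0), solved by bisection on pH ∈ [0, 14] to
  1e-4 pH units. The constants are Bjellqvist/Expasy-style values shipped in
  `data/residue_tables.json`.
* **GRAVY** — mean Kyte–Doolittle hydropathy.

Ambiguity codes resolve to probability vectors over their IUPAC support
(B={D,N}, Z={E,Q}, J={I,L}, X=all 20) proportional to Swiss-Prot-wide
natural-abundance priors; U→C and O→K map to their nearest canonical
residues. Every feature is the expectation under independent per-position
resolution; for dimers this means the product of the two marginal vectors —
independence is the only closed form, and the test suite verifies it against
exhaustive enumeration of all resolutions. Length counts positions and is
unaffected by ambiguity; molecular weight uses the expectation.

z-score normalization uses the sample standard deviation and is fitted on an
explicit reference row set. During cross-validation the state is fitted on
training folds only: a single global fit would leak held-out information
into the transform, and the leakage guard in the test suite asserts that
corrupting a test fold leaves the fitted state bit-identical. Zero-variance
features are flagged and mapped to 0.

Secondary structure is an *input* (3-state H/E/C strings). The bundled
`predict_ss_stub` — windowed Chou–Fasman propensity argmax, window 5 — is a
deterministic toy for plumbing when no real predictor output is available;
its output is synthetic and no result in this package depends on its
accuracy.

## Feature structure

Feature clustering uses the absolute Pearson correlation distance
d = 1 − |r| (anti-correlated features are informationally equivalent) with
an in-package Ward agglomeration: the Lance–Williams Ward recurrence applied
directly to the supplied dissimilarities (`ward.D` convention). The `D2`
variant (squaring first) is selectable and is cross-checked against scipy's
Ward on genuinely Euclidean data. Merge ties break lexicographically on
cluster labels (a cluster's label is its smallest member name), making every
cut deterministic. The default cut is k = 15 groups, a free parameter; the
exact memberships are data-dependent and not a stable surface of the method.

Feature selection follows the fast correlation-based filter scheme with
linear correlation in place of symmetrical uncertainty for both relevance
(c_iy, point-biserial against the 0/1 labels) and redundancy (c_ij). The
relevance threshold δ defaults to 0: the rank-based predominance rule — a
kept feature removes every lower-ranked feature it correlates with at least
as strongly as that feature correlates with the labels — does the pruning on
its own. Selection runs inside each training fold.

## Classification protocol

One-vs-all with stratified, shuffled, seeded 5-fold cross-validation (80/20
per the protocol), identical fold assignments for the SVM and the baseline
(asserted by hashing the index arrays). Per training fold, in order:
z-score fit, optional FCBF, SMOTE to class parity (k = 5 neighbors, the
original convention; interpolation x + u(z − x), u ~ U(0,1)), PSO tuning,
final fit.

PSO tunes (σ, C) of K(x, z) = exp(−‖x−z‖²/2σ²) in log10 space, boxes
σ ∈ [1e-3, 1e3] and C ∈ [1e-2, 1e3], canonical constants w = 0.72,
c1 = c2 = 1.49. The objective is the mean G-mean of an inner stratified
3-fold CV on the training portion, with SMOTE re-applied inside each inner
training split (and computed once per fold, since it does not depend on
σ, C). Production defaults are swarm 15 × 30 iterations; the desk-scale
experiment runners use swarm 6 × 8 iterations, which is ample for a
2-parameter search at these problem sizes and keeps a full synthetic study
in minutes on one CPU.

Fold metrics are sensitivity TP/(TP+FN), specificity TN/(TN+FP) (zero on an
empty denominator) and G-mean √(sens·spec); folds are averaged, not pooled,
so the dispersion over the five repetitions is available. Note the per-fold
average of G-mean under label permutation sits slightly *below* 0.5 (folds
where the tuned machine collapses to the majority class contribute G = 0),
which is why the null-calibration band is 0.5 ± 0.1 rather than a point.

Propagated evaluation: out-of-fold predictions per term are OR-ed into every
slim ancestor, reference labels are rebuilt with all descendants included
(asterisks removed), and accuracy = (TP+TN)/N is reported per term.

## Alignment-transfer baseline

Top-1 hit transfer: each test protein takes the complete slim-label row of
its highest-scoring training sequence under Smith–Waterman local alignment
(BLOSUM62, open 11 / extend 1), ties broken by database id, no hit below a
raw-score threshold (default 50, configurable — E-value statistics are out
of scope). Top-k voting is deliberately not the default: top-1 is the
simplest faithful operationalization of annotation transfer, and anything
richer belongs to the GOtcha/Blast2GO family of methods.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* a rooted complete `is_a` tree per namespace (default depth 3, branching 2)
  with a seeded slim subset drawn from non-root terms;
* class-conditional residue composition — a class's distribution is the
  Swiss-Prot abundance prior with named residues multiplied and
  renormalized. Signals are planted at the monomer level only; dimer and
  physical-chemical effects emerge as consequences, mirroring the view that
  charge/hydropathy composition drives predictability;
* families: founders copied with per-position substitutions at rate m, so
  within-family identity concentrates near (1−m)²;
* annotations assigned to random contributing terms of each class's slim
  term (exercising the blocking rule), background proteins annotated to the
  namespace root;
* secondary structure from a first-order Markov chain over {H, E, C} with
  helix/sheet-persistent defaults.

Bundled study conditions: `planted-easy` (two classes of 100 — K/R ×2.5 and
L/I/V/F ×2.0 — plus 300 background, mean length ≈ 180), `imbalanced-30`
(one class at exactly the 30-positive floor against 470 background), `null`
(80 "class" members drawn from the background distribution; empty signal
ledger), and `family-bias` (two classes of 12 families × 4 copies at
mutation rate 0.20, within-family identity ≈ 0.65, so an 80% cutoff keeps
families intact while 30% collapses them; 104 background, mean length ≈ 120,
evaluated with `min_size` 10 because classes shrink to ~12 representatives
at the strict cutoff).

What passing these scenarios shows: the pipeline recovers planted
compositional signal (mean G-mean ≥ 0.85 on `planted-easy`), does not
manufacture signal from noise (null permutations at 0.5 ± 0.1), attributes
performance to the feature group carrying the signal (contrast gap ≥ 0.2
between the composition cluster and the structure cluster), and reproduces
the qualitative homology-dependence asymmetry (alignment transfer collapses
at the 30% cutoff; the SVM degrades much less). What it does **not** show:
performance on real proteomes — real sequences have domain architecture,
indels, phylogenetic correlation and annotation noise that the generator
deliberately omits, and real class signals are far weaker than the planted
ones.

## Numerical conventions and degenerate inputs

* Dimer frequencies of a length-1 sequence are an all-zero vector with a
  logged warning, not an error.
* Missing secondary structure: the 12 structural features are zeroed and the
  protein flagged (default), or a hard error under the `error` policy.
* Zero-variance features: distance 1 to everything in clustering, relevance
  0 in selection, transformed to 0 by the normalizer.
* Normalization statistics are computed on a materialized contiguous array
  so identical values always produce identical state, independent of
  DataFrame memory layout.
* SMOTE lowers k to n−1 with a warning when the minority is smaller than
  k+1, and duplicates a singleton minority.
* PSO scores a non-finite objective as −∞ and continues.
* CSV matrices: first column row ids, first row feature names, empty
  top-left cell; the Western-European dialect (semicolon separator, comma
  decimal) is supported for interoperability with the published
  supplementary matrices. Floats are written at full precision by default
  (lossless round trip); a significant-digit format is available.

## Known limitations

* The redundancy filter is O(n²) in alignments and meant for desk-scale
  inputs; a production run over ~10⁵ sequences would need an external
  clustering tool behind the same interface.
* The identity at a 30% cutoff is below the reliable range of word-filter
  heuristics in dedicated tools; the direct-alignment stand-in sidesteps the
  issue at a computational cost.
* `predict_ss_stub` is not a secondary-structure predictor in any evaluative
  sense.
* Whether charged-residue percentages should include H (positive) or C/Y
  (negative at high pH) is convention-dependent; the shipped defaults are
  {K,R} / {D,E} and both sets are configurable.
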