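"""One-vs-all evaluation machinery for slim-term classifiers.

Each slim term defines a binary problem (members vs everything else), which
is heavily imbalanced by construction. Per outer fold of a stratified
5-fold cross-validation: feature normalization is fitted on the training
portion only, features are optionally selected by FCBF on the training
portion, the training minority class is brought to parity with SMOTE, the
Gaussian-kernel SVM hyperparameters (kernel width sigma, penalty C) are
tuned by particle swarm optimization against an inner cross-validated
G-mean, and the fitted model is scored on the held-out fold. Performance is
summarized by sensitivity, specificity and their geometric mean, which is
robust to class imbalance.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .feature_structure import FeatureClustering, fcbf_select
from .featurization import FeatureMatrix, apply_zscore, fit_zscore
from .ontology_labels import GoDag, LabelMatrix, build_closure_labels, propagate_predictions

logger = logging.getLogger("goslimpred")


@dataclass(frozen=True)
class PsoConfig:
    """Canonical particle swarm settings (constriction-style constants)."""

    swarm_size: int = 15
    iterations: int = 30
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49


@dataclass(frozen=True)
class SvmConfig:
    """Gaussian-kernel SVM with log-scale tuning boxes for sigma and C."""

    sigma: float = 1.0
    C: float = 10.0
    sigma_bounds: tuple = (1e-3, 1e3)
    C_bounds: tuple = (1e-2, 1e3)
    pso: PsoConfig = PsoConfig()

    def __post_init__(self):
        if self.sigma <= 0 or self.C <= 0:
            raise ValueError("sigma and C must be positive")
        for lo, hi in (self.sigma_bounds, self.C_bounds):
            if not (0 < lo < hi < math.inf):
                raise ValueError("tuning bounds must be finite, positive, ordered")


@dataclass(frozen=True)
class PipelineSettings:
    """Everything evaluate_term needs besides the data."""

    n_folds: int = 5
    inner_folds: int = 3
    seed: int = 0
    smote_k: int = 5
    use_smote: bool = True
    use_fcbf: bool = False
    fcbf_delta: float = 0.0
    tune: bool = True
    svm: SvmConfig = SvmConfig()


@dataclass
class BinaryProblem:
    """One slim term's one-vs-all task over an aligned feature view."""

    term: str
    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("feature rows and labels misaligned")
        if len(np.unique(self.y)) < 2:
            raise ValueError(f"{self.term}: both classes must be present")


@dataclass(frozen=True)
class FoldMetrics:
    fold: int
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def gmean(self) -> float:
        return math.sqrt(self.sensitivity * self.specificity)


def gmean(sensitivity: float, specificity: float) -> float:
    """Geometric mean of sensitivity and specificity."""
    return math.sqrt(sensitivity * specificity)


def confusion(y_true: np.ndarray, y_pred: np.ndarray, fold: int = 0) -> FoldMetrics:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return FoldMetrics(
        fold=fold,
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def smote(
    minority: np.ndarray,
    amount: float,
    k: int = 5,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Synthetic minority oversampling by neighbor interpolation.

    Emits ``ceil(amount/100 * n_minority)`` points, each of the form
    x + u (z - x) with z one of x's k nearest minority neighbors (Euclidean)
    and u ~ Uniform(0, 1). All output lies in the minority convex hull.
    """
    minority = np.asarray(minority, dtype=float)
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = len(minority)
    if n == 0:
        raise ValueError("empty minority set")
    n_new = math.ceil(amount / 100.0 * n)
    if n_new <= 0:
        return np.empty((0, minority.shape[1]))
    if n == 1:
        logger.warning("singleton minority class: SMOTE duplicates the sample")
        return np.repeat(minority, n_new, axis=0)
    if k >= n:
        logger.warning("k=%d >= minority size %d; lowering k to %d", k, n, n - 1)
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    _, idx = nn.kneighbors(minority)
    neighbors = idx[:, 1:]  # drop self
    out = np.empty((n_new, minority.shape[1]))
    for s in range(n_new):
        i = rng.integers(n)
        z = minority[neighbors[i, rng.integers(k)]]
        u = rng.uniform()
        out[s] = minority[i] + u * (z - minority[i])
    return out


def train_svm(X: np.ndarray, y: np.ndarray, sigma: float, C: float) -> SVC:
    """Fit an SVC with Gaussian kernel K(x,z) = exp(-||x-z||^2 / (2 sigma^2))."""
    if sigma <= 0 or C <= 0:
        raise ValueError("sigma and C must be positive")
    clf = SVC(kernel="rbf", gamma=1.0 / (2.0 * sigma**2), C=C)
    clf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
    return clf


def pso_tune(
    objective: Callable[[float, float], float],
    config: SvmConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float, float]:
    """Maximize ``objective(sigma, C)`` by PSO in log10 parameter space.

    Velocity update v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x);
    positions are clamped to the bounds. Returns (sigma*, C*, best score).
    Non-finite objective values score -inf and the run continues.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    pso = config.pso
    lo = np.log10([config.sigma_bounds[0], config.C_bounds[0]])
    hi = np.log10([config.sigma_bounds[1], config.C_bounds[1]])

    def score(pos: np.ndarray) -> float:
        sigma, C = 10.0 ** pos
        try:
            val = objective(sigma, C)
        except Exception:  # solver failures count as -inf, swarm continues
            return -math.inf
        return val if np.isfinite(val) else -math.inf

    x = rng.uniform(lo, hi, size=(pso.swarm_size, 2))
    v = np.zeros_like(x)
    pbest = x.copy()
    pbest_score = np.array([score(p) for p in x])
    g = int(pbest_score.argmax())
    gbest, gbest_score = pbest[g].copy(), pbest_score[g]

    for _ in range(pso.iterations):
        r1 = rng.uniform(size=x.shape)
        r2 = rng.uniform(size=x.shape)
        v = (
            pso.inertia * v
            + pso.cognitive * r1 * (pbest - x)
            + pso.social * r2 * (gbest - x)
        )
        x = np.clip(x + v, lo, hi)
        for i in range(pso.swarm_size):
            s = score(x[i])
            if s > pbest_score[i]:
                pbest[i], pbest_score[i] = x[i].copy(), s
                if s > gbest_score:
                    gbest, gbest_score = x[i].copy(), s
    sigma, C = 10.0 ** gbest
    return float(sigma), float(C), float(gbest_score)


def make_folds(
    y: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified, shuffled, seeded folds shared by SVM and baseline runs."""
    y = np.asarray(y, dtype=int)
    if y.sum() < n_folds:
        raise ValueError(
            f"only {int(y.sum())} positives: cannot stratify {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def fold_hash(folds: Sequence[tuple[np.ndarray, np.ndarray]]) -> str:
    h = hashlib.sha256()
    for tr, te in folds:
        h.update(np.asarray(tr, dtype=np.int64).tobytes())
        h.update(np.asarray(te, dtype=np.int64).tobytes())
    return h.hexdigest()


@dataclass
class FittedFold:
    """Everything fitted on one training fold (no test-fold information)."""

    zscore_hash: str
    selected: list[str]
    sigma: float
    C: float
    model: SVC


def _fit_fold(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    settings: PipelineSettings,
    rng: np.random.Generator,
):
    fm_train = FeatureMatrix(data=X_train)
    state = fit_zscore(fm_train)
    Xtr = apply_zscore(fm_train, state).data

    if settings.use_fcbf:
        sel = fcbf_select(Xtr, y_train, delta=settings.fcbf_delta)
        selected = sel.selected or [max(sel.relevance, key=sel.relevance.get)]
    else:
        selected = list(Xtr.columns)
    Xtr_sel = Xtr[selected].to_numpy()

    if settings.tune:
        sigma, C = _tune_on_train(Xtr_sel, y_train, settings, rng)
    else:
        sigma, C = settings.svm.sigma, settings.svm.C

    Xfit, yfit = _balance(Xtr_sel, y_train, settings, rng)
    model = train_svm(Xfit, yfit, sigma, C)
    fitted = FittedFold(
        zscore_hash=state.state_hash(), selected=selected, sigma=sigma, C=C, model=model
    )
    return fitted, state


def _balance(
    X: np.ndarray, y: np.ndarray, settings: PipelineSettings, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE the minority class up to parity with the majority."""
    if not settings.use_smote:
        return X, y
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == n_neg or min(n_pos, n_neg) == 0:
        return X, y
    minority_label = 1 if n_pos < n_neg else 0
    minority = X[y == minority_label]
    amount = 100.0 * (max(n_pos, n_neg) - len(minority)) / len(minority)
    synth = smote(minority, amount=amount, k=settings.smote_k, rng=rng)
    Xb = np.vstack([X, synth])
    yb = np.concatenate([y, np.full(len(synth), minority_label)])
    return Xb, yb


def _tune_on_train(
    X: np.ndarray, y: np.ndarray, settings: PipelineSettings, rng: np.random.Generator
) -> tuple[float, float]:
    """PSO over (sigma, C) scored by inner stratified CV mean G-mean."""
    inner_seed = int(rng.integers(2**31 - 1))
    n_inner = min(settings.inner_folds, int(y.sum()), int((1 - y).sum()))
    if n_inner < 2:
        return settings.svm.sigma, settings.svm.C
    inner = make_folds(y, n_inner, inner_seed)
    # SMOTE is independent of (sigma, C): balance each inner fold once so
    # the objective is deterministic across swarm evaluations
    balanced = [
        _balance(X[tr], y[tr], settings,
                 np.random.default_rng(int(rng.integers(2**31 - 1))))
        for tr, _ in inner
    ]

    def objective(sigma: float, C: float) -> float:
        scores = []
        for (tr, te), (Xb, yb) in zip(inner, balanced):
            clf = train_svm(Xb, yb, sigma, C)
            m = confusion(y[te], clf.predict(X[te]))
            scores.append(m.gmean)
        return float(np.mean(scores))

    tune_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
    sigma, C, _ = pso_tune(objective, settings.svm, rng=tune_rng)
    return sigma, C


def evaluate_term(
    problem: BinaryProblem,
    settings: PipelineSettings,
    folds: Optional[list] = None,
    return_details: bool = False,
):
    """Stratified k-fold evaluation of one slim term's one-vs-all problem.

    Normalization, feature selection, SMOTE and hyperparameter tuning all
    operate strictly inside each training fold; the held-out 20% only ever
    meets the fitted model. Returns a list of :class:`FoldMetrics`, plus a
    per-fold detail record (fitted-state hashes, chosen hyperparameters,
    test predictions) when ``return_details`` is set.
    """
    if folds is None:
        folds = make_folds(problem.y, settings.n_folds, settings.seed)
    rng = np.random.default_rng(settings.seed)
    fold_rngs = [np.random.default_rng(int(rng.integers(2**31 - 1))) for _ in folds]
    metrics: list[FoldMetrics] = []
    details = []
    for fi, (tr, te) in enumerate(folds):
        X_train = problem.X.iloc[tr]
        y_train = problem.y[tr]
        fitted, state = _fit_fold(X_train, y_train, settings, fold_rngs[fi])
        X_test = apply_zscore(FeatureMatrix(data=problem.X.iloc[te]), state).data
        y_pred = fitted.model.predict(X_test[fitted.selected].to_numpy())
        m = confusion(problem.y[te], y_pred, fold=fi)
        metrics.append(m)
        if return_details:
            details.append(
                {
                    "fold": fi,
                    "train_idx": np.asarray(tr),
                    "test_idx": np.asarray(te),
                    "zscore_hash": fitted.zscore_hash,
                    "selected": fitted.selected,
                    "sigma": fitted.sigma,
                    "C": fitted.C,
                    "test_pred": np.asarray(y_pred, dtype=int),
                }
            )
    if return_details:
        return metrics, details
    return metrics


def mean_gmean(metrics: Sequence[FoldMetrics]) -> float:
    return float(np.mean([m.gmean for m in metrics]))


@dataclass
class EvaluationGrid:
    """Per-(term, feature group) fold metrics, Figure-1 style.

    ``cells`` maps (term, group) -> list of FoldMetrics, with ``"full"`` as
    the whole-feature-set column (FCBF-selected).
    """

    cells: dict[tuple[str, str], list[FoldMetrics]]

    def to_long(self) -> pd.DataFrame:
        rows = []
        for (term, group), ms in self.cells.items():
            for m in ms:
                rows.append(
                    (term, group, m.fold, m.tp, m.tn, m.fp, m.fn,
                     m.sensitivity, m.specificity, m.gmean)
                )
        return pd.DataFrame(
            rows,
            columns=["term", "feature_group", "fold", "TP", "TN", "FP", "FN",
                     "sens", "spec", "gmean"],
        )

    def matrix(self) -> pd.DataFrame:
        """Mean G-mean matrix sorted: best terms on top, best groups left."""
        long = self.to_long()
        mat = long.pivot_table(index="term", columns="feature_group", values="gmean",
                               aggfunc="mean")
        row_order = mat.mean(axis=1).sort_values(ascending=False, kind="stable").index
        col_order = mat.mean(axis=0).sort_values(ascending=False, kind="stable").index
        return mat.loc[row_order, col_order]


def run_grid(
    X: pd.DataFrame,
    labels: LabelMatrix,
    clustering: FeatureClustering,
    terms: Optional[Sequence[str]] = None,
    settings: PipelineSettings = PipelineSettings(),
    include_full: bool = True,
) -> EvaluationGrid:
    """Evaluate every term against every feature cluster plus the full set.

    Per-cluster cells restrict the matrix to that cluster's columns (no
    FCBF); the ``"full"`` column applies FCBF over all features.
    """
    missing = set(clustering.assignment) - set(X.columns)
    if missing:
        raise ValueError(f"clustering names unknown features: {sorted(missing)[:5]}")
    terms = list(terms) if terms is not None else labels.terms
    cells: dict[tuple[str, str], list[FoldMetrics]] = {}
    for term in terms:
        y = labels.y(term)
        folds = make_folds(y, settings.n_folds, settings.seed)
        for cid in clustering.cluster_ids:
            cols = [c for c in X.columns if clustering.assignment.get(c) == cid]
            problem = BinaryProblem(term=term, X=X[cols], y=y)
            cells[(term, f"cluster_{cid}")] = evaluate_term(
                problem, replace(settings, use_fcbf=False), folds=folds
            )
        if include_full:
            problem = BinaryProblem(term=term, X=X, y=y)
            cells[(term, "full")] = evaluate_term(
                problem, replace(settings, use_fcbf=True), folds=folds
            )
    return EvaluationGrid(cells=cells)


def cross_val_predict_terms(
    X: pd.DataFrame,
    labels: LabelMatrix,
    settings: PipelineSettings,
    terms: Optional[Sequence[str]] = None,
) -> LabelMatrix:
    """Out-of-fold binary predictions per term, assembled protein-wise."""
    terms = list(terms) if terms is not None else labels.terms
    pred = pd.DataFrame(0, index=labels.proteins, columns=terms, dtype=np.int8)
    for term in terms:
        y = labels.y(term)
        problem = BinaryProblem(term=term, X=X, y=y)
        _, details = evaluate_term(problem, settings, return_details=True)
        for d in details:
            pred.iloc[d["test_idx"], pred.columns.get_loc(term)] = d["test_pred"].astype(np.int8)
    return LabelMatrix(df=pred, incomplete={t: True for t in terms})


def evaluate_propagated(
    predictions: LabelMatrix, ann, dag: GoDag
) -> pd.DataFrame:
    """Accuracy per slim term after propagating predictions to ancestors.

    Reference labels are rebuilt with every slim term including all its
    descendants (asterisks removed); accuracy = (TP + TN) / N.
    """
    propagated = propagate_predictions(predictions, dag)
    sub_dag = dag.with_slim(frozenset(predictions.terms))
    reference = build_closure_labels(ann, sub_dag, proteins=predictions.proteins)
    rows = []
    for term in propagated.terms:
        p = propagated.df[term].to_numpy()
        r = reference.df[term].to_numpy()
        m = confusion(r, p)
        rows.append((term, (m.tp + m.tn) / len(r), m.sensitivity, m.specificity))
    return pd.DataFrame(rows, columns=["term", "accuracy", "sens", "spec"]).set_index("term")
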