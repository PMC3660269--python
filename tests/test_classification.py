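import numpy as np
import pandas as pd
import pytest

from goslimpred.classification import (
    BinaryProblem,
    FoldMetrics,
    PipelineSettings,
    PsoConfig,
    SvmConfig,
    confusion,
    evaluate_term,
    fold_hash,
    gmean,
    make_folds,
    mean_gmean,
    pso_tune,
    run_grid,
    smote,
    train_svm,
)
from goslimpred.feature_structure import FeatureClustering

TINY = PipelineSettings(
    n_folds=5, inner_folds=3, seed=0, tune=True,
    svm=SvmConfig(pso=PsoConfig(swarm_size=5, iterations=5)),
)


def planted_frame(rng, n=120, n_pos=30, n_feat=6, shift=2.5):
    """Separable-by-construction binary problem with a couple of noise dims."""
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    X = rng.normal(size=(n, n_feat))
    X[:n_pos, :2] += shift
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_feat)],
                      index=[f"P{i}" for i in range(n)])
    perm = rng.permutation(n)
    return df.iloc[perm], y[perm]


class TestMetrics:
    def test_gmean_values(self):
        assert gmean(1, 1) == 1.0
        assert gmean(0, 0.9) == 0.0
        assert gmean(0.8, 0.5) == pytest.approx(0.6324555, abs=1e-6)

    def test_confusion_counts(self):
        m = confusion([1, 1, 0, 0, 0], [1, 0, 0, 1, 0])
        assert (m.tp, m.fn, m.fp, m.tn) == (1, 1, 1, 2)
        assert m.sensitivity == 0.5
        assert m.specificity == pytest.approx(2 / 3)

    def test_empty_denominators_are_zero(self):
        m = FoldMetrics(fold=0, tp=0, tn=3, fp=0, fn=0)
        assert m.sensitivity == 0.0 and m.gmean == 0.0


class TestSmote:
    def test_two_point_minority_interpolates_on_segment(self, rng):
        minority = np.array([[0.0, 0.0], [1.0, 1.0]])
        out = smote(minority, amount=100, k=1, rng=rng)
        assert out.shape == (2, 2)
        # convexity forces equal coordinates on the segment
        np.testing.assert_allclose(out[:, 0], out[:, 1], atol=1e-12)
        assert ((out >= 0) & (out <= 1)).all()

    def test_amount_zero_is_empty(self, rng):
        assert smote(np.ones((5, 2)), amount=0, k=2, rng=rng).shape == (0, 2)

    def test_output_in_convex_hull(self, rng):
        from scipy.spatial import Delaunay

        theta = rng.uniform(0, 2 * np.pi, 50)
        r = np.sqrt(rng.uniform(0, 1, 50))
        minority = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        out = smote(minority, amount=300, k=5, rng=rng)
        hull = Delaunay(minority)
        assert (hull.find_simplex(out) >= 0).all()

    def test_reproducible_under_seed(self):
        minority = np.random.default_rng(0).normal(size=(20, 3))
        a = smote(minority, amount=150, k=5, seed=11)
        b = smote(minority, amount=150, k=5, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_k_lowered_when_minority_small(self, rng):
        out = smote(np.eye(3), amount=100, k=5, rng=rng)
        assert out.shape == (3, 3)

    def test_singleton_minority_duplicates(self, rng):
        out = smote(np.array([[1.0, 2.0]]), amount=200, k=5, rng=rng)
        assert (out == [1.0, 2.0]).all()


class TestSvm:
    def test_separable_clusters_fit_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(4, 0.3, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        clf = train_svm(X, y, sigma=1.0, C=10.0)
        assert (clf.predict(X) == y).all()

    def test_xor_fit_with_small_sigma(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 1, 1, 0])
        clf = train_svm(X, y, sigma=0.3, C=100.0)
        assert (clf.predict(X) == y).all()

    def test_feature_permutation_invariance(self, rng):
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] + X[:, 2] > 0).astype(int)
        Xte = rng.normal(size=(20, 4))
        perm = [2, 0, 3, 1]
        a = train_svm(X, y, 1.0, 10.0).predict(Xte)
        b = train_svm(X[:, perm], y, 1.0, 10.0).predict(Xte[:, perm])
        np.testing.assert_array_equal(a, b)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            train_svm(np.eye(2), [0, 1], sigma=-1, C=1)


class TestPso:
    CONFIG = SvmConfig(sigma_bounds=(1e-3, 1e3), C_bounds=(1e-2, 1e3),
                       pso=PsoConfig(swarm_size=15, iterations=30))

    def test_recovers_known_quadratic_optimum(self):
        # maximum at log10(sigma)=0, log10(C)=1, i.e. (sigma, C) = (1, 10)
        obj = lambda s, C: -(np.log10(s)) ** 2 - (np.log10(C) - 1) ** 2
        sigma, C, score = pso_tune(obj, self.CONFIG, seed=3)
        assert abs(np.log10(sigma)) < 0.05
        assert abs(np.log10(C) - 1) < 0.05

    def test_same_seed_same_trajectory(self):
        obj = lambda s, C: -(np.log10(s) - 0.5) ** 2 - (np.log10(C)) ** 2
        assert pso_tune(obj, self.CONFIG, seed=5) == pso_tune(obj, self.CONFIG, seed=5)

    def test_zero_iterations_returns_best_initial(self):
        config = SvmConfig(pso=PsoConfig(swarm_size=8, iterations=0))
        obj = lambda s, C: -(np.log10(s)) ** 2
        sigma, C, score = pso_tune(obj, config, seed=1)
        assert np.isfinite(score)

    def test_non_finite_objective_survives(self):
        obj = lambda s, C: np.nan if s > 1 else -abs(np.log10(C))
        sigma, C, score = pso_tune(obj, self.CONFIG, seed=2)
        assert np.isfinite(score)


class TestEvaluateTerm:
    def test_planted_signal_recovered(self, rng):
        X, y = planted_frame(rng)
        metrics = evaluate_term(BinaryProblem("T", X, y), TINY)
        assert len(metrics) == 5
        assert mean_gmean(metrics) >= 0.85

    def test_perfect_oracle_backend_scores_one(self, rng):
        # inject a noiseless problem where the positives are a point mass:
        # any sensible classifier is exact, giving sens = spec = gmean = 1
        X, y = planted_frame(rng, shift=50.0)
        metrics = evaluate_term(BinaryProblem("T", X, y), TINY)
        for m in metrics:
            assert m.sensitivity == 1.0 and m.specificity == 1.0 and m.gmean == 1.0

    def test_too_few_positives_rejected(self, rng):
        X, _ = planted_frame(rng)
        y = np.zeros(len(X), dtype=int)
        y[:3] = 1
        with pytest.raises(ValueError):
            make_folds(y, 5, 0)

    def test_leakage_guard_test_rows_do_not_touch_fitting(self, rng):
        X, y = planted_frame(rng, n=80, n_pos=20)
        folds = make_folds(y, 5, 0)
        _, details = evaluate_term(BinaryProblem("T", X, y), TINY, folds=folds,
                                   return_details=True)
        # corrupt only fold 0's held-out rows: its fitted state must not move
        X2 = X.copy()
        X2.iloc[details[0]["test_idx"]] = 1e6
        _, details2 = evaluate_term(BinaryProblem("T", X2, y), TINY, folds=folds,
                                    return_details=True)
        d, d2 = details[0], details2[0]
        assert d["zscore_hash"] == d2["zscore_hash"]
        assert d["selected"] == d2["selected"]
        assert (d["sigma"], d["C"]) == (d2["sigma"], d2["C"])

    def test_deterministic_under_seed(self, rng):
        X, y = planted_frame(rng, n=60, n_pos=15)
        a = evaluate_term(BinaryProblem("T", X, y), TINY)
        b = evaluate_term(BinaryProblem("T", X, y), TINY)
        assert [(m.tp, m.tn, m.fp, m.fn) for m in a] == [
            (m.tp, m.tn, m.fp, m.fn) for m in b
        ]


class TestFolds:
    def test_stratification_keeps_positives_in_every_fold(self, rng):
        y = np.zeros(100, dtype=int)
        y[:20] = 1
        for tr, te in make_folds(y, 5, 1):
            assert y[te].sum() >= 1 and y[tr].sum() >= 1

    def test_fold_hash_stable(self):
        y = np.array([0, 1] * 20)
        assert fold_hash(make_folds(y, 5, 7)) == fold_hash(make_folds(y, 5, 7))
        assert fold_hash(make_folds(y, 5, 7)) != fold_hash(make_folds(y, 5, 8))


class TestRunGrid:
    def test_shape_and_sorting_contract(self, rng):
        from goslimpred.ontology_labels import LabelMatrix

        X1, y1 = planted_frame(rng, n=100, n_pos=25, n_feat=4)
        y2 = rng.permutation(y1)
        labels = LabelMatrix(df=pd.DataFrame(
            {"T1": y1, "T2": y2}, index=X1.index))
        clustering = FeatureClustering(
            k=2, assignment={"f0": 0, "f1": 0, "f2": 1, "f3": 1})
        grid = run_grid(X1, labels, clustering,
                        settings=PipelineSettings(tune=False, seed=0),
                        include_full=True)
        assert set(grid.cells) == {
            (t, g) for t in ("T1", "T2") for g in ("cluster_0", "cluster_1", "full")
        }
        assert all(len(ms) == 5 for ms in grid.cells.values())
        mat = grid.matrix()
        row_means = mat.mean(axis=1).to_numpy()
        col_means = mat.mean(axis=0).to_numpy()
        assert (np.diff(row_means) <= 1e-12).all()
        assert (np.diff(col_means) <= 1e-12).all()
        # signal lives in f0/f1 for T1
        assert mat.loc["T1", "cluster_0"] > mat.loc["T1", "cluster_1"] + 0.2
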