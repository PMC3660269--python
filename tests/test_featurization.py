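import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from goslimpred.io_formats import AA_CANONICAL, ProteinRecord, SequenceValidationError
from goslimpred.featurization import (
    DIMER_NAMES,
    FEATURE_BLOCKS,
    FEATURE_NAMES,
    MONOMER_NAMES,
    N_FEATURES,
    FeatureMatrix,
    apply_zscore,
    default_tables,
    dimer_frequencies,
    featurize,
    fit_zscore,
    isoelectric_point,
    monomer_frequencies,
    physchem,
    predict_ss_stub,
    ss_dimer_frequencies,
    ss_frequencies,
)

AA_IDX = {a: i for i, a in enumerate(AA_CANONICAL)}
seq_strategy = st.text(alphabet=AA_CANONICAL, min_size=2, max_size=60)


class TestMonomerFrequencies:
    def test_simple_counts(self):
        v = monomer_frequencies("AAC")
        assert v[AA_IDX["A"]] == pytest.approx(2 / 3)
        assert v[AA_IDX["C"]] == pytest.approx(1 / 3)
        assert v.sum() == pytest.approx(1.0)

    def test_b_code_closed_form(self):
        tables = default_tables()
        p = tables.abundance
        pd_, pn = p[AA_IDX["D"]], p[AA_IDX["N"]]
        v = monomer_frequencies("B")
        assert v[AA_IDX["D"]] == pytest.approx(pd_ / (pd_ + pn))
        assert v[AA_IDX["N"]] == pytest.approx(pn / (pd_ + pn))
        assert v.sum() == pytest.approx(1.0)

    def test_x_run_matches_monte_carlo_resolution(self, rng):
        # sampling oracle: resolve X by drawing residues from the priors
        tables = default_tables()
        n_draws = 100_000
        draws = rng.choice(20, size=n_draws, p=tables.abundance)
        empirical = np.bincount(draws, minlength=20) / n_draws
        expected = monomer_frequencies("X" * 10)
        sigma = np.sqrt(tables.abundance * (1 - tables.abundance) / n_draws)
        assert np.all(np.abs(empirical - expected) <= 3 * sigma + 1e-12)

    def test_illegal_character(self):
        with pytest.raises(SequenceValidationError, match="position 2"):
            monomer_frequencies("A1C")

    @given(seq=seq_strategy)
    def test_sums_to_one(self, seq):
        assert monomer_frequencies(seq).sum() == pytest.approx(1.0)

    @given(seq=seq_strategy)
    def test_permutation_invariant(self, seq):
        shuffled = "".join(sorted(seq))
        np.testing.assert_allclose(
            monomer_frequencies(seq), monomer_frequencies(shuffled), atol=1e-12
        )


def enumerate_ambiguity_resolutions(seq, tables):
    """Exhaustive oracle: expand every ambiguity code over its support and
    average dimer frequencies weighted by the product of priors."""
    options = []
    for ch in seq:
        v = tables.prob_vector(ch)
        options.append([(AA_CANONICAL[i], v[i]) for i in np.nonzero(v)[0]])
    total = np.zeros(400)
    for combo in itertools.product(*options):
        resolved = "".join(c for c, _ in combo)
        weight = np.prod([w for _, w in combo])
        total += weight * dimer_frequencies(resolved)
    return total


class TestDimerFrequencies:
    def test_simple_counts(self):
        v = dimer_frequencies("AAC")
        names = dict(zip(DIMER_NAMES, v))
        assert names["freq_AA"] == pytest.approx(0.5)
        assert names["freq_AC"] == pytest.approx(0.5)

    def test_ambiguous_closed_form(self):
        tables = default_tables()
        p = tables.ambiguity["B"]
        pd_, pn = p[AA_IDX["D"]], p[AA_IDX["N"]]
        v = dict(zip(DIMER_NAMES, dimer_frequencies("ABA")))
        assert v["freq_AD"] == pytest.approx(pd_ / 2)
        assert v["freq_AN"] == pytest.approx(pn / 2)
        assert v["freq_DA"] == pytest.approx(pd_ / 2)
        assert v["freq_NA"] == pytest.approx(pn / 2)

    def test_matches_exhaustive_enumeration_with_two_b(self):
        tables = default_tables()
        seq = "ABKBCE"
        np.testing.assert_allclose(
            dimer_frequencies(seq),
            enumerate_ambiguity_resolutions(seq, tables),
            atol=1e-12,
        )

    def test_length_one_is_zero_vector(self):
        assert dimer_frequencies("A").sum() == 0.0

    @given(seq=seq_strategy)
    def test_sums_to_one(self, seq):
        assert dimer_frequencies(seq).sum() == pytest.approx(1.0)


def oracle_net_charge(ph, seq):
    """Independent charge model for unambiguous sequences (test-local)."""
    t = default_tables()
    charge = 1 / (1 + 10 ** (ph - t.pka_nterm)) - 1 / (1 + 10 ** (t.pka_cterm - ph))
    for aa, pk in t.pka_positive.items():
        charge += seq.count(aa) / (1 + 10 ** (ph - pk))
    for aa, pk in t.pka_negative.items():
        charge -= seq.count(aa) / (1 + 10 ** (pk - ph))
    return charge


def oracle_pi(seq, tol=1e-6):
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if oracle_net_charge(mid, seq) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestPhyschem:
    def test_gravy_polyalanine_is_kd_value(self):
        assert physchem("AAAA")[5] == pytest.approx(1.8)

    def test_charge_percentages(self):
        v = physchem("ACDE")
        assert v[3] == pytest.approx(50.0)  # D+E negative
        assert v[2] == pytest.approx(0.0)

    def test_pi_ordering_acidic_vs_basic(self):
        assert physchem("DD")[4] < 7.0 < physchem("KK")[4]

    @pytest.mark.parametrize("seq", ["DDKK", "ACDEFGHIKL", "KKKRRR", "DDEECC"])
    def test_pi_matches_independent_bisection(self, seq):
        counts = np.zeros(20)
        for ch in seq:
            counts[AA_IDX[ch]] += 1
        assert isoelectric_point(counts) == pytest.approx(oracle_pi(seq), abs=2e-4)

    def test_mw_additivity(self):
        t = default_tables()
        s1, s2 = "ACDE", "KLMN"
        mw = lambda s: physchem(s)[1]
        assert mw(s1 + s2) == pytest.approx(mw(s1) + mw(s2) - t.water_mass)

    def test_mw_and_gravy_cross_check_biopython(self):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        seq = "ACDEFGHIKLMNPQRSTVWY"
        pa = ProteinAnalysis(seq)
        v = physchem(seq)
        assert v[1] == pytest.approx(pa.molecular_weight(), abs=0.5)
        assert v[5] == pytest.approx(pa.gravy(), abs=1e-6)

    def test_ambiguous_residue_contributes_expectation(self):
        # MW of B is between MW of D-protein and N-protein
        mw = lambda s: physchem(s)[1]
        assert min(mw("AD"), mw("AN")) < mw("AB") < max(mw("AD"), mw("AN"))


class TestSsFrequencies:
    def test_state_and_dimer_counts(self):
        v = ss_frequencies("HHCC")
        assert dict(zip("HEC", v)) == pytest.approx({"H": 0.5, "E": 0.0, "C": 0.5})
        d = ss_dimer_frequencies("HHCC")
        nonzero = {k: x for k, x in zip(
            [a + b for a in "HEC" for b in "HEC"], d) if x > 0}
        assert nonzero == pytest.approx({"HH": 1 / 3, "HC": 1 / 3, "CC": 1 / 3})

    def test_single_state_has_zero_dimers(self):
        assert ss_dimer_frequencies("H").sum() == 0.0

    def test_law_of_large_numbers_uniform(self, rng):
        s = "".join(rng.choice(list("HEC"), size=30_000))
        np.testing.assert_allclose(ss_frequencies(s), [1 / 3] * 3, atol=0.01)


class TestFeaturize:
    def test_dimensionality_partition(self):
        rec = ProteinRecord("P1", "ACDEFGHIKLMNPQRSTVWY" * 3, ss="HEC" * 20)
        fm = featurize([rec])
        assert fm.data.shape == (1, 438)
        assert sum(len(v) for v in FEATURE_BLOCKS.values()) == N_FEATURES
        assert tuple(len(FEATURE_BLOCKS[b]) for b in
                     ("physchem", "monomer", "dimer", "ss", "ss_dimer")) == (6, 20, 400, 3, 9)

    def test_column_names_stable_across_runs(self):
        rec = ProteinRecord("P1", "ACDE")
        a = featurize([rec]).data.columns
        b = featurize([rec]).data.columns
        assert list(a) == list(b) == list(FEATURE_NAMES)

    def test_monomer_block_sums_to_one(self):
        rec = ProteinRecord("P1", "MKKLLVV", ss="HHHHHHH")
        fm = featurize([rec])
        assert fm.block("monomer").iloc[0].sum() == pytest.approx(1.0)
        assert fm.block("ss").iloc[0].sum() == pytest.approx(1.0)

    def test_missing_ss_zeroed_and_flagged(self):
        fm = featurize([ProteinRecord("P1", "ACDE")])
        assert fm.missing_ss == {"P1"}
        assert fm.block("ss").iloc[0].sum() == 0.0

    def test_missing_ss_error_policy(self):
        with pytest.raises(ValueError):
            featurize([ProteinRecord("P1", "ACDE")], missing_ss_policy="error")

    def test_permuting_sequence_only_moves_dimer_block(self):
        a = featurize([ProteinRecord("P1", "ACDEKLMN")]).data.iloc[0]
        b = featurize([ProteinRecord("P1", "NMLKEDCA")]).data.iloc[0]
        mono = list(FEATURE_BLOCKS["monomer"])
        np.testing.assert_allclose(a[mono], b[mono], atol=1e-12)
        assert not np.allclose(
            a[list(FEATURE_BLOCKS["dimer"])], b[list(FEATURE_BLOCKS["dimer"])]
        )

    def test_ambiguity_monte_carlo_converges_to_closed_form(self, rng):
        # resolve each ambiguous position by sampling from its prior and
        # average the resulting feature vectors
        tables = default_tables()
        seq = "ACBZKXLM"
        n = 4000
        accum = np.zeros(426)  # monomer + dimer + physchem
        for _ in range(n):
            resolved = "".join(
                ch if ch in AA_IDX else
                AA_CANONICAL[rng.choice(20, p=tables.prob_vector(ch))]
                for ch in seq
            )
            accum += np.concatenate([
                physchem(resolved)[1:2],  # MW is linear in counts
                monomer_frequencies(resolved),
                dimer_frequencies(resolved),
                np.zeros(5),
            ])
        mc = accum / n
        exact = np.concatenate([
            physchem(seq)[1:2],
            monomer_frequencies(seq),
            dimer_frequencies(seq),
            np.zeros(5),
        ])
        # 3-sigma style tolerance on the sampler
        assert np.abs(mc[0] - exact[0]) < 3 * 60.0 / np.sqrt(n)
        np.testing.assert_allclose(mc[1:], exact[1:], atol=3 * 0.5 / np.sqrt(n))


class TestZscore:
    def _matrix(self, values, cols=None):
        import pandas as pd

        cols = cols or [f"f{i}" for i in range(np.shape(values)[1])]
        return FeatureMatrix(
            data=pd.DataFrame(values, index=[f"P{i}" for i in range(len(values))],
                              columns=cols)
        )

    def test_column_123_maps_to_unit_scale(self):
        fm = self._matrix([[1.0], [2.0], [3.0]])
        state = fit_zscore(fm)
        out = apply_zscore(fm, state)
        np.testing.assert_allclose(out.data["f0"], [-1.0, 0.0, 1.0])  # sample sd

    def test_fitted_subset_has_zero_mean_unit_sd(self, rng):
        fm = self._matrix(rng.normal(5, 3, size=(30, 4)))
        state = fit_zscore(fm)
        out = apply_zscore(fm, state).data
        np.testing.assert_allclose(out.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(ddof=1), 1.0, atol=1e-9)

    def test_constant_column_zeroed_and_flagged(self):
        fm = self._matrix([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]])
        state = fit_zscore(fm)
        assert state.zero_variance == ("f1",)
        out = apply_zscore(fm, state)
        assert (out.data["f1"] == 0.0).all()

    def test_heldout_rows_keep_their_shift(self, rng):
        fm = self._matrix(np.vstack([rng.normal(0, 1, (20, 2)),
                                     rng.normal(5, 1, (10, 2))]))
        train_rows = [f"P{i}" for i in range(20)]
        state = fit_zscore(fm, rows=train_rows)
        out = apply_zscore(fm, state).data
        held = out.loc[[f"P{i}" for i in range(20, 30)]]
        assert held.mean().abs().min() > 1.0  # no leakage of held-out rows


class TestSsStub:
    def test_polyalanine_is_mostly_helix(self):
        ss = predict_ss_stub("A" * 40)
        assert ss.count("H") / len(ss) > 0.9

    def test_length_preserved(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 400))
            seq = "".join(rng.choice(list(AA_CANONICAL), size=n))
            assert len(predict_ss_stub(seq)) == n

    def test_deterministic(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 4
        assert predict_ss_stub(seq) == predict_ss_stub(seq)
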