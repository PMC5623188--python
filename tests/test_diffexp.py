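"""Size factors, dispersion estimation, the NB Wald test and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ganglioseq import (
    NegativeBinomialDE,
    adjust_bh,
    estimate_dispersion,
    estimate_size_factors,
    generate_counts,
    wald_test,
)
from ganglioseq.errors import EstimationError, ValidationError

from conftest import brute_force_bh, null_config


class TestSizeFactors:
    def test_identical_samples_get_equal_factors(self):
        counts = pd.DataFrame({"s1": [5, 9, 20], "s2": [5, 9, 20], "s3": [5, 9, 20]})
        sf = estimate_size_factors(counts)
        assert np.allclose(sf, sf.iloc[0])

    def test_doubled_sample_gets_double_factor(self, toy_counts):
        """Hand evaluation on the 3-gene toy: S2 = 2 x S1 entrywise."""
        sf = estimate_size_factors(toy_counts)
        assert sf["S2"] / sf["S1"] == pytest.approx(2.0)

    def test_permutation_equivariance(self, toy_counts):
        sf = estimate_size_factors(toy_counts)
        permuted = toy_counts[["S3", "S1", "S4", "S2"]]
        sf_p = estimate_size_factors(permuted)
        for s in toy_counts.columns:
            assert sf_p[s] == pytest.approx(sf[s])

    def test_invariant_to_all_zero_gene(self, toy_counts):
        sf = estimate_size_factors(toy_counts)
        with_zero = pd.concat(
            [toy_counts, pd.DataFrame([[0, 0, 0, 0]], index=["gz"],
                                      columns=toy_counts.columns)]
        )
        pd.testing.assert_series_equal(sf, estimate_size_factors(with_zero))

    def test_error_when_no_gene_covers_all_samples(self):
        counts = pd.DataFrame({"s1": [3, 0], "s2": [0, 4]})
        with pytest.raises(EstimationError):
            estimate_size_factors(counts)


class TestDispersion:
    def _fit(self, exp):
        sf = estimate_size_factors(exp.counts)
        return estimate_dispersion(exp.counts, exp.conditions, sf)

    def test_poisson_counts_give_near_zero_dispersion(self):
        exp = generate_counts(null_config(n_genes=2000, dispersion=0.0, seed=7))
        disp = self._fit(exp)
        assert disp["final"].median() <= 0.01

    def test_nb_dispersion_recovered(self):
        exp = generate_counts(null_config(n_genes=2000, dispersion=0.2, seed=7))
        disp = self._fit(exp)
        assert 0.1 <= disp["final"].median() <= 0.3

    def test_constant_counts_within_condition_give_zero_genewise(self):
        counts = pd.DataFrame(
            {"a1": [7, 30], "a2": [7, 30], "b1": [9, 12], "b2": [9, 12]},
            index=["g1", "g2"],
        )
        conditions = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(counts, conditions, sf)
        assert (disp["genewise"] == 0).all()

    def test_final_between_genewise_and_trend_or_at_floor(self, small_experiment):
        disp = self._fit(small_experiment)
        lo = np.minimum(disp["genewise"], disp["trend"])
        hi = np.maximum(disp["genewise"], disp["trend"])
        ok = (disp["final"] >= np.maximum(lo, 1e-8) - 1e-12) & (
            disp["final"] <= hi + 1e-12
        )
        assert ok.all()

    def test_all_zero_matrix_is_an_error(self):
        counts = pd.DataFrame(np.zeros((5, 4), dtype=int))
        conditions = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        with pytest.raises(EstimationError):
            estimate_dispersion(counts, conditions, pd.Series(1.0, index=counts.columns))


class TestWaldTest:
    def test_null_simulation_is_calibrated(self):
        """Raw p < 0.05 on identical NB conditions (6 vs 4) within 0.05 +/- 0.01."""
        exp = generate_counts(null_config(n_genes=5000, dispersion=0.2, seed=11))
        res = NegativeBinomialDE(exp.counts, exp.conditions).fit()
        rate = (res.table["p_value"] < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_null_p_values_near_uniform(self):
        """Median KS distance to uniform over 5 seeds below 0.02 (a single KS
        draw at n=5000 has a 5% critical value of 0.019 even under exact
        uniformity, so the check aggregates seeds)."""
        ks = []
        for seed in range(5):
            exp = generate_counts(null_config(n_genes=5000, dispersion=0.2, seed=seed))
            res = NegativeBinomialDE(exp.counts, exp.conditions).fit()
            ks.append(stats.kstest(res.table["p_value"], "uniform").statistic)
        assert np.median(ks) < 0.02

    def test_twofold_effect_recovered(self):
        """Genes at true fold 2, mu = 100, alpha = 0.05: mean log2fc within 1 +/- 0.1."""
        props = {
            "common": 0.8, "de_up_a": 0.1, "de_up_b": 0.1, "exclusive_a": 0.0,
            "exclusive_b": 0.0, "glial_contaminant": 0.0, "silent": 0.0,
        }
        cfg = null_config(n_genes=2000, dispersion=0.05, seed=5)
        cfg = type(cfg)(**{
            **cfg.__dict__,
            "class_proportions": props,
            "baseline_mean_log_range": (np.log(100.0), np.log(100.0)),
        })
        exp = generate_counts(cfg)
        res = NegativeBinomialDE(exp.counts, exp.conditions).fit()
        up_a = (exp.truth["true_class"] == "de_up_a").to_numpy()
        up_b = (exp.truth["true_class"] == "de_up_b").to_numpy()
        oriented = np.concatenate(
            [-res.table["log2fc"].to_numpy()[up_a], res.table["log2fc"].to_numpy()[up_b]]
        )
        assert oriented.mean() == pytest.approx(1.0, abs=0.1)

    def test_all_zero_gene_flagged_not_failed(self, toy_counts, toy_conditions):
        counts = pd.concat(
            [toy_counts, pd.DataFrame([[0] * 4], index=["gz"], columns=toy_counts.columns)]
        )
        res = NegativeBinomialDE(counts, toy_conditions).fit()
        row = res.table.loc["gz"]
        assert row["log2fc"] == 0.0 and row["p_value"] == 1.0 and row["all_zero"]

    def test_log2fc_antisymmetric_under_label_swap(self, small_experiment):
        exp = small_experiment
        res = NegativeBinomialDE(exp.counts, exp.conditions).fit()
        swapped = exp.conditions.map({"A": "B", "B": "A"})
        res_swapped = NegativeBinomialDE(exp.counts, swapped).fit()
        np.testing.assert_allclose(
            res.table["log2fc"], -res_swapped.table["log2fc"], atol=1e-10
        )

    def test_exclusive_genes_get_large_finite_log2fc(self):
        props = {
            "common": 0.9, "de_up_a": 0.0, "de_up_b": 0.0, "exclusive_a": 0.0,
            "exclusive_b": 0.1, "glial_contaminant": 0.0, "silent": 0.0,
        }
        cfg = null_config(n_genes=500, seed=19)
        cfg = type(cfg)(**{**cfg.__dict__, "class_proportions": props})
        exp = generate_counts(cfg)
        res = NegativeBinomialDE(exp.counts, exp.conditions).fit()
        excl = (exp.truth["true_class"] == "exclusive_b").to_numpy()
        lfc = res.table["log2fc"].to_numpy()[excl]
        assert np.isfinite(lfc).all() and (lfc > 2).all()

    def test_rejects_bad_alpha_and_missing_condition(self, toy_counts, toy_conditions):
        sf = estimate_size_factors(toy_counts)
        disp = estimate_dispersion(toy_counts, toy_conditions, sf)
        with pytest.raises(ValidationError):
            wald_test(toy_counts, toy_conditions, sf, disp, alpha=1.5)
        only_a = pd.Series(["A"] * 4, index=toy_counts.columns)
        with pytest.raises(ValidationError):
            wald_test(toy_counts, only_a, sf, disp)


class TestAdjustBH:
    def test_single_p_is_identity(self):
        assert adjust_bh([0.03]) == pytest.approx([0.03])

    def test_hand_worked_four_values(self):
        """Step-up by hand at m=4, order-preserving against input order."""
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.04, 0.03, 0.05]), [0.04, 0.05, 0.05, 0.05]
        )

    def test_output_at_least_input_and_capped(self):
        p = np.array([0.2, 0.9, 1.0, 0.001])
        q = adjust_bh(p)
        assert (q >= p).all() and (q <= 1).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 1.2])
        with pytest.raises(ValidationError):
            adjust_bh([-0.1])

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=50)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(adjust_bh(p), brute_force_bh(p), rtol=1e-12)


class TestModelResultsApi:
    def test_fit_returns_results_with_summary(self, small_experiment):
        res = NegativeBinomialDE(
            small_experiment.counts, small_experiment.conditions
        ).fit()
        text = res.summary(top=3)
        assert "significant at FDR" in text
        assert res.n_significant == int(res.table["significant"].sum())
        assert set(res.significant_genes) == set(
            res.table.index[res.table["significant"]]
        )

    def test_adj_p_dominates_p(self, small_experiment):
        res = NegativeBinomialDE(
            small_experiment.counts, small_experiment.conditions
        ).fit()
        t = res.table
        assert (t["adj_p"] >= t["p_value"] - 1e-12).all()
        assert (t["adj_p"] <= 1).all()
        assert ((t["adj_p"] < 0.05) == t["significant"]).all()

    def test_rejects_negative_counts_and_bad_labels(self, toy_counts):
        with pytest.raises(ValidationError):
            NegativeBinomialDE(-toy_counts, ["A", "A", "B", "B"])
        with pytest.raises(ValidationError):
            NegativeBinomialDE(toy_counts, ["A", "A", "B", "C"])
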