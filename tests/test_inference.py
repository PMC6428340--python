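"""Growth-rate fits, hypothesis tests, size factors and the yield model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import spikecal as sc

GAMMAS = np.repeat([0.12, 0.20, 0.30], 3)


def _nb_draw(rng, mean, a, shape=None):
    mean = np.broadcast_to(mean, shape) if shape is not None else np.asarray(mean)
    return rng.poisson(rng.gamma(a, mean / a))


class TestGrowthModel:
    def test_noiseless_flat_data_gives_zero_phi1(self):
        scales = np.full(9, 20.0)
        y = np.round(scales * 7.0)[None, :]
        fit = sc.fit_growth_model(y, GAMMAS, scales, a=25.0)
        assert abs(fit.phi1[0]) < 1e-6
        assert fit.lrt[0] < 1e-8

    def test_noiseless_exponential_data_reproduces_generating_fold(self):
        phi1 = 8.0
        scales = np.full(9, 50.0)
        mean = scales * np.exp(3.0 + phi1 * (GAMMAS - GAMMAS.mean()))
        fit = sc.fit_growth_model(mean[None, :], GAMMAS, scales, a=500.0)
        fold = sc.fold_change_from_phi(fit.phi1[0], 0.12, 0.30)
        assert fold == pytest.approx(np.exp(phi1 * 0.18), rel=1e-4)

    def test_phi1_recovery_bias_under_five_percent(self, rng):
        """500 NB simulations at phi1 = 5.6, a = 25, 3 replicates per
        growth rate recover phi1 with < 5% bias."""
        phi1, a = 5.6, 25.0
        scales = np.full(9, 20.0)
        mean = scales * np.exp(np.log(5.0) + phi1 * (GAMMAS - GAMMAS.mean()))
        y = _nb_draw(rng, mean, a, shape=(500, 9))
        fit = sc.fit_growth_model(y, GAMMAS, scales, a)
        assert abs(fit.phi1.mean() / phi1 - 1.0) < 0.05

    def test_lrt_nonnegative_and_chi2_pvalues_valid(self, rng):
        scales = np.full(9, 10.0)
        y = _nb_draw(rng, 40.0 * scales, 25.0, shape=(50, 9))
        fit = sc.fit_growth_model(y, GAMMAS, scales, 25.0)
        assert np.all(fit.lrt >= 0)
        assert np.all((fit.p_chi2 >= 0) & (fit.p_chi2 <= 1))


class TestFoldChangeFromPhi:
    def test_upregulation_constant(self):
        assert round(sc.fold_change_from_phi(5.6, 0.12, 0.30), 1) == 2.7

    def test_downregulation_constant(self):
        assert round(sc.fold_change_from_phi(12.0, 0.12, 0.30), 1) == 8.7

    def test_zero_rate_constant_is_no_change(self):
        assert sc.fold_change_from_phi(0.0, 0.12, 0.30) == 1.0

    def test_rejects_reversed_rates(self):
        with pytest.raises(sc.ValidationError):
            sc.fold_change_from_phi(1.0, 0.30, 0.12)


class TestEmpiricalPvalues:
    def test_uniform_under_the_null(self, rng):
        """Parametric-bootstrap p-values on null (flat) transcripts are
        uniform (KS p > 0.01 over 200 transcripts)."""
        scales = np.full(9, 20.0)
        mu = rng.lognormal(np.log(5), 1.0, 200)
        y = _nb_draw(rng, mu[:, None] * scales, 25.0)
        fit = sc.empirical_pvalues(y, GAMMAS, scales, 25.0, null_sims=199, seed=11)
        assert stats.kstest(fit.p_empirical, "uniform").pvalue > 0.01

    def test_zero_lrt_gives_p_one(self):
        scales = np.full(9, 20.0)
        y = np.round(7.0 * scales)[None, :]
        fit = sc.empirical_pvalues(y, GAMMAS, scales, 25.0, null_sims=99, seed=0)
        assert fit.p_empirical[0] == 1.0

    def test_strong_signal_saturates_at_resolution_limit(self, rng):
        phi1, a = 10.0, 100.0
        scales = np.full(9, 20.0)
        mean = scales * np.exp(np.log(20.0) + phi1 * (GAMMAS - GAMMAS.mean()))
        y = _nb_draw(rng, mean, a)[None, :]
        B = 99
        fit = sc.empirical_pvalues(y, GAMMAS, scales, a, null_sims=B, seed=1)
        assert fit.p_empirical[0] == 1.0 / (B + 1)

    def test_agrees_with_chi2_for_well_behaved_data(self, rng):
        scales = np.full(9, 30.0)
        mu = rng.lognormal(np.log(30), 0.5, 60)
        y = _nb_draw(rng, mu[:, None] * scales, 200.0)
        fit = sc.empirical_pvalues(y, GAMMAS, scales, 200.0, null_sims=399, seed=3)
        # rank correlation between asymptotic and bootstrap p-values
        r = stats.spearmanr(fit.p_chi2, fit.p_empirical).statistic
        assert r > 0.95


class TestBhFdr:
    def test_all_ones_make_no_calls(self):
        q, calls = sc.bh_fdr(np.ones(10), q=0.05)
        assert not calls.any()

    def test_hand_example_at_strict_level(self):
        q, calls = sc.bh_fdr(np.array([0.001, 0.5, 0.9]), q=0.01)
        np.testing.assert_array_equal(calls, [True, False, False])

    @given(
        pvals=st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=50
        )
    )
    def test_qvalues_monotone_in_sorted_pvalues(self, pvals):
        p = np.array(pvals)
        q, _ = sc.bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestNbPairwiseTest:
    def test_type_one_error_calibrated(self, rng):
        """Identically simulated groups give a type-I error at p < 0.05
        within [0.03, 0.07] over 5000 transcripts."""
        groups = np.array(["A"] * 3 + ["B"] * 3)
        scales = np.full(6, 15.0)
        mu = rng.lognormal(np.log(8), 1.2, 5000)
        y = _nb_draw(rng, mu[:, None] * scales, 25.0)
        res = sc.nb_pairwise_test(y, scales, groups, 25.0)
        rate = np.mean(res.p_values[~res.excluded] < 0.05)
        assert 0.03 <= rate <= 0.07

    def test_fold_one_when_scaled_means_equal(self):
        groups = np.array(["A", "A", "B", "B"])
        scales = np.array([1.0, 2.0, 4.0, 0.5])
        y = np.round(10.0 * scales)[None, :]
        res = sc.nb_pairwise_test(y, scales, groups, 50.0)
        assert res.fold_change[0] == pytest.approx(1.0, rel=1e-6)
        assert res.lrt[0] < 1e-6

    def test_invariant_to_common_scale_factor(self, rng):
        groups = np.array(["A"] * 3 + ["B"] * 3)
        scales = rng.lognormal(0, 0.2, 6)
        y = _nb_draw(rng, 30.0 * scales, 25.0, shape=(100, 6))
        r1 = sc.nb_pairwise_test(y, scales, groups, 25.0)
        r2 = sc.nb_pairwise_test(y, 7.3 * scales, groups, 25.0)
        np.testing.assert_allclose(r1.lrt, r2.lrt, atol=1e-6)
        np.testing.assert_allclose(r1.fold_change, 7.3 * 0 + r1.fold_change)
        np.testing.assert_allclose(r2.mean1 * 7.3, r1.mean1, rtol=1e-6)

    def test_all_zero_transcripts_excluded(self, rng):
        groups = np.array(["A", "A", "B", "B"])
        y = np.vstack([np.zeros(4), [5, 6, 7, 8]]).astype(int)
        res = sc.nb_pairwise_test(y, np.ones(4), groups, 25.0)
        assert res.excluded[0] and not res.excluded[1]
        assert np.isnan(res.p_values[0])

    def test_per_condition_shapes_accepted(self, rng):
        groups = np.array(["A"] * 3 + ["B"] * 3)
        y = _nb_draw(rng, 50.0, 25.0, shape=(20, 6))
        res = sc.nb_pairwise_test(y, np.ones(6), groups, {"A": 23.0, "B": 34.0})
        assert np.all(np.isfinite(res.p_values))


class TestGlobalAmplificationDemonstration:
    def test_spikein_sizing_sees_global_shift_median_sizing_hides_it(self):
        """A global 2x down-regulation is reported as predominantly
        negative fold changes under spike-in (nu*delta) sizing but appears
        spuriously null/symmetric under median-of-ratios sizing."""
        cfg = sc.SimulationConfig(
            conditions=("ctrl", "pert"),
            n_transcripts=2000,
            condition_fold={"pert": 0.5},
            shape=50.0,
        )
        ds = sc.simulate_dataset(cfg, seed=6)
        calib = sc.calibrate(ds.spikein_counts, ds.annotation)
        conds = np.array(
            [ds.library_meta[l].condition for l in ds.native_counts.library_ids]
        )
        keep = sc.detection_filter(ds.native_counts)
        y = ds.native_counts.counts[keep]
        z_tilde = sc.counts_to_abundance(y, calib.nu, pseudocount=1.0)
        d = sc.compute_delta(z_tilde, conds)

        spike = sc.nb_pairwise_test(
            y, calib.nu * d, conds, 50.0, group_order=("ctrl", "pert")
        )
        med = sc.nb_pairwise_test(
            y,
            sc.median_size_factors(y),
            conds,
            50.0,
            group_order=("ctrl", "pert"),
        )
        assert np.nanmean(spike.log2_fold_change) < -0.5
        assert (spike.direction[spike.significant] < 0).mean() > 0.9
        assert abs(np.nanmean(med.log2_fold_change)) < 0.15
        assert med.significant.sum() < 0.05 * len(y)


class TestMedianSizeFactors:
    def test_identical_libraries_give_unit_factors(self):
        y = np.tile(np.array([[4], [9], [25]]), (1, 3))
        np.testing.assert_allclose(sc.median_size_factors(y), 1.0)

    def test_brute_force_oracle_on_small_matrix(self, rng):
        y = rng.integers(1, 100, size=(5, 3)).astype(float)
        s = sc.median_size_factors(y)
        gm = np.prod(y, axis=1) ** (1.0 / 3.0)
        expected = np.median(y / gm[:, None], axis=0)
        np.testing.assert_allclose(s, expected, rtol=1e-12)

    def test_doubled_library(self):
        y = np.tile(np.array([[4.0], [9.0], [25.0]]), (1, 3))
        y[:, 1] *= 2.0
        s = sc.median_size_factors(y)
        # geometric means absorb 2^(1/3); medians of order ~1
        assert s[1] / s[0] == pytest.approx(2.0, rel=1e-12)
        assert np.median(s) == pytest.approx(1.0, rel=0.3)

    def test_requires_all_positive_row(self):
        y = np.array([[0, 5], [3, 0]])
        with pytest.raises(sc.SpikecalError):
            sc.median_size_factors(y)


class TestYieldModel:
    def test_constant_alpha_gives_zero_covariate_effects(self, rng):
        n = 40
        fit = sc.fit_yield_model(
            np.ones(n),
            rng.uniform(250, 2000, n),
            rng.uniform(0.3, 0.7, n),
            -rng.uniform(50, 500, n),
        )
        np.testing.assert_allclose(fit.beta[1:], 0.0, atol=1e-10)
        assert fit.nrmse_range == 0.0

    def test_recovers_known_log_linear_model(self, rng):
        n = 92
        length = rng.uniform(250, 2000, n)
        gc = rng.uniform(0.3, 0.7, n)
        energy = -rng.uniform(50, 500, n)
        beta_true = np.array([0.4, 0.0008, 0.9, -0.001])
        alpha = np.exp(
            beta_true[0]
            + beta_true[1] * length
            + beta_true[2] * gc
            + beta_true[3] * energy
            + rng.normal(0, 0.02, n)
        )
        fit = sc.fit_yield_model(alpha, length, gc, energy)
        np.testing.assert_allclose(fit.beta, beta_true, rtol=0.1)
        assert fit.nrmse_sd < 0.3

    def test_reports_both_rmse_normalisations(self, rng):
        n = 30
        alpha = rng.lognormal(0, 0.5, n)
        fit = sc.fit_yield_model(
            alpha,
            rng.uniform(250, 2000, n),
            rng.uniform(0.3, 0.7, n),
            -rng.uniform(50, 500, n),
        )
        assert fit.nrmse_range > 0
        assert fit.nrmse_sd > fit.nrmse_range  # range >= sd always

    def test_too_few_spikeins_rejected(self):
        with pytest.raises(sc.ValidationError):
            sc.fit_yield_model(
                np.ones(5), np.ones(5), np.full(5, 0.5), -np.ones(5)
            )
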