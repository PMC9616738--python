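"""Spike binning, cross-correlograms, coherence, MI and prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pose2thal as p2t
from pose2thal.errors import InvalidArgumentError
from pose2thal.neural_coupling import (
    _plugin_mi_bits,
    cross_correlation,
    fit_predictive_model,
    pairwise_mi,
    quantile_discretize,
    shift_control,
    top_code_counts,
)


class TestBinSpikes:
    def test_even_spikes_one_per_bin(self):
        times = 0.335 + 0.67 * np.arange(10)
        bc = p2t.bin_spikes(times, [(0.0, 6.7)], 0.67)
        assert len(bc.counts) == 1
        assert np.array_equal(bc.counts[0], np.ones(10, int))

    def test_empty_train_all_zero(self):
        bc = p2t.bin_spikes(np.array([]), [(0.0, 10.0)], 0.67)
        assert bc.concatenated().sum() == 0

    def test_count_conservation_and_outside_logging(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 30, 200))
        epochs = [(2.0, 12.0), (15.0, 25.0)]
        bc = p2t.bin_spikes(times, epochs, 0.5)
        inside = sum(((times >= s) & (times < e)).sum() for s, e in epochs)
        assert bc.concatenated().sum() == inside  # 0.5 divides both epochs
        assert bc.n_spikes_outside == len(times) - inside

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            p2t.bin_spikes(np.array([1.0]), [(0.0, 5.0), (4.0, 8.0)], 0.5)


class TestCrossCorrelation:
    def test_self_correlation_is_one_at_zero_lag(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(1.0, 400).astype(float)
        lags, curve = cross_correlation([x], [x], bin_s=1 / 15)
        mid = len(lags) // 2
        assert lags[mid] == 0.0
        assert curve[mid] == pytest.approx(1.0, abs=1e-9)
        assert np.abs(curve).max() <= 1.0 + 1e-12

    def test_rate_coupled_peak_at_zero_positive(self):
        rng = np.random.default_rng(2)
        y = np.convolve(rng.normal(size=600), np.ones(8) / 8, mode="same")
        x = rng.poisson(np.exp(0.5 + 1.5 * y)).astype(float)
        lags, curve = cross_correlation([x], [y], bin_s=1 / 15)
        assert lags[np.argmax(curve)] == pytest.approx(0.0, abs=1e-9)
        assert curve.max() > 0.2

    def test_time_reversal_mirrors_curve(self):
        rng = np.random.default_rng(3)
        x = rng.poisson(1.0, 300).astype(float)
        y = rng.normal(size=300)
        _, c = cross_correlation([x], [y], bin_s=1 / 15)
        _, c_rev = cross_correlation([x[::-1]], [y[::-1]], bin_s=1 / 15)
        assert np.allclose(c_rev, c[::-1], atol=1e-12)

    def test_short_epochs_excluded(self):
        with pytest.raises(InvalidArgumentError):
            cross_correlation([np.ones(10)], [np.ones(10)], bin_s=1 / 15)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.poisson(1.0, 300).astype(float)
        y = rng.normal(size=300)
        _, c1 = cross_correlation([x], [y], bin_s=1 / 15)
        _, c2 = cross_correlation([x], [3.0 * y + 7.0], bin_s=1 / 15)
        assert np.allclose(c1, c2, atol=1e-12)


class TestCrossCorrSignificance:
    def test_coupled_unit_detected_near_planted_lag(self, kinematics, behavior,
                                                    om_covariate):
        var = om_covariate.covariates["OM"]
        tun = p2t.TuningSpec(unit="x", lag_s=0.2)
        _, counts = p2t.generate_spikes(behavior, tun, kinematics.epochs,
                                        bin_s=1 / 15, seed=7)
        res = p2t.crosscorr_significance(counts, var, n_perm=400, seed=0)
        assert res.significant
        assert abs(res.peak_lag_s - 0.2) <= 1 / 15 + 1e-9
        assert res.peak_value > 0

    def test_independent_unit_rarely_significant(self, om_covariate):
        rng = np.random.default_rng(5)
        var = om_covariate.covariates["OM"]
        lens = [len(v) for v in var]
        n_sig = 0
        for u in range(40):
            counts = [rng.poisson(0.33, size=n) for n in lens]
            res = p2t.crosscorr_significance(counts, var, n_perm=400, seed=u)
            n_sig += res.significant
        assert n_sig <= 6  # nominal familywise level is ~5-6%

    def test_few_epochs_warns(self):
        rng = np.random.default_rng(6)
        counts = [rng.poisson(1.0, 200).astype(float) for _ in range(3)]
        var = [rng.normal(size=200) for _ in range(3)]
        with pytest.warns(UserWarning, match="fewer than 10"):
            p2t.crosscorr_significance(counts, var, n_perm=50, seed=0)


class TestCoherence:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(7)
        x = rng.poisson(1.0, 512).astype(float)
        res = p2t.magnitude_squared_coherence([x], [x], n_shifts=10, seed=0)
        assert np.allclose(res["msc"], 1.0, atol=1e-9)

    def test_coupled_excess_concentrated_below_2hz(self, kinematics, behavior,
                                                   om_covariate):
        var = om_covariate.covariates["OM"]
        tun = p2t.TuningSpec(unit="m")
        _, counts = p2t.generate_spikes(behavior, tun, kinematics.epochs,
                                        bin_s=1 / 15, seed=8)
        res = p2t.magnitude_squared_coherence(counts, var, n_shifts=40, seed=1)
        low = res["freqs"] <= 2.0
        excess = res["msc"] - res["null_mean"]
        assert np.all(res["above_null"][low & (res["freqs"] > 0)])
        assert excess[low].mean() > excess[~low].mean()

    def test_independent_within_null_band(self, om_covariate):
        # the mean + 2 SD band leaves a few percent single-tail exceedance
        # for the skewed MSC null; average over units to beat granularity
        rng = np.random.default_rng(9)
        var = om_covariate.covariates["OM"]
        fracs = []
        for u in range(8):
            counts = [rng.poisson(0.33, size=len(v)) for v in var]
            res = p2t.magnitude_squared_coherence(counts, var, n_shifts=60,
                                                  seed=u)
            fracs.append(res["above_null"].mean())
        assert np.mean(fracs) <= 0.10


class TestQuantileDiscretize:
    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 8))
    def test_equal_occupancy(self, seed, n_bins):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=500)
        lab = quantile_discretize(x, n_bins)
        occ = np.bincount(lab, minlength=n_bins)
        assert occ.max() - occ.min() <= 1

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=400)
        assert np.array_equal(quantile_discretize(x, 5),
                              quantile_discretize(np.exp(x), 5))

    def test_constant_series_single_bin(self):
        with pytest.warns(UserWarning, match="distinct"):
            lab = quantile_discretize(np.ones(100), 5)
        assert set(lab) == {0}

    def test_top_coding_caps_counts(self):
        counts = np.concatenate([np.zeros(990, int), np.full(10, 50, int)])
        capped = top_code_counts(counts)
        assert capped.max() <= 50
        assert capped.max() < counts.max() or np.quantile(counts, 0.99) >= 50


class TestMutualInformation:
    def test_identity_eight_states(self):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 8, 10_000)
        est = p2t.mutual_information(x, x, seed=0)
        assert est.plugin == pytest.approx(3.0, abs=2e-3)
        assert est.corrected == pytest.approx(3.0, abs=1e-3)

    def test_binary_symmetric_channel_closed_form(self):
        rng = np.random.default_rng(12)
        n = 10_000
        s = rng.integers(0, 2, n)
        r = np.where(rng.random(n) < 0.11, 1 - s, s)
        est = p2t.mutual_information(r, s, seed=0)
        h2 = -(0.11 * np.log2(0.11) + 0.89 * np.log2(0.89))
        assert est.corrected == pytest.approx(1 - h2, abs=0.02)

    def test_plugin_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(13)
        r = rng.integers(0, 4, 2000)
        s = rng.integers(0, 6, 2000)
        assert _plugin_mi_bits(r, s) == pytest.approx(_plugin_mi_bits(s, r))
        assert _plugin_mi_bits(r, s) >= 0

    def test_bias_correction_improves_mae(self):
        rng = np.random.default_rng(14)
        for n in (250, 1000, 4000):
            plug, corr = [], []
            for rep in range(30):
                a = rng.integers(0, 5, n)
                b = rng.integers(0, 5, n)
                est = p2t.mutual_information(a, b, seed=rep)
                plug.append(abs(est.plugin))
                corr.append(abs(est.corrected))
            assert np.mean(corr) < np.mean(plug)

    def test_low_sample_flag(self):
        est = p2t.mutual_information(np.arange(50) % 3, np.arange(50) % 2, seed=0)
        assert est.low_sample


@pytest.fixture(scope="module")
def labelled():
    rng = np.random.default_rng(15)
    n = 10_000
    a = rng.integers(0, 5, n)
    b = rng.integers(0, 5, n)
    return rng, n, a, b


class TestPairwiseMI:
    def test_counts_driven_by_one_variable(self, labelled):
        rng, n, a, b = labelled
        counts = rng.poisson(np.exp(0.3 * a))
        mi2, mi1 = pairwise_mi(top_code_counts(counts), a, b, seed=0)
        assert abs(mi2.corrected - mi1.corrected) < 0.03

    def test_additive_drivers_exceed_single_control(self, labelled):
        rng, n, a, b = labelled
        counts = rng.poisson(np.exp(0.25 * a + 0.25 * b))
        mi2, mi1 = pairwise_mi(top_code_counts(counts), a, b, seed=1)
        assert mi2.corrected > mi1.corrected + 0.05

    def test_shuffling_both_kills_information(self, labelled):
        rng, n, a, b = labelled
        counts = rng.poisson(np.exp(0.3 * a + 0.3 * b))
        perm = rng.permutation(n)
        mi2, _ = pairwise_mi(top_code_counts(counts), a[perm],
                             b[rng.permutation(n)], seed=2)
        assert abs(mi2.corrected) < 0.02


class TestPrediction:
    def test_step_function_learnable(self):
        rng = np.random.default_rng(16)
        x = rng.uniform(-1, 1, 1200)
        y = np.where(x > 0.2, 8.0, 1.0)
        res = fit_predictive_model(x, y, kind="continuous", seed=0)
        assert res.accuracy > 0.95

    def test_independent_target_near_zero(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=1000)
        y = rng.poisson(2.0, 1000).astype(float)
        res = fit_predictive_model(x, y, kind="counts", seed=0)
        assert abs(res.accuracy) < 0.1

    def test_shift_control_involution_and_autocorr(self):
        rng = np.random.default_rng(18)
        x = np.cumsum(rng.normal(size=(400, 2)), axis=0)
        shifted = shift_control(x)
        assert np.array_equal(shift_control(shifted), x)

        def ac1(v):
            return np.corrcoef(v[:-1], v[1:])[0, 1]

        half = len(x) // 2
        assert ac1(shifted[:half, 0]) == pytest.approx(ac1(x[half:, 0]))


class TestCompareTuning:
    def _curves(self, rng, n_units=12, noise=0.3):
        c1, c2 = {}, {}
        for i in range(n_units):
            base = np.convolve(rng.normal(size=122), np.ones(5) / 5, "same")
            c1[f"u{i}"] = base + noise * rng.normal(size=122)
            c2[f"u{i}"] = base + noise * rng.normal(size=122)
        return c1, c2

    def test_identical_conditions_all_one(self):
        rng = np.random.default_rng(19)
        c1, _ = self._curves(rng)
        res = p2t.compare_tuning(c1, {k: v.copy() for k, v in c1.items()},
                                 n_shuffles=500, seed=0)
        assert np.allclose(res["rho_cc"].to_numpy(), 1.0, atol=1e-9)

    def test_stable_tuning_beats_null(self):
        rng = np.random.default_rng(20)
        c1, c2 = self._curves(rng, n_units=20)
        res = p2t.compare_tuning(c1, c2, n_shuffles=2000, seed=1)
        assert res["observed_mean"] > np.quantile(res["null_means"], 0.99)

    def test_unit_permuted_copy_matches_null(self):
        rng = np.random.default_rng(21)
        c1, _ = self._curves(rng, n_units=16)
        units = list(c1)
        perm = rng.permutation(len(units))
        c2 = {units[i]: c1[units[perm[i]]] for i in range(len(units))}
        res = p2t.compare_tuning(c1, c2, n_shuffles=2000, seed=2)
        lo, hi = np.quantile(res["null_means"], [0.025, 0.975])
        assert lo <= res["observed_mean"] <= hi

    def test_too_few_shared_units_rejected(self):
        with pytest.raises(InvalidArgumentError):
            p2t.compare_tuning({"a": np.ones(10)}, {"a": np.ones(10)})
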