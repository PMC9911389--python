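import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import erpsig as es
from erpsig.quality import cohort_median_mad, moving_average, window_means

from conftest import make_epochs

WINDOW = (0.0, 0.3)  # covers all 30 samples of the toy epochs


def scipy_pct_significant(a, b, window, alpha=0.05):
    """Independent oracle: per-channel pooled two-sample t-test via scipy,
    with the zero-variance convention applied explicitly."""
    wa, wb = window_means(a, window), window_means(b, window)
    n_sig = 0
    for c in range(wa.shape[1]):
        x, y = wa[:, c], wb[:, c]
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            n_sig += x.mean() != y.mean()
            continue
        p = stats.ttest_ind(x, y, equal_var=True).pvalue
        n_sig += p < alpha
    return 100.0 * n_sig / wa.shape[1]


class TestChannelSignificance:
    def test_identical_conditions_give_zero(self, rng):
        d = rng.normal(size=(4, 30, 20))
        a, b = make_epochs(d, condition="A"), make_epochs(d.copy(), condition="B")
        assert es.channel_significance(a, b, WINDOW) == 0.0

    def test_half_of_channels_shifted_matches_scipy_oracle(self, rng):
        d_a = rng.normal(size=(4, 30, 50))
        d_b = rng.normal(size=(4, 30, 50))
        d_b[:2] += 5.0  # unmissable shift on channels 0-1 ...
        d_b[2:] = d_a[2:]  # ... and exactly equal trials (t = 0) on channels 2-3
        a, b = make_epochs(d_a), make_epochs(d_b, condition="B")
        got = es.channel_significance(a, b, WINDOW)
        assert got == scipy_pct_significant(a, b, WINDOW)
        assert got == 50.0

    def test_matches_scipy_on_random_data(self, epoch_pair):
        a, b = epoch_pair
        assert es.channel_significance(a, b, WINDOW) == scipy_pct_significant(a, b, WINDOW)

    def test_scale_invariance(self, epoch_pair):
        a, b = epoch_pair
        a10, b10 = a.copy(), b.copy()
        a10.data *= 10.0
        b10.data *= 10.0
        assert es.channel_significance(a, b, WINDOW) == es.channel_significance(
            a10, b10, WINDOW
        )

    def test_channel_permutation_invariance(self, epoch_pair):
        a, b = epoch_pair
        perm = [3, 0, 2, 1]
        ap, bp = a.copy(), b.copy()
        ap.data, bp.data = a.data[perm], b.data[perm]
        ap.channel_labels = bp.channel_labels = [a.channel_labels[i] for i in perm]
        assert es.channel_significance(a, b, WINDOW) == es.channel_significance(ap, bp, WINDOW)

    def test_trial_order_invariance(self, epoch_pair, rng):
        a, b = epoch_pair
        ash = a.copy()
        ash.data = a.data[:, :, rng.permutation(a.n_trials)]
        assert es.channel_significance(a, b, WINDOW) == es.channel_significance(ash, b, WINDOW)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           shift=st.floats(min_value=-50.0, max_value=50.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_common_affine_transform(self, scale, shift):
        """Applying the same positive rescaling and offset to both conditions
        (a change of units / reference) leaves the t-decisions unchanged."""
        r = np.random.default_rng(7)
        d_a = r.normal(size=(4, 10, 12))
        d_b = r.normal(size=(4, 10, 12))
        d_b[:2] += 1.0
        a, b = make_epochs(d_a), make_epochs(d_b, condition="B")
        a2 = make_epochs(scale * d_a + shift)
        b2 = make_epochs(scale * d_b + shift, condition="B")
        win = (0.0, 0.1)
        assert es.channel_significance(a, b, win) == es.channel_significance(a2, b2, win)

    def test_zero_variance_conventions(self):
        const = np.ones((2, 10, 5))
        a = make_epochs(const)
        b_equal = make_epochs(const.copy(), condition="B")
        assert es.channel_significance(a, b_equal, (0.0, 0.1)) == 0.0  # t := 0
        b_shift = make_epochs(const + 1.0, condition="B")
        assert es.channel_significance(a, b_shift, (0.0, 0.1)) == 100.0  # t -> inf

    def test_mismatched_channels_rejected(self, epoch_pair):
        a, b = epoch_pair
        bad = b.copy()
        bad.channel_labels = ["x"] * b.n_channels
        with pytest.raises(ValueError, match="mismatched channels"):
            es.channel_significance(a, bad, WINDOW)

    def test_window_outside_epoch_rejected(self, epoch_pair):
        a, b = epoch_pair
        with pytest.raises(ValueError, match="window"):
            es.channel_significance(a, b, (5.0, 6.0))


class TestResampledMetric:
    def test_single_repetition_equals_one_draw(self, epoch_pair):
        a, b = epoch_pair
        cfg = es.MetricConfig(window=WINDOW, n_boot=1, n_resample=10, seed=42)
        res = es.resampled_metric(a, b, cfg)
        # replay the engine's single draw by hand
        rng = np.random.default_rng(42)
        ia = rng.integers(0, a.n_trials, size=(1, 10))[0]
        ib = rng.integers(0, b.n_trials, size=(1, 10))[0]
        ra = make_epochs(a.data[:, :, ia])
        rb = make_epochs(b.data[:, :, ib], condition="B")
        assert res.mean_pct_significant == es.channel_significance(ra, rb, WINDOW)

    def test_deterministic_given_seed(self, epoch_pair):
        a, b = epoch_pair
        cfg = es.MetricConfig(window=WINDOW, n_boot=200, seed=7)
        r1 = es.resampled_metric(a, b, cfg)
        r2 = es.resampled_metric(a, b, cfg)
        assert r1.mean_pct_significant == r2.mean_pct_significant
        np.testing.assert_array_equal(r1.per_channel_rate, r2.per_channel_rate)
        assert r1.rep_sd == r2.rep_sd

    def test_exhaustive_enumeration_small_pool(self, rng):
        """With 3 trials/condition and resample size 2 there are 3²·3² = 81
        equally likely joint draws; the bootstrap mean must converge to the
        enumerated expectation."""
        d_a = rng.normal(size=(4, 10, 3))
        d_b = rng.normal(size=(4, 10, 3))
        d_b[:2] += 1.0
        a, b = make_epochs(d_a), make_epochs(d_b, condition="B")
        win = (0.0, 0.1)

        pcts = []
        for draw_a in itertools.product(range(3), repeat=2):
            ra = make_epochs(d_a[:, :, list(draw_a)])
            for draw_b in itertools.product(range(3), repeat=2):
                rb = make_epochs(d_b[:, :, list(draw_b)], condition="B")
                pcts.append(scipy_pct_significant(ra, rb, win))
        expectation = np.mean(pcts)

        cfg = es.MetricConfig(window=win, n_resample=2, n_boot=20000, seed=5)
        res = es.resampled_metric(a, b, cfg)
        mc_se = np.std(pcts) / np.sqrt(cfg.n_boot)
        assert abs(res.mean_pct_significant - expectation) < 3 * max(mc_se, 1e-9)

    def test_all_trials_mode_draws_pool_sizes(self, epoch_pair):
        a, b = epoch_pair
        cfg = es.MetricConfig(window=WINDOW, n_boot=50, seed=3)
        res = es.all_trials_metric(a, b, cfg)
        assert res.mode == "all_trials"
        assert res.n_trials_used == {"a": a.n_trials, "b": b.n_trials}

    def test_all_trials_null_level_free_of_trial_count(self, rng):
        """The all-trials variant's null level depends only on drawing n from
        a pool of n (variance inflation factor 2), so halving a null pool
        leaves the mean metric unchanged up to Monte-Carlo error."""
        d_a = rng.normal(size=(16, 10, 80))
        d_b = rng.normal(size=(16, 10, 80))
        a, b = make_epochs(d_a), make_epochs(d_b, condition="B")
        a2 = make_epochs(d_a[:, :, :40])
        b2 = make_epochs(d_b[:, :, :40], condition="B")
        cfg = es.MetricConfig(window=(0.0, 0.1), n_boot=1500, seed=9)
        full = es.all_trials_metric(a, b, cfg).mean_pct_significant
        half = es.all_trials_metric(a2, b2, cfg).mean_pct_significant
        assert abs(full - half) < 4.0

    def test_resample_size_below_two_rejected(self):
        with pytest.raises(ValueError, match="n_resample"):
            es.MetricConfig(window=WINDOW, n_resample=1)

    def test_monotone_in_effect_amplitude(self):
        """With shared seeds, a larger injected effect never lowers the mean
        metric (1-pp slack)."""
        vals = []
        for amp in (0.0, 1.0, 2.0, 4.0):
            cfg = es.SyntheticConfig(
                n_subjects=1, n_channels=16, n_trials=60, seed=77
            ).clean()
            cfg.effect.amplitude = amp
            cfg.inter_subject_amplitude_sd = 0.0
            (a, b), = es.generate_epoch_cohort(cfg)
            mcfg = es.MetricConfig(window=(0.30, 0.40), n_boot=400, seed=11)
            vals.append(es.resampled_metric(a, b, mcfg).mean_pct_significant)
        assert all(v2 >= v1 - 1.0 for v1, v2 in zip(vals, vals[1:]))

    def test_null_metric_matches_finite_pool_expectation(self):
        """Under the null the metric's level is NOT alpha: drawing 50 trials
        with replacement from a 100-trial pool inflates the t statistic by
        sqrt(1 + 50/100).  The simulated cohort mean must match the analytic
        finite-pool rate, and that rate must recover 100·alpha as the pool
        grows unboundedly."""
        cfg = es.SyntheticConfig(n_subjects=8, n_channels=16, n_trials=100, seed=303).clean()
        cfg.effect.amplitude = 0.0
        expected = es.expected_metric(cfg, n_resample=50, alpha=0.05, highpass_hz=0.5)
        assert expected == pytest.approx(10.84, abs=0.1)
        assert es.expected_metric(cfg, 50, 0.05, n_pool=10**9) == pytest.approx(5.0, abs=0.01)

        vals = []
        for i, (a, b) in enumerate(es.generate_epoch_cohort(cfg, highpass_hz=0.5)):
            mcfg = es.MetricConfig(window=(0.30, 0.40), n_boot=1000, seed=1000 + i)
            vals.append(es.resampled_metric(a, b, mcfg).mean_pct_significant)
        assert abs(np.mean(vals) - expected) < 1.5


class TestLatencyScan:
    def test_single_subject_median_is_own_curve(self, rng):
        d_a = rng.normal(size=(4, 50, 20))
        d_b = rng.normal(size=(4, 50, 20))
        d_b[:, 20:30, :] += 2.0  # effect at 0.20-0.30 s
        a, b = make_epochs(d_a), make_epochs(d_b, condition="B")
        cfg = es.MetricConfig(n_boot=100, n_resample=10, seed=1)
        curve = es.latency_scan([(a, b)], cfg)
        np.testing.assert_array_equal(curve.median, curve.per_subject[0])
        np.testing.assert_array_equal(curve.mad, np.zeros_like(curve.mad))
        assert curve.latencies.size == 10  # 0.5 s of 50-ms bins

    def test_sixty_bins_over_long_epoch(self):
        cfg = es.SyntheticConfig(n_subjects=1, n_channels=8, n_trials=20, seed=55).clean()
        cohort = es.generate_epoch_cohort(cfg, epoch_window=(-1.0, 2.0))
        curve = es.latency_scan(cohort, es.MetricConfig(n_boot=50, n_resample=10, seed=2))
        assert curve.latencies.size == 60
        assert curve.tmin == pytest.approx(-1.0)
        assert curve.tmax == pytest.approx(2.0)

    def test_median_mad_hand_example(self):
        med, mad = cohort_median_mad(np.array([[10.0], [20.0], [60.0]]))
        assert med[0] == 20.0
        assert mad[0] == 10.0


class TestEffectWindow:
    def test_hand_smoothing_example(self):
        lat = np.array([0.0, 0.05, 0.10, 0.15, 0.20])
        med = np.array([0.0, 10.0, 50.0, 10.0, 0.0])
        np.testing.assert_allclose(
            moving_average(med, 3), [5.0, 20.0, 70.0 / 3.0, 20.0, 5.0]
        )
        curve = es.SignificanceCurve(lat, med[None, :], med, np.zeros(5))
        win = es.find_effect_window(curve)
        assert win.center == pytest.approx(0.10)
        assert (win.start, win.end) == (pytest.approx(0.05), pytest.approx(0.15))

    @given(st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=1, max_size=30),
           st.sampled_from([1, 3, 5, 7]))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_smoothing_stays_within_data_range(self, values, length):
        """The truncated moving average never leaves the [min, max] envelope
        of the curve and preserves constants exactly."""
        x = np.array(values)
        sm = moving_average(x, length)
        assert sm.min() >= x.min() - 1e-9
        assert sm.max() <= x.max() + 1e-9
        const = moving_average(np.full(7, x[0]), length)
        np.testing.assert_allclose(const, x[0], rtol=1e-12)

    def test_monotone_curve_peaks_at_final_latency(self):
        lat = np.arange(5) * 0.05
        med = np.arange(5, dtype=float)
        curve = es.SignificanceCurve(lat, med[None, :], med, np.zeros(5))
        assert es.find_effect_window(curve).center == pytest.approx(0.20)

    def test_constant_curve_ties_break_earliest(self):
        lat = np.arange(5) * 0.05
        med = np.full(5, 7.0)
        curve = es.SignificanceCurve(lat, med[None, :], med, np.zeros(5))
        assert es.find_effect_window(curve).center == pytest.approx(0.0)

    def test_window_clipped_at_epoch_edge_with_warning(self):
        lat = np.arange(5) * 0.05
        med = np.array([9.0, 0.0, 0.0, 0.0, 0.0])
        curve = es.SignificanceCurve(lat, med[None, :], med, np.zeros(5), tmin=0.0, tmax=0.25)
        with pytest.warns(UserWarning, match="clipped"):
            win = es.find_effect_window(curve)
        assert win.start == 0.0
        assert win.center == pytest.approx(0.0)

    def test_window_is_100ms(self):
        win = es.EffectWindow.from_center(0.35)
        assert win.end - win.start == pytest.approx(0.100, abs=1e-9)
        assert win.start == pytest.approx(0.30)
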