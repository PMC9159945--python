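"""GLR peak model: likelihood, fitting, calibration, detection."""

import warnings

import numpy as np
import pytest
from scipy import stats

import dpimap as dp
from dpimap.peaks import (
    DetectionConfig,
    EmissionData,
    GaussPeak,
    NullCalibration,
    PeakModelParams,
    calibrate_null,
    detect_peaks,
    fit_background,
    fit_single_peak,
    loglik,
)


def random_instance(seed, n_sites=20, n_reps=3, peak=None, b=0.02, depth=40):
    rng = np.random.default_rng(seed)
    x = np.sort(rng.choice(n_sites * 12, size=n_sites, replace=False))
    params = PeakModelParams(b=b, peaks=(peak,) if peak else ())
    p = params.rate(x)
    n = rng.poisson(depth, size=(n_sites, n_reps))
    c = rng.binomial(n, p[:, None])
    return EmissionData("c1", x, n, c), params


class TestLoglik:
    def test_all_reference_under_zero_rate(self):
        data = EmissionData("c1", [5], [[10]], [[0]])
        ll = loglik(data, PeakModelParams(b=0.0))
        assert abs(ll) < 1e-7

    def test_single_bernoulli_closed_form(self):
        data = EmissionData("c1", [5], [[2]], [[1]])
        ll = loglik(data, PeakModelParams(b=0.5))
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_pmf_summation_oracle(self, seed):
        """Direct scipy binomial PMF summation as the independent path."""
        data, params = random_instance(seed, peak=GaussPeak(120.0, 0.3, 30.0))
        p = params.rate(data.x)
        oracle = sum(
            stats.binom.logpmf(data.c[i, r], data.n[i, r], p[i])
            for i in range(data.n_sites)
            for r in range(data.n.shape[1])
        )
        assert loglik(data, params) == pytest.approx(oracle, abs=1e-9)

    def test_invariant_to_replicate_relabeling(self):
        data, params = random_instance(7)
        perm = np.random.default_rng(0).permutation(data.n.shape[1])
        shuffled = EmissionData("c1", data.x, data.n[:, perm], data.c[:, perm])
        assert loglik(data, params) == pytest.approx(loglik(shuffled, params))

    def test_invariant_to_zero_depth_sites(self):
        data, params = random_instance(8)
        x2 = np.concatenate([data.x, [data.x[-1] + 13, data.x[-1] + 29]])
        pad = np.zeros((2, data.n.shape[1]), dtype=int)
        data2 = EmissionData("c1", x2, np.vstack([data.n, pad]),
                             np.vstack([data.c, pad]))
        assert loglik(data2, params) == pytest.approx(loglik(data, params))

    def test_zero_amplitude_peak_is_identity(self):
        data, params = random_instance(9)
        with_null_peak = PeakModelParams(
            b=params.b, peaks=(GaussPeak(100.0, 0.0, 50.0),)
        )
        assert loglik(data, with_null_peak) == pytest.approx(
            loglik(data, params)
        )


class TestFitBackground:
    def test_analytic_mle(self):
        data = EmissionData("c1", [0, 10], [[100], [100]], [[5], [15]])
        assert fit_background(data) == pytest.approx(0.1)

    def test_all_zero_alt(self):
        data = EmissionData("c1", [0, 10], [[100], [100]], [[0], [0]])
        assert fit_background(data) == 0.0

    def test_zero_depth_everywhere_rejected(self):
        data = EmissionData("c1", [0, 10], [[0], [0]], [[0], [0]])
        with pytest.raises(ValueError):
            fit_background(data)

    def test_recovers_simulated_rate_within_3se(self):
        rng = np.random.default_rng(42)
        S, depth, b = 2000, 100, 0.01
        n = np.full((S, 1), depth)
        c = rng.binomial(n, b)
        data = EmissionData("c1", np.arange(S) * 9, n, c)
        se = np.sqrt(b * (1 - b) / (S * depth))
        assert abs(fit_background(data) - b) < 3 * se


def grid_search_ll(data, b_hat, cfg):
    """Exhaustive grid over (mu, A, sigma) with b fixed at its MLE."""
    best = -np.inf
    amps = np.geomspace(1e-3, 0.5, 12)
    sigmas = np.geomspace(cfg.sigma_min, cfg.sigma_max, 9)
    for mu in data.x:
        for A in amps:
            for s in sigmas:
                params = PeakModelParams(b=b_hat, peaks=(GaussPeak(float(mu), A, s),))
                ll = loglik(data, params)
                if ll > best:
                    best = ll
    return best


class TestFitSinglePeak:
    def test_beats_grid_search_oracle(self):
        cfg = DetectionConfig(seed=0)
        for seed in (11, 12, 13):
            data, _ = random_instance(
                seed, n_sites=40, peak=GaussPeak(240.0, 0.25, 40.0), depth=60
            )
            b_hat = fit_background(data)
            null = PeakModelParams(b=b_hat)
            resid = data.pooled_freq() - null.rate(data.x)
            seed_pos = float(data.x[int(np.argmax(resid))])
            fit = fit_single_peak(data, null, seed_pos, cfg)
            grid_ll = grid_search_ll(data, b_hat, cfg)
            assert fit.loglik >= grid_ll - 1e-3

    def test_improves_on_null(self):
        data, _ = random_instance(20, n_sites=50, peak=GaussPeak(300.0, 0.2, 50.0))
        null = PeakModelParams(b=fit_background(data))
        fit = fit_single_peak(data, null, 300.0, DetectionConfig())
        assert fit.loglik >= loglik(data, null) - 1e-6

    def test_background_only_data_gives_tiny_amplitude(self):
        rng = np.random.default_rng(33)
        x = np.arange(0, 3000, 10)
        n = np.full((len(x), 4), 100)
        c = rng.binomial(n, 0.005)
        data = EmissionData("c1", x, n, c)
        null = PeakModelParams(b=fit_background(data))
        fit = fit_single_peak(data, null, float(x[len(x) // 2]), DetectionConfig())
        lam = 2 * (loglik(data, PeakModelParams(
            b=fit.b, peaks=(GaussPeak(fit.mu, fit.A, fit.sigma),)
        )) - loglik(data, null))
        assert fit.A < 0.02
        assert lam < 30  # far below any planted-peak statistic

    def test_seed_outside_span_rejected(self):
        data, _ = random_instance(1)
        with pytest.raises(ValueError):
            fit_single_peak(data, PeakModelParams(b=0.01), -1e9)


class TestCalibrateNull:
    def make_data(self, seed=0, S=150):
        rng = np.random.default_rng(seed)
        x = np.arange(S) * 9
        n = np.full((S, 4), 60)
        c = rng.binomial(n, 0.01)
        return EmissionData("c1", x, n, c)

    def test_threshold_is_order_statistic(self):
        data = self.make_data()
        cfg = DetectionConfig(bootstrap_B=39, seed=5)
        cal = calibrate_null(data, 0.01, cfg)
        k = int(np.ceil((1 - cfg.alpha) * (cfg.bootstrap_B + 1)))  # 38th of 39
        assert cal.threshold == np.sort(cal.null_stats)[k - 1]

    def test_pvalue_plus_one_correction(self):
        data = self.make_data()
        cal = calibrate_null(data, 0.01, DetectionConfig(bootstrap_B=39, seed=5))
        assert cal.pvalue(1e9) == pytest.approx(1 / 40)
        assert cal.pvalue(-1.0) == pytest.approx(1.0)

    def test_b_too_small_for_alpha_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            DetectionConfig(bootstrap_B=19, alpha=0.01)

    def test_chi2_mode(self):
        cal = NullCalibration("chi2_df3", 0.05, float(stats.chi2.ppf(0.95, 3)))
        assert cal.pvalue(cal.threshold) == pytest.approx(0.05, rel=1e-6)


class TestDetectPeaks:
    def test_planted_peak_recovered(self):
        scfg = dp.SimConfig(seed=101, peaks=(dp.PeakSpec(5000, 0.05, 50),))
        reps, _ = dp.simulate_counts(dp.simulate_genome(10000, 0.66, seed=101), scfg)
        result = detect_peaks(EmissionData.from_replicates(reps),
                              DetectionConfig(seed=101))
        assert len(result) >= 1
        assert min(abs(p.mu - 5000) for p in result.peaks) <= 25

    def test_glr_nonnegative_and_pvalues_valid(self):
        scfg = dp.SimConfig(seed=55, peaks=(dp.PeakSpec(3000, 0.04, 60),
                                            dp.PeakSpec(7000, 0.03, 40)))
        reps, _ = dp.simulate_counts(dp.simulate_genome(10000, 0.66, seed=55), scfg)
        result = detect_peaks(EmissionData.from_replicates(reps),
                              DetectionConfig(seed=55))
        for pk in result.peaks:
            assert pk.glr >= 0
            assert 0 < pk.p_value <= 1
        glrs = [pk.glr for pk in result.peaks]
        assert glrs == sorted(glrs, reverse=True)

    def test_chi2_mode_runs(self):
        scfg = dp.SimConfig(seed=56, peaks=(dp.PeakSpec(5000, 0.05, 50),))
        reps, _ = dp.simulate_counts(dp.simulate_genome(10000, 0.66, seed=56), scfg)
        result = detect_peaks(EmissionData.from_replicates(reps),
                              DetectionConfig(seed=56, calibration_mode="chi2_df3"))
        assert len(result) >= 1

    def test_determinism(self):
        scfg = dp.SimConfig(seed=57, peaks=(dp.PeakSpec(5000, 0.05, 50),))
        reps, _ = dp.simulate_counts(dp.simulate_genome(8000, 0.66, seed=57), scfg)
        data = EmissionData.from_replicates(reps)
        r1 = detect_peaks(data, DetectionConfig(seed=57))
        r2 = detect_peaks(data, DetectionConfig(seed=57))
        assert [(p.mu, p.A, p.glr, p.p_value) for p in r1.peaks] == [
            (p.mu, p.A, p.glr, p.p_value) for p in r2.peaks
        ]

    def test_too_few_sites_warns_and_returns_empty(self):
        data = EmissionData("c1", [0, 10, 20], np.full((3, 4), 50),
                            np.full((3, 4), 2))
        with pytest.warns(UserWarning, match="degenerate"):
            result = detect_peaks(data, DetectionConfig())
        assert len(result) == 0

    def test_all_zero_alt_warns_and_returns_empty(self):
        x = np.arange(0, 500, 10)
        data = EmissionData("c1", x, np.full((len(x), 4), 50),
                            np.zeros((len(x), 4), dtype=int))
        with pytest.warns(UserWarning):
            result = detect_peaks(data, DetectionConfig())
        assert len(result) == 0
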