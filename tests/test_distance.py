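"""Depth correction and the distance-sampling engine."""

import numpy as np
import pytest
from scipy import integrate, stats

from cachalot import distance as dist


def _truncated_halfnormal(sigma, w, n, rng):
    out = np.empty(0)
    while out.size < n:
        draw = np.abs(rng.normal(0.0, sigma, 2 * n))
        out = np.concatenate([out, draw[draw <= w]])
    return out[:n]


class TestCorrectDistance:
    def test_pythagorean(self):
        assert dist.correct_distance(1000.0, 600.0) == pytest.approx(800.0)

    def test_coercion_to_zero(self):
        assert dist.correct_distance(400.0, 411.0) == 0.0
        assert dist.correct_distance(400.0, 400.0) == 0.0

    def test_zero_depth_identity(self):
        assert dist.correct_distance(1234.5, 0.0) == 1234.5

    def test_never_increases(self):
        rng = np.random.default_rng(0)
        slant = rng.uniform(0, 6500, 500)
        depth = rng.uniform(0, 2000, 500)
        corrected = dist.correct_distance(slant, depth)
        assert np.all(corrected <= slant)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            dist.correct_distance(-1.0, 0.0)

    def test_first_bin_grows_after_correction(self):
        # the bias the correction removes: deep whales near the trackline
        # pile into the first 500-m bin once corrected
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 6000, 400)
        z = rng.uniform(200, 1200, 400)
        slant = np.hypot(y, z)
        corrected = dist.correct_distance(slant, z)
        first = lambda x: np.count_nonzero(x <= 500)  # noqa: E731
        assert first(corrected) >= first(slant)


class TestAssumedDepth:
    def test_weighted_mean(self):
        assert dist.assumed_depth([400.0, 800.0], [100.0, 300.0], "mean") == 700.0

    def test_equal_weight_q1_matches_type7(self):
        got = dist.assumed_depth([400.0, 600.0, 800.0], rule="Q1")
        assert got == pytest.approx(np.quantile([400.0, 600.0, 800.0], 0.25))
        assert got == pytest.approx(500.0)

    def test_single_event(self):
        for rule in ("Q1", "mean", "Q3"):
            assert dist.assumed_depth([500.0], [42.0], rule) == 500.0

    def test_weights_pull_quantile(self):
        # heavy weight on the mid event pulls Q1 up toward it
        equal = dist.assumed_depth([400.0, 600.0, 800.0], [1.0, 1.0, 1.0], "Q1")
        heavy = dist.assumed_depth([400.0, 600.0, 800.0], [1.0, 10.0, 1.0], "Q1")
        assert equal == pytest.approx(500.0)
        assert heavy > equal

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dist.assumed_depth([])


class TestDetectionFunction:
    def test_halfnormal_esw_closed_form(self):
        # ESW = sigma*sqrt(pi/2)*erf(w/(sigma*sqrt(2))) = 2503.7 m
        rng = np.random.default_rng(2)
        x = _truncated_halfnormal(2000.0, 6500.0, 600, rng)
        fit = dist.fit_detection_function(x, "half_normal", w=6500.0)
        from scipy.special import erf

        analytic = fit.sigma_ * np.sqrt(np.pi / 2) * erf(6500.0 / (fit.sigma_ * np.sqrt(2)))
        numeric = integrate.quad(
            lambda u: np.exp(-(u**2) / (2 * fit.sigma_**2)), 0, 6500.0
        )[0]
        assert fit.esw_ == pytest.approx(analytic, rel=1e-12)
        assert fit.esw_ == pytest.approx(numeric, rel=1e-6)
        # and the reference value at sigma=2000 exactly
        assert 2000.0 * np.sqrt(np.pi / 2) * erf(6500.0 / (2000.0 * np.sqrt(2))) == (
            pytest.approx(2503.7, abs=0.1)
        )

    def test_uniform_key_flat(self):
        x = np.random.default_rng(3).uniform(0, 6500, 100)
        fit = dist.fit_detection_function(x, "uniform", w=6500.0)
        assert fit.esw_ == pytest.approx(6500.0)
        assert fit.p_ == pytest.approx(1.0)
        assert fit.n_params_ == 0

    def test_sigma_recovery_within_three_se(self):
        rng = np.random.default_rng(4)
        x = _truncated_halfnormal(2500.0, 6500.0, 1000, rng)
        fit = dist.fit_detection_function(x, "half_normal", w=6500.0)
        se_sigma = 2500.0 / np.sqrt(2 * 1000)  # asymptotic, untruncated approx
        assert abs(fit.sigma_ - 2500.0) < 3 * se_sigma * 1.6

    def test_pdf_normalized_and_p_times_w(self):
        rng = np.random.default_rng(5)
        x = _truncated_halfnormal(2200.0, 6500.0, 400, rng)
        for key in ("half_normal", "hazard_rate"):
            fit = dist.fit_detection_function(x, key, w=6500.0)
            area = integrate.quad(lambda u: float(fit.pdf(u)), 0, 6500.0, limit=200)[0]
            assert area == pytest.approx(1.0, abs=1e-6)
            assert fit.p_ * fit.w == pytest.approx(fit.esw_)
            assert 0 < fit.esw_ <= fit.w

    def test_adjustment_improves_loglik(self):
        rng = np.random.default_rng(6)
        x = _truncated_halfnormal(2500.0, 6500.0, 500, rng)
        base = dist.fit_detection_function(x, "half_normal", w=6500.0)
        adj = dist.fit_detection_function(
            x, "half_normal", "cosine", (2,), w=6500.0
        )
        assert adj.loglik_ >= base.loglik_ - 1e-6

    def test_g_zero_is_one(self):
        rng = np.random.default_rng(7)
        x = _truncated_halfnormal(2000.0, 6500.0, 300, rng)
        for key in ("half_normal", "hazard_rate", "uniform"):
            fit = dist.fit_detection_function(x, key, w=6500.0)
            assert float(fit.g(0.0)) == pytest.approx(1.0)

    def test_sklearn_params_roundtrip(self):
        fit = dist.DetectionFunction(key="hazard_rate", w=5000.0)
        params = fit.get_params()
        clone = dist.DetectionFunction(**params)
        assert clone.get_params() == params


class TestModelSelection:
    def test_lowest_aic_wins(self):
        a = dist.DetectionFunction("hazard_rate")
        a.aic_, a.converged_, a.n_params_ = 7509.205, True, 2
        b = dist.DetectionFunction("half_normal")
        b.aic_, b.converged_, b.n_params_ = 7515.933, True, 1
        assert dist.select_model([b, a]) is a

    def test_tie_prefers_fewer_parameters(self):
        a = dist.DetectionFunction("half_normal")
        a.aic_, a.converged_, a.n_params_ = 100.0, True, 1
        b = dist.DetectionFunction("hazard_rate")
        b.aic_, b.converged_, b.n_params_ = 100.0, True, 2
        assert dist.select_model([b, a]) is a

    def test_non_converged_excluded(self):
        a = dist.DetectionFunction()
        a.aic_, a.converged_, a.n_params_ = 10.0, False, 1
        with pytest.raises(ValueError):
            dist.select_model([a])

    def test_hazard_rate_family_recovered(self):
        # data simulated from a hazard-rate model: the hazard-rate key
        # must win the AIC comparison in >= 80% of replicates
        w = 6500.0
        grid = np.linspace(0, w, 2049)
        g = 1.0 - np.exp(-((grid[1:] / 2500.0) ** (-3.0)))
        cdf = np.concatenate([[0.0], np.cumsum(g)])
        cdf /= cdf[-1]
        wins = 0
        reps = 50
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            x = np.interp(rng.uniform(0, 1, 431), cdf, grid)
            hn = dist.fit_detection_function(x, "half_normal", w=w)
            hz = dist.fit_detection_function(x, "hazard_rate", w=w)
            if hz.aic_ < hn.aic_:
                wins += 1
        assert wins / reps >= 0.8


class TestGOF:
    def test_ks_statistic_hand_computed(self):
        # three points against Uniform(0,4): D = 0.25 by direct ECDF
        fit = dist.fit_detection_function(np.array([1.0, 2.0, 3.0]), "uniform", w=4.0)
        ks, cvm = dist._ks_cvm_stats(fit, np.array([1.0, 2.0, 3.0]))
        assert ks == pytest.approx(0.25, abs=1e-9)
        assert cvm > 0

    def test_well_specified_model_passes(self):
        rng = np.random.default_rng(8)
        x = _truncated_halfnormal(2500.0, 6500.0, 431, rng)
        fit = dist.fit_detection_function(x, "half_normal", w=6500.0)
        ks_p, cvm_p = dist.gof(fit, x, n_boot=99, seed=1)
        assert ks_p > 0.05
        assert cvm_p > 0.05

    def test_misspecified_model_fails(self):
        # steep half-normal data fitted with a flat uniform key
        rng = np.random.default_rng(9)
        x = _truncated_halfnormal(1200.0, 6500.0, 431, rng)
        fit = dist.fit_detection_function(x, "uniform", w=6500.0)
        ks_p, cvm_p = dist.gof(fit, x, n_boot=99, seed=2)
        assert ks_p < 0.05
        assert cvm_p < 0.05


class TestAbundance:
    def test_density_from_printed_esw_hazard(self):
        est = dist.estimate_abundance(n=431, L_km=5661.0, esw_m=5099.0)
        assert est.density_per_km2 == pytest.approx(0.00747, abs=5e-5)

    def test_density_from_printed_esw_halfnormal(self):
        est = dist.estimate_abundance(n=431, L_km=5661.0, esw_m=4566.0)
        assert est.density_per_km2 == pytest.approx(0.00833, abs=5e-5)

    def test_zero_detections(self):
        est = dist.estimate_abundance(n=0, L_km=100.0, esw_m=3000.0, A_km2=1000.0)
        assert est.density_per_km2 == 0.0
        assert est.abundance == 0.0

    def test_cv_composition(self):
        est = dist.estimate_abundance(
            n=40, L_km=100.0, esw_m=3000.0, esw_cv=0.05,
            leg_lengths_km=[25.0, 25.0, 25.0, 25.0], leg_counts=[12, 8, 11, 9],
        )
        assert est.cv == pytest.approx(np.hypot(est.cv_encounter, 0.05))

    def test_single_leg_flagged(self):
        with pytest.warns(UserWarning, match="single transect leg"):
            cv = dist.encounter_rate_cv([100.0], [40])
        assert np.isnan(cv)

    def test_abundance_ci_covers_truth_across_replicates(self):
        # end-to-end statistical pipeline at reduced scale: whales placed
        # at known density, thinned by a half-normal detection process,
        # distances depth-corrected, refit, N-hat CI checked against truth
        w_m = 6500.0
        L_km = 400.0
        A = 2 * 6.5 * L_km
        density = 0.08
        covered = 0
        reps = 50
        n_legs = 8
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            n_true = rng.poisson(density * A)
            y = rng.uniform(0, w_m, n_true)
            z = rng.uniform(300.0, 1200.0, n_true)
            xpos = rng.uniform(0, L_km, n_true)
            slant = np.hypot(y, z)
            p_det = np.exp(-(slant**2) / (2 * 3500.0**2))
            det = rng.uniform(size=n_true) < p_det
            corrected = dist.correct_distance(slant[det], z[det])
            fit = dist.fit_detection_function(corrected, "half_normal", w=w_m)
            legs = np.linspace(0, L_km, n_legs + 1)
            counts = np.histogram(xpos[det], bins=legs)[0]
            est = dist.estimate_abundance(
                fit, n=int(det.sum()), L_km=L_km, A_km2=A,
                leg_lengths_km=np.diff(legs), leg_counts=counts,
            )
            lo, hi = est.lognormal_ci()
            if lo <= density * A <= hi:
                covered += 1
        assert covered / reps >= 0.9
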