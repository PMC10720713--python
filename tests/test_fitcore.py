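"""Unit and property tests for the per-decay estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import least_squares

from rtflim import (
    Decay,
    FitWindow,
    InvalidParameterError,
    InvalidWindowError,
    chi_square,
    decay_model,
    fit_lma,
    fit_rld,
    phasor,
)


class TestDecayModel:
    def test_flat_limit_at_huge_tau(self):
        w = FitWindow(0, 12, 0.05)
        d = decay_model(0.0, 1000.0, 1e12, w)
        assert np.allclose(d.counts, 1000.0)

    def test_zero_amplitude_gives_background(self):
        w = FitWindow(0, 12, 0.05)
        d = decay_model(5.0, 0.0, 1.0, w)
        assert np.allclose(d.counts, 5.0)

    def test_analytic_ratio(self):
        # counts[k] = 1000 * exp(-0.025 k); bin 40 over bin 0 is e^-1
        w = FitWindow(0, 64, 0.05)
        d = decay_model(0.0, 1000.0, 2.0, w)
        assert d.counts[40] / d.counts[0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_nonpositive_tau_rejected(self):
        w = FitWindow(0, 12, 0.05)
        with pytest.raises(InvalidParameterError):
            decay_model(0.0, 100.0, 0.0, w)


class TestRLD:
    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0, 5.0])
    @pytest.mark.parametrize("Z", [0.0, 10.0])
    def test_exact_on_noiseless_decay(self, tau, Z):
        """Gate differences cancel the background, so the closed form is exact."""
        w = FitWindow(0, 240, 0.05)
        d = decay_model(Z, 1000.0, tau, w)
        r = fit_rld(d, w).single()
        assert r.valid
        assert r.tau == pytest.approx(tau, rel=1e-9)
        assert r.A == pytest.approx(1000.0, rel=1e-9)
        assert r.Z == pytest.approx(Z, abs=1e-7)

    def test_gate_ratio_identity_by_direct_summation(self):
        """Independent oracle: sum the three gates by hand and check that
        (S1-S2)/(S2-S3) = exp(m*delta/tau) for geometric bin samples."""
        tau, delta, Z = 2.0, 0.05, 10.0
        w = FitWindow(0, 240, delta)
        m = 80
        counts = Z + 1000.0 * np.exp(-np.arange(240) * delta / tau)
        S1, S2, S3 = (counts[i * m:(i + 1) * m].sum() for i in range(3))
        ratio = (S1 - S2) / (S2 - S3)
        assert ratio == pytest.approx(np.exp(m * delta / tau), rel=1e-12)
        tau_oracle = m * delta / np.log(ratio)
        r = fit_rld(Decay(counts, delta), w).single()
        assert r.tau == pytest.approx(tau_oracle, rel=1e-12)

    def test_trailing_remainder_bins_ignored(self):
        # 240-bin fit and a 242-bin window differ only in ignored remainder
        tau, delta = 1.5, 0.05
        counts = 500.0 * np.exp(-np.arange(242) * delta / tau)
        r242 = fit_rld(Decay(counts, delta), FitWindow(0, 242, delta)).single()
        assert r242.tau == pytest.approx(tau, rel=1e-9)

    @pytest.mark.parametrize(
        "counts",
        [np.full(30, 7.0), np.zeros(30), np.linspace(0, 100, 30)],
        ids=["constant", "dark", "rising"],
    )
    def test_signal_free_pixels_flagged_invalid(self, counts):
        r = fit_rld(Decay(counts, 0.05), FitWindow(0, 30, 0.05)).single()
        assert not r.valid
        assert np.isnan(r.tau) and np.isnan(r.A) and np.isnan(r.Z)

    def test_window_shorter_than_three_bins_rejected(self):
        with pytest.raises(InvalidWindowError):
            FitWindow(0, 2, 0.05)

    def test_window_beyond_histogram_rejected(self):
        with pytest.raises(InvalidWindowError):
            fit_rld(Decay(np.ones(10), 0.05), FitWindow(0, 20, 0.05))

    def test_batch_equals_per_pixel_loop(self, rng, window128):
        """Frame-wide vectorized fit must match fitting each pixel alone."""
        t = window128.times()
        taus = rng.uniform(0.5, 4.0, size=(4, 5))
        frames = rng.poisson(
            200 * np.exp(-t / taus[..., None])
        ).astype(float)
        frames[1, 2] = 0.0  # a dark pixel
        field = fit_rld(frames, window128)
        for i in range(4):
            for j in range(5):
                single = fit_rld(Decay(frames[i, j], 0.1), window128).single()
                assert bool(field.valid[i, j]) == single.valid
                if single.valid:
                    assert field.tau[i, j] == pytest.approx(single.tau, rel=1e-12)
                    assert field.chi2[i, j] == pytest.approx(single.chi2, rel=1e-12)


class TestPhasor:
    def test_delta_at_time_zero_maps_to_unit_point(self):
        counts = np.zeros(4096)
        counts[0] = 1e5
        p = phasor(Decay(counts, 0.01), FitWindow(0, 4096, 0.01)).single()
        assert p.g == pytest.approx(1.0, abs=1e-5)
        assert p.s == pytest.approx(0.0, abs=1e-2)

    def test_uniform_decay_maps_to_origin(self):
        p = phasor(Decay(np.full(256, 9.0), 0.05), FitWindow(0, 256, 0.05)).single()
        assert abs(p.g) < 1e-12 and abs(p.s) < 1e-12

    def test_matches_continuous_closed_form(self):
        w = FitWindow(0, 1024, 0.05)
        d = decay_model(0.0, 1000.0, 2.0, w)
        p = phasor(d, w).single()
        wt = p.omega * 2.0
        assert p.g == pytest.approx(1 / (1 + wt**2), abs=1e-3)
        assert p.s == pytest.approx(wt / (1 + wt**2), abs=1e-3)

    def test_semicircle_residual_shrinks_with_bin_count(self):
        """Mono-exponential phasors approach the universal semicircle as the
        window is refined (span fixed, bins doubled)."""
        span, tau = 51.2, 2.0
        residuals = []
        for n in (64, 128, 256, 512, 1024):
            w = FitWindow(0, n, span / n)
            p = phasor(decay_model(0.0, 1000.0, tau, w), w).single()
            residuals.append(abs((p.g - 0.5) ** 2 + p.s**2 - 0.25))
        assert all(a > b for a, b in zip(residuals, residuals[1:]))
        assert residuals[-1] < 1e-3

    def test_harmonic_scales_frequency(self):
        w = FitWindow(0, 512, 0.05)
        d = decay_model(0.0, 1000.0, 2.0, w)
        p1 = phasor(d, w, harmonic=1).single()
        p2 = phasor(d, w, harmonic=2).single()
        assert p2.omega == pytest.approx(2 * p1.omega)
        assert p2.g < p1.g  # higher frequency pushes toward the origin

    def test_zero_count_pixels_flagged(self, window128):
        frames = np.zeros((2, 2, 128))
        frames[0, 0, 3] = 5.0
        field = phasor(frames, window128)
        assert field.valid[0, 0] and not field.valid[1, 1]
        assert np.isnan(field.g[1, 1])

    @given(
        tau1=st.floats(0.3, 5.0),
        tau2=st.floats(0.3, 5.0),
        a1=st.floats(10.0, 1e4),
        a2=st.floats(10.0, 1e4),
    )
    @settings(max_examples=50, deadline=None)
    def test_mixture_is_photon_weighted_average(self, tau1, tau2, a1, a2):
        """Linearity: the phasor of a summed decay is the photon-weighted
        convex combination of the component phasors."""
        w = FitWindow(0, 256, 0.05)
        d1 = decay_model(0.0, a1, tau1, w).counts
        d2 = decay_model(0.0, a2, tau2, w).counts
        p1 = phasor(d1, w).single()
        p2 = phasor(d2, w).single()
        pm = phasor(d1 + d2, w).single()
        t1, t2 = d1.sum(), d2.sum()
        assert pm.g == pytest.approx((t1 * p1.g + t2 * p2.g) / (t1 + t2), abs=1e-12)
        assert pm.s == pytest.approx((t1 * p1.s + t2 * p2.s) / (t1 + t2), abs=1e-12)


class TestChiSquare:
    def test_perfect_fit_is_zero(self):
        w = FitWindow(0, 32, 0.05)
        d = decay_model(2.0, 100.0, 1.0, w)
        assert chi_square(d, d, w).value == 0.0

    def test_unit_offset_poisson_weights(self):
        w = FitWindow(0, 32, 0.05)
        model = decay_model(0.0, 50.0, 1.0, w)
        obs = Decay(model.counts + 1.0, 0.05)
        expected = np.sum(1.0 / np.maximum(obs.counts, 1.0))
        assert chi_square(obs, model, w).value == pytest.approx(expected, rel=1e-12)

    def test_gaussian_noise_model_is_unweighted(self):
        w = FitWindow(0, 32, 0.05)
        model = decay_model(0.0, 50.0, 1.0, w)
        obs = Decay(model.counts + 1.0, 0.05)
        assert chi_square(obs, model, w, noise_model="gaussian").value == pytest.approx(32.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chi_square(np.ones(10), np.ones(12))

    def test_monte_carlo_reduced_chi2_near_one(self, rng):
        """200 Poisson draws from a fixed model have mean reduced chi2 ~ 1.

        The observed-count (Neyman) weighting is biased high by ~2/mu per
        bin, so the model is kept bright enough for that bias to stay small.
        """
        w = FitWindow(0, 128, 0.1)
        model = decay_model(50.0, 1000.0, 2.0, w)
        red = [
            chi_square(rng.poisson(model.counts).astype(float), model.counts, w).reduced
            for _ in range(200)
        ]
        assert 0.9 < np.mean(red) < 1.15


class TestLMA:
    def test_fixed_point_on_noiseless_data(self):
        w = FitWindow(0, 128, 0.1)
        d = decay_model(5.0, 800.0, 1.5, w)
        r = fit_lma(d, w, init=(5.0, 800.0, 1.5))
        assert r.converged and r.n_iterations <= 1
        assert r.chi2 == 0.0

    def test_recovers_truth_from_rld_init(self):
        w = FitWindow(0, 128, 0.1)
        d = decay_model(5.0, 800.0, 1.5, w)
        init = fit_rld(d, w).single()
        r = fit_lma(d, w, init=init)
        assert r.converged
        assert r.Z == pytest.approx(5.0, rel=1e-6, abs=1e-6)
        assert r.A == pytest.approx(800.0, rel=1e-6)
        assert r.tau == pytest.approx(1.5, rel=1e-6)

    def test_never_worse_than_initialization(self, rng, window128):
        """Only improving steps are accepted, so the final chi2 is bounded by
        the RLD seed's on every noisy decay."""
        t = window128.times()
        for _ in range(25):
            tau = rng.uniform(0.5, 4.0)
            counts = rng.poisson(300 * np.exp(-t / tau) + 2).astype(float)
            init = fit_rld(counts, window128).single()
            if not init.valid:
                continue
            r = fit_lma(counts, window128, init=init)
            assert r.chi2 <= init.chi2 + 1e-9
            if r.converged:
                assert r.tau > 0

    def test_agrees_with_scipy_least_squares(self, rng, window128):
        """Independent oracle: scipy's trust-region least squares with the
        same fixed weights lands on the same optimum."""
        t = window128.times()
        counts = rng.poisson(400 * np.exp(-t / 2.2) + 3).astype(float)
        init = fit_rld(counts, window128).single()
        ours = fit_lma(counts, window128, init=init)
        wgt = 1.0 / np.sqrt(np.maximum(counts, 1.0))

        def resid(p):
            return wgt * (counts - p[0] - p[1] * np.exp(-t / p[2]))

        ref = least_squares(resid, [init.Z, init.A, init.tau], method="lm")
        assert ours.tau == pytest.approx(ref.x[2], rel=1e-4)
        assert ours.chi2 == pytest.approx(2 * ref.cost, rel=1e-6)

    def test_invalid_init_rejected(self, window128):
        d = decay_model(0.0, 100.0, 1.0, window128)
        with pytest.raises(InvalidParameterError):
            fit_lma(d, window128, init=(0.0, 100.0, -1.0))
        bad_rld = fit_rld(Decay(np.full(128, 5.0), 0.1), window128).single()
        with pytest.raises(InvalidParameterError):
            fit_lma(d, window128, init=bad_rld)
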