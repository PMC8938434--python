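"""FRAP normalization, recovery fitting, and diffusion-coefficient algebra."""

import math

import numpy as np
import pytest

from fgphase import frap, simulate


class TestNormalize:
    def test_plain_rescaling(self):
        t = np.arange(0.0, 10.0, 1.0)
        roi = np.linspace(20.0, 100.0, t.size)
        series = frap.FrapSeries(t, roi, prebleach_level=100.0,
                                 reference_signal=np.full(t.size, 50.0))
        c = frap.normalize(series)
        assert c[0] == pytest.approx(0.2)
        assert c[-1] == pytest.approx(1.0)

    def test_reference_decay_cancels_exactly(self):
        t = np.arange(0.0, 20.0, 1.0)
        clean = np.linspace(30.0, 95.0, t.size)
        decay = 1.0 - 0.1 * t / t[-1]  # 10% linear acquisition bleaching
        series = frap.FrapSeries(t, clean * decay, prebleach_level=100.0,
                                 reference_signal=100.0 * decay)
        c = frap.normalize(series)
        assert np.allclose(c, clean / 100.0, atol=1e-9)

    def test_idempotent(self):
        t = np.arange(0.0, 20.0, 1.0)
        roi = np.linspace(20.0, 90.0, t.size)
        series = frap.FrapSeries(t, roi, prebleach_level=100.0,
                                 reference_signal=np.full(t.size, 1.0))
        once = frap.normalize(series)
        series2 = frap.FrapSeries(t, once, prebleach_level=1.0,
                                  reference_signal=np.full(t.size, 1.0))
        assert np.allclose(frap.normalize(series2), once)

    def test_zero_reference_rejected(self):
        t = np.arange(0.0, 10.0, 1.0)
        ref = np.linspace(1.0, 0.0, t.size)
        series = frap.FrapSeries(t, np.linspace(10, 50, t.size), 100.0, ref)
        with pytest.raises(ValueError):
            frap.normalize(series)

    def test_correction_removes_acquisition_bleach_bias(self):
        # With 5% of the signal lost to acquisition bleaching over the record,
        # the corrected pipeline recovers the programmed D within 5% while the
        # uncorrected fit carries a visible bias.
        d_true = 0.06
        rate = 0.05 / 300.0
        series = simulate.gen_frap(d_um2_s=d_true, radius_um=2.5,
                                   acq_bleach_rate=rate)
        corrected = frap.analyze(series, radius_um=2.5)
        assert corrected.d == pytest.approx(d_true, rel=0.05)
        uncorr = frap.FrapSeries(series.times, series.roi_signal,
                                 series.prebleach_level, None)
        uncorrected = frap.analyze(uncorr, radius_um=2.5)
        assert abs(uncorrected.d - d_true) > 10 * abs(corrected.d - d_true)


class TestFitRecovery:
    def test_noiseless_generative_identity(self):
        t = np.arange(0.0, 300.0, 2.0)
        c = 0.9 * (1.0 - np.exp(-t / 30.0))
        fit = frap.fit_recovery(t, c)
        assert fit.a == pytest.approx(0.9, rel=1e-6)
        assert fit.tau == pytest.approx(30.0, rel=1e-6)

    def test_flat_trace_flagged_immobile(self):
        t = np.arange(0.0, 300.0, 2.0)
        fit = frap.fit_recovery(t, np.full(t.size, 0.05), rebase=False)
        assert fit.immobile
        assert fit.tau is None and fit.d is None

    def test_noisy_tau_recovery_bias(self):
        # A = 0.95, tau = 23 s, 3% additive noise, 2 s frames over 300 s,
        # 100 replicates: mean tau bias under 5%.
        rng = np.random.default_rng(11)
        t = np.arange(0.0, 300.0, 2.0)
        taus = []
        for _ in range(100):
            c = 0.95 * (1.0 - np.exp(-t / 23.0)) + 0.03 * rng.standard_normal(t.size)
            taus.append(frap.fit_recovery(t, c, rebase=False).tau)
        assert np.mean(taus) == pytest.approx(23.0, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            frap.fit_recovery(np.arange(3.0), np.arange(3.0) / 3.0)


class TestAlgebraicSteps:
    def test_half_time_is_ln2_tau(self):
        assert frap.half_time(1.0) == pytest.approx(0.6931, abs=1e-4)
        assert frap.half_time(30.0) == pytest.approx(20.79, abs=0.01)
        with pytest.raises(ValueError):
            frap.half_time(0.0)

    def test_diffusion_coefficient(self):
        # The condensed-phase magnitude: R = 2.5 um, t_half = 23.3 s -> 0.060.
        assert frap.diffusion_coefficient(23.3, 2.5) == pytest.approx(0.0601, abs=2e-4)
        assert frap.diffusion_coefficient(10.0, 2.0) == \
            pytest.approx(4 * frap.diffusion_coefficient(10.0, 1.0))
        assert frap.diffusion_coefficient(0.224, 1.0) == pytest.approx(1.0)


class TestBleachRadius:
    def test_rectangular_dip(self):
        x = np.linspace(-6, 6, 1201)
        y = np.where(np.abs(x) <= 2.0, 0.2, 1.0)
        assert frap.bleach_radius(x, y) == pytest.approx(2.0, abs=0.02)

    def test_gaussian_dip_closed_form(self):
        # Half-width at 86% of bleach depth = sigma * sqrt(2 ln(1/0.14)).
        sigma = 1.2
        x = np.linspace(-8, 8, 400001)
        y = 1.0 - 0.8 * np.exp(-x ** 2 / (2 * sigma ** 2))
        expected = sigma * math.sqrt(2.0 * math.log(1.0 / 0.14))
        assert frap.bleach_radius(x, y) == pytest.approx(expected, rel=1e-6)

    def test_generator_defaults_give_two_to_three_micron_spot(self):
        # A nominal ~1.5 um bleach blurred by the beam presents as an
        # effective 2-3 um radius.
        x, y = simulate.gen_bleach_profile()
        assert 2.0 <= frap.bleach_radius(x, y) <= 3.0

    def test_no_dip_rejected(self):
        x = np.linspace(0, 5, 50)
        with pytest.raises(ValueError):
            frap.bleach_radius(x, np.ones(50))


class TestPipeline:
    def test_noiseless_round_trip_is_exact(self):
        for d_true in (0.06, 0.02):
            series = simulate.gen_frap(d_um2_s=d_true, radius_um=2.5,
                                       immobile_frac=0.05)
            fit = frap.analyze(series, radius_um=2.5)
            assert fit.d == pytest.approx(d_true, rel=1e-6)
            assert fit.a == pytest.approx(0.95, rel=1e-6)

    def test_fully_immobile_flagged(self):
        series = simulate.gen_frap(immobile_frac=1.0)
        fit = frap.analyze(series, radius_um=2.5)
        assert fit.immobile

    def test_replicate_summary(self):
        fits = [frap.analyze(simulate.gen_frap(d_um2_s=0.06, noise=0.01, seed=s),
                             radius_um=2.5) for s in range(5)]
        summary = frap.summarize_replicates(fits)
        assert summary["n"] == 5
        assert summary["d_mean"] == pytest.approx(0.06, rel=0.1)
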