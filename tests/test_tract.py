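"""TRACT decay fitting, eta_xy inversion, and Monte-Carlo error propagation."""

import numpy as np
import pytest

from fgphase import simulate
from fgphase import tract as tr


def make_series(rate, label="X", state="alpha", n=7, i0=100.0, noise=0.0, rng=None):
    t_max = np.log(1 / 0.3) / rate
    t = np.linspace(0.0, t_max, n)
    y = i0 * np.exp(-rate * t)
    if noise:
        y = y * (1.0 + noise * rng.standard_normal(n))
    return tr.RelaxationSeries(label, state, t, y)


class TestFitDecay:
    def test_noiseless_exact(self):
        fit = tr.fit_decay(make_series(5.0))
        assert fit.rate == pytest.approx(5.0, abs=1e-9)
        assert fit.sd == pytest.approx(0.0, abs=1e-6)
        assert not fit.flagged

    def test_constant_trace_flagged_not_raised(self):
        series = tr.RelaxationSeries("X", "alpha", np.linspace(0, 1, 7), np.full(7, 10.0))
        fit = tr.fit_decay(series)
        assert fit.rate == 0.0
        assert fit.flagged

    def test_monte_carlo_oracle_rate_recovery(self):
        # 200 noisy replicates of R = 12 /s at the 7-delay / 30%-residual
        # design: the mean recovered rate is unbiased to 1% and the reported
        # per-fit sd agrees with the empirical scatter.
        rng = np.random.default_rng(42)
        fits = [tr.fit_decay(make_series(12.0, noise=0.02, rng=rng)) for _ in range(200)]
        rates = np.array([f.rate for f in fits])
        assert rates.mean() == pytest.approx(12.0, rel=0.01)
        reported_sd = np.mean([f.sd for f in fits])
        assert reported_sd == pytest.approx(rates.std(ddof=1), rel=0.35)

    def test_too_few_delays_rejected(self):
        with pytest.raises(ValueError):
            tr.RelaxationSeries("X", "alpha", np.array([0.0, 0.1]), np.array([1.0, 0.5]))


class TestEtaXy:
    def test_values_and_sign(self):
        assert tr.eta_xy(10.0, 20.0) == 5.0
        assert tr.eta_xy(7.0, 7.0) == 0.0
        assert tr.eta_xy(20.0, 10.0) == -5.0


class TestEtaForward:
    def test_zero_tau(self, spin_params):
        assert tr.eta_forward(0.0, spin_params) == 0.0

    def test_strict_monotonicity(self, spin_params):
        taus = np.logspace(-12, -6, 200)
        etas = [tr.eta_forward(t, spin_params) for t in taus]
        assert np.all(np.diff(etas) > 0)


class TestInversion:
    @pytest.mark.parametrize("tau_ns", [0.5, 2.0, 5.0, 11.0])
    def test_round_trip(self, spin_params, tau_ns):
        eta = tr.eta_forward(tau_ns * 1e-9, spin_params)
        assert tr.tau_c_from_eta(eta, spin_params) == pytest.approx(tau_ns, rel=1e-6)

    def test_round_trip_across_decades(self, spin_params):
        for tau in np.logspace(-11.5, -7.5, 9):
            eta = tr.eta_forward(tau, spin_params)
            assert tr.tau_c_from_eta(eta, spin_params) * 1e-9 == pytest.approx(tau, rel=1e-6)

    def test_small_eta_gives_small_tau(self, spin_params):
        assert tr.tau_c_from_eta(1e-6, spin_params) < 1e-3  # ns

    def test_nonpositive_eta_is_indeterminate(self, spin_params):
        assert tr.tau_c_from_eta(0.0, spin_params) is None
        assert tr.tau_c_from_eta(-3.0, spin_params) is None

    def test_eta_above_bracket_rejected(self, spin_params):
        with pytest.raises(ValueError, match="bracket"):
            tr.tau_c_from_eta(1e9, spin_params)


class TestMonteCarloSd:
    def test_zero_sds_give_zero(self, spin_params):
        fa = tr.RateFit(rate=30.0, sd=0.0, amplitude=100.0, rss=0.0)
        fb = tr.RateFit(rate=50.0, sd=0.0, amplitude=100.0, rss=0.0)
        sd, indet = tr.monte_carlo_sd(fa, fb, spin_params, n_iter=100, seed=0)
        assert sd == 0.0 and not indet

    def test_seeded_reproducibility(self, spin_params):
        fa = tr.RateFit(rate=30.0, sd=0.3, amplitude=100.0, rss=0.0)
        fb = tr.RateFit(rate=50.0, sd=0.3, amplitude=100.0, rss=0.0)
        a = tr.monte_carlo_sd(fa, fb, spin_params, n_iter=500, seed=7)
        b = tr.monte_carlo_sd(fa, fb, spin_params, n_iter=500, seed=7)
        assert a == b

    def test_linear_scaling_against_first_order_propagation(self, spin_params):
        # First-order oracle: sd_tau = sd_eta / (d eta / d tau) with
        # sd_eta = sqrt(sd_a^2 + sd_b^2) / 2.
        r_a, r_b = 30.0, 50.0
        eta = tr.eta_xy(r_a, r_b)
        tau = tr.tau_c_from_eta(eta, spin_params) * 1e-9
        h = 1e-12
        deta_dtau = (tr.eta_forward(tau + h, spin_params) -
                     tr.eta_forward(tau - h, spin_params)) / (2 * h)
        for sd in (0.1, 0.2, 0.4):
            fa = tr.RateFit(rate=r_a, sd=sd, amplitude=100.0, rss=0.0)
            fb = tr.RateFit(rate=r_b, sd=sd, amplitude=100.0, rss=0.0)
            mc_sd, indet = tr.monte_carlo_sd(fa, fb, spin_params, n_iter=4000, seed=1)
            expected = (np.sqrt(2) * sd / 2.0) / deta_dtau * 1e9
            assert not indet
            assert mc_sd == pytest.approx(expected, rel=0.1)

    def test_overlapping_rates_indeterminate(self, spin_params):
        fa = tr.RateFit(rate=40.0, sd=5.0, amplitude=100.0, rss=0.0)
        fb = tr.RateFit(rate=40.0, sd=5.0, amplitude=100.0, rss=0.0)
        sd, indet = tr.monte_carlo_sd(fa, fb, spin_params, n_iter=1000, seed=3)
        assert indet and sd is None


class TestRunTract:
    def test_flat_profile_recovery(self, spin_params):
        # All residues tumbling at the same ~2 ns: the recovered profile is
        # flat at 2 ns (the aqueous-state scenario).
        profile = {f"R{i}": 2.0 for i in range(1, 12)}
        alpha, beta = simulate.gen_tract(profile, spin_params, noise=0.0)
        results = tr.run_tract(alpha, beta, spin_params, n_iter=10)
        taus = [r.tau_c_ns for r in results]
        assert len(taus) == 11
        assert np.allclose(taus, 2.0, rtol=1e-6)

    def test_overlapping_residues_flagged(self, spin_params):
        profile = {"G1": 2.0, "F4": 5.0, "T8": 3.0}
        alpha, beta = simulate.gen_tract(profile, spin_params, noise=0.0)
        # Overwrite three residues' beta decays with their alpha decays:
        # R_alpha == R_beta means eta_xy = 0, i.e. indeterminate.
        for label in ("G1", "T8"):
            s = alpha[label]
            beta[label] = tr.RelaxationSeries(label, "beta", s.delays, s.intensities)
        results = {r.residue_label: r for r in tr.run_tract(alpha, beta, spin_params, n_iter=10)}
        assert results["G1"].indeterminate and results["T8"].indeterminate
        assert results["G1"].tau_c_ns is None
        assert not results["F4"].indeterminate

    def test_empty_input(self, spin_params):
        assert tr.run_tract({}, {}, spin_params) == []

    def test_mismatched_residues_rejected(self, spin_params):
        alpha, _ = simulate.gen_tract({"G1": 2.0}, spin_params)
        _, beta = simulate.gen_tract({"F4": 2.0}, spin_params)
        with pytest.raises(ValueError, match="F4"):
            tr.run_tract(alpha, beta, spin_params)

    def test_results_frame_missing_marker(self, spin_params):
        profile = {"G1": 2.0}
        alpha, beta = simulate.gen_tract(profile, spin_params)
        beta["G1"] = tr.RelaxationSeries("G1", "beta", alpha["G1"].delays,
                                         alpha["G1"].intensities)
        frame = tr.results_to_frame(tr.run_tract(alpha, beta, spin_params, n_iter=10))
        assert bool(frame["indeterminate"].iloc[0])
        assert np.isnan(frame["tau_c_ns"].iloc[0])
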