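"""Noise construction, martingale behaviour and conditioned sampling of the
frequency/richness diffusions."""

import math

import numpy as np
import pytest

from specdrift.analytics import fixation_probability
from specdrift.diffusion import (
    STATUS_EXTINCT,
    STATUS_TRAIT0_FIXED,
    AcceptanceRateError,
    ConfigurationError,
    DiffusionSpec,
    covariation_arrays,
    covariation_estimate,
    mc_extinction,
    mc_fixation,
    noise_weights,
    simulate,
    simulate_conditioned,
    simulate_ensemble,
    step,
)
from specdrift.diffusion import _coefficients
from specdrift.params import CapacityConfig, MacroParams, ParameterError


def make_spec(variant="general", beta0=1.0, beta1=0.5, tau0=2.0, tau1=1.0,
              rho01=0.0, rho10=0.0, cap=None, **kw):
    macro = MacroParams(beta0, beta1, tau0, tau1, rho01, rho10)
    return DiffusionSpec(variant=variant, macro=macro,
                         cap=cap or CapacityConfig.none(), **kw)


class TestSpecValidation:
    def test_unknown_variant(self):
        with pytest.raises(ConfigurationError):
            make_spec(variant="bogus")

    def test_symmetry_constraints_enforced(self):
        with pytest.raises(ConfigurationError):
            make_spec(variant="sym_beta", beta0=1.0, beta1=0.9)
        with pytest.raises(ConfigurationError):
            make_spec(variant="neutral", tau0=2.0, tau1=1.0, beta0=1.0, beta1=1.0)

    def test_quasi_neutral_derives_kappa(self):
        spec = make_spec(variant="quasi_neutral", beta0=1.0, beta1=2.0, tau0=3.0, tau1=6.0)
        assert spec.kappa == pytest.approx(3.0)
        with pytest.raises(ConfigurationError):
            make_spec(variant="quasi_neutral", beta0=1.0, beta1=2.0, tau0=3.0, tau1=5.0)

    def test_logistic_variants_require_capacity(self):
        with pytest.raises(ConfigurationError):
            make_spec(variant="logistic_common")
        with pytest.raises(ConfigurationError):
            make_spec(variant="general", cap=CapacityConfig.common(5.0))


class TestNoiseConstruction:
    def test_unit_variance_mixing(self):
        p = np.linspace(0.01, 0.99, 25)
        u0, u1, w0, w1 = noise_weights(3.0, 1.0, p)
        np.testing.assert_allclose(u0**2 + u1**2, 1.0, atol=1e-12)
        np.testing.assert_allclose(w0**2 + w1**2, 1.0, atol=1e-12)

    def test_correlation_closed_form(self):
        tau0, tau1 = 3.0, 1.0
        p = np.linspace(0.01, 0.99, 25)
        u0, u1, w0, w1 = noise_weights(tau0, tau1, p)
        corr = u0 * w0 - u1 * w1
        expected = (tau0 - tau1) * np.sqrt(p * (1 - p)) / np.sqrt(
            (tau0 * p + tau1 * (1 - p)) * (tau0 * (1 - p) + tau1 * p)
        )
        np.testing.assert_allclose(corr, expected, atol=1e-12)

    def test_equal_turnover_gives_independent_noises(self):
        p = np.linspace(0.0, 1.0, 21)
        u0, u1, w0, w1 = noise_weights(2.0, 2.0, p)
        np.testing.assert_allclose(u0 * w0 - u1 * w1, 0.0, atol=1e-12)

    def test_empirical_step_covariance(self, rng):
        """Cov(dP, dR) over one Euler step equals (tau0-tau1) p(1-p) dt."""
        spec = make_spec(beta0=1.0, beta1=1.0, tau0=3.0, tau1=1.0)
        p0, r0, dt, n = 0.5, 10.0, 1e-3, 100000
        z = (rng.standard_normal(n), rng.standard_normal(n))
        p1, r1 = step(spec, (np.full(n, p0), np.full(n, r0)), dt, z)
        prods = (p1 - p0) * (r1 - r0)
        target = (spec.macro.tau0 - spec.macro.tau1) * p0 * (1 - p0) * dt
        se = prods.std(ddof=1) / math.sqrt(n)
        assert abs(prods.mean() - target) <= 3 * se

    def test_equal_turnover_step_increments_uncorrelated(self, rng):
        spec = make_spec(beta0=1.0, beta1=1.0, tau0=2.0, tau1=2.0)
        p0, r0, dt, n = 0.3, 8.0, 1e-3, 100000
        z = (rng.standard_normal(n), rng.standard_normal(n))
        p1, r1 = step(spec, (np.full(n, p0), np.full(n, r0)), dt, z)
        prods = (p1 - np.mean(p1)) * (r1 - np.mean(r1))
        se = prods.std(ddof=1) / math.sqrt(n)
        assert abs(prods.mean()) <= 3 * se


class TestStep:
    def test_boundary_absorbing_without_inflow(self, rng):
        spec = make_spec(rho01=0.5, rho10=0.0)
        for _ in range(20):
            z = (rng.standard_normal(), rng.standard_normal())
            p1, r1 = step(spec, (0.0, 5.0), 1e-3, z)
            assert p1 == 0.0

    def test_rejects_nonpositive_dt(self):
        spec = make_spec()
        with pytest.raises(ParameterError):
            step(spec, (0.5, 1.0), 0.0, (0.1, 0.2))

    def test_quasi_neutral_coefficients_match_general(self, rng):
        """Case-d diffusion coefficient equals sqrt(p(1-p)(b0(1-p)+b1 p) kappa / r)."""
        kappa = 2.5
        beta0, beta1 = 1.2, 0.8
        spec = make_spec(variant="quasi_neutral", beta0=beta0, beta1=beta1,
                         tau0=kappa * beta0, tau1=kappa * beta1)
        gen = make_spec(variant="general", beta0=beta0, beta1=beta1,
                        tau0=kappa * beta0, tau1=kappa * beta1)
        p = rng.uniform(0.01, 0.99, 100)
        r = rng.uniform(0.5, 50.0, 100)
        _, sp_q, _, _ = _coefficients(spec, p, r)
        _, sp_g, _, _ = _coefficients(gen, p, r)
        closed = np.sqrt(p * (1 - p) * (beta0 * (1 - p) + beta1 * p) * kappa / r)
        np.testing.assert_allclose(sp_q, closed, atol=1e-12)
        np.testing.assert_allclose(sp_q, sp_g, atol=1e-12)


class TestSimulate:
    def test_bounds_and_freezing(self):
        spec = make_spec(tau0=3.0, tau1=1.0)
        times, P, R, status = simulate_ensemble(spec, 0.5, 2.0, T=2.0, dt=1e-3,
                                                seed=11, n_paths=50)
        assert np.all((P >= 0) & (P <= 1)) and np.all(R >= 0)
        for j in range(50):
            if status[j] != 0:
                stop = np.argmax(
                    (P[j] == P[j, -1]) & (R[j] == R[j, -1])
                    if status[j] == STATUS_EXTINCT else (P[j] == P[j, -1])
                )
                # frozen from the absorption point onward
                assert np.all(P[j, stop:] == P[j, -1])

    def test_critical_feller_mean_is_initial_value(self):
        spec = make_spec(variant="feller", beta0=0.0, beta1=0.0, tau0=1.0, tau1=1.0)
        _, _, R, _ = simulate_ensemble(spec, 1.0, 1.0, T=1.0, dt=1e-3, seed=3,
                                       n_paths=4000)
        se = R[:, -1].std(ddof=1) / math.sqrt(4000)
        assert abs(R[:, -1].mean() - 1.0) <= 3 * se

    def test_neutral_wright_fisher_frequency_martingale(self):
        spec = make_spec(variant="wright_fisher", beta0=1.0, beta1=1.0,
                         tau0=1.0, tau1=1.0, gamma=0.0)
        _, P, _, _ = simulate_ensemble(spec, 0.3, 1.0, T=0.5, dt=1e-3, seed=4,
                                       n_paths=4000)
        se = P[:, -1].std(ddof=1) / math.sqrt(4000)
        assert abs(P[:, -1].mean() - 0.3) <= 3 * se

    def test_neutral_variant_frequency_martingale(self):
        spec = make_spec(variant="neutral", beta0=0.5, beta1=0.5, tau0=1.0, tau1=1.0)
        _, P, _, _ = simulate_ensemble(spec, 0.4, 20.0, T=1.0, dt=1e-3, seed=6,
                                       n_paths=4000)
        se = P[:, -1].std(ddof=1) / math.sqrt(4000)
        assert abs(P[:, -1].mean() - 0.4) <= 3 * se

    def test_single_path_wrapper_labels_absorption(self):
        spec = make_spec(variant="time_changed_X", tau0=1.0, tau1=1.0,
                         beta0=1.0, beta1=1.0)
        path = simulate(spec, 0.9, 1.0, T=50.0, dt=1e-3, seed=2)
        assert path.absorbed_trait in ("trait0_fixed", "trait1_fixed")
        tail = path.p[-10:]
        assert np.all(tail == tail[0]) and tail[0] in (0.0, 1.0)

    def test_logistic_feller_mean_tracks_logistic_ode(self):
        """Neutral common-capacity richness follows r' = beta r (1 - r/c) in mean."""
        from scipy.integrate import solve_ivp

        c, beta, r0 = 500.0, 1.0, 50.0
        spec = make_spec(variant="feller", beta0=beta, beta1=beta, tau0=1.0, tau1=1.0,
                         cap=CapacityConfig.common(c))
        times, _, R, _ = simulate_ensemble(spec, 1.0, r0, T=1.0, dt=1e-3, seed=10,
                                           n_paths=300)
        sol = solve_ivp(lambda _t, y: beta * y * (1 - y / c), (0, 1.0), [r0],
                        t_eval=times[::100], rtol=1e-10, atol=1e-10)
        mean = R[:, ::100].mean(axis=0)
        se = R[:, ::100].std(axis=0, ddof=1) / math.sqrt(300)
        z = (mean[1:] - sol.y[0][1:]) / se[1:]
        assert np.all(np.abs(z) <= 3.0)


class TestConditioned:
    def test_fixation_from_one_is_immediate(self):
        spec = make_spec(variant="time_changed_X")
        res = simulate_conditioned(spec, 1.0, 1.0, None, 1e-3, 1, 100)
        assert np.all(res.status == STATUS_TRAIT0_FIXED)

    def test_requires_absorbing_boundaries(self):
        spec = make_spec(rho01=0.5, rho10=0.5)
        with pytest.raises(ConfigurationError):
            simulate_conditioned(spec, 0.5, 1.0, None, 1e-3, 1, 10)

    def test_acceptance_floor_trips(self):
        # richness started far above a tiny capacity crashes through a
        # high extinction threshold before any frequency boundary is hit
        spec = make_spec(variant="logistic_common", beta0=5.0, beta1=5.0,
                         tau0=0.5, tau1=0.5, cap=CapacityConfig.common(0.01))
        with pytest.raises(AcceptanceRateError):
            simulate_conditioned(spec, 0.5, 1.0, 5.0, 1e-3, 5, 200, r_tol=0.5)

    def test_neutral_fixation_probability_is_initial_frequency(self):
        spec = make_spec(variant="time_changed_X", tau0=1.5, tau1=1.5)
        est = mc_fixation(spec, 0.3, 1.0, 1e-3, 21, 4000)
        assert abs(est.value - 0.3) <= 3 * est.std_error

    def test_skewed_turnover_fixation(self):
        spec = make_spec(variant="time_changed_X", tau0=2.0, tau1=1.0)
        est = mc_fixation(spec, 0.5, 1.0, 1e-3, 22, 6000)
        q = fixation_probability(0.5, 2.0, 1.0)
        assert abs(est.value - q) <= 3 * est.std_error


class TestExtinction:
    def test_feller_extinction_frequency(self):
        spec = make_spec(variant="feller", beta0=0.5, beta1=0.5, tau0=1.0, tau1=1.0)
        est = mc_extinction(spec, 1.0, T=15.0, dt=1e-3, seed=30, n_paths=3000)
        assert abs(est.value - math.exp(-1.0)) <= 3 * est.std_error


class TestCovariation:
    def test_plugin_zero_when_turnover_equal(self):
        spec = make_spec(beta0=1.0, beta1=0.5, tau0=2.0, tau1=2.0,
                         rho01=0.2, rho10=0.2)
        path = simulate(spec, 0.5, 10.0, T=0.5, dt=1e-3, seed=5)
        realized, plugin = covariation_estimate(path, spec.macro)
        np.testing.assert_array_equal(plugin, 0.0)

    def test_frozen_frequency_contributes_nothing_further(self):
        spec = make_spec(variant="time_changed_X", tau0=2.0, tau1=1.0)
        path = simulate(spec, 0.1, 1.0, T=60.0, dt=1e-3, seed=8)
        assert path.absorbed_trait != "none"
        realized, plugin = covariation_estimate(path, spec.macro)
        stop = np.argmax(path.p == path.p[-1])
        assert realized[-1] == pytest.approx(realized[stop], abs=1e-15)

    def test_realized_matches_plugin_in_mean(self):
        spec = make_spec(beta0=1.0, beta1=1.0, tau0=3.0, tau1=1.0,
                         rho01=0.3, rho10=0.3)
        times, P, R, _ = simulate_ensemble(spec, 0.5, 10.0, T=0.5, dt=1e-3,
                                           seed=14, n_paths=3000)
        realized, plugin = covariation_arrays(times, P, R, spec.macro)
        diff = realized[:, -1] - plugin[:, -1]
        se = diff.std(ddof=1) / math.sqrt(diff.size)
        assert abs(diff.mean()) <= 3 * se
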