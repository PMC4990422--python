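"""Kinetic fitters against analytic and ODE oracles; rate prediction."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from thermonet import (
    ConcentrationState,
    FitError,
    ModelError,
    TimeCourse,
    fit_hill_isotherm,
    fit_michaelis_menten,
    fit_quadratic_binding,
    fit_unwinding_timecourse,
    predict_k_unw,
    quadratic_isotherm,
)
from thermonet.synthetic import simulate_mst_series

TIMES = np.array([0.25, 0.5, 1, 2, 4, 8, 15, 30, 45, 60.0])


def two_rate(t, ku, ka):
    k = ku + ka
    return ku / k * (1 - np.exp(-k * t))


class TestUnwindingTimecourse:
    def test_noiseless_exact_recovery_without_annealing(self):
        tc = TimeCourse(TIMES, two_rate(TIMES, 0.2, 0.0))
        fit = fit_unwinding_timecourse(tc)
        assert fit.k_unw == pytest.approx(0.2, rel=1e-6)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-6)

    def test_two_rate_curve_matches_ode_oracle(self):
        """The closed form equals the integrated d[ss]/dt = ku(1-ss) - ka*ss."""
        ku, ka = 0.3, 0.1
        sol = solve_ivp(lambda t, y: ku * (1 - y) - ka * y, (0, 60), [0.0],
                        t_eval=TIMES, rtol=1e-10, atol=1e-12)
        assert np.allclose(sol.y[0], two_rate(TIMES, ku, ka), atol=1e-6)

    def test_amplitude_identity_on_noiseless_curve(self):
        """Fitted amplitude equals k_unw/(k_unw+k_ann); rate is 0.4/min."""
        tc = TimeCourse(TIMES, two_rate(TIMES, 0.3, 0.1))
        fit = fit_unwinding_timecourse(tc)
        assert fit.k_unw == pytest.approx(0.3, rel=1e-6)
        assert fit.k_ann == pytest.approx(0.1, rel=1e-6)
        assert fit.amplitude == pytest.approx(0.75, abs=1e-6)
        assert fit.k_obs == pytest.approx(0.4, rel=1e-6)

    def test_monte_carlo_recovery(self, rng):
        """200 noisy curves (sd 0.03): mean recovered k_unw within 5%."""
        ku, ka = 0.2, 0.05
        clean = two_rate(TIMES, ku, ka)
        fits = []
        for _ in range(200):
            noisy = clean + rng.normal(0, 0.03, TIMES.size)
            fits.append(fit_unwinding_timecourse(TimeCourse(TIMES, noisy)).k_unw)
        assert np.mean(fits) == pytest.approx(ku, rel=0.05)

    def test_too_few_points(self):
        with pytest.raises(FitError, match="4 time points"):
            fit_unwinding_timecourse(TimeCourse([1, 2, 3], [0.1, 0.2, 0.3]))

    def test_all_zero_signal(self):
        with pytest.raises(FitError, match="all-zero"):
            fit_unwinding_timecourse(TimeCourse(TIMES, np.zeros(TIMES.size)))

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ModelError, match="strictly increasing"):
            TimeCourse([1, 1, 2, 3], [0, 0.1, 0.2, 0.3])


class TestHillIsotherm:
    def test_recovery_with_noise(self, rng):
        K, n, kmax = 2e-7, 3.0, 1.0
        x = np.geomspace(2e-8, 2e-6, 10)
        y = kmax * x**n / (K**n + x**n) + rng.normal(0, 0.02, x.size)
        fit = fit_hill_isotherm(x, y)
        assert fit.hill_n == pytest.approx(n, abs=0.3)
        assert fit.K_half == pytest.approx(K, rel=0.15)

    def test_hyperbolic_half_saturation(self):
        K, kmax = 1e-7, 2.0
        x = np.geomspace(1e-9, 1e-5, 12)
        y = kmax * x / (K + x)
        fit = fit_hill_isotherm(x, y, fix_n=1.0)
        assert fit.K_half == pytest.approx(K, rel=1e-6)
        # response at x = K is half of k_max
        assert kmax * K / (K + K) == pytest.approx(fit.k_max / 2, rel=1e-6)

    def test_degenerate_responses(self):
        with pytest.raises(FitError, match="degenerate"):
            fit_hill_isotherm([1e-8, 1e-7, 1e-6, 1e-5], [0.5, 0.5, 0.5, 0.5])


class TestMichaelisMenten:
    def test_noiseless_exact(self):
        K, vmax = 3e-4, 1.5
        S = np.geomspace(1e-5, 1e-2, 10)
        fit = fit_michaelis_menten(S, vmax * S / (K + S))
        assert fit.K_half == pytest.approx(K, rel=1e-6)
        assert fit.v_max == pytest.approx(vmax, rel=1e-6)

    def test_rate_at_K_is_half_vmax(self):
        K, vmax = 3e-4, 1.0
        assert vmax * K / (K + K) == pytest.approx(vmax / 2)

    def test_noisy_replicates_median_within_10pct(self, rng):
        K, vmax = 3e-4, 1.0
        S = np.geomspace(1e-5, 5e-3, 10)
        Ks = []
        for _ in range(100):
            v = vmax * S / (K + S) + rng.normal(0, 0.03, S.size)
            Ks.append(fit_michaelis_menten(S, v).K_half)
        assert np.median(Ks) == pytest.approx(K, rel=0.10)

    def test_k_cat_from_enzyme_conc(self):
        K, vmax = 3e-4, 1.0
        S = np.geomspace(1e-5, 1e-2, 8)
        fit = fit_michaelis_menten(S, vmax * S / (K + S), enzyme_conc=0.5)
        assert fit.k_cat == pytest.approx(2.0, rel=1e-6)


class TestQuadraticBinding:
    def test_limit_small_site_concentration_is_hyperbola(self):
        K = 1e-8
        a = K / 1e6
        x = np.geomspace(1e-10, 1e-6, 30)
        assert np.abs(quadratic_isotherm(x, K, a) - x / (x + K)).max() < 1e-6

    def test_stoichiometric_limit_breakpoint(self):
        a = 3.6e-8
        f = quadratic_isotherm(np.array([a]), 0.0, a)
        assert f[0] == pytest.approx(1.0, abs=1e-9)
        f_half = quadratic_isotherm(np.array([a / 2]), 0.0, a)
        assert f_half[0] == pytest.approx(0.5, abs=1e-9)

    def test_recovery_from_noisy_mst_series(self):
        """MST-style design: 36 nM sites, K = 5 nM, 2% noise -> K +- 2 nM."""
        a, K = 3.6e-8, 5e-9
        x = np.geomspace(1e-9, 1e-6, 16)
        x, y = simulate_mst_series(K, a, x, sigma=0.02, seed=7)
        fit = fit_quadratic_binding(x, y, fixed_site_conc=a)
        assert fit.K_prime_half == pytest.approx(K, abs=2e-9)

    def test_invalid_site_concentration(self):
        with pytest.raises(FitError, match="positive"):
            fit_quadratic_binding([1e-9, 1e-8, 1e-7, 1e-6], [0.1, 0.3, 0.8, 1.0], 0.0)


class TestPredictUnwinding:
    def test_zero_atp_means_zero_rate(self, model, params):
        st = ConcentrationState({"D": 1e-6, "A": 2e-6, "G": 1e-7, "T": 0.0})
        assert predict_k_unw(model, params, st) == pytest.approx(0.0, abs=1e-12)

    def test_homogeneous_in_rate_constants(self, model, params):
        st = ConcentrationState({"D": 1e-7, "A": 2e-6, "G": 1e-7, "T": 4e-3})
        k1 = predict_k_unw(model, params, st)
        doubled = params.updated(k_max={k: 2 * v for k, v in params.k_max.items()})
        assert predict_k_unw(model, doubled, st) == pytest.approx(2 * k1, rel=1e-12)

    def test_bounded_by_largest_rate_constant(self, model, params, rng):
        kmax = max(params.k_max.values())
        for _ in range(5):
            st = ConcentrationState({
                "D": 10 ** rng.uniform(-8, -5), "A": 10 ** rng.uniform(-8, -5),
                "G": 10 ** rng.uniform(-8, -5), "T": 10 ** rng.uniform(-5, -2)})
            assert 0.0 <= predict_k_unw(model, params, st) <= kmax

    def test_trimer_saturation_approaches_its_rate(self, model, params):
        """Ded1p and ATP saturating, no partners: prediction -> k_max(trimer).

        The approach is asymptotic: the inactive RNA-bound Ded1p monomer
        competes for substrate until the trimer weight (cubic in free
        Ded1p) overwhelms it.
        """
        st = ConcentrationState({"D": 3e-3, "T": 4e-3})
        assert predict_k_unw(model, params, st) == pytest.approx(
            params.k_max["k_D3"], rel=0.10)
        # monotone approach from below
        lower = predict_k_unw(model, params, ConcentrationState({"D": 3e-4, "T": 4e-3}))
        assert lower < predict_k_unw(model, params, st) <= params.k_max["k_D3"]

    def test_prediction_is_occupancy_weighted_sum(self, model, params):
        """Dual route: prediction equals the manual sum over active classes."""
        from thermonet import substrate_partition

        st = ConcentrationState({"D": 2e-7, "A": 2e-6, "G": 1e-7, "T": 4e-3})
        part = substrate_partition(model, params, st)
        manual = sum(params.k_max[a.rate] * sum(part[s] for s in a.species)
                     for a in model.active)
        assert predict_k_unw(model, params, st) == pytest.approx(manual, rel=1e-12)

    def test_eif4a_atp_state_irrelevant_in_ded1p_eif4a_complex(self, model, params):
        """Both eIF4A ATP sub-states of D-A contribute with the same rate, so
        the prediction counts their combined occupancy once."""
        from thermonet import substrate_partition

        st = ConcentrationState({"D": 2e-7, "A": 2e-6, "T": 4e-3})
        part = substrate_partition(model, params, st)
        da = next(a for a in model.active if a.rate == "k_DA")
        occ_empty = part["DA-R-TD"]
        occ_bound = part["DA-R-TD-TA"]
        assert occ_empty > 0 and occ_bound > 0
        manual = params.k_max["k_DA"] * (occ_empty + occ_bound)
        others = sum(params.k_max[a.rate] * sum(part[s] for s in a.species)
                     for a in model.active if a.rate != "k_DA")
        assert predict_k_unw(model, params, st) == pytest.approx(manual + others, rel=1e-12)

    def test_missing_rate_parameter(self, model, params):
        from thermonet import ParameterSet

        incomplete = ParameterSet(dict(params.K), {"k_D3": 1.0}, params.fixed)
        with pytest.raises(ModelError, match="missing rate"):
            predict_k_unw(model, incomplete, ConcentrationState({"D": 1e-7, "T": 4e-3}))


class TestUnitInvariance:
    def test_fitters_invariant_to_joint_rescaling(self, rng):
        """Rescaling doses and K together leaves fitted shape parameters fixed."""
        K, n, kmax = 2e-7, 2.0, 1.0
        x = np.geomspace(2e-8, 2e-6, 10)
        y = kmax * x**n / (K**n + x**n)
        fit_M = fit_hill_isotherm(x, y)
        fit_nM = fit_hill_isotherm(x * 1e9 / 1e9, y)  # same scale sanity
        scale = 1e3
        fit_scaled = fit_hill_isotherm(x * scale, y)
        assert fit_scaled.K_half == pytest.approx(fit_M.K_half * scale, rel=1e-5)
        assert fit_scaled.hill_n == pytest.approx(fit_M.hill_n, rel=1e-5)
        assert fit_nM.k_max == pytest.approx(fit_M.k_max, rel=1e-9)
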