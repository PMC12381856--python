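"""Forward model of three-state irreversible unfolding: rates,
propagation, signals and curve descriptors."""

import numpy as np
import pytest

from crypticfold import (
    ExperimentCurve,
    KineticParams,
    barrier_at,
    bcm_from_spectrum,
    curve_metrics,
    dsc_signal,
    mre_convert,
    propagate_isothermal,
    propagate_scan,
    rate_constant,
    reversibility_ratio,
    spectro_signal,
    state_fraction_sls_correlation,
)
from crypticfold.kinetics import KineticsError, rate_from_barrier


class TestRateConstant:
    def test_unity_at_tstar(self, truth_params):
        assert rate_constant(truth_params, 1, truth_params.Tstar1) == pytest.approx(1.0)
        assert rate_constant(truth_params, 2, truth_params.Tstar2) == pytest.approx(1.0)

    def test_zero_activation_energy_gives_unit_rate_everywhere(self):
        p = KineticParams(Ea1=0.0, Tstar1=330.0, Ea2=0.0, Tstar2=340.0)
        for T in (280.0, 320.0, 390.0):
            assert rate_constant(p, 1, T) == pytest.approx(1.0)

    def test_arbitrary_precision_oracle(self):
        # frozen from an independent sympy evaluation of
        # exp((200000/8.314)*(1/340 - 1/350))
        p = KineticParams(Ea1=200.0, Tstar1=340.0, Ea2=100.0, Tstar2=350.0)
        assert rate_constant(p, 1, 350.0) == pytest.approx(
            7.54961519784327, rel=1e-12)

    def test_monotone_in_temperature(self, truth_params):
        T = np.linspace(300.0, 380.0, 50)
        k = rate_constant(truth_params, 1, T)
        assert np.all(np.diff(k) > 0)

    def test_nonpositive_temperature_rejected(self, truth_params):
        with pytest.raises(KineticsError):
            rate_constant(truth_params, 1, -5.0)


class TestPropagateScan:
    def test_cold_scan_stays_native(self):
        p = KineticParams(Ea1=200.0, Tstar1=370.0, Ea2=200.0, Tstar2=380.0)
        fr = propagate_scan(p, 280.0, 305.0, 1.0)
        assert np.all(fr.xN >= 0.999)

    @pytest.mark.parametrize("v", [0.5, 1.0, 2.0])
    def test_conservation(self, sharp_params, v):
        fr = propagate_scan(sharp_params, 293.15, 363.15, v)
        assert fr.conservation_defect() < 1e-9

    def test_monotone_native_decay(self, truth_params):
        fr = propagate_scan(truth_params, 293.15, 363.15, 1.0)
        assert np.all(np.diff(fr.xN) <= 1e-12)

    def test_matches_fine_step_explicit_euler(self, truth_params):
        """Brute-force explicit Euler at 1e-4 K steps as oracle (the
        step is chosen so the oracle's own first-order error, ~5e-6
        here, stays below the 1e-5 comparison tolerance)."""
        T0, T1, v = 320.0, 338.0, 1.0
        h = 1e-4
        fine = np.arange(T0, T1 + h / 2, h)
        k1 = rate_constant(truth_params, 1, fine)
        k2 = rate_constant(truth_params, 2, fine)
        xn = np.empty(fine.size)
        xi = np.empty(fine.size)
        xn[0], xi[0] = 1.0, 0.0
        for j in range(fine.size - 1):
            xn[j + 1] = xn[j] + h * (-k1[j] * xn[j] / v)
            xi[j + 1] = xi[j] + h * ((k1[j] * xn[j] - k2[j] * xi[j]) / v)
        stride = 10000
        grid = fine[::stride]
        fr = propagate_scan(truth_params, T0, T1, v, grid=grid)
        assert np.max(np.abs(fr.xN - xn[::stride])) < 1e-5
        assert np.max(np.abs(fr.xI - xi[::stride])) < 1e-5

    def test_exp_stepper_matches_adaptive_reference(self, sharp_params):
        grid = np.linspace(293.15, 363.15, 150)
        fa = propagate_scan(sharp_params, 0, 0, 1.0, grid=grid, method="exp")
        fb = propagate_scan(sharp_params, 0, 0, 1.0, grid=grid, method="ivp")
        assert np.max(np.abs(fa.xN - fb.xN)) < 1e-6
        assert np.max(np.abs(fa.xI - fb.xI)) < 1e-6

    def test_invalid_inputs(self, truth_params):
        with pytest.raises(KineticsError):
            propagate_scan(truth_params, 350.0, 320.0, 1.0)
        with pytest.raises(KineticsError):
            propagate_scan(truth_params, 300.0, 350.0, -1.0)


class TestPropagateIsothermal:
    def test_initial_condition(self, truth_params):
        fr = propagate_isothermal(truth_params, 330.0, np.array([0.0, 1.0, 5.0]))
        assert fr.xN[0] == 1.0 and fr.xI[0] == 0.0 and fr.xD[0] == 0.0

    def test_single_step_limit(self, truth_params):
        t = np.linspace(0.0, 10.0, 50)
        fr = propagate_isothermal(truth_params, 333.0, t, k2_zero=True)
        k1 = rate_constant(truth_params, 1, 333.0)
        assert np.allclose(fr.xD, 0.0, atol=1e-12)
        assert np.allclose(fr.xI, 1.0 - np.exp(-k1 * t), atol=1e-12)

    def test_degenerate_rates_match_ode(self):
        # k1 == k2 == 1/min exactly at both Tstar
        p = KineticParams(Ea1=250.0, Tstar1=335.0, Ea2=250.0, Tstar2=335.0)
        t = np.linspace(0.0, 5.0, 40)
        fr = propagate_isothermal(p, 335.0, t)
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda _, y: [-y[0], y[0] - y[1]], (0, t[-1]), [1.0, 0.0],
            t_eval=t, rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(fr.xN - sol.y[0])) < 1e-6
        assert np.max(np.abs(fr.xI - sol.y[1])) < 1e-6

    def test_scan_consistency_at_constant_temperature(self, truth_params):
        """Analytic isothermal fractions agree with the scan ODE solved
        over a vanishing temperature ramp."""
        T = 334.0
        t = np.linspace(0.0, 2.0, 30)
        iso = propagate_isothermal(truth_params, T, t)
        # a scan over [T, T + v*t_max] with tiny v spends the same time
        v = 1e-5
        fr = propagate_scan(truth_params, T, T + v * t[-1], v,
                            grid=T + v * t, substep=v * t[-1] / 2000)
        assert np.max(np.abs(iso.xN - fr.xN)) < 1e-6
        assert np.max(np.abs(iso.xI - fr.xI)) < 1e-6


class TestSignals:
    def test_dsc_zero_enthalpies(self, truth_params):
        fr = propagate_scan(truth_params, 293.15, 363.15, 1.0)
        p0 = KineticParams(**{**truth_params.as_dict(), "dHcal1": 0.0, "dHcal2": 0.0})
        assert np.allclose(dsc_signal(p0, fr, 1.0), 0.0)

    @pytest.mark.parametrize("v", [0.5, 1.0, 2.0])
    def test_dsc_area_conservation(self, sharp_params, v):
        fr = propagate_scan(sharp_params, 283.15, 373.15, v, n_grid=2000)
        cp = dsc_signal(sharp_params, fr, v)
        area = np.trapezoid(cp, fr.grid)
        total = sharp_params.dHcal1 + sharp_params.dHcal2
        assert area == pytest.approx(total, rel=0.01)

    def test_dsc_peak_shifts_with_scan_rate(self, truth_params):
        peaks = []
        for v in (0.3, 0.5, 1.0, 2.0):
            fr = propagate_scan(truth_params, 293.15, 363.15, v, n_grid=2000)
            cp = dsc_signal(truth_params, fr, v)
            peaks.append(fr.grid[np.argmax(cp)])
        assert np.all(np.diff(peaks) > 0)

    def test_dsc_scan_rate_mismatch_rejected(self, truth_params):
        fr = propagate_scan(truth_params, 293.15, 363.15, 1.0)
        with pytest.raises(KineticsError):
            dsc_signal(truth_params, fr, 2.0)

    def test_spectro_constant_baselines(self, truth_params):
        fr = propagate_scan(truth_params, 293.15, 363.15, 1.0)
        base = {s: (5.0, 0.0) for s in "NID"}
        assert np.allclose(spectro_signal(fr, base), 5.0)

    def test_spectro_pure_native(self):
        from crypticfold.kinetics import StateFractions

        grid = np.array([300.0, 320.0, 340.0])
        fr = StateFractions(grid, np.ones(3), np.zeros(3), np.zeros(3))
        y = spectro_signal(fr, {"N": (2.0, 0.1), "I": (9.0, 9.0), "D": (7.0, 7.0)},
                           Tref=300.0)
        assert np.allclose(y, 2.0 + 0.1 * (grid - 300.0))

    def test_spectro_hand_computed_mixture(self):
        from crypticfold.kinetics import StateFractions

        grid = np.array([300.0, 310.0])
        fr = StateFractions(grid, np.array([0.5, 0.2]), np.array([0.3, 0.3]),
                            np.array([0.2, 0.5]))
        base = {"N": (1.0, 0.0), "I": (2.0, 0.1), "D": (3.0, 0.0)}
        y = spectro_signal(fr, base, Tref=300.0)
        # hand arithmetic: at 300 K: .5*1 + .3*2 + .2*3 = 1.7
        #                 at 310 K: .2*1 + .3*(2+1) + .5*3 = 2.6
        assert y == pytest.approx([1.7, 2.6])


class TestBarriers:
    def test_default_grid_is_40_60_80C(self, truth_params):
        rep = barrier_at(truth_params)
        assert np.allclose(rep.temperatures, [313.15, 333.15, 353.15])

    def test_value_at_tstar_closed_form(self):
        # frozen from sympy: -R*333*ln((1/60)*h/(kB*333))/1000
        p = KineticParams(Ea1=300.0, Tstar1=333.0, Ea2=300.0, Tstar2=333.0)
        rep = barrier_at(p, [333.0])
        assert rep.dG1[0] == pytest.approx(93.196621045225, rel=1e-10)

    def test_roundtrip_to_rate(self, truth_params):
        rep = barrier_at(truth_params, [313.15, 333.15, 353.15])
        for T, dg in zip(rep.temperatures, rep.dG1):
            k = rate_constant(truth_params, 1, T)
            assert rate_from_barrier(dg, T) == pytest.approx(k, rel=1e-9)

    def test_barriers_decrease_with_temperature_for_high_ea(self):
        p = KineticParams(Ea1=300.0, Tstar1=340.0, Ea2=300.0, Tstar2=350.0)
        T = np.linspace(300.0, 370.0, 71)
        rep = barrier_at(p, T)
        assert np.all(np.diff(rep.dG1) < 0)
        assert np.all(np.diff(rep.dG2) < 0)


class TestCurveDescriptors:
    def test_bcm_trivia(self):
        assert bcm_from_spectrum([330.0], [7.0]) == 330.0
        assert bcm_from_spectrum([300.0, 400.0], [1.0, 3.0]) == 375.0
        wl = np.linspace(300, 400, 101)
        sym = np.exp(-((wl - 350.0) ** 2) / 200.0)
        assert bcm_from_spectrum(wl, sym) == pytest.approx(350.0)
        with pytest.raises(KineticsError):
            bcm_from_spectrum([300.0, 310.0], [0.0, 0.0])

    def test_mre_arithmetic(self):
        assert mre_convert(0.0, 33000, 300, 0.175, 0.1) == 0.0
        v1 = mre_convert(10.0, 33000, 300, 0.175, 0.1)
        assert v1 == pytest.approx(6285714.285714285)
        assert mre_convert(10.0, 33000, 300, 0.35, 0.1) == pytest.approx(v1 / 2)
        with pytest.raises(KineticsError):
            mre_convert(1.0, 33000, 300, 0.0, 0.1)

    def test_tm_peak_on_gaussian(self):
        T = np.linspace(300, 370, 141)
        y = np.exp(-((T - 338.0) ** 2) / 20.0)
        c = ExperimentCurve("DSC", T, y, scan_rate=1.0)
        assert curve_metrics(c, "tm_peak") == pytest.approx(338.0)

    def test_tm_midpoint_on_logistic(self):
        T = np.linspace(300, 360, 200)
        y = 1.0 / (1.0 + np.exp(-(T - 330.0) / 2.0))
        c = ExperimentCurve("DSF_BCM", T, y, scan_rate=1.0)
        assert curve_metrics(c, "tm_midpoint") == pytest.approx(330.0, abs=0.01)

    def test_tm_midpoint_rejects_non_sigmoid(self, rng):
        T = np.linspace(300, 360, 100)
        c = ExperimentCurve("DSF_BCM", T, rng.normal(size=100), scan_rate=1.0)
        with pytest.raises(KineticsError):
            curve_metrics(c, "tm_midpoint")

    def test_agg_max_respects_window(self):
        T = np.linspace(283.15, 373.15, 400)
        y = np.where(np.abs(T - 340.0) < 0.5, 4278.0, 100.0)
        y[T > 360.0] = 9999.0  # outside the 20-80 degC window
        c = ExperimentCurve("SLS", T, y, scan_rate=1.0)
        assert curve_metrics(c, "agg_max") == 4278.0

    def test_t_onset(self):
        T = np.linspace(300, 360, 300)
        y = np.where(T >= 345.0, 50.0, 0.0) + 0.01 * np.sin(T)
        c = ExperimentCurve("SLS", T, y, scan_rate=1.0)
        onset = curve_metrics(c, "t_onset")
        assert 344.5 <= onset <= 345.5

    def test_reversibility_ratio(self):
        T = np.linspace(300, 360, 200)
        y = np.exp(-((T - 330.0) ** 2) / 30.0)
        first = ExperimentCurve("DSC", T, y, scan_rate=1.0)
        same = ExperimentCurve("DSC", T, y.copy(), scan_rate=1.0)
        zero = ExperimentCurve("DSC", T, np.zeros_like(y), scan_rate=1.0)
        scaled = ExperimentCurve("DSC", T, 0.29 * y, scan_rate=1.0)
        assert reversibility_ratio(first, same)[0] == pytest.approx(100.0)
        assert reversibility_ratio(first, zero)[0] == pytest.approx(0.0)
        assert reversibility_ratio(first, scaled)[0] == pytest.approx(29.0)
        with pytest.raises(KineticsError):
            reversibility_ratio(zero, first)


class TestSLSCorrelation:
    @pytest.mark.parametrize("species", ["I", "D"])
    def test_exact_fraction_recovered(self, truth_params, species):
        from crypticfold.synthetic import gen_sls_curve

        sls = gen_sls_curve(truth_params, v=1.0, follows=species, noise_sd=0.0)
        res = state_fraction_sls_correlation(truth_params, 1.0, sls)
        assert res["best_match"] == species
        assert res["r"][species] == pytest.approx(1.0, abs=1e-9)

    def test_noisy_intermediate_tracking(self, truth_params):
        from crypticfold.synthetic import gen_sls_curve

        sls = gen_sls_curve(truth_params, v=1.0, follows="I",
                            noise_sd=0.05, seed=3)
        res = state_fraction_sls_correlation(truth_params, 1.0, sls)
        assert res["best_match"] == "I"
        assert res["r"]["I"] > 0.9

    def test_constant_signal_flagged(self, truth_params):
        T = np.linspace(300, 360, 100)
        sls = ExperimentCurve("SLS", T, np.ones(100), scan_rate=1.0)
        with pytest.raises(KineticsError):
            state_fraction_sls_correlation(truth_params, 1.0, sls)
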