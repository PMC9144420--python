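"""Transit-compartment PK model, NCA metrics, and daily exposure."""

import numpy as np
import pytest
from scipy import integrate

from hupkpd.dosing import AnthroSeries, DailyDoseSeries
from hupkpd.pk import (
    PKParameters,
    auc_exact,
    blood_volume,
    daily_average_cp,
    nca_metrics,
    plasma_volume,
    simulate_daily_exposure,
    simulate_plasma,
    transit_input_rate,
    ug_per_ml_to_uM,
)


class TestVolumes:
    def test_small_child_weight_scaling(self):
        assert blood_volume(20.0, 110.0, "male") == pytest.approx(1.400)

    def test_nadler_male(self):
        # 0.3669·1.70³ + 0.03219·70 + 0.6041 = 4.65998
        assert blood_volume(70.0, 170.0, "male") == pytest.approx(4.660, abs=5e-4)

    def test_nadler_female(self):
        assert blood_volume(60.0, 160.0, "female") == pytest.approx(3.627, abs=5e-4)

    def test_literal_centimeter_flag(self):
        # the (dimensionally implausible) printed form cubes centimeters
        v = blood_volume(70.0, 170.0, "male", nadler_literal_cm=True)
        assert v == pytest.approx(0.3669 * 170**3 + 0.03219 * 70 + 0.6041)

    def test_invalid_anthropometry_rejected(self):
        with pytest.raises(ValueError):
            blood_volume(-1.0, 150.0, "male")

    def test_plasma_volume(self):
        assert plasma_volume(4.0, 25.0) == pytest.approx(3.0)
        assert plasma_volume(1.4, 23.46) == pytest.approx(1.0716, abs=5e-5)
        assert plasma_volume(4.0, 1e-9) == pytest.approx(4.0)

    def test_plasma_volume_hct_range(self):
        with pytest.raises(ValueError):
            plasma_volume(4.0, 0.0)
        with pytest.raises(ValueError):
            plasma_volume(4.0, 100.0)


class TestTransitInput:
    def test_zero_at_time_zero_for_positive_nt(self, pk_population_mean):
        assert transit_input_rate(0.0, 500.0, pk_population_mean) == 0.0

    def test_integrates_to_bioavailable_dose(self, pk_population_mean):
        p = pk_population_mean
        total, _ = integrate.quad(lambda t: transit_input_rate(t, 500.0, p), 0, np.inf)
        assert total == pytest.approx(p.F * 500.0, rel=1e-8)

    @pytest.mark.parametrize("nt", [0, 1, 2, 5])
    def test_matches_integer_chain_ode(self, nt):
        """Gamma-density input == terminal outflow of an explicit first-order chain."""
        F, ktr, dose = 0.4, 3.0, 500.0
        p = PKParameters(F=F, ktr=ktr, Nt=float(nt), ke=0.5)
        n_comp = nt + 1

        def chain_rhs(t, a):
            da = np.empty(n_comp)
            da[0] = -ktr * a[0]
            for i in range(1, n_comp):
                da[i] = ktr * (a[i - 1] - a[i])
            return da

        a0 = np.zeros(n_comp)
        a0[0] = F * dose
        t_eval = np.linspace(0.05, 12.0, 60)
        sol = integrate.solve_ivp(chain_rhs, (0, 12.0), a0, t_eval=t_eval,
                                  rtol=1e-11, atol=1e-13)
        oracle = ktr * sol.y[-1]
        model = transit_input_rate(t_eval, dose, p)
        assert np.max(np.abs(model - oracle) / np.max(oracle)) < 1e-6

    def test_negative_time_rejected(self, pk_population_mean):
        with pytest.raises(ValueError):
            transit_input_rate(-0.1, 500.0, pk_population_mean)


class TestSimulatePlasma:
    def test_zero_dose_gives_zero_curve(self, pk_population_mean):
        prof = simulate_plasma(0.0, pk_population_mean, 1.77)
        assert np.all(prof.Cp == 0.0)

    def test_bateman_tmax_for_single_compartment(self):
        # Nt=0 reduces to first-order absorption: Tmax = ln(ktr/ke)/(ktr-ke)
        p = PKParameters(F=0.5, ktr=2.0, Nt=0.0, ke=0.5)
        prof = simulate_plasma(500.0, p, 2.0)
        m = nca_metrics(prof, p)
        assert m.Tmax == pytest.approx(np.log(4.0) / 1.5, abs=1e-4)

    def test_auc_to_infinity_is_dose_over_clearance(self, pk_population_mean):
        p, dose, vp = pk_population_mean, 740.0, 1.77
        auc_tot = auc_exact(2000.0, dose, p, vp)
        assert auc_tot == pytest.approx(p.F * dose / (p.ke * vp), rel=1e-8)

    def test_mass_balance(self, pk_population_mean):
        """F·D = plasma amount + gut remainder + eliminated, at several times."""
        from hupkpd.pk import _absorbed_by, _plasma_amount

        p, dose, vp = pk_population_mean, 740.0, 1.77
        for T in (0.5, 2.0, 8.0, 24.0):
            ap = float(_plasma_amount(np.array([T]), dose, p)[0])
            absorbed = _absorbed_by(T, dose, p)
            gut = p.F * dose - absorbed
            eliminated = p.ke * auc_exact(T, dose, p, vp) * vp
            assert ap + gut + eliminated == pytest.approx(p.F * dose, rel=1e-8)

    def test_cmax_scales_with_dose_tmax_does_not(self, pk_population_mean):
        m1 = nca_metrics(simulate_plasma(400.0, pk_population_mean, 1.77), pk_population_mean)
        m2 = nca_metrics(simulate_plasma(800.0, pk_population_mean, 1.77), pk_population_mean)
        assert m2.Cmax == pytest.approx(2 * m1.Cmax, rel=1e-6)
        assert m2.Tmax == pytest.approx(m1.Tmax, abs=1e-5)


class TestNCAMetrics:
    def test_mrt_is_aumc_over_auc(self, pk_population_mean):
        m = nca_metrics(simulate_plasma(500.0, pk_population_mean, 1.77), pk_population_mean)
        assert m.MRT_inf == m.AUMC_inf / m.AUC_inf
        assert m.AUC <= m.AUC_inf

    def test_cmax_agrees_with_dense_resimulation(self, pk_population_mean):
        p = pk_population_mean
        prof = simulate_plasma(500.0, p, 1.77, np.linspace(0, 24, 481))  # 3-min grid
        m = nca_metrics(prof, p)
        dense = simulate_plasma(500.0, p, 1.77, np.linspace(0, 24, 4801))
        assert m.Cmax == pytest.approx(dense.Cp.max(), rel=1e-3)

    def test_lambda_z_equals_ke(self, pk_population_mean):
        m = nca_metrics(simulate_plasma(500.0, pk_population_mean, 1.77), pk_population_mean)
        assert m.lambda_z == pk_population_mean.ke

    def test_terminal_slope_matches_ke(self):
        # when absorption is much faster than elimination the log-linear
        # terminal slope of the simulated curve is ke itself
        p = PKParameters(F=0.3, ktr=8.0, Nt=1.0, ke=0.4)
        prof = simulate_plasma(500.0, p, 2.0)
        mask = prof.t >= 12.0
        slope = np.polyfit(prof.t[mask], np.log(prof.Cp[mask]), 1)[0]
        assert -slope == pytest.approx(p.ke, rel=1e-3)

    def test_short_grid_rejected(self, pk_population_mean):
        prof = simulate_plasma(500.0, pk_population_mean, 1.77, np.linspace(0, 8, 100))
        with pytest.raises(ValueError):
            nca_metrics(prof, pk_population_mean)


class TestDailyAverage:
    def test_zero_profile(self, pk_population_mean):
        prof = simulate_plasma(0.0, pk_population_mean, 1.77)
        assert daily_average_cp(prof) == (0.0, 0.0)

    def test_cohort_mean_auc_implies_printed_average(self):
        # AUC∞ of 92.98 µg·h/mL over 24 h → 3.874 µg/mL → 50.94 µM
        cbar = 92.98 / 24.0
        assert cbar == pytest.approx(3.874, abs=5e-4)
        assert ug_per_ml_to_uM(cbar) == pytest.approx(50.94, abs=5e-3)

    def test_micromolar_conversion_roundtrip(self):
        assert ug_per_ml_to_uM(3.874) == pytest.approx(3.874 * 1000 / 76.055)


def _flat_anthro(days=10):
    return AnthroSeries(age_years=np.array([10.0, 12.0]), weight_kg=np.array([30.0, 30.0]),
                        height_cm=np.array([130.0, 130.0]), hct_percent=np.array([25.0, 25.0]),
                        sex="male")


def _series(dose_mg):
    dose_mg = np.asarray(dose_mg, dtype=float)
    n = dose_mg.size
    return DailyDoseSeries(
        day_index=np.arange(n), dose_mg=dose_mg, dose_mg_per_kg=dose_mg / 30.0,
        adherent=dose_mg > 0, extra_carryover=np.array([0]),
    )


class TestDailyExposure:
    def test_all_nonadherent_gives_zero_exposure(self, pk_population_mean):
        exp = simulate_daily_exposure(_series(np.zeros(5)), pk_population_mean, _flat_anthro())
        assert np.all(exp.cbar_uM == 0.0)

    def test_constant_dose_constant_exposure(self, pk_population_mean):
        exp = simulate_daily_exposure(_series(np.full(5, 600.0)), pk_population_mean, _flat_anthro())
        assert np.ptp(exp.cbar_uM) == 0.0
        assert np.all(exp.cbar_uM > 0.0)

    def test_linearity_in_dose(self, pk_population_mean):
        exp = simulate_daily_exposure(_series([600.0, 1200.0, 600.0]), pk_population_mean, _flat_anthro())
        assert exp.cbar_uM[1] == pytest.approx(2 * exp.cbar_uM[0], rel=1e-9)
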