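"""Erythropoiesis + MCV model: rate laws, steady states, simulation."""

import numpy as np
import pytest

from hupkpd.erythro import (
    ErythroParams,
    ErythroState,
    drug_free_steady_state,
    erythro_rhs,
    kde,
    kdse,
    kpe,
    simulate_erythro,
)


def _bisect_ss_ne(params, tol=1e-12):
    """Independent bisection oracle for the drug-free circulating pool."""
    f = lambda ne: kpe(ne, params) - params.kde_max * ne
    lo, hi = 0.0, params.kpe_max / params.kde_max
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * hi:
            break
    return 0.5 * (lo + hi)


class TestRateLaws:
    def test_proliferation_hill_limits(self, erythro_median):
        p = erythro_median
        assert kpe(0.0, p) == pytest.approx(p.kpe_max)
        assert kpe(p.psi_e, p) == pytest.approx(p.kpe_max / 2)
        assert kpe(1e20, p) < 1e-6 * p.kpe_max

    def test_drug_kill_hill_limits(self, erythro_median):
        p = erythro_median
        assert kdse(0.0, p) == 0.0
        assert kdse(p.Kdse50, p) == pytest.approx(p.kdse_max / 2)
        assert kdse(1e9, p) == pytest.approx(p.kdse_max, rel=1e-6)

    def test_death_rate_decreases_with_exposure(self, erythro_median):
        p = erythro_median
        assert kde(0.0, p) == pytest.approx(p.kde_max)
        assert kde(p.Kde50, p) == pytest.approx(p.kde_max / 2)
        grid = kde(np.linspace(0, 1000, 50), p)
        assert np.all(np.diff(grid) < 0)

    def test_negative_inputs_rejected(self, erythro_median):
        with pytest.raises(ValueError):
            kpe(-1.0, erythro_median)
        with pytest.raises(ValueError):
            kdse(-0.1, erythro_median)
        with pytest.raises(ValueError):
            kde(-0.1, erythro_median)


class TestRHS:
    def test_vanishes_at_drug_free_steady_state(self, erythro_median):
        ss = drug_free_steady_state(erythro_median)
        dy = erythro_rhs(ss, 0.0, erythro_median)
        scale = np.abs(ss.as_array())
        assert np.all(np.abs(dy) < 1e-8 * np.maximum(scale, 1.0))

    def test_mcv_fixed_point_independent_of_cell_counts(self, erythro_median):
        p = erythro_median
        cbar = 42.0
        state = ErythroState(Nse=1e10, Ne1=2e10, Ne2=3e10, Ne3=4e10, Ne=5e11,
                             Vm=p.alpha * cbar + p.Vm0)
        assert erythro_rhs(state, cbar, p)[5] == pytest.approx(0.0, abs=1e-12)

    def test_origin_only_produces_stem_cells(self, erythro_median):
        dy = erythro_rhs(np.zeros(6), 0.0, erythro_median)
        assert dy[0] == pytest.approx(erythro_median.kpe_max)
        assert np.all(dy[1:5] == 0.0)


class TestSteadyState:
    def test_matches_bisection_oracle(self, erythro_median):
        ss = drug_free_steady_state(erythro_median)
        assert ss.Ne == pytest.approx(_bisect_ss_ne(erythro_median), rel=1e-10)

    def test_oracle_agreement_for_random_draws(self, rng):
        for _ in range(10):
            p = ErythroParams(
                kpe_max=10 ** rng.uniform(11, 14), psi_e=10 ** rng.uniform(10, 12.5),
                gamma_e=rng.uniform(0.5, 4.0), kdse_max=rng.uniform(0.02, 0.7),
                Kdse50=rng.uniform(0.01, 4.0), kte=rng.uniform(0.05, 0.4),
                kde_max=rng.uniform(0.01, 0.06), Kde50=rng.uniform(60, 900),
                alpha=rng.uniform(0.2, 0.5), Vm0=rng.uniform(70, 100),
            )
            ss = drug_free_steady_state(p)
            assert ss.Ne == pytest.approx(_bisect_ss_ne(p), rel=1e-8)

    def test_steep_feedback_limit_pins_pool_at_psi(self):
        # γe→∞ turns the feedback into a switch at Ψe
        p = ErythroParams(kpe_max=2.1e12, psi_e=2.2e11, gamma_e=200.0, kdse_max=0.17,
                          Kdse50=0.43, kte=0.2, kde_max=0.03, Kde50=310, alpha=0.37, Vm0=85.0)
        assert p.kpe_max / (p.kde_max * p.psi_e) > 1
        assert drug_free_steady_state(p).Ne == pytest.approx(p.psi_e, rel=0.05)


class TestSimulation:
    def test_flat_from_steady_state_without_drug(self, erythro_median):
        ss = drug_free_steady_state(erythro_median)
        traj = simulate_erythro(erythro_median, np.zeros(200), ss)
        assert np.allclose(traj[-1], ss.as_array(), rtol=1e-7)

    def test_mcv_approaches_shifted_setpoint(self, erythro_median):
        # constant 50 µM with α=0.37 fL/µM shifts the MCV setpoint by +18.5 fL
        ss = drug_free_steady_state(erythro_median)
        traj = simulate_erythro(erythro_median, np.full(3000, 50.0), ss)
        assert traj[-1, 5] == pytest.approx(erythro_median.Vm0 + 18.5, abs=0.05)

    def test_mcv_rises_then_falls_with_exposure_steps(self, erythro_median):
        ss = drug_free_steady_state(erythro_median)
        cbar = np.concatenate([np.full(300, 50.0), np.zeros(300)])
        traj = simulate_erythro(erythro_median, cbar, ss)
        vm = traj[:, 5]
        assert vm[300] > vm[0]  # rise under drug
        assert vm[-1] < vm[300]  # fall after withdrawal

    def test_non_negativity_from_perturbed_start(self, erythro_median, rng):
        ss = drug_free_steady_state(erythro_median).as_array()
        init = ErythroState.from_array(ss * rng.uniform(0.2, 2.0, size=6))
        traj = simulate_erythro(erythro_median, np.full(400, 30.0), init)
        assert np.all(traj >= 0.0)

    def test_returns_to_steady_state_after_perturbation(self, erythro_median):
        ss = drug_free_steady_state(erythro_median)
        init = ErythroState.from_array(ss.as_array() * 1.3)
        traj = simulate_erythro(erythro_median, np.zeros(4000), init)
        assert np.allclose(traj[-1], ss.as_array(), rtol=1e-3)

    def test_rk4_agrees_with_lsoda(self, erythro_median):
        ss = drug_free_steady_state(erythro_median)
        cbar = np.concatenate([np.full(60, 55.0), np.zeros(30), np.full(60, 40.0)])
        a = simulate_erythro(erythro_median, cbar, ss, method="rk4")
        b = simulate_erythro(erythro_median, cbar, ss, method="lsoda")
        assert np.allclose(a, b, rtol=1e-5)

    def test_root_solve_matches_long_run_for_random_draws(self, rng):
        for _ in range(10):
            p = ErythroParams(
                kpe_max=10 ** rng.uniform(11.5, 13), psi_e=10 ** rng.uniform(10.5, 12),
                gamma_e=rng.uniform(1.0, 3.0), kdse_max=rng.uniform(0.05, 0.4),
                Kdse50=rng.uniform(0.1, 2.0), kte=rng.uniform(0.1, 0.3),
                kde_max=rng.uniform(0.02, 0.05), Kde50=rng.uniform(100, 600),
                alpha=rng.uniform(0.2, 0.5), Vm0=rng.uniform(75, 95),
            )
            ss = drug_free_steady_state(p)
            traj = simulate_erythro(p, np.zeros(6000), ErythroState.from_array(ss.as_array() * 1.2))
            assert np.allclose(traj[-1], ss.as_array(), rtol=2e-3)
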