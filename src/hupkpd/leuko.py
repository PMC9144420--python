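"""Leukopoiesis / absolute-neutrophil-count dynamics under hydroxyurea.

Mirrors the erythropoiesis model structure: a stem/progenitor pool Nsl with
Hill feedback from circulating neutrophils (a stand-in for the GM-CSF
loop), three maturation compartments, and a circulating pool Nl whose death
rate kdl is drug-independent.  Hydroxyurea acts only through the kill rate
kdsl(C̄p) on the stem compartment, so — unlike red cells — sustained
exposure unambiguously lowers the neutrophil steady state.  This
myelosuppression is the dose-limiting toxicity: clinicians titrate to the
maximum tolerated dose when ANC settles in the 2000-4000 cells/µL band.

With a steep feedback (large γl) and a long maturation chain the closed
loop can destabilize into sustained oscillations instead of a steady state;
``scan_dynamics`` classifies long-run behavior on a grid of constant
exposures and is used to screen parameter bounds for the ANC fit.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import optimize

from . import _kernels
from .erythro import _lsoda_daily

CELLS_PER_L_TO_PER_UL = 1e-6  # cells/µL = cells/L × 1e−6


@dataclass(frozen=True)
class LeukoParams:
    """Rate constants of the leukopoiesis model (units as in ErythroParams)."""

    kpl_max: float  # cells/L/day
    psi_l: float  # cells/L
    gamma_l: float
    kdsl_max: float  # 1/day
    Kdsl50: float  # µM
    ktl: float  # 1/day
    kdl: float  # 1/day

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "LeukoParams":
        return cls(*(float(x) for x in a))


@dataclass
class LeukoState:
    """Compartment cell concentrations (cells/L); Nl is the circulating ANC."""

    Nsl: float
    Nl1: float
    Nl2: float
    Nl3: float
    Nl: float

    def as_array(self) -> np.ndarray:
        return np.array([self.Nsl, self.Nl1, self.Nl2, self.Nl3, self.Nl])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "LeukoState":
        return cls(*(float(x) for x in a))


def kpl(Nl: float | np.ndarray, params: LeukoParams) -> float | np.ndarray:
    """Proliferation flux (cells/L/day), Hill-suppressed by circulating ANC."""
    Nl = np.asarray(Nl, dtype=float)
    if np.any(Nl < 0):
        raise ValueError("Nl must be non-negative")
    with np.errstate(over="ignore"):  # Nl >> Ψl overflows to inf → kpl 0
        out = params.kpl_max / (1.0 + (Nl / params.psi_l) ** params.gamma_l)
    return float(out) if out.ndim == 0 else out


def kdsl(cbar_uM: float | np.ndarray, params: LeukoParams) -> float | np.ndarray:
    """Drug-induced stem-cell kill rate (1/day), saturating in exposure."""
    c = np.asarray(cbar_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("exposure must be non-negative")
    out = params.kdsl_max * c / (params.Kdsl50 + c)
    return float(out) if out.ndim == 0 else out


def leuko_rhs(state: LeukoState | np.ndarray, cbar_uM: float, params: LeukoParams) -> np.ndarray:
    """Time derivative of the five-dimensional leukopoiesis state."""
    y = state.as_array() if isinstance(state, LeukoState) else np.asarray(state, dtype=float)
    dy = np.empty(5)
    _kernels._leuko_rhs(y, float(cbar_uM), params.as_array(), dy)
    return dy


def steady_state_leuko(params: LeukoParams, cbar_uM: float = 0.0) -> LeukoState:
    """Equilibrium at constant exposure (not necessarily stable).

    At equilibrium the chain passes the net stem outflow through, so the
    circulating pool solves kpl(Nl)·ktl/(ktl + kdsl) = kdl·Nl.
    """
    frac = params.ktl / (params.ktl + kdsl(cbar_uM, params))
    f = lambda nl: kpl(nl, params) * frac - params.kdl * nl
    hi = params.kpl_max * frac / params.kdl
    nl = optimize.brentq(f, 1e-30 * hi, hi, rtol=1e-14)
    through = params.kdl * nl / params.ktl  # Nl1..3 level
    # stem pool holds the proliferation flux divided by its total exit rate
    nsl = kpl(nl, params) / (params.ktl + kdsl(cbar_uM, params))
    return LeukoState(Nsl=nsl, Nl1=through, Nl2=through, Nl3=through, Nl=nl)


def drug_free_steady_state_leuko(params: LeukoParams) -> LeukoState:
    """Equilibrium at zero exposure: kpl(Nl) = kdl·Nl."""
    return steady_state_leuko(params, 0.0)


def _substeps(params: LeukoParams) -> int:
    rate = max(params.ktl + params.kdsl_max, params.kdl, params.ktl)
    return max(4, int(np.ceil(2.0 * rate)))


def simulate_leuko(
    params: LeukoParams,
    cbar_uM: np.ndarray,
    init: LeukoState,
    obs_days: np.ndarray | None = None,
    *,
    method: str = "rk4",
) -> np.ndarray:
    """Integrate over a daily exposure series; see ``simulate_erythro``."""
    cbar = np.ascontiguousarray(cbar_uM, dtype=float)
    y0 = init.as_array()
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    if method == "rk4":
        daily = _kernels.leuko_integrate(params.as_array(), cbar, y0, _substeps(params))
    elif method == "lsoda":
        daily = _lsoda_daily(lambda y, c: leuko_rhs(y, c, params), cbar, y0)
    else:
        raise ValueError(f"unknown method {method!r}")
    if obs_days is None:
        return daily
    return daily[np.asarray(obs_days, dtype=int)]


def in_mtd_band(anc_cells_per_uL: float, lo: float = 2000.0, hi: float = 4000.0) -> bool:
    """Whether an ANC value lies in the maximum-tolerated-dose target band."""
    return lo <= anc_cells_per_uL <= hi


def scan_dynamics(
    params: LeukoParams,
    cbar_grid: np.ndarray,
    *,
    t_run_days: int = 2000,
    rel_amplitude_threshold: float = 0.01,
) -> list[dict]:
    """Classify long-run behavior at each constant exposure level.

    Runs the model for ``t_run_days`` from a 10%-perturbed drug-free steady
    state (so an unstable equilibrium is actually probed rather than sat on)
    and inspects the final 20% of the trajectory: a peak-to-trough amplitude of
    the circulating pool above ``rel_amplitude_threshold`` of its mean marks
    a sustained oscillation, otherwise a steady state.  A deterministic
    numerical stand-in for a formal bifurcation scan, used to screen
    parameter bounds for the ANC fit.
    """
    init = LeukoState.from_array(drug_free_steady_state_leuko(params).as_array() * 1.1)
    results = []
    for c in np.asarray(cbar_grid, dtype=float):
        traj = simulate_leuko(params, np.full(t_run_days, c), init)
        tail = traj[int(0.8 * t_run_days):, 4]
        mean = float(np.mean(tail))
        amp = float(np.max(tail) - np.min(tail))
        oscillatory = mean > 0 and amp / mean > rel_amplitude_threshold
        results.append({
            "cbar_uM": float(c),
            "regime": "oscillatory" if oscillatory else "steady_state",
            "mean_Nl": mean,
            "rel_amplitude": amp / mean if mean > 0 else 0.0,
            "terminal_anc_per_uL": mean * CELLS_PER_L_TO_PER_UL,
        })
    return results
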