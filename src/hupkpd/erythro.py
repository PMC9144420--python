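"""Erythropoiesis and mean-cell-volume dynamics under hydroxyurea.

A five-compartment cell-kinetic model: a stem/early-progenitor pool Nse
proliferates at a rate down-regulated by circulating red cells (Hill
feedback standing in for the EPO loop), transitions through three
maturation-only precursor stages (Ne1-Ne3) at rate kte, and enters the
circulating pool Ne.  Hydroxyurea acts twice, in opposite directions:

* myelosuppression — a drug-dependent kill rate kdse(C̄p) on the
  proliferating stem compartment (saturating Hill form), and
* lifespan extension — the red-cell death rate kde(C̄p) *decreases* with
  exposure, reflecting reduced hemolysis of drug-exposed cells.

Mean cell volume is carried as a per-cell state: newly released cells enter
with volume Vm0 + α·C̄p (a linear drug effect on the inflowing volume), and

    dVm/dt = (α C̄p + Vm0 − Vm) · kte · Ne3 / Ne,

so for constant exposure the MCV steady state is exactly Vm0 + α·C̄p,
independent of every cell-kinetic parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import integrate as _sciint
from scipy import optimize

from . import _kernels


@dataclass(frozen=True)
class ErythroParams:
    """Rate constants of the erythropoiesis + MCV model.

    kpe_max : maximum proliferation flux (cells/L/day).
    psi_e : red-cell feedback scale Ψe (cells/L).
    gamma_e : feedback steepness γe.
    kdse_max, Kdse50 : maximum drug kill rate (1/day) and its
        half-saturation exposure (µM).
    kte : maturation/transition rate (1/day).
    kde_max, Kde50 : drug-free red-cell death rate (1/day) and the
        half-saturation exposure (µM) of its drug-induced reduction.
    alpha : MCV drug slope α (fL/µM).
    Vm0 : baseline inflowing cell volume (fL).
    """

    kpe_max: float
    psi_e: float
    gamma_e: float
    kdse_max: float
    Kdse50: float
    kte: float
    kde_max: float
    Kde50: float
    alpha: float
    Vm0: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "ErythroParams":
        return cls(*(float(x) for x in a))


@dataclass
class ErythroState:
    """Compartment cell concentrations (cells/L) and mean cell volume (fL)."""

    Nse: float
    Ne1: float
    Ne2: float
    Ne3: float
    Ne: float
    Vm: float

    def as_array(self) -> np.ndarray:
        return np.array([self.Nse, self.Ne1, self.Ne2, self.Ne3, self.Ne, self.Vm])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "ErythroState":
        return cls(*(float(x) for x in a))


def kpe(Ne: float | np.ndarray, params: ErythroParams) -> float | np.ndarray:
    """Proliferation flux (cells/L/day), Hill-suppressed by circulating RBC."""
    Ne = np.asarray(Ne, dtype=float)
    if np.any(Ne < 0):
        raise ValueError("Ne must be non-negative")
    with np.errstate(over="ignore"):  # Ne >> Ψe overflows to inf → kpe 0
        out = params.kpe_max / (1.0 + (Ne / params.psi_e) ** params.gamma_e)
    return float(out) if out.ndim == 0 else out


def kdse(cbar_uM: float | np.ndarray, params: ErythroParams) -> float | np.ndarray:
    """Drug-induced stem-cell kill rate (1/day), saturating in exposure."""
    c = np.asarray(cbar_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("exposure must be non-negative")
    out = params.kdse_max * c / (params.Kdse50 + c)
    return float(out) if out.ndim == 0 else out


def kde(cbar_uM: float | np.ndarray, params: ErythroParams) -> float | np.ndarray:
    """Red-cell death rate (1/day); decreases with exposure (longer lifespan)."""
    c = np.asarray(cbar_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("exposure must be non-negative")
    out = params.kde_max * (1.0 - c / (params.Kde50 + c))
    return float(out) if out.ndim == 0 else out


def erythro_rhs(state: ErythroState | np.ndarray, cbar_uM: float, params: ErythroParams) -> np.ndarray:
    """Time derivative of the six-dimensional erythro + MCV state.

    The MCV equation divides by Ne; a floor of 1 cell/L guards the
    (unphysical for this application) regime of a vanishing red-cell pool.
    """
    y = state.as_array() if isinstance(state, ErythroState) else np.asarray(state, dtype=float)
    dy = np.empty(6)
    _kernels._erythro_rhs(y, float(cbar_uM), params.as_array(), dy)
    return dy


def drug_free_steady_state(params: ErythroParams) -> ErythroState:
    """Equilibrium at zero exposure.

    At C̄p = 0 the chain is pass-through, so the circulating pool solves the
    scalar balance kpe(Ne) = kde_max·Ne and every upstream compartment holds
    kde_max·Ne/kte cells.  The root is bracketed on (0, kpe_max/kde_max].
    """
    f = lambda ne: kpe(ne, params) - params.kde_max * ne
    hi = params.kpe_max / params.kde_max
    if f(hi) > 0:
        raise RuntimeError("no positive steady state: production exceeds death at the bracket end")
    ne = optimize.brentq(f, 1e-30 * hi, hi, xtol=1e-300, rtol=1e-14)
    up = params.kde_max * ne / params.kte
    return ErythroState(Nse=up, Ne1=up, Ne2=up, Ne3=up, Ne=ne, Vm=params.Vm0)


def _substeps(params: ErythroParams) -> int:
    # λ·dt ≤ 0.5 keeps RK4 comfortably stable and accurate for these
    # smooth, mildly stiff kinetics
    rate = max(params.kte + params.kdse_max, params.kde_max, params.kte)
    return max(4, int(np.ceil(2.0 * rate)))


def simulate_erythro(
    params: ErythroParams,
    cbar_uM: np.ndarray,
    init: ErythroState,
    obs_days: np.ndarray | None = None,
    *,
    method: str = "rk4",
) -> np.ndarray:
    """Integrate the model over a daily exposure series.

    Parameters
    ----------
    cbar_uM : array of per-day average exposure (µM), day 0 first.
    init : state at day 0.
    obs_days : integer days at which to report the state (default: all day
        boundaries 0..n_days).
    method : "rk4" (fixed-step, default — fast, used inside optimizers) or
        "lsoda" (scipy adaptive reference path).

    Returns
    -------
    ndarray of shape (len(obs_days), 6): columns Nse, Ne1, Ne2, Ne3, Ne, Vm.
    """
    cbar = np.ascontiguousarray(cbar_uM, dtype=float)
    y0 = init.as_array()
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    if method == "rk4":
        daily = _kernels.erythro_integrate(params.as_array(), cbar, y0, _substeps(params))
    elif method == "lsoda":
        daily = _lsoda_daily(lambda y, c: erythro_rhs(y, c, params), cbar, y0)
    else:
        raise ValueError(f"unknown method {method!r}")
    if obs_days is None:
        return daily
    return daily[np.asarray(obs_days, dtype=int)]


def _lsoda_daily(rhs, cbar: np.ndarray, y0: np.ndarray) -> np.ndarray:
    """Reference integration: LSODA, restarted at each day boundary."""
    n_days = cbar.size
    out = np.empty((n_days + 1, y0.size))
    out[0] = y0
    y = y0.copy()
    d = 0
    while d < n_days:
        # batch consecutive days with identical exposure into one solve
        d2 = d + 1
        while d2 < n_days and cbar[d2] == cbar[d]:
            d2 += 1
        sol = _sciint.solve_ivp(
            lambda t, yy: rhs(yy, cbar[d]),
            (float(d), float(d2)), y,
            t_eval=np.arange(d + 1, d2 + 1, dtype=float),
            method="LSODA", rtol=1e-9, atol=1e-12 * max(1.0, float(np.max(np.abs(y)))),
        )
        if not sol.success:
            raise RuntimeError(f"PD ODE integration failed: {sol.message}")
        out[d + 1 : d2 + 1] = sol.y.T
        y = out[d2].copy()
        d = d2
    return out
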