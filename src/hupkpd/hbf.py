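"""Fetal-hemoglobin induction kinetics under hydroxyurea.

Hydroxyurea metabolizes to nitric oxide and related species that, through
the sGC/cGMP axis, activate γ-globin transcription.  The signaling cascade
is lumped into a single intermediate Ci (µM) produced from plasma drug by
Michaelis-Menten kinetics and degraded first-order; the mean per-cell fetal
hemoglobin Fm (pg/cell) is produced at a basal rate kbf plus a Hill-
activated rate driven by the intermediate, and degrades first-order:

    dCi/dt = kmet C̄p / (Kmet + C̄p) − kdi Ci
    dFm/dt = kbf + kaf Ci^n / (Kaf^n + Ci^n) − kdf Fm

The Hill denominator uses the half-saturation constant Kaf (the standard
form); ``literal_kaf_denominator=True`` substitutes kaf there instead, for
comparison with sources that print the activation constant in that slot.

Laboratory HbF% and MCH convert to the model observable under the
uniform-distribution assumption: Fm = (HbF%/100) × MCH.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from . import _kernels
from .erythro import _lsoda_daily


@dataclass(frozen=True)
class HbFParams:
    """Rate constants of the intermediate + HbF activation model.

    kmet : maximum intermediate production rate (µM/day).
    Kmet : Michaelis constant of intermediate production (µM).
    kdi : intermediate degradation rate (1/day).
    kbf : basal HbF production (pg/day).
    kaf : maximum activated HbF production (pg/day).
    Kaf : activation half-saturation (µM of intermediate).
    n : Hill coefficient of activation.
    kdf : HbF degradation rate (1/day).
    """

    kmet: float
    Kmet: float
    kdi: float
    kbf: float
    kaf: float
    Kaf: float
    n: float
    kdf: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    def as_array(self, *, literal_kaf_denominator: bool = False) -> np.ndarray:
        """Kernel parameter vector; the Hill half-saturation enters pre-raised
        to the power n (slot 5), using kaf there under the literal flag."""
        half = self.kaf if literal_kaf_denominator else self.Kaf
        return np.array(
            [self.kmet, self.Kmet, self.kdi, self.kbf, self.kaf, half**self.n, self.n, self.kdf]
        )

    @classmethod
    def from_array(cls, a: np.ndarray) -> "HbFParams":
        """Construct from plain field-order values (Kaf raw, not raised)."""
        return cls(*(float(x) for x in a))


@dataclass
class HbFState:
    """Intermediate concentration (µM) and mean-cell fetal hemoglobin (pg)."""

    Ci: float
    Fm: float

    def as_array(self) -> np.ndarray:
        return np.array([self.Ci, self.Fm])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "HbFState":
        return cls(Ci=float(a[0]), Fm=float(a[1]))


def hbf_rhs(
    state: HbFState | np.ndarray,
    cbar_uM: float,
    params: HbFParams,
    *,
    literal_kaf_denominator: bool = False,
) -> np.ndarray:
    """Time derivative of (Ci, Fm)."""
    y = state.as_array() if isinstance(state, HbFState) else np.asarray(state, dtype=float)
    if np.any(y < 0):
        raise ValueError("state must be non-negative")
    dy = np.empty(2)
    _kernels._hbf_rhs(y, float(cbar_uM), params.as_array(literal_kaf_denominator=literal_kaf_denominator), dy)
    return dy


def hbf_steady_state(
    cbar_uM: float,
    params: HbFParams,
    *,
    literal_kaf_denominator: bool = False,
) -> HbFState:
    """Closed-form fixed point at constant exposure.

    Ci* = kmet C̄p / ((Kmet + C̄p) kdi);
    Fm* = (kbf + kaf Ci*^n / (Kaf^n + Ci*^n)) / kdf.
    """
    if cbar_uM < 0:
        raise ValueError("exposure must be non-negative")
    ci = params.kmet * cbar_uM / ((params.Kmet + cbar_uM) * params.kdi)
    half = params.kaf if literal_kaf_denominator else params.Kaf
    act = params.kaf * ci**params.n / (half**params.n + ci**params.n) if ci > 0 else 0.0
    fm = (params.kbf + act) / params.kdf
    return HbFState(Ci=ci, Fm=fm)


def fm_from_labs(hbf_percent: float | np.ndarray, mch_pg: float | np.ndarray) -> float | np.ndarray:
    """Mean-cell fetal hemoglobin (pg) from lab HbF% and MCH.

    Assumes fetal hemoglobin is uniformly distributed across red cells:
    Fm = (HbF%/100) × MCH.
    """
    h = np.asarray(hbf_percent, dtype=float)
    m = np.asarray(mch_pg, dtype=float)
    if np.any((h < 0) | (h > 100)):
        raise ValueError("HbF% must lie in [0, 100]")
    if np.any(m <= 0):
        raise ValueError("MCH must be positive")
    out = h / 100.0 * m
    return float(out) if out.ndim == 0 else out


def _substeps(params: HbFParams) -> int:
    rate = max(params.kdi, params.kdf)
    return max(2, int(np.ceil(4.0 * rate)))


def simulate_hbf(
    params: HbFParams,
    cbar_uM: np.ndarray,
    init: HbFState,
    obs_days: np.ndarray | None = None,
    *,
    method: str = "rk4",
    literal_kaf_denominator: bool = False,
) -> np.ndarray:
    """Integrate over a daily exposure series; see ``simulate_erythro``.

    Returns shape ``(len(obs_days), 2)``: columns Ci, Fm.
    """
    cbar = np.ascontiguousarray(cbar_uM, dtype=float)
    y0 = init.as_array()
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    p = params.as_array(literal_kaf_denominator=literal_kaf_denominator)
    if method == "rk4":
        daily = _kernels.hbf_integrate(p, cbar, y0, _substeps(params))
    elif method == "lsoda":
        def rhs(y, c):
            dy = np.empty(2)
            _kernels._hbf_rhs(y, c, p, dy)
            return dy

        daily = _lsoda_daily(rhs, cbar, y0)
    else:
        raise ValueError(f"unknown method {method!r}")
    if obs_days is None:
        return daily
    return daily[np.asarray(obs_days, dtype=int)]
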