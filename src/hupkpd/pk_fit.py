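"""Per-participant PK parameter estimation from clinical NCA summaries.

The clinical PK study reports no concentration-time samples, only the
non-compartmental summaries (AUC to 8 h, AUC∞, MRT∞, Tmax, Cmax, λz).  The
four model constants (F, ktr, Nt, ke) are therefore estimated by matching
the model-computed NCA metrics to the clinical ones in a weighted
least-squares sense,

    min_θ Σ_j ((ŷ_j(θ) − y_j) / w_j)²,   j over the six summaries,

with AUMC∞ entering as MRT∞ × AUC∞ and with population means of each
summary as weights (the weighting that produced the best fits).  Plasma
volume is fixed from anthropometry, which restores identifiability of F
(otherwise F and Vp trade off freely).  The optimization is a seeded
multistart of bounded trust-region least squares from uniform draws within
the parameter box.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .pk import NCAMetrics, PKParameters, nca_metrics, simulate_plasma

#: default parameter box: brackets the population mean ± 4 SD
DEFAULT_PK_BOUNDS: dict[str, tuple[float, float]] = {
    "F": (0.01, 1.0),
    "ktr": (0.1, 30.0),
    "Nt": (0.0, 10.0),
    "ke": (0.05, 3.0),
}

_PARAM_ORDER = ("F", "ktr", "Nt", "ke")


@dataclass(frozen=True)
class ClinicalPKTargets:
    """One participant's clinical NCA values plus study-day dosing context.

    ``AUMC_inf`` may be given directly or derived as MRT∞ × AUC∞.
    """

    AUC: float
    AUC_inf: float
    AUMC_inf: float
    Tmax: float
    Cmax: float
    lambda_z: float
    dose_mg: float
    Vp_L: float

    def __post_init__(self) -> None:
        for name in ("AUC", "AUC_inf", "AUMC_inf", "Tmax", "Cmax", "lambda_z", "dose_mg", "Vp_L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_mrt(cls, *, AUC, AUC_inf, MRT_inf, Tmax, Cmax, lambda_z, dose_mg, Vp_L):
        return cls(AUC=AUC, AUC_inf=AUC_inf, AUMC_inf=MRT_inf * AUC_inf,
                   Tmax=Tmax, Cmax=Cmax, lambda_z=lambda_z, dose_mg=dose_mg, Vp_L=Vp_L)

    def as_array(self) -> np.ndarray:
        """Order matches NCAMetrics.as_array: AUC, AUC∞, AUMC∞, Tmax, Cmax, λz."""
        return np.array([self.AUC, self.AUC_inf, self.AUMC_inf, self.Tmax, self.Cmax, self.lambda_z])


@dataclass
class PKFitResult:
    params: PKParameters
    cost: float
    n_starts: int
    converged_starts: int
    best_start_seed: int
    start_costs: list


def model_nca(params: PKParameters, dose_mg: float, Vp_L: float, n_grid: int = 1441) -> NCAMetrics:
    """NCA metrics of the model profile at the given dose and plasma volume."""
    profile = simulate_plasma(dose_mg, params, Vp_L, np.linspace(0.0, 24.0, n_grid))
    return nca_metrics(profile, params)


def population_weights(all_targets: Sequence[ClinicalPKTargets]) -> np.ndarray:
    """Per-summary weights: the population mean of each clinical parameter."""
    if len(all_targets) == 0:
        raise ValueError("at least one participant is required to form weights")
    return np.mean([t.as_array() for t in all_targets], axis=0)


def pk_residuals(params: PKParameters, targets: ClinicalPKTargets, weights: np.ndarray) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (6,):
        raise ValueError("exactly six weights are required")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    yhat = model_nca(params, targets.dose_mg, targets.Vp_L).as_array()
    return (yhat - targets.as_array()) / weights


def pk_cost(params: PKParameters, targets: ClinicalPKTargets, weights: np.ndarray) -> float:
    """Weighted sum of squared NCA residuals."""
    r = pk_residuals(params, targets, weights)
    return float(np.dot(r, r))


def fit_pk(
    targets: ClinicalPKTargets,
    weights: np.ndarray,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 25,
    seed: int = 0,
    x0: PKParameters | None = None,
) -> PKFitResult:
    """Best-of-``n_starts`` bounded least-squares fits from seeded uniform starts.

    If ``x0`` is given it replaces the first random start.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    bounds = dict(DEFAULT_PK_BOUNDS, **(bounds or {}))
    lo = np.array([bounds[k][0] for k in _PARAM_ORDER])
    hi = np.array([bounds[k][1] for k in _PARAM_ORDER])
    rng = np.random.default_rng(seed)

    def resid(x: np.ndarray) -> np.ndarray:
        p = PKParameters(F=x[0], ktr=x[1], Nt=x[2], ke=x[3])
        return pk_residuals(p, targets, weights)

    best = None
    start_costs = []
    converged = 0
    for s in range(n_starts):
        xs = rng.uniform(lo, hi)
        if s == 0 and x0 is not None:
            xs = np.clip(np.array([x0.F, x0.ktr, x0.Nt, x0.ke]), lo, hi)
        try:
            sol = optimize.least_squares(
                resid, xs, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
            )
            cost = 2.0 * sol.cost  # scipy halves the SSE
            start_costs.append(cost)
            converged += int(sol.success)
            if best is None or cost < best[0]:
                best = (cost, sol.x, s)
        except Exception as exc:  # keep multistart alive on solver failures
            start_costs.append(("failed", repr(exc)))
    if best is None:
        raise RuntimeError(f"all {n_starts} starts failed: {start_costs}")
    cost, x, s = best
    return PKFitResult(
        params=PKParameters(F=float(x[0]), ktr=float(x[1]), Nt=float(x[2]), ke=float(x[3])),
        cost=float(cost),
        n_starts=n_starts,
        converged_starts=converged,
        best_start_seed=s,
        start_costs=start_costs,
    )
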