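"""Pharmacodynamic parameter estimation by weighted multistart least squares.

Each PD model is fit per participant to one or more observed lab variables
(MCV and RBC jointly for the erythropoiesis model, ANC for leukopoiesis,
mean-cell HbF for the activation model) by minimizing

    Σ_j Σ_i ((ŷ_j(t_i | θ) − y_j(t_i)) / w_j)²

where w_j defaults to the per-variable mean of that participant's
observations.  The search runs 25 independent starts drawn log-uniformly
from the parameter box (the parameters span several decades); each start is
refined by bounded trust-region least squares in log10-parameter space and
then polished with a derivative-free Nelder-Mead pass, and the lowest-cost
start wins.  Failed integrations inside the optimizer return a large finite
penalty so the search continues.

Default parameter boxes span quartile/10 to quartile×10 around the
population statistics of each model's fitted constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .erythro import ErythroParams, simulate_erythro
from .hbf import HbFParams, simulate_hbf
from .leuko import LeukoParams, simulate_leuko

FAILED_SIM_PENALTY = 1e12

#: per-parameter (low, high) boxes: population quartiles widened by ×/÷10.
#: Vm0 has no population table entry; its box is the physiological MCV range.
DEFAULT_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "erythro": {
        "kpe_max": (1.3e10, 1.9e15),
        "psi_e": (7.1e9, 1.1e13),
        "gamma_e": (0.052, 33.0),
        "kdse_max": (0.002, 7.1),
        "Kdse50": (0.001, 44.0),
        "kte": (0.005, 3.7),
        "kde_max": (0.001, 0.6),
        "Kde50": (6.2, 8600.0),
        "alpha": (0.023, 5.1),
        "Vm0": (60.0, 120.0),
    },
    "leuko": {
        "kpl_max": (3.3e9, 1.8e15),
        "psi_l": (1.5e7, 1.2e10),
        "gamma_l": (0.2, 43.0),
        "kdsl_max": (0.004, 12.0),
        "Kdsl50": (0.001, 300.0),
        "ktl": (0.003, 3.2),
        "kdl": (0.003, 4.5),
    },
    "hbf": {
        "kmet": (0.005, 35.0),
        "Kmet": (0.4, 1100.0),
        "kdi": (0.001, 0.6),
        "kbf": (0.004, 6.4),
        "kaf": (0.03, 43.0),
        "Kaf": (0.22, 450.0),
        "n": (0.16, 45.0),
        "kdf": (0.002, 3.0),
    },
}

_MODEL_SPECS = {
    "erythro": (ErythroParams, simulate_erythro, {"MCV": (5, 1.0), "RBC": (4, 1e-6)}),
    "leuko": (LeukoParams, simulate_leuko, {"ANC": (4, 1e-6)}),
    "hbf": (HbFParams, simulate_hbf, {"Fm": (1, 1.0)}),
}


@dataclass
class ObservationSet:
    """Observations of one lab variable: times (days), values, fit weight.

    ``variable`` is one of MCV (fL), RBC (cells/µL), ANC (cells/µL),
    Fm (pg/cell).  The weight defaults to the mean of the observed values.
    """

    variable: str
    times: np.ndarray
    values: np.ndarray
    weight: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if np.any(self.values <= 0):
            raise ValueError("observed values must be positive")
        if self.weight is None:
            self.weight = float(np.mean(self.values))
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass
class PDFitResult:
    model_id: str
    params: object
    cost: float
    n_starts: int
    start_costs: list = field(default_factory=list)
    seed: int = 0


def _check_model(model_id: str):
    if model_id not in _MODEL_SPECS:
        raise ValueError(f"unknown model {model_id!r}; expected one of {sorted(_MODEL_SPECS)}")
    return _MODEL_SPECS[model_id]


def default_bounds(model_id: str) -> dict[str, tuple[float, float]]:
    """Per-parameter fit box for the given PD model."""
    _check_model(model_id)
    return dict(DEFAULT_BOUNDS[model_id])


def _residual_vector(model_id, x, observations, cbar_uM, init):
    cls, simulate, varmap = _MODEL_SPECS[model_id]
    try:
        params = cls.from_array(np.asarray(x, dtype=float))
    except ValueError:
        return None
    all_days = np.unique(np.concatenate([o.times for o in observations]))
    try:
        states = simulate(params, cbar_uM, init, obs_days=all_days)
    except Exception:
        return None
    if not np.all(np.isfinite(states)):
        return None
    idx = {d: i for i, d in enumerate(all_days)}
    res = []
    for o in observations:
        col, scale = varmap[o.variable]
        yhat = states[[idx[d] for d in o.times], col] * scale
        res.append((yhat - o.values) / o.weight)
    return np.concatenate(res)


def pd_cost(
    params,
    observations: Sequence[ObservationSet],
    cbar_uM: np.ndarray,
    init,
    model_id: str | None = None,
) -> float:
    """Weighted sum of squared residuals of a PD model against observations.

    Returns a large finite penalty (``FAILED_SIM_PENALTY``) if the
    simulation fails, so multistart searches can continue.
    """
    if model_id is None:
        model_id = {ErythroParams: "erythro", LeukoParams: "leuko", HbFParams: "hbf"}[type(params)]
    spec = _check_model(model_id)
    for o in observations:
        if o.variable not in spec[2]:
            raise ValueError(f"variable {o.variable!r} is not produced by model {model_id!r}")
        if o.times.max() > len(cbar_uM):
            raise ValueError("observation times extend beyond exposure coverage")
    from dataclasses import fields as _fields

    x = np.array([getattr(params, f.name) for f in _fields(params)])
    r = _residual_vector(model_id, x, observations, cbar_uM, init)
    if r is None:
        return FAILED_SIM_PENALTY
    return float(np.dot(r, r))


def fit_pd(
    model_id: str,
    observations: Sequence[ObservationSet],
    cbar_uM: np.ndarray,
    init,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 25,
    seed: int = 0,
    *,
    max_nfev: int = 150,
    polish_maxfev: int = 200,
    fixed: dict[str, float] | None = None,
) -> PDFitResult:
    """Multistart weighted least-squares fit of one PD model.

    Starts are drawn log-uniformly within ``bounds``; each is refined by
    ``scipy.optimize.least_squares`` (trust-region reflective, log10-
    parameter space) followed by a Nelder-Mead polish of the scalar cost.
    ``fixed`` pins named parameters (e.g. ``Vm0`` from the baseline lab)
    and removes them from the search space.  Deterministic given ``seed``.
    """
    cls, _, varmap = _check_model(model_id)
    for o in observations:
        if o.variable not in varmap:
            raise ValueError(f"variable {o.variable!r} is not produced by model {model_id!r}")
    box = dict(DEFAULT_BOUNDS[model_id], **(bounds or {}))
    names = list(box)
    fixed = fixed or {}
    free = [k for k in names if k not in fixed]
    if not free:
        raise ValueError("at least one parameter must be free")
    lo = np.log10([box[k][0] for k in free])
    hi = np.log10([box[k][1] for k in free])

    def expand(z: np.ndarray) -> np.ndarray:
        vals = dict(zip(free, 10.0 ** np.asarray(z, dtype=float)))
        vals.update(fixed)
        return np.array([vals[k] for k in names])

    def resid(z: np.ndarray) -> np.ndarray:
        r = _residual_vector(model_id, expand(z), observations, cbar_uM, init)
        if r is None:
            n = sum(o.times.size for o in observations)
            return np.full(n, np.sqrt(FAILED_SIM_PENALTY / n))
        return r

    def cost(z: np.ndarray) -> float:
        r = resid(np.clip(z, lo, hi))
        return float(np.dot(r, r))

    rng = np.random.default_rng(seed)
    best = None
    start_costs = []
    for s in range(n_starts):
        z0 = rng.uniform(lo, hi)
        try:
            sol = optimize.least_squares(
                resid, z0, bounds=(lo, hi), method="trf",
                xtol=1e-10, ftol=1e-10, max_nfev=max_nfev,
            )
            z, c = sol.x, 2.0 * sol.cost
            nm = optimize.minimize(
                cost, z, method="Nelder-Mead",
                options={"maxfev": polish_maxfev, "xatol": 1e-8, "fatol": 1e-10},
            )
            if nm.fun < c:
                z, c = np.clip(nm.x, lo, hi), float(nm.fun)
            start_costs.append(float(c))
            if best is None or c < best[0]:
                best = (float(c), z)
        except Exception as exc:
            start_costs.append(("failed", repr(exc)))
    if best is None:
        raise RuntimeError(f"all {n_starts} starts failed: {start_costs}")
    c, z = best
    # final refinement of the winning start: a longer least-squares pass and
    # direct-search polish pull marginally converged winners into their basin
    try:
        sol = optimize.least_squares(resid, z, bounds=(lo, hi), method="trf",
                                     xtol=1e-12, ftol=1e-12, max_nfev=3 * max_nfev)
        if 2.0 * sol.cost < c:
            c, z = 2.0 * sol.cost, sol.x
        nm = optimize.minimize(cost, z, method="Nelder-Mead",
                               options={"maxfev": 3 * polish_maxfev,
                                        "xatol": 1e-10, "fatol": 1e-12})
        if nm.fun < c:
            c, z = float(nm.fun), np.clip(nm.x, lo, hi)
    except Exception:
        pass
    return PDFitResult(
        model_id=model_id,
        params=cls.from_array(expand(z)),
        cost=c,
        n_starts=n_starts,
        start_costs=start_costs,
        seed=seed,
    )
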