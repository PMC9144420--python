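"""Daily hydroxyurea dose reconstruction from pharmacy refill records.

Clinical dosing information is rarely recorded day by day; what a pharmacy
keeps is the refill ledger — at each clinic visit, the total drug dispensed
and the number of days it was meant to cover.  This module turns that ledger
into a per-day dose series with explicit non-adherence flags, under the
standard refill-gap assumptions:

* the daily dose is constant between consecutive visits and equals the
  dispensed total divided by the days supplied;
* a capsule that is available is taken — a missed day can only arise from
  running out of capsules before the next visit;
* capsules left over from earlier intervals are carried forward (starting
  stock is zero) and consumed, at the daily dose of the visit that dispensed
  them, once the current dispense runs out;
* when the interval is longer than the available supply, the shortfall days
  are non-adherent and are placed uniformly at random within the interval.

Day counting uses 365.25 days/year on cumulative ages (half-up rounding of
cumulative days, then differenced) so that interval lengths always sum to
the total follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DAYS_PER_YEAR = 365.25


class RefillValidationError(ValueError):
    """A pharmacy refill record violates a structural requirement."""


@dataclass(frozen=True)
class RefillRecord:
    """One pharmacy dispensing event.

    Parameters
    ----------
    visit_index : int
        Ordinal position of the clinic visit.
    age_years : float
        Participant age at the visit, in years.
    total_dose_mg : float
        Total drug dispensed at the visit (mg).
    days_supplied : int
        Number of days the dispensed drug is meant to cover.
    """

    visit_index: int
    age_years: float
    total_dose_mg: float
    days_supplied: int

    def __post_init__(self) -> None:
        if self.total_dose_mg < 0:
            raise RefillValidationError(
                f"visit {self.visit_index}: total_dose_mg must be >= 0"
            )
        if self.days_supplied < 0:
            raise RefillValidationError(
                f"visit {self.visit_index}: days_supplied must be >= 0"
            )
        if self.days_supplied == 0 and self.total_dose_mg > 0:
            raise RefillValidationError(
                f"visit {self.visit_index}: drug dispensed with zero days supplied"
            )

    @property
    def daily_dose_mg(self) -> float:
        """Per-day dose implied by this dispense (0 if nothing dispensed)."""
        if self.days_supplied == 0:
            return 0.0
        return self.total_dose_mg / self.days_supplied


@dataclass(frozen=True)
class AnthroSeries:
    """Anthropometry sampled at clinic visits: weight, height, hematocrit."""

    age_years: np.ndarray
    weight_kg: np.ndarray
    height_cm: np.ndarray
    hct_percent: np.ndarray
    sex: str  # "male" | "female"

    def __post_init__(self) -> None:
        for name in ("age_years", "weight_kg", "height_cm", "hct_percent"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.age_years.size == 0:
            raise ValueError("AnthroSeries requires at least one measurement")
        if np.any(np.diff(self.age_years) < 0):
            raise ValueError("AnthroSeries ages must be non-decreasing")
        if np.any(self.weight_kg <= 0) or np.any(self.height_cm <= 0):
            raise ValueError("weight and height must be positive")
        if np.any((self.hct_percent <= 0) | (self.hct_percent >= 100)):
            raise ValueError("HCT must lie strictly between 0 and 100 percent")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass
class DailyDoseSeries:
    """Reconstructed per-day dose with adherence flags.

    ``day_index`` counts days since the first refill record; day 0 is the
    treatment-start day.  ``dose_mg`` is exactly zero on non-adherent days.
    ``extra_carryover[j]`` is the capsule-day stock carried past the end of
    interval ``j`` (the final entry excludes the last visit's own dispense,
    which is never consumable within the covered window).
    """

    day_index: np.ndarray
    dose_mg: np.ndarray
    dose_mg_per_kg: np.ndarray
    adherent: np.ndarray
    extra_carryover: np.ndarray
    nonadherent_per_interval: np.ndarray = field(default_factory=lambda: np.array([]))
    interval_edges: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_days(self) -> int:
        return self.day_index.size

    @property
    def n_nonadherent(self) -> int:
        return int(np.sum(~self.adherent))


def _validate_records(records: Sequence[RefillRecord]) -> None:
    if len(records) < 2:
        raise RefillValidationError(
            "at least two refill records are needed to define an interval"
        )
    ages = [r.age_years for r in records]
    for i in range(1, len(ages)):
        if ages[i] <= ages[i - 1]:
            raise RefillValidationError(
                f"visit {records[i].visit_index}: age {ages[i]} does not "
                f"increase over previous visit age {ages[i - 1]}"
            )


def _cumulative_days(ages: Sequence[float]) -> np.ndarray:
    """Half-up rounded cumulative day index for each visit age."""
    rel = np.asarray(ages, dtype=float) - ages[0]
    return np.floor(rel * DAYS_PER_YEAR + 0.5).astype(int)


def days_between_visits(records: Sequence[RefillRecord]) -> np.ndarray:
    """Number of days between consecutive clinic visits.

    Computed from visit ages as differences of half-up-rounded cumulative
    days, so the interval lengths sum exactly to the rounded total follow-up.

    Raises
    ------
    RefillValidationError
        If fewer than two records are given, ages are non-increasing, or any
        interval rounds to less than one day.
    """
    _validate_records(records)
    days = np.diff(_cumulative_days([r.age_years for r in records]))
    if np.any(days < 1):
        j = int(np.argmax(days < 1))
        raise RefillValidationError(
            f"visits {records[j].visit_index} -> {records[j + 1].visit_index}: "
            "interval rounds to less than one day"
        )
    return days


def reconstruct_adherence(
    records: Sequence[RefillRecord],
    seed: int | np.random.Generator | None = 0,
    anthro: AnthroSeries | None = None,
) -> DailyDoseSeries:
    """Reconstruct the daily dose series and non-adherent days.

    Walks the refill intervals with a carryover stock that starts at zero.
    In interval ``j`` (between visits ``j-1`` and ``j``) the available supply
    is the dispense at visit ``j-1`` plus the carryover; if the interval is
    longer, the shortfall days are non-adherent and placed uniformly at
    random (without replacement) using ``seed``.  Leftover capsule-days carry
    forward, tagged with the daily dose of the visit that dispensed them.

    Parameters
    ----------
    records : sequence of RefillRecord
    seed : int, Generator or None
        Randomness source for placing non-adherent days.  The *number* of
        non-adherent days per interval is deterministic; only their position
        varies with the seed.
    anthro : AnthroSeries, optional
        If given, per-day weight is interpolated (anchored so that the first
        refill age is day 0) and ``dose_mg_per_kg`` is filled; otherwise
        ``dose_mg_per_kg`` is NaN.
    """
    _validate_records(records)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    edges = _cumulative_days([r.age_years for r in records])
    nbcv = np.diff(edges)

    total_days = int(edges[-1])
    dose_mg = np.zeros(total_days)
    adherent = np.zeros(total_days, dtype=bool)
    n_intervals = nbcv.size
    extra_after = np.zeros(n_intervals, dtype=int)
    nonad_per_interval = np.zeros(n_intervals, dtype=int)

    # FIFO stock of (capsule-days, daily dose) carried across intervals
    stock: list[list[float]] = []
    for j in range(n_intervals):
        rec = records[j]
        supply_units: list[list[float]] = []
        if rec.days_supplied > 0:
            supply_units.append([float(rec.days_supplied), rec.daily_dose_mg])
        supply_units.extend([list(u) for u in stock])
        supply = int(sum(u[0] for u in supply_units))

        n_days_j = int(nbcv[j])
        n_nonad = max(0, n_days_j - supply)
        n_taken = n_days_j - n_nonad
        nonad_per_interval[j] = n_nonad

        day_lo = int(edges[j])
        missed = rng.choice(n_days_j, size=n_nonad, replace=False) if n_nonad else np.array([], dtype=int)
        taken_days = np.setdiff1d(np.arange(n_days_j), missed) + day_lo

        # consume from the front of the supply queue, in chronological day order
        k = 0
        for d in taken_days:
            while supply_units[k][0] <= 0:
                k += 1
            dose_mg[d] = supply_units[k][1]
            adherent[d] = True
            supply_units[k][0] -= 1
        stock = [u for u in supply_units if u[0] > 0]
        extra_after[j] = int(sum(u[0] for u in stock))

    if anthro is not None:
        start_age = records[0].age_years
        days = np.arange(total_days)
        w = interpolate_anthro(anthro, days, start_age_years=start_age)["weight_kg"]
        dose_mg_per_kg = np.where(adherent, dose_mg / w, 0.0)
    else:
        dose_mg_per_kg = np.full(total_days, np.nan)
        dose_mg_per_kg[~adherent] = 0.0

    return DailyDoseSeries(
        day_index=np.arange(total_days),
        dose_mg=dose_mg,
        dose_mg_per_kg=dose_mg_per_kg,
        adherent=adherent,
        extra_carryover=extra_after,
        nonadherent_per_interval=nonad_per_interval,
        interval_edges=edges,
    )


def interpolate_anthro(
    series: AnthroSeries,
    day: float | np.ndarray,
    start_age_years: float | None = None,
) -> dict[str, np.ndarray | float]:
    """Weight, height and HCT at a given treatment day.

    Linear interpolation between measurements, constant extrapolation beyond
    the endpoints.  ``start_age_years`` anchors day 0 (defaults to the first
    measurement's age).
    """
    if start_age_years is None:
        start_age_years = float(series.age_years[0])
    sample_days = (series.age_years - start_age_years) * DAYS_PER_YEAR
    day = np.asarray(day, dtype=float)
    out = {
        "weight_kg": np.interp(day, sample_days, series.weight_kg),
        "height_cm": np.interp(day, sample_days, series.height_cm),
        "hct_percent": np.interp(day, sample_days, series.hct_percent),
    }
    if day.ndim == 0:
        return {k: float(v) for k, v in out.items()}
    return out


def capsule_conservation_check(records: Sequence[RefillRecord], series: DailyDoseSeries) -> bool:
    """Exact integer identity: consumed supply = adherent days + terminal stock.

    The last record's dispense is excluded — it is never consumable within
    the window the series covers (which ends at the last visit).
    """
    supplied = sum(r.days_supplied for r in records[:-1])
    return supplied == int(np.sum(series.adherent)) + int(series.extra_carryover[-1])
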