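"""Virtual-participant generator for end-to-end pipeline testing.

Real longitudinal hydroxyurea cohorts are not publicly distributable, so
this module fabricates participants carrying the same data structure a
pediatric HU trial produces: demographics and growth, pharmacy refill
records with configurable adherence, a set of clinical NCA summaries from a
PK study day, ground-truth PK/PD parameters drawn from published population
statistics, and noisy scheduled lab panels (MCV, RBC, ANC, HbF%/MCH).

Sampling anchors:

* starting age N(10.12, 4.72) years, male fraction 54/85;
* PK constants: normal with the population mean/SD of (F, ktr, Nt, ke),
  truncated to the fit bounds;
* PD constants: lognormal with median equal to the population median and
  log-spread matched to the reported interquartile ratio, truncated to the
  default fit boxes so the search space always contains the truth;
* baseline labs: MCV N(85.34, 6.958) fL, RBC N(2.777, 0.552)×10⁶ cells/µL,
  ANC N(6814, 3384) cells/µL, MCH N(29.76, 2.842) pg, HCT N(23.46, 3.649)%,
  baseline HbF% uniform on 0-28%.

The basal HbF production rate is tied to the sampled baseline
(kbf = kdf × Fm₀) so each participant starts at their own basal fixed
point.  Observation noise is multiplicative Gaussian with per-variable CVs;
HbF is observed every other lab visit (it is drawn less often in practice).
Everything is deterministic given (seed, participant index).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import dosing, pk
from .dosing import AnthroSeries, DailyDoseSeries, RefillRecord, reconstruct_adherence
from .erythro import ErythroParams, ErythroState, simulate_erythro
from .hbf import HbFParams, HbFState, simulate_hbf
from .leuko import LeukoParams, LeukoState, simulate_leuko
from .pd_fit import DEFAULT_BOUNDS
from .pk import PKParameters
from .pk_fit import DEFAULT_PK_BOUNDS, ClinicalPKTargets, model_nca

# population statistics of the fitted PK constants: mean, SD
PK_POP = {"F": (0.12, 0.04), "ktr": (5.02, 2.61), "Nt": (1.14, 1.08), "ke": (0.54, 0.26)}

# population medians and quartiles of the fitted PD constants
ERYTHRO_POP = {
    "kpe_max": (2.10e12, 1.30e11, 1.90e14),
    "psi_e": (2.20e11, 7.10e10, 1.10e12),
    "gamma_e": (1.6, 0.52, 3.3),
    "kdse_max": (0.17, 0.02, 0.71),
    "Kdse50": (0.43, 0.01, 4.4),
    "kte": (0.2, 0.05, 0.37),
    "kde_max": (0.03, 0.01, 0.06),
    "Kde50": (310.0, 62.0, 860.0),
    "alpha": (0.37, 0.23, 0.51),
}
LEUKO_POP = {
    "kpl_max": (1.10e12, 3.30e10, 1.80e14),
    "psi_l": (4.70e8, 1.50e8, 1.20e9),
    "gamma_l": (3.5, 2.0, 4.3),
    "kdsl_max": (0.16, 0.04, 1.2),
    "Kdsl50": (0.3, 0.01, 30.0),
    "ktl": (0.09, 0.03, 0.32),
    "kdl": (0.13, 0.03, 0.45),
}
HBF_POP = {
    "kmet": (1.2, 0.05, 3.5),
    "Kmet": (27.0, 4.0, 110.0),
    "kdi": (0.03, 0.01, 0.06),
    "kbf": (0.16, 0.04, 0.64),
    "kaf": (1.5, 0.3, 4.3),
    "Kaf": (13.0, 2.2, 45.0),
    "n": (3.2, 1.6, 4.5),
    "kdf": (0.07, 0.02, 0.3),
}

BASELINE_LABS = {
    "MCV": (85.34, 6.958),  # fL
    "RBC": (2.777e6, 0.5517e6),  # cells/µL
    "ANC": (6814.0, 3384.0),  # cells/µL
    "MCH": (29.76, 2.842),  # pg
    "HCT": (23.46, 3.649),  # %
}

_Z_QUARTILE = 0.6744897501960817  # Φ⁻¹(0.75)


@dataclass
class AdherenceScenario:
    """How dispensed supply relates to interval length.

    mode "full": every interval fully supplied.
    mode "random": each interval supplied for Binomial(N_interval, p) days.
    mode "block": one contiguous stretch [start_day, start_day+length) of
    the follow-up is unsupplied (a refill shortfall), full supply elsewhere.
    """

    mode: str = "full"
    p: float = 0.85
    start_day: int = 365
    length: int = 60

    def __post_init__(self) -> None:
        if self.mode not in ("full", "random", "block"):
            raise ValueError(f"unknown adherence mode {self.mode!r}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("adherence probability must lie in [0, 1]")


@dataclass
class CohortConfig:
    """Study-design knobs for the virtual cohort."""

    n_participants: int = 10
    seed: int = 0
    age_mean: float = 10.12
    age_sd: float = 4.72
    age_range: tuple = (2.0, 17.0)
    male_fraction: float = 54 / 85
    follow_up_days: int = 730
    visit_interval_days: int = 91
    obs_interval_days: int = 30
    hbf_every_k_visits: int = 2
    adherence: AdherenceScenario = field(default_factory=AdherenceScenario)
    # (start_day, mg/kg/day): starting dose with an escalation step, giving
    # the exposure series two distinct plateaus
    dose_schedule: tuple = ((0, 20.0), (365, 30.0))
    noise_cv: dict = field(default_factory=lambda: {"MCV": 0.03, "RBC": 0.05, "ANC": 0.15, "Fm": 0.10, "MCH": 0.03})
    pk_dose_mg_per_kg: float = 20.0
    # when False, parameter/record sampling only (no truth trajectories,
    # labs or NCA targets) — cheap mode for marginal-statistics checks
    simulate_truth: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        d["dose_schedule"] = [list(x) for x in self.dose_schedule]
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SyntheticParticipant:
    """One virtual participant: inputs, ground truth, and noisy observations."""

    id: str
    sex: str
    age_start_years: float
    anthro: AnthroSeries
    records: list
    adherence_seed: int
    pk_params: PKParameters
    erythro_params: ErythroParams
    leuko_params: LeukoParams
    hbf_params: HbFParams
    nca_targets: ClinicalPKTargets
    dose_series: DailyDoseSeries
    cbar_uM: np.ndarray
    erythro_init: ErythroState
    leuko_init: LeukoState
    hbf_init: HbFState
    truth_erythro: np.ndarray  # (days+1, 6) daily states
    truth_leuko: np.ndarray  # (days+1, 5)
    truth_hbf: np.ndarray  # (days+1, 2)
    labs: dict  # variable -> (days, values); HbF stored as Fm plus HbF%/MCH
    baseline: dict


def _trunc_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _lognormal_quartile_matched(rng, median, q1, q3, lo, hi):
    """Lognormal draw with the given median and IQR ratio, truncated to [lo, hi]."""
    sigma = np.log(q3 / q1) / (2.0 * _Z_QUARTILE)
    for _ in range(1000):
        x = float(np.exp(np.log(median) + sigma * rng.standard_normal()))
        if lo <= x <= hi:
            return x
    return float(np.clip(median, lo, hi))


def _weight_kg(age_years: float) -> float:
    """Crude pediatric growth: 10 kg at age 2, +2.5 kg/year thereafter."""
    return 10.0 + 2.5 * max(age_years - 2.0, 0.0)


def _height_cm(age_years: float) -> float:
    """Crude pediatric growth: 85 cm at age 2, +5 cm/year thereafter."""
    return 85.0 + 5.0 * max(age_years - 2.0, 0.0)


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def sample_participant(config: CohortConfig, index: int) -> SyntheticParticipant:
    """Draw one virtual participant, deterministically from (seed, index)."""
    rng = _participant_rng(config.seed, index)
    sex = "male" if rng.random() < config.male_fraction else "female"
    age0 = _trunc_normal(rng, config.age_mean, config.age_sd, *config.age_range)

    # ---- growth and labs baseline
    hct0 = _trunc_normal(rng, *BASELINE_LABS["HCT"], 15.0, 35.0)
    visit_days = np.arange(0, config.follow_up_days + 1, config.visit_interval_days)
    if visit_days[-1] != config.follow_up_days:
        visit_days = np.append(visit_days, config.follow_up_days)
    visit_ages = age0 + visit_days / dosing.DAYS_PER_YEAR
    # on-treatment hematocrit recovers by ~3.6 points with a ~90-day time scale
    hct_t = hct0 + 3.6 * (1.0 - np.exp(-visit_days / 90.0))
    anthro = AnthroSeries(
        age_years=visit_ages,
        weight_kg=np.array([_weight_kg(a) for a in visit_ages]),
        height_cm=np.array([_height_cm(a) for a in visit_ages]),
        hct_percent=hct_t,
        sex=sex,
    )

    # ---- refill records under the adherence scenario
    nbcv = np.diff(np.floor((visit_ages - visit_ages[0]) * dosing.DAYS_PER_YEAR + 0.5).astype(int))

    def dose_per_kg(day: int) -> float:
        rate = config.dose_schedule[0][1]
        for start, r in config.dose_schedule:
            if day >= start:
                rate = r
        return rate

    records = []
    scen = config.adherence
    for j, day in enumerate(visit_days):
        if j < nbcv.size:
            n_int = int(nbcv[j])
            if scen.mode == "full":
                supplied = n_int
            elif scen.mode == "random":
                supplied = int(rng.binomial(n_int, scen.p))
            else:  # block shortfall
                overlap = max(0, min(day + n_int, scen.start_day + scen.length) - max(day, scen.start_day))
                supplied = n_int - overlap
        else:
            supplied = int(config.visit_interval_days)
        daily_mg = dose_per_kg(int(day)) * _weight_kg(age0 + day / dosing.DAYS_PER_YEAR)
        records.append(
            RefillRecord(
                visit_index=j,
                age_years=float(visit_ages[j]),
                total_dose_mg=daily_mg * supplied,
                days_supplied=supplied,
            )
        )

    adherence_seed = int(rng.integers(0, 2**31 - 1))
    series = reconstruct_adherence(records, seed=adherence_seed, anthro=anthro)

    # ---- PK truth and clinical NCA summaries
    pk_params = PKParameters(**{
        k: _trunc_normal(rng, *PK_POP[k], *DEFAULT_PK_BOUNDS[k])
        for k in ("F", "ktr", "Nt", "ke")
    })
    w0, h0 = _weight_kg(age0), _height_cm(age0)
    vp0 = pk.plasma_volume(pk.blood_volume(w0, h0, sex), hct0)
    pk_dose = config.pk_dose_mg_per_kg * w0
    if config.simulate_truth:
        m = model_nca(pk_params, pk_dose, vp0)
        nca_targets = ClinicalPKTargets(
            AUC=m.AUC, AUC_inf=m.AUC_inf, AUMC_inf=m.AUMC_inf,
            Tmax=m.Tmax, Cmax=m.Cmax, lambda_z=m.lambda_z,
            dose_mg=pk_dose, Vp_L=vp0,
        )
        # ---- daily exposure from the reconstructed dosing history
        exposure = pk.simulate_daily_exposure(series, pk_params, anthro)
        cbar_uM = exposure.cbar_uM
    else:
        nca_targets = None
        cbar_uM = None

    # ---- PD truth parameters
    def draw(pop, box):
        return {k: _lognormal_quartile_matched(rng, *pop[k], *box[k]) for k in pop}

    vm0 = _trunc_normal(rng, *BASELINE_LABS["MCV"], *DEFAULT_BOUNDS["erythro"]["Vm0"])
    ery = ErythroParams(Vm0=vm0, **draw(ERYTHRO_POP, DEFAULT_BOUNDS["erythro"]))
    leu = LeukoParams(**draw(LEUKO_POP, DEFAULT_BOUNDS["leuko"]))

    mch0 = _trunc_normal(rng, *BASELINE_LABS["MCH"], 20.0, 40.0)
    hbf_pct0 = float(rng.uniform(0.0, 28.0))
    fm0 = max(hbf_pct0, 0.5) / 100.0 * mch0  # floor keeps kbf positive
    hbf_draw = draw(HBF_POP, DEFAULT_BOUNDS["hbf"])
    hbf_draw["kbf"] = float(np.clip(hbf_draw["kdf"] * fm0, *DEFAULT_BOUNDS["hbf"]["kbf"]))
    hb = HbFParams(**hbf_draw)

    # ---- initial states from baseline labs
    rbc0 = _trunc_normal(rng, *BASELINE_LABS["RBC"], 1.0e6, 5.0e6) * 1e6  # cells/L
    anc0 = _trunc_normal(rng, *BASELINE_LABS["ANC"], 1500.0, 18000.0) * 1e6  # cells/L
    up_e = ery.kde_max * rbc0 / ery.kte
    ery_init = ErythroState(Nse=up_e, Ne1=up_e, Ne2=up_e, Ne3=up_e, Ne=rbc0, Vm=vm0)
    up_l = leu.kdl * anc0 / leu.ktl
    leu_init = LeukoState(Nsl=up_l, Nl1=up_l, Nl2=up_l, Nl3=up_l, Nl=anc0)
    hbf_init = HbFState(Ci=0.0, Fm=hb.kbf / hb.kdf)

    if config.simulate_truth:
        # ---- truth trajectories
        truth_e = simulate_erythro(ery, cbar_uM, ery_init)
        truth_l = simulate_leuko(leu, cbar_uM, leu_init)
        truth_h = simulate_hbf(hb, cbar_uM, hbf_init)

        # ---- noisy scheduled labs
        n_days = cbar_uM.size
        obs_days = np.arange(0, n_days + 1, config.obs_interval_days)
        cv = config.noise_cv

        def noisy(truth_vals, cvk):
            vals = truth_vals * (1.0 + cv[cvk] * rng.standard_normal(truth_vals.size))
            # assay detection floor keeps observations strictly positive
            return np.maximum(vals, 0.01 * float(np.mean(truth_vals)) + 1e-12)

        labs = {
            "MCV": (obs_days, noisy(truth_e[obs_days, 5], "MCV")),
            "RBC": (obs_days, noisy(truth_e[obs_days, 4] * 1e-6, "RBC")),
            "ANC": (obs_days, noisy(truth_l[obs_days, 4] * 1e-6, "ANC")),
        }
        hbf_days = obs_days[:: config.hbf_every_k_visits]
        fm_truth = truth_h[hbf_days, 1]
        fm_obs = noisy(fm_truth, "Fm")
        mch_truth = mch0 * truth_e[hbf_days, 5] / vm0  # constant-MCHC scaling
        mch_obs = noisy(mch_truth, "MCH")
        labs["Fm"] = (hbf_days, fm_obs)
        labs["MCH"] = (hbf_days, mch_obs)
        labs["HbF_pct"] = (hbf_days, np.clip(fm_obs / mch_obs * 100.0, 0.0, 100.0))
    else:
        truth_e = truth_l = truth_h = None
        labs = {}

    return SyntheticParticipant(
        id=f"P{index:03d}",
        sex=sex,
        age_start_years=age0,
        anthro=anthro,
        records=records,
        adherence_seed=adherence_seed,
        pk_params=pk_params,
        erythro_params=ery,
        leuko_params=leu,
        hbf_params=hb,
        nca_targets=nca_targets,
        dose_series=series,
        cbar_uM=cbar_uM,
        erythro_init=ery_init,
        leuko_init=leu_init,
        hbf_init=hbf_init,
        truth_erythro=truth_e,
        truth_leuko=truth_l,
        truth_hbf=truth_h,
        labs=labs,
        baseline={"RBC": rbc0 * 1e-6, "ANC": anc0 * 1e-6, "MCV": vm0, "MCH": mch0,
                  "HbF_pct": hbf_pct0, "HCT": hct0},
    )


def generate_cohort(config: CohortConfig) -> tuple[list, dict]:
    """Generate the full cohort plus a reproducibility manifest."""
    participants = [sample_participant(config, i) for i in range(config.n_participants)]
    manifest = {
        "n_participants": config.n_participants,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "config": config.to_dict(),
        "participant_ids": [p.id for p in participants],
    }
    return participants, manifest


def corrupt_dosing_record(participant: SyntheticParticipant, mode: str) -> list:
    """Return refill records that misstate supply, for fit-degradation studies.

    mode "none": identity.  mode "hide_nonadherence": every interval is
    reported fully supplied, so reconstruction finds zero non-adherent days
    even when the participant truly missed doses.
    """
    if mode == "none":
        return list(participant.records)
    if mode != "hide_nonadherence":
        raise ValueError(f"unknown corruption mode {mode!r}")
    recs = participant.records
    ages = [r.age_years for r in recs]
    nbcv = np.diff(np.floor((np.array(ages) - ages[0]) * dosing.DAYS_PER_YEAR + 0.5).astype(int))
    out = []
    for j, r in enumerate(recs):
        n = int(nbcv[j]) if j < nbcv.size else r.days_supplied
        if n <= 0:
            n = max(r.days_supplied, 1)
        daily = r.daily_dose_mg if r.days_supplied > 0 else (
            out[-1].daily_dose_mg if out else 0.0
        )
        out.append(RefillRecord(visit_index=r.visit_index, age_years=r.age_years,
                                total_dose_mg=daily * n, days_supplied=n))
    return out
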