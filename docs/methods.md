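# Methods

## Scope and purpose

`hupkpd` implements an integrated pharmacokinetic–pharmacodynamic (PK-PD)
description of hydroxyurea (HU) therapy in children with sickle cell
disease: reconstruction of the daily dose from pharmacy refill ledgers,
a transit-compartment model of oral HU plasma kinetics calibrated against
non-compartmental (NCA) summaries, and three mechanistic response models —
erythropoiesis with mean cell volume (MCV), leukopoiesis with absolute
neutrophil count (ANC), and fetal-hemoglobin (HbF) induction — driven by
the daily average plasma concentration C̄p.  Because longitudinal clinical
HU cohorts are not publicly distributable, the package carries a synthetic
cohort generator whose marginals are anchored to published population
statistics, so every stage of the pipeline is testable end to end.

## Dose reconstruction

Refill ledgers record, per clinic visit, the total drug dispensed and the
days it should cover.  Interval lengths N_bcv are obtained from visit ages
at 365.25 days/year; cumulative days are rounded half-up and differenced so
intervals always sum to the rounded total follow-up.  Within interval *j*
the available supply is the dispense at visit *j−1* plus the carried-over
stock (initially zero).  Shortfall days are non-adherent and placed
uniformly at random within the interval (the ledger fixes only their
count); surplus capsule-days are carried forward indefinitely and consumed,
oldest dispense first after the current one, at the daily dose of the visit
that dispensed them.  Two exact integer identities hold by construction and
are enforced in tests: consumed supply = adherent days + terminal stock
(the last visit's dispense is excluded — it is never consumable inside the
covered window), and shortfall × surplus = 0 per interval.  The daily dose
in mg/kg uses weight linearly interpolated between visits (constant
extrapolation at the ends).

## PK model

A dose D passes through Nt+1 transit compartments with rate ktr and is
eliminated from plasma first-order with ke.  The terminal-compartment
outflow is the gamma-density input

    in(t) = F·D·ktr·(ktr·t)^Nt·e^(−ktr·t)/Γ(Nt+1),

which for integer Nt coincides exactly with an explicit first-order chain
(kept as a test oracle) and allows the non-integer Nt values population
fits produce.  The plasma amount has a closed form through the regularized
lower incomplete gamma function when ktr > ke; an LSODA fallback covers the
degenerate regime.  Plasma volume is the Nadler blood volume (weight ≥ 25
kg; height in meters before cubing — the centimeter form some sources print
is dimensionally implausible, but a `nadler_literal_cm` flag reproduces it)
or 70 mL/kg below 25 kg, times (1 − HCT/100).

NCA summaries are computed from the simulated curve: AUC by trapezoid to
8 h (the last clinical sampling time), AUC∞ and AUMC∞ to 24 h, MRT∞ =
AUMC∞/AUC∞, Cmax/Tmax by grid argmax refined with bounded scalar
maximization of the closed-form curve, and λz identified with ke.  Daily
exposure C̄p is AUC(0–24 h)/24, evaluated exactly from the mass-balance
identity ∫Ap = (absorbed − Ap)/ke; each treatment day is simulated
independently from zero drug (HU is cleared well within 24 h at clinical
elimination rates), with plasma volume recomputed daily from interpolated
anthropometry.  PD drug constants are tabulated in µM while PK runs in
µg/mL; conversion uses the HU molar mass 76.055 g/mol.

PK calibration minimizes the weighted sum of squared differences between
the six model and clinical NCA values (MRT∞ enters through AUMC∞ =
MRT∞·AUC∞, keeping six residuals), with population means of each summary
as weights.  Plasma volume is fixed from anthropometry, restoring
identifiability of F.  The search is a seeded multistart (uniform draws in
F∈(0.01,1], ktr∈(0.1,30)/h, Nt∈[0,10], ke∈(0.05,3)/h — a box bracketing
the population mean ± 4 SD) of bounded trust-region least squares.

## PD models

All three response models take the per-day C̄p (µM), held piecewise
constant within each day.

**Erythropoiesis/MCV.**  Five compartments: stem/progenitor pool Nse with
proliferation flux kpe(Ne) = kpe_max/(1+(Ne/Ψe)^γe) (Hill feedback standing
in for the EPO loop), three maturation stages at rate kte, circulating pool
Ne.  HU kills proliferating cells at kdse(C̄p) = kdse_max·C̄p/(Kdse50+C̄p)
and extends red-cell lifespan, kde(C̄p) = kde_max·(1−C̄p/(Kde50+C̄p)) — two
opposing effects on Ne.  MCV is carried per cell: inflowing cells have
volume Vm0 + α·C̄p, giving dVm/dt = (α·C̄p + Vm0 − Vm)·kte·Ne3/Ne, whose
constant-exposure fixed point Vm0 + α·C̄p is independent of all
cell-kinetic parameters (an exact invariant used in tests).  The division
by Ne is guarded at 1 cell/L; that regime is unphysical for this data.

**Leukopoiesis/ANC.**  Same structure with drug action only on the stem
compartment, so exposure unambiguously lowers the neutrophil equilibrium.
Steep feedback with a slow maturation chain can destabilize into sustained
oscillations; `scan_dynamics` classifies long-run behavior on a grid of
constant exposures by the relative peak-to-trough amplitude of the final
20% of a 2000-day run started from a 10%-perturbed equilibrium (threshold
1% — our construction; only the existence of periodic solutions is
population-documented).  A helper reports membership of the 2000–4000
cells/µL maximum-tolerated-dose band.

**HbF induction.**  The NO/sGC/cGMP cascade is lumped into one
intermediate: dCi/dt = kmet·C̄p/(Kmet+C̄p) − kdi·Ci, and mean-cell fetal
hemoglobin dFm/dt = kbf + kaf·Ci^n/(Kaf^n+Ci^n) − kdf·Fm.  The Hill
denominator uses the half-saturation constant Kaf (standard form); a
`literal_kaf_denominator` flag substitutes kaf there for comparison with
sources that print the activation constant in that slot.  Lab HbF% and MCH
convert to the observable via Fm = (HbF%/100)·MCH under the
uniform-distribution assumption.  Closed-form fixed points (Ci* =
kmet·C̄p/((Kmet+C̄p)·kdi), Fm* = (kbf + activated)/kdf) serve as oracles.

### Numerical integration

Exposure is constant within each day, so the PD ODEs are integrated with a
classical RK4 using an integer number of substeps per day, landing exactly
on day boundaries where observations live.  Substep counts scale with the
fastest linear rate λ in the parameter set (≥ 4/day, λ·dt ≤ 0.5), keeping
RK4 well inside its stable, accurate regime across the fit boxes; negative excursions are clamped at zero, preserving the
non-negativity invariant.  The kernels are numba-compiled (pure-Python
fallback included) because the optimizers call them thousands of times.  An
LSODA path (scipy, restarted per constant-exposure block, rtol 1e−9)
serves as the adaptive reference; tests assert agreement.  PK uses closed
forms wherever possible and LSODA (rtol 1e−8/atol 1e−10) otherwise.
Steady states are found with Brent root-finding on the scalar balance
equations and cross-checked against plain bisection oracles in tests.

## PD calibration

Weighted least squares over one or more variables, Σ_j Σ_i ((ŷ_j(t_i|θ) −
y_j(t_i))/w_j)², with w_j the per-variable mean of that participant's
observations (mirroring the PK weighting choice).  MCV and RBC are fit
jointly (they share the erythropoiesis model); ANC and Fm separately.  The
search draws 25 starts log-uniformly from the parameter boxes (parameters
span decades), refines each by bounded trust-region least squares in
log10-parameter space, polishes with a derivative-free Nelder–Mead pass
(least-squares and direct search in series), and keeps the lowest cost.
Failed integrations return a finite 1e12 penalty so the search continues.
Default boxes span [Q1/10, Q3×10] around the population quartiles of each
parameter; Vm0, which has no published quartiles, uses the physiological
MCV range 60–120 fL.

Initial conditions come from baseline labs: Ne (or Nl) from the baseline
count, precursor compartments at the drug-free pass-through level
(death-rate·pool/transition-rate), Vm at baseline MCV, and Fm at the basal
fixed point kbf/kdf.  Because the baseline MCV that seeds Vm(0) is also the
inflow volume before any drug, Vm0 is pinned to it during erythropoiesis
fits; the drug slope α is then identified by the exposure plateaus.  With
Vm0 free, α and Vm0 trade off along an identifiability ridge and α recovery
degrades — the trajectory fit is unaffected, which is why the trajectory,
not the parameter vector, is the calibration contract.

## Synthetic cohort

The generator emulates the data structure of a pediatric HU trial.
Sampling anchors: starting age N(10.12, 4.72) years truncated to 2–17,
male fraction 54/85; PK constants truncated-normal with the population
mean/SD; PD constants lognormal with the population median and log-spread
matched to the reported interquartile ratio, truncated to the fit boxes so
the search space always contains the truth; baseline labs from the
population baseline means/SDs; baseline HbF% uniform on 0–28%.  The basal
production rate is tied to the sampled baseline (kbf = kdf·Fm₀) so each
participant starts at their own basal fixed point.  Growth is linear
(2.5 kg/year and 5 cm/year from 10 kg/85 cm at age 2); hematocrit recovers
by ~3.6 points with a 90-day time scale on treatment.  Dosing starts at
20 mg/kg/day and escalates to 30 mg/kg/day at one year, giving the exposure
two distinct plateaus (the condition under which α is identifiable).
Refills occur every 91 days; adherence scenarios are full supply, random
(binomial fraction of each interval), or a contiguous block shortfall.
Observation noise is multiplicative Gaussian with CVs 3% (MCV), 5% (RBC),
15% (ANC), 10% (Fm), 3% (MCH), floored at 1% of the truth mean (an assay
detection floor that keeps observations positive); labs are monthly, HbF
every other visit.  MCH scales with simulated MCV at constant MCHC.

What the generator does **not** emulate: transfusions, infections and other
ANC spikes, HPFH genetics, PK-PD parameter covariance (drawn
independently), assay rounding, or irregular visit timing.  Passing
recovery tests therefore demonstrates internal consistency of the pipeline
under the stated noise model, not performance on real clinical data.

## Reference experiments and problem sizes

`hupkpd.experiments` packages three seeded experiments: (1) single-dose PK
at the population-mean constants (740 mg ≈ 25 mg/kg in a 30 kg child — the
dose that reproduces the population AUC∞ scale); (2) recovery on a
10-participant cohort (2-year follow-up, monthly labs, stated CVs, 25
multistarts per fit), reporting pooled trajectory RMSE per variable as a
multiple of the noise SD — the pooled SD of multiplicative noise is the
RMS of per-observation SDs, CV × RMS(y), so the ratio is ~1 when the fit
matches the truth — and per-participant relative error of α; (3)
dosing-information sensitivity — for ten drug-responsive participants with
a 60-day refill shortfall, the HbF model is fit (6 multistarts) against
exposure from true records and from records doctored to hide the gap, and
the costs are compared.  Replicates are screened for drug response (truth
Fm dynamic range above three noise SDs): a flat responder carries no
information about dosing either way.  These sizes are the package's
reference configuration; all scale linearly if enlarged.

## Known limitations

* Single-dose-per-day PK with independent days; residual carry-over below
  ~2% of daily AUC at typical ke is ignored.
* The leukopoiesis fit does not choose between periodic and steady-state
  regimes explicitly; the optimizer simply matches trajectories.
* No uncertainty quantification (bootstrap/profile likelihood) — point
  estimates with multistart diagnostics only.
* kbf constant in age; no transfusion or infection modeling.
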