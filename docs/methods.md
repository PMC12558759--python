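# Methods

## Model structure and assumptions

The model is a minimal flow-limited PBPK description of orally dosed
matrine in growing pigs.  Four anatomical spaces are resolved — the
intestinal lumen (the observable), liver, blood and a lumped
other-organs pool — plus a stomach depot.  Assumptions:

1. every rate process is first-order;
2. compartments are well stirred and tissue uptake is perfusion-limited
   with fixed tissue-to-blood partition coefficients;
3. the lumen concentration equals the intestinal-content concentration,
   and tissue/content density is 1 kg/L, so μg/kg ≡ μg/L and
   μg/g ≡ μg/mL ≡ mg/kg;
4. biliary excretion returns hepatic drug to the lumen (first-order in
   the hepatic amount), which is what produces the characteristic
   two-phase decline of lumen concentrations;
5. no metabolism (matrine shows no first-pass loss in rodents) and no
   arterial/venous split — the single blood pool supplies the arterial
   concentration `Ca`.

Oral dosing (feed medication or gavage alike) is instantaneous loading
of the stomach depot; a constant-rate interpretation of the depot term
would inject drug forever, whereas first-order gastric emptying of a
depot is the standard reading and matches the observed rapid rise of
lumen concentrations.

Because all states are amounts and every coefficient is constant, the
system is linear and time-invariant.  Two useful consequences: dose
linearity and superposition hold exactly (both are tested), and lumen
concentrations are independent of body weight (doses, flows and volumes
all scale linearly with BW), which is why a mid-range 27 kg animal
represents the 24.3–31.1 kg study population.

## Protein binding: why uptake is free-fraction limited

The published blood balance removes `Q_tot·Ca·(1−Pb)` from blood while
the tissue balances receive `Q_tot·Ca`.  Taken literally, that pair
creates mass at rate `Q_tot·Ca·Pb` (≈ 42.6·Ca L/h at 27 kg) against a
total elimination of only ≈ 7.6·Ca L/h, and the fitted parameter set
then diverges — amounts grow without bound and no steady state exists.
The package therefore defaults to `pb_mode="free_uptake"`: only the
unbound fraction `fu = 1−Pb` of the arterial concentration enters the
tissues and the renal route.  This keeps the blood equation exactly in
its published form *and* closes the mass balance (every column of the
system matrix sums to zero, which is tested).  The literal variant is
retained as `pb_mode="verbatim"` for auditing: `mass_balance_residual`
then reproduces `−∫ Q_tot·Ca·Pb dt` (verified against quadrature).

## Bioavailability placement

`F` appears in the parameter table but in no printed equation.  Two
documented placements are provided:

- `f_mode="systemic_scale"` (package default): the lumen loses the full
  absorptive flux `k_a·A_int` — preserving the printed intestinal
  balance — while only `F·k_a·A_int` reaches blood; the remainder goes
  to an "unabsorbed" sink.
- `f_mode="dose_scale"`: the depot is loaded with `F×dose` and the whole
  absorptive flux reaches blood.

The two modes give identical systemic kinetics and differ only in the
early lumen scale (by the factor F); the late, biliary-driven lumen
phase is identical.  The regimen conclusions hold in both modes.  The
synthetic-data generator uses `dose_scale`, because that placement
reproduces the observed single-dose (40 mg/kg) group-mean peak
(simulated ≈ 840 μg/g on the sampling grid vs 784 ± 324 μg/g observed),
whereas `systemic_scale` predicts ≈ 1060 μg/g.

## Parameters

`ModelParameters` carries the seventeen physiological/compound constants
plus BW, validates the physical constraints (fractions in [0,1],
`Qc_l + Qc_ot = 1`, fractional volumes summing to ≤ 1) and exposes the
absolute flows/volumes.  Two packaged files hold the fitted values and
the literature starting values; hematocrit (PCV) is carried for
completeness but enters no equation.  `Qc_ot` and `Vc_ot` are balancing
entries ("by calculation"): they are adjusted, never independently
perturbed or fitted.

## Numerics

- Default integrator: LSODA (stiff-capable, adaptive), rtol 1e−8,
  atol 1e−10, with an exact restart at every dose event.  Because the
  system is linear, an exact matrix-exponential propagator
  (`method="expm"`) is also provided; the two agree to 1e−6 relative
  and the exact path is used inside estimation and steady-state loops,
  where an adaptive solver would dominate the runtime.  Both are checked
  against an independently coded fixed-step RK4 at dt = 0.001 h.
- Negative amounts beyond −1e−9 of the administered dose raise; smaller
  excursions are clipped to zero.
- Steady state of a repeating regimen is declared on the first day whose
  24-h lumen Cmax changes by < 0.5% from the previous day (reached on
  day 2–3 for q8h matrine; the terminal lumen phase has a ~25 h
  half-life, so accumulation is modest); simulation is capped at 30 days.
- %T>threshold uses linearly interpolated crossing times on a 0.02 h
  window grid (checked against a 0.01 h counting oracle to 0.5
  percentage points).

## Non-compartmental analysis

Linear trapezoidal AUC on observed points only (no extrapolation beyond
the last observation; interior end-times interpolated).  λz is the OLS
slope of ln C vs t over the suffix of ≥ 3 uncensored points strictly
after Tmax that maximizes the adjusted R² — automatic because two-phase
profiles make manual phase selection ambiguous; the selected points and
R² are reported for audit.  t1/2 = 0.693/λz with the conventional
rounded constant for comparability with the published tables.
AUC∞ adds `C_last/λz`; AUMC∞ adds the two-term tail
`C_last·t_last/λz + C_last/λz²`; MRT = AUMC∞/AUC∞;
CL/F = dose/AUC∞ per kg and V/F = (CL/F)/λz.  Censoring policy at the
2 μg/kg LLOQ: pre-Tmax censored points count as zero, post-Tmax censored
points are excluded; ties for Tmax go to the first occurrence.

## Estimation

The likelihood is Gaussian on log concentration (log-normal residuals)
with the residual SD profiled out analytically; intestinal profiles span
five orders of magnitude, which makes an additive model (available via
`error_model="additive"`) inappropriate as a default.  The default data
reduction fits the group geometric-mean profile (the study fitted one
pooled single-dose data set); per-subject pooled residuals are
available.  Optimization is Nelder–Mead in a logit-transformed space so
every iterate respects its plausibility bounds, with up to three seeded
restarts from perturbed incumbents; convergence uses scipy's simplex
tolerances (xatol 1e−8).  Any parameter subset can be fitted with the
rest fixed (batched optimization).  Non-positive predictions at
uncensored points yield a large finite penalty, never NaN.

## Sensitivity

NSC by central differences at ±0.1%, normalized by parameter and by the
response value at each time slice; the response is the lumen
concentration on the single-dose sampling schedule; classification uses
the maximum of |NSC| over time with the 0.1 cutoff (the reduction over
time slices is a package choice; the cutoff is the field convention).
On the fitted model the structure is: positive — Vc_l, F, k_bi, P_l;
negative — Vc_int (exactly −1 at all times, since V_int only rescales
the concentration), k_a, Cl_renal; sign-changing — k_st, P_ot.  k_e is
*not* sensitive (max |NSC| ≈ 0.03): in lumen-only data it is confounded
with k_a (total lumen removal is k_a + k_e with k_e/k_a ≈ 0.9%), so k_e
is structurally non-identifiable from these observations — recovery
harnesses show 2–7% median error for k_st/k_a/k_bi but no meaningful
recovery of k_e, and the corresponding end-to-end check is expected to
fail by construction.

## Synthetic data

The generator emulates the two study designs: (1) six T-cannulated pigs
of 24.3–31.1 kg, single oral dose, sampling at 0.25–120 h; (2) 25 pigs
of 9.8–10.3 kg, 50 mg/kg/d × 5 d, five pigs sacrificed at each of 0.5,
1, 3, 6 and 12 d after the last dose (one terminal lumen sample per
pig).  Virtual pigs draw unit-median log-normal factors (30% CV) on the
four transfer rates (k_st, k_a, k_bi, k_e) and uniform body weights;
measurements get 20% CV multiplicative log-normal residual error and are
censored at the 2 μg/kg LLOQ.  The IIV/residual magnitudes are generator
conventions (the studies report only observed SDs); parameter-recovery
checks therefore use residual error only, so that they measure the
estimator rather than cohort sampling.  Randomness is counter-based
(seed × subject), so subjects are reproducible and independent of cohort
size.

What the generator does *not* emulate: food effects on gastric emptying,
circadian variation, correlated IIV, assay error structure beyond a
single multiplicative term, or any misspecification of the model itself
— generated data come from the same model family that is fitted to
them.  Passing recovery tests therefore demonstrate estimator
correctness under the stated noise, not robustness to structural error.
One observed-data feature is knowingly *not* reproducible: the single
40 mg/kg group mean exceeded 300 μg/g for at most 2 h in the study,
but the fitted model (and hence any model-based cohort) holds the mean
profile above that bound for ≈ 3.5 h — with k_st ≈ k_a ≈ 0.855/h the
peak shape forces C(3 h) ≈ 0.54·Cmax, which is above 300 μg/g whenever
Cmax exceeds ≈ 560 μg/g.  The observed profiles decline faster between
2–5 h than the fitted model allows; resolving this would require
re-estimating the model against the original animal data, which are not
available.

## PK/PD evaluation

Regimens are scored against the in vitro window by the steady-state
lumen Cmax fold over each bound and %T>threshold across 24 h.  For
70 mg/kg q8h at 27 kg the package computes a steady-state Cmax of
≈ 1897 μg/g (3.79-fold over 500 μg/mL, 6.32-fold over 300) with 62.1% of
the day above 300 μg/g — comfortably supporting the q8h recommendation,
and somewhat above the originally reported prediction (2.15–3.59-fold,
> 55.75%), consistent with the free-fraction uptake reading and the
bioavailability placement being package choices the original report did
not specify.

## Problem sizes

Default problem sizes keep the full test suite at about a minute:
recovery harnesses use 6 virtual pigs × 15 sampling times × 10 seeds;
the Monte-Carlo likelihood check uses 100 replicates; steady-state
windows use a 0.02 h grid.  All are package defaults, not limits — every
routine accepts larger cohorts, denser grids and more seeds.
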