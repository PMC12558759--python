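# matrine-pbpk

A minimal physiologically based pharmacokinetic (PBPK) toolkit for matrine
(MT) in the **pig intestinal lumen** — the site where enterotoxigenic
*Escherichia coli* colonizes and where MT's resistance-reversal activity
would have to act.  The package is aimed at veterinary PK/PD modellers who
want to simulate oral MT regimens, estimate model parameters from
intestinal concentration–time data, and score dosage regimens against the
in vitro effective-concentration window (300–500 μg/mL).

## The model

Four compartments — stomach depot, intestinal lumen, liver, blood and a
lumped "other organs" pool — connected by first-order processes and blood
flows (flow-limited distribution, all processes first-order, no
metabolism):

```
dA_st/dt  = −k_st·A_st
dA_int/dt =  k_st·A_st + k_bi·A_l − (k_a + k_e)·A_int
dA_l/dt   =  Q_l·(fu·Ca − C_l/P_l) − k_bi·A_l
dA_ot/dt  =  Q_ot·(fu·Ca − C_ot/P_ot) − fu·Ca·Cl_renal·BW
dA_b/dt   =  F·k_a·A_int + Q_l·C_l/P_l + Q_ot·C_ot/P_ot − Q_tot·Ca·(1−Pb)
```

with amounts `A` (μg), concentrations `C = A/V`, arterial concentration
`Ca = C_b`, free fraction `fu = 1 − Pb`, hepatic/other flows
`Q_l, Q_ot` and total `Q_tot = Qcar·BW`.  Gastric emptying (`k_st`) fills
the lumen, absorption (`k_a`, bioavailability `F`) and fecal excretion
(`k_e`) empty it, and biliary excretion (`k_bi`) recycles hepatic drug
back — the mechanism behind the observed two-phase decline of lumen
concentrations.  Tissue densities are taken as 1 kg/L, so μg/kg ≡ μg/L
and μg/g ≡ μg/mL ≡ mg/kg.

The package ships the fitted parameter set for growing pigs
(`optimized_parameters()`) and the literature starting values
(`starting_parameters()`), plus modules for

- forward simulation of arbitrary oral regimens (`simulate`, adaptive
  LSODA or an exact linear propagator) with a mass-balance audit,
- non-compartmental analysis (Cmax, Tmax, AUC by linear trapezoid, λz by
  automatic terminal-phase selection, t1/2 = 0.693/λz, MRT, CL/F, V/F),
- Nelder–Mead maximum-likelihood estimation within plausibility bounds
  and normalized sensitivity coefficients (±0.1% central differences,
  sensitive when max |NSC| > 0.1),
- steady-state PK/PD regimen metrics (Cmax fold over threshold,
  %T>threshold over 24 h),
- predicted-vs-observed statistics (regression/Pearson, one- and
  two-sample t tests), and
- a synthetic-data generator emulating both pig studies (log-normal
  inter-individual and residual variability, censoring at the 2 μg/kg
  LLOQ).

## Worked example

Score the recommended regimen — 70 mg/kg every 8 h in a 27 kg pig — at
steady state:

```sh
$ matrine-pbpk regimen --dose-mg-per-kg 70 --interval-h 8 --bw-kg 27
                regimen  threshold_ug_per_g  ss_Cmax_ug_per_g  Cmax_fold_over_threshold  pct_24h_above_threshold
70 mg/kg q8h (BW 27 kg)               300.0       1896.706485                  6.322355                62.137925
70 mg/kg q8h (BW 27 kg)               500.0       1896.706485                  3.793413                51.348522
```

The steady-state intestinal peak is ≈1897 μg/g, 3.8-fold above the upper
in vitro bound, and the lumen concentration stays above 300 μg/g for
about 62% of each day — a sustained exposure that a single 40 mg/kg dose
cannot deliver (its peak is only 1.6–2.6-fold above the window and falls
back within hours).

The same workflow is available from Python:

```python
from matrine_pbpk import optimized_parameters, evaluate_regimen

metrics = evaluate_regimen(optimized_parameters(BW=27.0), 70.0, 8.0)
print(metrics[0].pct_time_above)   # 62.137925...
```

Other subcommands: `simulate` (trajectories on the study sampling grid),
`nca`, `fit`, `sensitivity`, `evaluate` and `generate` (virtual
cohorts); see `matrine-pbpk COMMAND --help`.

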