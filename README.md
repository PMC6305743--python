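# cfdeff

Design-effect analysis and power planning for clustered CFTR-corrector
assays.

## The problem

Corrector drugs such as lumacaftor partially rescue the misfolded
F508del-CFTR channel, and their efficacy can be compared *in vitro* on a
patient's own bronchial epithelial cells: each air-liquid-interface
culture is mounted in an Ussing chamber and the forskolin + genistein
stimulated short-circuit current increase (ΔI_sc, μA/cm²) measures
functional correction. In practice the cultures come from *aliquots* of a
larger cell isolate — group samples. Cultures within an aliquot are
correlated, so replicates are not independent: naive t-tests between two
correctors reject a true null far more often than their nominal α, and
sample sizes from standard power calculations are underestimates.

`cfdeff` quantifies that clustering and corrects the planning:

- **ICC (ρ)** by the one-way random-effects ANOVA estimator,
  ρ = (MS_B − MS_W) / (MS_B + (η_o − 1) MS_W), with the effective group
  size η_o = (N − Σnᵢ²/N)/(k − 1) for unbalanced designs;
- **design effect** 1 + ρ(η_o − 1), the factor by which group sampling
  inflates the variance of a mean;
- **exact noncentral-t power** for the two-sided two-sample t-test and the
  smallest per-group n reaching a target power, multiplied by the design
  effect (ceiling applied after multiplication);
- **Diff** (per-culture corrector ΔI_sc minus the mean vehicle ΔI_sc),
  ΔI_sc extraction from annotated I_sc traces, residual normality
  diagnostics (Lilliefors KS, D'Agostino-Pearson K², Gaussian histogram
  fit), a balanced two-way patient × treatment variance partition, and a
  seeded hierarchical generator of synthetic assay datasets.

It is written for lab statisticians and electrophysiologists planning
corrector-comparison experiments on group-sampled primary cultures.

## Worked example

Simulate a group-sampling experiment (one patient's pool split into 23
aliquots, 3–9 cultures per arm per aliquot, between-aliquot variance 0.605
and within-aliquot variance 1.0, i.e. true ρ = 0.377), estimate the ICC on
the corrector arm, and plan a corrector-B comparison:

```sh
cfdeff simulate --preset aliquot-bcf00572-like --seed 7 --out sim.csv
cfdeff estimate sim.csv --treatment corrector --out est.json
cfdeff plan --from-estimate est.json --power 0.8 --effect 0.2 --effect 1.0
```

which prints

```
patient P01  treatment corrector
k = 23 groups, N = 141 cultures, sizes [5, 8, 9, 8, 6, 3, 3, 7, 4, 4, 4, 7, 3, 4, 8, 5, 9, 9, 9, 9, 8, 6, 3]
eta_o = 6.09
MS_between = 3.712  MS_within = 0.8959
F(22, 118) = 4.144, p = 2.29e-07
rho = 0.3403 (truncated 0.3403)
design effect = 2.73

replicates per group (alpha=0.05, mu1=3.3, sigma=0.962, design effect=2.73..., ceil applied after multiplication):
effect_fraction  0.2  1.0
power
0.8               96    9
```

Reading: the aliquot groups differ significantly (F test), the estimated
intraclass correlation 0.34 with ~6.1 effective replicates per group gives
a design effect of 2.7 — every independently-planned replicate count must
be multiplied by ~2.7. Detecting a 20 % better corrector at 80 % power
(two-sided α = 0.05, mean 3.3 μA/cm², s.d. 0.962) needs 35 independent
cultures per arm, hence 96 group-sampled cultures per arm here; a 100 %
improvement needs only 9.

The same workflow in one step: `cfdeff run sim.csv --treatment corrector
--out report.json`. Residual diagnostics: `cfdeff diagnose sim.csv
--treatment corrector`. Everything is importable from Python
(`from cfdeff import estimate_icc_pipeline, replicate_table, ...`).

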