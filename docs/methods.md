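# Methods

## Statistical model

One arm of a group-sampling experiment is modelled as a one-way
random-effects layout: aliquot (group) j of a single cell pool contributes
cultures with responses

    y_ij = mu + b_j + e_ij,   b_j ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_w^2),

so the intraclass correlation is rho = sigma_b^2 / (sigma_b^2 + sigma_w^2).
rho is estimated by the ANOVA (method-of-moments) estimator

    rho_hat = (MS_B - MS_W) / (MS_B + (eta_o - 1) MS_W),

with MS_B and MS_W the between- and within-group mean squares and

    eta_o = (N - sum_i n_i^2 / N) / (k - 1)

the effective average group size of an unbalanced design (equal to the
common size when balanced). No REML or likelihood alternative is offered:
the moments estimator is the quantity the design-effect correction is
defined through, and at the design sizes used here (k ~ 20 groups) its
small-sample bias is a few hundredths (visible in the recovery
simulations, which recover rho = 0.377 to within about 0.02 on average).

The design effect of sampling a mean from clustered data is

    deff = 1 + rho (eta_o - 1),

ranging from 1 (no clustering) to eta_o (perfect within-group
consistency). Sample sizes planned under independence are multiplied by
deff.

**Negative rho estimates.** The raw estimator can fall below zero (down to
-1/(eta_o - 1)) by sampling noise. The raw value is always reported, but
the design effect defaults to max(rho_hat, 0): a deff < 1 would
*anti-conservatively* shrink planned sample sizes on the strength of
noise. `truncate=False` propagates the raw value for sensitivity analysis.

## Power and sample size

Corrector comparisons use the two-sided, equal-variance, equal-allocation
two-sample t-test (Welch and paired variants are out of scope). With n per
group and standardised effect d = (mu2 - mu1)/sigma, the test statistic
under the alternative is noncentral t with 2n - 2 df and noncentrality
d sqrt(n/2); power is the two-tailed exceedance of the central-t critical
value, so power at d = 0 equals alpha exactly. The minimal n is found by
exhaustive increment from n = 2 (deterministic; guarded at 10^6).

**Counting convention.** Replicate counts are per treatment group, and the
design effect multiplies the per-group count with the ceiling applied
after multiplication: n_adj = ceil(n * deff). Per-group counting with late
rounding is the conservative choice among the defensible conventions, and
the output labels it (`counting_basis: per_group`).

Defaults: alpha = 0.05 two-sided; mu1 = 3.3 uA/cm^2 and sigma = 0.962
uA/cm^2, the pooled corrector-treated mean and s.d. of the reference
20-patient panel (sigma = 1.0 is the other printed convention and can be
passed explicitly); effect fractions 0.2/0.3/0.5/1.0; target powers
0.60-0.95. Configuration takes `target_power` (= 1 - beta) rather than
beta to avoid ambiguity.

## Two-way patient x treatment partition

Patient-to-patient variability in corrector response is quantified by a
balanced two-way mixed ANOVA (treatment fixed, patient random). Reported
"percent of variability" values are shares of the total sum of squares,
which sum to 100 by construction in balanced designs; the interaction F
test uses the residual mean square. Unbalanced grids raise an error rather
than silently selecting a Type-I/II/III sum-of-squares convention; v1 is
balanced-only because the reference design (3 vehicle + 3 corrector
cultures per patient) is balanced. The module takes a single declared
response column; whether that response is delta I_sc or separate
baseline/maximum currents is the caller's modelling choice.

## Trace extraction

delta I_sc is the increase from the steady-state baseline before the
forskolin addition to the maximum current after the genistein addition:

- baseline = mean current over a window (default 60 s) ending at the
  forskolin event — a windowed mean rather than a single sample for
  robustness;
- peak = maximum over [genistein, inhibitor) if a CFTR-inhibitor event is
  annotated (the inhibitor abolishes CFTR current, so later samples are
  not signal), else to the end of the trace;
- resistance-check pulse deflections (2 s bipolar steps at 100 s
  intervals) are blanked +/- 3 s around each annotated pulse event before
  either statistic is computed.

Secretory current is positive by convention.

## Normality diagnostics

Residuals are observation minus group mean (zero-sum per group; their
squared sum equals SS_within). The KS test estimates the normal parameters
from the sample, which is the Lilliefors situation: the default p-value is
Lilliefors-corrected (the uncorrected KS p is anti-conservative there and
available by flag; Lilliefors tables start at n = 4, so n = 3 falls back
to the uncorrected value). The D'Agostino-Pearson K^2 omnibus statistic
(squared skewness and kurtosis z-scores against chi-square with 2 df) is
restricted to groups with n >= 9; smaller groups raise an explicit error.
The pooled-residual histogram uses fixed-width bins over [min, max]
(default width 0.5 uA/cm^2) and fits a scaled Gaussian by least squares;
outlier bins are excluded greedily by largest absolute fit residual with a
refit after each exclusion, and r^2 is monotone nondecreasing in the
number of exclusions. Shapiro-Wilk and Anderson-Darling are deliberately
not offered.

## Synthetic data

`simulate_grouped_assay` draws, per patient: a patient baseline shift
a_p ~ N(0, patient_sd^2) applied to both arms, a patient-specific
treatment deviation g_p ~ N(0, interaction_sd^2) applied to the corrector
arm, and per aliquot a group effect b ~ N(0, group_sd^2) — drawn
independently per treatment arm by default, since the two arms of one
aliquot are distinct sets of cultures and the reference experiments
estimated separate ICCs per arm (a shared-effect mode exists). Each
aliquot contributes equal numbers of vehicle and corrector cultures; group
sizes are uniform on a configurable range. Draws use per-patient
substreams spawned from the master seed, so adding patients never perturbs
earlier patients' data, and identical configs give byte-identical CSVs.

Defaults are the reference group-sampling conditions: 23 aliquots, 3-9
cultures per arm, corrector mean 3.3 uA/cm^2, vehicle mean 0.2,
sigma_b^2 = 0.605, sigma_w^2 = 1.0 (true rho = 0.377). Presets:
`aliquot-bcf00572-like` (those defaults), `aliquot-bcf00710-like`
(19 aliquots, sizes 2-7, rho = 0.2816; the per-aliquot sizes of the
original experiment are unpublished, so the size range was chosen to give
eta_o near the reported 4.34), and `patient-panel-20` (20 patients, one
aliquot each, 3 + 3 cultures, patient_sd = 0.68, interaction_sd = 0.32,
within_sd = 0.60 — chosen by algebra so the corrector-arm total s.d. is
sqrt(0.68^2 + 0.32^2 + 0.60^2) = 0.962). Responses are not truncated at
zero: the normal model is exactly what the ANOVA assumes.

What the generator does **not** emulate: vehicle-arm variance is not
scaled down relative to the corrector arm (real DMSO controls are roughly
an order of magnitude less variable); there is no positive skew,
truncation, plate/run batch structure, or mechanistic pharmacology. Tests
passing on this generator therefore validate the estimators under their
own assumptions, not robustness to real-data pathologies (the diagnostics
module exists for the latter).

`simulate_trace` builds a piecewise recording — flat post-amiloride
baseline (default 0 uA/cm^2), a forskolin ramp to half the response, a
genistein rise to baseline + delta, exponential decay after the inhibitor,
an ATP transient, and pulse artifacts. Noise is a stationary
Ornstein-Uhlenbeck drift (default s.d. 0, correlation time 600 s) rather
than white noise: recording noise in these chambers is dominated by slow
baseline drift, and a white model at 1 Hz would bias the peak statistic
upward by roughly 2.7 noise-s.d., destroying the round-trip property the
generator is for (white noise is available with `noise_tau = 0`). With
zero noise, extraction returns the configured delta exactly, pulses or
not.

## Numerical choices and degenerate inputs

- SS decompositions are plain two-pass sums about means; the identity
  SS_total = SS_between + SS_within holds to relative 1e-9 and is
  property-tested against an independent double-loop oracle.
- Zero within-group variance flags the ANOVA degenerate (F infinite or
  undefined); both mean squares zero make the ICC an error, as does an
  all-singleton design. eta_o <= 1 is rejected for ICC estimation.
- p-values are upper-tail F probabilities; no multiple-testing correction
  anywhere.
- CSV responses are serialised with shortest-repr decimals so
  write-then-read round trips are bit-exact.
- CLI exit codes: 0 success, 2 schema errors, 3 precondition/argument
  errors, 4 degenerate data, 5 insufficient data.

## Problem sizes

The test suite and the acceptance script use: 1000 simulated datasets for
ICC recovery (k = 23, sizes 3-9), 10^5 Monte-Carlo t-tests per power
calibration point, and 10^4 simulated null experiments (4 groups of 6 per
arm, so eta_o = 6 exactly, at rho = 0.377) for the clustered-inference
demonstration. At those sizes the Monte-Carlo standard errors are an order
of magnitude below the tolerances checked.

## Known limitations

- Balanced-only two-way ANOVA; no Welch/paired power variants; no
  confidence intervals for rho (a possible extension); no cost-optimal
  choice of groups vs cultures per group — only fixed-deff inflation.
- The ANOVA ICC estimator's finite-k bias is inherited by design; at
  k = 23 the recovery simulations show a mean underestimate of ~0.02 at
  rho = 0.377.
- The printed replicate counts of the reference analysis depend on
  per-group vs total counting, the s.d. convention (0.962 vs 1.0) and
  rounding order; all conventions are exposed via flags rather than
  guessed, and this package's defaults are stated above.
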