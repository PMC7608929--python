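# Methods

This note documents the statistical models, the calibration of the
synthetic cohort, the numerical choices, and what the tests do and do not
demonstrate.

## Scoring

**PRAGMA-CF.** A grid annotation is 10 axial slice grids with one label
per cell.  Subscores are volume fractions: each label's share of lung
cells pooled over all slices, every lung cell weighted equally.  Equal
weighting is what a uniform grid implies; no per-slice lung-area
reweighting is applied.  Grid resolution is annotation-supplied (synthetic
default 20×20): scores are fractions, so resolution only sets the
quantization, which is at most 100/n_lung_cells percentage points per
subscore.  The label hierarchy (bronchiectasis > mucus plugging > AWT >
atelectasis > normal) is a data-entry rule; files store the resolved
label, and `resolve_hierarchy` is provided for multi-label sources.

**CF-CT.** Extent codes 0–3 per region and component are multiplied by
per-component weights.  The published rubric states only the component
maxima (72/54/36/54, total 216); the default weight table
{bronchiectasis 4, AWT 3, mucus plugging 2, parenchyma 3} is the unique
single-multiplier table reproducing those maxima over 6 regions × max
code 3.  Any other rubric can be supplied, but weights that break the
published maxima require an explicit override flag.  The %Disease
composite for CF-CT is the summed airway raw score as a percentage of its
summed maximum (162): a literal sum of three percent-of-maximum values
can exceed 100 and does not correspond to any tabulated composite, so it
is not used on the CF-CT side (on the PRAGMA side the subscores share one
denominator and the literal sum is correct).

Percentages are carried at full float precision; report rendering rounds
half-up (2 decimals for scores, 3–4 for coefficients and p-values).

## Agreement

The intra-observer ICC is the two-way mixed-effects, consistency,
single-measurement form, computed from the ANOVA mean squares:
ICC = (MS_subjects − MS_error)/(MS_subjects + (k−1)·MS_error).  A
rescoring design has fixed raters, for which consistency is the
conventional reading of a "two-way mixed" ICC.  Tables with zero
between-subject variance (all-zero mucus-plugging scores in a mild cohort
are the canonical case) are flagged degenerate rather than given a
number.  Interpretation bands: poor [−1, 0.4), moderate [0.4, 0.6), good
[0.6, 0.8], excellent (0.8, 1] — the boundary 0.4 is moderate and both
0.6 and 0.8 are good, since "greater than 0.8" defines excellent.

Cross-system association uses Pearson correlation and simple regression
after square-rooting both score vectors (percent scores are right-skewed
with variance growing with the mean); the p-value is the two-sided t test
with n−2 df.  No multiple-testing correction is applied anywhere in the
pipeline: each outcome is reported at its nominal level.

Bland–Altman analysis z-standardizes each vector over its own subjects
(the two systems live on different scales) before forming differences;
the bias of standardized pairs is 0 by construction and the 1.96·SD
limits of agreement carry the information.  Standardization is applied to
the raw subscores; a √ transform beforehand is available but not the
default.

## Progression model

For outcome y of patient i at visit j ∈ {SOS, EOS}:

    y_ij = β0 + β1·I(EOS) + β2·I(placebo) + β3·I(tobra)
         + β4·I(EOS)I(placebo) + β5·I(EOS)I(tobra) + β6·I(placebo)I(tobra)
         + u_i + ε_ij,      u_i ~ N(0, τ²),  ε_ij ~ N(0, σ²)

estimated by REML.  With two timepoints a random slope is confounded with
the residual, so the random part is an intercept only.  PRAGMA volume
fractions are analysed on the √ scale (they are heteroscedastic on the
raw scale and approximately Gaussian after the transform; √0 = 0 is
valid); CF-CT percent-of-maximum scores and FEV1 %predicted use the
identity scale.  Patients with a single scorable visit are retained.

Wald t-tests use the nested within/between df convention: time terms (and
the intercept) get n_obs − n_patients − p_within df, patient-level terms
get n_patients − p_between − 1.  Satterthwaite df are not implemented;
the convention is documented and isolated in one function.

Two REML routes exist and are cross-checked in tests.  For complete
two-visit cohorts the per-patient difference d_i and mean m_i are
independent under the model (Var d = 2σ², Var m = τ² + σ²/2) and the
fixed-effect spaces separate, so REML reduces to two exact OLS problems —
this closed form also powers the Monte-Carlo replicates.  Unbalanced
cohorts go through statsmodels `MixedLM` (response standardized for
conditioning, optimizer fallback lbfgs → powell → nm).

## Power simulation

A trial of n patients per arm is simulated on the analysis (√) scale:

    SOS_i = μ + u_i + ε_i1
    EOS_i = μ + δ·(1 − r·I(active)) + u_i + ε_i2

with δ the 48-week progression and r the reduction fraction (10/30/50%
scenarios).  Each replicate is analysed with the reduced LMM (intercept,
time, arm, time×arm); power is the rejection fraction of the time×arm
Wald test at two-sided α = 0.05.  For this balanced design the test is
exactly the two-sample t test on change scores, which supplies an
analytic oracle.  Replicates draw from substreams spawned off one master
seed, so runs are bit-reproducible and enlarging the replicate count or
grid never reshuffles earlier replicates.  Raw power estimates are
isotonically smoothed before the smallest adequate n is read off.

**Scenario calibration.** The reference scenarios carry the published
√-scale intercepts and time effects (%Disease: 2.839 and 0.212; %Mucus
Plugging: 1.114 and 0.175).  The between-patient variance comes from an
exact moment inversion of the published raw-scale mean/SD (if √Y ~
N(m, s²) then E Y = m² + s² and Var Y = 2s⁴ + 4m²s²).  The residual
variance of the original power simulation was not published, and the
published time-effect standard errors imply a residual far too large to
yield the published sample sizes; the residual is therefore recovered
analytically from the published requirement "110 per arm give 0.9 power
under a 50% %Disease reduction" by inverting the exact noncentral-t
two-sample power formula (change-score SD 0.2414, residual variance
0.0291).  Both scenarios share this residual — the two published
time-effect SEs are nearly identical (0.079 vs 0.080), consistent with a
common measurement noise — which makes the %Mucus Plugging sample size an
out-of-sample check: the calibrated machinery puts it at 160–170 per arm
against the published 170.

Simulated scores are Gaussian on the analysis scale and not truncated at
zero by default: the published sample sizes derive from a Gaussian
mixed-model simulation, and truncation concentrates mass at zero that
attenuates the arm contrast materially at small baselines (for the
%Mucus Plugging scenario it would raise the required n by ~15–20%).  A
`truncate_at_zero` option exists for studying exactly that distortion.

## Synthetic cohort generator

The generator emulates the published cohort's summary statistics, not its
patients: 238 enrolled, 210 with scans, scorable-visit probabilities
195/210 and 196/210, √(%Disease) ~ N(2.897, 1.565) at SOS (the exact
moment inversion of 9.96 ± 7.58; note the published model intercept 2.839
is the reference-group value and falls out consistently), progression
0.212 on the √ scale, no arm or tobramycin effect, 1:1 arms, tobramycin
50% (allocation fractions are config; the published tobramycin fraction
is not restated).  Generating on the √ scale and squaring back injects
exactly the mean-dependent heteroscedasticity that motivates the √
transform in the analysis, so the transform decision is testable.

The √-scale variance splits into between-patient τ² and residual σ²
(default 0.48).  The residual default is calibrated so the fitted
time-effect SE reproduces the published 0.079 at the published cohort
size — deliberately different from the power scenarios' residual (0.171),
because the published SEs and the published sample sizes are mutually
inconsistent; each component is calibrated to the quantity it must
reproduce, and both constants are exposed in config.

%Disease is split into bronchiectasis / mucus plugging / AWT by a
patient-level Dirichlet draw centred on the published subscore shares
(0.782/0.217/0.001, concentration 25 — a documented guess, the joint
subscore distribution is unpublished); atelectasis is a zero-inflated
exponential add-on (present 50%, mean 0.24%).  Because subscores derive
from %Disease, their √-scale progressions are emergent (~0.10–0.17)
rather than injected; the three published per-subscore coefficients and
raw-scale additivity cannot all hold exactly under a square root, and the
composite is the quantity this generator is calibrated to.  CF-CT
%Disease is an affine-plus-noise function of √(%Disease) calibrated to
the published cross-system correlation (r = 0.74) and CF-CT moments
(17.94 ± 6.71); component scores scale with the published component
profile.  FEV1 %predicted gets a patient level (61.3 ± 14.7) and a small
non-significant decline (−0.6, residual SD 5).

Annotation realizations invert the scoring systems.  Grid labels are
apportioned to lung cells (an inscribed-ellipse mask) by
largest-remainder rounding and shuffled, so rescoring reproduces each
target within one cell.  CF-CT extent codes are spread over the six
regions as evenly as the 0–3 codes allow; the rubric's coarseness is part
of what is emulated.  Rescoring draws a uniform without-replacement
subset (default 20 scans) and adds Gaussian noise with variance
2v(1−t)/t, where v is the first-occasion score variance, which makes the
two-way consistency ICC estimator converge to the target t.

Every patient draws from an independent substream spawned from the
config seed, so cohorts are bit-reproducible and enlarging the cohort
never reshuffles existing patients.  The missing-scan mechanism is
completely at random (no mechanism is published).

**What the generator does not emulate**: observer-specific bias and
drift, correlation between scorability and disease severity, lobar
spatial structure within the lung mask, zero-inflation beyond what
√-scale truncation induces, and longitudinal FEV1 trajectories beyond two
visits.  Passing tests demonstrate the pipeline's arithmetic and its
statistical calibration under this generative model — not that the
clinical conclusions would replicate on real imaging data, which is not
available.

## Problem sizes in the test suite

Monte-Carlo suites use sizes chosen to keep estimator error well inside
the asserted bounds: sample-size searches run 1,000 replicates per grid
point (MC SE ≤ 0.016); type-I error calibration uses 500 replicate
cohorts of 150 complete-case patients (the closed-form REML route makes
this cheap); parameter recovery averages 25 cohorts of 500 patients;
the end-to-end annotation-level recovery runs 200 cohorts of 40 patients
on 10×10 grids.  All suites are seeded and deterministic.

## Known limitations

* The Wald df convention is nested within/between only; Satterthwaite or
  Kenward-Roger df would differ slightly in small cohorts.
* `estimate_power` analyses the reduced 4-term model; the original
  simulation may have refit the 7-term model (unpublished either way).
* CF-CT component scores in the generator are proportional to the CF-CT
  composite within a visit, so their mixed-model results are collinear
  replicas of the composite's; adding per-component noise would lift this
  at the cost of more unpublished parameters.
* `%Trapped Air` is out of scope (expiratory scans were mostly absent in
  the source cohort), as are DICOM reading, lung segmentation, and the
  visual scoring act itself.
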