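# Methods

`metabodiet` re-implements, end to end, a dietary-metabotyping analysis for
urinary ¹H-NMR spectroscopy from a controlled crossover feeding design: a
two-class PLS-DA classifier of healthy- vs unhealthy-pattern urine
profiles, validated by Monte Carlo cross-validation, with bootstrap
significance for discriminant spectral variables, projection of unlabelled
cohorts, nonparametric group statistics and DASH dietary scoring.  Because
no real spectra ship with the package, a first-class synthetic generator
reproduces the statistical structure the analysis assumes; every stage is
tested against planted ground truth.

## Synthetic cohort model

A cohort follows the crossover layout `n_subjects x diets x days`
(defaults 19 x 4 x 3 = 228 samples; diets labelled 1 = most
guideline-concordant to 4 = least).  Spectra are digitised over
δ 0.5–9.5 ppm (default 16 000 points; most tests and the acceptance run use
2 000–4 000 points, which preserves every statistical property at a fraction
of the cost — problem sizes are stated below).

Each metabolite is a set of Lorentzian resonances
`L(x) = 1 / (1 + ((x − pos)/w)²)` with half-width `w = 0.002` ppm
(≈ 1.2 Hz at 600 MHz).  The concentration of metabolite *m* in the sample
of subject *s*, diet *d*, day *t* is

```
c_msdt = diet_effect_m(d) · exp(σ_b,m Z_s) · exp(σ_w,m Z_st)
```

with log-normal between-subject and day-to-day effects
(σ from the respective CV: discriminants 0.40 / 0.15, background
0.25 / 0.10).  The spectrum is the linear mixture of the metabolite basis
spectra, plus additive Gaussian baseline noise (sd 0.02), all multiplied by
a log-normal dilution factor (log-sd 0.3) emulating urine osmolality.

The default library plants 28 discriminant metabolites — 19 elevated under
diet 1 and 9 under diet 4, with extreme-diet concentration ratios drawn
from 2–4 and graded log-linearly across diets 1→4 so diets 2 and 3 are
genuine intermediates — among 60 diet-stable background metabolites.
Composition mirrors real urine: background species carry multiplets (3–4
peaks each, ~230 of the ~280 total peaks), right-skewed levels 1–5 with a
dominant creatinine-like singlet (level 10) and a broad urea-like resonance
(width 0.03 ppm, level 6), while food-derived discriminants are
lower-concentration species (base level 0.3–1).  This matters for
normalisation: the dilution quotient must be anchored on abundant stable
signal, as it is in practice.  Peak apexes sit on a shuffled grid with
≥ 0.03 ppm separation and none in the water region δ 4.5–5.0.

Randomness derives from one master seed through named substreams (per
subject, per sample), so enlarging a design never perturbs existing
samples and identical seeds give bit-identical cohorts.

What the generator does **not** emulate: phasing/baseline artefacts,
chemical-shift drift and peak misalignment, J-coupling fine structure, and
drug interferences.  Passing tests therefore demonstrate the statistical
machinery — not robustness to instrumental artefacts of real spectra.

## Preprocessing: region exclusion and PQN

The water presaturation region δ 4.50–5.00 is excluded by default before
anything else.  Probabilistic Quotient Normalization divides each spectrum
by the median ratio of its intensities to a reference — the per-variable
median spectrum of diets 1 and 4 combined.  External cohorts are always
normalised to the *training* reference, never to their own median.  Even
subset sizes use midpoint medians.

Quotient-eligible variables are those where the reference exceeds 10% of
its maximum.  This floor deserves its own paragraph.  The ratio median is
only an unbiased dilution estimate when the variables entering it are
predominantly composition-stable.  Spectral variables on the wings of
food-responsive peaks have diet-dependent ratios; when 28 of 88 metabolites
respond to diet, including every above-noise variable lets that asymmetric
mass (19 up vs 9 down) drag the median by several percent in a
diet-correlated way.  Because the quotient multiplies the whole sample,
this error is *coherent* across all stable variables and correlated with
class — precisely the kind of signal a multivariate classifier amplifies —
and it manufactures spurious "diet-4-elevated" significance on null
metabolites (compositional closure).  Restricting the quotient to strong
resonances (463 of ~3 800 variables at the 4 000-point scale), which in
urine are the abundant homeostatically stable species, reduces the
differential bias below 1% and the artifact below the calling threshold on
most seeds.  A rare residual false call (≤ 1–2 per cohort on some seeds,
always in the diet-4 direction) is the remaining footprint of this
artifact; it is inherent to median-quotient normalisation of compositional
data, not a defect of the inference.  The floor is configurable
(`eligible_floor`).

In the noise-free setting where dilution is the only between-sample
difference, PQN inverts the planted factors exactly (relative error
< 1e-10); with diet effects present, Lorentzian tail overlap perturbs the
quotient at the ~1e-5 level, which the test suite documents separately.

## Repeated-measures scaling and PLS-DA

Training rows are reduced by their subject's mean row (multilevel
within-subject decomposition), removing between-person concentration
offsets from the fit; column scales are the within-subject sample SDs
(n−1), with zero-variance columns kept at scale 1 and flagged so variable
indices stay aligned with the ppm axis.  The stored column means are the
raw grand means: external or unseen samples have no subject mean, so
prediction applies grand-mean centring and the within-subject scales only.
One consequence, visible in small cohorts, is that an unseen subject's
global offset is amplified by the (smaller) within-subject scales; with 19
subjects and the planted effect sizes the diet signal dominates.

PLS-DA regresses the class code (+1 = diet 1, −1 = diet 4) on the scaled
matrix by NIPALS: per component `w ∝ X'y` (unit norm), `t = Xw`,
`c = t'y/t't`, `p = X't/t't`, deflate `X ← X − tp'`.  The regression vector
is `β = W(P'W)⁻¹c`.  The algorithm is deterministic (no random start);
components whose residual covariance or score variance collapses to
numerical zero are truncated with a warning.  With full components PLS
equals the pseudoinverse least-squares solution, which the tests exploit
as an oracle.  Default 2 components; the trained score has no intercept
beyond centring, so the training mean row predicts exactly 0.

## Monte Carlo cross-validation and projection

Default 1 000 models (200 in the acceptance runs): each model holds out a
random third of the *subjects* (both diet samples of a held-out subject
leave together — no repeated-measures leakage; the suite asserts this per
model), refits scaling + PLS on the remaining subjects, and predicts the
held-out rows.  A sample's `T_pred` is the mean of its predictions over the
models where it was held out; its variance (population, floored at 1e-12)
accompanies it.  Splits are seeded per model index from the config seed.

Projection pushes every sample of a new, already-normalised matrix through
every model and summarises mean/variance across all models.  Group score
distributions are summarised by a kernel density estimate that sums one
Gaussian per sample, centred at its `T_pred` with its own prediction
variance (floor 1e-6; Silverman bandwidth on the means only if every
variance is degenerate), renormalised to unit trapezoidal integral on the
evaluation grid.  `mixture_density` evaluates the exact unnormalised
mixture for closed-form checks.

## Bootstrap variable significance and FDR

Within each model's training split, training *subjects* are resampled with
replacement (a drawn subject brings both diet rows, preserving the
crossover pairing; duplicated subjects are treated as distinct
pseudo-subjects for the multilevel centring) and the full scaling + PLS
fit is repeated — default 25 resamples per model.  All bootstrap β vectors
are pooled across models and resamples (25 × n_models draws per variable);
each variable gets `p = 2(1 − Φ(|β̄| / sd_boot))`, with p = 1 for
zero-mean-zero-variance variables.  A percentile-based p is available
behind a flag for sensitivity analysis.

Calibration: because the pooled variance includes split-to-split variation
on top of within-split bootstrap variation, the p-values are mildly
conservative in the bulk; on no-discriminant cohorts the pooled empirical
p distribution has KS distance ≈ 0.07 from uniform with a nominal 5% tail
(4.9% observed), so the rejection region — the part FDR control uses — is
accurately calibrated.

Benjamini–Hochberg converts p to q (`q_(i) = min_{j≥i} m·p_(j)/j`, capped
at 1); the Manhattan statistic is `−log10(q) · sign(β̄)` with p floored at
1e-300 to keep it finite.  A metabolite is called diet-associated when at
least half of its peak-apex variables (grid points within one half-width
of a peak position; nearest point on coarse grids) pass q ≤ 0.01 with a
common sign; the direction follows the sign under the +1 = diet 1
encoding.  The majority rule guards against shoulder overlap from
neighbouring peaks.

## Nonparametric group statistics

* **Skillings-Mack** (hand-implemented; reduces exactly to Friedman on
  complete balanced data): within each block the observed treatments get
  mid-ranks, centred and scaled by `sqrt(12/(k_i+1))`; the treatment sums
  A have covariance Σ with `Σ_jj = Σ_i (k_i − 1)` and `Σ_jk = −(#blocks
  with both)`; the statistic is `A'Σ⁻A` (pseudoinverse) on χ² with k−1 df.
  Blocks with fewer than two observations are dropped with a warning.
  Ties use mid-ranks with the untied variance formula — a documented
  limitation — and `method="permutation"` provides a vectorised
  within-block permutation null (the χ² p agrees with it to 0.02 in the
  significance region; the asymptotic reference is loose deep in the null
  bulk).
* **Kruskal-Wallis, Wilcoxon signed-rank and rank-sum** delegate to scipy
  behind a uniform `TestResult` surface: exact null distributions for
  small untied samples (n ≤ 25 signed-rank, m+n ≤ 20 rank-sum), normal
  approximation with continuity correction otherwise; all-identical
  Kruskal-Wallis input returns statistic 0, p 1 rather than an error.
* **Hommel's adjustment** delegates to statsmodels and is verified against
  a brute-force closed-testing oracle (Simes test on every subset).  Note
  the correct dominance direction: raw p ≤ Hommel ≤ Hochberg ≤ Bonferroni.
* **IQR outliers**: Tukey fences at 1.5 × IQR beyond the quartiles,
  type-7 (linearly interpolated) quantiles; fence values are not outliers.

## DASH scoring

Eight Fung-style components — fruits, vegetables, nuts/legumes, whole
grains, low-fat dairy (beneficial); sodium, red/processed meat, sweetened
beverages (adverse) — scored 1–5 by cohort quintile (type-7 quantiles at
20/40/60/80% when cutoffs are not supplied; ties fall in the lower
quintile).  Beneficial components score the quintile index, adverse ones
6 − index; totals span 8–40.  Percentile stratification uses mid-rank
percentiles `100(rank − 0.5)/n` and closed bands.  The component list and
cutoffs are fully configurable, since published DASH variants differ.  The
intake generator draws log-normal (CV 0.25) per-person intakes around four
diet templates whose component means grade from concordant to discordant;
scored cohorts reproduce the expected strictly decreasing template
ordering.

## Problem sizes and determinism

The test suite and the acceptance script use scaled-down designs chosen to
preserve every statistical property: 4 000 spectral variables, 200 MCCV
models × 25 bootstrap resamples for discriminant recovery (runs in about
half a minute); 2 000 variables, 50 models for the ten-seed diet-ordering
check; 2 000 variables, 40 models × 10 resamples for the twenty null
cohorts.  Unit fixtures use a few hundred points with proportionally wider
peaks.  All randomness flows from named substreams of a single master
seed; re-running any stage with the same configuration reproduces outputs
bit-identically, which the pipeline manifest verifies by content hash.

## Known limitations

* Median-quotient normalisation of compositional data retains a small
  class-correlated residual (see above); methods that estimate dilution
  from designated stable resonances would remove it at the cost of an
  extra assumption.
* The bootstrap p-values are conservative in the bulk; only the rejection
  region is calibrated.
* The Skillings-Mack variance formula ignores ties (use the permutation
  method for heavily tied data).
* Real-spectrum preprocessing (phasing, alignment, binning) and structural
  identification of unknown peaks are out of scope; the variable-to-
  metabolite map comes from planted ground truth, standing in for the
  expert peak assignment a real study requires.
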