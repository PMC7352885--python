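# Methods

## The localization statistic

Each tissue sample is fractionated into a mitochondrial and a cytosolic
fraction; western-blot bands are quantified by densitometry.  Raw
intensities are only comparable within one blot and antibody, so every blot
carries a titration of one common HeLa whole-cell lysate per analyte.  The
titration is fitted per blot × analyte and sample bands are back-calculated
through it into HeLa-equivalent amounts, which are then normalized to the
fraction loading controls (COX IV for the mitochondrial, β-ACTIN for the
cytosolic fraction).  The relative localization of an analyte is the
quotient of relative mitochondrial over relative cytosolic protein; all
cohort statistics are computed on log10 of that quotient, and paired tumor
shifts as Δ = log10 rel_loc(T) − log10 rel_loc(N).

A patient is called **BAX-protected** when Δ(BAX) ≤ −1.0 log10.  The planted
biology puts protected tumors near −2 and everything else near 0, so the
midpoint separates shift from measurement noise; the threshold is inclusive
at the boundary.  An alternative `threshold="auto"` derives the cut from a
1-D two-means split of the cohort's deltas, for use when no external
threshold is defensible.  The threshold is a package default, not a claim
about how the original cohort's 11/23 grouping was drawn; the 11/23 split is
never hard-coded.

**Categorization.**  Patients are rank-ordered by non-tumor relative
mitochondrial BAX — stable (value, patient_id) order under ties — and split
into four ordered categories with balanced sizes: ⌊n/4⌋ each, remainder to
the middle (moderate) categories first, then outward (low_moderate,
high_moderate, high_extreme).  For n = 34 this yields 8/9/9/8.

**Carbonate extraction.**  The mitochondrial pool splits into an
OMM-integral (carbonate pellet) and an OMM-associated (supernatant) part;
the distribution statistic is integral/associated, reported on log10 scale.

## The synthetic cohort generator

Ground truth per patient, tissue and analyte is a memoryless two-compartment
exchange at steady state: translocation to the mitochondria at rate
`k_trans`, retrotranslocation at `k_retro`, giving a mitochondrial fraction
`k_trans/(k_trans+k_retro)`.  No time integration is performed — only the
equilibrium matters for localization.  The default cohort ("study_cohort"):

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `n_patients` | 34 | paired cohort size |
| `fraction_protected` | 11/34 | planted protected subgroup |
| `protected_retro_fold` | 100 | tumor BAX `k_retro` multiplier in protected patients → a 2-log10 cytosolic shift |
| `noise_sd_log10` | 0.15 | multiplicative lognormal densitometry noise per band |
| `gain_sd_log10` | 0.30 | blot × antibody gain spread (cancelled by calibration) |
| `loading_sd_log10` | 0.20 | per sample × fraction loading factor (cancelled by marker normalization) |
| `rate_jitter_log10` | 0.05 | biological tumor/non-tumor rate jitter |
| `retro_spread_log10` | 0.50 | cohort-wide spread of baseline `k_retro` (sets the Fig-1-like geometry of localization values) |
| `abundance_sd_log10` | 0.20 | spread of total analyte abundance |
| `marker_sd_log10` | 0.05 | spread of COX IV / β-ACTIN abundance — markers are loading controls, chosen for stability; four marker terms enter every paired shift, so this must be small for marker normalization to be meaningful |
| `standard_amounts` | 0.25–4 | five-point HeLa titration on every blot |

Non-tumor BAX and BAK retrotranslocate at similar, strongly correlated rates
(shared patient factor ± 0.15 log10); protection multiplies only the tumor
BAX rate.  Blots are rendered band-by-band: intensity =
gain(blot, analyte) × loaded amount × 10^N(0, noise).  A patient's two
tissues are never split across blots, so paired comparisons share one
calibration — the standard convention for paired blot designs.  The
protected flags are hidden ground truth: they never appear in lane tables
and no scoring/classification stage reads them (only the separately-emitted,
clearly-labelled evaluation report does).

Matched expression matrices are log2 intensities with per-gene baselines
N(8, 1.5), within-group sd 0.5, `n_de` planted group differences of
`effect_log2` (alternating sign) and completely-at-random detection
failures.  Survival times are exponential with a subgroup hazard ratio and
independent exponential censoring.

What the generator does **not** emulate: probe-level array artifacts and
background correction, non-random (intensity-dependent) detection failure,
saturating film response, correlation between baseline mitochondrial BAX and
the probability of protection (the categories therefore show no planted
trend in Δ), and any drug-response biology.  Passing tests show the analysis
chain is correct and well-calibrated under this model, not that the
biological conclusions transfer to any real cohort.

## Numerical choices

* **Standard-curve form.**  `fit_standard_curve` defaults to an affine OLS
  line (tolerant of a constant background offset), with a through-origin
  option.  The pipeline defaults to **through-origin**: under multiplicative
  band noise around a proportional response the affine intercept is pure fit
  noise of magnitude ~0.3 × gain, which censors bands far below the
  titration range — exactly the mitochondrial BAX bands of protected tumors
  (~10⁻³ HeLa-equivalents) — and biases log-ratios.  Through-origin
  calibration keeps every back-calculated amount positive.  Back-calculated
  amounts outside the titration range are kept but flagged extrapolated
  (extreme localizations legitimately span log scales); nonpositive amounts
  (possible in affine mode) are excluded and logged rather than floored,
  since flooring fabricates signal in log-ratios.
* **Statistics.**  Student's pooled-variance two-sample t-test is the
  default (Welch by flag); all p-values are two-sided.  Pearson p comes from
  t = r√((n−2)/(1−r²)) on n−2 df.  Holm–Šidák: ordered raw p's get
  1−(1−p_(i))^(m−i+1), enforced monotone.  Degenerate inputs (zero variance,
  constant nonzero paired differences) raise errors instead of returning
  ±∞ statistics; identical inputs return t = 0, p = 1.
* **Expression.**  Quantile normalization maps each sample's ranks onto the
  across-sample mean of order statistics, ties averaged via interpolation at
  mean rank (idempotent); samples with missing entries are mapped through
  the reference by fractional-rank interpolation.  The presence filter is
  inclusive at the boundary (exactly 80% present is kept).  Differential
  expression reports unadjusted p < α (default 0.05) selections with
  Benjamini–Hochberg values alongside; genes with < 2 observed values per
  class or zero pooled variance are skipped and logged.
* **Distances and clustering.**  Pearson distance is 1 − r on
  pairwise-complete values (≥ 3 shared observations required), Euclidean is
  taken over shared observed values; complete linkage throughout, with
  scipy's deterministic merge order.  Signature clustering uses
  Pearson/complete; patient integration uses Euclidean/complete.  kNN
  imputation fills a hole with the unweighted mean of the k (default 10)
  nearest genes by plain Euclidean distance over shared observed samples;
  entries without donors are reported and left masked.
* **Survival.**  Product-limit estimation and the Mantel–Cox chi-square
  (df = 1) are delegated to lifelines; tied events share one risk-set row
  and subjects censored at an event time count as at risk there.  The
  signature projection cuts the dendrogram at k = 2 by default (two-curve
  comparison) and compares the two largest clusters when k > 2.
* **Determinism.**  Every stage seed derives from the global seed and stage
  name via CRC-32 (< 2³¹); reruns with one config are byte-identical
  (fixed `%.10g` float formatting in all TSVs).

## Problem sizes

The packaged analyses run at the study's own scale: 34 patients × 2
tissues, ~750 bands on 17 blots, 2000 genes with 50 planted effects, and a
300-patient external cohort with hazard ratio 3.  Replicated checks
(classification recovery, shift recovery, null calibration of the tests)
use 20–100 replicate cohorts or 1000–2000 simulated nulls, which keeps every
suite at desk scale while leaving binomial/Monte-Carlo error well below the
asserted tolerances.

## Known limitations

* The kinetic form is an equilibrium abstraction; it cannot represent
  transient redistribution (e.g. drug-induced shifts over hours).
* Calibration assumes a linear detector response across the titration;
  saturating (film-like) responses would need the monotone-form hook.
* The protection threshold and the k = 2 projection cut are documented
  defaults, not inferred from data; `auto` thresholding assumes the delta
  distribution is genuinely two-component.
* Quantile normalization with heavy, unbalanced missingness relies on
  rank interpolation and is only approximately multiset-identical across
  samples in that regime.
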