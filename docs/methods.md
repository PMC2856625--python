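# Methods

This note documents the measurement model, the synthetic-data generator,
the numerical conventions, and the design decisions behind `serochip`.

## Measurement model and processing order

A two-channel allergen array is scanned at 635 nm ("red", the anti-IgE
detection channel) and 532 nm ("green").  The model is:

- every spot autofluoresces in both channels; autofluorescence differs
  between allergens and between spots of one allergen;
- the red intensity of a spot is the sum of autofluorescence and bound
  secondary antibody, R = R_AF + R_IgE;
- the green channel is unaffected by antibody binding, G = G_AF;
- on mock arrays (buffer plus labelled secondary antibody, no serum) the
  two channels are linearly related per allergen, R_AF = m·G_AF + b.

Processing order per array: (1) discard flagged spots (flag < 0, the
scanner convention for bad/absent spots; the code treats the cut-off as
configurable since instrument exports do not standardize which codes mean
"bad"); (2) log2-transform both channels, flooring intensities at 1 so a
zero-intensity spot maps to log2 = 0 rather than −∞; (3) subtract the
per-allergen fitted prediction m_a·log2 G + b_a from log2 R ("corrected"
value); (4) subtract the per-allergen detection threshold τ_a
("thresholded" value; positive call ⇔ strictly > 0); (5) aggregate
replicate spots.

Fitting and correction operate on log2 intensities by default, following
the stated processing order, even though the additive decomposition
R = R_AF + R_IgE is exact on the raw scale: on the log2 scale the
correction is a signal-to-background log-ratio, which is the quantity the
downstream statistics use.  A `scale="raw"` mode fits and corrects raw
intensities for sensitivity analysis.

The per-allergen fit is ordinary least squares over all unflagged mock
spots pooled across mock arrays.  Fewer than 3 spots → the allergen is
marked uncalibratable (no correction, no column in the IgE matrix; counted
in the run report).  Zero green variance → intercept-only fallback (m = 0,
b = mean log2 R) with a warning.  Correcting the training mocks themselves
yields per-allergen corrected values with mean exactly 0 — the standard
residual property of least squares with an intercept, used as an invariant
test.

## Threshold calibration and the quantile convention

τ_a is an interpolated empirical quantile, at p = 0.99 by default, of the
allergen's corrected mock values pooled across mock arrays.  Two
interpolation conventions are implemented:

- `"exceedance"` (default): plotting position (n+1)p (interpolating
  between the ⌊(n+1)p⌋-th and ⌈(n+1)p⌉-th order statistics).  Because
  E[P(X > X_(k))] = (n+1−k)/(n+1) for a continuous distribution, this
  choice makes the expected probability that a *fresh* null value exceeds
  the threshold equal to 1 − p (up to interpolation), independent of n.
- `"linear"`: plotting position (n−1)p + 1, the numpy/R default (e.g. the
  99th percentile of 1..100 is 99.01).

The distinction matters at this assay's calibration depth.  With 36 mock
arrays × triplicate spots ≈ 106 unflagged values per allergen, the
`"linear"` quantile's expected held-out exceedance at p = 0.99 is
≈ 2/(n+1) ≈ 1.9% — nearly double the nominal rate — while the
exceedance-calibrated position delivers ≈ 1.0%.  Since the threshold's
entire purpose is false-positive control at the stated 1% rate, the
exceedance-calibrated convention is the default; the textbook convention
remains selectable via `convention="linear"`.  Thresholds supported by
fewer than 20 values are flagged low-confidence.

Threshold subtraction can produce negative microarray units; values are
reported as-is (positivity is the strict > 0 rule, not a clip), with
flooring left to display code.

## Replicate aggregation

"Microarray units" for a serum–allergen cell are the one-step Tukey
biweight mean of the cell's replicate thresholded values: location starts
at the median, scale is the unscaled median absolute deviation, points
beyond c·MAD (c = 5) get zero weight, and a zero MAD returns the median.
One step (no iteration) keeps the estimate exactly reproducible and is
sufficient at n = 3.  The Tukey trimean and the plain mean are available
alternatives.  A cell with more than 50% of its expected replicates
missing is discarded (NaN); the rule is applied per serum–allergen cell
within each array (the stricter, local reading of "allergens with >50%
missing data were discarded"), and again when replicate arrays of one
serum are averaged into a single row.

## Synthetic-data generator

The generator exists so every pipeline stage can be tested against known
ground truth.  It emulates:

- per-label autofluorescence: log2 G ~ Normal(mu_G, sigma_G) and
  log2 R = m·log2 G + b + eps, eps ~ Normal(0, sigma_eps), with
  (mu_G, m, b) drawn once per label from uniform ranges — mu_G ∈ [7, 11],
  m ∈ [0.7, 1.1], b ∈ [−1, 2], sigma_G = 0.8, sigma_eps = 0.3.  No
  published distribution exists for between-allergen autofluorescence
  variation; these ranges were chosen once to give a strong positive
  red-on-green trend spanning a realistic intensity range and are not
  tuned thereafter.  Standard-curve spots of one isotype share a single
  parameter draw (one material printed at several amounts);
- serum-specific IgE as a nonnegative log2-scale increment to the red
  channel only, scaled by dilution through h(d) = d/d_ref (d_ref = 0.25,
  the assay's working dilution) — the simplest monotone response
  consistent with a predictable, consistent signal decrease under serial
  dilution.  A raw-scale-additive variant sits behind
  `signal_scale="raw"`;
- IgE standard curves gaining red signal ∝ log2(1 + pg/spot) (gain 0.8),
  on mock and serum arrays alike, since the labelled anti-IgE binds
  printed IgE directly; IgG/IgA standards gain nothing.  These feed only
  the monotonicity QC (Spearman ρ > 0.9), never normalization;
- spot flagging as i.i.d. Bernoulli(0.02);
- the reproducibility design: 80 allergens in triplicate plus controls and
  standards, 12 arrays per slide; 6 sera × 18 replicate arrays + 36 mock
  arrays = 144 arrays on 12 slides.  Per day, each serum's 6 arrays are
  spread 2-per-slide over the day's 3 shared slides, with serum-to-
  position assignment randomized.  The published description of the
  replication scheme is internally over-constrained (6 same-slide arrays,
  3 same-day slides and 3 days cannot all coexist within 18 replicates);
  this layout is the one that provides ≥2 observations at all three
  replication levels the CV report distinguishes.  Serum profiles draw a
  per-serum breadth multiplier so panels span a wide range of overall
  reactivity;
- an ELISA panel in kU/L: non-sensitized pairs measure max(0, Normal(0,
  noise_sd)); sensitized pairs exceed the 0.35 kU/L clinical cutoff with
  a configurable probability (default 0.81) and magnitudes scaling with
  the true effect.

All generators are pure functions of (config, seed): parameters, spot
noise, flags, design fill and ELISA values come from named substreams of
one seed sequence.

What the generator does *not* model — and hence what passing tests do not
establish about real data: spatial artifacts and print-tip effects,
scanner saturation, non-linear or heteroscedastic autofluorescence,
cross-reactivity structure beyond planted correlation blocks, lot-to-lot
extract variability, and day/slide batch effects (days and slides differ
only through sampling noise, so the synthetic inter-assay CV is optimistic
relative to a real laboratory).

## Statistics

CV = sd/mean over replicates, computed at three levels: within slide
(arrays of one serum on one slide, same day), between slides (per-slide
means within a day), and between assays (per-day means).  Cells with
replicate mean ≤ 0.5 microarray units are excluded — near-zero means make
CV explode on pure noise — and medians are reported per allergen class
(surface / cytoplasm / pollen extract / non-pollen extract / recombinant).

ANOVA variance shares use a crossed fixed-main-effects model with
sequential (type I) sums of squares in the order array position, slide,
serum, allergen, with the residual as error; %SS_T = SS/ΣSS × 100 against
the total including error.  The factor list and order are configurable;
single-level factors are dropped.  Nested alternatives were considered and
rejected as the default because the replication scheme cannot be uniquely
reconstructed; the crossed decomposition matches the factor list reported
for this assay class.

Replicate concordance regresses every pair of same-serum replicate arrays
(profile over allergens) by OLS, reporting per-pair slope and R² and their
medians.  Matched-pairs comparisons between allergen fractions use the
paired t-test on per-serum differences with two-tailed p-values and no
multiple-testing correction by default (Bonferroni/BH available); an
all-zero difference vector raises rather than reporting p = 1.  ELISA
positivity is strictly > 0.35 kU/L; the concordance table reports 2×2
counts, proportions of total, and the fraction of ELISA positives captured
by the array.

## Clustering with bootstrap support

Allergen columns of the IgE matrix are clustered by UPGMA on correlation
distance d = 1 − Pearson r, computed over pairwise-complete sera (no value
imputation).  Zero-variance columns are excluded with a warning; a pair
with fewer than two complete rows gets distance 1 (r = 0).  Agglomeration
ties are broken by the lexicographically smallest pair of cluster keys, so
the tree is invariant to input column order; the hand-rolled implementation
is cross-checked in tests against both scipy's average linkage and an
exhaustive mean-over-leaf-pairs oracle.

BP support of a clade is the fraction of B row-resampled trees containing
exactly that leaf set (B = 1000 by default).  AU support follows the
multiscale-bootstrap construction: bootstrap at resample sizes round(r·n)
for r ∈ {0.5, …, 1.4} (step 0.1, scale 1 always included), transform
z_r = Φ⁻¹(1 − BP_r) with BP_r clipped to [1/(B+1), B/(B+1)] to keep the
probit finite, fit z_r = v√r + c/√r by weighted least squares (delta-method
weights B·φ(z)²/(BP(1−BP))), and report AU = 1 − Φ(v − c).  A clade seen
never or always at every scale short-circuits to AU 0 or 1 with a
degenerate-fit flag.  Newick export writes merge-height branch lengths
(leaves at height 0) and "AU/BP" internal labels, quoting labels containing
spaces or metacharacters.

## Pipeline, determinism, problem sizes

`run_pipeline` chains preprocess → fit → correct → calibrate → threshold →
aggregate → statistics → cluster from a slide manifest, writing every
artifact with the run's config hash and seed, counting every discarded
spot, uncalibratable allergen and skipped stage in `run_report.json`, and
failing with an actionable message when the manifest holds no mock arrays.
Identical config and inputs produce byte-identical artifacts.

Simulation sizes in the examples, tests and acceptance script are chosen
to estimate each quantity well past its decision boundary: ≥35,000
held-out null spots for the false-positive rate (binomial SE ≈ 0.05
percentage points; the residual run-to-run spread is dominated by the
per-allergen threshold estimates themselves, ≈ 0.1 points when averaged
over 80 allergens), ~200 mock spots per allergen for parameter recovery,
the full 918-pair replicate design for concordance, and B = 1000 bootstrap
replicates for clade support.

## Known limitations

- The raw-scale correction mode subtracts a fitted raw-intensity line;
  at high autofluorescence its corrected values are not comparable across
  allergens the way log-ratios are.
- AU p-values carry no standard errors, and the weighted fit assumes
  independent BP_r across scales (they share no resamples, but the
  observed tree is common to all).
- The >50%-missing rule interacts with the triplicate layout coarsely:
  with 3 replicates, a single surviving spot is discarded, two survive.
- Clustering assumes enough sera rows (≥3, realistically ≥10) for stable
  correlation estimates; with few sera BP values are anti-conservative.
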