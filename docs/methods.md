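# Methods

This note documents the statistical models implemented in `adaptomics`,
their assumptions, the defaults and why, what the synthetic-data
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Isobaric quantification by median sweeping

A PSM (peptide-spectrum match) carries ten reporter-ion intensities,
one per TMT 10-plex channel. Reporter intensities are informative only
*relatively*: ionisation efficiency and sampling depth differ per
spectrum by orders of magnitude. Median sweeping removes the
spectrum-level scale by subtracting each PSM's row median on the log2
scale; a gene's profile is then the per-channel median over its
*unique* PSMs (shared peptides are excluded because their signal mixes
genes), and a final column-median centring removes channel-loading
differences. The procedure is therefore invariant to multiplying any
single PSM's intensities by a positive constant, which the tests assert
directly.

Missing reporter values are excluded from row medians rather than
imputed — the median is robust to missingness and any imputation would
have to invent a scale that sweeping immediately removes. PSMs with
fewer than two quantified channels carry no relative information and
are dropped with a warning. `min_psms` defaults to 1: single-PSM genes
are retained (with their PSM count recorded so the moderated test can
down-weight them through its variance prior).

### Bridging two multiplex sets

Sample channels in different MS runs are not directly comparable. The
supported design dedicates channel 10 of each set to a pooled internal
reference (a physical mix of all sample channels of all sets). Each
sample column is expressed as a log2 ratio to its own set's reference
column, the reference columns are dropped, and the sets are joined on
the genes quantified in both. Because the reference is the *same
material* in both sets, any set-level additive offset cancels — the
tests assert invariance under a constant shift of one whole set. The
ratio-to-reference arithmetic is the standard pooled-reference design;
no other cross-set alignment (e.g. quantile matching) is attempted.

### Picked protein FDR

Protein-level confidence uses target/decoy competition on gene symbols:
for each symbol only the higher-scoring of its target/decoy entries is
kept (score ties keep the target — the conservative convention, since a
tie carries no evidence for the decoy), entries are ranked by
decreasing score, FDR at rank k is `#decoys/#targets` within the top k
(0/0 → 0, capped at 1), and the q-value is the running minimum of FDR
from the bottom of the ranking. Targets with q ≤ 0.01 pass. On
exchangeable (null) scores the fraction of targets reaching q ≤ 0.01
stays below 2%, verified over 200 simulations.

## Differential expression

### Protein level: PSM-count-aware moderated t

Per gene, the residual variance s² is pooled over all conditions with
≥ 2 replicates. The defining idea is that a gene's quantification
precision grows with its spectral evidence, so the empirical-Bayes
prior variance s₀² follows a smoothed trend of log s² against
log2(PSM count), fitted by lowess (frac = 0.75); below 50 genes the
trend falls back to the global mean. The prior degrees of freedom d₀
come from the method of moments on the trend residuals using
Var[log s²] = ψ′(d/2) + ψ′(d₀/2) under the scaled-F model (ψ′ inverted
by Newton iteration); d₀ is capped at 100 for stability on small
simulations — at that point the test is already essentially a pooled
z-test. The posterior variance is the usual precision-weighted blend
`(d₀ s₀² + d s²)/(d₀ + d)` and the moderated t has d + d₀ degrees of
freedom.

Calibration on null simulations (2000 genes, triplicates, homoscedastic
log2 noise): raw p-values are uniform by KS test and the false-positive
rate at the significance cutoffs is far below 1%. Power exceeds the
unmoderated two-sample t-test at triplicate n, and planted log2
fold-changes are recovered without bias. Conditions with only duplicate
samples are never tested — they can be summarised descriptively, but
the residual-df accounting assumes at least triplicates for a stable
pooled variance.

### mRNA level: simplified negative-binomial Wald test

This is a deliberately simplified stand-in for full NB-GLM machinery,
adequate for single-factor, two-level contrasts:

* size factors by median-of-ratios against the geometric-mean
  pseudo-reference (genes with a zero anywhere are excluded from the
  reference, all-zero genes from the analysis);
* gene-wise dispersion by the method of moments on within-condition
  variances, floored at 1e-8, then shrunk 50/50 toward the parametric
  trend α(μ) = a₀ + a₁/μ (coefficients fitted by least squares and
  clipped at 0);
* Wald statistic on log2((m̄_B + ½)/(m̄_A + ½)) of normalised means,
  with delta-method standard error from Var(m̄) = (μ + αμ²)/n.

The reference distribution is t with a Satterthwaite-style effective
df. The two naive choices both fail: a plain normal reference is
anti-conservative (measured ≈ 2.0× nominal type-I error at α = 0.01 at
triplicate n, because the plug-in variance ignores estimation error),
while t with the residual df (4) is so conservative that the BH step-up
collapses on realistic effect sizes. Because the shrunk dispersion is
`0.5·gene-wise + 0.5·trend` and the trend is estimated from thousands
of genes (effectively infinite df), the variance of the shrunk
estimator is w² = 0.25 times the gene-wise one, giving
df_eff = df_resid / w² = 16 at triplicates. Measured calibration at
df_eff: 1.01× / 0.88× nominal at α = 0.05 / 0.01. No claim of
numerical agreement with any specific NB-GLM implementation is made.

### Cutoffs and clustering

Significance is |log2FC| > 1 with BH-adjusted p < 0.01 at mRNA level
and |log2FC| > 0.5 with p < 0.01 at protein level (protein fold
changes are compressed relative to mRNA, hence the lower threshold).
Sample clustering uses 1 − Pearson r as the distance with average
linkage; the distance is the only fixed choice, linkage is
configurable, and zero-variance columns are rejected by name rather
than silently producing NaN correlations.

## Drug-screen scoring

### Normalisation

Per plate, viability is linear between the mean DMSO (negative,
100% viable) and benzethonium-chloride (positive, 0% viable) control
signals; % inhibition is 100 − viability. Normalised responses are
then clamped to [0, 100] by default. The clamp matters: the
dose-response model below is itself bounded to [0, 100], so reader
noise that pushes a zero-effect well to −15% inhibition cannot be
absorbed by the fit and would inflate the residual standard error —
with 5 doses and 4 parameters the SE has a single degree of freedom —
causing the SE-based QC filter to discard arms whose only defect is
ordinary well noise (measured: ~30% of arms at 10-point noise,
collapsing hit recall from ≈ 92% to ≈ 63%). Screening pipelines
conventionally clamp to the assay's physical domain for the same
reason. `clip_range=None` disables the clamp.

### 4PL fit and DSS

Each compound-arm is fitted with
`y(x) = d + (a − d)/(1 + 10^{b(c − x)})` (x = log10 dose) by bounded
least squares: a ∈ [0, 100], d ∈ [0, a] (parameterised as a fraction
of a so the constraint holds inside the box), b ∈ (0, 10], c within
± 2 log10 units of the tested window. The residual standard error is
`sqrt(SSR/(n − 4))` (floored at 1 df) in % units. A failed or
non-finite fit falls back to a flat curve at the mean response, flagged
non-converged, and is excluded from hit calling so optimizer failures
can never manufacture synergy.

The drug sensitivity score integrates inhibition above an activity
threshold t (default 10%) over the tested window [x_min, x_max] in
closed form, using the antiderivative
`F(x) = d·x + (a − d)·ln(1 + 10^{b(x−c)})/(b ln 10)` and the crossing
point `x₁ = c − log10((a − t)/(t − d))/b` (clipped to the window;
x₁ = x_min when d ≥ t; DSS = 0 when a ≤ t):

    DSS1 = 100 · [F(x_max) − F(x₁) − t(x_max − x₁)] / ((100 − t)(x_max − x_min))

so a curve pinned at 100% inhibition scores exactly 100. The closed
form agrees with adaptive quadrature of (y − t)+ to 1e-6 relative
error over 1000 random curves, and is monotone increasing in a and in
potency (decreasing c). DSS2/DSS3 variants accept an extra
configurable normalisation factor; DSS1 is the default and the only
variant with an asserted closed form, because published DSS variants
differ in normalisation details that are not fixed here.

### Synergy and QC

`sDSS = DSS_combo − DSS_mono` (antisymmetric under arm swap). A hit
requires sDSS > 5 and both arms passing QC: residual SE ≤ 19 (strict
exclusion above 19, a value retained exactly at the threshold) and a
converged fit. The anchor-drug concentration in the combination arm is
metadata only; it never enters the dose axis.

## Integration and enrichment

Gene identity is the upper-cased symbol string throughout — no alias
resolution, keeping all set logic deterministic and dependency-free.
ChIP consensus keeps genes evidenced in ≥ `min_experiments` (default 4
of 7) experiments; candidates are the consensus intersected with genes
significantly up-regulated at protein level in at least one tested
condition (a gene up in one condition and down in another still
qualifies — only the ≥ 1 up call is required, a documented assumption).
Drug-target annotation is a deduplicated union across sources.

ORA uses the upper-tail hypergeometric probability P(X ≥ k) for an
overlap of k between the query and a set of size m inside a background
universe of size N (equivalently one-sided Fisher, which the tests use
as the independent oracle). Gene sets are restricted to the background
*before* m and N are computed, matching the use of profiled-gene
reference lists as background; sets outside [5, 2000] members after
restriction are not tested (configurable — the conventional window, not
a calibrated one). BH-FDR < 0.05 flags enrichment; plot ranking is by
descending −log10(FDR) with alphabetical tie-breaks and zero FDRs
capped at 300.

## Synthetic data: what it emulates, and what it does not

The generators produce the full input surface at desk scale with known
truth, under one seed (`numpy.random.default_rng`; all downstream
tables are written in sorted order so runs are byte-reproducible):

* **PSM tables** — two 10-plex sets, triplicate conditions
  (untreated / 24 h / 48 h treatment under control- and
  target-silencing arms), pooled reference in channel 10. Log2
  intensity = gene baseline (N(16, 1.5)) + per-PSM offset (N(0, 1),
  absorbed by sweeping) + planted condition effect + N(0, noise_sd).
  PSM counts are 1 + Poisson(mean − 1), default mean 3. The reference
  channel carries the pooled mean intensity over every sample condition
  of every set, so bridging cancels it exactly. Default noise 0.2 log2
  units — typical of TMT ratio scatter after sweeping.
* **Count matrices** — NB(mean = lib_size · baseline · 2^lfc, α) via
  the Gamma-Poisson mixture (α = 0 degenerates to Poisson), log-normal
  baselines around 250 counts, triplicates of an untreated control and
  three treatment durations, planted time-increasing fold changes.
  Default α = 0.05, typical of cell-line RNA-seq.
* **Screen plates** — 528 compounds (17 planted synergists by
  default), 5 doses spanning a 10,000-fold range from 1 nM, mono +
  combination arms, 16 DMSO and 8 positive-control wells per 40-compound
  plate. Curves are 4PL with top U[0, 100], bottom 0, slope U[0.5, 3],
  inflection uniform in the log10 window. Planted synergists are drawn
  with potency headroom (top ≥ 60, slope ≥ 1, inflection in the upper
  half of the window) and get a −1.5 log10 potency shift in the
  combination arm — without the headroom constraint a "planted"
  synergist could carry a true sDSS of ~0 and recovery would be
  untestable; with it the minimum true sDSS exceeds the hit cutoff by
  a wide margin. Non-synergists respond identically in both arms.
  Default well noise 5% inhibition; the assay's true noise is unknown,
  so this is a configurable choice, not a calibration.
* **ChIP experiments** — every planted consensus gene enters ≥ 4 of 7
  experiments; all universe genes additionally enter each experiment
  independently at `background_rate` (default 0.1).
* **Decoy scores** — one target and one decoy score per gene; shift 0
  gives the exchangeable null for FDR calibration.

Not emulated: raw spectra, isotope impurity, reads, plate spatial
effects, batch effects, dose-dependent noise, or any correlation
structure between genes. Passing tests therefore demonstrate the
correctness and calibration of the *procedures* under their stated
models — not robustness to the full messiness of real acquisitions.

## Problem sizes and degenerate inputs

Simulation scales were chosen as the smallest that make the statistical
assertions stable: 2000 genes for calibration checks, 200 compounds
for exact screen recovery, 50 seeded replicates for noisy recall, 200
simulations for FDR and ORA null rates. Degenerate inputs fail loudly
and early: empty matrices, missing reference columns, inverted control
signals, non-positive intensities, out-of-range rates and windows all
raise with the offending object named. One statistical edge case is
handled specially: at exactly zero noise the residual variance is zero
for every gene and a moderated test is undefined, so planted-truth
recovery is exercised at minimal (0.05 log2) noise with effect sizes
that dwarf it, which recovers the planted sets exactly.
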