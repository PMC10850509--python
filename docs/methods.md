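# Methods

This note documents the models, conventions, defaults and known
limitations behind each stage of the package.  Everything quantitative
here is computed by the test suite or `scripts/acceptance.py`; nothing is
asserted that the code does not reproduce.

## Highly enriched region calling

The caller follows the superenhancer-style recipe: blacklist filtering,
stitching, input-subtracted density, rank normalization, slope-1 cutoff,
nearest-gene annotation.

**Stitching.** The gap between peaks is edge-to-edge
(`next.start - prev.end`) and a gap exactly equal to the stitch distance
*D* (default 40 000 bp) merges.  Stitching of sorted peaks by running-gap
merge is exactly the transitive closure of the pairwise relation
`gap <= D`; the suite verifies this against a brute-force union-find
oracle on a thousand random instances, and verifies idempotence.

**Density.** Only constituent-peak bases count:
`density = (chip_sum - input_sum) / constituent_width`, where the sums run
over peak bases and the width is the summed peak width.  Densities may be
negative when input exceeds ChIP; such regions sort below all positive
regions and can never be flagged.  Coverage between peaks is provably
irrelevant (tested by perturbing gap coverage).

**Slope-1 threshold.** Signals are sorted ascending, normalized to the
maximum (= 1), and plotted against fractional rank i/n (highest = 1).
On this square plot the average slope is 1, so "slope = 1" marks where the
curve leaves its flat tail.  Two constructions are selectable via
`CallerConfig.threshold_method`:

* `tangent` (default): the point minimizing `normalized - rank`, i.e.
  where a slope-1 line is tangent to the (convex) curve.  This is the
  construction used by widely circulated superenhancer implementations.
  It is global, so near-ties between adjacent strong regions cannot
  displace it — important when only tens of regions exist, where a local
  derivative estimate crosses 1 spuriously between near-tied top regions.
* `derivative`: a centered secant over a rank window (default 1% of
  points, minimum 3); the threshold sits at the largest rank where the
  derivative transitions from < 1 to >= 1, so flat tails do not dilute
  the cutoff.

Degenerate curves behave identically under both: an everywhere-steep
(e.g. exactly linear) curve flags all regions; an everywhere-flat curve
flags none and returns a warning flag.  Both methods place the threshold
of the analytic curve s_i = (i/n)^2 at rank 0.50 and normalized signal
0.25.  Regions strictly above the threshold are flagged.

**Nearest genes.** Peak midpoint (floor of (start+end)/2) to TSS; ties go
to the lower TSS coordinate.  A region's gene set is the union over its
constituent peaks.

## Loop model and target-gene scores

**Retention.** `pet_count >= min_pets` (default 4, inclusive) and
`fdr < max_fdr` (default 0.01, strict).  Filtering is order-independent
and idempotent.

**Anchor classes.** An H3K27ac anchor overlapping >= 1 VCP peak by >= 1 bp
is a VCP anchor; otherwise control.  A loop with at least one VCP anchor
is a VCP loop (either-end convention, mirroring paired-interval
intersection tools); a loop with none is control.  An optional mode
restricts the VCP peak set to peaks inside highly enriched regions,
yielding superenhancer-grade VCP loops.

**Normalized loop score.** The strength of a loop relative to library
depth.  Default: PET divided by the mean PET of retained loops, so the
NLS has unit mean and is invariant to uniform PET scaling.  Per-million
and median-scaled variants are selectable; all satisfy the same
invariances.

**Gene aggregate score.** Promoter context: peak center within
±`promoter_window` (default 2 500 bp) of the TSS, half-open on the right.
Looped-enhancer context: peak center inside one anchor whose partner
anchor intersects the gene's promoter window.  Enrichment `E_f(p)` is the
*mean* (not sum) of the factor's track over the 1 kb window centered on
the peak center, making scores bin-size invariant.  The aggregate adds
promoter enrichments and NLS-weighted looped-enhancer enrichments; genes
with any enhancer pair are classed `looped_enhancer`, with only promoter
peaks `promoter_only`, otherwise `untargeted` (score exactly 0).  Scores
are additive over evidence: removing a loop removes exactly its
`E x NLS` term.  `nls_per_promoter` sums NLS over VCP-class loops whose
anchor touches the gene's promoter window.

**Depletion contrast.** Conditions are matched by exact anchor
coordinates (valid whenever anchors derive from one peak set; a
reciprocal-overlap matcher is provided for external callers).  Per
matched loop: `log2((pet_d/M_d + eps) / (pet_b/M_b + eps))` with M the
condition totals and pseudocount eps = 0.5 on the depth-normalized scale
(guards lost loops against -inf).  VCP vs control ratio distributions are
compared with a two-sided Mann-Whitney test; an all-tied ratio vector
short-circuits to p = 1.  At depletion factor 1 the rejection rate is
calibrated (~5% over 200 simulated datasets); at 0.5 with >= 500 loops
the shift is detected (p < 0.01, VCP median below control) in every
tested seed.

## Proteomics enrichment

PSMs are median-aggregated per (protein, peptide, channel); even counts
use the mean of the two middle values; peptides matching multiple master
proteins are excluded.  Per peptide, a two-sample t statistic on log2
intensities (pooled variance, df = n1+n2-2) gives a p-value; zeros are
offset by half the smallest nonzero intensity first (configurable).  Per
protein, fold enrichment is the median peptide linear ratio and the
p-value is the (k+1)-th smallest peptide p (k = floor(n/2)) evaluated
under its exact Beta(k+1, n-k) order-statistic null — the probability
integral transform keeps protein-level null p-values exactly uniform,
verified by KS on a 2 000-protein null simulation.  A pooled variance
floor is available (`variance_floor_quantile`); the default of 0 keeps
the null exact and only a numerical guard remains.  This statistic is a
self-contained surrogate for peptide-level enrichment-curve analysis and
deliberately not a reimplementation of any external package; precomputed
protein tables are accepted wherever a different upstream is preferred.

The ranking score is read literally as a product:
`-log10(q) x (2 x fold_enrichment)`, fold on the linear scale.  It is
strictly increasing in fold at fixed q and strictly decreasing in q at
fixed positive fold; q = 0 is clamped to the smallest positive float.

## Association statistics

* **Peak-count bins**: genes binned by associated peak count; two-sided
  Welch t between the pooled 1–2 group and the >= 3 group; groups with
  < 2 genes skip the test but still report bins.
* **Overlap chi-square**: observed = peaks overlapping >= 1 feature by
  >= 1 bp; random = the same count after width-preserving uniform
  re-placement within each peak's own chromosome, averaged over
  `n_draws` and rounded.  The 2x2 table is tested without continuity
  correction at df = 1.  With `n_draws = 1` (default) the random arm is a
  genuine single realization and the type-I rate is ~5% at alpha = 0.05;
  averaging many draws shrinks the random arm's variance and makes the
  test conservative — use draws > 1 only for a stable point estimate of
  the random overlap, not for calibrated inference.
* **Fold-change correlation**: Spearman (midrank ties) and Pearson over
  the gene-set intersection; requires >= 3 shared genes.
* **Responsive genes**: linear fold >= 8 (log2fc >= 3, inclusive) AND
  adjusted p < 0.01 (strict) in *every* supplied contrast; a gene absent
  from a contrast fails it.  Selection is monotone in both thresholds.
* **Top-percent / PC1**: top ceil(n x pct/100) genes by score (ties by
  gene id); PCA by eigen-decomposition of the gene-wise covariance of the
  row-centered expression matrix over the selected genes.  PC1's sign is
  fixed by positive correlation of its loadings with the mean
  control-minus-knockdown difference, making "coefficient > 0.05"
  well-defined; coefficients are signed, not absolute.

## Synthetic data: what it emulates, and what it does not

The generator lays loci on a jittered grid (spacing 70 kb, above the
40 kb stitch distance) over a small genome (default 3 x 15 Mb):

* **Peaks**: `n_clusters` clusters of `peaks_per_cluster` factor peaks
  within `cluster_span` (the planted highly enriched regions), plus
  singleton peaks split between gene promoters and distal sites.  Factor
  B ("vcp") mirrors factor A ("at3") with <= 50 bp jitter.  H3K27ac peaks
  span clusters, flank singleton sites, and mark loop-target promoters.
* **Tracks**: per-bin (50 bp) Poisson counts around planted means —
  background 10 per bin (an ordinary sequencing depth for a track in
  count units), singleton peaks 5x background, cluster peaks
  `signal_fold` (default 4) above singletons, per-site strengths
  U(0.7, 1.5) shared between factors through `factor_correlation`.  The
  input track is pure background.  A `noise=False` switch yields exact
  means for closed-form tests.  At these levels the planted clusters are
  statistically recoverable; at background ~1 per bin the window-level
  Poisson noise exceeds the max/n gap scale of the rank curve and *no*
  slope-1 rule separates the populations — a depth, not algorithm, limit.
* **Loops**: anchors join cluster H3K27ac intervals (VCP loops) or
  H3K27ac-only enhancer sites (control loops) to promoter H3K27ac
  intervals.  PET ~ NegBin(mean 24 x U(0.75, 1.5), dispersion 10).  A
  configured number of loops passes the retention filter by construction:
  passing loops draw PET conditioned >= 4 (in both conditions, so a
  depletion factor of 1 leaves distributions exactly identical and the
  class contrast calibrated) and FDR below 0.009; failing loops alternate
  between a PET deficit and an FDR excess.  Depletion multiplies the PET
  mean of passing VCP loops by delta and resamples.  The conditioning
  introduces a small truncation lift in the delta = 0.5 mean-PET ratio
  (~0.52 rather than 0.50); the suite checks the exact truncated-NB
  expectation.
* **Expression**: target-gene log2FC = -beta x scaled propensity + noise,
  beta = 2, sigma = 0.5; the true propensity is the expected aggregate
  score under the planted means and expected NLS.  `effect_correlation`
  (default 0.8) is defined as the *total* inter-perturbation correlation
  among target genes; since the shared propensity term already
  contributes covariance, the generator solves for the residual noise
  correlation analytically so the planted value is what an analyst
  measures.  Adjusted p-values come from the known noise scale with BH.
* **Proteomics**: the protein table carries planted interactor folds
  (U(3, 8)) and q-values verbatim with nulls centered at fold 1; the PSM
  table realizes the same folds at reporter-intensity level (lognormal
  peptide bases, 3 IP vs 3 control channels, 1–3 PSMs per peptide).

Determinism: every output family draws from its own seeded RNG stream, so
identical (config, seed) gives byte-identical files (checksum-verified)
and adding an output never perturbs the others.

What the fixtures do **not** model: read-level data (FASTQ/BAM), fragment
length and GC structure, realistic loop distance decay, inter-locus
signal correlation, contaminant proteins, or genome-scale annotation
density.  Passing tests therefore demonstrate correctness of the
computations and their statistical calibration under the stated
generative model — not performance on real libraries, where peak calling,
normalization and batch structure dominate.

## Problem sizes and numerical choices

Default study conditions: 20 clusters x 5 peaks + 200 singletons
(regions), 120 loops / 100 passing (target scoring), 600 loops / 550
passing for contrast power and calibration (20 and 200 seeds), 2 000
proteins for null uniformity, 20 seeds for correlation recovery.  The
test suite and acceptance script both regenerate these from scratch.

Tolerances: slope comparisons use a 1e-9 guard so an exactly linear curve
counts as slope 1 under floating point; aggregate-score oracle equality
is asserted at 1e-9 relative; calibration bands are ±3 percentage points
around 5% (expressed as integer rejection counts to avoid float-edge
artifacts); recovery bands (precision/recall, AUC, Spearman >= 0.9) follow
the planted-condition analysis above.  Degenerate inputs (empty loop
sets, constant expression matrices, all-zero peptides, q = 0) raise or
warn explicitly rather than propagating NaNs.

## Known limitations

* The tangent and derivative thresholds can disagree on strongly
  non-convex rank curves; the package exposes both rather than deciding.
* The contrast's exact-coordinate loop matching assumes a shared anchor
  universe; external data should use the reciprocal-overlap matcher.
* The proteomics statistic assumes approximately log-normal reporter
  noise; heavy-tailed spectra would need a robust peptide statistic.
* The overlap test conditions on the observed feature set; it does not
  model feature clustering beyond what re-placement preserves.
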