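# Methods

`covbias` quantifies how evenly short-read resequencing (whole-exome
capture or whole-genome sequencing) covers coding sequence, separates the
sources of the unevenness, and predicts how much coding territory stays
below a usable depth at any nominal mean coverage. This note describes the
statistical machinery, the synthetic-data model behind the test suite, and
the numerical choices made where the design was genuinely open.

## Coverage tracks and filtering

All statistics operate on per-base read depth over a fixed interval
universe (typically the merged protein-coding CDS annotation), stored as
one integer array per universe interval. Two tracks are kept per sample:

* **filtered** — reads with mapping quality below a floor (`mq_min`,
  default MQ < 10) removed, matching what variant callers actually use;
* **unfiltered** — all reads regardless of MQ.

Duplicate-flagged reads and secondary/supplementary alignments are
excluded from *both* tracks. The **multimapping fraction** of a region is

    MF = (mean unfiltered depth − mean filtered depth) / mean unfiltered depth,

defined as 0 where the unfiltered depth is 0 and clamped to [0, 1]. MF is
also computed per base; the bp totals above thresholds (reported at 0.4
and 1.0 by default) measure how much sequence is reachable only by
ambiguously mapped reads. An alternative convention defines MF through
MQ = 0 reads only; `mq_min` is configurable so either reading can be
reproduced, and the subtraction form above is the default.

**Normalized coverage** divides depth by the sample's mean filtered depth
over the CDS universe (not over bait regions), so samples of different
sequencing depth are comparable.

## Evenness scores

Three scores on [0, 1], all equal to 1 for perfectly uniform coverage:

* **OE (overall evenness).** From the exceedance profile
  F(N) = fraction of CDS bases with normalized coverage ≥ N, evaluated on
  the grid N = 0.00, 0.01, …, 3.00:
  `OE = Σ_{k=1..100} 0.01 · F(0.01k)` — the area under F over N ∈ (0, 1].
  Implemented as the mean of F over those 100 grid points (identical sum,
  exact at the flat baseline).
* **BIE (between-interval evenness).** The same functional applied to the
  per-interval normalized *mean* coverages, one unit per interval
  regardless of length.
* **WIE (within-interval evenness, smoothness).** Every interval with mean
  depth strictly above 10× is split into 100 equal-bp bins (base j of an
  L-bp interval maps to bin ⌊100·j/L⌋); bin depths are divided by the
  interval mean and averaged across intervals into a shape x_1..x_100;
  `WIE = Σ_b 0.01 · min(x_b, 1)`. The capped sum over 100 bins of weight
  0.01 makes a flat shape score exactly 1. For intervals shorter than 100
  bp some bins receive no base; they are filled from the nearest populated
  bin before averaging so every qualifying interval contributes a full
  100-point shape. A `flank` option extends intervals symmetrically before
  binning (default 0).

OE confounds two phenomena that BIE and WIE separate: how depth is shared
*between* intervals and how it is distributed *within* each interval.

## The per-interval coverage model

For each interval i, across the samples of one technology, the model keeps
the mean M_i and standard deviation s_i (n−1 denominator) of normalized
mean coverage, plus a within-interval shape: the technology-average
100-bin profile stretched to the interval length and renormalized to mean
exactly 1. A simulated sample at nominal mean depth D draws

    C_i ~ Normal(M_i, s_i²)  truncated at 0,
    depth at base j of interval i = C_i · shape_ij · D,

and the expected bp below a depth threshold (default 10 reads) is the mean
count over `n_rep` replicate draws (default 100, seeded; the replicate
spread gives a Monte-Carlo standard error). Truncation at zero reflects
that normalized coverage cannot be negative; with s_i = 0 and flat shapes
the prediction reduces exactly to the closed form
Σ_i L_i · 1[M_i · D < threshold]. Averaging replicates rather than drawing
once trades a slight departure from the single-draw formulation for a much
less noisy curve; `n_rep` is configurable.

Because M_i and s_i are plug-in estimates, a prediction from a small fit
cohort carries an O(1/n_samples) inflation of the marginal spread of C_i
(the estimation variance of M_i adds s_i²/n). With 20 fit samples this is
a ≈2.5% inflation of the standard deviation, visible only when comparison
tolerances are a fraction of a percent; no bias correction is applied —
the fitted quantities are used exactly as defined.

### Systematically poorly covered intervals

An interval is *systematically* below a normalized-coverage cutoff (0.1 or
0.2) when a one-sided one-sample t-test (H1: mean < cutoff, n−1 df) on its
(M_i, s_i, n) survives step-down Holm correction at family level α = 0.05.
Zero-spread intervals degenerate to the deterministic rule
significant ⟺ M_i < cutoff. Holm controls family-wise error as the
procedure is named; a Benjamini–Hochberg option is provided. Results are
split by whether the interval overlaps (≥ 1 bp) the capture design.

### Reproducibility

Two statistics measure whether coverage dropouts are systematic: the mean
pairwise Pearson correlation of per-interval normalized coverage vectors
across samples (Spearman optional; zero-variance samples excluded from the
mean with a warning), and the intersection-to-union ratio
R = L_intersection / L_union of the per-sample sets of intervals with
normalized coverage < 0.1 (strict inequality), over k selected samples.

## GC bias

Variant sites are annotated with the GC fraction of their ±50 bp context
and split into 10 equal-count groups by GC (ties broken by genomic order);
per-decile mean *and* median normalized site depth are both reported since
either summary is defensible. Interval-level extremes are compared by
selecting GC bands (0–20% and 80–100% by default) and running a two-sided
Wilcoxon rank-sum test of each band against the remainder, with bp totals.

## Predictor importance

Which of GC content, interval length, MF, and design inclusion drives
per-interval coverage is assessed with three model families:

1. linear regression of normalized mean coverage — importance = |t| of
   each coefficient;
2. logistic classification of the low-coverage label
   (normalized mean < 0.1) on standardized predictors — importance = |z|;
   when the label is (near-)separable the unpenalized fit diverges and an
   L2-penalized fit's |standardized coefficient| stands in (flagged in the
   result notes);
3. random-forest classification with 2 candidate features per split —
   importance = mean impurity decrease.

Importances are rescaled within each family so the top predictor scores
100; classifier quality is reported as 5-fold stratified cross-validated
accuracy and Cohen's κ. Everything is deterministic under a seed. These
definitions (t-statistic for linear models, impurity decrease for forests)
are stated explicitly so ports to other ML stacks can match definitions
rather than chase numerics.

## Variant-site density (VSD)

Per-interval VSD = variant sites per bp. The depletion test compares the
unweighted mean VSD of intervals with MF > 0.4 (a pooled counts/length
mode is available behind a flag) against the means of `n_resamples`
equally sized subsets drawn without replacement from the MF ≤ 0.4 stratum;
the one-sided empirical p uses the +1 correction. Because the null
resamples from the *complement* of the query, the observed deviation is
inflated by a factor ≈ (1 + k/N_background) relative to the null spread;
the test is therefore calibrated (uniform p under label exchange) in the
small-query-fraction regime it targets — at query fractions above ~10% the
p-value becomes mildly anti-conservative in both tails. The calibration
study in the test suite probes a 2% query fraction for this reason.

## Variant-call summaries

From a VCF, per region set (all CDS, targeted CDS, …): counts of variant
genotypes (hom-ref and missing excluded; multi-allelic records counted
once, classified indel if any alt length differs from the ref — MNPs count
as SNVs), counts of low genotype-quality calls (GQ < 20 by default, the
genotype-refinement convention; missing GQ counted as lowGQ and reported
separately), and the **allele bias** AB = median of ref/(ref+alt) allele
depths over heterozygous biallelic sites with positive depth.

## The synthetic-data generator

The generator emulates the structure the statistics assume, with full
determinism under a seed (byte-identical files):

* **Intervals & genome** — disjoint intervals (default 200, 120–400 bp) on
  one synthetic chromosome; per-interval target GC ~ Beta(5, 5), realized
  by placing exactly round(GC·L) G/C bases, so realized GC matches the
  target within 0.5/L ≤ 0.02.
* **Coverage** — expected unfiltered depth =
  D · C_i · shape(position) · (1 − b·(GC − 0.5)) · inclusion factor, where
  C_i ~ Normal(M_i, (cv·M_i)²) truncated at 0 around a lognormal long-run
  interval mean (unit mean, σ = 0.5 by default; cv = 0.15), the shape is
  flat, dome (1 + a·cos(2πt − π), rescaled to mean 1) or edge-falloff
  (linear ramps over an edge fraction), b is the GC-bias slope (0 by
  default), and intervals dropped from the design (probability q, default
  0) fall to a 2% background factor. Observed unfiltered depth is Poisson
  around the expectation; the filtered track is a per-base binomial
  thinning with retention 1 − MF_i, which makes filtered ≤ unfiltered hold
  per base *exactly* and realizes MF in expectation. MF is a mixture:
  0 with probability 0.9, else Uniform(0.3, 1), with a 2% slice forced to
  exactly 1 (fully unmappable intervals). A `noise="none"` mode stores the
  latent expectations themselves for noise-free checks.
* **Variant calls** — heterozygous sites at a configurable density with
  allele depths Binomial(DP, p) at DP ~ Poisson(60); GQ = 99 except a
  configured low-GQ slice; an indel slice becomes 1-bp insertions.
* **Importance study table** — a dedicated generator reproduces the regime
  in which *continuous* coverage drifts with GC (multiplier slope 0.8)
  while the *low-coverage label* is driven by an MF > 0.9 threshold rule
  with imperfect penetrance (collapsed intervals keep Uniform(0.02, 0.18)
  of their coverage) plus rare (0.2%) design dropout. These settings were
  fixed once as the study condition for the importance analysis.

What the generator does **not** emulate: fragment-level correlation of
read placement (depths are independent Poisson per base, so the generator
understates the blockiness of real coverage), reference-bias in allele
depths beyond the binomial p, sequencing error, and alignment artifacts.
Tests passing on this generator therefore validate the *statistics*, not
the upstream alignment pipeline.

### Closed-loop validation

The central recovery property: fit (M_i, s_i, shape) on 20 generated
samples (1,000 intervals, nominal depth 80×, dome shape), then compare the
predicted bases-below-10× curve at D ∈ {20, 50, 100, 200} with the
generator's own count over 50 fresh samples, within three combined
Monte-Carlo standard errors. Both sides work in *normalized* coverage
units: the generator-truth counter rescales each sample's interval levels
by their length-weighted mean, exactly as real samples are normalized by
their realized mean CDS depth — using the nominal depth instead would
introduce a systematic offset equal to the length-weighted mean of the
drawn levels.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere internally; GTF (1-based
  inclusive) and VCF (1-based) positions are converted on ingestion.
* The chromosome whitelist for annotation ingestion is 1–22, X, Y, MT,
  with and without the `chr` prefix; scaffolds are excluded.
* Interval algebra is delegated to pyranges behind the `IntervalSet`
  container; inputs are merged before set operations, outputs are merged
  and sorted.
* `targeted` means ≥ 1 bp overlap with the design, not containment.
* Qualification for WIE is *strictly* more than 10× mean depth.
* Empty GC denominators (all-N intervals) yield NaN rather than 0.
* The within-interval profile tie-break for empty-bin filling prefers the
  left neighbour at equal distance.
* Bedgraph I/O round-trips the canonical form: adjacent equal-depth runs
  coalesced, zero runs explicit within the universe.
* No padding is applied to capture designs before intersection by default
  (`--pad` exposed).
* Orchestrated runs are content-addressed: each per-sample stage records a
  SHA-256 of its inputs and options and is skipped when unchanged.
* Reported problem sizes in the validation suite (e.g. 1,000-interval
  cohorts, 100-seed detection studies) were chosen so each property is
  measured with comfortable Monte-Carlo resolution while the full suite
  stays fast to iterate on.

## Known limitations

* The t-test treats per-interval normalized coverages as Normal; for
  intervals with means near 0 the truncation skews the distribution and
  the test becomes conservative.
* Depth-requirement predictions inherit the plug-in bias described above
  and carry no confidence band beyond the replicate spread.
* Fragment/mate structure is not modelled: reads are counted per base, and
  overlapping mates double-count, matching naive genomecov semantics.
* The VSD resampling p-value is mildly anti-conservative for large query
  fractions (see above).
* CRAM support is whatever the alignment reader provides; base-quality
  filtering and mate-overlap clipping are out of scope.
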