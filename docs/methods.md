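# Methods

`rtturnover` quantifies how the turnover of cis-regulatory elements
(enhancers) relates to the DNA replication-timing (RT) program, across
species and between healthy and tumor states. This note documents the models
and procedures, their assumptions, the parameters that matter, and the
numerical choices made where the design was genuinely open.

## Replication timing

RT is the z-scored log-ratio of early- vs late-S-phase Repli-seq coverage per
genomic bin: higher values replicate earlier. All statistics operate on the
standardized scale, so the two domain thresholds are fixed constants:

* **early**: RT > 0.5 in *every* assayed cell type,
* **late**: RT < −0.5 in every cell type,
* **dynamic**: everything else.

Both inequalities are strict; a value exactly at a threshold falls to
dynamic. `zscore_track` uses the population standard deviation (ddof = 0) and
raises on constant tracks. `bin_mean_rt` averages arbitrary-resolution source
records onto a fixed grid (default 200 kb) weighting by overlap length; bins
without coverage are missing and excluded downstream.

**Domain clustering** follows a two-step recipe: the number of clusters k is
chosen by Gaussian-mixture BIC over 1..k_max (default 20) on the bin ×
cell-type matrix, then k-means with that k assigns bins (seeded, 10
restarts). Cluster ids are reported 1..k ordered from earliest to latest mean
RT, which makes clusterings comparable across permuted inputs.

**Element RT** is the *unweighted* mean over all bins an element overlaps.
With 200 kb bins and ~1 kb elements the weighted/unweighted distinction is
almost always moot; a length-weighted variant is exposed
(`assign_element_rt(..., weighted=True)`) but off by default. RT quintiles
split ranked elements into five groups whose sizes differ by at most one;
ties are broken by (chrom, start) so the split is deterministic. Quintile 1
is the latest-replicating fifth by default and the output labels carry
explicit "latest"/"earliest" tags to keep the sign convention visible.

## Enhancer age and turnover

An enhancer (defined in the source data by enhancer-associated histone
marks: H3K27ac without H3K4me3, or H3K4me1) is **conserved** when the mark
co-occurs in at least two non-focal species in the element × species
presence matrix, otherwise **recent** (lineage-specific). The threshold is a
parameter (`min_other_species`), so robustness re-runs at ≥4 or ≥7 species
are one argument away.

Turnover per group (RT cluster or quintile) is
`log(n_recent / n_conserved)`. The log base is natural by default with a
flag for log2/log10; every conclusion drawn from the statistic (sign,
R², interaction tests) is base-invariant. Groups with a zero count report NA
rather than silently absorbing a pseudocount; an optional α restores
finiteness for plotting.

The summary effect size is

    P(recent | late RT) / P(recent | early RT)

computed from the constitutive classes, and the regression of group
log-ratios on group mean RT (OLS; R² is the squared Pearson r, p from the t
distribution with n − 2 df). Because higher RT means *earlier* replication,
a positive lateness effect appears as a **negative** slope on RT. Tissue
differences in the turnover-RT slope are tested with the interaction model
`log_ratio ~ mean_rt + tissue_pair + tissue_pair:mean_rt` (t test on the
interaction coefficient); the model has four parameters, so at least five
observations and four distinct design points are required.

Enrichment of a labeled element set in a second interval set (TE overlap,
eQTL, chromatin accessibility) uses Fisher's exact test on the 2 × 2 table of
label × overlaps, where "overlaps" means at least `min_overlap_frac` of the
element's base pairs are covered by the union footprint of the other set
(any overlap when the fraction is 0; 0.3 with alternative "greater" for the
accessibility check). The p value is always the exact hypergeometric tail
sum, never a chi-square approximation; the point estimate is the sample
cross-product ratio ad/bc; confidence intervals invert Fisher's noncentral
hypergeometric test (the R `fisher.test` convention).

**Singletons.** Pairwise homology hits (tabular BLAST, outfmt 6) are
filtered to E-value < 1e-6 (strict) and query coverage > 20 % (strict),
self-hits dropped, and connected components formed; elements in no surviving
component of size > 1 are singletons — elements without evidence of recent
duplication.

**Divergence expectation.** `expected_substitutions_per_kb(T, g, μ)` returns
(T·10⁶/g)·μ·1000: e.g. 29 Myr, 25 yr and 1.28e-8 per base per generation
give ≈14.85 (~15) substitutions/kb on the human lineage since the
human-macaque split; 12 Myr, 0.5 yr and 5e-9 give 120 on the mouse lineage
since the mouse-rat split.

**Cancer turnover.** A tumor peak reciprocally overlapping a healthy peak by
≥ 50 % (configurable) of the *shorter* of the two is "unchanged"; tumor-only
peaks are "gained", healthy-only "lost". Mutation burden is somatic variant
count divided by element width (per bp); the log form uses log10(burden + ε)
with configurable ε so zero-burden elements stay finite. Group comparisons
use the two-sided Mann-Whitney U test. Gain/loss quintile profiles report
gains/unchanged and −(losses/unchanged) per RT quintile (the sign flip is
the mirror-bar display convention).

## DAF selection scan

Variants are classed **rare** (derived allele frequency < 1.5 %, strict) or
**common** (> 5 %, strict); intermediate frequencies are excluded from every
count. Around a set of motif centers, rare and common variants are pooled
into 10 bp offset windows with floor division, so window 0 covers
[center, center + 10). Variants inside several centers' reach are counted
once per center — the pooled, stack-and-sum reading of a centered profile.

Per-window rates are normalized by the mean rates over the union of the
[−4000, −2000) and [2000, 4000) bp flanks. The per-window odds ratio
compares the window's rare/common counts against the pooled flank counts of
the same profile; when an explicit background profile is supplied the
comparison is at the same offset instead. 95 % bands come from 100 bootstrap
replicates of resampling the centers with replacement (percentile intervals,
not BCa — no bias-correction is warranted for plain resampling).
Size-matched background regions are drawn uniformly from a supplied
universe, non-overlapping, autosomes only when sex chromosomes are
recognizable by name.

## Motif composition and tissue specificity

The PWM **consensus** assigns a base only where its frequency is strictly
above 0.5, else N; GC proportion is counted over the consensus relative to
motif length. **Scanning** is a log-odds scan of both strands (Biopython
PSSM machinery, pseudocount 0.01); a hit requires a score of at least
`score_frac` (default 0.8) of the maximum attainable score. The source
analyses delegate scanning to an external annotation tool that publishes no
threshold; fraction-of-maximum is the standard replacement and the
"high-scoring motifs" rule (top quintile by score) is exposed as
`top_quintile_motifs`.

Motif RT enrichment is
`log2((present_early/absent_early)/(present_late/absent_late))` over
elements with/without at least one hit; zero cells give NA by default with
an optional Haldane pseudocount of 0.5. The statistic is antisymmetric under
swapping the early and late sets.

The substitution spectrum between aligned ancestor/descendant sequences
counts X→Y changes at ungapped positions, divides by the ancestral count of
X, and log10-transforms. A position is CpG-context when the ancestor has C
immediately followed by G; both positions are masked by default because CpG
deamination otherwise dominates the spectrum.

Tissue specificity uses tau: `τ = Σ(1 − x_i)/(N − 1)` with
x_i = expression/max; 0 is uniform, 1 single-tissue, and the index is
invariant to rescaling a gene's row. Tau is computed on values as given (an
optional log1p pre-transform exists but is off). TFs ranked by motif RT
enrichment are split into quintiles and consecutive quintiles compared by a
one-sided Mann-Whitney U with the alternative that the later-replicating
quintile has greater tau.

The 2-component Gaussian mixture on binding-site RT is fit by EM written in
this package (per-iteration log-likelihood traces are part of the contract):
k-means++ means, pooled-sd sigmas, uniform weights, sigma floored at 1e-6 to
prevent collapse, 5 restarts keeping the best log-likelihood, components
reported mu-ascending. The log-likelihood is non-decreasing across
iterations up to the floor's rounding.

## Synthetic data generator

The generator emulates the statistical structure the analysis consumes, not
the biology that produced it. One synthetic chromosome is tiled by 200 kb
bins (the analysis grid); all defaults below are the study conditions the
pipeline is validated under.

* **RT landscape** — smoothed Gaussian random field (autocorrelation length
  1 Mb), z-scored per cell type; 70 % of bins share a base field across the
  4 cell types (constitutive) and 30 % draw independently (dynamic). Truth
  records each bin's generating class via the ±0.5 thresholds on the shared
  field.
* **Enhancers** — an inhomogeneous point process over bins: expected
  abundance ∝ exp(0.5·RT) (more enhancers at early domains, as observed),
  ~20 per 200 kb bin, lengths lognormal around 1 kb, placed on a slotted
  grid so elements never overlap. Age is Bernoulli with
  logit P(recent) = −0.2 + 0.45·(−RT); the slope default makes recent
  enhancers roughly twice as frequent per element at late vs early domains.
  The mark matrix realizes the labels exactly under the ≥2-species rule
  (conserved: 2 + geometric(0.5) other species; recent: ≤1). Enhancer birth
  is modeled as labels over bins, not mutational histories, because every
  downstream statistic consumes counts and labels.
* **Sequences** — i.i.d. bases with GC probability
  logistic(logit(0.41) + 0.08·RT), matching the observed GC-RT coupling
  direction with a realistic dynamic range; optional planted PWM instances,
  AT-rich motifs weighted toward late elements.
* **Variants** — uniform placement over a region footprint at 0.01/bp; DAF
  drawn from a three-class spectrum (55 % rare, 20 % intermediate, 25 %
  common) so both scan classes are populated; at constrained motif positions
  the rare:common odds are multiplied by `selection_rare_excess`
  (1 = neutral).
* **Cancer** — per-element gain/loss probabilities 0.12·exp(0.6·lateness)
  (capped), unchanged peaks identical in both states; somatic counts Poisson
  with rate 0.002/bp · width · (1 + 0.3·lateness), doubled at gained/lost
  elements.
* **Expression** — genes drawn from tau target classes (0.1, 0.5, 0.9); the
  construction (one maximal tissue, others at 1 − τ) realizes the target
  exactly before a ±0.02 noise perturbation.

One global seed fans out to per-generator child streams
(`numpy.random.SeedSequence` spawn keys), so outputs are byte-identical
given a config and independent across generators.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic chromatin-state emission, linkage and
demography in the variant spectrum (only the rare/common dichotomy is
modeled), TE sequence content (TEs are labeled intervals), read-level noise,
multi-chromosome structure, and any mechanistic model of enhancer birth. The
generator validates that the statistics recover the relationships they are
built to measure, not that those relationships hold in any particular
dataset.

## Validation suite sizes

The acceptance-style checks run the pipeline end to end at desk scale,
chosen so the whole suite completes in a few minutes: turnover parameter
recovery uses 100 replicates of a 10 Mb genome (50 bins, ~2000 enhancers);
the DAF scan calibration uses 200 replicates of 600 centers at 0.03
variants/bp (the null central-window odds ratio then averages within ±0.05
of 1, and a 2× rare excess at the motif window is detected against the
flanks in ≥95 % of replicates); the exact-test oracle enumerates all 2 × 2
tables with margins ≤ 30 against a binomial-coefficient hypergeometric sum;
mixture recovery uses 2000 draws from μ = (−1, 1), σ = 0.3, λ = 0.5.

## Degenerate inputs and tie rules

* Constant tracks cannot be z-scored (error); near-constant matrices
  cluster to k = 1.
* Zero-count turnover groups, zero cells in enrichment statistics and
  odds-ratio tables report NA with a warning rather than a silently
  regularized number.
* Quintile ties break by genomic coordinate; cluster ids are RT-ordered;
  mixture components are mu-ordered.
* Elements overlapping no RT bin are "missing" and excluded from quintiles,
  classes and regressions.

## Known limitations

Coordinates are 0-based half-open throughout; 1-based inputs (VCF, PFM) are
converted at the I/O boundary only. Strand is carried but ignored by all
statistics except motif scanning, which scans both strands. BigWig/BAM are
out of scope (tracks are bedGraph); cross-assembly mapping, peak calling,
TE annotation and deep-learning TF-binding prediction are consumed as
standard-format outputs of external tools, never recomputed here.
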