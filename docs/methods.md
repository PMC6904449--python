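# Methods

## The problem

Transposable elements (TEs) make up roughly half of mammalian genomes.
Most copies are epigenetically silenced, but a subset carries regulatory
activity — open chromatin, enhancer/promoter chromatin states,
hypomethylated CpGs, transcription — that varies across tissues and
developmental stages.  Quantifying that activity requires overlaying
millions of short repeat annotations onto per-epigenome chromatin-state
segmentations, methylomes, peak calls, and expression tracks, and then
asking population-level questions at three phylogenetic resolutions:
class, subfamily, and individual copy.

This package implements that measurement machinery as a reusable
library, and validates it against a synthetic multi-epigenome generator
in which every effect is planted with known magnitude.

## Annotation conventions

All coordinates are 0-based half-open; 1-based external dialects are
converted at the reader boundary and nowhere else.  Strand is ignored in
all intersections.

**chromHMM states.**  A TE is annotated with a state when the center of
a 200 bp segmentation window carrying that state lies inside the TE
(`window_center`, the default).  The center of window `[a, a+200)` is
`a+100`, and "inside" means `start <= center < end`; both choices keep
the half-open convention symmetric.  A TE containing no window center is
assigned the single state with the largest bp overlap, ties broken by
state-alphabet order, so every TE on a covered chromosome receives at
least one state.  Two stricter conventions (`window_center_strict`
without the fallback; `block_center` requiring whole-block centers) and
one looser (`any_overlap`, >= 1 bp) are provided; free-form
segmentations (no fixed window, e.g. a second species annotated with a
different model) always use >= 1 bp overlap.  By construction the state
sets are nested: strict ⊆ default ⊆ any-overlap, and the ever-active
statistics inherit that ordering.

**Methylation.**  Per-CpG fractional methylation with read counts; CpGs
covered by <= 3 reads are missing values.  A TE's methylation level is
the mean over well-covered CpGs overlapping it; states are
hypomethylated (< 0.30), intermediate (0.30–0.70, both bounds
inclusive), hypermethylated (> 0.70), `missing` (CpGs present, none
well covered), and `no_cpg` (no CpG overlap — excluded from methylation
analyses, distinct from `missing`).  In aggregate CpG counting a CpG
with only one of its two bases inside a feature counts 0.5.

**Peaks.**  A TE overlaps a DNase or H3K27ac peak only if a peak summit
(single-base) lies inside it; the count of distinct summit positions is
retained, since single TEs can overlap many peaks.  Aggregate peak
composition uses full peak bodies; subfamily enrichment uses summits.

**Expression.**  Length-weighted mean coverage over the TE times the
track's normalization factor; "expressed" means RPKM strictly > 1.

**Missingness.**  Data layers absent for an epigenome (no WGBS, no
peaks, no RNA) are encoded as absent, never zero; a chromosome absent
from one epigenome's segmentation makes its TEs no-calls there, and
every denominator counts only epigenomes with data for that TE and
technique.

## Subfamily enrichment

Enrichment of subfamily *i* in state *j* in epigenome *k* is the log
odds ratio

    LOR = log2( 1e-20 + (ijk/ik) / (jk/k) )

with counts in bases (chromHMM), CpGs (WGBS), or peak summits (DHS,
H3K27ac; `ik`/`k` stay in bp).  The 1e-20 pseudocount floors zero
overlap at log2(1e-20) ≈ −66.44.  A cell is *eligible* with > 30
members (> 30 CpG-bearing members for WGBS) and *enriched* with > 10
members in the state and LOR > 1.5 (2^1.5 ≈ 2.8-fold over background).
Member counts come from the per-TE window-center calls; `ijk` comes from
direct interval arithmetic — the two member notions are deliberately
distinct.  For PCA embeddings, undefined LOR cells (state absent from an
epigenome) are imputed with the pseudocount floor, preserving "absent"
as extreme depletion; variables are restricted to positive variance and
standardized.

## Null models and tests

**Shuffled TEs** keep each copy's length and labels and are re-placed
uniformly over allowed, non-gap space (chromosome drawn proportional to
allowed length, then uniform start; resampling on collisions with
exclusions, overlap among shuffled TEs permitted).  For WGBS
enrichment, subfamily CpG totals are recomputed on the shuffled
positions.

**Permutation category tests** ask whether an epigenome category is
over-represented among epigenomes above (or below, tested separately)
a cross-epigenome reference.  Labels are permuted 1,000 times; the
p-value uses the add-one estimator (1 + #{null >= obs})/(1 + B) so it is
never zero.  Benjamini–Hochberg correction is applied only over
categories with at least one extreme epigenome in the tested direction
(and, for the preferential-enrichment variant, only over
subfamily-state-category combinations in active states with at least
one enriched epigenome) — correcting over structurally empty tests would
only dilute the family.

**Association** uses the chi-squared test without continuity
correction plus Cramér's V = sqrt(chi2/(n·(min(r,c)−1))); zero-margin
rows/columns are dropped with a warning.  Continuity correction is
disabled so effect sizes are comparable across table sizes.

## Age trends and conservation

TE age is the Jukes-Cantor distance d = −(3/4)·ln(1 − (4/3)p) from the
substitution proportion p against the subfamily consensus (p taken as
milliDiv/1000 from RepeatMasker-style input).  Continuous responses
(methylation-state persistence, length, CpG density, mappability) are
smoothed with penalized cubic smoothing splines, smoothing parameter by
generalized cross-validation; inputs with many observations are pooled
onto a count-weighted quantile grid of <= 400 support points first,
because GCV systems built on thousands of nearly-coincident predictor
values are numerically ill-posed.  Binary responses (CpG-island overlap)
use logistic regression with age as sole predictor, reporting the slope
and its Wald p-value.

Ortholog pairs are source TEs whose externally lifted coordinates
overlap (>= 1 bp) a same-subfamily TE in the target species; one pair is
emitted per overlapping target, so per-source and per-target tallies can
differ.  Conservation is summarized by state-by-state and
hypomethylated-vs-not contingency tables over anatomy-matched epigenome
pairs.  Each TE contributes one state per epigenome — its *primary*
(largest-bp-overlap) state — so every pair yields exactly one
(state1, state2) observation; this keeps the contingency table a true
cross-classification when long TEs span several states.  Tissue-specific
annotation means >= 2 epigenomes of one tissue but < 5 epigenomes
overall (an `exactly=2` reading is available behind a flag).

## The synthetic generator

`simulate()` emits a complete toy study: a 2 × 1 Mb genome with assembly
gaps, ~4,700 non-overlapping TEs in 20 subfamilies spanning the six
classes (lengths and CpG densities loosely shaped like SINE/LINE/LTR/
DNA/SVA/Other; CpG density decays with age), 12 epigenomes in 4 groups
with full metadata, per-epigenome segmentations in 200 bp windows over
the 15-state alphabet, peak sets with summits, per-CpG methylation with
a configurable low-coverage fraction (default 10%), and RNA coverage
keyed on transcribed states.

Planting is exact in expectation: to plant subfamily *i* at fold *f* in
state *j* for an epigenome category, windows overlapping members of *i*
draw state *j* with probability f·p_j, and the distribution for all
remaining windows is solved so that each state's genome-wide marginal
stays exactly p_j.  The subfamily's base fraction in *j* is then f times
the genome-wide fraction, and the recovered LOR is log2(f) with no
plug-in bias from the planting itself; an infeasible fold raises an
error reporting the maximum feasible fold.  Methylation is emitted from
Beta distributions keyed on chromatin context (active contexts
hypomethylated) and guaranteed peak summits are planted in members of
subfamilies enriched *in that epigenome's category*, so the concordance
of techniques observed in real data is reproduced by construction.

`simulate_ortholog_species()` lifts a configurable fraction of TEs into
a second genome, places same-subfamily targets over most lifted
intervals, and lets each target inherit its source's primary state (and
methylation state) with probability c, else draw from the species-2
background.  With a shared state alphabet the planted state-by-state
Cramér's V equals c exactly in expectation, giving a closed-form oracle
(`planted_cramers_v`).  Species-2 targets reserve whole windows so no
two targets share one.

What the generator does **not** emulate: nucleotide sequence (no
motifs, no mappability from alignment — mappability is an input
column), linkage between neighboring TEs and genes, realistic state
autocorrelation along the genome (windows are i.i.d. given the planted
design), read-level noise, or between-epigenome covariance beyond the
planted category structure.  Passing tests therefore demonstrate that
the measurement machinery recovers known inputs under the stated
conventions — not that any particular biological claim transfers to
real data.

## Validation experiments and problem sizes

`teprofiler.validation` (driven by `scripts/acceptance.py` and the
acceptance test suite) re-derives the pipeline's guarantees from
scratch at sizes chosen to keep the full suite in the minutes range on
one CPU:

* **LOR fold recovery** — folds {0.5, 1, 2, 4} planted in a 2 Mb
  single-chromosome bundle with 1,000-member subfamilies, 20 replicate
  seeds each; the mean recovered LOR lands within 0.1 of log2(fold)
  (measured worst error ≈ 0.04).
* **Permutation calibration** — 200 null datasets of 12 epigenomes;
  empirical type-I error ≈ 0.01 at α = 0.05 (the count statistic is
  discrete, hence conservative).
* **Shuffle abolition** — one shuffled iteration removes 100% of
  enriched cells on the default planted bundle (bound: >= 90%).
* **Conservation recovery** — planted conservation probabilities
  {0, 0.25, 0.5, 0.75, 1} on a 2 × 4 Mb bundle giving ~8,400 ortholog
  pairs; V is monotone and ≈ 0.04 at independence (small-sample bias of
  the uncorrected V; the closed-form expectation is 0).
* **Mode ordering** — ever-active fractions under strict, default, and
  any-overlap conventions are strictly ordered (67.5% / 79.8% / 91.6%
  on the default bundle at seed 1).

## Known limitations

* The per-TE annotation loop is pure Python over numpy primitives:
  linear in TEs × epigenomes and comfortable at 10^5–10^6 cells, but not
  engineered for the 4.4M × 127 scale of a full consortium reanalysis.
* Only text formats are read (BED-family, narrowPeak, bedGraph,
  tab-delimited tables); binary bigWig/bigBed inputs must be converted
  upstream.
* The permutation framework's resolution is bounded by the number of
  epigenomes; with 12 epigenomes the smallest achievable p is about
  5 × 10⁻³.
* Motif discovery and region-ontology enrichment for candidate
  subfamilies are out of scope; candidate TE lists export as BED for
  external tools.
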