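# Methods

`maldr-age` implements a gap-site centred RNA-seq screening pipeline for
age-related expression changes in cultured dermal fibroblasts, together
with a synthetic-data generator that reproduces the cohort's statistical
structure so that every stage is testable without sequencing data.

## The screening model

The analysis targets a cohort of 27 donors in three ordered age groups
(Young 18–25, Middle 35–49, Old 60–67 years), each contributing one
sun-exposed and one sun-protected skin sample: 54 samples, 18 per age
group, 13 female and 14 male donors. Expected age effects are small,
monotone in age, and buried in large inter-individual variation, which
motivates a filter sensitive to *ordering* rather than effect size.

**Gap-sites.** A gap-site is the pair of inner coordinates of a gapped
(spliced) read alignment; all reads covering the same splicing event
share them, so gap-sites act as splice-junction surrogates and their
read counts as expression estimates. Identity is coordinate-based —
`(chrom, left_end, right_start)`, 1-based inclusive; strand is stored
but does not distinguish sites. A read with several alignment gaps
contributes one count to each of its gap-sites. Candidate sites are
kept only when supported by at least one read in *every* sample and
when their coordinates exactly equal an annotated intron's boundaries.

**Pre-filter.** Gap-site counts are tested between the two extreme age
groups (Young vs Old) with a negative-binomial quasi-likelihood F-test:

- dispersions φ (Var = μ + φμ²) are estimated per feature by method of
  moments on library-size-normalised counts pooled within groups, then
  shrunk toward a mean-binned trend (shrinkage weight 0.5, 20 bins);
- group means are ML-fitted under NB with library-size offsets
  (vectorised Newton iterations; exact count-ratio solution at φ = 0);
- the deviance difference between the one-group and two-group fits,
  divided by the quasi-dispersion (full-model Pearson χ²/(n − 2)), is
  referenced against F(1, n − 2).

P-values are Benjamini–Hochberg adjusted; a gene enters the depth stage
when at least one of its gap-sites has FDR strictly below 0.1. The same
machinery serves the gender and location (sun-exposed vs sun-protected)
comparisons. This is a fresh implementation of the quasi-likelihood
framework; its calibration is validated by simulation (type-I error
5.0–5.6% at nominal 5% across seeds, n = 18 per group, 2000 features)
rather than by numerical agreement with any external package.

**Donor-level collapse.** Both samples of a donor share donor-level
biology, and in the age and gender contrasts they fall into the *same*
test group. Treating them as independent replicates inflates the test
(empirically ~14% rejections at nominal 5% under the generator's null).
`run_prefilter` therefore sums counts over samples sharing (donor,
level) into one donor-level pseudo-sample before testing, which restores
independent observations (rejection ~5%, KS distance to uniform ~0.02).
For the location factor a donor spans both groups, the collapse is a
no-op, and the donor pairing is deliberately ignored — each factor is
tested on the full cohort while ignoring heterogeneity in the others. A
paired analysis is intentionally out of the default path.

**MALDR (Monotone ALignment Depth Ratio).** For each pre-filtered gene:

1. *Intron cut.* Positions strictly inside any observed gap-site
   interval `(left_end, right_start)` are removed (union over the
   gene's gap-sites). Removal is driven by observed gap-sites, not by
   the annotation (an annotation-based option exists).
2. *Group means.* Per-position arithmetic mean of raw depth within each
   age group, in absolute numbers — no library-size scaling of depth (a
   normalisation flag exists but defaults off).
3. *Smoothing.* Each group's curve is loess-smoothed independently:
   local linear fit with tricube weights over the nearest
   `ceil(span·n)` positions, span 0.3 by default, output clipped at 0.
   Curves with fewer than 5 positions pass through unsmoothed.
4. *Low-coverage cut.* With M the maximum smoothed depth over all
   groups and positions, positions where **all** groups are below
   0.02·M are removed. If nothing survives the gene is unevaluable.
5. *Monotone fraction.* A position is increasing-monotone iff
   Middle/Young > 1.2 **and** Old/Middle > 1.2 (strict; decreasing
   analogously with reciprocals; zero denominators guarded by a
   pseudo-depth of 1e-9). The gene's fraction is that of the dominant
   direction over the kept positions (counted in positions, not genomic
   span); it passes when the fraction strictly exceeds 0.99.

The step order smooths before the coverage cut; a switch
(`cut_on_raw`) applies the cut to raw group means first instead, since
either reading is defensible. All thresholds live in
`MaldrParameters` (FDR 0.1, coverage fraction 0.02, ratio 1.2,
fraction 0.99, correlation 0.8, loess span 0.3); none is hard-coded
elsewhere.

**Expression summaries.** CPM values are plain ratios
(`count·1e6 / sample total`) with no model-based shrinkage, so
within-group variability stays visible. The co-expression screen finds
the largest gene set whose pairwise Pearson correlations of CPM values
all exceed 0.8 — an exact maximum clique of the thresholded correlation
graph (candidate sets are tens of genes, so exact search is cheap; ties
broken by lexicographic gene id; raw CPM by default, log2(CPM+1) and
Spearman available). DE direction summaries report counts and
integer-rounded percentages of positive/negative fold changes among
significant genes.

**Sample QC.** Before analysis, each sample's reads are reduced to the
relative frequencies of the 4⁶ forward-strand 6-mers (k-mers containing
non-ACGT symbols skipped). Sample distance is 1 − Pearson correlation
of log frequencies (pseudo-frequency 1/(4ᵏ·10)); a sample is excluded
when its median distance to all others exceeds the cohort median by
more than 3.5 MADs. The exclusion rule is a reproducible robust
stand-in for what is in practice a visual decision, and both k and the
MAD multiplier are configuration.

## The synthetic-data generator

The generator is first-class, tested code. It emulates:

- a synthetic chromosome of non-overlapping multi-exon gene models
  (every intron defines exactly one annotated gap-site), written as
  GTF;
- the cohort table above (ages drawn per group range, genders per-group
  counts, library sizes uniform in 200k–300k reads);
- gap-site counts: NB(mean, φ = 0.1 by default) via gamma–Poisson
  mixing, with mean = library size × gene weight (log-normal across
  genes, σ = 0.5, normalised) × effect multipliers × donor effect ×
  junction-crossing probability `(read_len − 1)/exonic_length`
  (read length 101);
- per-base depth: Poisson around mean
  `expected reads × read_len / exonic_length` on exons and 1% of that
  on introns (non-zero so the intron cut has observable effect);
- a donor random effect, log-normal with σ = 0.3 (configurable), drawn
  per donor × gene and shared between the donor's two samples. The true
  magnitude of donor-level correlation is not known for this design; 0.3
  is a stand-in exposed as configuration;
- injectable effects per gene: `monotone_up` / `monotone_down`
  (multiply the mean by `ratio` per adjacent age-group step),
  `outlier_donors` (a listed set of donors at `outlier_fold`× — the
  ID1-like pattern of a few strongly over-expressing individuals),
  `gender_biased`, `location_biased`, `null`.

Counts and depth called with the same genes, samples, effects and seed
share the gene-weight and donor-effect streams, so they agree up to
sampling noise (mean exonic depth ≈ per-junction count ×
read_len/(read_len − 1)). Depth is simulated directly per base, not via
simulated reads; a read-level FASTQ emitter with controllable GC
content exists only to build QC fixtures. The generator does not model
read-alignment artefacts, sequencing errors, positional coverage bias
along transcripts, or UV-dose response — passing tests therefore show
the pipeline's statistical behaviour under its own model assumptions,
not robustness to real-data artefacts.

## Numerical choices

- BH adjustment is the exact step-up (`min_{j≥i} m·p_(j)/j`, capped at
  1), checked against an independent implementation to 1e-12.
- The loess windows are contiguous in sorted position order (nearest-k
  neighbourhoods of sorted points are contiguous), and the weighted
  linear fit uses a closed form on centred abscissae; a degenerate
  window (zero spread) falls back to the weighted mean. Local linear
  fits reproduce exactly linear inputs to ~1e-12.
- Newton fits of NB means start from the Poisson MLE and are clamped
  positive; all-zero features are dropped from dispersion estimation
  with a log entry.
- Deterministic streams: every stochastic function takes a seed and
  derives independent substreams from it; identical inputs and seeds
  give byte-identical text outputs (floats written with 6 significant
  digits, LF endings), which the run manifest verifies by SHA-256.

## Operating characteristics and limitations

Measured by `scripts/acceptance.py` (seed 1; experiment sizes chosen to
run on a laptop in seconds): type-I error of the QL test 5.05% at
nominal 5%; null false-pass rate of the full pre-filter + MALDR chain
0.67% (150 null genes); recovery power for injected per-step ratio-1.5
monotone genes 84% (50 injected genes).

The power figure has a structural explanation. Each group's mean depth
averages only 9 independent donors, so with donor σ = 0.3 each adjacent
log group-ratio carries a standard deviation of ≈ 0.14 while the margin
between the true per-step ratio (1.5) and the threshold (1.2) is
log(1.5/1.2) ≈ 0.22; requiring *both* adjacent ratios to clear the
threshold at essentially every kept position caps per-gene pass
probability near 0.88. Detection of ratio-1.5 effects at this design is
therefore intrinsically limited by inter-individual variation — the
same property that makes the filter respond to a few strongly deviating
donors. That caveat is deliberate and reproduced as a test: a gene
expressed 10-fold in exactly 3 of 27 donors (two Young, one Middle)
passes the filter in the decreasing direction with no population trend
at all.

Other known limitations: the NB QL test is validated by calibration,
not by agreement with any reference implementation; exact-coordinate
annotation matching does not tolerate off-by-one conventions between
aligners (a mismatch across the whole input raises an error instead);
and whether a multi-gapped read should count once per gap-site (as
implemented) or once per read is a documented convention choice.
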