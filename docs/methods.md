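# Methods

This note records the models, defaults and design choices behind each
module, what the simulators do and do not emulate, and the numerical
details a maintainer would need.

## Gene-trap arm

**Model.** Each uniquely mapped read is an insertion site (chrom, 0-based
position, strand, read support). The caller is a composition of five
stages: deduplication, proximity collapse, disruptive classification,
per-gene counting, and Fisher/BH testing.

*Deduplication* merges records sharing (chrom, pos, strand); read support
counts the merged records. *Proximity collapse* removes sites 1–2 bp apart,
which arise from alignment jitter around a real integration: same-strand
sites are single-link chained at gap ≤ 2 bp (the `window` parameter) and
each chain keeps only its highest-support site, ties resolved toward the
smaller coordinate. Supports of discarded satellites are not summed — they
are treated as artifacts, not evidence. An alternative mode
(`drop_entire_cluster`) removes whole chains instead; the representative-
keeping behaviour is the default because satellite reads normally surround
a genuine site. Chaining is strand-separated since opposite-strand sites at
adjacent coordinates are distinct integration events.

*Disruptive classification* uses the standard haploid gene-trap convention:
an insertion disrupts a gene when it lies anywhere in the gene body in the
sense orientation, or inside an exon in either orientation. The rule is a
convention, not a law of the data; it is configurable in the sense that the
classification table exposes per-record orientation and exon status.
Insertions overlapping several genes count once for each.

*Testing.* For gene g, the 2×2 table [[a, A−a], [b, B−b]] compares the
gene's disruptive insertions in selected (a of A) vs control (b of B)
pools; p = one-sided hypergeometric tail, computed vectorized and floored
at the smallest positive double because extreme tables underflow. The BH
universe is the set of genes with at least one disruptive insertion in
either pool — that is the family of tests actually performed. Hits are
genes at adjusted p ≤ α (default 0.05); adjusted p < 10⁻¹⁰ sets the
`labeled` flag used by the figure exports. Ties in the hit ordering break
by descending selected-insertion count, then gene id.

**Toy aligner.** For synthetic end-to-end fixtures only, reads are aligned
by exact substring search over both strands of a toy genome; a read maps
iff it occurs exactly once, multi-mappers and non-mappers are counted and
dropped. This deliberately mirrors the discard-ambiguous policy of a real
aligner but is not a replacement for one: it exists so the FASTQ emitter
and the aligner can be verified against each other by round-trip.

## CRISPR arm

**Per-sgRNA model.** Counts are NB with mean
`μ_ij = s_j · exp(β₀ᵢ + β_Tᵢ·[final] + β_Rᵢ·[treated])` and dispersion
α_i (variance μ + αμ²). Initial samples are coded as untreated regardless
of the arm they later seed, since treatment has not been applied at
harvest; the design is additive (no interaction), so β_R is the
treatment-attributable log enrichment at the final timepoint — the screen's
readout. The design choice of main effects only reflects that the data
contain no initial-treated cell that could identify an interaction.

*Size factors* are median-of-ratios over guides positive in every sample,
rescaled to geometric mean 1; a total-count fallback (with warning) covers
degenerate matrices.

*Dispersion* is method-of-moments per guide, pooled across design cells
with ≥ 2 samples (df-weighted mean of (var − mean)/mean²), then shrunk:
a trend α(μ) = a₀ + a₁/μ is least-squares fitted over guides with positive
raw estimates and the final α is the log-space midpoint of raw and trend,
floored at 10⁻⁸. This is a deliberately simple, fully specified stand-in
for empirical-Bayes machinery; its adequacy is established by calibration
tests (null p-value uniformity, mixed-simulation FDP) rather than by
matching any particular tool.

*Fitting* is IRLS, vectorized across all guides at once (working weights
μ/(1+αμ), batched 3×3 normal equations), converged when the per-guide
deviance changes by < 10⁻⁸, capped at 100 iterations; a 10⁻¹⁰ ridge guards
singular systems and linear predictors are clipped to ±30. Non-converged or
all-zero guides report p = 1 and are flagged — conservative by design.
Wald p-values are two-sided normal; directionality (log2FC > 0) is imposed
at the selection step because these are enrichment screens.

**Gene aggregation.** The ranked list is, by default, only the
significantly enriched guides sorted by descending log2FC — the literal
two-step reading: first select, then aggregate. A `rank_all` flag ranks
every guide instead (significance still gates which genes are tested).
Genes need ≥ 2 significant guides to be tested at all; this is the
partial-penetrance defence — single-guide signals are as likely off-target
as real. The enrichment score uses weight exponent 1; the permutation null
redraws same-size guide sets uniformly, enumerated exhaustively when
C(N, k) ≤ 10,000 and sampled otherwise with the (1+b)/(1+n) estimator.
aLFC is the arithmetic mean log2FC of the gene's significant guides.

Because the default ranked list contains only significant guides (often a
few dozen), gene-level permutation p-values are coarse and their BH
adjustment is honest but weak; the ranking of hits (by adjusted p, then
guide count) is the operative output, matching how such screens are read.

## Enrichment core

The running sum adds |score|^w (normalized over hits) at member ranks and
subtracts 1/(N−k) elsewhere; ES is the extreme deviation with sign, a tie
between the +/− extremes resolving positive (enrichment screens test the
positive tail). ES is invariant to positive rescaling of scores; the
all-members case returns 1 exactly. No NES/FDR machinery from the original
GSEA formulation is included — callers apply BH across their own test
families instead, a simpler and better-understood correction at these
family sizes.

## Proteomics arm

log2FC = log2((mean_case + c)/(mean_control + c)) with pseudocount c = 0.5
(counts contain zeros; the choice is configurable and the printed set sizes
of any given dataset can shift by a few proteins under a different c).
All four values per condition (2 biological × 2 technical replicates) enter
the Welch test as independent observations; the technical-replicate
correlation this ignores makes the test slightly optimistic, which the
stringent fold-change filter partially offsets. Zero-variance degenerate
cases: equal means → p = 1; unequal → p = 0 (flagged by an infinite t).
Study set = {log2FC ≥ 1 and p < 0.05}; GSEA list = {p < 0.05} ranked by
log2FC; the study set is nested in the GSEA list by construction. Protein
identification and validation are upstream of the input contract — the
module consumes a validated protein × sample count table.

## Simulators

*Gene-trap*: control insertions are multinomial over genes with weights
defaulting to gene length (longer genes trap more integrations); selected
pools multiply resistance-gene weights by `enrichment_fold` (default 50).
Positions are uniform within the gene body on a random strand; 30% of
insertions land intergenic (drawn from the complement intervals); read
support is 1 + Poisson(1). Defaults of 100,000 control and 10,000 selected
insertions reflect a deeply sampled unselected pool versus a
bottlenecked resistant pool. Not modelled: PCR jackpotting, integration
hotspots, chromatin preference — so passing tests demonstrate the
statistics, not robustness to those artifacts.

*CRISPR*: the default library is 388 target genes × 6 guides + 120
essential-control guides (20 genes) + 120 non-targeting guides = 2,568.
Baseline abundance is log-normal (σ = 1, the skew real libraries show)
scaled to mean count 500 per guide; counts are NB with dispersion 0.05.
Guide efficacy is Bernoulli(0.8) fixed across samples; efficacious
resistance-gene guides gain `effect_lfc` (default 2) log2 units in
treated-final samples; essential-control guides lose 1 log2 unit in all
final samples, exercising the time factor. The default design is duplicate
screens per cell (screens are typically run in duplicate); calibration
studies use 3 replicates per cell.

*Proteomics*: NB counts (default dispersion 0.2, mean 20 — spectral counts
are small and noisy) under the 2×2×2 replicate layout, with the first
`n_diff` proteins shifted by `effect_lfc` in the case condition.

All generators are pure functions of (params, seed) through a single
`numpy.random.Generator`; null settings (fold 1, effect 0, n_diff 0)
produce data with no signal by construction and drive the false-positive
tests.

## Calibration results and problem sizes

The acceptance script measures, from scratch at each run: the mean FDP
among significant enriched guides over 100 mixed CRISPR simulations
(2,568 guides, 21 resistance genes × 6 guides ≈ 4.9% truly enriched at
log2 effect 2, efficacy 1, dispersion 0.05, mean count 500, 3 replicates
per cell), and the mean FDP among gene-trap hits over 50 mixed simulations
(10,000 genes, 20 resistance genes at fold 50, 100,000/10,000 insertions).
These sizes keep a full run within a few minutes on one CPU while holding
Monte-Carlo error on the mean FDP near 0.002. Under these conditions both
arms hold the realized FDP at or below the BH 5% target — the gene-trap arm
far below it, since discrete Fisher p-values are conservative.

## Known limitations

* The NB Wald test with plug-in shrunk dispersion is mildly
  anti-conservative at 2 replicates per cell (null p < 0.05 fraction near
  0.09); at 3 replicates it is close to nominal (≈ 0.065) and BH keeps the
  realized FDP under the 5% target in the mixed setting. Very small designs
  deserve a t-reference or more aggressive shrinkage.
* The exact-match toy aligner and the 20-nt substring guide counter are for
  synthetic genomes and clean reads; no quality- or error-model handling.
* The disruptive-insertion rule and the significant-only GSEA ranking are
  documented conventions with configurable alternatives, not assertions
  about any particular published pipeline.
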