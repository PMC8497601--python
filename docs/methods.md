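# Methods

## Scope and model

`methdiverge` analyses comparative WGBS data from several closely related
species sampled in one or more tissues with biological replicates. The
unit of observation is the symmetric CpG: methylated and unmethylated
read counts for the plus-strand C and the minus-strand G (one base
downstream) are summed onto the C position before any analysis
("destranding"), because the two strands report the same epigenetic
state. Methylation level at a site is methylated / (methylated +
unmethylated); sites are kept when the destranded coverage is >4 and
≤100 reads, the usual guard against undercovered and collapsed-repeat
sites. DMR calling is the exception: it consumes the counts directly and
performs no preliminary level estimation.

Counts are modelled as beta-binomial: given a site's methylation level
p and biological overdispersion φ ∈ [0,1), a replicate with coverage n
contributes a methylated count with mean np and variance
np(1−p)(1+(n−1)φ). The beta parameterisation is α = p(1−φ)/φ,
β = (1−p)(1−φ)/φ, so φ = 0 collapses to the binomial and moments are
closed-form — which is what the tests exploit.

## Differential methylation test

For two species groups at one CpG, the statistic is a score-type z on
the difference of pooled group proportions:

- group proportion p̂g = Σ m / Σ n over replicates;
- variance uses the *pooled* proportion across both groups (score test):
  Var = p̂q̂ · Σg Σi n_i(1+(n_i−1)φ̂)/(Σ n)². The pooled-p variance was
  chosen over the per-group Wald form because it is markedly better
  calibrated at these coverages (false-positive rate 0.042–0.049 at
  nominal 0.05 vs ≈0.06 for per-group variance in our beta-binomial null
  simulations);
- φ̂ is method-of-moments, from the within-group replicate scatter
  around the replicate-mean proportion, with numerator and denominator
  sums pooled over a ±250-bp neighbourhood and shrunk toward the
  genome-wide ratio with a pseudo-weight of 30 sites. With two
  replicates the raw per-window ratio is noisy enough to distort the
  variance of entire windows; the shrinkage removes that failure mode
  without biasing the genome-wide level;
- with a single replicate in either group the test falls back to
  Fisher's exact test on the pooled 2×2 table.

Two p-values are produced per site: the **raw** per-site p above, and a
**segmentation** p computed from the same statistic on counts pooled
over a 500-bp moving window — the moving-average smoothing that standard
WGBS differential callers apply. Smoothing restores per-site power at
low replicate numbers (raw per-site power at |Δ|=0.5, 15× coverage,
2v2 replicates is only ≈0.86, which fragments long regions).

## DMR segmentation

CpGs with segmentation p < 0.05 are chained while consecutive candidate
gaps stay ≤100 bp. Each chain is then **boundary-refined**: the reported
region is clipped to the outermost chain members that are individually
(raw-p) significant in the chain's direction, which undoes the ~200-bp
boundary bleed that window smoothing otherwise causes. A refined region
is reported iff it is ≥50 bp long, holds ≥4 CpGs, has |mean raw
difference| ≥ 25% and ≥50% of its CpGs significant. Effect size,
direction and the Stouffer-combined region p always use the raw per-site
statistics, so they are not inflated by smoothing correlation. Output
regions are sorted and disjoint; every reported region is re-asserted
against all four thresholds.

The 100-bp chaining gap and the 50%-significant-CpGs rule follow common
DMR-calling practice; both are exposed in `DmrParams`, as are the
smoothing toggle and window.

## Classification

A region is **species-S-specific** when DMRs overlapping it (≥1 bp)
exist in both pairwise comparisons involving S with the same direction
relative to S, and no DMR between the other two species overlaps it; the
output region is the coordinate union of supports. A species-S liver
region overlapping a species-S muscle region in the same direction
becomes one **multi-tissue** record; unmatched records remain
tissue-specific. Overlap is ≥1 bp throughout (bedtools-intersect
convention).

## Annotation universe

Promoters are TSS ± 500 bp; gene bodies are the gene extent minus the
first 500 bp downstream of the TSS in transcription direction;
intergenic space is the complement of gene extents padded by 500 bp.
CpG islands use the classic sliding-window rule (200-bp windows, step 1;
GC ≥ 50%, observed/expected CpG ≥ 0.6 with O/E = n_CpG·N/(n_C·n_G);
qualifying windows merged, merged intervals re-evaluated, length ≥ 200
bp) rather than an HMM: the window rule is deterministic and
dependency-free, at the cost of disagreeing with HMM predictors on
borderline islands — island counts and the promoter/orphan split are
therefore not comparable across predictors. CGIs overlapping a promoter
by ≥1 bp are promoter CGIs, the rest orphan. TEs come from RepeatMasker
`.out` files (or a 6-column TSV) with the percent-divergence column used
as the CpG-adjusted Kimura age proxy.

## Enrichment

Expected overlaps come from placing the same interval multiset uniformly
at random (contig chosen ∝ length among contigs long enough, start
uniform), 1000 iterations by default, mean count as the expectation;
O/E = observed/expected, empirical p with the add-one rule
(1+#{at least as extreme})/(iterations+1), chi-square goodness of fit
across categories. Overlap is counted per DMR (once per category);
shuffled intervals may overlap each other and no gap/isochore matching
is attempted. TE-family results are additionally display-filtered to
O/E ≥ 2 or ≤ 0.5. The TE-age profile compares divergence of TEs under
DMRs, outside all DMRs, and under shuffled DMRs pooled over 500
iterations, with Kruskal–Wallis and Dunn's tests (BH-adjusted, two
sided; Bonferroni available).

## Expression integration

DMRs are assigned to genes with precedence promoter > gene body >
vicinity, vicinity meaning a 0.5–4-kb gap to the gene extent (nearest
gene wins ties); the classes are thus mutually exclusive per DMR. DEGs
require q < 0.01 and a maximum between-species mean-TPM difference
≥50 TPM; the DE table itself is an input (the generator provides one
from its planted truth). pfDMRs are assigned DMRs whose gene is a DEG;
the excess over chance is an exact hypergeometric upper tail on gene
sets with the universe N = all genes in the expression matrix (a
configurable choice — no principled N exists without the full
annotation). Expression bins are OFF (TPM = 0 in every replicate) plus
10 equal-count bins of expressed genes; methylation bins are an
exactly-0% bin plus ten 10% increments — the "OFF/zero bin + 10" reading
of an 11-category scheme. Correlations are gene-wise Spearman between
mean feature methylation (from 50-bp windows overlapping the feature)
and mean TPM. Sample clustering computes the pairwise Spearman
correlation matrix over conserved CpGs (covered in every sample, not
hit by any C>T/G>A SNP) and applies complete-linkage clustering to
Euclidean distances between correlation rows, with columns pre-sorted by
sample id for deterministic tie-breaking.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with every planted element recorded as a machine-readable truth record:

- **Genome**: i.i.d. bases (GC ≈ 0.42) giving ≈1 CpG per 23 bp; CGI
  truth intervals are sampled first and their bases drawn GC-rich
  (GC = 0.6), so the island predictor has a real signal. An unmethylated
  spike contig is emitted at the non-conversion rate (default 0.002)
  over all cytosine contexts.
- **Methylation landscape**: background 0.8 (globally methylated
  vertebrate-like genome); per-gene promoter levels from a low-heavy
  mixture (70% Beta(2,10), 30% Beta(6,3)) and gene-body levels
  Beta(12,3); per-1-kb-block random offsets per tissue (sd 0.12) and per
  species (sd 0.04) reproduce the clustering hierarchy tissue > species
  > replicate seen in real comparative methylomes. Designs whose measured
  property is specificity or calibration (null calibration, planted-DMR
  recovery, zero-planted control, enrichment null) set the species
  offsets to zero, because there the property under test is behaviour in
  the absence of between-group signal.
- **Planted DMRs** (default 50 per Mb-scale genome, |Δ| = 0.5, 300–800
  bp): target species drawn uniformly; direction away from the local
  baseline (hypo where baseline ≥0.5) so the full effect size is
  realised; tissue scope multi-tissue for an exact 45% (configurable),
  the rest split between tissues. Placement requires ≥4 CpGs, no
  internal CpG gap >100 bp, CpGs within 50 bp of both edges, and ≥800 bp
  separation — i.e. planted regions are *callable as single distinct
  units* by a segmenter with a 100-bp gap rule and 500-bp smoothing;
  without these constraints ~16% of planted regions are unavoidably
  split or merged for reasons unrelated to caller quality. A
  configurable fraction (default 25%) is centred on gene promoters and
  drives the expression coupling.
- **Counts**: coverage Poisson (default 15×), methylated counts
  beta-binomial (default φ = 0.05 — a free choice; replicate variance
  is not constrained by published comparative data), reads split
  binomially across strands so destranding is exercised and exactly
  conserves counts.
- **TEs and SNPs**: TEs from eight named families; TEs overlapping
  planted DMRs draw young divergences (mean 5%), others old (mean 25%).
  Per species, SNPs are half bisulfite-confounded (C>T/G>A) and half
  other classes, all with verified reference alleles.
- **Expression**: log-normal TPM (baseline log2 ≈ N(7, 1.2)); promoter
  methylation couples at −3 log2-TPM per unit methylation and gene-body
  methylation at +2.5, calibrated so the emergent gene-wise correlations
  match the reported comparative scales (ρ ≈ −0.35 at promoters, ≈ +0.1
  at gene bodies); an exact off-fraction of genes (drawn from uncoupled
  genes so planted couplings stay observable) is silent in all samples.
  Genes whose promoter hosts a planted DMR shift expression opposite in
  sign to the methylation shift, and receive small q-values in the
  generated DE table.

What passing on this generator does **not** show: robustness to
non-uniform read coverage and mapping bias, M-bias, incomplete
bisulfite conversion beyond a scalar rate, CNVs/collapsed repeats,
non-CpG methylation, correlated replicate structure (batch effects), or
annotation error in real genomes.

## Determinism and numerics

All randomness flows from `numpy.random.default_rng` seeded with
`[design_seed, stage, sample]` tuples; the same design yields
byte-identical output files, and the pipeline manifest records SHA-256
hashes of every input and output. z-statistics are capped at |z| = 37
(the double-precision normal-tail floor); Stouffer combination uses
signed per-site z with the same cap; degenerate pooled proportions
(0 or 1) force equal groups and give p = 1 exactly. Hypergeometric tails
are summed in log space. Empirical p-values are never 0 by the add-one
rule. Dunn's z uses tie-corrected variance; Spearman p is an exact
permutation tail for n ≤ 9, else the t-approximation.

## Measurement designs (problem sizes)

The checks in `tests/test_acceptance.py` and `scripts/acceptance.py`
use: calibration on 10,000 null CpGs (1×250 kb, pure background); DMR
recovery on 2×500 kb with 100 planted DMRs at Δ = 0.5, 15×, scored by
≥50% reciprocal overlap; a zero-planted control on 2×600 kb (~50k
CpGs); enrichment null as the mean observed count over 50 independent
200-interval null draws against a 1000-shuffle expectation (a single
draw has sd(O/E) ≈ 0.2 and cannot testify to a ±10% band); multi-tissue
recovery on 2×1 Mb with 200 planted species-DMRs at 45% multi-tissue;
expression coupling on 2×4.5 Mb with 2000 genes; clustering on the
default 3×2×2 design. These sizes make every planted effect decisively
measurable while keeping a full run in minutes on one core.

## Known limitations

- The score test's normal approximation is slightly conservative at
  extreme methylation levels (p near 0 or 1), where discrete counts
  leave little two-sided tail mass.
- Boundary refinement requires at least one individually significant
  CpG per chain; very weak but broad differences detectable only after
  smoothing are dropped by design.
- The window CGI predictor and HMM predictors disagree on borderline
  islands; orphan/promoter fractions are predictor-specific.
- Classification treats ≥1-bp overlap as support; a reciprocal-overlap
  variant is configurable in the interval layer but not the default.
- The hypergeometric universe for the pfDMR test is the expression
  matrix's gene set; with incomplete expression annotation the test is
  conservative or anticonservative depending on which genes are missing.
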