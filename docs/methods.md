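# Methods

This note documents the models and procedures implemented in `epiloop`,
the defaults they run with, what the synthetic data does and does not
emulate, and the numerical choices made where the design was open.

## Coordinate and I/O conventions

All coordinates are 0-based half-open (BED convention). The TSS of a
'-' strand gene is `body.end - 1`, which keeps the TSS inside the body
under half-open semantics. Dialects are declared, never guessed: 1-based
inputs are not auto-detected, because silent convention guessing is the
classic genomics bug. Readers run strict by default — any record violating
a type invariant is an error naming file and line; a lenient flag skips
and counts instead. Uncovered bedGraph bases score 0 (sparsity
convention), and inter-chromosomal loops are rejected at parse in strict
mode since all downstream domain logic is intra-chromosomal.

## Condition-specific genes and breadth

The specificity call is a declared threshold rule, not a fitted count
model — inputs are already TPM/RPKM abundances. With pseudocount
c = 0.1, `log2FC = log2((mean_A + c)/(mean_B + c))`; a gene is A-specific
when log2FC >= 2 (a 4-fold change) and mean_A >= 1, symmetrically for B;
genes below 1 in both states are low-expressed; the rest are shared. All
thresholds are config-exposed. Expression breadth is the fraction of
panel cells with abundance >= 1; breadth <= 0.2 labels a gene
cell-specific. Promoter occupancy is binary: >= 1 RNAPII peak overlapping
TSS ± 2 kb.

## Interaction domains (RAID / CCD)

A domain is a connected component of the graph whose nodes are loops and
whose edges join loops with any pair of anchors within `merge_gap` bp
(overlap at the default 0). This is the simplest operational definition
consistent with the idea of an RNAPII-associated interaction domain; the
implementation uses a sorted anchor sweep plus union–find, which equals
the all-pairs anchor-proximity graph by transitivity and is verified
against an O(n²) oracle in the tests. Gene–domain membership is decided
by the TSS falling in the domain span (all promoter logic in the package
is TSS-anchored); one TSS = SG, two or more = MG.

## A/B compartments

The contact matrix is distance-normalized (observed/expected by diagonal
mean), bins are correlated, and the sign of the first principal component
of the correlation matrix labels each bin. Orientation is fixed by the
standard gene-density rule: the class with higher mean gene density is A.
Bins with a zero contact marginal are NA; a constant matrix degenerates
to all-NA with eigenvalue fraction 0. For desk-scale runs the pipeline
synthesizes the matrix from loops (each loop adds its PET count to its
anchor-bin cell, 100 kb bins), so no Hi-C input is required. The test
fixture plants two interleaved bin classes in **aperiodic** blocks: a
strictly periodic checkerboard makes the correlation matrix
near-circulant, and the class indicator then splits across two degenerate
Fourier-mode eigenvectors rather than loading on a single leading
component — an instructive failure mode of eigenvector compartment
calling on synthetic inputs, not a property of real genomes.

## Regulatory elements and the E–P network

Enhancer states follow histone co-occurrence: H3K4me1+H3K27ac = active,
H3K4me1 only = intermediate, H3K4me1+H3K27me3 = poised, no H3K4me1 =
unclassified (the rules are total and mutually exclusive; H3K27ac wins
over H3K27me3 when both are present). Promoter strength is
`log2((me3 + eps)/(me1 + eps))` over TSS ± 2 kb with eps = 0.1 so that
empty windows stay defined; ratio < 0 is enhancer-like (Ep), >= 0 strong
— the tie at exactly 0 goes to strong, since the boundary carries no
measure after eps-smoothing.

The enhancer universe is H3K4me1 peaks outside every promoter window,
intersected with RNAPII loop anchors (enhancers engaged in looping); a
flag relaxes the anchor requirement. Anchor annotation gives promoter
identity precedence over enhancer, and an anchor spanning several
promoter windows takes the nearest TSS (logged). Edges collapse loops per
unordered element pair and are typed literally from their anchor labels
(E–P, Ep–P, P–P, E–E, plus the mixed E–Ep and Ep–Ep forms). A gene's
connected-enhancer count is its distinct E partners plus partner genes
whose promoters are enhancer-like — Ep partners act as enhancers for
counting while the edge type still records their promoter identity.

## Statistical kernels

* **Rank-sum**: exact permutation enumeration over all C(n+m, n)
  labelings when the pooled size is <= 12 (valid under ties); above that,
  the normal approximation with tie correction and a 0.5 continuity
  correction. The crossover at 12 keeps the exact path oracle-verifiable.
* **Two-proportion z**: pooled variance; a pooled proportion of exactly
  0 or 1 returns z = 0, p = 1 (degenerate, logged).
* **Hypergeometric tail**: exact pmf sum from k upward, accumulated in
  log space.
* **KS**: D as the ECDF supremum with the asymptotic Kolmogorov p.
* **Fisher exact 2x2**: two-sided, probability-mass definition.
* **PWM scan**: both strands, log-odds sum against a threshold;
  reverse-strand hits reported in forward coordinates; non-ACGT bases
  contribute 0 (logged).

No multiple-testing correction happens inside kernels (reported p-values
are raw, matching field practice); Benjamini–Hochberg is applied at the
reporting layer where many simultaneous tests are emitted (DMC calling).

SNP enrichment counts at the element level (an element either contains a
SNP or not), which avoids element-length bias dominating the statistic;
N = universe elements, K = SNP-containing universe elements, n = target
elements, k = SNP-containing target elements. A SNP-universe mode
(trait set against a background SNP set) is available behind a flag.

## Co-transcription and the rewired null

Gene pairs joined by P–P (and by default Ep–P/Ep–Ep) edges are
correlated across a panel (Pearson; pairs with a zero-variance profile
are excluded from the reported fraction and logged). The null rewires
pairs by randomly rematching the multiset of gene slots, rejecting
self-pairs and observed pairs — degree within the paired set is preserved
exactly, the stricter and more defensible null than unconstrained
rewiring (which exists behind a flag). The empirical p uses the add-one
estimator (1 + #{null >= observed})/(n_perm + 1) and therefore never
reports 0. Calibration checks use 199 permutations so that 0.05 is an
attainable quantile of the discrete p distribution ((B+1)·α integral).

## CTCF binding and methylation

Differential binding works on merged footprints of both states' CTCF
peaks restricted to promoter windows; per-state intensity is the maximum
overlapping peak intensity (summit height convention; sum/mean exist
behind a flag), with `M = log2((I_A + eps)/(I_B + eps))`,
`A = 0.5·log2((I_A + eps)(I_B + eps))`, and calls at |M| >= 1 (2-fold;
the threshold is declared, config-exposed). Region methylation is the
coverage-weighted mean β over CpGs with coverage >= 5; motif regions are
219 bp windows centered on the site midpoint — 219 bp is treated purely
as a width parameter. DMCs are called per shared cytosine with both
coverages >= 5 by Fisher exact on the methylated/unmethylated table,
BH-corrected across all tested positions, requiring q <= 0.05 and
|Δβ| >= 0.25; no smoothing across cytosines (single-cytosine
resolution). The DMC procedure is a declared caller, not a
reconstruction of any published one.

## Synthetic data: what it emulates, and what it does not

The generator plants, per seed: 200 genes on 2 chromosomes of 5 Mb
(40 kb slots), 50 + 50 state-specific genes at a 16x expression ratio
before multiplicative log-normal noise (sd 0.25 in log2 units — the
standard abundance noise model, keeping ratios interpretable), 1–3
enhancers per specific gene (P = 0.4/0.3/0.3) whose count multiplies the
baseline by 1.8 per extra enhancer (an additive-in-log enhancer dosage
effect), E–P loops with one anchor on the enhancer and one in TSS ± 1 kb,
10 promoter–promoter pairs per state on adjacent slots sharing a latent
expression factor (pair correlation ≈ 0.9), enhancer states drawn
0.70/0.25/0.05 active/intermediate/poised, 20% enhancer-like promoters
among specific genes, a promoter-proximal CTCF site per gene
(differential at specific genes, common at shared ones) with a 219 bp
motif window whose ~7 CpGs sit at β ≈ 0.1 bound / 0.9 unbound when
inverse coupling is on (coverage ~20, binomial read sampling), CTCF
loops from each bound site, a 29-cell CTCF panel (differential sites
present in one cell, common sites in all) and a 20-cell expression panel
(specific genes expressed in 2 cells), GWAS leads inside enhancers with
4 LD satellites each at r² = exp(−0.01·d_kb) within 50 kb blocks, a
driver TF covering 90% of state-A vs 10% of state-B enhancers plus five
unbiased background TFs, and spurious loops at 20% of the planted count.
Enhancer offsets are fixed relative to the gene slot so planted loops
never bridge adjacent genes — domain ground truth stays well-defined.

Zero-noise mode (`SynthConfig.noiseless`) switches off loop noise,
expression noise, and binomial methylation sampling; recovery is then
exact by construction, which is what the end-to-end recovery tests
assert. Each file type draws from its own RNG stream derived from the
master seed, so adding a file type never perturbs existing outputs and a
given config+seed is byte-reproducible.

Not emulated: read-level data, realistic genome sequence composition,
inter-chromosomal structure, genomic distance effects on contact
frequency beyond the block fixture, batch effects, or cohort structure
in the panels. Passing tests therefore demonstrate correctness of the
pipeline's logic and calibration of its statistics under the planted
model — not performance on real ChIA-PET/WGBS data, where peak calling,
normalization, and anchor resolution dominate.

## Problem sizes and runtime choices

Default sizes (200 genes, ~400 loops, ~3,400 CpGs per state, 29 + 20
panel cells) were chosen as the smallest scale at which every analysis
stage is exercised with non-trivial counts; the full pipeline runs in a
few seconds and the entire suite in about a minute on one core.
Calibration checks use 2,000 null replicates; recovery checks use 10
seeds.

## Known limitations

* The specificity call is threshold-based; it does not model replicate
  variance (inputs are abundances, not counts).
* Domain construction depends on anchor resolution; `merge_gap` is the
  only knob for fragmented anchors.
* Compartment calling from loop-derived matrices is only meaningful at
  scales where loops tile the chromosome; sparse loop sets produce NA
  bins.
* The rewired null conditions on the observed gene multiset; genes
  appearing in many pairs dominate the null mean.
* Motif regions are positioned from site midpoints (or planted motif
  coordinates), not from sequence scanning, unless a FASTA and PWM are
  supplied to `pwm_scan` explicitly.
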