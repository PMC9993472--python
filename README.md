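# epiloop

Integrative 3D-epigenomic analysis of condition-specific transcription in
two cell states — for example a hepatocellular-carcinoma line against a
normal-hepatocyte line. Given RNAPII/CTCF chromatin loops (ChIA-PET style
BEDPE), histone-mark peaks and signal (BED/bedGraph), expression tables,
per-CpG bisulfite counts, and GWAS SNPs with LD pairs, the pipeline links
genes to the regulatory architecture around them:

* **Condition-specific genes** — threshold calls on
  `log2FC = log2((mean_A + c)/(mean_B + c))` with |log2FC| >= 2 (4-fold) and
  a minimum abundance, plus expression breadth across a multi-cell panel.
* **Interaction domains** — connected components of anchor-overlapping
  loops (RAID for RNAPII, CCD for CTCF), single-gene vs multi-gene classes,
  and A/B compartments from the leading eigenvector of the O/E correlation
  matrix, oriented by gene density.
* **Enhancer–promoter networks** — enhancer chromatin states
  (active = H3K4me1+H3K27ac, intermediate = H3K4me1 only,
  poised = H3K4me1+H3K27me3), promoter strength
  `log2(H3K4me3/H3K4me1)` (negative = enhancer-like, Ep), loop anchors
  annotated P/Ep/E, and typed E–P / P–P / E–E edges with per-gene connected
  enhancer counts.
* **Enrichment statistics** — Wilcoxon rank-sum (exact below pooled n = 12),
  pooled two-proportion z, log-space hypergeometric tails, two-sample KS,
  Fisher exact, PWM scanning, TF occupancy ranking, and LD expansion of
  GWAS leads (satellites at r² >= 0.8) with element-level enrichment.
* **Co-transcription** — Pearson correlation of P–P connected gene pairs
  across a sample panel against a degree-preserving rewired null with an
  add-one empirical p-value.
* **CTCF and methylation** — MA classification of differential promoter-
  proximal CTCF binding (`M = log2(I_A/I_B)`), binding breadth across a
  cell panel with KS comparison, coverage-weighted methylation at peak
  (~500 bp) and motif (219 bp) scales, and per-cytosine DMC calling
  (Fisher exact + Benjamini–Hochberg + |Δβ| gate).

A synthetic-data module generates a complete two-state dataset with planted
ground truth (specific genes, E–P loops, domains, methylation-coupled CTCF
sites, LD blocks, a driver TF), so every stage is testable end-to-end
without any download.

## Worked example

Generate a synthetic bundle and run the whole pipeline from its emitted
config:

```sh
epiloop synth --seed 1 --out bundle/
epiloop run-all --config bundle/config.yaml --out run/
```

`run/report.json` collects per-stage record counts and the headline
statistics. With seed 1 the run prints, among others:

```json
"cotx": {
  "n_pairs": 21,
  "fraction_r_above": 0.9523809523809523,
  "observed_mean_r": 0.8487560727466584,
  "empirical_p": 0.000999000999000999
},
"methylation_comparison": {
  "up_a": {
    "median_a": 0.09824682359893627,
    "median_b": 0.9032096915199201,
    "p_value": 7.050152069091487e-18
  }
}
```

Reading: the 21 promoter–promoter connected gene pairs have a mean Pearson
correlation of 0.85 across the expression panel — the rewired null never
reaches it in 1000 permutations (p = 1/1001) — and CTCF motifs at sites
bound in state A have median methylation β ≈ 0.10 in the bound state versus
β ≈ 0.90 where binding is lost, the planted inverse methylation–binding
coupling. Stage outputs land as TSVs next to the report
(`de_results.tsv`, `domains.tsv`, `epnet_A.tsv`, `ctcf_differential.tsv`,
`dmc.tsv`, ...).

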