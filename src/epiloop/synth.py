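"""Two-cell-state synthetic dataset with planted ground truth.

The generator emulates the data shapes of a two-state (tumor-like state A
vs normal-like state B) 3D-epigenomic study: state-specific genes with a
planted expression fold change, enhancers looping to promoters with
histone-mark states, promoter-promoter loops between co-expressed gene
pairs, promoter-proximal CTCF sites whose binding anticorrelates with
motif CpG methylation, LD blocks around trait SNPs planted in enhancers,
a TF occupancy panel with a planted driver factor, and multi-cell panels
for expression and CTCF-binding breadth.

Every random draw comes from a dedicated RNG stream derived from the
master seed, so adding a file type never perturbs existing outputs, and a
given (config, seed) always produces byte-identical bundles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .types import (
    CpGRecord,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    Loop,
    Peak,
    SNPRecord,
)

log = logging.getLogger(__name__)

# Named RNG streams (SeedSequence spawn keys); order is part of the contract.
_STREAMS = {
    "layout": 0,
    "expression": 1,
    "enhancers": 2,
    "loops": 3,
    "ctcf": 4,
    "methylation": 5,
    "snps": 6,
    "tf": 7,
    "breadth_panel": 8,
    "cotx_panel": 9,
    "noise_loops": 10,
    "ctcf_panel": 11,
}

GENE_SPACING = 40_000
GENE_BODY = 10_000
ENHANCER_WIDTH = 1_500
# candidate enhancer offsets from the gene-slot start; outside the +/-2 kb
# promoter window for either strand and clear of the neighboring slot, so
# planted loops never bridge adjacent genes
ENHANCER_OFFSETS = (-14_000, -10_000, 12_500, 16_500, 20_500)
TSS_ANCHOR_HALF = 1_000
CTCF_PEAK_WIDTH = 500
CTCF_LOOP_REACH = 30_000


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic two-state dataset."""

    seed: int
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 200
    n_specific_a: int = 50
    n_specific_b: int = 50
    fold_specific: float = 16.0
    enhancer_count_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)  # P(1,2,3)
    enhancer_boost: float = 1.8  # per extra enhancer, multiplies baseline
    expr_noise_sd: float = 0.25  # log2 units, multiplicative log-normal
    loop_noise_rate: float = 0.2  # spurious loops as a fraction of planted
    n_pp_pairs: int = 10  # planted P-P pairs per state
    ep_promoter_frac: float = 0.2  # specific genes with enhancer-like promoters
    n_panel_cells: int = 20  # expression breadth panel
    n_ctcf_panel_cells: int = 29  # CTCF binding breadth panel
    n_cotx_samples: int = 30
    methyl_inverse_coupling: bool = True
    beta_bound: float = 0.1
    beta_unbound: float = 0.9
    methyl_coverage: int = 20
    methyl_noise: bool = True  # binomial read sampling vs deterministic counts
    n_background_cpgs: int = 2000
    motif_width: int = 219
    ld_block_size: int = 50_000
    r2_decay: float = 0.01  # r2 = exp(-r2_decay * distance_kb)
    n_satellites_per_lead: int = 4
    dmc_delta: float = 0.8

    def __post_init__(self) -> None:
        if self.fold_specific <= 1:
            raise ValueError("fold_specific must be > 1")
        if not 0 <= self.loop_noise_rate <= 1:
            raise ValueError("loop_noise_rate must be in [0,1]")
        if abs(sum(self.enhancer_count_probs) - 1.0) > 1e-9:
            raise ValueError("enhancer_count_probs must sum to 1")
        if self.n_specific_a < 2 * self.n_pp_pairs or self.n_specific_b < 2 * self.n_pp_pairs:
            raise ValueError("need n_specific >= 2 * n_pp_pairs per state")

    @classmethod
    def noiseless(cls, seed: int, **overrides) -> "SynthConfig":
        """The zero-noise condition: planted structure only, no sampling noise."""
        base = dict(
            seed=seed, loop_noise_rate=0.0, expr_noise_sd=0.0, methyl_noise=False
        )
        base.update(overrides)
        return cls(**base)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )


@dataclass
class TruthTables:
    """Planted ground truth; every entity here exists in the emitted files."""

    specific_genes: pd.DataFrame  # gene_id, state
    promoter_class: pd.DataFrame  # gene_id, klass
    enhancers: pd.DataFrame  # enh_id, state, chrom, start, end, enh_state, gene_id
    ep_edges: pd.DataFrame  # state, enh_id, chrom, start, end, gene_id
    pp_pairs: pd.DataFrame  # state, gene_a, gene_b
    domains: pd.DataFrame  # state, domain_genes (comma-joined), gene_class
    ctcf_sites: pd.DataFrame  # chrom, start, end, call, gene_id, motif_start, motif_end
    dmcs: pd.DataFrame  # chrom, pos, delta
    snp_placements: pd.DataFrame  # rsid, trait_class, enh_id, state
    driver_tf: str

    def frames(self) -> dict[str, pd.DataFrame]:
        return {
            "specific_genes": self.specific_genes,
            "promoter_class": self.promoter_class,
            "enhancers": self.enhancers,
            "ep_edges": self.ep_edges,
            "pp_pairs": self.pp_pairs,
            "domains": self.domains,
            "ctcf_sites": self.ctcf_sites,
            "dmcs": self.dmcs,
            "snp_placements": self.snp_placements,
        }


@dataclass
class SynthBundle:
    config: SynthConfig
    genes: list[GeneModel]
    expression: dict[str, ExpressionTable]  # state -> 3-replicate table
    panel_expression: ExpressionTable
    cotx_panel: ExpressionTable
    peaks: dict[str, dict[str, list[Peak]]]  # state -> factor -> peaks
    signals: dict[str, dict[str, list[tuple[str, int, int, float]]]]
    loops: dict[str, dict[str, list[Loop]]]  # state -> factor -> loops
    methylation: dict[str, list[CpGRecord]]  # state -> CpGs
    snps: list[SNPRecord]
    tf_peaks: dict[str, list[Peak]]
    ctcf_panel: dict[str, list[Peak]]
    truth: TruthTables


def _gene_layout(cfg: SynthConfig) -> list[GeneModel]:
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    needed = 100_000 + per_chrom * GENE_SPACING + 100_000
    if needed > cfg.chrom_length:
        raise ValueError(
            f"planted genes exceed chromosome capacity ({needed} > "
            f"{cfg.chrom_length}); increase chrom_length"
        )
    rng = cfg.rng("layout")
    genes = []
    for i in range(cfg.n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        slot = 100_000 + (i % per_chrom) * GENE_SPACING
        strand = "+" if rng.random() < 0.5 else "-"
        body = GenomicInterval(chrom, slot, slot + GENE_BODY, strand=strand)
        genes.append(GeneModel(f"G{i:04d}", f"G{i:04d}", body, strand))
    return genes


def _assign_specificity(cfg: SynthConfig) -> tuple[dict[str, list[int]], list[tuple[int, int]], list[tuple[int, int]]]:
    """Pick specific-gene slots; P-P pairs sit on genomically adjacent slots."""
    rng = cfg.rng("layout")
    rng.random(cfg.n_genes)  # keep stream aligned past the layout draws
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    free = set(range(cfg.n_genes))

    def take_adjacent_pairs(n_pairs: int) -> list[tuple[int, int]]:
        pairs = []
        candidates = [
            i
            for i in sorted(free)
            if i + 1 in free and (i % per_chrom) + 1 < per_chrom
        ]
        chosen = rng.choice(len(candidates), size=len(candidates), replace=False)
        for ci in chosen:
            i = candidates[ci]
            if i in free and i + 1 in free and len(pairs) < n_pairs:
                pairs.append((i, i + 1))
                free.discard(i)
                free.discard(i + 1)
        if len(pairs) < n_pairs:
            raise ValueError("not enough adjacent gene slots for planted P-P pairs")
        return pairs

    pairs_a = take_adjacent_pairs(cfg.n_pp_pairs)
    pairs_b = take_adjacent_pairs(cfg.n_pp_pairs)

    def take_singles(n: int) -> list[int]:
        pool = sorted(free)
        picked = rng.choice(pool, size=n, replace=False)
        for i in picked:
            free.discard(int(i))
        return [int(i) for i in picked]

    spec_a = sorted([i for p in pairs_a for i in p] + take_singles(cfg.n_specific_a - 2 * cfg.n_pp_pairs))
    spec_b = sorted([i for p in pairs_b for i in p] + take_singles(cfg.n_specific_b - 2 * cfg.n_pp_pairs))
    return {"A": spec_a, "B": spec_b}, pairs_a, pairs_b


def generate_dataset(cfg: SynthConfig) -> SynthBundle:
    """Generate the full two-state bundle and its truth tables."""
    genes = _gene_layout(cfg)
    specific, pairs_a, pairs_b = _assign_specificity(cfg)
    spec_state = {}
    for state, idxs in specific.items():
        for i in idxs:
            spec_state[i] = state
    states = ("A", "B")

    # --- enhancers (state-specific genes only) ----------------------------
    rng_enh = cfg.rng("enhancers")
    enh_rows = []  # (state, enh_id, interval, enh_state, gene_idx)
    n_enh_by_gene: dict[int, int] = {}
    for state in states:
        for gi in specific[state]:
            n_enh = int(rng_enh.choice([1, 2, 3], p=cfg.enhancer_count_probs))
            n_enh_by_gene[gi] = n_enh
            offsets = rng_enh.choice(len(ENHANCER_OFFSETS), size=n_enh, replace=False)
            for oi in sorted(int(o) for o in offsets):
                off = ENHANCER_OFFSETS[oi]
                start = max(0, genes[gi].body.start + off)
                region = GenomicInterval(genes[gi].chrom, start, start + ENHANCER_WIDTH)
                enh_state = str(
                    rng_enh.choice(
                        ["active", "intermediate", "poised"], p=[0.7, 0.25, 0.05]
                    )
                )
                enh_id = f"E_{state}_{gi:04d}_{oi}"
                enh_rows.append((state, enh_id, region, enh_state, gi))

    # --- promoter classes (ride the enhancer stream) ----------------------
    promoter_class = {}
    for i, g in enumerate(genes):
        if i in spec_state:
            promoter_class[g.gene_id] = (
                "enhancer_like" if rng_enh.random() < cfg.ep_promoter_frac else "strong"
            )
        else:
            promoter_class[g.gene_id] = "strong"

    # --- expression -------------------------------------------------------
    rng_expr = cfg.rng("expression")
    base = np.empty(cfg.n_genes)
    for i in range(cfg.n_genes):
        if i in spec_state:
            base[i] = 4.0 * cfg.enhancer_boost ** (n_enh_by_gene[i] - 1)
        else:
            base[i] = float(2.0 ** rng_expr.normal(3.0, 1.0))
    mean_by_state = {s: np.empty(cfg.n_genes) for s in states}
    for i in range(cfg.n_genes):
        st = spec_state.get(i)
        for s in states:
            if st is None:
                mean_by_state[s][i] = base[i]
            elif st == s:
                mean_by_state[s][i] = base[i] * cfg.fold_specific
            else:
                mean_by_state[s][i] = base[i]
    gene_ids = [g.gene_id for g in genes]
    expression = {}
    for s in states:
        cols = {}
        for rep in range(3):
            noise = (
                2.0 ** rng_expr.normal(0.0, cfg.expr_noise_sd, cfg.n_genes)
                if cfg.expr_noise_sd > 0
                else np.ones(cfg.n_genes)
            )
            cols[f"{s}_{rep + 1}"] = mean_by_state[s] * noise
        expression[s] = ExpressionTable(pd.DataFrame(cols, index=gene_ids))

    # --- breadth panel ----------------------------------------------------
    rng_panel = cfg.rng("breadth_panel")
    n_cells = cfg.n_panel_cells
    panel = np.zeros((cfg.n_genes, n_cells))
    for i in range(cfg.n_genes):
        if i in spec_state:
            on = rng_panel.choice(n_cells, size=2, replace=False)  # breadth 0.1
            panel[i, on] = mean_by_state[spec_state[i]][i]
            panel[i, [c for c in range(n_cells) if c not in on]] = 0.01
        else:
            off = rng_panel.choice(n_cells, size=rng_panel.integers(0, 3), replace=False)
            panel[i, :] = base[i]
            panel[i, off] = 0.01
    panel_expression = ExpressionTable(
        pd.DataFrame(
            panel, index=gene_ids, columns=[f"cell_{c + 1:02d}" for c in range(n_cells)]
        )
    )

    # --- co-transcription panel -------------------------------------------
    rng_cotx = cfg.rng("cotx_panel")
    n_samp = cfg.n_cotx_samples
    log2_panel = rng_cotx.normal(3.0, 1.0, size=(cfg.n_genes, 1)) + rng_cotx.normal(
        0.0, 1.0, size=(cfg.n_genes, n_samp)
    )
    for pair_list in (pairs_a, pairs_b):
        for gi, gj in pair_list:
            latent = rng_cotx.normal(0.0, 1.0, n_samp)
            for g in (gi, gj):
                log2_panel[g] = (
                    rng_cotx.normal(3.0, 1.0)
                    + 1.5 * latent
                    + 0.5 * rng_cotx.normal(0.0, 1.0, n_samp)
                )
    cotx_panel = ExpressionTable(
        pd.DataFrame(
            2.0**log2_panel,
            index=gene_ids,
            columns=[f"s{j + 1:02d}" for j in range(n_samp)],
        )
    )

    # --- histone peaks and promoter signal --------------------------------
    peaks: dict[str, dict[str, list[Peak]]] = {s: {} for s in states}
    signals: dict[str, dict[str, list[tuple[str, int, int, float]]]] = {
        s: {} for s in states
    }
    for s in states:
        k4me1, k27ac, k27me3 = [], [], []
        for state, enh_id, region, enh_state, gi in enh_rows:
            if state != s:
                continue
            k4me1.append(Peak(region, "H3K4me1", 5.0, name=enh_id))
            if enh_state == "active":
                k27ac.append(Peak(region, "H3K27ac", 5.0, name=enh_id))
            if enh_state == "poised":
                k27me3.append(Peak(region, "H3K27me3", 5.0, name=enh_id))
        peaks[s]["H3K4me1"] = k4me1
        peaks[s]["H3K27ac"] = k27ac
        peaks[s]["H3K27me3"] = k27me3

        me3_rows, me1_rows = [], []
        for i, g in enumerate(genes):
            lo, hi = max(0, g.tss - 2000), g.tss + 2001
            if promoter_class[g.gene_id] == "enhancer_like" and spec_state.get(i) == s:
                me3, me1 = 2.0, 8.0
            else:
                me3, me1 = 8.0, 2.0
            me3_rows.append((g.chrom, lo, hi, me3))
            me1_rows.append((g.chrom, lo, hi, me1))
        # sort records and also cover enhancers with H3K4me1 signal
        for state, enh_id, region, enh_state, gi in enh_rows:
            if state == s:
                me1_rows.append((region.chrom, region.start, region.end, 5.0))
        signals[s]["H3K4me3"] = sorted(me3_rows)
        signals[s]["H3K4me1"] = sorted(me1_rows)

        # RNAPII peaks at promoters of genes active in this state
        rnapii = []
        for i, g in enumerate(genes):
            st = spec_state.get(i)
            if st is not None and st != s:
                continue
            region = GenomicInterval(g.chrom, max(0, g.tss - 500), g.tss + 500)
            rnapii.append(
                Peak(region, "RNAPII", float(mean_by_state[s][i]), name=g.gene_id)
            )
        peaks[s]["RNAPII"] = rnapii

    # --- RNAPII loops (E-P and P-P) ---------------------------------------
    rng_loops = cfg.rng("loops")
    loops: dict[str, dict[str, list[Loop]]] = {s: {} for s in states}
    ep_edge_rows = []
    for s in states:
        lst = []
        for state, enh_id, region, enh_state, gi in enh_rows:
            if state != s:
                continue
            tss = genes[gi].tss
            tss_anchor = GenomicInterval(
                genes[gi].chrom, max(0, tss - TSS_ANCHOR_HALF), tss + TSS_ANCHOR_HALF
            )
            pet = int(rng_loops.integers(5, 21))
            lst.append(Loop.make(region, tss_anchor, pet, "RNAPII"))
            ep_edge_rows.append(
                (s, enh_id, region.chrom, region.start, region.end, genes[gi].gene_id)
            )
        for gi, gj in pairs_a if s == "A" else pairs_b:
            a1 = GenomicInterval(
                genes[gi].chrom,
                max(0, genes[gi].tss - TSS_ANCHOR_HALF),
                genes[gi].tss + TSS_ANCHOR_HALF,
            )
            a2 = GenomicInterval(
                genes[gj].chrom,
                max(0, genes[gj].tss - TSS_ANCHOR_HALF),
                genes[gj].tss + TSS_ANCHOR_HALF,
            )
            pet = int(rng_loops.integers(5, 21))
            lst.append(Loop.make(a1, a2, pet, "RNAPII"))
        loops[s]["RNAPII"] = lst

    # spurious loops
    rng_noise = cfg.rng("noise_loops")
    for s in states:
        n_noise = int(round(cfg.loop_noise_rate * len(loops[s]["RNAPII"])))
        noise = []
        for _ in range(n_noise):
            chrom = f"chr{int(rng_noise.integers(1, cfg.n_chroms + 1))}"
            start = int(rng_noise.integers(0, cfg.chrom_length - 300_000))
            w1 = int(rng_noise.integers(1000, 3001))
            w2 = int(rng_noise.integers(1000, 3001))
            gap = int(rng_noise.integers(10_000, 200_000))
            noise.append(
                Loop.make(
                    GenomicInterval(chrom, start, start + w1),
                    GenomicInterval(chrom, start + gap, start + gap + w2),
                    int(rng_noise.integers(1, 4)),
                    "RNAPII",
                )
            )
        loops[s]["RNAPII"] = loops[s]["RNAPII"] + noise

    # --- CTCF sites, loops, panel -----------------------------------------
    rng_ctcf = cfg.rng("ctcf")
    ctcf_rows = []  # (chrom, start, end, call, gene_id, motif_start, motif_end, state)
    for i, g in enumerate(genes):
        center = g.tss + int(rng_ctcf.integers(-1000, 1001))
        start = max(0, center - CTCF_PEAK_WIDTH // 2)
        site = GenomicInterval(g.chrom, start, start + CTCF_PEAK_WIDTH)
        motif_start = site.midpoint - cfg.motif_width // 2
        st = spec_state.get(i)
        call = "common" if st is None else ("up_a" if st == "A" else "up_b")
        ctcf_rows.append(
            (site, call, g.gene_id, motif_start, motif_start + cfg.motif_width, st)
        )
    for s in states:
        lst = []
        for site, call, gid, m0, m1, st in ctcf_rows:
            bound_here = call == "common" or (st == s)
            if not bound_here:
                continue
            intensity = 8.0 * (
                2.0 ** rng_ctcf.normal(0.0, cfg.expr_noise_sd)
                if cfg.expr_noise_sd > 0
                else 1.0
            )
            lst.append(Peak(site, "CTCF", float(intensity), name=gid))
        peaks[s]["CTCF"] = lst

        ctcf_loops = []
        for site, call, gid, m0, m1, st in ctcf_rows:
            if not (call == "common" or st == s):
                continue
            a1 = GenomicInterval(site.chrom, site.midpoint - 1000, site.midpoint + 1000)
            a2_start = site.midpoint + CTCF_LOOP_REACH
            a2 = GenomicInterval(site.chrom, a2_start, a2_start + 2000)
            ctcf_loops.append(Loop.make(a1, a2, int(rng_ctcf.integers(5, 16)), "CTCF"))
        loops[s]["CTCF"] = ctcf_loops

    rng_cpanel = cfg.rng("ctcf_panel")
    ctcf_panel: dict[str, list[Peak]] = {
        f"cell_{c + 1:02d}": [] for c in range(cfg.n_ctcf_panel_cells)
    }
    cells = sorted(ctcf_panel)
    for site, call, gid, m0, m1, st in ctcf_rows:
        peak = Peak(site, "CTCF", 8.0, name=gid)
        if call == "common":
            for c in cells:
                ctcf_panel[c].append(peak)
        else:
            only = cells[int(rng_cpanel.integers(0, len(cells)))]
            ctcf_panel[only].append(peak)

    # --- methylation -------------------------------------------------------
    rng_meth = cfg.rng("methylation")
    methylation: dict[str, list[CpGRecord]] = {s: [] for s in states}
    dmc_rows = []

    def emit_cpg(state: str, chrom: str, pos: int, beta: float) -> None:
        cov = cfg.methyl_coverage
        if cfg.methyl_noise:
            cov = max(5, int(rng_meth.poisson(cfg.methyl_coverage)))
            meth = int(rng_meth.binomial(cov, beta))
        else:
            meth = int(round(beta * cov))
        methylation[state].append(CpGRecord(chrom, pos, meth, cov))

    for site, call, gid, m0, m1, st in ctcf_rows:
        cpg_pos = range(m0 + 15, m1 - 10, 30)
        for pos in cpg_pos:
            for s in states:
                bound_here = call == "common" or st == s
                if cfg.methyl_inverse_coupling:
                    beta = cfg.beta_bound if bound_here else cfg.beta_unbound
                else:
                    beta = 0.5
                emit_cpg(s, site.chrom, pos, beta)
            if call != "common" and cfg.methyl_inverse_coupling:
                delta = (cfg.beta_bound - cfg.beta_unbound) * (1 if st == "A" else -1)
                dmc_rows.append((site.chrom, pos, delta))
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    bg_start = 100_000 + per_chrom * GENE_SPACING + 50_000  # past the gene slots
    if bg_start >= cfg.chrom_length - 100_000:
        raise ValueError(
            "no intergenic room for background CpGs; increase chrom_length"
        )
    per_chrom_bg = cfg.n_background_cpgs // cfg.n_chroms
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        positions = np.sort(
            rng_meth.choice(
                np.arange(bg_start, cfg.chrom_length), size=per_chrom_bg, replace=False
            )
        )
        betas = rng_meth.uniform(0.3, 0.9, per_chrom_bg)
        for pos, beta in zip(positions, betas):
            for s in states:
                emit_cpg(s, chrom, int(pos), float(beta))
    for s in states:
        methylation[s].sort(key=lambda c: (c.chrom, c.pos))

    # --- SNPs ---------------------------------------------------------------
    rng_snp = cfg.rng("snps")
    snps: list[SNPRecord] = []
    snp_place_rows = []
    rs_counter = 1

    def plant_leads(state: str, trait: str, n_leads: int) -> None:
        nonlocal rs_counter
        rows = [r for r in enh_rows if r[0] == state]
        chosen = rng_snp.choice(len(rows), size=min(n_leads, len(rows)), replace=False)
        for ci in sorted(int(c) for c in chosen):
            _, enh_id, region, _, _ = rows[ci]
            pos = int(rng_snp.integers(region.start + 100, region.end - 100))
            rsid = f"rs{rs_counter}"
            rs_counter += 1
            lead = SNPRecord(rsid, region.chrom, pos, trait)
            snps.append(lead)
            snp_place_rows.append((rsid, trait, enh_id, state))
            for _ in range(cfg.n_satellites_per_lead):
                off = int(rng_snp.integers(1000, cfg.ld_block_size // 2)) * (
                    1 if rng_snp.random() < 0.5 else -1
                )
                sat_pos = max(0, pos + off)
                r2 = float(np.exp(-cfg.r2_decay * abs(off) / 1000.0))
                snps.append(
                    SNPRecord(
                        f"rs{rs_counter}", region.chrom, sat_pos, trait,
                        lead_rsid=rsid, r2=round(r2, 4),
                    )
                )
                rs_counter += 1

    plant_leads("A", "cancer_related", 8)
    plant_leads("B", "normal_function", 8)
    for _ in range(10):  # unrelated background leads away from gene slots
        chrom = f"chr{int(rng_snp.integers(1, cfg.n_chroms + 1))}"
        pos = int(rng_snp.integers(bg_start, cfg.chrom_length))
        snps.append(SNPRecord(f"rs{rs_counter}", chrom, pos, "other"))
        rs_counter += 1

    # --- TF occupancy panel -------------------------------------------------
    rng_tf = cfg.rng("tf")
    driver = "HNF4A"
    tf_peaks: dict[str, list[Peak]] = {}
    a_enh = [r for r in enh_rows if r[0] == "A"]
    b_enh = [r for r in enh_rows if r[0] == "B"]
    drv = []
    for _, enh_id, region, _, _ in a_enh:
        if rng_tf.random() < 0.9:
            drv.append(Peak(region, f"TF:{driver}", 5.0, name=enh_id))
    for _, enh_id, region, _, _ in b_enh:
        if rng_tf.random() < 0.1:
            drv.append(Peak(region, f"TF:{driver}", 5.0, name=enh_id))
    tf_peaks[driver] = drv
    for k in range(5):
        name = f"TF{k + 1}"
        lst = []
        for _, enh_id, region, _, _ in enh_rows:
            if rng_tf.random() < 0.3:
                lst.append(Peak(region, f"TF:{name}", 3.0, name=enh_id))
        tf_peaks[name] = lst

    # --- truth tables -------------------------------------------------------
    domain_rows = []
    for s, pair_list in (("A", pairs_a), ("B", pairs_b)):
        paired = {i for p in pair_list for i in p}
        for gi, gj in pair_list:
            domain_rows.append(
                (s, ",".join(sorted((genes[gi].gene_id, genes[gj].gene_id))), "MG")
            )
        for gi in specific[s]:
            if gi not in paired:
                domain_rows.append((s, genes[gi].gene_id, "SG"))
    truth = TruthTables(
        specific_genes=pd.DataFrame(
            [(genes[i].gene_id, s) for s in states for i in specific[s]],
            columns=["gene_id", "state"],
        ),
        promoter_class=pd.DataFrame(
            sorted(promoter_class.items()), columns=["gene_id", "klass"]
        ),
        enhancers=pd.DataFrame(
            [
                (enh_id, s, r.chrom, r.start, r.end, enh_state, genes[gi].gene_id)
                for s, enh_id, r, enh_state, gi in enh_rows
            ],
            columns=["enh_id", "state", "chrom", "start", "end", "enh_state", "gene_id"],
        ),
        ep_edges=pd.DataFrame(
            ep_edge_rows, columns=["state", "enh_id", "chrom", "start", "end", "gene_id"]
        ),
        pp_pairs=pd.DataFrame(
            [
                (s, genes[gi].gene_id, genes[gj].gene_id)
                for s, plist in (("A", pairs_a), ("B", pairs_b))
                for gi, gj in plist
            ],
            columns=["state", "gene_a", "gene_b"],
        ),
        domains=pd.DataFrame(domain_rows, columns=["state", "domain_genes", "gene_class"]),
        ctcf_sites=pd.DataFrame(
            [
                (site.chrom, site.start, site.end, call, gid, m0, m1)
                for site, call, gid, m0, m1, st in ctcf_rows
            ],
            columns=["chrom", "start", "end", "call", "gene_id", "motif_start", "motif_end"],
        ),
        dmcs=pd.DataFrame(dmc_rows, columns=["chrom", "pos", "delta"]),
        snp_placements=pd.DataFrame(
            snp_place_rows, columns=["rsid", "trait_class", "enh_id", "state"]
        ),
        driver_tf=driver,
    )

    return SynthBundle(
        config=cfg,
        genes=genes,
        expression=expression,
        panel_expression=panel_expression,
        cotx_panel=cotx_panel,
        peaks=peaks,
        signals=signals,
        loops=loops,
        methylation=methylation,
        snps=snps,
        tf_peaks=tf_peaks,
        ctcf_panel=ctcf_panel,
        truth=truth,
    )


def write_bundle(bundle: SynthBundle, out_dir: str | Path) -> pd.DataFrame:
    """Write every bundle file under ``out_dir``; returns the manifest.

    The manifest (also written as manifest.tsv) lists every emitted path
    with its record count.  A ready-to-run pipeline config is emitted as
    config.yaml.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[str, int]] = []

    def note(relpath: str, n: int) -> None:
        manifest.append((relpath, n))

    io.write_gene_table(bundle.genes, out / "genes.bed")
    note("genes.bed", len(bundle.genes))
    df = pd.concat(
        [bundle.expression["A"].frame, bundle.expression["B"].frame], axis=1
    )
    io.write_expression_table(ExpressionTable(df), out / "expression.tsv")
    note("expression.tsv", len(df))
    io.write_expression_table(bundle.panel_expression, out / "panel_expression.tsv")
    note("panel_expression.tsv", len(bundle.panel_expression.frame))
    io.write_expression_table(bundle.cotx_panel, out / "cotx_panel.tsv")
    note("cotx_panel.tsv", len(bundle.cotx_panel.frame))
    io.write_snp_table(bundle.snps, out / "snps.tsv")
    note("snps.tsv", len(bundle.snps))

    for s in ("A", "B"):
        sdir = out / f"state_{s.lower()}"
        sdir.mkdir(exist_ok=True)
        for factor, pk in sorted(bundle.peaks[s].items()):
            rel = f"state_{s.lower()}/peaks_{factor}.bed"
            io.write_bed(pk, out / rel)
            note(rel, len(pk))
        for factor, rows in sorted(bundle.signals[s].items()):
            rel = f"state_{s.lower()}/signal_{factor}.bedgraph"
            io.write_signal_bedgraph(rows, out / rel)
            note(rel, len(rows))
        for factor, lp in sorted(bundle.loops[s].items()):
            rel = f"state_{s.lower()}/loops_{factor}.bedpe"
            io.write_bedpe(lp, out / rel)
            note(rel, len(lp))
        rel = f"state_{s.lower()}/methylation.tsv"
        io.write_methylation_table(bundle.methylation[s], out / rel)
        note(rel, len(bundle.methylation[s]))

    tf_dir = out / "tf_peaks"
    tf_dir.mkdir(exist_ok=True)
    for name, pk in sorted(bundle.tf_peaks.items()):
        rel = f"tf_peaks/{name}.bed"
        io.write_bed(pk, out / rel)
        note(rel, len(pk))
    cp_dir = out / "ctcf_panel"
    cp_dir.mkdir(exist_ok=True)
    for cell, pk in sorted(bundle.ctcf_panel.items()):
        rel = f"ctcf_panel/{cell}.bed"
        io.write_bed(pk, out / rel)
        note(rel, len(pk))

    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name, frame in bundle.truth.frames().items():
        rel = f"truth/{name}.tsv"
        frame.to_csv(out / rel, sep="\t", index=False)
        note(rel, len(frame))
    (truth_dir / "driver_tf.txt").write_text(bundle.truth.driver_tf + "\n")
    note("truth/driver_tf.txt", 1)

    config = _pipeline_config(bundle)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    note("config.yaml", 1)

    mdf = pd.DataFrame(manifest, columns=["path", "n_records"])
    mdf.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return mdf


def _pipeline_config(bundle: SynthBundle) -> dict:
    cfg = bundle.config
    state_inputs = {}
    for s in ("A", "B"):
        sdir = f"state_{s.lower()}"
        state_inputs[s] = {
            "peaks": {
                factor: f"{sdir}/peaks_{factor}.bed"
                for factor in sorted(bundle.peaks[s])
            },
            "signals": {
                factor: f"{sdir}/signal_{factor}.bedgraph"
                for factor in sorted(bundle.signals[s])
            },
            "loops": {
                factor: f"{sdir}/loops_{factor}.bedpe"
                for factor in sorted(bundle.loops[s])
            },
            "methylation": f"{sdir}/methylation.tsv",
            "expression_samples": [f"{s}_{r}" for r in (1, 2, 3)],
        }
    return {
        "seed": int(cfg.seed),
        "strict": True,
        "inputs": {
            "genes": "genes.bed",
            "expression": "expression.tsv",
            "panel_expression": "panel_expression.tsv",
            "cotx_panel": "cotx_panel.tsv",
            "snps": "snps.tsv",
            "tf_peaks_dir": "tf_peaks",
            "ctcf_panel_dir": "ctcf_panel",
            "states": state_inputs,
        },
        "params": {
            "log2fc_min": 2.0,
            "min_level": 1.0,
            "pseudocount": 0.1,
            "breadth_threshold": 1.0,
            "breadth_max": 0.2,
            "flank": 2000,
            "merge_gap": 0,
            "m_min": 1.0,
            "eps": 0.1,
            "min_cov": 5,
            "min_cpgs": 1,
            "dmc_delta_min": 0.25,
            "dmc_q_max": 0.05,
            "r_min": 0.25,
            "n_perm": 1000,
            "r2_min": 0.8,
            "binsize": 100_000,
            "chrom_length": int(cfg.chrom_length),
            "n_chroms": int(cfg.n_chroms),
        },
    }


def make_block_contact_matrix(
    n_bins: int = 20,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Checkerboard contact matrix with two interleaved bin classes.

    Returns (matrix, planted class labels 0/1, gene density per bin);
    class 1 (gene-dense) is the planted A compartment.  Within-class
    contacts are enriched 3x over between-class, multiplied by a power-law
    distance decay and log-normal noise.  Class blocks of two bins are laid
    out in a random (aperiodic) order: a strictly periodic layout makes the
    correlation matrix near-circulant and splits the class signal across
    degenerate Fourier eigenvectors.
    """
    rng = np.random.default_rng(seed)
    n_blocks = (n_bins + 1) // 2
    block_classes = np.zeros(n_blocks, dtype=int)
    block_classes[rng.permutation(n_blocks)[: n_blocks // 2]] = 1
    classes = np.repeat(block_classes, 2)[:n_bins]
    dist = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
    decay = 1.0 / (1.0 + dist) ** 0.8
    same = (classes[:, None] == classes[None, :]).astype(float)
    base = decay * (1.0 + 2.0 * same) * 100.0
    noise = 2.0 ** rng.normal(0.0, noise_sd, size=(n_bins, n_bins))
    m = base * (noise + noise.T) / 2.0
    m = (m + m.T) / 2.0
    gene_density = np.where(classes == 1, 10.0, 1.0) + rng.uniform(0, 0.5, n_bins)
    return m, classes, gene_density


def make_null_panel(
    gene_ids: list[str], n_samples: int, seed: int
) -> ExpressionTable:
    """An i.i.d. log-normal expression panel with no planted correlation."""
    rng = np.random.default_rng(seed)
    vals = 2.0 ** rng.normal(3.0, 1.0, size=(len(gene_ids), n_samples))
    return ExpressionTable(
        pd.DataFrame(
            vals, index=gene_ids, columns=[f"s{j + 1:02d}" for j in range(n_samples)]
        )
    )
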