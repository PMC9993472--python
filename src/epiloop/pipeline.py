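"""End-to-end orchestration from a single YAML config.

Stages run in dependency order: io -> specificity/breadth -> domains ->
elements -> E-P network -> enrichment / co-transcription -> CTCF
differential binding / methylation / DMC -> compartments -> report.  A
stage whose inputs are absent from the config is skipped and noted in the
report.  Identical config + seed produces byte-identical data outputs
(wall time lives only in report.json).
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cotx as cotx_mod
from . import elements as el
from . import expression as ex
from . import io
from . import methylation as me
from . import stats as st
from . import topology as tp
from .types import GenomicInterval

log = logging.getLogger(__name__)

_TOP_KEYS = {"seed", "strict", "inputs", "params"}
_PARAM_DOMAINS: dict[str, tuple[float, float]] = {
    "log2fc_min": (0, math.inf),
    "min_level": (0, math.inf),
    "pseudocount": (0, math.inf),
    "breadth_threshold": (0, math.inf),
    "breadth_max": (0, 1),
    "flank": (1, math.inf),
    "merge_gap": (0, math.inf),
    "m_min": (0, math.inf),
    "eps": (0, math.inf),
    "min_cov": (1, math.inf),
    "min_cpgs": (1, math.inf),
    "dmc_delta_min": (0, 1),
    "dmc_q_max": (0, 1),
    "r_min": (-1, 1),
    "n_perm": (1, math.inf),
    "r2_min": (0, 1),
    "binsize": (1, math.inf),
    "chrom_length": (1, math.inf),
    "n_chroms": (1, math.inf),
    "motif_width": (1, math.inf),
}

DEFAULT_PARAMS: dict[str, Any] = {
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
    "motif_width": 219,
}


@dataclass
class RunConfig:
    base_dir: Path
    seed: int
    strict: bool
    inputs: dict
    params: dict

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        problems = validate_config(path)
        if problems:
            raise ValueError(
                "invalid config:\n" + "\n".join(f"  - {p}" for p in problems)
            )
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = dict(DEFAULT_PARAMS)
        params.update(raw.get("params", {}))
        return cls(
            base_dir=path.parent,
            seed=int(raw.get("seed", 0)),
            strict=bool(raw.get("strict", True)),
            inputs=raw["inputs"],
            params=params,
        )

    def path(self, rel: str) -> Path:
        return self.base_dir / rel


def validate_config(path: str | Path) -> list[str]:
    """Schema and domain checks on a config file; [] means valid.

    Collects every problem rather than stopping at the first; never reads
    the data files themselves.
    """
    path = Path(path)
    problems: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except OSError as exc:
        return [f"unreadable config: {exc}"]
    except yaml.YAMLError as exc:
        return [f"config is not valid YAML: {exc}"]
    if not isinstance(raw, dict):
        return ["config must be a mapping"]
    for key in raw:
        if key not in _TOP_KEYS:
            problems.append(f"unknown top-level key {key!r}")
    if "inputs" not in raw or not isinstance(raw.get("inputs"), dict):
        problems.append("missing 'inputs' mapping")
        return problems
    inputs = raw["inputs"]
    if "genes" not in inputs:
        problems.append("inputs.genes is required")
    states = inputs.get("states", {})
    if not isinstance(states, dict) or set(states) != {"A", "B"}:
        problems.append("inputs.states must define exactly states A and B")

    def check_path(rel: Any, key: str) -> None:
        if not isinstance(rel, str):
            problems.append(f"{key}: path must be a string")
        elif not (path.parent / rel).exists():
            problems.append(f"{key}: path {rel!r} does not exist")

    for key in ("genes", "expression", "panel_expression", "cotx_panel", "snps"):
        if key in inputs:
            check_path(inputs[key], f"inputs.{key}")
    for key in ("tf_peaks_dir", "ctcf_panel_dir"):
        if key in inputs:
            check_path(inputs[key], f"inputs.{key}")
    if isinstance(states, dict):
        for s, sdict in states.items():
            if not isinstance(sdict, dict):
                problems.append(f"inputs.states.{s} must be a mapping")
                continue
            for group in ("peaks", "signals", "loops"):
                for factor, rel in (sdict.get(group) or {}).items():
                    check_path(rel, f"inputs.states.{s}.{group}.{factor}")
            if "methylation" in sdict:
                check_path(sdict["methylation"], f"inputs.states.{s}.methylation")
    params = raw.get("params", {})
    if not isinstance(params, dict):
        problems.append("'params' must be a mapping")
    else:
        for key, value in params.items():
            if key not in _PARAM_DOMAINS:
                problems.append(f"unknown parameter {key!r}")
                continue
            lo, hi = _PARAM_DOMAINS[key]
            if not isinstance(value, (int, float)) or not (lo <= value <= hi):
                problems.append(
                    f"parameter {key!r} = {value!r} outside domain [{lo}, {hi}]"
                )
    return problems


@dataclass
class RunReport:
    stages: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    wall_time_s: float = 0.0

    def add(self, name: str, n_records: int, outputs: list[str]) -> None:
        self.stages.append(
            {"stage": name, "n_records": n_records, "outputs": outputs}
        )

    def skip(self, name: str, reason: str) -> None:
        self.stages.append({"stage": name, "skipped": reason})
        self.warnings.append(f"{name}: skipped ({reason})")

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": self.stages,
                "params": self.params,
                "outputs": self.outputs,
                "warnings": self.warnings,
                "wall_time_s": self.wall_time_s,
            },
            indent=2,
            sort_keys=True,
        )


def _write_tsv(frame: pd.DataFrame, path: Path) -> int:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
    return len(frame)


def run_all(config: RunConfig, out_dir: str | Path) -> RunReport:
    """Run every stage the config enables; returns (and writes) the report."""
    t0 = time.monotonic()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(params=dict(config.params))
    p = config.params
    strict = config.strict
    states = ("A", "B")

    # --- io ----------------------------------------------------------------
    genes = io.read_gene_table(config.path(config.inputs["genes"]), strict=strict)
    peaks = {s: {} for s in states}
    signals = {s: {} for s in states}
    loops = {s: {} for s in states}
    meth = {}
    for s in states:
        sdict = config.inputs["states"][s]
        for factor, rel in (sdict.get("peaks") or {}).items():
            peaks[s][factor] = io.read_bed(config.path(rel), factor, strict=strict)
        for factor, rel in (sdict.get("signals") or {}).items():
            signals[s][factor] = io.read_signal_bedgraph(config.path(rel), strict=strict)
        for factor, rel in (sdict.get("loops") or {}).items():
            loops[s][factor] = io.read_bedpe(config.path(rel), factor, strict=strict)
        if "methylation" in sdict:
            meth[s] = io.read_methylation_table(config.path(sdict["methylation"]), strict=strict)
    n_loaded = len(genes) + sum(
        len(v) for s in states for v in peaks[s].values()
    ) + sum(len(v) for s in states for v in loops[s].values())
    report.add("io", n_loaded, [])

    # --- condition-specific genes -------------------------------------------
    specific: dict[str, list[str]] = {s: [] for s in states}
    if "expression" in config.inputs:
        table = io.read_expression_table(config.path(config.inputs["expression"]))
        sub = {
            s: table.subset(config.inputs["states"][s]["expression_samples"])
            for s in states
        }
        de = ex.call_condition_specific_genes(
            sub["A"], sub["B"],
            log2fc_min=p["log2fc_min"], min_level=p["min_level"],
            pseudocount=p["pseudocount"],
        )
        de_frame = pd.DataFrame(
            [(d.gene_id, d.log2fc, d.mean_a, d.mean_b, d.call) for d in de],
            columns=["gene_id", "log2fc", "mean_a", "mean_b", "call"],
        )
        n = _write_tsv(de_frame, out / "de_results.tsv")
        report.add("de", n, ["de_results.tsv"])
        specific["A"] = [d.gene_id for d in de if d.call == "a_specific"]
        specific["B"] = [d.gene_id for d in de if d.call == "b_specific"]
        mean_expr = {
            s: dict(zip(sub[s].genes, sub[s].frame.mean(axis=1))) for s in states
        }
    else:
        report.skip("de", "no expression input")
        mean_expr = {s: {} for s in states}

    # --- expression breadth ---------------------------------------------------
    if "panel_expression" in config.inputs:
        panel = io.read_expression_table(config.path(config.inputs["panel_expression"]))
        breadth = ex.expression_breadth(
            panel, threshold=p["breadth_threshold"], breadth_max=p["breadth_max"]
        )
        frame = pd.DataFrame(
            [(b.gene_id, b.n_expressed, b.breadth, b.cell_specific) for b in breadth],
            columns=["gene_id", "n_expressed", "breadth", "cell_specific"],
        )
        n = _write_tsv(frame, out / "breadth.tsv")
        report.add("breadth", n, ["breadth.tsv"])
    else:
        report.skip("breadth", "no panel_expression input")

    # --- promoter RNAPII binding ----------------------------------------------
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for s in states:
        if "RNAPII" not in peaks[s] or not specific[s]:
            continue
        subset = [gene_by_id[g] for g in specific[s]]
        bound, frac = ex.promoter_binding_fraction(
            subset, peaks[s]["RNAPII"], flank=p["flank"]
        )
        rows.append((s, len(subset), sum(bound.values()), frac))
    if rows:
        frame = pd.DataFrame(
            rows, columns=["state", "n_specific", "n_bound", "fraction_bound"]
        )
        n = _write_tsv(frame, out / "promoter_binding.tsv")
        report.add("promoter_binding", n, ["promoter_binding.tsv"])

    # --- interaction domains ----------------------------------------------------
    domains = {s: {} for s in states}
    dom_rows, map_rows, frac_rows = [], [], []
    for s in states:
        for factor in ("RNAPII", "CTCF"):
            if factor not in loops[s]:
                continue
            doms = tp.cluster_loops_into_domains(loops[s][factor], merge_gap=p["merge_gap"])
            mapping, frac_inside = tp.assign_genes_to_domains(
                doms, genes, subset=specific[s] or None
            )
            domains[s][factor] = doms
            for d in doms:
                dom_rows.append(
                    (s, factor, d.domain_id, d.span.chrom, d.span.start,
                     d.span.end, len(d.member_loops), len(d.gene_ids), d.gene_class)
                )
            for gid, did in sorted(mapping.items()):
                map_rows.append((s, factor, gid, did))
            frac_rows.append((s, factor, frac_inside))
    n = _write_tsv(
        pd.DataFrame(
            dom_rows,
            columns=["state", "factor", "domain_id", "chrom", "start", "end",
                     "n_loops", "n_genes", "gene_class"],
        ),
        out / "domains.tsv",
    )
    _write_tsv(
        pd.DataFrame(map_rows, columns=["state", "factor", "gene_id", "domain_id"]),
        out / "gene_domain_map.tsv",
    )
    _write_tsv(
        pd.DataFrame(frac_rows, columns=["state", "factor", "fraction_specific_inside"]),
        out / "domain_fractions.tsv",
    )
    report.add("domains", n, ["domains.tsv", "gene_domain_map.tsv", "domain_fractions.tsv"])

    # --- regulatory elements and E-P network -------------------------------------
    networks = {}
    enhancer_regions = {}
    for s in states:
        if "H3K4me1" not in peaks[s] or "RNAPII" not in loops[s]:
            report.skip(f"elements_{s}", "missing H3K4me1 peaks or RNAPII loops")
            continue
        strengths = {}
        if "H3K4me3" in signals[s] and "H3K4me1" in signals[s]:
            for g in genes:
                strengths[g.gene_id] = el.promoter_strength_score(
                    g, signals[s]["H3K4me3"], signals[s]["H3K4me1"],
                    flank=p["flank"], eps=p["eps"],
                )
            _write_tsv(
                pd.DataFrame(
                    [(k.gene_id, k.me3_signal, k.me1_signal, k.log2_ratio, k.klass)
                     for k in strengths.values()],
                    columns=["gene_id", "me3", "me1", "log2_ratio", "klass"],
                ),
                out / f"promoter_strength_{s}.tsv",
            )
        enhancers = el.build_enhancer_elements(
            peaks[s]["H3K4me1"], genes, loops[s]["RNAPII"],
            other_marks={
                m: peaks[s].get(m, []) for m in ("H3K27ac", "H3K27me3")
            },
            flank=p["flank"],
        )
        enhancer_regions[s] = [e.region for e in enhancers]
        _write_tsv(
            pd.DataFrame(
                [(e.region.chrom, e.region.start, e.region.end, e.state,
                  ",".join(sorted(e.marks))) for e in enhancers],
                columns=["chrom", "start", "end", "state", "marks"],
            ),
            out / f"elements_{s}.tsv",
        )
        annot = el.AnchorAnnotator(genes, strengths, enhancers, flank=p["flank"])
        network = el.build_ep_network(loops[s]["RNAPII"], annot)
        networks[s] = network
        edge_frame = pd.DataFrame(
            [
                (repr(e.node_a), repr(e.node_b), e.edge_type,
                 ",".join(e.gene_ids), len(e.loop_indices))
                for e in network.edges
            ],
            columns=["node_a", "node_b", "type", "gene_ids", "n_loops"],
        )
        n = _write_tsv(edge_frame, out / f"epnet_{s}.tsv")
        report.add(
            f"elements_{s}", n,
            [f"elements_{s}.tsv", f"epnet_{s}.tsv", f"promoter_strength_{s}.tsv"],
        )
        if mean_expr[s]:
            try:
                effect = el.enhancer_count_effect(network, mean_expr[s])
                report.outputs[f"enhancer_count_effect_{s}"] = {
                    "medians": effect["medians"],
                    "pvalues": {f"{a}|{b}": v for (a, b), v in effect["pvalues"].items()},
                }
            except ValueError as exc:
                report.warnings.append(f"enhancer_count_effect_{s}: {exc}")

    # --- TF occupancy ranking ------------------------------------------------------
    if "tf_peaks_dir" in config.inputs and "A" in enhancer_regions and "B" in enhancer_regions:
        tf_dir = config.path(config.inputs["tf_peaks_dir"])
        tf_sets = {
            f.stem: io.read_bed(f, f"TF:{f.stem}", strict=strict)
            for f in sorted(tf_dir.glob("*.bed"))
        }
        if tf_sets:
            ranking = st.tf_occupancy_ranking(
                enhancer_regions["A"], enhancer_regions["B"], tf_sets
            )
            n = _write_tsv(
                pd.DataFrame(
                    [(r.tf_name, r.frac_a, r.frac_b, r.z, r.p_value, r.note)
                     for r in ranking],
                    columns=["tf", "frac_a", "frac_b", "z", "p_value", "note"],
                ),
                out / "tf_ranking.tsv",
            )
            report.add("enrich_tf", n, ["tf_ranking.tsv"])
    else:
        report.skip("enrich_tf", "no TF peak sets or enhancer sets")

    # --- SNP enrichment -------------------------------------------------------------
    if "snps" in config.inputs and "A" in enhancer_regions and "B" in enhancer_regions:
        all_snps = io.read_snp_table(config.path(config.inputs["snps"]), strict=strict)
        leads = [s for s in all_snps if s.lead_rsid is None]
        pairs = [
            (s.lead_rsid, s, s.r2) for s in all_snps if s.lead_rsid is not None
        ]
        universe = enhancer_regions["A"] + enhancer_regions["B"]
        rows = []
        for trait, target_state in (("cancer_related", "A"), ("normal_function", "B")):
            trait_leads = [s for s in leads if s.trait_class == trait]
            expanded = st.expand_ld(trait_leads, pairs, r2_min=p["r2_min"], strict=False)
            res = st.snp_element_enrichment(
                expanded, enhancer_regions[target_state], universe,
                set_label=f"{trait}->{target_state}",
            )
            rows.append(
                (res.set_label, len(expanded), res.k, res.n, res.K, res.N, res.p_value)
            )
        n = _write_tsv(
            pd.DataFrame(
                rows,
                columns=["set", "n_snps_expanded", "k", "n", "K", "N", "p_value"],
            ),
            out / "snp_enrichment.tsv",
        )
        report.add("enrich_snp", n, ["snp_enrichment.tsv"])
    else:
        report.skip("enrich_snp", "no SNP table or enhancer sets")

    # --- co-transcription --------------------------------------------------------
    if "cotx_panel" in config.inputs and networks:
        panel = io.read_expression_table(config.path(config.inputs["cotx_panel"]))
        pair_set = sorted(
            {
                pair
                for s in networks
                for pair in cotx_mod.extract_pp_pairs(networks[s])
            }
        )
        if len(pair_set) >= 2:
            correlations, frac = cotx_mod.pair_pearson(pair_set, panel, r_min=p["r_min"])
            frame = pd.DataFrame(
                [(c.gene_a, c.gene_b, c.r, c.n_samples) for c in correlations],
                columns=["gene_a", "gene_b", "r", "n_samples"],
            )
            n = _write_tsv(frame, out / "pair_correlations.tsv")
            null = cotx_mod.rewired_null(
                pair_set, panel, n_perm=int(p["n_perm"]), seed=config.seed
            )
            report.outputs["cotx"] = {
                "n_pairs": len(pair_set),
                "fraction_r_above": frac,
                "observed_mean_r": null["observed_mean_r"],
                "empirical_p": null["empirical_p"],
            }
            report.add("cotx", n, ["pair_correlations.tsv"])
        else:
            report.skip("cotx", "fewer than 2 P-P pairs")
    else:
        report.skip("cotx", "no cotx panel or networks")

    # --- differential CTCF binding -------------------------------------------------
    diff_sites = []
    if "CTCF" in peaks["A"] and "CTCF" in peaks["B"]:
        diff_sites = me.differential_binding(
            peaks["A"]["CTCF"], peaks["B"]["CTCF"], genes,
            flank=p["flank"], m_min=p["m_min"], eps=p["eps"],
        )
        frame = pd.DataFrame(
            [
                (d.site.chrom, d.site.start, d.site.end, d.intensity_a,
                 d.intensity_b, d.M, d.A, d.call, d.nearest_gene)
                for d in diff_sites
            ],
            columns=["chrom", "start", "end", "intensity_a", "intensity_b",
                     "M", "A", "call", "nearest_gene"],
        )
        n = _write_tsv(frame, out / "ctcf_differential.tsv")
        report.add("ctcf_diff", n, ["ctcf_differential.tsv"])

        anchor_rows = []
        for s in states:
            if "CTCF" in loops[s]:
                counts = tp.genes_with_anchor_at_tss(
                    loops[s]["CTCF"], genes, flank=p["flank"]
                )
                for gid, cnt in sorted(counts.items()):
                    anchor_rows.append((s, gid, cnt))
        _write_tsv(
            pd.DataFrame(anchor_rows, columns=["state", "gene_id", "n_anchors"]),
            out / "ctcf_anchor_genes.tsv",
        )
    else:
        report.skip("ctcf_diff", "missing CTCF peaks")

    # --- CTCF binding breadth --------------------------------------------------------
    if diff_sites and "ctcf_panel_dir" in config.inputs:
        panel_dir = config.path(config.inputs["ctcf_panel_dir"])
        cells = {
            f.stem: io.read_bed(f, "CTCF", strict=strict)
            for f in sorted(panel_dir.glob("*.bed"))
        }
        if len(cells) >= 2:
            specific_sites = [d.site for d in diff_sites if d.call != "common"]
            common_sites = [d.site for d in diff_sites if d.call == "common"]
            b_spec = me.binding_breadth(specific_sites, cells)
            b_comm = me.binding_breadth(common_sites, cells)
            if b_spec and b_comm:
                ks_d, ks_p = me.breadth_ks(b_spec, b_comm)
                report.outputs["ctcf_breadth"] = {
                    "mean_breadth_specific": float(np.mean(b_spec)),
                    "mean_breadth_common": float(np.mean(b_comm)),
                    "ks_d": ks_d,
                    "ks_p": ks_p,
                }
            frame = pd.DataFrame(
                [(s.chrom, s.start, s.end, "specific", b)
                 for s, b in zip(specific_sites, b_spec)]
                + [(s.chrom, s.start, s.end, "common", b)
                   for s, b in zip(common_sites, b_comm)],
                columns=["chrom", "start", "end", "group", "breadth"],
            )
            n = _write_tsv(frame, out / "ctcf_breadth.tsv")
            report.add("ctcf_breadth", n, ["ctcf_breadth.tsv"])
    else:
        report.skip("ctcf_breadth", "no differential sites or panel")

    # --- methylation at CTCF sites / motifs -------------------------------------------
    if meth and diff_sites:
        motif_w = int(p["motif_width"])
        rows = []
        summary = {}
        for group, sites in (
            ("up_a", [d.site for d in diff_sites if d.call == "up_a"]),
            ("up_b", [d.site for d in diff_sites if d.call == "up_b"]),
        ):
            if not sites:
                continue
            motifs = [
                GenomicInterval(s.chrom, max(0, s.midpoint - motif_w // 2),
                                max(0, s.midpoint - motif_w // 2) + motif_w)
                for s in sites
            ]
            for s_state in states:
                if s_state not in meth:
                    continue
                for kind, regions in (("peak_500bp", sites), (f"motif_{motif_w}bp", motifs)):
                    rms = me.methylation_in_regions(
                        meth[s_state], regions, level_kind=kind,
                        min_cov=int(p["min_cov"]), min_cpgs=int(p["min_cpgs"]),
                    )
                    for r in rms:
                        rows.append(
                            (group, s_state, kind, r.region.chrom, r.region.start,
                             r.region.end, r.n_cpgs, r.beta_mean)
                        )
            bound_state = "A" if group == "up_a" else "B"
            unbound_state = "B" if group == "up_a" else "A"
            if bound_state in meth and unbound_state in meth:
                bound = me.methylation_in_regions(
                    meth[bound_state], motifs, min_cov=int(p["min_cov"])
                )
                unbound = me.methylation_in_regions(
                    meth[unbound_state], motifs, min_cov=int(p["min_cov"])
                )
                summary[group] = me.compare_region_methylation(bound, unbound)
        frame = pd.DataFrame(
            rows,
            columns=["site_group", "meth_state", "level", "chrom", "start", "end",
                     "n_cpgs", "beta_mean"],
        )
        n = _write_tsv(frame, out / "region_methylation.tsv")
        report.outputs["methylation_comparison"] = summary
        report.add("methyl", n, ["region_methylation.tsv"])
    else:
        report.skip("methyl", "no methylation input or no differential sites")

    # --- DMC calling ---------------------------------------------------------------------
    if "A" in meth and "B" in meth:
        dmcs = me.call_dmc(
            meth["A"], meth["B"], min_cov=int(p["min_cov"]),
            delta_min=p["dmc_delta_min"], q_max=p["dmc_q_max"],
        )
        frame = pd.DataFrame(
            [(d.chrom, d.pos, d.beta_a, d.beta_b, d.delta, d.p_value, d.q_value)
             for d in dmcs],
            columns=["chrom", "pos", "beta_a", "beta_b", "delta", "p", "q"],
        )
        n = _write_tsv(frame, out / "dmc.tsv")
        report.add("dmc", n, ["dmc.tsv"])
    else:
        report.skip("dmc", "methylation missing for a state")

    # --- compartments --------------------------------------------------------------------
    if "chrom_length" in p and "n_chroms" in p:
        binsize = int(p["binsize"])
        chrom_length = int(p["chrom_length"])
        comp_rows = []
        switch_rows = []
        ba_counts = [0, 0]  # [B->A among A-specific, total A-specific classified]
        for c in range(int(p["n_chroms"])):
            chrom = f"chr{c + 1}"
            chrom_genes = [g for g in genes if g.chrom == chrom]
            per_state_tracks = {}
            for s in states:
                state_loops = [lp for factor in loops[s] for lp in loops[s][factor]]
                m = tp.contact_matrix_from_loops(state_loops, chrom, chrom_length, binsize)
                n_bins = m.shape[0]
                dens = np.zeros(n_bins)
                for g in chrom_genes:
                    if g.tss // binsize < n_bins:
                        dens[g.tss // binsize] += 1
                try:
                    track = tp.call_compartments(m, binsize, dens)
                except ValueError:
                    track = tp.CompartmentTrack(binsize, ["NA"] * n_bins, 0.0)
                per_state_tracks[s] = track
                comp_rows.extend(
                    (s, chrom, i * binsize, min((i + 1) * binsize, chrom_length), lab)
                    for i, lab in enumerate(track.labels)
                )
            # switch orientation: state B (normal-like) -> state A (tumor-like)
            classes, _ = tp.compartment_switch(
                per_state_tracks["B"], per_state_tracks["A"], chrom_genes
            )
            for gid, klass in sorted(classes.items()):
                switch_rows.append((chrom, gid, klass))
                if gid in specific["A"]:
                    ba_counts[1] += 1
                    if klass == "B->A":
                        ba_counts[0] += 1
        _write_tsv(
            pd.DataFrame(comp_rows, columns=["state", "chrom", "start", "end", "label"]),
            out / "compartments.tsv",
        )
        _write_tsv(
            pd.DataFrame(switch_rows, columns=["chrom", "gene_id", "switch"]),
            out / "compartment_switch.tsv",
        )
        if ba_counts[1]:
            report.outputs["compartment_switch"] = {
                "fraction_a_specific_b_to_a": ba_counts[0] / ba_counts[1]
            }
        report.add(
            "compartments", len(comp_rows),
            ["compartments.tsv", "compartment_switch.tsv"],
        )

    report.wall_time_s = time.monotonic() - t0
    (out / "report.json").write_text(report.to_json() + "\n")
    return report
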