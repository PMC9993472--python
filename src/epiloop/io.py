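"""Readers and writers for the tab-separated dialects the pipeline touches.

Dialects (all tab-separated, ``#`` comment lines ignored):

* BED4+score: chrom, start, end, name, score
* BEDPE (7 cols minimum): chromA, startA, endA, chromB, startB, endB,
  pet_count [, factor]
* gene table: BED6 with gene_id in the name column
* bedGraph: chrom, start, end, value
* methylation: chrom, pos, count_meth, count_total
* SNP table: rsid, chrom, pos, trait_class, lead_rsid, r2 ('.' = absent)
* expression: header row of sample labels, rows keyed by gene_id

In strict mode (default) any record violating a type invariant is an error
naming file and line; in lenient mode offending records are skipped and the
skip count is logged.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable, Iterable, Iterator, TypeVar

import pandas as pd

from .intervals import SignalTrack
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

T = TypeVar("T")


class ParseError(ValueError):
    """Malformed or invariant-violating record, with file and line number."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _parse_file(
    path: str | Path,
    parse_row: Callable[[list[str]], T],
    strict: bool,
    min_fields: int,
) -> list[T]:
    records: list[T] = []
    skipped = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < min_fields:
            err = ParseError(
                path, lineno, f"expected >= {min_fields} fields, got {len(fields)}"
            )
            if strict:
                raise err
            skipped += 1
            continue
        try:
            records.append(parse_row(fields))
        except (ValueError, IndexError) as exc:
            if strict:
                raise ParseError(path, lineno, str(exc)) from exc
            skipped += 1
    if skipped:
        log.warning("%s: skipped %d malformed records (lenient mode)", path, skipped)
    return records


# ---------------------------------------------------------------------------
# BED peaks


def read_bed(path: str | Path, factor: str, strict: bool = True) -> list[Peak]:
    def row(f: list[str]) -> Peak:
        region = GenomicInterval(f[0], int(f[1]), int(f[2]))
        name = f[3] if len(f) > 3 else "."
        score = float(f[4]) if len(f) > 4 else 0.0
        return Peak(region=region, factor=factor, intensity=score, name=name)

    return _parse_file(path, row, strict, min_fields=3)


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as out:
        for p in peaks:
            out.write(
                f"{p.region.chrom}\t{p.region.start}\t{p.region.end}"
                f"\t{p.name}\t{p.intensity:g}\n"
            )


def read_regions_bed(path: str | Path, strict: bool = True) -> list[GenomicInterval]:
    def row(f: list[str]) -> GenomicInterval:
        return GenomicInterval(f[0], int(f[1]), int(f[2]))

    return _parse_file(path, row, strict, min_fields=3)


# ---------------------------------------------------------------------------
# BEDPE loops


def read_bedpe(
    path: str | Path, factor: str | None = None, strict: bool = True
) -> list[Loop]:
    def row(f: list[str]) -> Loop:
        fac = f[7] if len(f) > 7 and factor is None else (factor or f[7])
        return Loop.make(
            GenomicInterval(f[0], int(f[1]), int(f[2])),
            GenomicInterval(f[3], int(f[4]), int(f[5])),
            int(f[6]),
            fac,
        )

    return _parse_file(path, row, strict, min_fields=7)


def write_bedpe(loops: Iterable[Loop], path: str | Path) -> None:
    with open(path, "w") as out:
        for lp in loops:
            out.write(
                f"{lp.anchor_a.chrom}\t{lp.anchor_a.start}\t{lp.anchor_a.end}"
                f"\t{lp.anchor_b.chrom}\t{lp.anchor_b.start}\t{lp.anchor_b.end}"
                f"\t{lp.pet_count}\t{lp.factor}\n"
            )


# ---------------------------------------------------------------------------
# Gene table (BED6, gene_id in name)


def read_gene_table(path: str | Path, strict: bool = True) -> list[GeneModel]:
    def row(f: list[str]) -> GeneModel:
        strand = f[5]
        body = GenomicInterval(f[0], int(f[1]), int(f[2]), strand=strand)
        return GeneModel(gene_id=f[3], name=f[3], body=body, strand=strand)

    return _parse_file(path, row, strict, min_fields=6)


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as out:
        for g in genes:
            out.write(
                f"{g.body.chrom}\t{g.body.start}\t{g.body.end}"
                f"\t{g.gene_id}\t0\t{g.strand}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph signal


def read_signal_bedgraph(path: str | Path, strict: bool = True) -> SignalTrack:
    def row(f: list[str]) -> tuple[str, int, int, float]:
        return (f[0], int(f[1]), int(f[2]), float(f[3]))

    return SignalTrack(_parse_file(path, row, strict, min_fields=4))


def write_signal_bedgraph(
    records: Iterable[tuple[str, int, int, float]], path: str | Path
) -> None:
    with open(path, "w") as out:
        for chrom, start, end, value in records:
            out.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Methylation


def read_methylation_table(path: str | Path, strict: bool = True) -> list[CpGRecord]:
    def row(f: list[str]) -> CpGRecord:
        return CpGRecord(f[0], int(f[1]), int(f[2]), int(f[3]))

    return _parse_file(path, row, strict, min_fields=4)


def write_methylation_table(cpgs: Iterable[CpGRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for c in cpgs:
            out.write(f"{c.chrom}\t{c.pos}\t{c.count_meth}\t{c.count_total}\n")


# ---------------------------------------------------------------------------
# SNP table


def read_snp_table(path: str | Path, strict: bool = True) -> list[SNPRecord]:
    def row(f: list[str]) -> SNPRecord:
        lead = f[4] if len(f) > 4 and f[4] not in (".", "") else None
        r2 = float(f[5]) if len(f) > 5 and f[5] not in (".", "") else None
        return SNPRecord(f[0], f[1], int(f[2]), f[3], lead_rsid=lead, r2=r2)

    return _parse_file(path, row, strict, min_fields=4)


def write_snp_table(snps: Iterable[SNPRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for s in snps:
            lead = s.lead_rsid if s.lead_rsid is not None else "."
            r2 = f"{s.r2:g}" if s.r2 is not None else "."
            out.write(
                f"{s.rsid}\t{s.chrom}\t{s.pos}\t{s.trait_class}\t{lead}\t{r2}\n"
            )


# ---------------------------------------------------------------------------
# Expression


def read_expression_table(path: str | Path) -> ExpressionTable:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise ParseError(path, 0, f"unreadable expression table: {exc}") from exc
    try:
        return ExpressionTable(frame)
    except ValueError as exc:
        raise ParseError(path, 0, str(exc)) from exc


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
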