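"""Core domain types shared by every pipeline stage.

All genomic coordinates are 0-based half-open (BED convention).  The TSS of a
'-' strand gene is ``body.end - 1`` so that it always falls inside the body
under half-open semantics.  Inputs using 1-based coordinates are not
auto-detected; the dialect is declared at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HISTONE_FACTORS = frozenset({"H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3"})
ARCH_FACTORS = frozenset({"CTCF", "RNAPII"})
LOOP_FACTORS = ARCH_FACTORS
TRAIT_CLASSES = frozenset({"cancer_related", "normal_function", "other"})


def _check_factor(factor: str) -> str:
    if factor in HISTONE_FACTORS or factor in ARCH_FACTORS:
        return factor
    if factor.startswith("TF:") and len(factor) > 3:
        return factor
    raise ValueError(f"unknown factor {factor!r}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene body; the TSS anchors all promoter logic."""

    gene_id: str
    name: str
    body: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be +/- (got {self.strand!r})")

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1

    @property
    def chrom(self) -> str:
        return self.body.chrom


@dataclass(frozen=True)
class Peak:
    """A factor binding or histone-mark peak with a signal intensity."""

    region: GenomicInterval
    factor: str
    intensity: float = 0.0
    summit: int | None = None
    name: str = "."

    def __post_init__(self) -> None:
        _check_factor(self.factor)
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0 (got {self.intensity})")
        if self.summit is not None and not (
            self.region.start <= self.summit < self.region.end
        ):
            raise ValueError("summit must lie inside the peak region")


@dataclass(frozen=True)
class Loop:
    """An intra-chromosomal paired-anchor chromatin contact.

    Anchors are kept in canonical order (``anchor_a`` starts first); use
    :meth:`make` to construct from unordered anchors.
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    pet_count: int
    factor: str

    def __post_init__(self) -> None:
        if self.factor not in LOOP_FACTORS:
            raise ValueError(f"loop factor must be one of {sorted(LOOP_FACTORS)}")
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValueError("inter-chromosomal loops are not supported")
        if self.pet_count < 1:
            raise ValueError("pet_count must be >= 1")
        if (self.anchor_a.start, self.anchor_a.end) > (
            self.anchor_b.start,
            self.anchor_b.end,
        ):
            raise ValueError("anchors not in canonical order; use Loop.make")

    @classmethod
    def make(
        cls,
        anchor_a: GenomicInterval,
        anchor_b: GenomicInterval,
        pet_count: int,
        factor: str,
    ) -> "Loop":
        if (anchor_a.start, anchor_a.end) > (anchor_b.start, anchor_b.end):
            anchor_a, anchor_b = anchor_b, anchor_a
        return cls(anchor_a, anchor_b, pet_count, factor)

    @property
    def chrom(self) -> str:
        return self.anchor_a.chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(self.anchor_a.start, self.anchor_b.start),
            max(self.anchor_a.end, self.anchor_b.end),
        )


@dataclass(frozen=True)
class CpGRecord:
    """Methylated / total read counts at a single cytosine."""

    chrom: str
    pos: int
    count_meth: int
    count_total: int

    def __post_init__(self) -> None:
        if self.count_total < 1:
            raise ValueError("count_total must be >= 1")
        if not (0 <= self.count_meth <= self.count_total):
            raise ValueError("need 0 <= count_meth <= count_total")

    @property
    def beta(self) -> float:
        return self.count_meth / self.count_total


@dataclass(frozen=True)
class SNPRecord:
    rsid: str
    chrom: str
    pos: int
    trait_class: str
    lead_rsid: str | None = None
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.trait_class not in TRAIT_CLASSES:
            raise ValueError(f"unknown trait_class {self.trait_class!r}")
        if (self.lead_rsid is None) != (self.r2 is None):
            raise ValueError("r2 must be present iff lead_rsid is present")
        if self.r2 is not None and not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 must be in [0,1]")


class ExpressionTable:
    """A genes x samples abundance matrix (TPM/RPKM), non-negative."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression table")
        arr = values.to_numpy(dtype=float)
        if np.any(arr < 0):
            raise ValueError("expression values must be non-negative")
        if np.any(~np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        self.frame = values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns)

    def subset(self, samples: list[str]) -> "ExpressionTable":
        missing = [s for s in samples if s not in self.frame.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return ExpressionTable(self.frame[samples])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionTable({len(self.frame)} genes x "
            f"{self.frame.shape[1]} samples)"
        )
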