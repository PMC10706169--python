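"""Core domain containers: panel geometry, coverage matrix, run configuration.

The panel is an ordered list of target regions (amplicons or capture
intervals) restricted to BRCA1 and BRCA2.  Every downstream matrix is
indexed by this fixed panel order, so the containers here are deliberately
thin wrappers around a numpy array plus bookkeeping.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

GENES = ("BRCA1", "BRCA2")

DELETION = "deletion"
AMPLIFICATION = "amplification"
KINDS = (DELETION, AMPLIFICATION)


class PanelError(ValueError):
    """Malformed or inconsistent panel geometry."""


@dataclass
class TargetRegion:
    """One amplified/captured interval of the panel.

    ``exons`` is the ordered tuple of exon labels this region overlaps;
    labels are opaque strings whose ordering follows the panel file, not a
    transcript database.  ``is_sole_cover`` maps each of those labels to
    True when no other region of the panel covers that exon; it is filled
    in by :class:`Panel` because it is a property of the panel, not of the
    region in isolation.
    """

    chrom: str
    start: int
    end: int
    gene: str
    exons: tuple[str, ...]
    pool_id: str | None = None
    name: str | None = None
    is_sole_cover: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelError(
                f"region {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.gene not in GENES:
            raise PanelError(f"unknown gene {self.gene!r}; expected one of {GENES}")
        if not self.exons:
            raise PanelError(f"region {self.chrom}:{self.start}-{self.end} lists no exons")
        if self.name is None:
            pool = f"|{self.pool_id}" if self.pool_id else ""
            self.name = f"{self.gene}|{'-'.join(self.exons)}{pool}"


class Panel:
    """Ordered target regions with exon/pool bookkeeping.

    Regions are sorted into panel order by (gene, chrom, start, end) at
    construction; all matrices downstream use this order.
    """

    def __init__(self, regions: Iterable[TargetRegion]):
        regs = sorted(regions, key=lambda r: (r.gene, r.chrom, r.start, r.end))
        if not regs:
            raise PanelError("empty panel")
        names = [r.name for r in regs]
        if len(set(names)) != len(names):
            raise PanelError("duplicate region names in panel")
        self.regions: list[TargetRegion] = regs
        # exon -> covering region indices, keyed by (gene, exon label)
        self.exon_regions: dict[tuple[str, str], list[int]] = {}
        for i, r in enumerate(regs):
            for ex in r.exons:
                self.exon_regions.setdefault((r.gene, ex), []).append(i)
        for r in regs:
            r.is_sole_cover = {
                ex: len(self.exon_regions[(r.gene, ex)]) == 1 for ex in r.exons
            }
        self.gene_slices: dict[str, slice] = {}
        for gene in GENES:
            idx = [i for i, r in enumerate(regs) if r.gene == gene]
            if idx:
                self.gene_slices[gene] = slice(idx[0], idx[-1] + 1)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def region_exons(self, index: int) -> tuple[str, ...]:
        return self.regions[index].exons

    def pool_ids(self) -> list[str | None]:
        return [r.pool_id for r in self.regions]

    @property
    def has_pools(self) -> bool:
        return any(r.pool_id for r in self.regions)


@dataclass
class CoverageTable:
    """Raw per-region coverage depth, one column per sample.

    The per-region depth summary (mean/median/min/max over bases) is
    metadata only; it must simply be uniform across samples.
    """

    panel: Panel
    samples: list[str]
    depth: np.ndarray  # shape (n_regions, n_samples)
    cluster_of: dict[str, str] | None = None
    cov_summary: str = "median"

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.panel), len(self.samples)):
            raise ValueError(
                f"depth matrix shape {self.depth.shape} != "
                f"({len(self.panel)} regions, {len(self.samples)} samples)"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        if not np.all(np.isfinite(self.depth)):
            raise ValueError("coverage table contains missing or non-finite cells")
        if np.any(self.depth < 0):
            raise ValueError("coverage table contains negative depth values")


@dataclass(frozen=True)
class Thresholds:
    """Copy-number-scale cutoffs for run qualification.

    ``del1``/``dupl1`` are the inner thresholds (at least one value must be
    beyond them); ``del2``/``dupl2`` are the outer ones (at most one value
    may violate them).  ``del1`` also serves as the base of the
    score-penalty power function.
    """

    del1: float = 1.3
    del2: float = 1.7
    dupl1: float = 2.7
    dupl2: float = 2.4

    def __post_init__(self) -> None:
        if not (1.0 < self.del1 < self.del2 < 2.0 < self.dupl2 < self.dupl1):
            raise ValueError(
                "thresholds must satisfy 1.0 < del1 < del2 < 2.0 < dupl2 < dupl1; "
                f"got {self}"
            )


@dataclass
class RunConfig:
    """All tunable parameters of a calling run."""

    del1: float = 1.3
    del2: float = 1.7
    dupl1: float = 2.7
    dupl2: float = 2.4
    min_median_cov: float = 100.0
    score_step1: float = 9.9
    score_step2: float = 2.0
    pval_step1: float = 0.01
    pval_step2: float = 0.02
    n_shuffles: int = 1000
    seed: int = 0
    score_form: str = "multiplicative"  # or "literal"
    cov_summary: str = "median"

    def __post_init__(self) -> None:
        self.thresholds  # validates ordering
        if self.n_shuffles < 100:
            raise ValueError("n_shuffles must be >= 100")
        if self.score_step2 > self.score_step1:
            raise ValueError("score_step2 must be <= score_step1")
        if self.score_form not in ("multiplicative", "literal"):
            raise ValueError(f"unknown score_form {self.score_form!r}")
        for name in ("pval_step1", "pval_step2"):
            p = getattr(self, name)
            if not (0 < p <= 1):
                raise ValueError(f"{name} must be in (0, 1]")

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(self.del1, self.del2, self.dupl1, self.dupl2)
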