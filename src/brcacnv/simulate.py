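"""Synthetic amplicon-panel cohorts with known copy-number truth.

The generator emulates the dominant structure of real targeted-panel
coverage: a multiplicative per-sample library-depth factor, a
multiplicative per-region (amplicon-efficiency) factor, a pool x sample
interaction (multiplex-PCR drift), heterozygous events that scale depth
by 0.5 (single-copy deletion) or 1.5 (single-copy duplication), and
overdispersed count noise.  A per-region noise multiplier makes a
minority of amplicons "flaky" — dispersed across all samples at the same
region — which is precisely the variation the row-stage shuffle null is
designed to absorb.  What it does not emulate: GC/length-driven
systematic waves, partial-exon breakpoints, tumor purity, or FFPE
degradation.

The default event catalog is weighted toward a BRCA1 ex19-ex23 deletion
hotspot, mirroring the real BRCA1/2 LR spectrum; the overlap is what
makes median normalization break down when CNV carriers approach half
the cohort.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .io import read_regions
from .model import AMPLIFICATION, DELETION, CoverageTable, Panel

__all__ = [
    "CNVEvent", "CohortSpec", "TruthEvent", "TruthSet",
    "toy_panel", "generate_cohort", "gene_exons",
]


def toy_panel() -> Panel:
    """The packaged BRCA1/BRCA2-like toy panel (90 regions, 2 pools)."""
    ref = resources.files("brcacnv").joinpath("data/toy_panel.bed")
    with resources.as_file(ref) as path:
        return read_regions(path)


def gene_exons(panel: Panel, gene: str) -> list[str]:
    """Ordered unique exon labels of one gene in panel order."""
    out: list[str] = []
    for r in panel.regions:
        if r.gene != gene:
            continue
        for ex in r.exons:
            if ex not in out:
                out.append(ex)
    return out


@dataclass(frozen=True)
class CNVEvent:
    """A catalog entry: an implantable exon-range event."""

    gene: str
    first_exon: str
    last_exon: str
    kind: str  # DELETION or AMPLIFICATION
    weight: float = 1.0

    @property
    def copy_multiplier(self) -> float:
        return 0.5 if self.kind == DELETION else 1.5


#: Heterozygous events echoing the classic BRCA1/2 LR spectrum, with the
#: deletion hotspot around BRCA1 ex19-ex23 carrying most of the weight.
DEFAULT_CATALOG: tuple[CNVEvent, ...] = (
    CNVEvent("BRCA1", "ex20", "ex23", DELETION, 4.0),
    CNVEvent("BRCA1", "ex19", "ex23", DELETION, 3.0),
    CNVEvent("BRCA1", "ex20", "ex21", DELETION, 2.0),
    CNVEvent("BRCA1", "ex2", "ex2", DELETION, 2.0),
    CNVEvent("BRCA1", "ex10", "ex11", DELETION, 1.0),
    CNVEvent("BRCA2", "ex21", "ex24", DELETION, 1.0),
    CNVEvent("BRCA1", "ex4", "ex6", AMPLIFICATION, 1.0),
    CNVEvent("BRCA1", "ex13", "ex17", AMPLIFICATION, 1.0),
)


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults describe a typical germline amplicon run: ~1000x mean depth,
    samples varying ~3x in library yield (log-sd 0.4), amplicon
    efficiencies spanning an order of magnitude (log-sd 0.7), mild pool
    drift (log-sd 0.25), 15% baseline count overdispersion with a
    heavy-ish tail of flaky amplicons (multiplier log-sd 0.35, so ~5% of
    regions exceed 30% CV), and a 10% CNV-positive fraction.
    """

    panel: Panel = field(default_factory=toy_panel)
    n_samples: int = 50
    positive_fraction: float = 0.1
    cnv_catalog: tuple[CNVEvent, ...] = DEFAULT_CATALOG
    depth_mean: float = 1000.0
    sample_depth_sd: float = 0.4
    region_effect_sd: float = 0.7
    pool_effect_sd: float = 0.25
    noise: float = 0.15
    region_noise_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive_fraction must be in [0, 1]")
        if self.positive_fraction > 0 and not self.cnv_catalog:
            raise ValueError("positive_fraction > 0 requires a non-empty cnv_catalog")


@dataclass(frozen=True)
class TruthEvent:
    gene: str
    first_exon: str
    last_exon: str
    kind: str


@dataclass
class TruthSet:
    """Implanted events per sample; consistent with the emitted table."""

    events: dict[str, list[TruthEvent]]

    @property
    def positive_samples(self) -> list[str]:
        return sorted(s for s, ev in self.events.items() if ev)

    def has_event(self, sample: str, gene: str, kind: str) -> bool:
        return any(
            e.gene == gene and e.kind == kind for e in self.events.get(sample, [])
        )


def _event_regions(panel: Panel, event: CNVEvent | TruthEvent) -> list[int]:
    exons = gene_exons(panel, event.gene)
    try:
        lo, hi = exons.index(event.first_exon), exons.index(event.last_exon)
    except ValueError as exc:
        raise ValueError(f"event {event} references exons absent from panel") from exc
    span = set(exons[lo : hi + 1])
    return [
        i for i, r in enumerate(panel.regions)
        if r.gene == event.gene and any(ex in span for ex in r.exons)
    ]


def generate_cohort(spec: CohortSpec) -> tuple[CoverageTable, TruthSet]:
    """Draw one cohort; deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    panel = spec.panel
    n_reg, n_smp = len(panel), spec.n_samples
    samples = [f"S{j + 1:03d}" for j in range(n_smp)]

    sample_f = rng.lognormal(0.0, spec.sample_depth_sd, size=n_smp)
    region_f = rng.lognormal(0.0, spec.region_effect_sd, size=n_reg)
    pools = sorted({r.pool_id for r in panel.regions if r.pool_id})
    pool_mat = np.ones((n_reg, n_smp))
    for pool in pools:
        factors = rng.lognormal(0.0, spec.pool_effect_sd, size=n_smp)
        rows = [i for i, r in enumerate(panel.regions) if r.pool_id == pool]
        pool_mat[rows, :] = factors[None, :]
    noise_mult = (
        rng.lognormal(0.0, spec.region_noise_sd, size=n_reg)
        if spec.region_noise_sd > 0
        else np.ones(n_reg)
    )

    truth: dict[str, list[TruthEvent]] = {s: [] for s in samples}
    copy_mult = np.ones((n_reg, n_smp))
    n_pos = math.ceil(spec.positive_fraction * n_smp) if spec.positive_fraction else 0
    if n_pos:
        pos_idx = np.sort(rng.choice(n_smp, size=n_pos, replace=False))
        weights = np.array([e.weight for e in spec.cnv_catalog], float)
        weights /= weights.sum()
        for j in pos_idx:
            event = spec.cnv_catalog[int(rng.choice(len(spec.cnv_catalog), p=weights))]
            rows = _event_regions(panel, event)
            copy_mult[rows, j] *= event.copy_multiplier
            truth[samples[j]].append(
                TruthEvent(event.gene, event.first_exon, event.last_exon, event.kind)
            )

    mu = spec.depth_mean * region_f[:, None] * sample_f[None, :] * pool_mat * copy_mult
    if spec.noise > 0:
        cv = spec.noise * noise_mult  # per-region overdispersion CV
        shape = 1.0 / cv**2
        lam = rng.gamma(shape[:, None], mu / shape[:, None])
        depth = rng.poisson(lam).astype(float)
    else:
        depth = mu
    table = CoverageTable(panel=panel, samples=samples, depth=depth)
    return table, TruthSet(events=truth)
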