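"""Candidate enumeration and the rule-based filters.

A candidate large rearrangement (LR) is a contiguous interval of panel
regions in one sample whose normalized copy numbers all sit below 2.0
(deletion) or above 2.0 (amplification).  Maximal runs are found per
gene, bridged across coverage-excluded regions, expanded into every
contiguous sub-interval, and then pruned by rules 3-9:

3. at least one affected exon must lie completely inside the interval
   (nearly all BRCA1/2 LRs are Alu-mediated whole-exon events);
4. deletions need >=1 value below ``del1``;
5. deletions allow at most one value above ``del2``;
6. deletions need values <= ``del2`` at >= half the interval length;
7-9. the mirror rules for amplifications against ``dupl1``/``dupl2``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AMPLIFICATION, DELETION, GENES, Panel, Thresholds
from .normalize import CopyNumberMatrix

# Sub-run enumeration is quadratic in run length; beyond this bound only
# extremum-anchored endpoints are considered.  Panels here have <100
# regions, so the bound is effectively never hit.
MAX_FULL_ENUMERATION = 60


@dataclass
class CandidateLR:
    """A contiguous candidate interval within one gene of one sample.

    ``region_span`` is the inclusive (start, end) pair of global panel
    indices; ``region_indices`` lists the observed (non-excluded) indices
    inside it, and ``values`` their normalized copy numbers.  Bridged
    excluded regions inside the span carry no values and no exons.
    """

    sample: str
    kind: str
    gene: str
    region_span: tuple[int, int]
    region_indices: tuple[int, ...]
    values: np.ndarray
    exon_span: tuple[str, ...]
    full_exons: tuple[str, ...]

    @property
    def L(self) -> int:
        return len(self.values)

    @property
    def first_exon(self) -> str:
        return self.exon_span[0]

    @property
    def last_exon(self) -> str:
        return self.exon_span[-1]


def _annotate(
    panel: Panel,
    sample: str,
    kind: str,
    gene: str,
    indices: list[int],
    column: np.ndarray,
) -> CandidateLR:
    """Build a CandidateLR from the observed indices of a span."""
    start, end = indices[0], indices[-1]
    exons: list[str] = []
    for i in indices:
        for ex in panel.regions[i].exons:
            if ex not in exons:
                exons.append(ex)
    full = []
    for ex in exons:
        covering = panel.exon_regions[(gene, ex)]
        if all(start <= i <= end for i in covering):
            full.append(ex)
    return CandidateLR(
        sample=sample,
        kind=kind,
        gene=gene,
        region_span=(start, end),
        region_indices=tuple(indices),
        values=column[indices].copy(),
        exon_span=tuple(exons),
        full_exons=tuple(full),
    )


def find_runs(
    column: np.ndarray, panel: Panel, sample: str, kind: str
) -> list[CandidateLR]:
    """Maximal same-direction runs per gene (excluded regions break runs).

    ``column`` is one sample's normalized values in panel order with NaN
    at excluded positions.  Runs never cross the BRCA1/BRCA2 boundary.
    """
    runs: list[CandidateLR] = []
    for gene in GENES:
        sl = panel.gene_slices.get(gene)
        if sl is None:
            continue
        current: list[int] = []
        for i in range(sl.start, sl.stop):
            v = column[i]
            inside = np.isfinite(v) and (
                v < 2.0 if kind == DELETION else v > 2.0
            )
            if inside:
                current.append(i)
            elif current:
                runs.append(_annotate(panel, sample, kind, gene, current, column))
                current = []
        if current:
            runs.append(_annotate(panel, sample, kind, gene, current, column))
    return runs


def join_runs(
    runs: list[CandidateLR], column: np.ndarray, panel: Panel
) -> list[CandidateLR]:
    """Merge same-kind runs separated only by coverage-excluded regions.

    The merge is transitive: chains across several excluded gaps collapse
    into one span.  Excluded positions contribute no values.
    """
    merged: list[CandidateLR] = []
    for run in sorted(runs, key=lambda r: r.region_span):
        if merged:
            prev = merged[-1]
            gap = range(prev.region_span[1] + 1, run.region_span[0])
            if (
                prev.gene == run.gene
                and prev.kind == run.kind
                and len(gap) > 0
                and all(not np.isfinite(column[g]) for g in gap)
            ):
                indices = list(prev.region_indices) + list(run.region_indices)
                merged[-1] = _annotate(
                    panel, run.sample, run.kind, run.gene, indices, column
                )
                continue
        merged.append(run)
    return merged


def enumerate_subruns(
    run: CandidateLR, column: np.ndarray, panel: Panel
) -> list[CandidateLR]:
    """All contiguous sub-intervals of a maximal run, anchored at observed
    positions.

    For pathologically long runs only endpoints at local extrema (minima
    for deletions, maxima for amplifications) and the run ends are used.
    """
    obs = list(run.region_indices)
    n = len(obs)
    if n > MAX_FULL_ENUMERATION:
        v = run.values
        sign = 1.0 if run.kind == DELETION else -1.0
        anchors = {0, n - 1}
        for k in range(1, n - 1):
            if sign * v[k] <= sign * v[k - 1] and sign * v[k] <= sign * v[k + 1]:
                anchors.add(k)
        positions = sorted(anchors)
    else:
        positions = list(range(n))
    out = []
    for ai, a in enumerate(positions):
        for b in positions[ai:]:
            out.append(
                _annotate(
                    panel, run.sample, run.kind, run.gene, obs[a : b + 1], column
                )
            )
    return out


@dataclass
class FilterOutcome:
    candidate: CandidateLR
    failed_rules: tuple[int, ...]

    @property
    def passed(self) -> bool:
        return not self.failed_rules


def apply_filters(candidate: CandidateLR, th: Thresholds) -> FilterOutcome:
    """Evaluate rules 3-9 on one candidate."""
    v = candidate.values
    L = candidate.L
    failed: list[int] = []
    if not candidate.full_exons:
        failed.append(3)
    half = (L + 1) // 2  # "half of the length", rounded up
    if candidate.kind == DELETION:
        if int(np.sum(v < th.del1)) < 1:
            failed.append(4)
        if int(np.sum(v > th.del2)) > 1:
            failed.append(5)
        if int(np.sum(v <= th.del2)) < half:
            failed.append(6)
    else:
        if int(np.sum(v > th.dupl1)) < 1:
            failed.append(7)
        if int(np.sum(v < th.dupl2)) > 1:
            failed.append(8)
        if int(np.sum(v >= th.dupl2)) < half:
            failed.append(9)
    return FilterOutcome(candidate=candidate, failed_rules=tuple(failed))


def candidate_lrs(
    matrix: CopyNumberMatrix, sample: str, kind: str
) -> list[CandidateLR]:
    """find -> join -> enumerate for one sample and direction."""
    column = matrix.column(sample)
    runs = join_runs(
        find_runs(column, matrix.panel, sample, kind), column, matrix.panel
    )
    out: list[CandidateLR] = []
    for run in runs:
        out.extend(enumerate_subruns(run, column, matrix.panel))
    return out
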