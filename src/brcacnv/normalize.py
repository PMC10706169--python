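"""Coverage QC and the four-step median-normalization cascade.

The cascade removes, in order: (1) between-sample depth differences
(each sample column divided by its own median), (2) between-region
efficiency differences (each region row divided by its median across
samples), (3) primer-pool efficiency drift within a sample (optional),
and (4) batch effects between sample clusters (optional).  The result is
finally multiplied by 2 so that a copy-neutral diploid target sits at
2.0, a heterozygous deletion near 1.0 and a single-copy duplication near
3.0.  Median normalization is only meaningful while the majority of
samples at any given region are copy-neutral; that assumption is the
root of the tool's cohort-composition limits.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import CoverageTable, Panel

log = logging.getLogger(__name__)

REASON_LOW_COV = "low coverage"
REASON_DEGENERATE = "degenerate median"


class InsufficientCoverageError(RuntimeError):
    """Raised when QC leaves no usable sample."""


@dataclass
class QCReport:
    """Per-sample/per-region median depths and the exclusions they justify."""

    min_median_cov: float
    sample_medians: dict[str, float]
    region_medians: dict[str, float]  # over retained samples
    excluded_samples: dict[str, str] = field(default_factory=dict)
    excluded_regions: dict[int, str] = field(default_factory=dict)


def exclude_low_coverage(table: CoverageTable, min_median_cov: float) -> QCReport:
    """Flag samples, then regions, whose median raw depth is below threshold.

    Sample exclusion is applied first; region medians are then computed
    over the remaining samples only.  The coverage matrix itself is not
    modified.
    """
    depth = table.depth
    sample_med = {
        s: float(np.median(depth[:, j])) for j, s in enumerate(table.samples)
    }
    excluded_samples = {
        s: REASON_LOW_COV for s, m in sample_med.items() if m < min_median_cov
    }
    keep = [j for j, s in enumerate(table.samples) if s not in excluded_samples]
    if not keep:
        raise InsufficientCoverageError(
            f"all {len(table.samples)} samples have median coverage below "
            f"{min_median_cov}"
        )
    region_med = {
        name: float(np.median(depth[i, keep]))
        for i, name in enumerate(table.panel.names)
    }
    excluded_regions = {
        i: REASON_LOW_COV
        for i, name in enumerate(table.panel.names)
        if region_med[name] < min_median_cov
    }
    return QCReport(
        min_median_cov=min_median_cov,
        sample_medians=sample_med,
        region_medians=region_med,
        excluded_samples=excluded_samples,
        excluded_regions=excluded_regions,
    )


@dataclass
class CopyNumberMatrix:
    """Fully normalized matrix on the copies-per-diploid-genome scale.

    Excluded rows/columns hold NaN and are skipped downstream.
    ``region_iqr`` carries the per-region (Q1, Q3) across samples on the
    x2 scale, used for the grey diagnostic band in the ratio plots.
    """

    panel: Panel
    samples: list[str]
    values: np.ndarray  # (n_regions, n_samples), NaN where excluded
    excluded_samples: dict[str, str]
    excluded_regions: dict[int, str]
    region_iqr: np.ndarray  # (n_regions, 2)

    @property
    def active_samples(self) -> list[str]:
        return [s for s in self.samples if s not in self.excluded_samples]

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def column(self, sample: str) -> np.ndarray:
        return self.values[:, self.sample_index(sample)]


MIN_CLUSTER_SIZE = 3


def _merge_small_clusters(clusters: dict[str, str]) -> dict[str, str]:
    """Clusters below MIN_CLUSTER_SIZE are folded into the largest cluster."""
    sizes: dict[str, int] = {}
    for c in clusters.values():
        sizes[c] = sizes.get(c, 0) + 1
    if len(sizes) < 2:
        return clusters
    largest = max(sizes, key=lambda c: (sizes[c], c))
    small = {c for c, n in sizes.items() if n < MIN_CLUSTER_SIZE and c != largest}
    if small:
        log.warning(
            "merging %d undersized sample cluster(s) %s into %r",
            len(small), sorted(small), largest,
        )
        clusters = {
            s: (largest if c in small else c) for s, c in clusters.items()
        }
    return clusters


def normalize_matrix(
    table: CoverageTable,
    qc: QCReport | None = None,
    clusters: dict[str, str] | None = None,
    use_pools: bool = True,
) -> CopyNumberMatrix:
    """Run the median cascade and scale to copy-number units.

    ``qc`` carries the prior low-coverage exclusions (pass None to skip
    QC entirely, e.g. for idealized matrices).  Pool normalization runs
    only when the panel carries pool IDs; cluster normalization only when
    at least two (sufficiently large) clusters are provided.  A zero
    median encountered at any step excludes the affected sample or region
    rather than dividing by it.
    """
    panel = table.panel
    excluded_samples = dict(qc.excluded_samples) if qc else {}
    excluded_regions = dict(qc.excluded_regions) if qc else {}

    x = table.depth.astype(float).copy()
    for j, s in enumerate(table.samples):
        if s in excluded_samples:
            x[:, j] = np.nan
    for i in excluded_regions:
        x[i, :] = np.nan

    def _sample_cols():
        return [
            (j, s) for j, s in enumerate(table.samples) if s not in excluded_samples
        ]

    # step 1: per-sample median over target regions
    for j, s in _sample_cols():
        med = np.nanmedian(x[:, j])
        if not np.isfinite(med) or med <= 0:
            excluded_samples[s] = REASON_DEGENERATE
            x[:, j] = np.nan
            continue
        x[:, j] /= med
    if not _sample_cols():
        raise InsufficientCoverageError("no sample survived normalization")

    # step 2: per-region median across samples
    for i in range(len(panel)):
        if i in excluded_regions:
            continue
        med = np.nanmedian(x[i, :])
        if not np.isfinite(med) or med <= 0:
            excluded_regions[i] = REASON_DEGENERATE
            x[i, :] = np.nan
            continue
        x[i, :] /= med

    # step 3: per-pool median within each sample
    if use_pools and panel.has_pools:
        pools: dict[str, list[int]] = {}
        for i, r in enumerate(panel.regions):
            if r.pool_id is not None and i not in excluded_regions:
                pools.setdefault(r.pool_id, []).append(i)
        for j, s in _sample_cols():
            for pool, idx in pools.items():
                med = np.nanmedian(x[idx, j])
                if not np.isfinite(med) or med <= 0:
                    excluded_samples[s] = f"{REASON_DEGENERATE} (pool {pool})"
                    x[:, j] = np.nan
                    break
                x[idx, j] /= med

    # step 4: per-cluster median within each region row
    if clusters:
        active = {s for _, s in _sample_cols()}
        clusters = _merge_small_clusters(
            {s: c for s, c in clusters.items() if s in active}
        )
        labels = set(clusters.values())
        if len(labels) >= 2:
            groups = {
                c: [j for j, s in _sample_cols() if clusters.get(s) == c]
                for c in labels
            }
            for i in range(len(panel)):
                if i in excluded_regions:
                    continue
                for c, cols in groups.items():
                    med = np.nanmedian(x[i, cols])
                    if not np.isfinite(med) or med <= 0:
                        excluded_regions[i] = f"{REASON_DEGENERATE} (cluster {c})"
                        x[i, :] = np.nan
                        break
                    x[i, cols] /= med

    x *= 2.0
    iqr = np.full((len(panel), 2), np.nan)
    for i in range(len(panel)):
        row = x[i, np.isfinite(x[i, :])]
        if row.size:
            iqr[i] = np.percentile(row, [25, 75])
    return CopyNumberMatrix(
        panel=panel,
        samples=list(table.samples),
        values=x,
        excluded_samples=excluded_samples,
        excluded_regions=excluded_regions,
        region_iqr=iqr,
    )
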