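"""Per-sample normalized-ratio plots.

Blue dots: regions not part of any reported call; red: regions inside a
reported call; black at 0: coverage-excluded regions.  The grey band is
the per-region (Q1, Q3) of normalized values across samples, so a clean
sample hugs 2.0 inside the band.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import GENES
from .normalize import CopyNumberMatrix
from .significance import LRCall


def render_sample_plot(
    sample: str,
    matrix: CopyNumberMatrix,
    calls: list[LRCall],
    out_base: str | Path,
    formats: tuple[str, ...] = ("png", "svg"),
) -> list[Path]:
    """Render one sample's ratio plot; returns the files written."""
    if sample in matrix.excluded_samples:
        raise ValueError(f"sample {sample!r} was excluded by QC")
    col = matrix.column(sample)
    n = len(matrix.panel)
    x = np.arange(n)
    sample_calls = [c for c in calls if c.sample == sample]
    in_call = np.zeros(n, bool)
    for c in sample_calls:
        in_call[list(c.candidate.region_indices)] = True
    excluded = ~np.isfinite(col)

    fig, ax = plt.subplots(figsize=(12, 4))
    ax.fill_between(
        x, matrix.region_iqr[:, 0], matrix.region_iqr[:, 1],
        color="0.8", label="cohort Q1-Q3",
    )
    ax.axhline(2.0, color="0.5", lw=0.8)
    ax.plot(x[~in_call & ~excluded], col[~in_call & ~excluded], "o", ms=3, color="tab:blue")
    if in_call.any():
        ax.plot(x[in_call], col[in_call], "o", ms=4, color="tab:red")
    if excluded.any():
        ax.plot(x[excluded], np.zeros(excluded.sum()), "o", ms=3, color="black")
    # exon labels, thinned; gene boundary marked
    ticks, labels = [], []
    last = None
    for i, r in enumerate(matrix.panel.regions):
        lab = f"{r.exons[0]}"
        if lab != last:
            ticks.append(i)
            labels.append(lab)
            last = lab
    ax.set_xticks(ticks[::2])
    ax.set_xticklabels(labels[::2], rotation=90, fontsize=6)
    for gene in GENES[1:]:
        sl = matrix.panel.gene_slices.get(gene)
        if sl:
            ax.axvline(sl.start - 0.5, color="0.3", lw=0.8, ls="--")
    ax.set_ylabel("normalized copy number")
    ax.set_ylim(bottom=-0.2)
    title = sample
    if sample_calls:
        best = max(sample_calls, key=lambda c: c.score)
        title += f"  {best.span_label}  score={best.score:.2f}  p={best.p_value:.4f}"
    ax.set_title(title, fontsize=10)
    fig.tight_layout()
    out_base = Path(out_base)
    written = []
    for fmt in formats:
        path = out_base.with_suffix(f".{fmt}")
        fig.savefig(path)
        written.append(path)
    plt.close(fig)
    return written
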