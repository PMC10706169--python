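"""Tabular outputs: calls TSV, XLSX workbook, normalized-matrix dump."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import DELETION, RunConfig
from .normalize import CopyNumberMatrix, QCReport
from .significance import LRCall

CALL_COLUMNS = [
    "sample", "gene", "kind", "first_exon", "last_exon",
    "score", "p_value", "step", "span",
]


@dataclass
class RunReport:
    calls: list[LRCall]
    qc: QCReport
    config: RunConfig
    matrix: CopyNumberMatrix
    plot_paths: dict[str, str] = field(default_factory=dict)


def calls_frame(calls: list[LRCall]) -> pd.DataFrame:
    rows = [
        {
            "sample": c.sample,
            "gene": c.gene,
            "kind": "del" if c.kind == DELETION else "dupl",
            "first_exon": c.candidate.first_exon,
            "last_exon": c.candidate.last_exon,
            "score": c.score,
            "p_value": c.p_value,
            "step": c.step,
            "span": c.span_label,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def qc_frames(qc: QCReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    samples = pd.DataFrame(
        {
            "sample": list(qc.sample_medians),
            "median_depth": list(qc.sample_medians.values()),
            "excluded_reason": [
                qc.excluded_samples.get(s, "") for s in qc.sample_medians
            ],
        }
    )
    regions = pd.DataFrame(
        {
            "region": list(qc.region_medians),
            "median_depth": list(qc.region_medians.values()),
        }
    )
    return samples, regions


def components_frame(calls: list[LRCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        comp = c.components
        rows.append(
            {
                "sample": c.sample,
                "span": c.span_label,
                "k1": comp.k1, "k2": comp.k2, "k3": comp.k3, "k4": comp.k4,
                "N": comp.N, "D": comp.D, "I": comp.I, "L": comp.L, "E": comp.E,
                "mdist": comp.mdist, "sum_term": comp.sum_term,
                "exponent": comp.exponent, "score": comp.score,
                "form": comp.form, "n_shuffles": c.n_shuffles_used,
            }
        )
    return pd.DataFrame(rows)


def write_tables(report: RunReport, out_dir: str | Path) -> dict[str, Path]:
    """Write calls.tsv and report.xlsx (calls, QC and components sheets).

    The TSV is formatted with fixed precision so identical runs are
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    calls = calls_frame(report.calls)
    tsv_path = out / "calls.tsv"
    with open(tsv_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for r in calls.itertuples(index=False):
            fh.write(
                f"{r.sample}\t{r.gene}\t{r.kind}\t{r.first_exon}\t{r.last_exon}\t"
                f"{r.score:.4f}\t{r.p_value:.6f}\t{r.step}\t{r.span}\n"
            )
    xlsx_path = out / "report.xlsx"
    qc_samples, qc_regions = qc_frames(report.qc)
    with pd.ExcelWriter(xlsx_path, engine="openpyxl") as xw:
        calls.to_excel(xw, sheet_name="calls", index=False)
        qc_samples.to_excel(xw, sheet_name="qc_samples", index=False)
        qc_regions.to_excel(xw, sheet_name="qc_regions", index=False)
        components_frame(report.calls).to_excel(
            xw, sheet_name="components", index=False
        )
    return {"calls": tsv_path, "xlsx": xlsx_path}


def write_normalized(matrix: CopyNumberMatrix, path: str | Path) -> Path:
    """Dump the normalized copy-number matrix (4-decimal fixed point)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("region\t" + "\t".join(matrix.samples) + "\n")
        for i, name in enumerate(matrix.panel.names):
            cells = "\t".join(
                "NA" if not np.isfinite(v) else f"{v:.4f}" for v in matrix.values[i]
            )
            fh.write(f"{name}\t{cells}\n")
    return path
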