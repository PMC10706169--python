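"""ROC evaluation and the cohort-design limitation sweeps.

Each sample contributes one comparison per (gene, kind) — four in total
— labeled positive when the truth set implants an event of that gene and
direction.  Two ranking statistics are available: the best
filter-passing candidate score (``"score"``), and one minus the best
evaluated p-value from the full two-step pipeline (``"pvalue"``).  The
score ranking ignores the cross-sample null entirely, so only the
p-value ranking reflects how calling quality depends on cohort size;
the sweep harness therefore ranks by p-value.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .detect import apply_filters, candidate_lrs
from .model import GENES, KINDS, RunConfig
from .normalize import exclude_low_coverage, normalize_matrix
from .score import score_candidate
from .significance import call_two_step
from .simulate import CohortSpec, TruthSet, generate_cohort


def run_pipeline(table, cfg: RunConfig, clusters=None):
    """QC -> normalize -> two-step calling; returns (matrix, calls, audit)."""
    qc = exclude_low_coverage(table, cfg.min_median_cov)
    matrix = normalize_matrix(table, qc=qc, clusters=clusters)
    calls, audit = call_two_step(matrix, cfg, collect_audit=True)
    return matrix, calls, audit


def comparison_table(
    table, cfg: RunConfig, statistic: str = "score", clusters=None
) -> pd.DataFrame:
    """One row per (sample, gene, kind) with ranking stat, call flag, span."""
    matrix, calls, audit = run_pipeline(table, cfg, clusters=clusters)
    th = cfg.thresholds
    best_score: dict[tuple[str, str, str], float] = {}
    if statistic == "score":
        for sample in matrix.active_samples:
            for kind in KINDS:
                for cand in candidate_lrs(matrix, sample, kind):
                    if not apply_filters(cand, th).passed:
                        continue
                    s = score_candidate(cand, th, matrix.panel, cfg.score_form).score
                    key = (sample, cand.gene, kind)
                    best_score[key] = max(best_score.get(key, 0.0), s)
    best_p: dict[tuple[str, str, str], float] = {}
    for a in audit:
        key = (a.sample, a.gene, a.kind)
        best_p[key] = min(best_p.get(key, 1.0), a.p_value)
    call_by_key = {}
    for c in calls:
        key = (c.sample, c.gene, c.kind)
        if key not in call_by_key or c.score > call_by_key[key].score:
            call_by_key[key] = c
    rows = []
    for sample in matrix.samples:
        if sample in matrix.excluded_samples:
            continue
        for gene in GENES:
            for kind in KINDS:
                key = (sample, gene, kind)
                call = call_by_key.get(key)
                if statistic == "score":
                    stat = best_score.get(key, 0.0)
                elif statistic == "pvalue":
                    stat = 1.0 - best_p.get(key, 1.0)
                else:
                    raise ValueError(f"unknown statistic {statistic!r}")
                rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "kind": kind,
                        "stat": stat,
                        "called": call is not None,
                        "first_exon": call.candidate.first_exon if call else None,
                        "last_exon": call.candidate.last_exon if call else None,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class EvalResult:
    auc: float  # NaN when truth is one-class
    sensitivity: float
    specificity: float
    match_fraction: float
    n_comparisons: int
    n_positive: int


def roc_evaluate(comparisons: pd.DataFrame, truth: TruthSet) -> EvalResult:
    """Score the comparison table against the implanted truth.

    ``match_fraction`` is the share of implanted events whose reported
    span matches the implanted exon span exactly.
    """
    labels = np.array(
        [
            truth.has_event(r.sample, r.gene, r.kind)
            for r in comparisons.itertuples()
        ]
    )
    stats = comparisons["stat"].to_numpy(float)
    called = comparisons["called"].to_numpy(bool)
    auc = (
        float(roc_auc_score(labels, stats))
        if 0 < labels.sum() < labels.size
        else float("nan")
    )
    pos, neg = labels, ~labels
    sensitivity = float(called[pos].mean()) if pos.any() else float("nan")
    specificity = float((~called[neg]).mean()) if neg.any() else float("nan")
    spans = {
        (r.sample, r.gene, r.kind): (r.first_exon, r.last_exon)
        for r in comparisons.itertuples()
        if r.called
    }
    n_events = matches = 0
    for sample, events in truth.events.items():
        for e in events:
            n_events += 1
            if spans.get((sample, e.gene, e.kind)) == (e.first_exon, e.last_exon):
                matches += 1
    return EvalResult(
        auc=auc,
        sensitivity=sensitivity,
        specificity=specificity,
        match_fraction=matches / n_events if n_events else float("nan"),
        n_comparisons=len(comparisons),
        n_positive=int(labels.sum()),
    )


def sweep_experiment(
    base: CohortSpec,
    axis: str,
    grid: list,
    replicates: int,
    cfg: RunConfig | None = None,
    statistic: str = "pvalue",
) -> pd.DataFrame:
    """Replicated cohort sweeps along ``n_samples`` or ``positive_fraction``.

    Per grid point, ``replicates`` independent cohorts are generated,
    called, and summarized as (mean AUC, Q1, Q3).  Replicate seeds derive
    from ``base.seed`` via a SeedSequence spawn, so the whole sweep is
    reproducible.
    """
    if axis not in ("n_samples", "positive_fraction"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    cfg = cfg or RunConfig()
    children = np.random.SeedSequence(base.seed).spawn(len(grid) * replicates)
    rows = []
    k = 0
    for value in grid:
        aucs = []
        for _ in range(replicates):
            seed = int(children[k].generate_state(1)[0] % 2**31)
            k += 1
            spec = replace(base, **{axis: value}, seed=seed)
            run_cfg = replace_cfg_seed(cfg, seed)
            table, truth = generate_cohort(spec)
            comp = comparison_table(table, run_cfg, statistic=statistic)
            aucs.append(roc_evaluate(comp, truth).auc)
        arr = np.array(aucs, float)
        rows.append(
            {
                "value": value,
                "mean_auc": float(np.nanmean(arr)),
                "q1_auc": float(np.nanpercentile(arr, 25)),
                "q3_auc": float(np.nanpercentile(arr, 75)),
                "replicates": replicates,
            }
        )
    return pd.DataFrame(rows)


def replace_cfg_seed(cfg: RunConfig, seed: int) -> RunConfig:
    return replace(cfg, seed=seed)
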