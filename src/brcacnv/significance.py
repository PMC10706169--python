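"""Shuffle-bootstrap significance and the two-step calling orchestration.

The null question for a candidate of length L is: how often does a
random set of L normalized values look as extreme as the observed one?
Extremeness is measured by a stripped-down score that is normalized only
by length (so it is comparable across shuffles):

    score = sum(a_i over qualifying positions) / del1 ** (M / L)

with ``a_i = 4 - value`` for deletions and ``a_i = value`` for
amplifications, qualifying positions those beyond the inner threshold
(``del1``/``dupl1``), M their count, and score 0 when M = 0.

The empirical null pools two stages: (a) the candidate sample's own
column permuted ``n_column_shuffles`` times (within-sample variation)
and (b) the values of the *same* target regions in every other eligible
sample (between-sample, region-level variation).  Calling proceeds in
two steps: obvious events (score >= 9.9, p <= 0.01) are called first and
their samples removed from the row-stage pool, which sharpens the null
for the second, more sensitive pass.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .detect import CandidateLR, apply_filters, candidate_lrs
from .model import DELETION, KINDS, RunConfig, Thresholds
from .normalize import CopyNumberMatrix
from .score import ScoreComponents, score_candidate

log = logging.getLogger(__name__)


def shuffle_score(values: np.ndarray, kind: str, th: Thresholds) -> float:
    """Length-normalized score of one window of values."""
    return float(_shuffle_scores(np.asarray(values, float)[None, :], kind, th)[0])


def _shuffle_scores(windows: np.ndarray, kind: str, th: Thresholds) -> np.ndarray:
    """Vectorized shuffle score over rows of a (k, L) window matrix."""
    L = windows.shape[1]
    if kind == DELETION:
        qual = windows < th.del1
        evidence = 4.0 - windows
    else:
        qual = windows > th.dupl1
        evidence = windows
    m = qual.sum(axis=1)
    total = np.where(qual, evidence, 0.0).sum(axis=1)
    with np.errstate(all="ignore"):
        scores = total / th.del1 ** (m / L)
    scores[m == 0] = 0.0
    return scores


@dataclass
class ShuffleScheme:
    """How the permutation null for one candidate is assembled."""

    n_column_shuffles: int = 1000
    row_shuffle_samples: tuple[str, ...] = ()
    rng: np.random.Generator = field(default_factory=np.random.default_rng)


def empirical_pvalue(
    candidate: CandidateLR,
    matrix: CopyNumberMatrix,
    scheme: ShuffleScheme,
    th: Thresholds,
) -> tuple[float, int]:
    """Pseudocount-corrected empirical p-value for one candidate.

    Returns ``(p, n_null)`` with ``p = (1 + #{null >= observed}) /
    (1 + n_null)``, so p is never 0 and floors at ~1/(n_null+1).
    Column shuffles draw from the candidate sample's QC-passing values
    only; the row stage scores the same window in each eligible other
    sample (the window score is permutation-invariant, so one draw per
    sample is exactly one null value).
    """
    L = candidate.L
    obs = shuffle_score(candidate.values, candidate.kind, th)
    column = matrix.column(candidate.sample)
    pool = column[np.isfinite(column)]
    if pool.size < L:
        raise ValueError("candidate longer than the QC-passing column")
    nulls = []
    if scheme.n_column_shuffles > 0:
        idx = np.tile(np.arange(pool.size), (scheme.n_column_shuffles, 1))
        idx = scheme.rng.permuted(idx, axis=1)[:, :L]
        nulls.append(_shuffle_scores(pool[idx], candidate.kind, th))
    row_windows = []
    win = np.array(candidate.region_indices)
    for s in scheme.row_shuffle_samples:
        if s == candidate.sample:
            continue
        w = matrix.values[win, matrix.sample_index(s)]
        w = w[np.isfinite(w)]
        if w.size == L:
            row_windows.append(w)
    if row_windows:
        nulls.append(_shuffle_scores(np.vstack(row_windows), candidate.kind, th))
    elif scheme.row_shuffle_samples:
        log.warning(
            "no eligible row-shuffle sample for %s %s; p from column shuffles only",
            candidate.sample, candidate.region_span,
        )
    null = np.concatenate(nulls) if nulls else np.empty(0)
    n_null = int(null.size)
    if n_null == 0:
        raise ValueError("empty null distribution (no shuffles requested)")
    p = (1.0 + int(np.sum(null >= obs))) / (1.0 + n_null)
    return p, n_null


@dataclass
class LRCall:
    """A reported CNV/CNA with its provenance."""

    candidate: CandidateLR
    components: ScoreComponents
    p_value: float
    step: int
    n_shuffles_used: int

    @property
    def sample(self) -> str:
        return self.candidate.sample

    @property
    def gene(self) -> str:
        return self.candidate.gene

    @property
    def kind(self) -> str:
        return self.candidate.kind

    @property
    def score(self) -> float:
        return self.components.score

    @property
    def span_label(self) -> str:
        prefix = "del" if self.kind == DELETION else "dupl"
        return (
            f"{prefix}_{self.gene}_"
            f"{self.candidate.first_exon}-{self.candidate.last_exon}"
        )


@dataclass
class CandidateAudit:
    """One evaluated (scored and p-valued) candidate, called or not."""

    sample: str
    gene: str
    kind: str
    span: tuple[int, int]
    score: float
    p_value: float
    step: int
    called: bool


def _best_candidates(
    matrix: CopyNumberMatrix, cfg: RunConfig
) -> dict[tuple[str, str, str], list[tuple[ScoreComponents, CandidateLR]]]:
    """Filter-passing candidates per (sample, gene, kind), best score first."""
    th = cfg.thresholds
    groups: dict[tuple[str, str, str], list[tuple[ScoreComponents, CandidateLR]]] = {}
    for sample in matrix.active_samples:
        for kind in KINDS:
            for cand in candidate_lrs(matrix, sample, kind):
                if not apply_filters(cand, th).passed:
                    continue
                comp = score_candidate(cand, th, matrix.panel, cfg.score_form)
                groups.setdefault((sample, cand.gene, kind), []).append((comp, cand))
    for key in groups:
        groups[key].sort(key=lambda t: (-t[0].score, t[1].region_span))
    return groups


def call_two_step(
    matrix: CopyNumberMatrix,
    cfg: RunConfig,
    collect_audit: bool = False,
) -> list[LRCall] | tuple[list[LRCall], list[CandidateAudit]]:
    """Full two-step calling on a normalized matrix.

    Step 1 evaluates candidates with score >= ``score_step1`` against a
    row pool of all active samples and calls those with
    p <= ``pval_step1``; their samples leave the pool.  Step 2 evaluates
    the remaining groups down to ``score_step2`` against the reduced pool
    and calls at p <= ``pval_step2``.  Per (sample, gene, kind) only the
    best-scoring surviving candidate is reported.  Deterministic for a
    fixed (matrix, cfg.seed, n_shuffles).
    """
    if len(matrix.active_samples) < 2:
        raise RuntimeError(
            "at least 2 QC-passing samples are required for a reference distribution"
        )
    th = cfg.thresholds
    rng = np.random.default_rng(cfg.seed)
    groups = _best_candidates(matrix, cfg)
    order = sorted(
        groups,
        key=lambda k: (matrix.sample_index(k[0]), k[1], k[2]),
    )
    calls: list[LRCall] = []
    audit: list[CandidateAudit] = []
    step1_samples: set[str] = set()
    called_groups: set[tuple[str, str, str]] = set()
    all_active = tuple(matrix.active_samples)

    def _evaluate(key, step, pool, score_min, p_max):
        sample = key[0]
        for comp, cand in groups[key]:
            if comp.score < score_min:
                break  # sorted by score, nothing below qualifies
            scheme = ShuffleScheme(
                n_column_shuffles=cfg.n_shuffles,
                row_shuffle_samples=tuple(s for s in pool if s != sample),
                rng=rng,
            )
            p, n_null = empirical_pvalue(cand, matrix, scheme, th)
            called = p <= p_max
            audit.append(
                CandidateAudit(
                    sample=sample, gene=key[1], kind=key[2],
                    span=cand.region_span, score=comp.score,
                    p_value=p, step=step, called=called,
                )
            )
            if called:
                calls.append(
                    LRCall(
                        candidate=cand, components=comp, p_value=p,
                        step=step, n_shuffles_used=n_null,
                    )
                )
                return True
        return False

    # step 1: obvious events against the full pool
    for key in order:
        if _evaluate(key, 1, all_active, cfg.score_step1, cfg.pval_step1):
            step1_samples.add(key[0])
            called_groups.add(key)
    # step 2: remaining groups against the reduced pool
    pool2 = tuple(s for s in all_active if s not in step1_samples)
    for key in order:
        if key in called_groups:
            continue
        if _evaluate(key, 2, pool2, cfg.score_step2, cfg.pval_step2):
            called_groups.add(key)

    calls.sort(
        key=lambda c: (
            matrix.sample_index(c.sample), c.gene, c.kind,
            c.candidate.region_span,
        )
    )
    if collect_audit:
        return calls, audit
    return calls
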