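"""Deletion and amplification scores.

The score of a candidate interval is the sum of its copy-number evidence
(``4 - a_i`` for deletions, ``a_i`` for amplifications, over the values
that qualify against the outer threshold), damped by a power of ``del1``
whose exponent collects everything that makes the candidate less
believable: the fraction of weak values (D/L or I/L), a sole-coverage
penalty (2*k4), a short-event penalty (1/E) and the local jumpiness of
the profile (Mdist).  Boundary and exon-completeness factors k1-k3 take
the value 0.5 when violated.

Two numerator arrangements are provided.  The default ``multiplicative``
form applies k1*k2*k3 as factors, which keeps scores positive and makes
bad boundaries strictly damp the score.  The ``literal`` form subtracts
``4*k2 + 4*k3`` from the k1-scaled sum instead; it is kept for
auditability but yields negative scores for clean single-region events
and is not used by default.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import CandidateLR
from .model import DELETION, Panel, Thresholds

# Exons exempt from the sole-coverage penalty: the promoter-adjacent
# BRCA1 exon 2 is a frequent real deletion despite single-amplicon
# coverage, so k4 stays 0 there.
K4_EXEMPT: frozenset[tuple[str, str]] = frozenset({("BRCA1", "ex2")})


@dataclass
class ScoreComponents:
    """Every factor entering a candidate's score, for the audit trail."""

    k1: float
    k2: float
    k3: float
    k4: int
    N: int
    D: int
    I: int
    L: int
    E: int
    mdist: float
    sum_term: float
    exponent: float
    score: float
    form: str


def median_neighbor_distance(values: np.ndarray) -> float:
    """Median absolute difference between neighboring values (0 if L < 2)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(v))))


def _k4(candidate: CandidateLR, panel: Panel) -> int:
    """Sole-coverage penalty flag: single-region candidates whose exon is
    covered by that one region only (BRCA1 ex2 exempt)."""
    if candidate.L != 1:
        return 0
    region = panel.regions[candidate.region_indices[0]]
    for ex in candidate.exon_span:
        if (candidate.gene, ex) in K4_EXEMPT:
            continue
        if region.is_sole_cover.get(ex, False):
            return 1
    return 0


def _score(
    candidate: CandidateLR,
    th: Thresholds,
    panel: Panel,
    form: str,
) -> ScoreComponents:
    v = candidate.values
    L = candidate.L
    if candidate.kind == DELETION:
        qualifying = v <= th.del2
        evidence = 4.0 - v
        weak = int(np.sum(v > th.del1))
        first_ok = v[0] <= th.del2
        last_ok = v[-1] <= th.del2
        D, I = weak, 0
    else:
        qualifying = v >= th.dupl2
        evidence = v.astype(float)
        weak = int(np.sum(v < th.dupl1))
        first_ok = v[0] >= th.dupl2
        last_ok = v[-1] >= th.dupl2
        D, I = 0, weak
    k1 = 1.0 if set(candidate.exon_span) == set(candidate.full_exons) else 0.5
    k2 = 1.0 if first_ok else 0.5
    k3 = 1.0 if last_ok else 0.5
    k4 = _k4(candidate, panel)
    E = len(candidate.exon_span)
    mdist = median_neighbor_distance(v)
    sum_term = float(np.sum(evidence[qualifying]))
    exponent = weak / L + 2.0 * k4 + 1.0 / E + mdist
    denom = th.del1 ** exponent
    if form == "multiplicative":
        score = k1 * k2 * k3 * sum_term / denom
    elif form == "literal":
        score = (k1 * sum_term - 4.0 * k2 - 4.0 * k3) / denom
    else:
        raise ValueError(f"unknown score form {form!r}")
    return ScoreComponents(
        k1=k1, k2=k2, k3=k3, k4=k4,
        N=int(np.sum(qualifying)), D=D, I=I, L=L, E=E,
        mdist=mdist, sum_term=sum_term, exponent=exponent,
        score=score, form=form,
    )


def score_deletion(
    candidate: CandidateLR,
    th: Thresholds,
    panel: Panel,
    form: str = "multiplicative",
) -> ScoreComponents:
    if candidate.kind != DELETION:
        raise ValueError("score_deletion requires a deletion candidate")
    return _score(candidate, th, panel, form)


def score_amplification(
    candidate: CandidateLR,
    th: Thresholds,
    panel: Panel,
    form: str = "multiplicative",
) -> ScoreComponents:
    if candidate.kind == DELETION:
        raise ValueError("score_amplification requires an amplification candidate")
    return _score(candidate, th, panel, form)


def score_candidate(
    candidate: CandidateLR,
    th: Thresholds,
    panel: Panel,
    form: str = "multiplicative",
) -> ScoreComponents:
    """Dispatch on candidate kind."""
    return _score(candidate, th, panel, form)
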