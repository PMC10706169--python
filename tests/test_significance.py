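import numpy as np
import pytest

from brcacnv import (
    AMPLIFICATION,
    DELETION,
    CohortSpec,
    CoverageTable,
    RunConfig,
    ShuffleScheme,
    Thresholds,
    call_two_step,
    empirical_pvalue,
    exclude_low_coverage,
    generate_cohort,
    normalize_matrix,
    shuffle_score,
    toy_panel,
)
from brcacnv.detect import CandidateLR, candidate_lrs
from brcacnv.simulate import CNVEvent

from conftest import make_panel, make_table

TH = Thresholds()


class TestShuffleScore:
    @pytest.mark.parametrize(
        "values,kind,expected",
        [
            ([2.0, 2.0], DELETION, 0.0),                  # nothing qualifies
            ([1.0], DELETION, 3.0 / 1.3),
            ([3.0, 3.0], AMPLIFICATION, 6.0 / 1.3),
            ([1.0, 1.6], DELETION, 3.0 / 1.3**0.5),       # only the deep value sums
            ([3.0, 2.5], AMPLIFICATION, 3.0 / 1.3**0.5),
        ],
    )
    def test_examples(self, values, kind, expected):
        assert shuffle_score(np.array(values), kind, TH) == pytest.approx(
            expected, abs=1e-12
        )


def _matrix_from_values(panel, values):
    """Wrap a ready-made normalized matrix (no QC, values already x2)."""
    table = make_table(panel, np.asarray(values) * 100.0)  # depths irrelevant
    m = normalize_matrix(table)
    m.values = np.asarray(values, float)
    return m


def _window_candidate(matrix, sample, indices, kind=DELETION):
    col = matrix.column(sample)
    gene = matrix.panel.regions[indices[0]].gene
    return CandidateLR(
        sample=sample, kind=kind, gene=gene,
        region_span=(indices[0], indices[-1]),
        region_indices=tuple(indices),
        values=col[list(indices)],
        exon_span=("exX",), full_exons=("exX",),
    )


class TestEmpiricalPvalue:
    def test_permutation_invariant_column_gives_p_one(self):
        panel = make_panel([("BRCA1", f"ex{i}", None) for i in range(1, 9)])
        values = np.full((8, 4), 1.5)  # constant everywhere
        m = _matrix_from_values(panel, values)
        cand = _window_candidate(m, "S1", [2, 3])
        scheme = ShuffleScheme(
            n_column_shuffles=200,
            row_shuffle_samples=tuple(m.samples),
            rng=np.random.default_rng(0),
        )
        p, n_null = empirical_pvalue(cand, m, scheme, TH)
        assert p == 1.0
        assert n_null == 203  # 200 column shuffles + 3 other samples

    def test_zero_exceedance_floor(self):
        # a unique 3-deep window in a 90-region column; no null window can
        # assemble all three deep values under this seed
        panel = toy_panel()
        values = np.full((90, 2), 2.0)
        values[10:13, 0] = [1.0, 1.1, 0.9]
        m = _matrix_from_values(panel, values)
        cand = _window_candidate(m, "S1", [10, 11, 12])
        scheme = ShuffleScheme(
            n_column_shuffles=1000, row_shuffle_samples=(), rng=np.random.default_rng(5)
        )
        p, n_null = empirical_pvalue(cand, m, scheme, TH)
        assert n_null == 1000
        assert p == pytest.approx(1.0 / 1001.0, abs=1e-15)

    def test_bit_identical_under_fixed_seed(self):
        spec = CohortSpec(n_samples=20, seed=4)
        table, _ = generate_cohort(spec)
        m = normalize_matrix(table, qc=exclude_low_coverage(table, 100))
        cfg = RunConfig(seed=99, n_shuffles=200)
        calls_a = call_two_step(m, cfg)
        calls_b = call_two_step(m, cfg)
        assert [(c.sample, c.span_label, c.p_value) for c in calls_a] == [
            (c.sample, c.span_label, c.p_value) for c in calls_b
        ]

    def test_implanted_deletion_significant(self):
        # noise-free 4-exon deletion in a 50-sample cohort: the deep window
        # is unreachable by permuting near-constant columns
        spec = CohortSpec(
            n_samples=50, positive_fraction=0.02, noise=0.0, seed=2,
            cnv_catalog=(CNVEvent("BRCA1", "ex20", "ex23", DELETION),),
        )
        table, truth = generate_cohort(spec)
        m = normalize_matrix(table, qc=exclude_low_coverage(table, 100))
        sample = truth.positive_samples[0]
        cands = [
            c for c in candidate_lrs(m, sample, DELETION)
            if (c.first_exon, c.last_exon) == ("ex20", "ex23")
        ]
        cand = max(cands, key=lambda c: c.L)
        scheme = ShuffleScheme(
            n_column_shuffles=1000,
            row_shuffle_samples=tuple(m.active_samples),
            rng=np.random.default_rng(1),
        )
        p, _ = empirical_pvalue(cand, m, scheme, TH)
        assert p <= 0.01

    def test_null_pvalues_conservative(self):
        """Forced (unfiltered) windows in a CNV-free cohort are not
        anti-conservative."""
        spec = CohortSpec(n_samples=30, positive_fraction=0.0, seed=6)
        table, _ = generate_cohort(spec)
        m = normalize_matrix(table, qc=exclude_low_coverage(table, 100))
        rng = np.random.default_rng(11)
        ps = []
        for sample in m.samples[:10]:
            for start in (5, 40, 70):
                idx = [start, start + 1, start + 2]
                vals = m.column(sample)[idx]
                if not np.all(np.isfinite(vals)):
                    continue
                kind = DELETION if vals.mean() < 2.0 else AMPLIFICATION
                cand = _window_candidate(m, sample, idx, kind=kind)
                scheme = ShuffleScheme(
                    n_column_shuffles=300,
                    row_shuffle_samples=tuple(m.active_samples),
                    rng=rng,
                )
                ps.append(empirical_pvalue(cand, m, scheme, TH)[0])
        ps = np.array(ps)
        assert ps.mean() >= 0.45
        assert (ps <= 0.05).mean() <= 0.1


class TestTwoStepCalling:
    def test_cnv_free_cohort_no_step1_calls(self):
        spec = CohortSpec(n_samples=50, positive_fraction=0.0, seed=8)
        table, _ = generate_cohort(spec)
        m = normalize_matrix(table, qc=exclude_low_coverage(table, 100))
        calls = call_two_step(m, RunConfig(seed=8, n_shuffles=300))
        assert [c for c in calls if c.step == 1] == []

    def test_single_implanted_event_called_exactly(self):
        spec = CohortSpec(
            n_samples=30, positive_fraction=0.03, noise=0.0, seed=5,
            cnv_catalog=(CNVEvent("BRCA1", "ex20", "ex23", DELETION),),
        )
        table, truth = generate_cohort(spec)
        m = normalize_matrix(table, qc=exclude_low_coverage(table, 100))
        calls = call_two_step(m, RunConfig(seed=5, n_shuffles=300))
        assert len(calls) == 1
        call = calls[0]
        assert call.sample == truth.positive_samples[0]
        assert call.span_label == "del_BRCA1_ex20-ex23"
        assert call.step == 1

    def test_step1_exclusion_rescues_second_positive(self):
        """Two samples with the same event: calling the first must not
        suppress the second, and dropping a step-1 positive from the row
        pool never hurts the other true positive."""
        panel = toy_panel()
        spec = CohortSpec(
            panel=panel, n_samples=20, positive_fraction=0.1, noise=0.05,
            region_noise_sd=0.0, seed=13,
            cnv_catalog=(CNVEvent("BRCA1", "ex20", "ex23", DELETION),),
        )
        table, truth = generate_cohort(spec)
        assert len(truth.positive_samples) == 2
        m = normalize_matrix(table, qc=exclude_low_coverage(table, 100))
        calls = call_two_step(m, RunConfig(seed=13, n_shuffles=500))
        called = {c.sample for c in calls if c.kind == DELETION and c.gene == "BRCA1"}
        assert set(truth.positive_samples) <= called
        # p-value of one positive against a pool with vs without the other
        sample_a, sample_b = truth.positive_samples
        cands = [
            c for c in candidate_lrs(m, sample_a, DELETION)
            if (c.first_exon, c.last_exon) == ("ex20", "ex23")
        ]
        cand = max(cands, key=lambda c: c.L)
        full_pool = tuple(m.active_samples)
        reduced = tuple(s for s in full_pool if s != sample_b)
        p_full, n_full = empirical_pvalue(
            cand, m,
            ShuffleScheme(500, full_pool, np.random.default_rng(3)), TH,
        )
        p_reduced, n_reduced = empirical_pvalue(
            cand, m,
            ShuffleScheme(500, reduced, np.random.default_rng(3)), TH,
        )
        # compare null exceedance counts: the +1/+1 floor itself shifts by
        # one part in ~500 when the pool shrinks, which is not a real increase
        exceed_full = round(p_full * (1 + n_full)) - 1
        exceed_reduced = round(p_reduced * (1 + n_reduced)) - 1
        assert exceed_reduced <= exceed_full

    def test_tiny_cohort_rejected(self):
        panel = make_panel([("BRCA1", f"ex{i}", None) for i in range(1, 5)])
        table = make_table(panel, np.full((4, 1), 200.0))
        m = normalize_matrix(table)
        with pytest.raises(RuntimeError, match="2 QC-passing samples"):
            call_two_step(m, RunConfig(n_shuffles=100))
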