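"""Unit and property tests for the TE/KEV core."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from kevtools import (
    AnalysisConfig,
    classify,
    compute_kevs,
    kev_distribution,
    kev_test,
    replicate_filter,
    summarize_condition,
    translational_efficiency,
)


@pytest.mark.parametrize(
    "poly,free,expected",
    [(3.0, 1.5, 2.0), (7.0, 7.0, 1.0), (0.1, 0.1, 1.0)],
)
def test_te_is_polysomal_over_free(poly, free, expected):
    assert translational_efficiency(poly, free) == pytest.approx(expected)


@pytest.mark.parametrize("poly,free", [(1.0, 0.0), (0.0, 1.0), (-1.0, 2.0), (1.0, None)])
def test_te_degenerate_inputs_are_missing_not_zero(poly, free):
    assert math.isnan(translational_efficiency(poly, free))


class TestSummarizeCondition:
    def test_constant_values(self, analysis_config):
        s = summarize_condition([2.0, 2.0, 2.0], analysis_config)
        assert (s.mean_te, s.sd_te, s.cv) == (2.0, 0.0, 0.0)
        assert s.n_used == 3 and not s.excluded_replicates

    def test_obvious_outlier_excluded(self, analysis_config):
        # CV of [1.0, 1.1, 0.9, 10.0] is ~1.38 >= 0.60; 10.0 sits 9 units
        # from the others' mean while their sd is 0.1, so it is removed.
        s = summarize_condition([1.0, 1.1, 0.9, 10.0], analysis_config)
        assert s.n_used == 3
        assert s.mean_te == pytest.approx(1.0)
        assert [v for v, r in s.excluded_replicates if r == "outlier"] == [10.0]

    def test_high_cv_pair_is_kept(self, analysis_config):
        # removal from n=2 would leave sd undefined: keep both, flag high CV
        s = summarize_condition([1.0, 3.0], analysis_config)
        assert s.n_used == 2 and s.high_cv and not s.excluded_replicates

    def test_empty_input_unusable(self, analysis_config):
        s = summarize_condition([], analysis_config)
        assert not s.usable and s.n_used == 0

    @given(
        values=st.lists(
            st.floats(min_value=0.01, max_value=100.0, allow_nan=False),
            min_size=1, max_size=6,
        )
    )
    def test_matches_leave_one_out_oracle(self, values):
        """The outlier rule equals a brute-force leave-one-out CV search."""
        config = AnalysisConfig()
        arr = np.array(values)

        def cv_of(a):
            return np.std(a, ddof=1) / np.mean(a) if a.size >= 2 else 0.0

        expected = sorted(values)
        if cv_of(arr) >= config.cv_threshold and arr.size >= 4:
            cvs = [cv_of(np.delete(arr, i)) for i in range(arr.size)]
            i = int(np.argmin(cvs))
            if cvs[i] < cv_of(arr):
                others = np.delete(arr, i)
                if abs(arr[i] - others.mean()) > config.outlier_k * np.std(others, ddof=1):
                    expected = sorted(np.delete(arr, i).tolist())
        s = summarize_condition(values, config)
        assert sorted(s.te_values) == pytest.approx(expected)


@pytest.mark.parametrize(
    "n_untreated,n_treated,passes", [(3, 3, True), (5, 2, False), (3, 4, True), (2, 2, False)]
)
def test_replicate_filter(n_untreated, n_treated, passes, analysis_config):
    su = summarize_condition([1.0] * n_untreated, analysis_config)
    st_ = summarize_condition([1.0] * n_treated, analysis_config)
    assert replicate_filter(su, st_, analysis_config) is passes


def test_filter_applies_after_outlier_exclusion(analysis_config):
    # 4 replicates, one excluded as outlier -> 3 remain -> still passes
    su = summarize_condition([1.0, 1.1, 0.9, 10.0], analysis_config)
    st_ = summarize_condition([1.0, 1.0, 1.0], analysis_config)
    assert su.n_used == 3
    assert replicate_filter(su, st_, analysis_config)


def _summaries_from_ratios(ratios, config):
    out = {}
    for i, r in enumerate(ratios):
        su = summarize_condition([1.0, 1.0, 1.0], config)
        st_ = summarize_condition([r, r, r], config)
        out[f"g{i}"] = (su, st_)
    return out


class TestComputeKEVs:
    def test_median_zero_leaves_ratios_unchanged(self, analysis_config):
        # raw log2 ratios {-1, 0, 2} have median 0: no shift
        records = compute_kevs(_summaries_from_ratios([0.5, 1.0, 4.0], analysis_config),
                               analysis_config)
        assert sorted(r.kev for r in records) == pytest.approx([0.5, 1.0, 4.0])

    def test_global_scale_invariance(self, analysis_config):
        records = compute_kevs(_summaries_from_ratios([3.0, 3.0, 3.0, 3.0], analysis_config),
                               analysis_config)
        assert all(r.kev == pytest.approx(1.0) for r in records)

    def test_median_log2_kev_is_exactly_zero(self, analysis_config):
        rng = np.random.default_rng(5)
        ratios = 2.0 ** rng.normal(0.7, 1.0, size=101)
        records = compute_kevs(_summaries_from_ratios(ratios, analysis_config),
                               analysis_config)
        assert float(np.median([r.log2_kev for r in records])) == 0.0

    def test_rescaling_treated_intensities_leaves_kevs_unchanged(self, analysis_config):
        rng = np.random.default_rng(6)
        ratios = 2.0 ** rng.normal(0.0, 1.0, size=50)
        base = compute_kevs(_summaries_from_ratios(ratios, analysis_config), analysis_config)
        scaled = compute_kevs(_summaries_from_ratios(ratios * 17.3, analysis_config),
                              analysis_config)
        assert [r.kev for r in base] == pytest.approx([r.kev for r in scaled])


@pytest.mark.parametrize(
    "kev,label",
    [
        (0.25, "sensitive"),
        (5.21, "resistant"),
        (1.44, "average"),
        (0.5, "sensitive"),   # boundary inclusive
        (2.0, "resistant"),   # boundary inclusive
        (0.50001, "average"),
        (float("nan"), "excluded"),
    ],
)
def test_classify(kev, label, analysis_config):
    assert classify(kev, analysis_config) == label


def test_classify_partition_is_exhaustive_and_exclusive(analysis_config):
    rng = np.random.default_rng(2)
    kevs = 2.0 ** rng.normal(0, 1.2, size=500)
    labels = [classify(k, analysis_config) for k in kevs]
    assert set(labels) <= {"sensitive", "average", "resistant"}
    assert len(labels) == 500


class TestKevTest:
    def test_identical_sets_give_p_one(self):
        assert kev_test([1.0, 2.0, 4.0], [1.0, 2.0, 4.0]) == pytest.approx(1.0)

    def test_matches_independent_welch_formula(self):
        """Welch statistic coded directly from its formula, on log2 TEs."""
        a = np.array([0.0, 0.0, 0.1])
        b = np.array([2.0, 2.0, 2.1])
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / a.size + vb / b.size
        t = (a.mean() - b.mean()) / math.sqrt(se2)
        df = se2**2 / (
            (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
        )
        expected = 2.0 * stats.t.sf(abs(t), df)
        observed = kev_test(list(2.0**a), list(2.0**b))
        assert observed == pytest.approx(expected, rel=1e-12)

    def test_insufficient_replicates_give_none(self):
        assert kev_test([1.0], [1.0, 2.0, 3.0]) is None


class TestKevDistribution:
    def test_single_gene_at_one_falls_in_zero_bin(self, analysis_config):
        records = compute_kevs(_summaries_from_ratios([1.0], analysis_config),
                               analysis_config)
        counts, edges = kev_distribution(records)
        assert counts.sum() == 1
        hit = int(np.flatnonzero(counts)[0])
        assert edges[hit] <= 0.0 < edges[hit + 1]

    def test_counts_sum_to_records(self, analysis_config):
        rng = np.random.default_rng(3)
        records = compute_kevs(
            _summaries_from_ratios(2.0 ** rng.normal(0, 1, size=123), analysis_config),
            analysis_config,
        )
        counts, _ = kev_distribution(records)
        assert counts.sum() == 123

    def test_mirrored_input_gives_symmetric_histogram(self, analysis_config):
        values = np.array([0.1, 0.4, 0.9, 1.7])
        ratios = np.concatenate([2.0**values, 2.0**-values])
        records = compute_kevs(_summaries_from_ratios(ratios, analysis_config),
                               analysis_config)
        counts, edges = kev_distribution(records)
        assert np.allclose(edges, -edges[::-1])
        assert (counts == counts[::-1]).all()
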