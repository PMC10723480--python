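"""Unit tests for percentile ranks, ROI summaries and the scoring methods."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone
from sklearn.pipeline import Pipeline

from pscore import (
    DegenerateDistributionError,
    NormativeTable,
    PscoreScaler,
    RoiDistributionSummary,
    ValidationError,
    ZscoreScaler,
    log_transform_table,
    percentile_rank,
    pscore,
    pscore_table,
    score_individual,
    summarize_roi,
    zscore_table,
)


def oracle_column_pscores(col, scale=1.645):
    """Brute-force reference: sort, interpolate edges by hand, apply formula."""
    x = sorted(float(v) for v in col)
    n = len(x)

    def edge(p):
        h = 1 + (p / 100.0) * (n - 1)
        k = math.floor(h)
        frac = h - k
        if k >= n:
            return x[-1]
        return x[k - 1] + frac * (x[k] - x[k - 1])

    med = (x[(n - 1) // 2] + x[n // 2]) / 2.0
    d5, d95 = med - edge(5), edge(95) - med
    out = []
    for v in col:
        d = v - med
        if d < 0:
            out.append(scale * d / d5)
        elif d > 0:
            out.append(scale * d / d95)
        else:
            out.append(0.0)
    return out


class TestPercentileRank:
    def test_direct_counts(self):
        table = NormativeTable(np.array([[1.0], [2.0], [3.0], [4.0]]))
        ranks = percentile_rank(table).ranks.to_numpy().ravel()
        assert ranks.tolist() == [25.0, 50.0, 75.0, 100.0]

    def test_smallest_of_n_distinct_ranks_100_over_n(self):
        col = np.arange(1.0, 8.0).reshape(-1, 1)
        ranks = percentile_rank(NormativeTable(col)).ranks.to_numpy().ravel()
        assert ranks[0] == pytest.approx(100.0 / 7)
        assert ranks[-1] == 100.0

    def test_ties_share_maximal_rank(self):
        table = NormativeTable(np.array([[1.0], [2.0], [2.0], [3.0]]))
        ranks = percentile_rank(table).ranks.to_numpy().ravel()
        assert ranks.tolist() == [25.0, 75.0, 75.0, 100.0]

    def test_invariant_under_strictly_increasing_transform(self, small_table):
        base = percentile_rank(small_table).ranks.to_numpy()
        warped = NormativeTable(np.exp(small_table.values * 3.0))
        assert np.array_equal(percentile_rank(warped).ranks.to_numpy(), base)

    def test_column_bounds(self, small_table):
        r = percentile_rank(small_table)
        ranks = r.ranks.to_numpy()
        assert (ranks.max(axis=0) == 100.0).all()
        assert (ranks >= 100.0 / r.n_ns - 1e-12).all()


class TestSummarizeRoi:
    def test_hand_interpolated_edges_1_to_100(self):
        s = summarize_roi(np.arange(1.0, 101.0))
        assert s.median == 50.5
        assert s.p5_edge == pytest.approx(5.95)
        assert s.p95_edge == pytest.approx(95.05)
        assert s.d5 == pytest.approx(44.55)
        assert s.d95 == pytest.approx(44.55)

    def test_constant_column_is_degenerate(self):
        with pytest.raises(DegenerateDistributionError, match="gcc"):
            summarize_roi(np.full(10, 3.14), roi_label="gcc")

    @pytest.mark.parametrize("n,expected_beyond", [(960, 48), (912, 46), (100, 5)])
    def test_tie_free_counts_beyond_edges_are_floor_determined(self, n, expected_beyond):
        """Linear interpolation pins the strictly-beyond-edge count by n alone."""
        for seed in range(10):
            col = np.random.default_rng(seed).normal(size=n)
            s = summarize_roi(col)
            assert np.count_nonzero(col < s.p5_edge) == expected_beyond
            assert np.count_nonzero(col > s.p95_edge) == expected_beyond

    def test_short_column_rejected(self):
        with pytest.raises(ValidationError):
            summarize_roi([1.0, 2.0])


class TestPscore:
    SUMMARY = RoiDistributionSummary("roi", median=10.0, p5_edge=6.0,
                                     p95_edge=20.0, d5=4.0, d95=10.0, n=100)

    @pytest.mark.parametrize("x,expected", [
        (10.0, 0.0),          # at the median
        (20.0, 1.645),        # at the 95th-percentile edge
        (15.0, 0.8225),       # 1.645 * 5/10
        (6.0, -1.645),        # at the 5th-percentile edge
        (2.0, -3.29),         # -1.645 * 8/4: beyond the edge is legal
    ])
    def test_anchored_values(self, x, expected):
        assert pscore(x, self.SUMMARY) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            pscore(float("nan"), self.SUMMARY)

    def test_sign_matches_side_of_median(self, small_table):
        st = pscore_table(small_table)
        med = np.median(small_table.values, axis=0)
        assert np.array_equal(np.sign(st.values), np.sign(small_table.values - med))


class TestPscoreTable:
    def test_tie_free_even_n_splits_signs_50_50(self, dt_like_table):
        scores = pscore_table(dt_like_table).values
        assert (np.count_nonzero(scores > 0, axis=0) == 480).all()
        assert (np.count_nonzero(scores < 0, axis=0) == 480).all()

    def test_affine_invariance(self, small_table):
        base = pscore_table(small_table).values
        shifted = NormativeTable(3.7 * small_table.values + 11.0)
        assert np.allclose(pscore_table(shifted).values, base, atol=1e-10)

    def test_virtual_individual_at_median_scores_zero(self):
        ref = NormativeTable(np.arange(1.0, 101.0).reshape(-1, 1))
        s = score_individual([50.5], ref, method="pscore")
        assert s.iloc[0] == 0.0

    def test_monotone_in_x_within_column(self):
        rng = np.random.default_rng(5)
        col = rng.gamma(2.0, size=200)
        scores = pscore_table(NormativeTable(col.reshape(-1, 1))).values.ravel()
        order = np.argsort(col)
        assert (np.diff(scores[order]) > 0).all()  # tie-free: strictly increasing

    def test_degenerate_column_raises_with_label(self):
        values = np.random.default_rng(0).normal(size=(10, 2))
        values[:, 1] = 5.0
        with pytest.raises(DegenerateDistributionError, match="bad"):
            pscore_table(NormativeTable(values, roi_labels=["ok", "bad"]))

    def test_brute_force_oracle_equivalence_short_columns(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(3, 13))
            col = rng.normal(size=n)
            if np.unique(col).size < n:
                continue
            try:
                got = pscore_table(NormativeTable(col.reshape(-1, 1))).values.ravel()
            except DegenerateDistributionError:
                continue
            assert np.allclose(got, oracle_column_pscores(col), atol=1e-12)

    def test_gaussian_limit_matches_zscore(self):
        """For a large normal sample the 5th/95th edges sit at ∓1.645 SD."""
        col = np.random.default_rng(99).normal(size=(100_000, 1))
        t = NormativeTable(col)
        p = pscore_table(t).values.ravel()
        z = zscore_table(t).values.ravel()
        assert np.mean(np.abs(p - z)) < 0.05


class TestZscore:
    def test_already_standardized_column_unchanged(self):
        t = NormativeTable(np.array([[-1.0], [0.0], [1.0]]))
        assert np.allclose(zscore_table(t).values.ravel(), [-1.0, 0.0, 1.0])

    def test_hand_computed_values(self):
        t = NormativeTable(np.array([[2.0], [4.0], [6.0], [8.0]]))
        expected = [-1.161895, -0.387298, 0.387298, 1.161895]
        assert np.allclose(zscore_table(t).values.ravel(), expected, atol=1e-6)

    def test_columns_standardized_and_match_scipy(self, small_table):
        got = zscore_table(small_table).values
        assert np.allclose(got.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(got.std(axis=0, ddof=1), 1.0, atol=1e-10)
        assert np.allclose(got, stats.zscore(small_table.values, axis=0, ddof=1))

    def test_zero_sd_column_degenerate(self):
        values = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(DegenerateDistributionError):
            zscore_table(NormativeTable(values))


class TestLogTransform:
    def test_unit_and_e(self):
        t = NormativeTable(np.array([[1.0], [np.e], [np.e ** 2]]))
        assert np.allclose(log_transform_table(t).values.ravel(), [0.0, 1.0, 2.0])

    def test_preserves_order(self, small_table):
        logged = log_transform_table(small_table).values
        for j in range(small_table.n_rois):
            assert np.array_equal(np.argsort(logged[:, j]),
                                  np.argsort(small_table.values[:, j]))

    def test_nonpositive_cell_named(self):
        values = np.ones((4, 2))
        values[2, 1] = -0.5
        with pytest.raises(ValidationError, match="row 2, column 1"):
            log_transform_table(NormativeTable(values))

    def test_not_on_z_scale(self, small_table):
        assert not log_transform_table(small_table).on_z_scale


class TestScoreIndividual:
    def test_at_medians_scores_zero(self, small_table):
        med = np.median(small_table.values, axis=0)
        s = score_individual(med, small_table, method="pscore")
        assert np.allclose(s.to_numpy(), 0.0)

    def test_at_p95_edges_scores_scale_constant(self, small_table):
        edges = np.percentile(small_table.values, 95, axis=0)
        s = score_individual(edges, small_table, method="pscore")
        assert np.allclose(s.to_numpy(), 1.645)

    def test_reference_member_matches_table_row(self, small_table):
        row = small_table.data.iloc[4]
        s = score_individual(row, small_table, method="pscore", leave_self_in=True)
        table_row = pscore_table(small_table).data.iloc[4]
        assert np.allclose(s.to_numpy(), table_row.to_numpy())

    def test_leave_one_out_drops_the_member(self, small_table):
        row = small_table.data.iloc[0]
        loo = score_individual(row, small_table, method="pscore",
                               leave_self_in=False, participant_id="p0")
        ref = NormativeTable(small_table.data.drop(index="p0"))
        expected = score_individual(row, ref, method="pscore")
        assert np.allclose(loo.to_numpy(), expected.to_numpy())

    def test_roi_mismatch_rejected(self, small_table):
        with pytest.raises(ValidationError, match="missing ROI"):
            score_individual(pd.Series({"gcc": 1.0}), small_table)

    def test_zscore_method(self, small_table):
        means = small_table.values.mean(axis=0)
        s = score_individual(means, small_table, method="zscore")
        assert np.allclose(s.to_numpy(), 0.0, atol=1e-12)


class TestSklearnIntegration:
    def test_fit_reference_transform_new_data(self, small_table):
        scaler = PscoreScaler().fit(small_table.data)
        new = small_table.values[:3] * 1.0
        out = scaler.transform(new)
        assert out.shape == (3, 3)

    def test_clone_and_params_roundtrip(self):
        scaler = PscoreScaler(scale_constant=2.0, tail_probs=(10.0, 90.0))
        params = scaler.get_params()
        assert params["scale_constant"] == 2.0
        cloned = clone(scaler)
        assert cloned.get_params() == params

    def test_pipeline_composition(self, small_table):
        pipe = Pipeline([("pscore", PscoreScaler())])
        scores = pipe.fit_transform(small_table.data)
        assert np.allclose(scores, pscore_table(small_table).values)

    def test_summaries_accessor(self, small_table):
        scaler = PscoreScaler().fit(small_table)
        summaries = scaler.summaries()
        assert [s.roi_label for s in summaries] == ["gcc", "bcc", "scc"]
        assert all(s.d5 > 0 and s.d95 > 0 for s in summaries)

    def test_feature_count_mismatch(self, small_table):
        scaler = ZscoreScaler().fit(small_table)
        with pytest.raises(ValidationError):
            scaler.transform(np.ones((2, 5)))


class TestNormativeTableValidation:
    def test_too_few_participants(self):
        with pytest.raises(ValidationError):
            NormativeTable(np.ones((2, 3)))

    def test_duplicate_ids(self):
        with pytest.raises(ValidationError, match="duplicate participant"):
            NormativeTable(np.random.default_rng(0).normal(size=(3, 2)),
                           participant_ids=["a", "a", "b"])

    def test_non_finite_cell_located(self):
        v = np.ones((4, 2))
        v[1, 0] = np.nan
        with pytest.raises(ValidationError, match="non-finite"):
            NormativeTable(v)

    def test_small_n_warns(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="pscore.tables"):
            NormativeTable(np.random.default_rng(1).normal(size=(5, 2)))
        assert any("unstable" in r.message for r in caplog.records)
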