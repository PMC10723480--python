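"""Percentile deviation scores and comparison normalizations.

The central statistic is the *Pscore*: an individual's deviation from the
ROI median, normalized by the distance from the median to the 5th percentile
edge (left tail) or the 95th percentile edge (right tail), and scaled by
1.645 — the standard-normal Z value at those percentiles — so that Pscores
live on the familiar Z scale:

    P = -1.645 * (m - x) / (m - q05)    if x < m
    P = +1.645 * (x - m) / (q95 - m)    if x > m
    P = 0                               if x = m

where ``m`` is the column median and ``q05``/``q95`` are linearly
interpolated percentile edges. Because the anchors are order statistics,
an individual at the 95th-percentile edge scores exactly +1.645 whatever
the shape of the normative distribution — this is what keeps the extreme
tails balanced at 5%/5% for skewed data where classical Z scores fail.

Estimators follow the scikit-learn fit/transform contract and compose with
pipelines; the module-level ``*_table`` functions are thin wrappers that
carry participant/ROI labels through :class:`~pscore.tables.ScoreTable`.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import DegenerateDistributionError, ValidationError
from .tables import (
    DEFAULT_TAIL_PROBS,
    NORMAL_TAIL_Z,
    NormativeTable,
    PercentileRankTable,
    RoiDistributionSummary,
    ScoreTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PscoreScaler",
    "ZscoreScaler",
    "LogTransformer",
    "PercentileRankTransformer",
    "summarize_roi",
    "pscore",
    "percentile_rank",
    "pscore_table",
    "zscore_table",
    "log_transform_table",
    "score_individual",
]


def _check_matrix(X, *, estimator, min_samples=3):
    X = check_array(X, dtype=float, ensure_all_finite=True, ensure_2d=True,
                    ensure_min_samples=min_samples, estimator=estimator)
    return X


def _column_names(X, n_cols):
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    if isinstance(X, NormativeTable):
        return X.roi_labels
    return [f"x{j}" for j in range(n_cols)]


class PscoreScaler(TransformerMixin, BaseEstimator):
    """Scale features to percentile deviation scores (Pscores).

    ``fit`` learns each column's median and tail-probability percentile
    edges from the normative reference; ``transform`` maps values onto the
    Z-anchored percentile-deviation scale. Unlike
    :class:`sklearn.preprocessing.StandardScaler`, the two tails are
    normalized independently, so skewed references still produce balanced
    extreme-value proportions.

    Parameters
    ----------
    scale_constant : float, default 1.645
        Z value the percentile edges are mapped to (standard-normal
        5th/95th percentile for the default tail probabilities).
    tail_probs : pair of float, default (5.0, 95.0)
        Percentiles (0-100) anchoring the left and right tails.

    Attributes
    ----------
    median_ : ndarray of shape (n_features,)
        Per-column reference medians.
    p5_edge_, p95_edge_ : ndarray of shape (n_features,)
        Linearly interpolated percentile edges.
    d5_, d95_ : ndarray of shape (n_features,)
        Median-to-edge distances (the tail denominators), strictly positive.
    n_samples_seen_ : int
        Reference sample size.

    Raises
    ------
    DegenerateDistributionError
        At fit time, if any column's median coincides with a percentile
        edge (e.g. a constant column): such a column cannot anchor scores.
    """

    def __init__(self, scale_constant: float = NORMAL_TAIL_Z,
                 tail_probs: tuple[float, float] = DEFAULT_TAIL_PROBS):
        self.scale_constant = scale_constant
        self.tail_probs = tail_probs

    def fit(self, X, y=None):
        lo, hi = self.tail_probs
        if not (0 < lo < 50 < hi < 100):
            raise ValidationError(f"tail_probs must satisfy 0 < lo < 50 < hi < 100, got {self.tail_probs}")
        names = _column_names(X, None)
        if isinstance(X, NormativeTable):
            X = X.data
        V = _check_matrix(X, estimator=self)
        self.n_features_in_ = V.shape[1]
        self.feature_names_in_ = np.asarray(names[: V.shape[1]], dtype=object)
        self.n_samples_seen_ = V.shape[0]
        self.median_ = np.median(V, axis=0)
        # linear interpolation between order statistics at h = 1+(p/100)(n-1)
        self.p5_edge_, self.p95_edge_ = np.percentile(V, [lo, hi], axis=0, method="linear")
        self.d5_ = self.median_ - self.p5_edge_
        self.d95_ = self.p95_edge_ - self.median_
        bad = np.flatnonzero((self.d5_ <= 0) | (self.d95_ <= 0))
        if bad.size:
            label = str(self.feature_names_in_[bad[0]])
            raise DegenerateDistributionError(
                f"column {label!r}: median coincides with a percentile edge "
                f"(d5={self.d5_[bad[0]]:.6g}, d95={self.d95_[bad[0]]:.6g}); "
                "cannot anchor percentile deviation scores",
                roi_label=label,
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "median_")
        if isinstance(X, NormativeTable):
            X = X.data
        V = check_array(X, dtype=float, ensure_all_finite=True, ensure_2d=True, estimator=self)
        if V.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {V.shape[1]} features, but {type(self).__name__} "
                f"was fitted with {self.n_features_in_}"
            )
        d = V - self.median_
        scores = np.where(
            d < 0,
            self.scale_constant * d / self.d5_,
            self.scale_constant * d / self.d95_,
        )
        return scores

    def summaries(self) -> list[RoiDistributionSummary]:
        """Per-column :class:`RoiDistributionSummary` records."""
        check_is_fitted(self, "median_")
        return [
            RoiDistributionSummary(
                roi_label=str(name), median=float(m), p5_edge=float(lo),
                p95_edge=float(hi), d5=float(d5), d95=float(d95),
                n=self.n_samples_seen_,
            )
            for name, m, lo, hi, d5, d95 in zip(
                self.feature_names_in_, self.median_, self.p5_edge_,
                self.p95_edge_, self.d5_, self.d95_,
            )
        ]


class ZscoreScaler(TransformerMixin, BaseEstimator):
    """Classical standardization ``(x - mean) / SD`` with the n-1 sample SD.

    The comparator method. Kept as its own estimator because
    ``StandardScaler`` uses the population (n) SD while normative-reference
    practice is the unbiased sample (n-1) SD.
    """

    def fit(self, X, y=None):
        names = _column_names(X, None)
        if isinstance(X, NormativeTable):
            X = X.data
        V = _check_matrix(X, estimator=self)
        self.n_features_in_ = V.shape[1]
        self.feature_names_in_ = np.asarray(names[: V.shape[1]], dtype=object)
        self.n_samples_seen_ = V.shape[0]
        self.mean_ = V.mean(axis=0)
        self.scale_ = V.std(axis=0, ddof=1)
        bad = np.flatnonzero(self.scale_ <= 0)
        if bad.size:
            label = str(self.feature_names_in_[bad[0]])
            raise DegenerateDistributionError(
                f"column {label!r} has zero sample standard deviation",
                roi_label=label,
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        if isinstance(X, NormativeTable):
            X = X.data
        V = check_array(X, dtype=float, ensure_all_finite=True, ensure_2d=True, estimator=self)
        if V.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {V.shape[1]} features, but {type(self).__name__} "
                f"was fitted with {self.n_features_in_}"
            )
        return (V - self.mean_) / self.scale_


class LogTransformer(TransformerMixin, BaseEstimator):
    """Element-wise natural logarithm of strictly positive values.

    The weakest of the compared normalizations: it rescales but cannot
    symmetrize arbitrary skew, and its output is not on the Z/P score
    scale, so it is excluded from score-scale tail comparisons.
    """

    def fit(self, X, y=None):
        if isinstance(X, NormativeTable):
            X = X.data
        V = _check_matrix(X, estimator=self, min_samples=1)
        self.n_features_in_ = V.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        if isinstance(X, NormativeTable):
            X = X.data
        V = check_array(X, dtype=float, ensure_all_finite=True, ensure_2d=True, estimator=self)
        bad = np.argwhere(V <= 0)
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"log transform requires strictly positive values; "
                f"cell (row {i}, column {j}) = {V[i, j]!r}"
            )
        return np.log(V)


class PercentileRankTransformer(TransformerMixin, BaseEstimator):
    """Percentile ranks against a stored normative reference.

    For a value ``x`` in column ``j``, the rank is
    ``100 * #{reference values <= x} / n_ref`` — tied values share the
    maximal count, so the reference maximum ranks exactly 100 and every
    reference member ranks at least ``100 / n_ref``.
    """

    def fit(self, X, y=None):
        if isinstance(X, NormativeTable):
            X = X.data
        V = _check_matrix(X, estimator=self)
        self.n_features_in_ = V.shape[1]
        self.n_samples_seen_ = V.shape[0]
        self.reference_sorted_ = np.sort(V, axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_sorted_")
        if isinstance(X, NormativeTable):
            X = X.data
        V = check_array(X, dtype=float, ensure_all_finite=True, ensure_2d=True, estimator=self)
        if V.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {V.shape[1]} features, but {type(self).__name__} "
                f"was fitted with {self.n_features_in_}"
            )
        n = self.n_samples_seen_
        ranks = np.empty_like(V)
        for j in range(V.shape[1]):
            counts = np.searchsorted(self.reference_sorted_[:, j], V[:, j], side="right")
            ranks[:, j] = 100.0 * counts / n
        return ranks


# ---------------------------------------------------------------------------
# functional layer


def summarize_roi(column: Sequence[float], probs: tuple[float, float] = DEFAULT_TAIL_PROBS,
                  roi_label: str = "roi") -> RoiDistributionSummary:
    """Median, percentile edges and tail denominators of one ROI column.

    Edges use linear interpolation between adjacent order statistics at
    fractional index ``h = 1 + (p/100)(n-1)``; the median of an even-length
    column is the mean of the two central order statistics.

    Raises
    ------
    DegenerateDistributionError
        If either tail denominator is zero (``d5 = 0`` or ``d95 = 0``).
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValidationError(f"need a 1-D column of length >= 3, got shape {x.shape}")
    if not np.isfinite(x).all():
        raise ValidationError(f"ROI {roi_label!r}: non-finite values in column")
    med = float(np.median(x))
    lo, hi = np.percentile(x, probs, method="linear")
    d5, d95 = med - float(lo), float(hi) - med
    if d5 <= 0 or d95 <= 0:
        raise DegenerateDistributionError(
            f"ROI {roi_label!r}: degenerate distribution (d5={d5:.6g}, d95={d95:.6g})",
            roi_label=roi_label,
        )
    return RoiDistributionSummary(roi_label=roi_label, median=med, p5_edge=float(lo),
                                  p95_edge=float(hi), d5=d5, d95=d95, n=x.size)


def pscore(x: float, summary: RoiDistributionSummary,
           scale_constant: float = NORMAL_TAIL_Z) -> float:
    """Percentile deviation score of a single value against an ROI summary.

    Negative below the median (left-tail denominator ``d5``), positive
    above it (right-tail denominator ``d95``), exactly 0 at the median.
    A value at the 95th-percentile edge scores ``+scale_constant``.
    """
    if not np.isfinite(x):
        raise ValidationError(f"non-finite value {x!r}")
    if summary.d5 <= 0 or summary.d95 <= 0:
        raise DegenerateDistributionError(
            f"ROI {summary.roi_label!r}: degenerate summary", roi_label=summary.roi_label
        )
    d = float(x) - summary.median
    if d < 0:
        return scale_constant * d / summary.d5
    if d > 0:
        return scale_constant * d / summary.d95
    return 0.0


def percentile_rank(table: NormativeTable) -> PercentileRankTable:
    """Within-column percentile ranks of every participant.

    ``p_ij = 100 * #{x_kj <= x_ij} / N``; ties share the maximal rank, the
    column maximum ranks 100, and no rank is below ``100 / N``.
    """
    tr = PercentileRankTransformer().fit(table.data)
    ranks = tr.transform(table.data)
    return PercentileRankTable(
        ranks=pd.DataFrame(ranks, index=table.data.index, columns=table.data.columns),
        n_ns=table.n_participants,
        metric_name=table.metric_name,
    )


def pscore_table(table: NormativeTable, scale_constant: float = NORMAL_TAIL_Z,
                 tail_probs: tuple[float, float] = DEFAULT_TAIL_PROBS) -> ScoreTable:
    """Pscore every cell of a normative table against its own columns."""
    scaler = PscoreScaler(scale_constant=scale_constant, tail_probs=tail_probs)
    scores = scaler.fit(table).transform(table)
    return ScoreTable(
        data=pd.DataFrame(scores, index=table.data.index, columns=table.data.columns),
        method="pscore", scale_constant=scale_constant,
        source_metric=table.metric_name, tail_probs=tail_probs,
    )


def zscore_table(table: NormativeTable) -> ScoreTable:
    """Column-wise Z standardization of a normative table (n-1 SD)."""
    scores = ZscoreScaler().fit(table).transform(table)
    return ScoreTable(
        data=pd.DataFrame(scores, index=table.data.index, columns=table.data.columns),
        method="zscore", source_metric=table.metric_name,
    )


def log_transform_table(table: NormativeTable) -> ScoreTable:
    """Element-wise natural log of a strictly positive normative table."""
    scores = LogTransformer().fit(table).transform(table)
    return ScoreTable(
        data=pd.DataFrame(scores, index=table.data.index, columns=table.data.columns),
        method="log", source_metric=table.metric_name,
    )


def percentile_rank_table(table: NormativeTable) -> ScoreTable:
    """Percentile ranks packaged as a ScoreTable (method ``percentile_rank``)."""
    prt = percentile_rank(table)
    return ScoreTable(data=prt.ranks, method="percentile_rank",
                      source_metric=table.metric_name)


def score_individual(x, reference: NormativeTable, method: str = "pscore",
                     leave_self_in: bool = True, participant_id: str | None = None,
                     scale_constant: float = NORMAL_TAIL_Z,
                     tail_probs: tuple[float, float] = DEFAULT_TAIL_PROBS) -> pd.Series:
    """Score one individual's per-ROI values against a normative reference.

    The reference is never mutated; medians, edges (or means/SDs) are
    computed from the reference alone. If the individual is themselves a
    reference member, ``leave_self_in=True`` (default) reproduces the
    corresponding row of the full score table; ``leave_self_in=False`` with
    ``participant_id`` given drops that row before summarizing, giving a
    leave-one-out score.

    Parameters
    ----------
    x : mapping, Series or 1-D array
        One value per reference ROI. Mappings/Series are aligned by ROI
        label; plain arrays must match the reference column order.
    method : {"pscore", "zscore"}
    """
    if method not in ("pscore", "zscore"):
        raise ValidationError(f"method must be 'pscore' or 'zscore', got {method!r}")
    labels = reference.roi_labels
    if isinstance(x, dict):
        x = pd.Series(x)
    if isinstance(x, pd.Series):
        missing = [r for r in labels if r not in x.index]
        if missing:
            raise ValidationError(f"individual is missing ROI values: {missing[:5]}")
        vec = x.reindex(labels).to_numpy(dtype=float)
    else:
        vec = np.asarray(x, dtype=float).ravel()
        if vec.size != len(labels):
            raise ValidationError(
                f"individual has {vec.size} values but reference has {len(labels)} ROIs"
            )
    if not np.isfinite(vec).all():
        raise ValidationError("individual contains non-finite values")

    ref = reference.data
    if not leave_self_in and participant_id is not None and participant_id in ref.index:
        ref = ref.drop(index=participant_id)

    if method == "pscore":
        scaler = PscoreScaler(scale_constant=scale_constant, tail_probs=tail_probs)
    else:
        scaler = ZscoreScaler()
    scores = scaler.fit(ref).transform(vec.reshape(1, -1))[0]
    return pd.Series(scores, index=labels, name=participant_id or "individual")
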