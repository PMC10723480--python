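"""Typed containers for normative tables, score tables and ROI summaries.

A *normative table* is the reference cohort: one row per participant, one
column per region of interest (ROI), cells holding the participant's average
metric value in that region (e.g. mean fractional anisotropy over a
white-matter tract). Scoring methods turn a normative table into a *score
table* of the same shape. Both are thin, validated wrappers around a pandas
DataFrame so that labels travel with the numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: Score below/above which a value counts as extreme: the 5th/95th percentile
#: of the standard normal distribution (two-sided 10% tail mass).
NORMAL_TAIL_Z = 1.645

#: Default tail probabilities (percent) anchoring the score scale.
DEFAULT_TAIL_PROBS = (5.0, 95.0)

SCORE_METHODS = ("pscore", "zscore", "log", "percentile_rank")


def _as_dataframe(values, participant_ids, roi_labels) -> pd.DataFrame:
    if isinstance(values, pd.DataFrame):
        df = values.copy()
        if participant_ids is not None:
            df.index = pd.Index(participant_ids, name="participant_id")
        if roi_labels is not None:
            df.columns = pd.Index(roi_labels, name="roi")
        return df
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D participants × ROIs array, got ndim={arr.ndim}")
    n, m = arr.shape
    if participant_ids is None:
        participant_ids = [f"sub-{i + 1:04d}" for i in range(n)]
    if roi_labels is None:
        roi_labels = [f"roi-{j + 1:02d}" for j in range(m)]
    return pd.DataFrame(
        arr,
        index=pd.Index(participant_ids, name="participant_id"),
        columns=pd.Index(roi_labels, name="roi"),
    )


@dataclass
class NormativeTable:
    """Participants × ROIs matrix of raw metric values.

    Parameters
    ----------
    data : DataFrame
        Rows indexed by participant ID, columns by ROI label, float cells.
    metric_name : str
        Name of the quantitative metric (e.g. ``"FA"``).

    Raises
    ------
    ValidationError
        On non-finite cells, duplicate IDs/labels, or fewer than 3 rows.
    """

    data: pd.DataFrame
    metric_name: str = "metric"

    def __init__(self, values, participant_ids=None, roi_labels=None,
                 metric_name: str = "metric"):
        self.data = _as_dataframe(values, participant_ids, roi_labels)
        self.metric_name = str(metric_name)
        self._validate()

    def _validate(self) -> None:
        df = self.data
        if df.shape[0] < 3:
            raise ValidationError(
                f"need at least 3 participants to compute scores, got {df.shape[0]}"
            )
        if df.shape[1] < 1:
            raise ValidationError("table has no ROI columns")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate participant IDs: {dupes[:5]}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ROI labels: {dupes[:5]}")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))
            i, j = bad[0]
            raise ValidationError(
                f"{len(bad)} non-finite cell(s); first at participant "
                f"{df.index[i]!r}, ROI {df.columns[j]!r}"
            )
        self.data = df.astype(float)
        if df.shape[0] < 20:
            logger.warning(
                "normative sample has only %d participants; "
                "5th/95th percentile edges will be unstable", df.shape[0],
            )

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def participant_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def roi_labels(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"NormativeTable(metric={self.metric_name!r}, "
                f"n_participants={self.n_participants}, n_rois={self.n_rois})")


@dataclass
class PercentileRankTable:
    """Percentile ranks p_ij of every participant within every ROI column.

    ``ranks`` has the same shape and labels as the source table; ``n_ns`` is
    the normative sample size used as the rank denominator, so every entry
    lies in ``[100/n_ns, 100]`` and the column maximum is exactly 100.
    """

    ranks: pd.DataFrame
    n_ns: int
    metric_name: str = "metric"


@dataclass(frozen=True)
class RoiDistributionSummary:
    """Median and percentile-edge anchors of one ROI's normative column.

    ``d5 = median - p5_edge`` and ``d95 = p95_edge - median`` are the
    left- and right-tail denominators of the percentile deviation score.
    """

    roi_label: str
    median: float
    p5_edge: float
    p95_edge: float
    d5: float
    d95: float
    n: int

    def __post_init__(self):
        if not (self.p5_edge <= self.median <= self.p95_edge):
            raise ValidationError(
                f"ROI {self.roi_label!r}: edge ordering violated "
                f"({self.p5_edge} <= {self.median} <= {self.p95_edge})"
            )


@dataclass
class ScoreTable:
    """Participants × ROIs matrix of scores under one normalization method.

    ``method`` is one of ``pscore`` (percentile deviation score), ``zscore``
    (classical standardization), ``log`` (natural log of the raw values; not
    on the Z/P scale and excluded from score-scale comparisons) or
    ``percentile_rank``.
    """

    data: pd.DataFrame
    method: str
    scale_constant: float = NORMAL_TAIL_Z
    source_metric: str = "metric"
    tail_probs: tuple[float, float] = field(default=DEFAULT_TAIL_PROBS)

    def __post_init__(self):
        if self.method not in SCORE_METHODS:
            raise ValidationError(
                f"unknown score method {self.method!r}; expected one of {SCORE_METHODS}"
            )

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def on_z_scale(self) -> bool:
        """Whether scores are comparable to standard-normal Z values."""
        return self.method in ("pscore", "zscore")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape
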