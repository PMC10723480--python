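"""Extreme-value and sign-balance audits of score distributions.

For a normative cohort scored on the Z scale, 5% of values should fall
above +1.645 and 5% below -1.645. Skewed raw distributions break this for
Z scores; percentile deviation scores restore it by construction. This
module flattens a score table into one vector per metric and tabulates the
number (NEV) and percentage (PEV) of extreme values in each tail, together
with the positive/negative balance around zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .scoring import pscore_table, zscore_table
from .tables import NORMAL_TAIL_Z, NormativeTable, ScoreTable

logger = logging.getLogger(__name__)

__all__ = ["ImbalanceRecord", "concatenate_scores", "extreme_value_counts",
           "imbalance_table", "records_to_frame", "write_imbalance_csv"]

#: Header layout of the audit table (sign-balance columns appended on demand).
TABLE_COLUMNS = ["Metric", "Method", "NEV>95", "NEV<5", "NTotal",
                 "PEV>95(%)", "PEV<5(%)"]
SIGN_COLUMNS = ["PctPositive(%)", "PctNegative(%)", "NZero"]


@dataclass(frozen=True)
class ImbalanceRecord:
    """One audit row: tail counts/percentages for one metric × method.

    Percentages are stored at full precision; rounding to the one-decimal
    presentation format happens only in the CSV writer.
    """

    metric: str
    method: str
    nev_gt95: int
    nev_lt5: int
    n_total: int
    pev_gt95: float
    pev_lt5: float
    pct_positive: float
    pct_negative: float
    n_zero: int
    threshold: float = NORMAL_TAIL_Z

    def __post_init__(self):
        if self.n_total <= 0:
            raise ValidationError("empty score vector")
        assert self.nev_gt95 + self.nev_lt5 <= self.n_total


def concatenate_scores(score_table: ScoreTable) -> np.ndarray:
    """Flatten an N × M score table into one vector of length N·M.

    Column-major order (participants vary fastest within each ROI block);
    the audit statistics are order-invariant, but a fixed order keeps
    vectors reproducible for debugging.
    """
    if score_table.method not in ("zscore", "pscore"):
        raise ValidationError(
            f"tail audit is defined on the Z/P score scale, not {score_table.method!r}"
        )
    vec = score_table.values.ravel(order="F")
    logger.debug("concatenated %d scores (%d × %d)", vec.size, *score_table.shape)
    return vec


def extreme_value_counts(scores: np.ndarray, threshold: float = NORMAL_TAIL_Z,
                         metric: str = "metric", method: str = "pscore") -> ImbalanceRecord:
    """Count scores strictly beyond ±threshold and the sign balance around 0.

    Strict inequalities on both tails; scores exactly 0 are tallied in
    their own bucket, in neither the positive nor the negative share.
    """
    v = np.asarray(scores, dtype=float).ravel()
    if v.size == 0:
        raise ValidationError("empty score vector")
    if not np.isfinite(v).all():
        raise ValidationError("non-finite scores in audit vector")
    n = v.size
    gt = int(np.count_nonzero(v > threshold))
    lt = int(np.count_nonzero(v < -threshold))
    pos = int(np.count_nonzero(v > 0))
    neg = int(np.count_nonzero(v < 0))
    return ImbalanceRecord(
        metric=metric, method=method,
        nev_gt95=gt, nev_lt5=lt, n_total=n,
        pev_gt95=100.0 * gt / n, pev_lt5=100.0 * lt / n,
        pct_positive=100.0 * pos / n, pct_negative=100.0 * neg / n,
        n_zero=n - pos - neg, threshold=threshold,
    )


def audit_table(table: NormativeTable, method: str,
                threshold: float = NORMAL_TAIL_Z) -> ImbalanceRecord:
    """Score one normative table and audit the concatenated vector."""
    if method == "pscore":
        st = pscore_table(table)
    elif method == "zscore":
        st = zscore_table(table)
    else:
        raise ValidationError(f"method must be 'pscore' or 'zscore', got {method!r}")
    return extreme_value_counts(concatenate_scores(st), threshold=threshold,
                                metric=table.metric_name, method=method)


def imbalance_table(tables: list[tuple[str, NormativeTable]],
                    methods: tuple[str, ...] = ("zscore", "pscore"),
                    threshold: float = NORMAL_TAIL_Z) -> list[ImbalanceRecord]:
    """One :class:`ImbalanceRecord` per metric × method, in input order."""
    records = []
    for metric, table in tables:
        for method in methods:
            table = NormativeTable(table.data, metric_name=metric) \
                if table.metric_name != metric else table
            records.append(audit_table(table, method, threshold=threshold))
    return records


def records_to_frame(records: list[ImbalanceRecord],
                     include_sign_balance: bool = False) -> pd.DataFrame:
    """Records as a DataFrame in the audit-table column layout."""
    rows = []
    for r in records:
        row = {"Metric": r.metric,
               "Method": "Zscore" if r.method == "zscore" else "Pscore",
               "NEV>95": r.nev_gt95, "NEV<5": r.nev_lt5, "NTotal": r.n_total,
               "PEV>95(%)": r.pev_gt95, "PEV<5(%)": r.pev_lt5}
        if include_sign_balance:
            row.update({"PctPositive(%)": r.pct_positive,
                        "PctNegative(%)": r.pct_negative, "NZero": r.n_zero})
        rows.append(row)
    cols = TABLE_COLUMNS + (SIGN_COLUMNS if include_sign_balance else [])
    return pd.DataFrame(rows, columns=cols)


def write_imbalance_csv(records: list[ImbalanceRecord], path,
                        include_sign_balance: bool = False,
                        round_percent: int | None = 1) -> None:
    """Write an audit CSV; percentages rounded at presentation time only."""
    df = records_to_frame(records, include_sign_balance=include_sign_balance)
    if round_percent is not None:
        for c in df.columns:
            if c.endswith("(%)"):
                df[c] = df[c].round(round_percent)
    df.to_csv(path, index=False)
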