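"""Reading and writing normative tables, score tables and sidecars.

Wide layout: header row of ROI labels, first column the participant ID.
Long layout: columns ``participant_id, roi, metric, value`` (pivoted to
wide on read). Score tables are written full-precision with a JSON sidecar
recording the method, scale constant, tail probabilities, edge-estimator
name and an input checksum, so every output is reproducible from its
sidecar alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .exceptions import ValidationError
from .tables import NormativeTable, ScoreTable

logger = logging.getLogger(__name__)

__all__ = ["read_normative_table", "write_normative_table",
           "write_score_table", "read_score_table", "sha256_of"]

EDGE_ESTIMATOR = "linear-interpolation-order-statistics"


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_normative_table(path, layout: str = "wide", metric: str | None = None,
                         strict: bool = False) -> NormativeTable:
    """Read a participants × ROIs table from CSV/TSV.

    Participants with any missing cell are dropped (count logged) unless
    ``strict`` is set, in which case missing data is a hard error.

    Parameters
    ----------
    layout : {"wide", "long"}
        Wide: one row per participant, one column per ROI. Long: tidy rows
        ``participant_id, roi, metric, value``; ``metric`` selects which
        metric to pivot out (required when the file holds several).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if layout == "wide":
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        metric_name = metric or path.stem
    elif layout == "long":
        long_df = pd.read_csv(path, sep=sep, dtype={"participant_id": str, "roi": str})
        required = {"participant_id", "roi", "value"}
        if not required.issubset(long_df.columns):
            raise ValidationError(
                f"long layout needs columns {sorted(required)}, got {list(long_df.columns)}"
            )
        if "metric" in long_df.columns:
            metrics = long_df["metric"].unique().tolist()
            if metric is None:
                if len(metrics) > 1:
                    raise ValidationError(f"file holds metrics {metrics}; pass metric=")
                metric = metrics[0]
            long_df = long_df[long_df["metric"] == metric]
            if long_df.empty:
                raise ValidationError(f"metric {metric!r} not found in {path}")
        metric_name = metric or path.stem
        df = long_df.pivot(index="participant_id", columns="roi", values="value")
    else:
        raise ValidationError(f"layout must be 'wide' or 'long', got {layout!r}")

    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        coerced = df[non_numeric].apply(pd.to_numeric, errors="coerce")
        bad_cells = coerced.isna() & df[non_numeric].notna()
        if bad_cells.any().any():
            col = bad_cells.any()[bad_cells.any()].index[0]
            row = bad_cells[col][bad_cells[col]].index[0]
            raise ValidationError(
                f"non-numeric cell at participant {row!r}, ROI {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        df[non_numeric] = coerced

    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        if strict:
            raise ValidationError(f"{n_missing} participant(s) with missing cells (strict mode)")
        logger.warning("dropping %d participant(s) with missing cells", n_missing)
        df = df.dropna(axis=0)

    table = NormativeTable(df, metric_name=metric_name)
    logger.info("read %s: N=%d participants, M=%d ROIs, %d dropped",
                path.name, table.n_participants, table.n_rois, n_missing)
    return table


def write_normative_table(table: NormativeTable, path) -> None:
    """Write a table in the wide CSV layout the readers accept."""
    table.data.to_csv(path, index=True)


def write_score_table(score_table: ScoreTable, path, input_path=None) -> Path:
    """Write scores as CSV (full precision) plus a JSON sidecar.

    Returns the sidecar path (``<path>.json``).
    """
    path = Path(path)
    score_table.data.to_csv(path, index=True, float_format="%.17g")
    sidecar = {
        "method": score_table.method,
        "scale_constant": score_table.scale_constant,
        "tail_probs": list(score_table.tail_probs),
        "edge_estimator": EDGE_ESTIMATOR,
        "source_metric": score_table.source_metric,
        "n_participants": score_table.shape[0],
        "n_rois": score_table.shape[1],
        "input_sha256": sha256_of(input_path) if input_path else None,
    }
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return sidecar_path


def read_score_table(path) -> ScoreTable:
    """Round-trip read of a score CSV written by :func:`write_score_table`."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return ScoreTable(
        data=df,
        method=meta.get("method", "pscore"),
        scale_constant=meta.get("scale_constant", 1.645),
        source_metric=meta.get("source_metric", path.stem),
        tail_probs=tuple(meta.get("tail_probs", (5.0, 95.0))),
    )
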