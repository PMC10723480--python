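"""Small-sample reliability assessment by repeated random subsampling.

Draws many random subsamples of the normative cohort (without replacement
within each iteration, e.g. 100 of 960 participants), recomputes the
scores *within each subsample* — medians and percentile edges come from
the subsample itself, not the parent — and audits the extreme-value
balance of each iteration. For tie-free data, percentile deviation scores
keep exactly 5% of values beyond each tail in every iteration (zero
variance across iterations), which is the method's small-sample
robustness claim; Z scores on skewed data do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDistributionError, PscoreError, ValidationError
from .imbalance import ImbalanceRecord, audit_table
from .tables import NORMAL_TAIL_Z, NormativeTable

logger = logging.getLogger(__name__)

__all__ = ["BootstrapResult", "subsample", "bootstrap_audit",
           "iterations_to_frame", "summary_to_frame"]


def _iteration_seed(master_seed: int, iteration: int) -> int:
    """Per-iteration seed: SeedSequence keyed on (master_seed, iteration).

    Iterations are mutually independent streams and each one can be
    re-run in isolation from its (master_seed, iteration) pair.
    """
    return int(np.random.SeedSequence([master_seed, iteration]).generate_state(1)[0])


@dataclass
class BootstrapIteration:
    """One subsampling iteration: its index, seed, and per-method audits."""
    index: int
    seed: int
    records: dict[str, ImbalanceRecord]  # method -> record


@dataclass
class BootstrapResult:
    """All iterations plus the across-iteration mean ± SD tail summary."""

    metric: str
    iterations: list[BootstrapIteration]
    summary: pd.DataFrame  # rows: method; cols: mean/sd of each tail pct
    subsample_size: int
    n_iterations: int
    master_seed: int


def subsample(table: NormativeTable, size: int, seed: int,
              replace: bool = False) -> NormativeTable:
    """Random draw of ``size`` participant rows; deterministic given seed.

    Without replacement by default (repeated subsampling); a
    with-replacement mode exists for methodological comparison with the
    classical bootstrap. All ROI columns are retained.
    """
    n = table.n_participants
    if size < 3:
        raise ValidationError(f"subsample size must be >= 3, got {size}")
    if size > n and not replace:
        raise ValidationError(f"subsample size must be <= {n} without replacement, got {size}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=size, replace=replace)
    sub = table.data.iloc[idx]
    if replace and sub.index.has_duplicates:
        # keep IDs unique under resampling so the table validates
        sub = sub.set_axis(
            [f"{pid}#{k}" for k, pid in enumerate(sub.index)], axis=0)
        sub.index.name = "participant_id"
    return NormativeTable(sub, metric_name=table.metric_name)


def bootstrap_audit(table: NormativeTable, size: int = 100,
                    n_iterations: int = 100, master_seed: int = 0,
                    methods: tuple[str, ...] = ("zscore", "pscore"),
                    threshold: float = NORMAL_TAIL_Z,
                    replace: bool = False) -> BootstrapResult:
    """Repeat the score-vs-score tail audit on random subsamples.

    Each iteration draws ``size`` participants (seed derived from
    ``master_seed`` and the iteration index), rescores the subsample
    against its own medians/edges, and records each method's tail counts.
    Results are bit-reproducible given (master_seed, size, n_iterations).

    Raises
    ------
    DegenerateDistributionError
        If a subsample column degenerates; the error names the iteration,
        seed and ROI so the draw can be reproduced.
    """
    if n_iterations < 1:
        raise ValidationError(f"n_iterations must be >= 1, got {n_iterations}")
    iterations: list[BootstrapIteration] = []
    for it in range(n_iterations):
        seed = _iteration_seed(master_seed, it)
        sub = subsample(table, size, seed, replace=replace)
        records = {}
        for method in methods:
            try:
                records[method] = audit_table(sub, method, threshold=threshold)
            except DegenerateDistributionError as err:
                raise DegenerateDistributionError(
                    f"iteration {it} (seed {seed}): {err}", roi_label=err.roi_label
                ) from err
        iterations.append(BootstrapIteration(index=it, seed=seed, records=records))

    rows = []
    for method in methods:
        gt = np.array([i.records[method].pev_gt95 for i in iterations])
        lt = np.array([i.records[method].pev_lt5 for i in iterations])
        rows.append({
            "method": method,
            "mean_pev_gt95": gt.mean(), "sd_pev_gt95": gt.std(ddof=1) if len(gt) > 1 else 0.0,
            "mean_pev_lt5": lt.mean(), "sd_pev_lt5": lt.std(ddof=1) if len(lt) > 1 else 0.0,
        })
    summary = pd.DataFrame(rows).set_index("method")
    return BootstrapResult(metric=table.metric_name, iterations=iterations,
                           summary=summary, subsample_size=size,
                           n_iterations=n_iterations, master_seed=master_seed)


def iterations_to_frame(result: BootstrapResult) -> pd.DataFrame:
    """Long-format iteration table (one row per iteration × method)."""
    rows = []
    for it in result.iterations:
        for method, r in it.records.items():
            rows.append({
                "metric": result.metric, "iteration": it.index, "seed": it.seed,
                "method": "Zscore" if method == "zscore" else "Pscore",
                "NEV>95": r.nev_gt95, "NEV<5": r.nev_lt5, "NTotal": r.n_total,
                "PEV>95(%)": r.pev_gt95, "PEV<5(%)": r.pev_lt5,
            })
    return pd.DataFrame(rows)


def summary_to_frame(result: BootstrapResult) -> pd.DataFrame:
    """Mean ± SD summary with run metadata columns."""
    df = result.summary.reset_index()
    df.insert(0, "metric", result.metric)
    df["subsample_size"] = result.subsample_size
    df["n_iterations"] = result.n_iterations
    df["master_seed"] = result.master_seed
    return df
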