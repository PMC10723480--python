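"""Run configuration and heatmap binning, validated before any computation."""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .exceptions import ValidationError

__all__ = ["HeatmapBinning", "RunConfig"]

DEFAULT_HEATMAP_EDGES = (1.0, 1.65, 2.0, 2.5, 3.0)


class HeatmapBinning(BaseModel):
    """Symmetric discrete score bins for participant × ROI heatmaps.

    ``positive_edges`` lists the cut points above 0; the negative side is
    mirrored. Positive bins are left-open/right-closed — a score of
    exactly 1.65 falls in the ``1 < Z <= 1.65`` bin — and the negative
    side mirrors that (right-open/left-closed), so the map is symmetric
    under score negation. The outermost bins are unbounded.
    """

    positive_edges: tuple[float, ...] = DEFAULT_HEATMAP_EDGES

    @field_validator("positive_edges")
    @classmethod
    def _ordered(cls, v):
        if len(v) < 1 or any(b <= a for a, b in zip(v, v[1:])) or v[0] <= 0:
            raise ValueError(f"edges must be strictly increasing and > 0, got {v}")
        return v

    @property
    def full_edges(self) -> np.ndarray:
        """All cut points, symmetric about 0: [-inf, ..., -e1, 0, e1, ..., inf]."""
        pos = np.asarray(self.positive_edges)
        return np.concatenate([[-np.inf], -pos[::-1], [0.0], pos, [np.inf]])

    def bin_index(self, scores: np.ndarray) -> np.ndarray:
        """Map scores to integer bin codes, symmetric about the central pair.

        Codes run from most-negative bin (0) to most-positive
        (``2 * len(positive_edges) + 1``). The convention is right-closed
        on the positive side and mirrored below zero.
        """
        s = np.asarray(scores, dtype=float)
        k = len(self.positive_edges)
        pos_edges = np.asarray(self.positive_edges)
        # positive side: (0, e1], (e1, e2], ..., (ek, inf)
        idx = np.empty(s.shape, dtype=int)
        abs_s = np.abs(s)
        # side='left' makes x == edge fall into the bin the edge closes
        band = np.searchsorted(pos_edges, abs_s, side="left")
        idx = np.where(s >= 0, k + 1 + band, k - band)
        # scores exactly 0 belong to the first positive band (0, e1] closure
        return idx

    def labels(self) -> list[str]:
        """Human-readable interval label per bin code."""
        e = [f"{v:g}" for v in self.positive_edges]
        neg = [f"(-inf, -{e[-1]})"] + [
            f"[-{e[i + 1]}, -{e[i]})" for i in reversed(range(len(e) - 1))
        ] + [f"[-{e[0]}, 0)"]
        pos = [f"[0, {e[0]}]"] + [
            f"({e[i]}, {e[i + 1]}]" for i in range(len(e) - 1)
        ] + [f"({e[-1]}, inf)"]
        return neg + pos


class RunConfig(BaseModel):
    """Validated configuration for a scoring/audit run.

    Recorded verbatim into every output manifest so results are
    reproducible from the manifest alone.
    """

    inputs: list[str] = Field(default_factory=list)
    layout: Literal["wide", "long"] = "wide"
    methods: list[Literal["pscore", "zscore", "log", "percentile_rank"]] = \
        Field(default_factory=lambda: ["pscore", "zscore"])
    scale_constant: float = 1.645
    tail_probs: tuple[float, float] = (5.0, 95.0)
    threshold: float = 1.645
    bootstrap_size: int = 100
    bootstrap_iterations: int = 100
    master_seed: int = 0
    out_dir: str = "."
    strict: bool = False
    figures: bool = False

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.tail_probs
        if not (0 < lo < 50 < hi < 100):
            raise ValueError(f"tail_probs must satisfy 0 < lo < 50 < hi < 100, got {self.tail_probs}")
        if self.scale_constant <= 0 or self.threshold <= 0:
            raise ValueError("scale_constant and threshold must be > 0")
        if self.bootstrap_size < 3 or self.bootstrap_iterations < 1:
            raise ValueError("bootstrap_size >= 3 and bootstrap_iterations >= 1 required")
        return self


def validate_config(data: dict) -> RunConfig:
    """Parse and validate a config mapping, raising ValidationError on failure."""
    try:
        return RunConfig.model_validate(data)
    except Exception as err:  # pydantic.ValidationError
        raise ValidationError(f"invalid run configuration: {err}") from err
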