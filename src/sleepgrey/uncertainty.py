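"""Hypnodensity-to-uncertainty mapping.

Each metric maps a probability row p = (p1, ..., p5) over the five sleep
stages to a scalar in [0, 1] where 0 means full confidence (a one-hot row)
and larger values mean more uncertainty.  With p(1) the largest entry and
p(2) the largest entry over the remaining stage indices (so an exact k-way
tie at the top gives p(2) = p(1)), and n = 5 stages:

* least confidence      U_L = (1 - p(1)) * n / (n - 1)
* margin of confidence  U_M = 1 - (p(1) - p(2))
* ratio of confidence   U_R = p(2) / p(1)
* unalikeability        U_U = 1 - sum_i p_i^2
* classification entropy U_E = -sum_i p_i log2 p_i / log2 n   (0 log 0 = 0)

The ratio is conventionally quoted as p(1)/p(2), which is unbounded and
*decreases* with uncertainty; it is stored here as its reciprocal so all
five metrics share the same orientation and a [0, 1] range.  The transform
is strictly order-reversing, so rankings — and hence every percentile-based
grey-area analysis — are unaffected.

U_U is the coefficient of unalikeability (equivalently the Gini impurity /
one minus the Simpson index); its maximum over 5 categories is 1 - 1/5 = 0.8
at the uniform row, whereas the other four metrics reach 1 there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import EpochGrid, Hypnodensity, N_STAGES, PROB_TOL

__all__ = [
    "UncertaintySeries",
    "least_confidence",
    "margin_confidence",
    "ratio_confidence",
    "unalikeability",
    "entropy",
    "uncertainty_series",
    "METRICS",
]


@dataclass(frozen=True)
class UncertaintySeries:
    """Per-epoch scalar uncertainty under one named metric.

    Values are NaN at UNSCORED-masked epochs; those epochs never take part
    in ranking or thresholding.
    """

    grid: EpochGrid
    values: np.ndarray = field(repr=False)
    metric: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1 or values.shape[0] != self.grid.n_epochs:
            raise ValueError(
                f"values must be 1-D of length {self.grid.n_epochs}, "
                f"got shape {values.shape}"
            )
        object.__setattr__(self, "values", values)

    @property
    def scored(self) -> np.ndarray:
        return np.isfinite(self.values)

    def __len__(self) -> int:
        return self.grid.n_epochs


def _as_rows(p: np.ndarray) -> np.ndarray:
    """Validate a row or matrix of probability vectors."""
    p = np.asarray(p, dtype=np.float64)
    squeeze = p.ndim == 1
    rows = np.atleast_2d(p)
    if rows.shape[1] != N_STAGES:
        raise ValueError(f"expected {N_STAGES} probabilities, got {rows.shape[1]}")
    live = ~np.isnan(rows).all(axis=1)
    if (rows[live] < 0).any() or np.isnan(rows[live]).any():
        raise ValueError("probabilities must be non-negative and finite")
    if (np.abs(rows[live].sum(axis=1) - 1.0) > PROB_TOL).any():
        raise ValueError("probability rows must sum to 1")
    return rows if not squeeze else rows


def _top_two(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    srt = np.sort(rows, axis=1)
    return srt[:, -1], srt[:, -2]


def _lc(rows: np.ndarray) -> np.ndarray:
    p1, _ = _top_two(rows)
    return (1.0 - p1) * N_STAGES / (N_STAGES - 1)


def _margin(rows: np.ndarray) -> np.ndarray:
    p1, p2 = _top_two(rows)
    return 1.0 - (p1 - p2)


def _ratio(rows: np.ndarray) -> np.ndarray:
    p1, p2 = _top_two(rows)
    out = np.zeros(rows.shape[0])
    nz = p1 > 0
    out[nz] = p2[nz] / p1[nz]
    return out


def _unalike(rows: np.ndarray) -> np.ndarray:
    return 1.0 - np.square(rows).sum(axis=1)


def _entropy(rows: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rows > 0, rows * np.log2(rows), 0.0)
    return -terms.sum(axis=1) / np.log2(N_STAGES)


_VECTORIZED: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "least_confidence": _lc,
    "margin": _margin,
    "ratio": _ratio,
    "unalikeability": _unalike,
    "entropy": _entropy,
}

#: Metric names accepted everywhere a metric tag is expected.
METRICS = tuple(_VECTORIZED)


def _scalar(metric: str, p: np.ndarray) -> float:
    rows = _as_rows(np.asarray(p, dtype=np.float64).reshape(1, -1))
    return float(_VECTORIZED[metric](rows)[0])


def least_confidence(p) -> float:
    """U_L = (1 - max p) * n/(n-1); 0 at one-hot, 1 at uniform."""
    return _scalar("least_confidence", p)


def margin_confidence(p) -> float:
    """U_M = 1 - (p(1) - p(2)); 0 at one-hot, 1 at any tied top pair."""
    return _scalar("margin", p)


def ratio_confidence(p) -> float:
    """U_R = p(2)/p(1) (reciprocal of the conventional confidence ratio)."""
    return _scalar("ratio", p)


def unalikeability(p) -> float:
    """U_U = 1 - sum p_i^2; ranges over [0, 0.8] for 5 stages."""
    return _scalar("unalikeability", p)


def entropy(p) -> float:
    """U_E = -sum p_i log2 p_i / log2 n, with 0 log 0 = 0."""
    return _scalar("entropy", p)


def uncertainty_series(hd: Hypnodensity, metric: str) -> UncertaintySeries:
    """Apply one metric row-wise to a hypnodensity.

    UNSCORED-masked epochs (all-NaN rows) yield NaN values, which every
    ranking and masking operation downstream excludes.
    """
    if metric not in _VECTORIZED:
        raise ValueError(f"unknown uncertainty metric {metric!r}; choose from {METRICS}")
    rows = _as_rows(hd.probs)
    values = np.full(rows.shape[0], np.nan)
    live = ~np.isnan(rows).all(axis=1)
    if live.any():
        values[live] = _VECTORIZED[metric](rows[live])
    return UncertaintySeries(hd.grid, values, metric)
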