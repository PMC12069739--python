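"""Domain types and tabular I/O for sleep-staging artifacts.

The package works on three aligned per-epoch series:

* :class:`Hypnogram` — one discrete sleep stage per 30-s epoch;
* :class:`Hypnodensity` — one probability vector over the five scoreable
  stages per epoch, produced either by a classifier ensemble or by the vote
  fractions of a scorer panel;
* :class:`ScorerPanel` — aligned stage labels from several human scorers,
  optionally with per-epoch "uncertain" marks.

All probability matrices use the fixed column order W, N1, N2, N3, REM
(integer codes 0–4).  Epochs that carry no scoreable information are coded
``UNSCORED`` (-1) in hypnograms and as all-NaN rows in hypnodensities; such
epochs are excluded from every metric and every uncertainty ranking.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Stage",
    "UNSCORED",
    "N_STAGES",
    "EPOCH_SECONDS",
    "PROB_TOL",
    "STAGE_LABELS",
    "AlignmentError",
    "EpochGrid",
    "Hypnogram",
    "Hypnodensity",
    "ScorerPanel",
    "check_aligned",
    "read_hypnogram",
    "write_hypnogram",
    "read_hypnodensity",
    "write_hypnodensity",
    "read_scorer_panel",
    "write_scorer_panel",
    "write_report",
    "read_report",
]

#: Number of scoreable sleep stages.
N_STAGES = 5

#: Fixed epoch duration in seconds.
EPOCH_SECONDS = 30.0

#: Tolerance on |sum(p) - 1| below which a probability row is renormalized.
PROB_TOL = 1e-6

#: Integer code for an epoch without a scoreable stage.
UNSCORED = -1


class Stage(IntEnum):
    """Scoreable sleep stages, in canonical column order.

    The integer order doubles as the tie-break priority: when votes or
    probabilities tie exactly, the stage with the *lowest* code wins
    (Wake > N1 > N2 > N3 > REM).
    """

    WAKE = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4


#: Canonical CSV labels, indexed by stage code.
STAGE_LABELS = ("W", "N1", "N2", "N3", "R")

_LABEL_TO_CODE: dict[str, int] = {
    "W": 0,
    "WAKE": 0,
    "N1": 1,
    "N2": 2,
    "N3": 3,
    "R": 4,
    "REM": 4,
    "UNSCORED": UNSCORED,
}


class AlignmentError(ValueError):
    """Raised when two per-epoch series do not share the same epoch grid."""


@dataclass(frozen=True)
class EpochGrid:
    """A uniform 30-second epoch grid.

    Epoch ``i`` covers the half-open interval
    ``[start_time_s + 30 i, start_time_s + 30 (i + 1))``.
    """

    n_epochs: int
    start_time_s: float = 0.0
    epoch_duration_s: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        if self.n_epochs < 0:
            raise ValueError(f"n_epochs must be >= 0, got {self.n_epochs}")
        if self.epoch_duration_s != EPOCH_SECONDS:
            raise ValueError(
                f"epoch_duration_s is fixed at {EPOCH_SECONDS}, "
                f"got {self.epoch_duration_s}"
            )

    def epoch_start(self, i: int) -> float:
        return self.start_time_s + self.epoch_duration_s * i


def check_aligned(*objs: "Hypnogram | Hypnodensity | ScorerPanel") -> EpochGrid:
    """Assert that all arguments share one epoch grid; return it.

    Misalignment is always an error — series are never silently truncated.
    """
    grids = {o.grid for o in objs}
    if len(grids) > 1:
        raise AlignmentError(f"epoch grids differ: {sorted(g.n_epochs for g in grids)}")
    return objs[0].grid


@dataclass(frozen=True)
class Hypnogram:
    """A per-epoch sequence of stage codes (0–4, or ``UNSCORED``)."""

    grid: EpochGrid
    stages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        stages = np.asarray(self.stages, dtype=np.int8)
        if stages.ndim != 1 or stages.shape[0] != self.grid.n_epochs:
            raise ValueError(
                f"stages must be 1-D of length {self.grid.n_epochs}, "
                f"got shape {stages.shape}"
            )
        valid = ((stages >= 0) & (stages < N_STAGES)) | (stages == UNSCORED)
        if not valid.all():
            bad = int(np.flatnonzero(~valid)[0])
            raise ValueError(f"invalid stage code {stages[bad]} at epoch {bad}")
        object.__setattr__(self, "stages", stages)

    @property
    def scored(self) -> np.ndarray:
        """Boolean mask of epochs that carry a scoreable stage."""
        return self.stages != UNSCORED

    def __len__(self) -> int:
        return self.grid.n_epochs


def _validate_probs(probs: np.ndarray, tol: float = PROB_TOL) -> np.ndarray:
    """Validate and renormalize an (n, 5) probability matrix.

    Rows that are entirely NaN are passed through untouched (UNSCORED mask);
    every other row must be non-negative and sum to 1 within *tol*, and is
    renormalized to sum to 1 exactly.
    """
    probs = np.array(probs, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[1] != N_STAGES:
        raise ValueError(f"probs must have shape (n, {N_STAGES}), got {probs.shape}")
    masked = np.isnan(probs).all(axis=1)
    live = ~masked
    if np.isnan(probs[live]).any():
        bad = int(np.flatnonzero(live & np.isnan(probs).any(axis=1))[0])
        raise ValueError(f"partially NaN probability row at epoch {bad}")
    if (probs[live] < 0).any():
        bad = int(np.flatnonzero(live & (probs < 0).any(axis=1))[0])
        raise ValueError(f"negative probability at epoch {bad}")
    sums = probs[live].sum(axis=1)
    off = np.abs(sums - 1.0) > tol
    if off.any():
        bad = int(np.flatnonzero(live)[np.flatnonzero(off)[0]])
        raise ValueError(
            f"probability row at epoch {bad} sums to "
            f"{probs[bad].sum():.9f}, outside 1 +/- {tol}"
        )
    probs[live] = probs[live] / sums[:, None]
    return probs


@dataclass(frozen=True)
class Hypnodensity:
    """Per-epoch probability distributions over the five stages.

    ``source`` records whether the rows came from a model ensemble
    (``"model"``) or from scorer vote fractions (``"scorer_panel"``).
    All-NaN rows mark UNSCORED epochs.
    """

    grid: EpochGrid
    probs: np.ndarray = field(repr=False)
    source: str = "model"

    def __post_init__(self) -> None:
        if self.source not in ("model", "scorer_panel"):
            raise ValueError(f"unknown hypnodensity source {self.source!r}")
        probs = _validate_probs(self.probs)
        if probs.shape[0] != self.grid.n_epochs:
            raise AlignmentError(
                f"probs has {probs.shape[0]} rows for a grid of "
                f"{self.grid.n_epochs} epochs"
            )
        object.__setattr__(self, "probs", probs)

    @property
    def scored(self) -> np.ndarray:
        return ~np.isnan(self.probs).all(axis=1)

    def __len__(self) -> int:
        return self.grid.n_epochs


@dataclass(frozen=True)
class ScorerPanel:
    """Aligned stage labels from S scorers, with optional uncertain marks.

    Scorers may mark an epoch as uncertain while still assigning their most
    likely stage; marks never change the vote, they only drive stratified
    analyses downstream.
    """

    grid: EpochGrid
    labels: np.ndarray = field(repr=False)
    uncertain_marks: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        if labels.ndim != 2 or labels.shape[0] != self.grid.n_epochs:
            raise ValueError(
                f"labels must be (n_epochs, S), got shape {labels.shape}"
            )
        if labels.shape[1] < 1:
            raise ValueError("a scorer panel needs at least one scorer")
        valid = ((labels >= 0) & (labels < N_STAGES)) | (labels == UNSCORED)
        if not valid.all():
            raise ValueError("panel contains invalid stage codes")
        object.__setattr__(self, "labels", labels)
        marks = self.uncertain_marks
        if marks is None:
            marks = np.zeros_like(labels, dtype=bool)
        else:
            marks = np.asarray(marks, dtype=bool)
            if marks.shape != labels.shape:
                raise ValueError(
                    f"uncertain_marks shape {marks.shape} != labels shape "
                    f"{labels.shape}"
                )
        object.__setattr__(self, "uncertain_marks", marks)

    @property
    def n_scorers(self) -> int:
        return self.labels.shape[1]

    def __len__(self) -> int:
        return self.grid.n_epochs


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def _stage_to_code(label: str, where: str) -> int:
    code = _LABEL_TO_CODE.get(str(label).strip().upper())
    if code is None:
        warnings.warn(
            f"unknown stage label {label!r} in {where}; mapping to UNSCORED",
            stacklevel=3,
        )
        return UNSCORED
    return code


def read_hypnogram(path: str | Path, dialect: str = "csv") -> Hypnogram:
    """Read a hypnogram CSV with header ``epoch,stage``.

    Stage labels are W, N1, N2, N3, R (or UNSCORED); unknown labels map to
    UNSCORED with a warning.
    """
    if dialect != "csv":
        raise ValueError(f"unknown hypnogram dialect {dialect!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"stage": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty hypnogram file: {path}") from None
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed hypnogram CSV {path}: {exc}") from exc
    if not {"epoch", "stage"} <= set(df.columns):
        raise ValueError(f"{path}: expected header 'epoch,stage', got {list(df.columns)}")
    if len(df) == 0:
        raise ValueError(f"empty hypnogram file: {path}")
    codes = np.array(
        [_stage_to_code(s, f"{path} line {i + 2}") for i, s in enumerate(df["stage"])],
        dtype=np.int8,
    )
    return Hypnogram(EpochGrid(len(codes)), codes)


def write_hypnogram(hg: Hypnogram, path: str | Path) -> None:
    labels = [
        STAGE_LABELS[s] if s != UNSCORED else "UNSCORED" for s in hg.stages
    ]
    pd.DataFrame({"epoch": np.arange(len(hg)), "stage": labels}).to_csv(
        path, index=False
    )


_PROB_COLS = ["pW", "pN1", "pN2", "pN3", "pR"]


def read_hypnodensity(path: str | Path, source: str = "model") -> Hypnodensity:
    """Read a hypnodensity CSV with header ``epoch,pW,pN1,pN2,pN3,pR``.

    Rows are renormalized when their sum is within 1e-6 of 1; anything
    further off, or any negative entry, raises with the epoch index.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty hypnodensity file: {path}") from None
    if not set(_PROB_COLS) <= set(df.columns):
        raise ValueError(
            f"{path}: expected probability columns {_PROB_COLS}, got {list(df.columns)}"
        )
    if len(df) == 0:
        raise ValueError(f"empty hypnodensity file: {path}")
    probs = df[_PROB_COLS].to_numpy(dtype=np.float64)
    return Hypnodensity(EpochGrid(len(df)), probs, source=source)


def write_hypnodensity(hd: Hypnodensity, path: str | Path) -> None:
    """Write a hypnodensity CSV; probabilities round-trip to < 1e-12."""
    df = pd.DataFrame(hd.probs, columns=_PROB_COLS)
    df.insert(0, "epoch", np.arange(len(hd)))
    df.to_csv(path, index=False, float_format="%.17g")


def read_scorer_panel(path: str | Path) -> ScorerPanel:
    """Read a panel CSV: ``epoch,scorer_1,...,scorer_S[,unc_1,...,unc_S]``."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty panel file: {path}") from None
    scorer_cols = [c for c in df.columns if c.startswith("scorer_")]
    unc_cols = [c for c in df.columns if c.startswith("unc_")]
    if not scorer_cols:
        raise ValueError(f"{path}: no scorer_* columns found")
    if len(df) == 0:
        raise ValueError(f"empty panel file: {path}")
    labels = np.empty((len(df), len(scorer_cols)), dtype=np.int8)
    for j, col in enumerate(scorer_cols):
        labels[:, j] = [
            _stage_to_code(s, f"{path} column {col} line {i + 2}")
            for i, s in enumerate(df[col].astype(str))
        ]
    marks = None
    if unc_cols:
        if len(unc_cols) != len(scorer_cols):
            raise ValueError(
                f"{path}: {len(unc_cols)} unc_* columns for "
                f"{len(scorer_cols)} scorers"
            )
        marks = df[unc_cols].to_numpy(dtype=np.int64).astype(bool)
    return ScorerPanel(EpochGrid(len(df)), labels, marks)


def write_scorer_panel(panel: ScorerPanel, path: str | Path) -> None:
    data: dict[str, Any] = {"epoch": np.arange(len(panel))}
    for j in range(panel.n_scorers):
        data[f"scorer_{j + 1}"] = [
            STAGE_LABELS[s] if s != UNSCORED else "UNSCORED"
            for s in panel.labels[:, j]
        ]
    if panel.uncertain_marks.any():
        for j in range(panel.n_scorers):
            data[f"unc_{j + 1}"] = panel.uncertain_marks[:, j].astype(int)
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JSON report
# ---------------------------------------------------------------------------

_REPORT_KEYS = ("config", "performance", "curves", "agreement", "seed")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_report(results: Mapping[str, Any], path: str | Path) -> None:
    """Write a machine-readable JSON report.

    Top-level keys are ``config``, ``performance``, ``curves``,
    ``agreement`` and ``seed``; sections absent from *results* are emitted
    empty so every report has the same shape.  NaN values are serialized as
    JSON null.
    """
    report: dict[str, Any] = {k: {} for k in _REPORT_KEYS}
    report["seed"] = None
    for k, v in results.items():
        report[str(k)] = _jsonable(v)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, allow_nan=False)
        fh.write("\n")


def read_report(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)
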