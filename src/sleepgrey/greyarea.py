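"""Grey-area flagging: mark epochs whose uncertainty warrants manual review.

Two strategies are supported, mirroring the two ways a human-in-the-loop
workflow can budget reviewer time:

* **threshold** — flag every epoch whose uncertainty strictly exceeds a
  fixed value (e.g. unalikeability > 0.6).  The number of flagged epochs
  then varies per recording with scoring difficulty and model calibration.
* **percentile** — flag exactly ``floor(f * N_scored)`` epochs, the most
  uncertain by rank pooled over the whole dataset (optionally per
  recording), so the review budget is fixed regardless of difficulty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import EpochGrid
from .uncertainty import UncertaintySeries

__all__ = ["GreyAreaMask", "threshold_mask", "percentile_mask"]


@dataclass(frozen=True)
class GreyAreaMask:
    """Per-epoch review flags plus the strategy/parameter that made them.

    ``flags`` is False wherever the epoch is not scored; ``scored`` records
    which epochs took part at all, so prevalence is computed over scored
    epochs only.
    """

    grid: EpochGrid
    flags: np.ndarray = field(repr=False)
    strategy: str = "threshold"
    parameter: float = 0.0
    scored: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags, dtype=bool)
        if flags.ndim != 1 or flags.shape[0] != self.grid.n_epochs:
            raise ValueError(
                f"flags must be 1-D of length {self.grid.n_epochs}, got {flags.shape}"
            )
        if self.strategy not in ("threshold", "percentile"):
            raise ValueError(f"unknown grey-area strategy {self.strategy!r}")
        object.__setattr__(self, "flags", flags)
        scored = self.scored
        scored = np.ones_like(flags) if scored is None else np.asarray(scored, bool)
        if scored.shape != flags.shape:
            raise ValueError("scored mask must match flags in shape")
        if (flags & ~scored).any():
            raise ValueError("flags may only be set on scored epochs")
        object.__setattr__(self, "scored", scored)

    @property
    def fraction_flagged(self) -> float:
        """Flagged fraction of scored epochs (NaN for zero scored epochs)."""
        n = int(self.scored.sum())
        return float(self.flags.sum() / n) if n else float("nan")

    def __len__(self) -> int:
        return self.grid.n_epochs


def threshold_mask(u: UncertaintySeries, threshold: float) -> GreyAreaMask:
    """Flag epochs with uncertainty strictly greater than *threshold*.

    The comparison is strict: an epoch exactly at the threshold is not a
    grey area.  Unscored (NaN) epochs are never flagged.
    """
    values = u.values
    flags = np.zeros(len(u), dtype=bool)
    scored = u.scored
    flags[scored] = values[scored] > threshold
    return GreyAreaMask(u.grid, flags, "threshold", float(threshold), scored)


def percentile_mask(
    series: UncertaintySeries | Sequence[UncertaintySeries],
    fraction: float,
    per_recording: bool = False,
) -> GreyAreaMask | list[GreyAreaMask]:
    """Flag the most-uncertain ``floor(fraction * N_scored)`` epochs.

    *series* may be a single recording or a sequence of recordings whose
    uncertainty values are pooled into one dataset-wide ranking (the
    default).  With ``per_recording=True`` each recording is ranked and
    budgeted on its own instead.  Ties at the cut are broken by
    (recording index, epoch index) ascending, so the mask is deterministic.
    Masks are nested in *fraction*: a smaller budget is always a subset of
    a larger one.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    single = isinstance(series, UncertaintySeries)
    series_list = [series] if single else list(series)
    if len(series_list) == 0:
        raise ValueError("percentile_mask needs at least one uncertainty series")

    if per_recording and not single:
        return [percentile_mask(s, fraction) for s in series_list]

    rec_idx = np.concatenate(
        [np.full(len(s), r, dtype=np.int64) for r, s in enumerate(series_list)]
    )
    epoch_idx = np.concatenate(
        [np.arange(len(s), dtype=np.int64) for s in series_list]
    )
    values = np.concatenate([s.values for s in series_list])
    scored = np.isfinite(values)
    n_scored = int(scored.sum())
    if n_scored == 0:
        raise ValueError("no scored epochs to rank")
    k = int(np.floor(fraction * n_scored))

    flat_flags = np.zeros(values.size, dtype=bool)
    if k > 0:
        pool = np.flatnonzero(scored)
        # primary: value descending; then recording, then epoch ascending
        order = np.lexsort((epoch_idx[pool], rec_idx[pool], -values[pool]))
        flat_flags[pool[order[:k]]] = True

    masks: list[GreyAreaMask] = []
    offset = 0
    for s in series_list:
        n = len(s)
        masks.append(
            GreyAreaMask(
                s.grid,
                flat_flags[offset : offset + n],
                "percentile",
                float(fraction),
                s.scored,
            )
        )
        offset += n
    return masks[0] if single else masks
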