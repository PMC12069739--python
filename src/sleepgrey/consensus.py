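"""Multi-scorer consensus: vote-fraction hypnodensities and majority scores.

A panel of S scorers induces a hypnodensity directly: the probability of a
stage at an epoch is the fraction of (scoreable) votes it received.  The
majority score is the modal stage per epoch; exact ties among top-count
stages are broken by the fixed priority Wake > N1 > N2 > N3 > REM, the same
convention used for probability ties everywhere in this package, so
``majority_score(panel)`` always agrees with
``to_hypnogram(panel_to_hypnodensity(panel))``.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import Hypnodensity, Hypnogram, N_STAGES, ScorerPanel, UNSCORED

__all__ = ["vote_counts", "panel_to_hypnodensity", "majority_score", "uncertain_any"]


def vote_counts(panel: ScorerPanel) -> np.ndarray:
    """Per-epoch vote counts over the five stages, ignoring UNSCORED labels."""
    counts = np.empty((len(panel), N_STAGES), dtype=np.int64)
    for s in range(N_STAGES):
        counts[:, s] = (panel.labels == s).sum(axis=1)
    return counts


def panel_to_hypnodensity(panel: ScorerPanel) -> Hypnodensity:
    """Vote fractions as a hypnodensity (source ``"scorer_panel"``).

    An epoch where every scorer left the stage unscored has no votes to
    normalize; it becomes an UNSCORED-masked (all-NaN) row, with a warning.
    """
    counts = vote_counts(panel)
    n_valid = counts.sum(axis=1)
    probs = np.full((len(panel), N_STAGES), np.nan)
    live = n_valid > 0
    probs[live] = counts[live] / n_valid[live, None]
    if not live.all():
        warnings.warn(
            f"{int((~live).sum())} epoch(s) have no scoreable votes; "
            "masked as UNSCORED",
            stacklevel=2,
        )
    return Hypnodensity(panel.grid, probs, source="scorer_panel")


def majority_score(panel: ScorerPanel) -> tuple[Hypnogram, np.ndarray]:
    """Modal stage per epoch, plus a per-epoch tie indicator.

    Ties among the stages sharing the maximal vote count are broken by the
    priority order Wake > N1 > N2 > N3 > REM (lowest stage code wins).  An
    epoch is flagged tied iff >= 2 stages share the maximal count.  Epochs
    with no scoreable votes are UNSCORED and not flagged.
    """
    counts = vote_counts(panel)
    n_valid = counts.sum(axis=1)
    # argmax returns the first (lowest-code = highest-priority) maximal stage
    modal = counts.argmax(axis=1).astype(np.int8)
    top = counts.max(axis=1)
    tied = (counts == top[:, None]).sum(axis=1) >= 2
    dead = n_valid == 0
    modal[dead] = UNSCORED
    tied[dead] = False
    return Hypnogram(panel.grid, modal), tied


def uncertain_any(panel: ScorerPanel) -> np.ndarray:
    """True at epochs at least one scorer marked as uncertain."""
    return panel.uncertain_marks.any(axis=1)
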