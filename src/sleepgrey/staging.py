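"""Channel-wise staging, ensemble averaging, and the reference classifier.

Any per-epoch classifier can drive the pipeline: either a plain callable
mapping one epoch block to a 5-vector of stage probabilities, or an object
with a scikit-learn-style ``predict_proba`` over a stack of blocks.  Each
channel is scored independently; the per-channel hypnodensities are then
averaged element-wise (an unweighted ensemble over channels) and the final
hypnogram takes the most probable stage per epoch, with exact probability
ties broken by the stage priority Wake > N1 > N2 > N3 > REM.

The bundled :class:`BandPowerStagingClassifier` is a deliberately simple,
deterministic, CPU-trainable model — log spectral band powers fed to a
multinomial logistic regression.  It exists to exercise the full pipeline
end-to-end at desk scale and makes no claim to clinical staging accuracy;
any stronger model that satisfies the same contract can be dropped in.
"""

from __future__ import annotations

from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .core import (
    EpochGrid,
    Hypnodensity,
    Hypnogram,
    N_STAGES,
    PROB_TOL,
    UNSCORED,
    check_aligned,
)

__all__ = [
    "EpochClassifier",
    "BandPowerStagingClassifier",
    "BANDS",
    "predict_channel",
    "ensemble_average",
    "to_hypnogram",
    "fit_reference_classifier",
]

#: Spectral bands (Hz) used by the reference classifier's features:
#: delta, theta, alpha, sigma, beta.
BANDS = ((0.5, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 16.0), (16.0, 32.0))


@runtime_checkable
class EpochClassifier(Protocol):
    """Contract for pluggable staging models."""

    def predict_proba(self, blocks: np.ndarray) -> np.ndarray:
        """Map ``(n_epochs, samples_per_epoch)`` blocks to ``(n_epochs, 5)``
        stage probabilities."""
        ...


def log_band_powers(blocks: np.ndarray, fs: float) -> np.ndarray:
    """Log10 power per spectral band per epoch block.

    Periodogram powers are summed within each of the five classic EEG bands
    (delta/theta/alpha/sigma/beta); the log makes the features approximately
    additive in gain, so IQR-normalized inputs behave well.
    """
    blocks = np.asarray(blocks, dtype=np.float64)
    if blocks.ndim != 2:
        raise ValueError(f"blocks must be (n_epochs, n_samples), got {blocks.shape}")
    n = blocks.shape[1]
    spec = np.abs(np.fft.rfft(blocks, axis=1)) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    feats = np.empty((blocks.shape[0], len(BANDS)))
    for j, (lo, hi) in enumerate(BANDS):
        sel = (freqs >= lo) & (freqs < hi)
        feats[:, j] = spec[:, sel].sum(axis=1)
    return np.log10(feats + 1e-12)


class BandPowerStagingClassifier(ClassifierMixin, BaseEstimator):
    """Desk-scale reference staging model: log band powers -> softmax.

    Parameters
    ----------
    fs : float
        Sampling rate of the epoch blocks, Hz.
    C : float
        Inverse regularization strength of the logistic layer.
    max_iter : int
        L-BFGS iteration budget.
    random_state : int or None
        Seed; the fit is deterministic given seed and data.

    Attributes
    ----------
    classes_ : ndarray
        Stage codes seen in training.
    pipeline_ : sklearn Pipeline
        Fitted scaler + multinomial logistic regression.
    """

    def __init__(
        self,
        fs: float = 64.0,
        C: float = 1.0,
        max_iter: int = 500,
        random_state: int | None = None,
    ):
        self.fs = fs
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BandPowerStagingClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_epochs, n_samples) aligned with y")
        keep = y != UNSCORED
        X, y = X[keep], y[keep]
        if np.unique(y).size < 2:
            raise ValueError(
                "training data must contain at least two distinct sleep stages"
            )
        feats = log_band_powers(X, self.fs)
        self.pipeline_ = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "logreg",
                    LogisticRegression(
                        C=self.C,
                        max_iter=self.max_iter,
                        random_state=self.random_state,
                    ),
                ),
            ]
        )
        self.pipeline_.fit(feats, y)
        self.classes_ = self.pipeline_.named_steps["logreg"].classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probabilities over all 5 stages (zeros for stages unseen in training)."""
        check_is_fitted(self, "pipeline_")
        feats = log_band_powers(np.asarray(X, dtype=np.float64), self.fs)
        raw = self.pipeline_.predict_proba(feats)
        out = np.zeros((raw.shape[0], N_STAGES))
        out[:, np.asarray(self.classes_, dtype=int)] = raw
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def fit_reference_classifier(
    blocks: np.ndarray, stages: np.ndarray, fs: float = 64.0, seed: int = 0
) -> BandPowerStagingClassifier:
    """Fit the bundled reference classifier on labelled epoch blocks."""
    return BandPowerStagingClassifier(fs=fs, random_state=seed).fit(blocks, stages)


def predict_channel(
    clf: EpochClassifier | Callable[[np.ndarray], np.ndarray],
    blocks: np.ndarray,
) -> Hypnodensity:
    """Score one channel's epoch blocks into a hypnodensity.

    Every output row must be a valid probability vector to 1e-6 (rows are
    renormalized); a violation raises naming the offending epoch.
    """
    blocks = np.asarray(blocks, dtype=np.float64)
    if blocks.ndim != 2 or blocks.shape[0] == 0:
        raise ValueError("blocks must be a nonempty (n_epochs, n_samples) array")
    if hasattr(clf, "predict_proba"):
        probs = np.asarray(clf.predict_proba(blocks), dtype=np.float64)
    else:
        probs = np.asarray([clf(b) for b in blocks], dtype=np.float64)
    if probs.shape != (blocks.shape[0], N_STAGES):
        raise ValueError(
            f"classifier returned shape {probs.shape}, "
            f"expected ({blocks.shape[0]}, {N_STAGES})"
        )
    bad = (probs < 0).any(axis=1) | (np.abs(probs.sum(axis=1) - 1.0) > PROB_TOL)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"classifier contract violation at epoch {i}: "
            f"row {probs[i]} is not a probability vector"
        )
    return Hypnodensity(EpochGrid(blocks.shape[0]), probs, source="model")


def ensemble_average(per_channel: Sequence[Hypnodensity]) -> Hypnodensity:
    """Unweighted element-wise mean of per-channel hypnodensities.

    All inputs must share one epoch grid; the mean of valid probability rows
    is again a valid probability row (convexity), and the operation is
    invariant to channel order.
    """
    if len(per_channel) == 0:
        raise ValueError("ensemble_average needs at least one hypnodensity")
    check_aligned(*per_channel)
    stacked = np.stack([hd.probs for hd in per_channel])
    return Hypnodensity(per_channel[0].grid, stacked.mean(axis=0), source="model")


def to_hypnogram(hd: Hypnodensity) -> Hypnogram:
    """Most probable stage per epoch; exact ties go to the higher-priority
    stage (W > N1 > N2 > N3 > REM).  UNSCORED-masked rows stay UNSCORED."""
    probs = np.where(np.isnan(hd.probs), -np.inf, hd.probs)
    # argmax takes the first maximal index = highest-priority stage
    stages = probs.argmax(axis=1).astype(np.int8)
    stages[~hd.scored] = UNSCORED
    return Hypnogram(hd.grid, stages)
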