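"""Synthetic sleep-study generator.

Emulates, at desk scale, the data properties the grey-area framework needs
to be exercised end-to-end with no external recordings:

* a night-long hypnogram with realistic stage persistence (first-order
  Markov chain, high self-transition probabilities);
* a panel of human scorers whose disagreement — and whose "uncertain"
  marks — concentrate at epochs adjacent to stage transitions, the place
  real scorers disagree; with ten scorers at the default rates roughly one
  epoch in ten carries a mark from at least one scorer;
* calibrated model hypnodensities: rows are Dirichlet draws centred on the
  true stage whose concentration drops near transitions, so the argmax
  prediction errs exactly where uncertainty metrics read high;
* stage-separable PSG-like signals (coloured noise with stage-dependent
  band-power profiles) to drive preprocessing and the reference classifier.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` child streams (hypnogram=0, panel=1,
model=2, psg=3), so every artifact is bit-reproducible.  The default
transition matrix, scorer confusion kernel and band-power profiles are
shipped as JSON data files alongside this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .core import EpochGrid, Hypnodensity, Hypnogram, N_STAGES, ScorerPanel
from .signal_prep import SignalChannel

__all__ = [
    "SimConfig",
    "default_transition_matrix",
    "default_confusion_kernel",
    "generate_hypnogram",
    "simulate_scorer_panel",
    "simulate_model_hypnodensity",
    "synthesize_psg",
    "transition_adjacent",
]

_STREAM_HYPNOGRAM = 0
_STREAM_PANEL = 1
_STREAM_MODEL = 2
_STREAM_PSG = 3


def _load_data(name: str) -> dict:
    with resources.files("sleepgrey.data").joinpath(name).open() as fh:
        return json.load(fh)


def default_transition_matrix() -> np.ndarray:
    """The shipped 5x5 row-stochastic stage transition matrix."""
    return np.asarray(_load_data("transition_matrix.json")["matrix"], dtype=np.float64)


def default_confusion_kernel() -> np.ndarray:
    """The shipped scorer-error kernel (zero diagonal, rows sum to 1)."""
    return np.asarray(_load_data("confusion_kernel.json")["kernel"], dtype=np.float64)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated recording.

    Parameters
    ----------
    n_epochs : int
        Recording length in 30-s epochs (960 = 8 h).
    transition_matrix : ndarray or None
        5x5 row-stochastic stage dynamics; None loads the shipped default.
    n_scorers : int
        Panel size (10 matches a large multi-centre scoring panel).
    scorer_reliability : float
        Per-epoch probability a scorer reproduces the true stage at a
        stable epoch.
    transition_ambiguity_boost : float
        Multiplier (>= 1) on the scorer error probability and on model
        difficulty at epochs adjacent to a true stage transition.
    model_calibration_temp : float
        Temperature of the simulated model; -> 0 gives one-hot rows at the
        truth, larger values flatten the hypnodensity.
    uncertain_mark_rate : float
        Per-scorer per-epoch probability of an "uncertain" mark at stable
        epochs; at transition-adjacent epochs it is multiplied by
        ``uncertain_transition_mult``.
    uncertain_transition_mult : float
        Elevation of the mark rate near transitions.
    seed : int
        Root seed of all random streams.
    """

    n_epochs: int = 960
    transition_matrix: np.ndarray | None = None
    n_scorers: int = 10
    scorer_reliability: float = 0.85
    transition_ambiguity_boost: float = 3.0
    model_calibration_temp: float = 1.0
    uncertain_mark_rate: float = 0.004
    uncertain_transition_mult: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.n_scorers < 1:
            raise ValueError("n_scorers must be >= 1")
        for name in ("scorer_reliability", "uncertain_mark_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.transition_ambiguity_boost < 1.0:
            raise ValueError("transition_ambiguity_boost must be >= 1")
        if self.model_calibration_temp <= 0:
            raise ValueError("model_calibration_temp must be positive")
        tm = self.transition_matrix
        if tm is not None:
            tm = np.asarray(tm, dtype=np.float64)
            if tm.shape != (N_STAGES, N_STAGES) or (tm < 0).any():
                raise ValueError("transition_matrix must be a non-negative 5x5 matrix")
            if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("transition_matrix rows must sum to 1")
            object.__setattr__(self, "transition_matrix", tm)

    def matrix(self) -> np.ndarray:
        return (
            self.transition_matrix
            if self.transition_matrix is not None
            else default_transition_matrix()
        )

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


def generate_hypnogram(cfg: SimConfig) -> Hypnogram:
    """Sample a first-order Markov hypnogram; starts awake."""
    tm = cfg.matrix()
    rng = cfg._rng(_STREAM_HYPNOGRAM)
    cum = tm.cumsum(axis=1)
    draws = rng.random(cfg.n_epochs)
    stages = np.empty(cfg.n_epochs, dtype=np.int8)
    state = 0  # Wake at lights-off
    for i in range(cfg.n_epochs):
        stages[i] = state
        state = int(np.searchsorted(cum[state], draws[i], side="right"))
        state = min(state, N_STAGES - 1)
    return Hypnogram(EpochGrid(cfg.n_epochs), stages)


def transition_adjacent(truth: Hypnogram) -> np.ndarray:
    """True at epochs whose stage differs from either neighbour's."""
    s = truth.stages
    adj = np.zeros(len(truth), dtype=bool)
    if len(truth) > 1:
        change = s[1:] != s[:-1]
        adj[1:] |= change
        adj[:-1] |= change
    return adj


def simulate_scorer_panel(truth: Hypnogram, cfg: SimConfig) -> ScorerPanel:
    """Simulate S independent scorers of one true hypnogram.

    Each scorer reproduces the true stage with probability r (the
    reliability), otherwise draws a wrong stage from the confusion kernel
    row of the true stage.  At transition-adjacent epochs the error
    probability is multiplied by ``transition_ambiguity_boost`` (capped at
    1), and the uncertain-mark rate is elevated by
    ``uncertain_transition_mult`` — disagreement and marks thus both
    concentrate where real scorers struggle.
    """
    rng = cfg._rng(_STREAM_PANEL)
    kernel = default_confusion_kernel()
    kcum = kernel.cumsum(axis=1)
    n, S = len(truth), cfg.n_scorers
    adj = transition_adjacent(truth)

    err = np.full(n, 1.0 - cfg.scorer_reliability)
    err[adj] = np.minimum(err[adj] * cfg.transition_ambiguity_boost, 1.0)
    mark_rate = np.full(n, cfg.uncertain_mark_rate)
    mark_rate[adj] = np.minimum(
        mark_rate[adj] * cfg.uncertain_transition_mult, 1.0
    )

    labels = np.tile(truth.stages[:, None], (1, S)).astype(np.int8)
    wrong = rng.random((n, S)) < err[:, None]
    if wrong.any():
        rows, cols = np.nonzero(wrong)
        u = rng.random(rows.size)
        picks = np.array(
            [
                np.searchsorted(kcum[truth.stages[r]], x, side="right")
                for r, x in zip(rows, u)
            ],
            dtype=np.int8,
        )
        labels[rows, cols] = np.minimum(picks, N_STAGES - 1)
    marks = rng.random((n, S)) < mark_rate[:, None]
    return ScorerPanel(truth.grid, labels, marks)


def simulate_model_hypnodensity(truth: Hypnogram, cfg: SimConfig) -> Hypnodensity:
    """Calibrated model hypnodensity for a true hypnogram.

    Row i is a Dirichlet draw with concentration
    ``a * onehot(truth_i) + c * kernel_row + b`` where
    ``a = a0 / (temp * difficulty)``; difficulty is 1 at stable epochs and
    ``transition_ambiguity_boost`` next to transitions.  Low difficulty
    gives sharp, almost one-hot rows; high difficulty flattens the row
    toward the plausible confusions, so argmax errors and high uncertainty
    co-occur by construction (confidence correlates with correctness).
    """
    rng = cfg._rng(_STREAM_MODEL)
    kernel = default_confusion_kernel()
    n = len(truth)
    adj = transition_adjacent(truth)
    difficulty = np.where(adj, cfg.transition_ambiguity_boost, 1.0)

    a0, c0, b0 = 5.0, 1.8, 0.30
    a = a0 / (cfg.model_calibration_temp * difficulty)
    alpha = np.full((n, N_STAGES), b0)
    alpha += c0 * difficulty[:, None] * kernel[truth.stages]
    alpha[np.arange(n), truth.stages] += a
    draws = rng.gamma(shape=alpha)
    probs = draws / draws.sum(axis=1, keepdims=True)
    return Hypnodensity(truth.grid, probs, source="model")


def synthesize_psg(
    truth: Hypnogram,
    fs: float = 128.0,
    n_channels: int = 4,
    seed: int = 0,
    channel_gains: np.ndarray | None = None,
    spectral_jitter: float = 0.5,
) -> list[SignalChannel]:
    """Stage-separable PSG-like signals for a true hypnogram.

    Each channel is coloured noise: white noise filtered into the five
    classic EEG bands, with per-epoch band weights and amplitude taken from
    the stage's shipped spectral profile (alpha-dominant wake, theta-heavy
    N1/REM, sigma-weighted N2, delta-dominant N3), plus a small broadband
    floor.  ``spectral_jitter`` is the log-normal sigma of per-epoch band
    weight variability, shared across channels: it makes individual epochs
    spectrally ambiguous (as real epochs are), so a classifier's errors
    concentrate on ambiguous epochs rather than vanishing entirely.
    Channels carry independent noise and individual gains.  Not
    physiologically faithful — spectrally separable by design, which is
    all the reference classifier needs.
    """
    from scipy import signal as sps

    if fs < 64:
        raise ValueError(f"fs must be >= 64 Hz, got {fs}")
    spe = int(round(fs * 30.0))
    profile = _load_data("band_profiles.json")
    bands = profile["bands_hz"]
    weights = np.asarray(profile["weights"], dtype=np.float64)
    scale = np.asarray(profile["amplitude_scale"], dtype=np.float64)
    broadband = float(profile["broadband_level"])

    n = len(truth)
    n_samples = n * spe
    gains = (
        np.ones(n_channels)
        if channel_gains is None
        else np.asarray(channel_gains, dtype=np.float64)
    )
    if gains.shape != (n_channels,):
        raise ValueError("channel_gains must have one entry per channel")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_PSG]))

    stage_idx = truth.stages.astype(int).clip(0)  # UNSCORED epochs synthesized as W
    # per-epoch weight per band, expanded to sample resolution
    w_epoch = weights[stage_idx]  # (n, 5)
    amp_epoch = scale[stage_idx]  # (n,)
    if spectral_jitter > 0:
        w_epoch = w_epoch * rng.lognormal(0.0, spectral_jitter, size=w_epoch.shape)
        w_epoch /= w_epoch.sum(axis=1, keepdims=True)
        amp_epoch = amp_epoch * rng.lognormal(0.0, 0.2, size=n)

    channels = []
    for c in range(n_channels):
        acc = np.zeros(n_samples)
        for j, (lo, hi) in enumerate(bands):
            white = rng.standard_normal(n_samples)
            sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
            band = sps.sosfilt(sos, white)
            band /= band.std() + 1e-12
            env = np.repeat(np.sqrt(w_epoch[:, j]) * amp_epoch, spe)
            acc += band * env
        acc += broadband * rng.standard_normal(n_samples)
        channels.append(
            SignalChannel(acc * gains[c], fs, label=f"synthetic_ch{c + 1}")
        )
    return channels
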