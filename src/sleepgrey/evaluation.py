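"""Staging performance metrics and grey-area validation analyses.

Three analyses quantify whether uncertainty-derived grey areas are worth a
reviewer's time:

* **exclusion curve** — staging performance (accuracy, Cohen's kappa, F1)
  recomputed on the epochs *retained* after excluding the most-uncertain
  fraction f, for a sweep of f.  A rising curve means uncertainty
  concentrates the model's mistakes.
* **confusion capture curve** — the fraction of model-vs-reference
  disagreements that fall inside the grey areas at budget f.  An oracle
  ranking reaches capture 1 as soon as f covers the error rate; an
  uninformative ranking gives capture(f) ~ f.
* **grey-area agreement** — 2x2 confusion between manual-derived and
  model-derived grey-area masks, stratified by whether any scorer marked
  the epoch uncertain.

Per-stage precision/recall/F1 are reported alongside macro (unweighted) and
support-weighted averages; stages with zero reference support are reported
absent and excluded from macro averages with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    confusion_matrix as _sk_confusion,
    precision_recall_fscore_support,
)

from .core import AlignmentError, Hypnogram, N_STAGES, STAGE_LABELS, check_aligned
from .greyarea import GreyAreaMask, percentile_mask
from .uncertainty import UncertaintySeries

__all__ = [
    "StagingMetrics",
    "confusion_matrix",
    "staging_metrics",
    "exclusion_curve",
    "confusion_capture_curve",
    "greyarea_agreement",
    "greyarea_prevalence",
]

_ALL_STAGES = list(range(N_STAGES))


@dataclass(frozen=True)
class StagingMetrics:
    """Epoch-wise agreement bundle between a prediction and a reference.

    ``per_stage`` maps stage label -> dict(precision, recall, f1, support);
    stages with zero reference support are absent.  ``macro_*`` are
    unweighted means over the present stages; ``weighted_f1`` weights by
    reference support.
    """

    accuracy: float
    kappa: float
    per_stage: dict[str, dict[str, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_f1: float
    n_epochs: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "per_stage": self.per_stage,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "n_epochs": self.n_epochs,
        }


def _joint_scored(pred: Hypnogram, ref: Hypnogram) -> np.ndarray:
    check_aligned(pred, ref)
    return pred.scored & ref.scored


def confusion_matrix(pred: Hypnogram, ref: Hypnogram) -> np.ndarray:
    """5x5 count matrix; rows = reference stage, columns = predicted stage.

    Epochs where either side is UNSCORED are excluded, so the cell sum
    equals the number of jointly scored epochs.
    """
    keep = _joint_scored(pred, ref)
    return _sk_confusion(ref.stages[keep], pred.stages[keep], labels=_ALL_STAGES)


def staging_metrics(pred: Hypnogram, ref: Hypnogram) -> StagingMetrics:
    """Accuracy, Cohen's kappa, and per-stage precision/recall/F1.

    Kappa is chance-corrected agreement, (p_o - p_e)/(1 - p_e) with p_e
    from the marginal products.  Raises if no epoch is jointly scored.
    """
    keep = _joint_scored(pred, ref)
    n = int(keep.sum())
    if n == 0:
        raise ValueError("no jointly scored epochs to evaluate")
    y_pred, y_ref = pred.stages[keep], ref.stages[keep]
    acc = float(accuracy_score(y_ref, y_pred))
    kappa = 1.0 if np.array_equal(y_ref, y_pred) else float(
        cohen_kappa_score(y_ref, y_pred, labels=_ALL_STAGES)
    )
    prec, rec, f1, support = precision_recall_fscore_support(
        y_ref, y_pred, labels=_ALL_STAGES, zero_division=0
    )
    present = support > 0
    if not present.all():
        missing = [STAGE_LABELS[i] for i in np.flatnonzero(~present)]
        warnings.warn(
            f"stage(s) {missing} have zero reference support; "
            "excluded from macro averages",
            stacklevel=2,
        )
    per_stage = {
        STAGE_LABELS[i]: {
            "precision": float(prec[i]),
            "recall": float(rec[i]),
            "f1": float(f1[i]),
            "support": int(support[i]),
        }
        for i in np.flatnonzero(present)
    }
    return StagingMetrics(
        accuracy=acc,
        kappa=kappa,
        per_stage=per_stage,
        macro_precision=float(prec[present].mean()),
        macro_recall=float(rec[present].mean()),
        macro_f1=float(f1[present].mean()),
        weighted_f1=float(np.average(f1[present], weights=support[present])),
        n_epochs=n,
    )


def exclusion_curve(
    pred: Hypnogram,
    ref: Hypnogram,
    u: UncertaintySeries,
    fractions: Sequence[float],
) -> list[tuple[float, StagingMetrics | None]]:
    """Retained-set staging performance as grey areas grow.

    For each fraction f, the most-uncertain floor(f * N_scored) epochs are
    excluded and the metric bundle is recomputed on the jointly scored
    remainder.  A fraction that leaves nothing retained yields None.
    The computation is deterministic — no internal randomness.
    """
    check_aligned(pred, ref, u)
    out: list[tuple[float, StagingMetrics | None]] = []
    for f in fractions:
        mask = percentile_mask(u, f)
        retained = ~mask.flags
        sub_pred = Hypnogram(pred.grid, np.where(retained, pred.stages, -1))
        sub_ref = Hypnogram(ref.grid, np.where(retained, ref.stages, -1))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out.append((float(f), staging_metrics(sub_pred, sub_ref)))
        except ValueError:
            out.append((float(f), None))
    return out


def confusion_capture_curve(
    pred: Hypnogram,
    ref: Hypnogram,
    u: UncertaintySeries,
    fractions: Sequence[float],
) -> list[tuple[float, float]]:
    """Fraction of staging disagreements captured inside the grey areas.

    capture(f) = #(disagreeing epochs flagged at budget f) / #disagreeing.
    With zero disagreements the curve is undefined and reported as NaN
    with a warning.
    """
    check_aligned(pred, ref, u)
    joint = _joint_scored(pred, ref)
    disagree = joint & (pred.stages != ref.stages)
    n_dis = int(disagree.sum())
    if n_dis == 0:
        warnings.warn("no disagreements; capture curve is undefined", stacklevel=2)
        return [(float(f), float("nan")) for f in fractions]
    out = []
    for f in fractions:
        mask = percentile_mask(u, f)
        out.append((float(f), float((disagree & mask.flags).sum() / n_dis)))
    return out


def greyarea_agreement(
    manual_mask: GreyAreaMask,
    model_mask: GreyAreaMask,
    split: np.ndarray | None = None,
) -> dict[str, dict]:
    """Agreement between manual- and model-derived grey areas, stratified.

    *split* (typically ``uncertain_any`` of a panel) partitions epochs into
    a "marked" and an "unmarked" stratum; without it a single "all" stratum
    is reported.  Each stratum gets a 2x2 matrix (rows: manual grey yes/no;
    columns: model grey yes/no), the capture (fraction of manual grey
    epochs also flagged by the model), and both prevalences.
    """
    if manual_mask.grid != model_mask.grid:
        raise AlignmentError("grey-area masks are not aligned")
    joint = manual_mask.scored & model_mask.scored
    if split is None:
        strata = {"all": joint}
    else:
        split = np.asarray(split, dtype=bool)
        if split.shape[0] != len(manual_mask):
            raise ValueError("split length does not match the epoch grid")
        strata = {"marked": joint & split, "unmarked": joint & ~split}
    out: dict[str, dict] = {}
    for name, keep in strata.items():
        man = manual_mask.flags[keep]
        mod = model_mask.flags[keep]
        matrix = np.array(
            [
                [int((man & mod).sum()), int((man & ~mod).sum())],
                [int((~man & mod).sum()), int((~man & ~mod).sum())],
            ]
        )
        n_man = int(man.sum())
        out[name] = {
            "matrix": matrix,
            "n_epochs": int(keep.sum()),
            "capture": float(matrix[0, 0] / n_man) if n_man else float("nan"),
            "manual_grey_fraction": float(man.mean()) if keep.any() else float("nan"),
            "model_grey_fraction": float(mod.mean()) if keep.any() else float("nan"),
        }
    return out


def greyarea_prevalence(
    masks: Sequence[GreyAreaMask],
) -> tuple[float, list[float]]:
    """Per-recording flagged fractions and their median.

    Fractions are over scored epochs of each recording.
    """
    if len(masks) == 0:
        raise ValueError("greyarea_prevalence needs at least one mask")
    fractions = [m.fraction_flagged for m in masks]
    return float(np.median(fractions)), fractions
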