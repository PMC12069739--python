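"""Staging metrics and the grey-area validation analyses."""

import numpy as np
import pytest

from sleepgrey import (
    EpochGrid,
    GreyAreaMask,
    Hypnogram,
    UncertaintySeries,
    UNSCORED,
    confusion_capture_curve,
    confusion_matrix,
    exclusion_curve,
    greyarea_agreement,
    greyarea_prevalence,
    staging_metrics,
    threshold_mask,
)
from sleepgrey.core import AlignmentError


def _hg(stages):
    stages = np.asarray(stages, dtype=np.int8)
    return Hypnogram(EpochGrid(len(stages)), stages)


def _u(values):
    values = np.asarray(values, dtype=float)
    return UncertaintySeries(EpochGrid(len(values)), values, "unalikeability")


class TestConfusionMatrix:
    def test_identical_sequences_are_diagonal(self):
        hg = _hg([0, 1, 2, 3, 4, 2, 2])
        m = confusion_matrix(hg, hg)
        assert np.array_equal(m, np.diag([1, 1, 3, 1, 1]))

    def test_single_off_diagonal_cell(self):
        pred = _hg([0, 0, 0])
        ref = _hg([2, 2, 2])
        m = confusion_matrix(pred, ref)
        assert m[2, 0] == 3 and m.sum() == 3

    def test_cell_sum_conservation_with_unscored(self):
        pred = _hg([0, 1, UNSCORED, 2])
        ref = _hg([0, UNSCORED, 2, 2])
        m = confusion_matrix(pred, ref)
        assert m.sum() == 2  # only jointly scored epochs

    def test_grid_mismatch(self):
        with pytest.raises(AlignmentError):
            confusion_matrix(_hg([0, 1]), _hg([0, 1, 2]))


class TestStagingMetrics:
    def test_perfect_agreement(self):
        hg = _hg([0, 1, 2, 3, 4] * 4)
        m = staging_metrics(hg, hg)
        assert m.accuracy == 1.0
        assert m.kappa == 1.0
        assert m.macro_f1 == 1.0

    def test_kappa_one_third_for_2x2_counts(self):
        """Counts [[2,1],[1,2]] between two stages: p_o = 2/3, p_e = 1/2,
        kappa = (2/3 - 1/2) / (1 - 1/2) = 1/3."""
        ref = _hg([0, 0, 0, 1, 1, 1])
        pred = _hg([0, 0, 1, 0, 1, 1])
        m = staging_metrics(pred, ref)
        assert m.kappa == pytest.approx(1 / 3, abs=1e-12)
        assert m.accuracy == pytest.approx(2 / 3)

    def test_f1_harmonic_mean(self):
        # stage 0: precision 0.5 (2 of 4 predicted), recall 1 (2 of 2) -> F1 2/3
        ref = _hg([0, 0, 1, 1, 1, 1])
        pred = _hg([0, 0, 0, 0, 1, 1])
        m = staging_metrics(pred, ref)
        assert m.per_stage["W"]["precision"] == pytest.approx(0.5)
        assert m.per_stage["W"]["recall"] == pytest.approx(1.0)
        assert m.per_stage["W"]["f1"] == pytest.approx(2 / 3)

    def test_zero_support_stage_absent_from_macro_with_warning(self):
        ref = _hg([0, 0, 1, 1])
        pred = _hg([0, 1, 1, 2])
        with pytest.warns(UserWarning, match="zero reference support"):
            m = staging_metrics(pred, ref)
        assert set(m.per_stage) == {"W", "N1"}

    def test_no_jointly_scored_epochs_errors(self):
        with pytest.raises(ValueError):
            staging_metrics(_hg([UNSCORED, 0]), _hg([1, UNSCORED]))

    def test_kappa_near_zero_for_independent_streams(self):
        rng = np.random.default_rng(123)
        a = _hg(rng.integers(0, 5, 10_000))
        b = _hg(rng.integers(0, 5, 10_000))
        m = staging_metrics(a, b)
        assert abs(m.kappa) < 0.03


class TestExclusionCurve:
    def test_zero_fraction_equals_full_metrics(self):
        rng = np.random.default_rng(5)
        ref = _hg(rng.integers(0, 5, 300))
        pred_st = ref.stages.copy()
        pred_st[::7] = (pred_st[::7] + 1) % 5
        pred = _hg(pred_st)
        u = _u(rng.random(300))
        curve = exclusion_curve(pred, ref, u, [0.0])
        full = staging_metrics(pred, ref)
        assert curve[0][1].accuracy == full.accuracy
        assert curve[0][1].kappa == full.kappa

    def test_oracle_uncertainty_reaches_perfect_accuracy(self):
        """When all errors rank strictly above all correct epochs, excluding
        the error-rate fraction removes every error."""
        rng = np.random.default_rng(6)
        ref = _hg(rng.integers(0, 5, 500))
        pred_st = ref.stages.copy()
        err_idx = rng.choice(500, size=100, replace=False)
        pred_st[err_idx] = (pred_st[err_idx] + 1) % 5
        pred = _hg(pred_st)
        u_vals = np.full(500, 0.1)
        u_vals[err_idx] = 0.9
        curve = exclusion_curve(pred, ref, _u(u_vals), [0.2, 0.5])
        assert curve[0][1].accuracy == 1.0
        assert curve[1][1].accuracy == 1.0

    def test_uninformative_uncertainty_leaves_accuracy_flat(self):
        """Uncertainty independent of errors: retained accuracy stays within
        2 percentage points over f in [0, 0.5]."""
        rng = np.random.default_rng(7)
        n = 10_000
        ref = _hg(rng.integers(0, 5, n))
        pred_st = ref.stages.copy()
        flip = rng.random(n) < 0.2
        pred_st[flip] = (pred_st[flip] + rng.integers(1, 5, n)[flip]) % 5
        pred = _hg(pred_st)
        u = _u(rng.random(n))  # independent of errors
        fractions = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
        curve = exclusion_curve(pred, ref, u, fractions)
        accs = [m.accuracy for _, m in curve]
        assert max(accs) - min(accs) < 0.02

    def test_full_exclusion_is_undefined(self):
        ref = _hg([0, 1])
        curve = exclusion_curve(ref, ref, _u([0.5, 0.6]), [1.0])
        assert curve[0][1] is None


class TestCaptureCurve:
    def _setup(self, seed=8, n=400, n_err=80):
        rng = np.random.default_rng(seed)
        ref = _hg(rng.integers(0, 5, n))
        pred_st = ref.stages.copy()
        err_idx = rng.choice(n, size=n_err, replace=False)
        pred_st[err_idx] = (pred_st[err_idx] + 1) % 5
        return _hg(pred_st), ref, err_idx

    def test_full_budget_captures_everything(self):
        pred, ref, _ = self._setup()
        rng = np.random.default_rng(9)
        curve = confusion_capture_curve(pred, ref, _u(rng.random(400)), [1.0])
        assert curve[0][1] == 1.0

    def test_oracle_ranking_captures_all_errors(self):
        pred, ref, err_idx = self._setup()
        u_vals = np.full(400, 0.1)
        u_vals[err_idx] = 0.9
        curve = confusion_capture_curve(pred, ref, _u(u_vals), [0.2, 0.6])
        assert curve[0][1] == 1.0  # 0.2 * 400 = 80 >= #errors
        assert curve[1][1] == 1.0

    def test_independent_uncertainty_tracks_fraction(self):
        rng = np.random.default_rng(10)
        n = 10_000
        ref = _hg(rng.integers(0, 5, n))
        pred_st = ref.stages.copy()
        flip = rng.random(n) < 0.2
        pred_st[flip] = (pred_st[flip] + 1) % 5
        pred = _hg(pred_st)
        u = _u(rng.random(n))
        for f, cap in confusion_capture_curve(pred, ref, u, [0.1, 0.3, 0.5, 0.7]):
            assert abs(cap - f) < 0.03

    def test_capture_exclusion_identity(self):
        """Retained-set error count equals total errors x (1 - capture(f))."""
        pred, ref, err_idx = self._setup(seed=11)
        rng = np.random.default_rng(12)
        u = _u(rng.random(400))
        for f in (0.1, 0.4, 0.8):
            cap = confusion_capture_curve(pred, ref, u, [f])[0][1]
            curve = exclusion_curve(pred, ref, u, [f])[0][1]
            retained_errors = round(curve.n_epochs * (1 - curve.accuracy))
            assert retained_errors == round(len(err_idx) * (1 - cap))

    def test_zero_disagreements_reported_undefined(self):
        hg = _hg([0, 1, 2])
        with pytest.warns(UserWarning, match="undefined"):
            curve = confusion_capture_curve(hg, hg, _u([0.1, 0.2, 0.3]), [0.5])
        assert np.isnan(curve[0][1])


class TestGreyAreaAgreement:
    def _mask(self, flags):
        flags = np.asarray(flags, dtype=bool)
        return GreyAreaMask(EpochGrid(len(flags)), flags, "threshold", 0.6)

    def test_identical_masks(self):
        m = self._mask([True, False, True, False])
        out = greyarea_agreement(m, m)
        mat = out["all"]["matrix"]
        assert mat[0, 1] == 0 and mat[1, 0] == 0
        assert out["all"]["capture"] == 1.0

    def test_model_all_true_captures_everything(self):
        manual = self._mask([True, False, False, False])
        model = self._mask([True, True, True, True])
        out = greyarea_agreement(manual, model)
        assert out["all"]["capture"] == 1.0
        assert out["all"]["matrix"][1, 1] == 0  # no true negatives

    def test_disjoint_masks_capture_zero(self):
        manual = self._mask([True, True, False, False])
        model = self._mask([False, False, True, True])
        out = greyarea_agreement(manual, model)
        assert out["all"]["capture"] == 0.0

    def test_stratified_by_marks(self):
        manual = self._mask([True, True, False, False])
        model = self._mask([True, False, False, False])
        split = np.array([True, False, True, False])
        out = greyarea_agreement(manual, model, split)
        assert set(out) == {"marked", "unmarked"}
        assert out["marked"]["capture"] == 1.0
        assert out["unmarked"]["capture"] == 0.0
        assert out["marked"]["n_epochs"] == 2

    def test_mask_misalignment(self):
        with pytest.raises(AlignmentError):
            greyarea_agreement(self._mask([True]), self._mask([True, False]))


class TestPrevalence:
    def test_all_false_masks(self):
        masks = [
            GreyAreaMask(EpochGrid(4), np.zeros(4, dtype=bool), "threshold", 0.6)
            for _ in range(3)
        ]
        med, fractions = greyarea_prevalence(masks)
        assert med == 0.0 and fractions == [0.0, 0.0, 0.0]

    def test_median_of_three_recordings(self):
        def mask(k, n=10):
            f = np.zeros(n, dtype=bool)
            f[:k] = True
            return GreyAreaMask(EpochGrid(n), f, "threshold", 0.6)

        med, fractions = greyarea_prevalence([mask(1), mask(2), mask(3)])
        assert fractions == [0.1, 0.2, 0.3]
        assert med == pytest.approx(0.2)

    def test_single_recording(self):
        u = _u([0.7, 0.1, 0.9, 0.2])
        med, fr = greyarea_prevalence([threshold_mask(u, 0.6)])
        assert med == fr[0] == 0.5

    def test_fractions_over_scored_epochs_only(self):
        u = _u([0.9, np.nan, 0.1, np.nan])
        med, _ = greyarea_prevalence([threshold_mask(u, 0.6)])
        assert med == 0.5  # 1 flagged of 2 scored
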