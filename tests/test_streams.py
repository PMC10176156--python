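"""Frame bookkeeping, masking, super-segments, and playtime detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import motorchart as mc
from motorchart.streams import PlaytimeClassifier, SuperSegment


def make_frames(n, posture="sitting", movement="still", carried=False,
                quality=True, playtime=True):
    return pd.DataFrame({
        "frame_index": np.arange(n),
        "posture": posture if isinstance(posture, str) else posture,
        "movement": movement,
        "carried_flag": carried,
        "quality_flag": quality,
        "playtime_truth": playtime,
    })


class TestFrameGrid:
    def test_wearable_geometry_120_samples_60_hop(self):
        """2.3 s frames at 52 Hz are 120 samples with a 60-sample hop."""
        grid = mc.frame_grid(1000, 52.0, 2.3, 0.5)
        start, end = grid[0]
        assert end - start == 120
        assert grid[1][0] - grid[0][0] == 60

    def test_shorter_than_one_frame_is_empty(self):
        assert mc.frame_grid(100, 52.0, 2.3, 0.5) == []

    def test_maximal_tiling_discards_partial_frame(self):
        assert mc.frame_grid(240, 52.0, 2.3, 0.5) == [(0, 120), (60, 180), (120, 240)]

    @given(n=st.integers(0, 5000), overlap=st.floats(0.0, 0.9))
    @settings(max_examples=50, deadline=None)
    def test_frames_tile_within_bounds(self, n, overlap):
        grid = mc.frame_grid(n, 52.0, 2.3, overlap)
        for start, end in grid:
            assert 0 <= start < end <= n
            assert end - start == 120
        if grid:
            hop = int(round(120 * (1 - overlap)))
            assert n - grid[-1][1] < hop  # maximal: no room for one more frame

    def test_invalid_rate_and_overlap(self):
        with pytest.raises(ValueError):
            mc.frame_grid(100, 0.0, 2.3, 0.5)
        with pytest.raises(ValueError):
            mc.frame_grid(100, 52.0, 2.3, 1.0)


class TestMasks:
    def test_quality_mask_counts(self):
        frames = make_frames(1000)
        frames.loc[:99, "quality_flag"] = False
        assert len(mc.apply_quality_mask(frames)) == 900

    def test_all_good_identity(self):
        frames = make_frames(50)
        assert mc.apply_quality_mask(frames).equals(frames)

    def test_alternating_carried_keeps_half(self):
        frames = make_frames(1000)
        frames["carried_flag"] = np.arange(1000) % 2 == 0
        assert len(mc.apply_carried_mask(frames)) == 500

    def test_mask_order_is_irrelevant(self):
        rng = np.random.default_rng(0)
        frames = make_frames(500)
        frames["quality_flag"] = rng.random(500) > 0.2
        frames["carried_flag"] = rng.random(500) < 0.3
        a = mc.apply_carried_mask(mc.apply_quality_mask(frames))
        b = mc.apply_quality_mask(mc.apply_carried_mask(frames))
        assert a.equals(b)


class TestSuperSegments:
    def test_window_count_and_starts(self):
        frames = make_frames(1040)
        windows = mc.super_segments(frames)
        assert [w.start_frame for w in windows] == [0, 260, 520]

    def test_exactly_one_window(self):
        windows = mc.super_segments(make_frames(520))
        assert len(windows) == 1 and not windows[0].short

    def test_short_recording_flagged(self):
        windows = mc.super_segments(make_frames(100))
        assert len(windows) == 1 and windows[0].short

    def test_pure_window_feature_is_one_hot(self):
        windows = mc.super_segments(make_frames(520, posture="sitting",
                                                movement="still"))
        f = windows[0].features
        p = f[:len(mc.POSTURES)]
        m = f[len(mc.POSTURES):]
        assert p[list(mc.POSTURES).index("sitting")] == 1.0 and p.sum() == 1.0
        assert m[list(mc.MOVEMENTS).index("still")] == 1.0 and m.sum() == 1.0


class _ThresholdModel:
    """Stub classifier: positive iff first feature exceeds 0.5."""

    def predict(self, X):
        return (np.asarray(X)[:, 0] > 0.5).astype(int)


class TestPlaytimeDetection:
    def test_untrained_model_rejected(self):
        with pytest.raises(ValueError, match="trained"):
            mc.detect_playtime([], None, 10)

    def test_all_positive_windows_mark_all_frames(self):
        clf = PlaytimeClassifier(model=_ThresholdModel(), seed=0)
        windows = [SuperSegment(0, 520, np.array([1.0])),
                   SuperSegment(260, 780, np.array([1.0]))]
        mask = mc.detect_playtime(windows, clf, n_frames=800)
        assert mask.mask.all()
        assert mask.retained_hours == pytest.approx(800 * 1.15 / 3600)

    def test_tie_between_windows_counts_as_playtime(self):
        clf = PlaytimeClassifier(model=_ThresholdModel(), seed=0)
        windows = [SuperSegment(0, 520, np.array([1.0])),    # positive
                   SuperSegment(260, 780, np.array([0.0]))]  # negative
        mask = mc.detect_playtime(windows, clf, n_frames=780)
        # frames 260..519 are covered by one + and one - window: tie -> playtime
        assert mask.mask[260:520].all()
        assert not mask.mask[520:].any()

    def test_training_on_separable_windows_is_perfect(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (40, 3)), rng.normal(3, 0.1, (40, 3))])
        y = np.repeat([0, 1], 40)
        clf = mc.train_playtime_classifier(X, y, seed=0)
        assert (clf.model.predict(X) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            mc.train_playtime_classifier(np.zeros((10, 3)), np.zeros(10))

    def test_shuffled_labels_give_chance_accuracy(self):
        from sklearn.model_selection import cross_val_score
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.5, (100, 4)), rng.normal(2, 0.5, (100, 4))])
        y = rng.permutation(np.repeat([0, 1], 100))
        clf = mc.train_playtime_classifier(X, y, seed=0)
        scores = cross_val_score(clf.model, X, y, cv=5)
        assert abs(scores.mean() - 0.5) < 0.1

    def test_refit_same_seed_identical_weights(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 5))
        y = (X[:, 0] + 0.3 * rng.normal(size=60) > 0).astype(int)
        a = mc.train_playtime_classifier(X, y, seed=3)
        b = mc.train_playtime_classifier(X, y, seed=3)
        np.testing.assert_array_equal(a.coef_, b.coef_)

    def test_heldout_balanced_accuracy_on_synthetic_cohort(self):
        """Windows of generated playtime vs non-playtime blocks are separable:
        balanced accuracy on held-out recordings is at least 0.9."""
        from sklearn.metrics import balanced_accuracy_score
        cfg = mc.SyntheticConfig(n_subjects=8, seed=21)
        cohort, _ = mc.generate_motor_cohort(cfg)
        sessions = mc.cohort_sessions(cohort)
        half = len(sessions) // 2
        feats, labels = [], []
        for rec in sessions[:half]:
            for w in mc.super_segments(rec.frames):
                truth = rec.frames["playtime_truth"].to_numpy()[w.start_frame:w.end_frame]
                feats.append(w.features)
                labels.append(int(truth.mean() >= 0.5))
        clf = mc.train_playtime_classifier(np.vstack(feats), np.array(labels), seed=0)
        truths, preds = [], []
        for rec in sessions[half:]:
            mask = mc.detect_playtime(mc.super_segments(rec.frames), clf,
                                      len(rec.frames))
            truths.append(rec.frames["playtime_truth"].to_numpy())
            preds.append(mask.mask)
        score = balanced_accuracy_score(np.concatenate(truths), np.concatenate(preds))
        assert score >= 0.9


class TestAnalysisSelection:
    def make_session(self, frames, rec_id="r0"):
        return mc.RecordingSession(recording_id=rec_id, subject_id="s0",
                                   dataset_tag="T", age_months=8.0, frames=frames)

    def test_clean_hour_retains_one_hour(self):
        sel = mc.select_analysis_frames(self.make_session(make_frames(3130)))
        assert sel.retained_hours == pytest.approx(1.0, abs=1.15 / 3600)
        assert not sel.excluded

    def test_all_carried_recording_excluded_with_reason(self):
        frames = make_frames(3130, carried=True)
        sel = mc.select_analysis_frames(self.make_session(frames))
        assert sel.excluded and "minimum" in sel.reason

    def test_selection_is_mask_intersection(self):
        rng = np.random.default_rng(4)
        frames = make_frames(2000)
        frames["quality_flag"] = rng.random(2000) > 0.1
        frames["carried_flag"] = rng.random(2000) < 0.2
        frames["playtime_truth"] = rng.random(2000) < 0.7
        sel = mc.select_analysis_frames(self.make_session(frames),
                                        min_playtime_hours=0.0)
        manual = frames[frames["quality_flag"] & ~frames["carried_flag"]
                        & frames["playtime_truth"]]
        assert sel.frames.equals(manual)

    def test_truth_oracle_playtime_equals_truth_column(self):
        """Wiring check: with the truth mask supplied explicitly the
        selection matches the parental-annotation path exactly."""
        cfg = mc.SyntheticConfig(n_subjects=1, seed=5)
        cohort, _ = mc.generate_motor_cohort(cfg)
        rec = mc.cohort_sessions(cohort)[0]
        via_truth = mc.select_analysis_frames(rec, min_playtime_hours=0.0)
        via_mask = mc.select_analysis_frames(
            rec, playtime_mask=rec.frames["playtime_truth"].to_numpy(),
            min_playtime_hours=0.0)
        assert via_truth.frames.equals(via_mask.frames)

    def test_retained_never_exceeds_total(self):
        cfg = mc.SyntheticConfig(n_subjects=2, seed=6)
        cohort, _ = mc.generate_motor_cohort(cfg)
        for rec in mc.cohort_sessions(cohort):
            sel = mc.select_analysis_frames(rec, min_playtime_hours=0.0)
            total = len(rec.frames) * rec.hop_seconds / 3600
            assert sel.retained_hours <= total + 1e-9

    def test_frames_must_be_ordered(self):
        frames = make_frames(10)
        frames["frame_index"] = frames["frame_index"].to_numpy()[::-1]
        with pytest.raises(ValueError, match="strictly increasing"):
            self.make_session(frames)
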