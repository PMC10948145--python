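"""Clip extraction, fixed-length sampling, augmentation, set assembly."""

import numpy as np
import pytest

from apodetect.data import (
    ClipSequence,
    LoaderConfig,
    assemble_training_set,
    augment2d,
    extract_training_crops,
    mine_hard_negatives,
    sample_fixed_length,
)
from apodetect.io import EventAnnotation, Timelapse


def _movie(T=30, H=100, W=100, interval=5.0, fill=0):
    return Timelapse(frames=np.full((T, H, W), fill, dtype=np.uint8),
                     frame_interval=interval)


def _clip(rng, K=5, label=1):
    return ClipSequence(frames=rng.integers(0, 255, (K, 59, 59)).astype(np.uint8),
                        label=label)


class TestExtractTrainingCrops:
    @pytest.mark.parametrize(
        "interval,expected_offsets",
        [(5.0, [-2, 0, 2, 4, 6, 8, 10]), (10.0, [-1, 0, 1, 2, 3, 4, 5])],
    )
    def test_minute_window_converts_to_frame_offsets(self, interval, expected_offsets):
        # independently derived: round(linspace(-10, 50, 7) / interval)
        movie = _movie(interval=interval)
        # tag each frame with its index so the sampled offsets are readable
        for t in range(movie.n_frames):
            movie.frames[t] = t
        ann = EventAnnotation(x=50, y=50, t=12)
        (clip,) = extract_training_crops(movie, [ann])
        sampled = [int(f[0, 0]) - 12 for f in clip.frames]
        assert sampled == expected_offsets

    def test_border_annotation_is_padded_to_full_size(self):
        movie = _movie()
        ann = EventAnnotation(x=0, y=50, t=10)
        (clip,) = extract_training_crops(movie, [ann])
        assert clip.frames.shape == (7, 59, 59)

    def test_too_small_movie_rejected(self):
        movie = _movie(H=40, W=40)
        with pytest.raises(ValueError, match="smaller"):
            extract_training_crops(movie, [EventAnnotation(x=10, y=10, t=5)])


class TestSampleFixedLength:
    @pytest.mark.parametrize(
        "length,expected",
        [(7, [0, 2, 3, 5, 6]), (5, [0, 1, 2, 3, 4]), (9, [0, 2, 4, 6, 8])],
    )
    def test_uniform_subsampling_indices(self, length, expected):
        frames = np.arange(length)[:, None, None] * np.ones((1, 3, 3))
        out = sample_fixed_length(frames, K=5)
        assert [int(f[0, 0]) for f in out] == expected

    def test_short_input_repeats_edges(self):
        frames = np.arange(3)[:, None, None] * np.ones((1, 2, 2))
        out = sample_fixed_length(frames, K=5)
        got = [int(f[0, 0]) for f in out]
        assert got[0] == 0 and got[-1] == 2 and len(got) == 5

    def test_first_and_last_always_included(self, rng):
        for L in range(5, 30):
            frames = np.arange(L)[:, None, None] * np.ones((1, 2, 2))
            got = [int(f[0, 0]) for f in sample_fixed_length(frames, K=5)]
            assert got[0] == 0 and got[-1] == L - 1
            assert got == sorted(got)


class TestAugment2d:
    def test_zero_magnitudes_are_identity(self, rng):
        clip = _clip(rng)
        cfg = LoaderConfig(shift_frac=0, zoom_range=(1.0, 1.0), rotation_deg=0,
                           flip_horizontal=False, flip_vertical=False)
        out = augment2d(clip, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out.frames, clip.frames)

    def test_label_shape_and_determinism(self, rng):
        clip = _clip(rng, label=1)
        cfg = LoaderConfig()
        a = augment2d(clip, cfg, np.random.default_rng(7))
        b = augment2d(clip, cfg, np.random.default_rng(7))
        assert a.label == 1
        assert a.frames.shape == clip.frames.shape
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_transform_is_frame_consistent(self, rng):
        # identical input frames must stay identical after augmentation
        frame = rng.integers(0, 255, (59, 59)).astype(np.uint8)
        clip = ClipSequence(frames=np.stack([frame] * 5), label=0)
        out = augment2d(clip, LoaderConfig(), np.random.default_rng(3))
        for k in range(1, 5):
            np.testing.assert_array_equal(out.frames[k], out.frames[0])


class TestAssembleTrainingSet:
    def test_ratio_draws_the_right_negative_count(self, rng):
        pos = [_clip(rng, label=1) for _ in range(10)]
        neg = [_clip(rng, label=0) for _ in range(120)]
        train, val = assemble_training_set(pos, neg, ratio=10.0, val_frac=0.12)
        assert len(train) + len(val) == 110
        with pytest.raises(ValueError, match="negatives"):
            assemble_training_set(pos, neg[:50], ratio=10.0)

    def test_validation_fraction_split(self, rng):
        pos = [_clip(rng, label=1) for _ in range(500)]
        neg = [_clip(rng, label=0) for _ in range(500)]
        train, val = assemble_training_set(pos, neg, ratio=1.0, val_frac=0.12)
        assert (len(train), len(val)) == (880, 120)

    def test_fivefold_split_never_shares_movies(self, rng):
        clips = []
        for m in range(10):
            for _ in range(6):
                c = _clip(rng, label=int(rng.integers(0, 2)))
                c.movie_id = f"movie{m}"
                clips.append(c)
        pos = [c for c in clips if c.label == 1]
        neg = [c for c in clips if c.label == 0]
        ratio = len(neg) / max(1, len(pos))
        splits = assemble_training_set(pos, neg, ratio=ratio, folds=5)
        assert len(splits) == 5
        for train, val in splits:
            assert {c.movie_id for c in train} & {c.movie_id for c in val} == set()


class _StubModel:
    """Fires with fixed probability on every clip."""

    def __init__(self, prob):
        self.prob = prob

    def predict_proba(self, X):
        return np.column_stack([np.full(len(X), 1 - self.prob),
                                np.full(len(X), self.prob)])


class TestMineHardNegatives:
    def _control_movie(self):
        frames = np.full((12, 100, 100), 5, dtype=np.uint8)
        for (cx, cy) in [(30, 30), (70, 60)]:
            frames[:, cy - 6:cy + 6, cx - 6:cx + 6] = 180
        return Timelapse(frames=frames)

    def test_every_detection_becomes_a_label0_clip(self):
        from apodetect.pipeline import PipelineConfig, detect

        movie = self._control_movie()
        model = _StubModel(0.999)
        cfg = PipelineConfig(prob_threshold=0.99)
        dets = detect(movie, model, cfg)
        mined = mine_hard_negatives(model, [movie], cfg)
        assert len(mined) == len(dets) > 0
        assert all(c.label == 0 for c in mined)
        assert all(c.frames.shape == (5, 59, 59) for c in mined)

    def test_confident_model_mines_nothing(self):
        movie = self._control_movie()
        mined = mine_hard_negatives(_StubModel(0.0), [movie])
        assert mined == []
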