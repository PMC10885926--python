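"""ROI detection, cropping, quadrant splitting, and label alignment."""

import numpy as np
import pytest

from vidspo2.exceptions import (AlignmentError, DetectionFailureError,
                                InvalidParameterError, ShapeError)
from vidspo2.preprocess import (BoundingBox, FixedBoxDetector,
                                SkinColorDetector, VideoClip, crop_resize,
                                detect_roi, prepare_labels, split_quadrants)
from vidspo2.signalcore import Waveform, compute_psd
from vidspo2.synthetic import SceneConfig, generate


@pytest.fixture(scope="module")
def face_sample():
    return generate(SceneConfig(duration_s=6.0, size=32, hr_bpm=72.0, seed=3))


class TestDetectRoi:
    def test_skin_detector_matches_known_ellipse(self, face_sample):
        boxes = detect_roi(face_sample.face_clip, "face")
        for box in boxes:
            assert box.iou(face_sample.face_bbox) > 0.7

    def test_fixed_box_passthrough(self, face_sample):
        box = BoundingBox(2, 3, 10, 12)
        boxes = detect_roi(face_sample.face_clip, "face",
                           detector=FixedBoxDetector(box))
        assert all(b == box for b in boxes)

    def test_background_only_clip_fails_with_frame_index(self):
        frames = np.full((4, 16, 16, 3), 0.45, dtype=np.float32)
        frames[..., 2] = 0.55                     # bluish: not skin
        with pytest.raises(DetectionFailureError, match="frame 0"):
            detect_roi(VideoClip(frames, 30.0), "face")


class TestCropResize:
    def test_output_always_128(self, face_sample):
        boxes = [BoundingBox(1, 1, 9, 11)] * face_sample.face_clip.n_frames
        out = crop_resize(face_sample.face_clip, boxes, out_size=128)
        assert out.frames.shape[1:3] == (128, 128)

    def test_full_frame_same_size_is_identity(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(size=(3, 16, 16, 3)).astype(np.float32)
        clip = VideoClip(frames, 30.0)
        out = crop_resize(clip, [BoundingBox(0, 0, 16, 16)] * 3, out_size=16)
        np.testing.assert_allclose(out.frames, frames, atol=1e-6)

    def test_constant_region_stays_constant(self):
        frames = np.full((2, 20, 20, 3), 0.25, dtype=np.float32)
        out = crop_resize(VideoClip(frames, 30.0),
                          [BoundingBox(2, 2, 10, 10)] * 2, out_size=32)
        np.testing.assert_allclose(out.frames, 0.25, atol=1e-6)

    def test_out_of_frame_box_clipped_with_warning(self):
        frames = np.full((2, 16, 16, 3), 0.5, dtype=np.float32)
        clip = VideoClip(frames, 30.0)
        with pytest.warns(UserWarning, match="clipped"):
            out = crop_resize(clip, [BoundingBox(-4, 0, 8, 20)] * 2, out_size=8)
        assert out.frames.shape[1:3] == (8, 8)
        with pytest.raises(InvalidParameterError):
            crop_resize(clip, [BoundingBox(20, 0, 30, 8)] * 2, out_size=8)

    def test_pixel_range_preserved(self, face_sample):
        boxes = detect_roi(face_sample.face_clip, "face")
        out = crop_resize(face_sample.face_clip, boxes, out_size=16)
        assert out.frames.min() >= 0.0 and out.frames.max() <= 1.0

    def test_box_count_mismatch(self, face_sample):
        with pytest.raises(ShapeError):
            crop_resize(face_sample.face_clip, [BoundingBox(0, 0, 4, 4)])


class TestSplitQuadrants:
    def test_partition_reassembles_exactly(self, face_sample):
        clip = face_sample.face_clip
        tl, tr, bl, br = split_quadrants(clip)
        assert tl.frames.shape[1:3] == (16, 16)
        top = np.concatenate([tl.frames, tr.frames], axis=2)
        bottom = np.concatenate([bl.frames, br.frames], axis=2)
        np.testing.assert_array_equal(
            np.concatenate([top, bottom], axis=1), clip.frames)

    def test_quadrants_share_psd_peak(self):
        s = generate(SceneConfig(duration_s=10.0, size=32, hr_bpm=72.0, seed=6))
        peaks = []
        for quad in split_quadrants(s.face_clip):
            g = quad.channel_means()[1]
            peaks.append(compute_psd(Waveform(g - g.mean(), 30.0)).peak_freq)
        assert len(set(peaks)) == 1

    def test_odd_dims_rejected(self):
        frames = np.zeros((2, 15, 16, 3), dtype=np.float32)
        frames += 0.5
        with pytest.raises(InvalidParameterError):
            split_quadrants(VideoClip(frames, 30.0))


class TestPrepareLabels:
    def test_rate_and_length_alignment(self, face_sample):
        rate = 60.0
        n = int(face_sample.face_clip.n_frames / 30.0 * rate) + 300
        t = np.arange(n) / rate
        ppg = Waveform(np.sin(2 * np.pi * 1.2 * t), rate)
        aligned, labels = prepare_labels(ppg, face_sample.spo2_trace,
                                         face_sample.face_clip)
        assert aligned.rate == 30.0
        assert len(aligned) == face_sample.face_clip.n_frames

    def test_constant_spo2_gives_constant_labels(self, face_sample):
        aligned, labels = prepare_labels(
            face_sample.ppg, np.full(6, 97.0), face_sample.face_clip,
            window_frames=60)
        np.testing.assert_allclose(labels, 97.0)

    def test_psd_peak_unchanged_by_processing(self, face_sample):
        aligned, _ = prepare_labels(face_sample.ppg, face_sample.spo2_trace,
                                    face_sample.face_clip)
        raw = face_sample.ppg
        p_raw = compute_psd(Waveform(raw.samples - raw.samples.mean(), raw.rate))
        p_out = compute_psd(aligned)
        assert p_out.peak_freq == pytest.approx(p_raw.peak_freq, abs=0.2)

    def test_coverage_shortfall_rejected(self, face_sample):
        short = Waveform(face_sample.ppg.samples[:60], 30.0)
        with pytest.raises(AlignmentError):
            prepare_labels(short, face_sample.spo2_trace,
                           face_sample.face_clip)


def test_pipeline_determinism(face_sample):
    boxes1 = detect_roi(face_sample.face_clip, "face")
    boxes2 = detect_roi(face_sample.face_clip, "face")
    assert boxes1 == boxes2
    out1 = crop_resize(face_sample.face_clip, boxes1, out_size=16)
    out2 = crop_resize(face_sample.face_clip, boxes2, out_size=16)
    np.testing.assert_array_equal(out1.frames, out2.frames)
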