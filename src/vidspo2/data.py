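"""Window-level training units shared by the contrastive and SpO2 stages.

A ``TrainingWindow`` bundles everything one analysis window needs: the
face/hand ROI clips as channel-first arrays, the relative photometric
traces and manual features of the face ROI, the processed contact-PPG
reference, and the window's SpO2 label (the mean of the per-second
reference values it spans).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import VideoClip, crop_resize, prepare_labels
from .spo2_head import manual_features, photometric_summary, photometric_traces
from .synthetic import SyntheticSample

__all__ = ["TrainingWindow", "build_windows", "roi_clip"]


@dataclass
class TrainingWindow:
    """One T-frame analysis window of one subject."""

    subject_id: str
    face: np.ndarray                 # (3, T, S, S), raw [0, 1] ROI pixels
    hand: np.ndarray
    photo: np.ndarray                # (3, T) relative photometric traces (%)
    photo_summary: np.ndarray        # (6,) AC amplitudes + log-ratios
    features: np.ndarray             # (6,) manual feature vector C_w
    ppg: np.ndarray | None           # (T,) processed reference PPG
    label: float                     # window SpO2 in percent
    rate: float
    start: int = 0


def roi_clip(clip: VideoClip, bbox, out_size: int) -> VideoClip:
    """Fixed-box ROI crop of a whole clip, rescaled to out_size."""
    return crop_resize(clip, [bbox] * clip.n_frames, out_size=out_size)


def build_windows(sample: SyntheticSample, window_frames: int,
                  max_windows: int | None = None,
                  roi_size: int | None = None) -> list[TrainingWindow]:
    """Cut a synthetic sample into non-overlapping training windows.

    Windows are taken at evenly spaced start positions when ``max_windows``
    limits their number, so short and long recordings are treated alike.
    """
    size = roi_size or sample.face_clip.size[0]
    face_roi = roi_clip(sample.face_clip, sample.face_bbox, size)
    hand_roi = roi_clip(sample.hand_clip, sample.hand_bbox, size)
    aligned, _ = prepare_labels(sample.ppg, sample.spo2_trace, sample.face_clip)

    T = face_roi.n_frames
    starts = list(range(0, T - window_frames + 1, window_frames))
    if max_windows is not None and len(starts) > max_windows:
        idx = np.unique(np.linspace(0, len(starts) - 1, max_windows).round().astype(int))
        starts = [starts[i] for i in idx]

    rate = sample.face_clip.rate
    spo2 = np.asarray(sample.spo2_trace, dtype=np.float64)
    out = []
    for start in starts:
        sl = slice(start, start + window_frames)
        face_win = VideoClip(face_roi.frames[sl], rate)
        s0 = int(np.floor(start / rate))
        s1 = int(np.ceil((start + window_frames) / rate))
        label = float(spo2[s0:min(s1, spo2.size)].mean())
        photo = photometric_traces(face_win)
        out.append(TrainingWindow(
            subject_id=sample.subject_id,
            face=face_win.frames.transpose(3, 0, 1, 2).copy(),
            hand=hand_roi.frames[sl].transpose(3, 0, 1, 2).copy(),
            photo=photo,
            photo_summary=photometric_summary(photo),
            features=manual_features(face_win).values,
            ppg=aligned.samples[sl].copy(),
            label=label,
            rate=rate,
            start=start,
        ))
    return out
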