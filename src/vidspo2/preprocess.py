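"""ROI detection, cropping, quadrant sub-ROIs, and label alignment.

The pipeline mirrors the usual camera-oximetry front end: find the skin
region in every frame, crop it, rescale to a fixed spatial size (128x128
by default), split it into four quadrant sub-ROIs along the center lines,
and align the contact-PPG / SpO2 references with the video timeline.

Object detection itself is pluggable: any callable mapping a frame to a
bounding box (or ``None``) can stand in for a learned detector.  Two
implementations ship with the package: a skin-color heuristic (largest
connected skin-colored component) and a fixed-box detector for synthetic
scenes with known geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.transform import resize as _sk_resize

from .exceptions import (
    AlignmentError,
    DetectionFailureError,
    InvalidParameterError,
    ShapeError,
)
from .signalcore import CARDIAC_BAND, Waveform, bandpass_fir, normalize, resample

__all__ = [
    "VideoClip",
    "BoundingBox",
    "SkinColorDetector",
    "FixedBoxDetector",
    "detect_roi",
    "crop_resize",
    "split_quadrants",
    "prepare_labels",
]


@dataclass(frozen=True)
class VideoClip:
    """A T x H x W x 3 stack of RGB frames in [0, 1] plus the frame rate."""

    frames: np.ndarray
    rate: float

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=np.float32)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 4 or frames.shape[-1] != 3:
            raise ShapeError(f"frames must be (T, H, W, 3), got {frames.shape}")
        if frames.shape[0] < 2:
            raise InvalidParameterError("a clip needs at least 2 frames")
        if self.rate <= 0:
            raise InvalidParameterError(f"frame rate must be positive, got {self.rate}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def size(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def channel_means(self) -> np.ndarray:
        """Per-frame spatial mean of each color channel, shape (3, T)."""
        return self.frames.mean(axis=(1, 2)).T.astype(np.float64)


@dataclass(frozen=True)
class BoundingBox:
    """0-based, half-open pixel box [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise InvalidParameterError(f"degenerate box {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def iou(self, other: "BoundingBox") -> float:
        ix0, iy0 = max(self.x0, other.x0), max(self.y0, other.y0)
        ix1, iy1 = min(self.x1, other.x1), min(self.y1, other.y1)
        inter = max(0, ix1 - ix0) * max(0, iy1 - iy0)
        union = (self.width * self.height + other.width * other.height - inter)
        return inter / union if union else 0.0


class SkinColorDetector:
    """Largest connected skin-colored component.

    Skin pixels are redder than they are blue or green; the thresholds are
    deliberately loose so that global illumination drift does not break
    detection.
    """

    def __init__(self, min_area: int = 16):
        self.min_area = min_area

    def __call__(self, frame: np.ndarray) -> BoundingBox | None:
        r, g, b = frame[..., 0], frame[..., 1], frame[..., 2]
        mask = (r - b > 0.06) & (r - g > 0.03) & (r > 0.25)
        if not mask.any():
            return None
        labels = measure.label(mask)
        regions = measure.regionprops(labels)
        best = max(regions, key=lambda reg: reg.area)
        if best.area < self.min_area:
            return None
        y0, x0, y1, x1 = best.bbox
        return BoundingBox(x0, y0, x1, y1)


class FixedBoxDetector:
    """Returns one configured box for every frame."""

    def __init__(self, box: BoundingBox):
        self.box = box

    def __call__(self, frame: np.ndarray) -> BoundingBox:
        return self.box


def detect_roi(clip: VideoClip, region: str = "face",
               detector=None) -> list[BoundingBox]:
    """One bounding box per frame; raises naming the first failing frame."""
    if region not in ("face", "hand"):
        raise InvalidParameterError(f"region must be 'face' or 'hand', got {region!r}")
    detector = detector or SkinColorDetector()
    boxes = []
    for i, frame in enumerate(clip.frames):
        box = detector(frame)
        if box is None:
            raise DetectionFailureError(f"no {region} region found in frame {i}")
        boxes.append(box)
    return boxes


def crop_resize(clip: VideoClip, boxes: list[BoundingBox],
                out_size: int = 128) -> VideoClip:
    """Crop each frame to its box and rescale to out_size x out_size (bilinear)."""
    if len(boxes) != clip.n_frames:
        raise ShapeError(f"{len(boxes)} boxes for {clip.n_frames} frames")
    H, W = clip.size
    out = np.empty((clip.n_frames, out_size, out_size, 3), dtype=np.float32)
    for i, (frame, box) in enumerate(zip(clip.frames, boxes)):
        x0, y0 = max(0, box.x0), max(0, box.y0)
        x1, y1 = min(W, box.x1), min(H, box.y1)
        if (x0, y0, x1, y1) != (box.x0, box.y0, box.x1, box.y1):
            warnings.warn(f"box {box} clipped to frame bounds at frame {i}")
        if x1 <= x0 or y1 <= y0:
            raise InvalidParameterError(f"box {box} has zero area inside the frame")
        patch = frame[y0:y1, x0:x1]
        if patch.shape[:2] == (out_size, out_size):
            out[i] = patch
        else:
            out[i] = _sk_resize(patch, (out_size, out_size), order=1,
                                anti_aliasing=False, preserve_range=True)
    np.clip(out, 0.0, 1.0, out=out)
    return VideoClip(out, clip.rate)


def split_quadrants(clip: VideoClip) -> tuple[VideoClip, VideoClip, VideoClip, VideoClip]:
    """Center-line split into (top-left, top-right, bottom-left, bottom-right)."""
    H, W = clip.size
    if H % 2 or W % 2:
        raise InvalidParameterError(f"need even spatial dims to split, got {H}x{W}")
    h, w = H // 2, W // 2
    f = clip.frames
    return (
        VideoClip(f[:, :h, :w], clip.rate),
        VideoClip(f[:, :h, w:], clip.rate),
        VideoClip(f[:, h:, :w], clip.rate),
        VideoClip(f[:, h:, w:], clip.rate),
    )


def prepare_labels(ppg: Waveform, spo2: np.ndarray, clip: VideoClip,
                   band: tuple[float, float] = CARDIAC_BAND,
                   window_frames: int | None = None,
                   ) -> tuple[Waveform, np.ndarray]:
    """Align reference signals with a clip.

    The PPG is band-passed, z-scored, resampled to the clip frame rate and
    truncated to the clip length.  SpO2 labels come as one value per second;
    each analysis window of ``window_frames`` frames (default: the whole
    clip) is labelled with the mean of the per-second values it spans.
    """
    T = clip.n_frames
    if ppg.duration + 1e-9 < T / clip.rate:
        raise AlignmentError(
            f"PPG covers {ppg.duration:.2f} s but the clip needs {T / clip.rate:.2f} s"
        )
    # cap the FIR order for short recordings (filtfilt needs len > taps)
    default_order = int(round(4.0 * ppg.rate / band[0]))
    order = min(default_order, max(30, (len(ppg) // 3) | 1))
    processed = resample(normalize(bandpass_fir(ppg, *band, order=order)),
                         clip.rate)
    if len(processed) < T:
        raise AlignmentError("resampled PPG shorter than the clip")
    aligned = Waveform(processed.samples[:T], clip.rate)

    spo2 = np.asarray(spo2, dtype=np.float64)
    window_frames = window_frames or T
    n_windows = T // window_frames
    labels = np.empty(n_windows)
    for k in range(n_windows):
        t0 = k * window_frames / clip.rate
        t1 = (k + 1) * window_frames / clip.rate
        s0, s1 = int(np.floor(t0)), int(np.ceil(t1))
        seg = spo2[s0:min(s1, spo2.size)]
        if seg.size == 0:
            raise AlignmentError(f"SpO2 trace does not cover window {k}")
        labels[k] = seg.mean()
    return aligned, labels
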