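"""Synthetic pulsatile skin videos with known rPPG and SpO2 ground truth.

The generator emulates the recording setting the pipeline is built for: a
camera films a face and a hand at 30 fps; the skin region carries a small
cardiac-synchronous color oscillation (fundamental plus a 30% second
harmonic) on top of a static baseline; ambient light drifts slowly and
multiplicatively; the face may rotate in-plane; the sensor adds Gaussian
noise.

SpO2 is encoded through the classical linear ratio-of-ratios calibration

    SpO2 = A - B * (AC_R / DC_R) / (AC_B / DC_B)

with documented constants A = 110, B = 13, so that AC/DC amplitude ratios
of the red and blue channels carry the ground truth.  The blue and green
pulsatile fractions are fixed (blue 0.8%, green 1.2% of DC) and the red
fraction varies with SpO2.  ``invert_ratio_of_ratios`` applies the same
law in reverse and serves as the generator's self-consistency oracle.

Structural randomness (skin texture, phases) is controlled by a separate
``structure_seed`` so that different ``seed`` values change only the noise
realization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import rotate as _sk_rotate

from .exceptions import InsufficientLengthError, InvalidParameterError
from .preprocess import BoundingBox, VideoClip
from .signalcore import Waveform

__all__ = [
    "SceneConfig",
    "SyntheticSample",
    "generate",
    "invert_ratio_of_ratios",
    "constant_trace",
    "ramp_trace",
    "dip_trace",
]

_FACE_RGB = np.array([0.72, 0.55, 0.45])
_HAND_RGB = np.array([0.76, 0.60, 0.50])
_BG_RGB = np.array([0.42, 0.46, 0.52])


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic recording."""

    duration_s: float = 10.0
    rate: float = 30.0
    size: int = 32
    hr_bpm: float = 72.0
    spo2_trace: np.ndarray | None = None
    lighting_amp: float = 0.0
    rotation_deg: float = 0.0
    noise_sd: float = 0.003
    texture_amp: float = 0.005
    cal_a: float = 110.0
    cal_b: float = 13.0
    ac_green: float = 0.012
    ac_blue: float = 0.008
    seed: int = 0
    structure_seed: int = 0

    def __post_init__(self):
        f = self.hr_bpm / 60.0
        if not (0.5 <= f <= 4.0):
            raise InvalidParameterError(
                f"heart rate {self.hr_bpm} bpm is outside the 0.5-4 Hz band"
            )
        if self.rate <= 2.0 * f:
            raise InvalidParameterError("frame rate must exceed twice the heart rate")
        if self.size < 16 or self.size % 2:
            raise InvalidParameterError("frame size must be even and >= 16")
        if self.duration_s <= 0:
            raise InvalidParameterError("duration must be positive")
        trace = self.spo2_trace
        if trace is None:
            trace = np.full(int(np.ceil(self.duration_s)), 97.0)
        trace = np.asarray(trace, dtype=np.float64)
        if np.any(trace < 93.0) or np.any(trace > 100.0):
            raise InvalidParameterError("SpO2 trace must stay within [93, 100] %")
        object.__setattr__(self, "spo2_trace", trace)


@dataclass(frozen=True)
class SyntheticSample:
    """One generated recording: paired face/hand clips plus references."""

    face_clip: VideoClip
    hand_clip: VideoClip
    ppg: Waveform
    spo2_trace: np.ndarray
    meta: SceneConfig
    face_bbox: BoundingBox = None
    hand_bbox: BoundingBox = None
    subject_id: str = "s0"


def constant_trace(duration_s: float, value: float = 97.0) -> np.ndarray:
    return np.full(int(np.ceil(duration_s)), float(value))


def ramp_trace(duration_s: float, start: float = 93.0, stop: float = 100.0) -> np.ndarray:
    n = int(np.ceil(duration_s))
    return np.linspace(start, stop, n)


def dip_trace(duration_s: float, base: float, depth: float, center_s: float,
              width_s: float) -> np.ndarray:
    """Breath-hold-like desaturation dip, clipped to the [93, 100] range."""
    n = int(np.ceil(duration_s))
    t = np.arange(n) + 0.5
    trace = base - depth * np.exp(-0.5 * ((t - center_s) / width_s) ** 2)
    return np.clip(trace, 93.0, 100.0)


def _smooth_texture(rng: np.random.Generator, size: int, amp: float) -> np.ndarray:
    field_ = gaussian_filter(rng.standard_normal((size, size)), sigma=2.0)
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd
    return 1.0 + amp * field_


def _skin_mask(size: int, region: str) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cx = cy = (size - 1) / 2.0
    if region == "face":
        ax, ay = 0.30 * size, 0.38 * size
        return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    # hand: rounded rectangle
    m = int(round(0.18 * size))
    r = 0.12 * size
    inner = np.zeros((size, size), dtype=bool)
    inner[m:size - m, m:size - m] = True
    x0, x1 = m + r, size - 1 - m - r
    y0, y1 = m + r, size - 1 - m - r
    px = np.clip(xx, x0, x1)
    py = np.clip(yy, y0, y1)
    rounded = (xx - px) ** 2 + (yy - py) ** 2 <= r ** 2
    return inner & rounded


def _mask_bbox(mask: np.ndarray) -> BoundingBox:
    ys, xs = np.nonzero(mask)
    return BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)


def _render_region(cfg: SceneConfig, region: str, pulse: np.ndarray,
                   alphas: np.ndarray, lighting: np.ndarray,
                   angles: np.ndarray | None,
                   rng_structure: np.random.Generator,
                   rng_noise: np.random.Generator) -> tuple[VideoClip, BoundingBox]:
    size = cfg.size
    n = pulse.size
    mask = _skin_mask(size, region)
    skin_rgb = _FACE_RGB if region == "face" else _HAND_RGB
    tex_skin = _smooth_texture(rng_structure, size, cfg.texture_amp)
    tex_bg = _smooth_texture(rng_structure, size, 4.0 * cfg.texture_amp)
    skin = skin_rgb[None, None, :] * tex_skin[..., None]
    bg = _BG_RGB[None, None, :] * tex_bg[..., None]
    # pulsatile modulation per frame and channel: 1 - alpha_c(t) * p(t)
    mod = 1.0 - alphas * pulse[:, None]                       # (T, 3)
    m3 = mask[..., None]
    frames = (bg * ~m3)[None] + skin[None] * m3[None] * mod[:, None, None, :]
    frames *= lighting[:, None, None, None]
    if angles is not None and np.any(angles != 0.0):
        for i in range(n):
            if angles[i] != 0.0:
                frames[i] = _sk_rotate(frames[i], angles[i], order=1,
                                       mode="edge", preserve_range=True)
    if cfg.noise_sd > 0:
        frames = frames + rng_noise.normal(0.0, cfg.noise_sd, frames.shape)
    np.clip(frames, 0.0, 1.0, out=frames)
    return VideoClip(frames.astype(np.float32), cfg.rate), _mask_bbox(mask)


def generate(cfg: SceneConfig, subject_id: str = "s0") -> SyntheticSample:
    """Render one synthetic recording from its scene configuration."""
    rng_structure = np.random.default_rng(cfg.structure_seed)
    rng_noise = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.rate))
    t = np.arange(n) / cfg.rate
    f = cfg.hr_bpm / 60.0
    phi = rng_structure.uniform(0.0, 2.0 * np.pi)
    pulse = np.sin(2 * np.pi * f * t + phi) + 0.3 * np.sin(4 * np.pi * f * t + 2 * phi + 0.5)

    sec = np.arange(cfg.spo2_trace.size) + 0.5
    spo2_f = np.interp(t, sec, cfg.spo2_trace)
    r_ratio = (cfg.cal_a - spo2_f) / cfg.cal_b
    alphas = np.stack([
        r_ratio * cfg.ac_blue,                      # red varies with SpO2
        np.full(n, cfg.ac_green),
        np.full(n, cfg.ac_blue),
    ], axis=1)

    phase_l = rng_structure.uniform(0.0, 2.0 * np.pi)
    lighting = 1.0 + cfg.lighting_amp * np.sin(2 * np.pi * 0.1 * t + phase_l)
    angles = None
    if cfg.rotation_deg:
        angles = cfg.rotation_deg * np.sin(2 * np.pi * 0.25 * t)

    face_clip, face_bbox = _render_region(cfg, "face", pulse, alphas, lighting,
                                          angles, rng_structure, rng_noise)
    hand_clip, hand_bbox = _render_region(cfg, "hand", pulse, alphas, lighting,
                                          None, rng_structure, rng_noise)
    ppg = Waveform(pulse, cfg.rate)
    return SyntheticSample(face_clip, hand_clip, ppg, cfg.spo2_trace.copy(), cfg,
                           face_bbox, hand_bbox, subject_id)


def invert_ratio_of_ratios(clip: VideoClip, cal_a: float = 110.0,
                           cal_b: float = 13.0, window_s: float = 2.0,
                           ) -> np.ndarray:
    """Per-second SpO2 from AC/DC amplitude ratios of the red and blue channels.

    Serves as the generator-consistency oracle: on clips rendered without
    rotation or lighting drift it recovers the configured trace.  AC
    amplitudes are RMS values of linearly detrended channel-mean traces over
    a sliding ``window_s`` window, so that partial-cycle truncation biases
    cancel in the red/blue ratio.
    """
    duration = clip.n_frames / clip.rate
    if duration < window_s:
        raise InsufficientLengthError(
            f"clip of {duration:.2f} s is shorter than one {window_s:.1f} s window"
        )
    frame0 = clip.frames[0]
    r, g, b = frame0[..., 0], frame0[..., 1], frame0[..., 2]
    mask = (r - b > 0.06) & (r - g > 0.03) & (r > 0.25)
    if not mask.any():
        mask = np.ones(frame0.shape[:2], dtype=bool)
    traces = clip.frames[:, mask].mean(axis=1).astype(np.float64)   # (T, 3)

    n_sec = int(np.floor(duration))
    out = np.empty(n_sec)
    for s in range(n_sec):
        c = s + 0.5
        t0 = np.clip(c - window_s / 2.0, 0.0, duration - window_s)
        i0 = int(round(t0 * clip.rate))
        i1 = i0 + int(round(window_s * clip.rate))
        seg = traces[i0:i1]
        x = np.arange(seg.shape[0])
        ratios = {}
        for ch, name in ((0, "r"), (2, "b")):
            y = seg[:, ch]
            dc = y.mean()
            coef = np.polyfit(x, y, 1)
            ac = np.sqrt(np.mean((y - np.polyval(coef, x)) ** 2))
            ratios[name] = ac / dc
        out[s] = cal_a - cal_b * (ratios["r"] / ratios["b"])
    return out


def windows_of(sample: SyntheticSample, window_frames: int) -> list[int]:
    """Start indices of the non-overlapping analysis windows of a sample."""
    return list(range(0, sample.face_clip.n_frames - window_frames + 1, window_frames))


def subsample_clip(clip: VideoClip, start: int, length: int) -> VideoClip:
    return VideoClip(clip.frames[start:start + length], clip.rate)


def with_seed(cfg: SceneConfig, seed: int) -> SceneConfig:
    return replace(cfg, seed=seed)
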