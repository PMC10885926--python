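"""The 3DCNN rPPG estimator.

Maps a (3, T, S, S) RGB clip to a 6-channel time series of length T.  The
layer sequence is

    standardization
    -> 3DConv1 (1x5x5) -> AvgPool (1x2x2)
    -> [3DConv2 (3x3x3, temporal dilation 2)] x 2 -> AvgPool (2x2x2)
    -> [3DConv3 (3x3x3, dilation 2)] x 2        -> AvgPool (2x2x2, stride (1,2,2))
    -> [3DConv4 (3x3x3, dilation 2)] x 2
    -> temporal linear interpolation T/2 -> T
    -> 3DConv5 (3x3x3) -> global spatial average -> 3DConv6 -> (6, T)

Every convolution except the output layer is followed by instance
normalization and ReLU.  Spatial pooling is assigned adaptively so that the
feature map entering the global average is 16x16 (or smaller for small
inputs): a 128x128 clip pools at all three stages, 64x64 skips the first,
32x32 keeps only the third, and 16x16 or 8x8 quadrant inputs skip spatial
pooling entirely.  The temporal axis is pooled exactly once (stage 2) and restored
by interpolation, so the output length always equals the input length.

``width_mult`` scales the channel widths (reference widths 32/64) for
CPU-scale experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .exceptions import InvalidParameterError, ShapeError
from .preprocess import VideoClip

__all__ = [
    "RppgEstimatorConfig",
    "MultiChannelRppg",
    "RppgEstimator",
    "build_estimator",
    "forward",
    "standardize_clip",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class RppgEstimatorConfig:
    input_size: int = 128
    width_mult: float = 1.0
    out_channels: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.input_size not in (8, 16, 32, 64, 128):
            raise InvalidParameterError(
                f"input_size must be one of 8/16/32/64/128, got {self.input_size}"
            )
        if self.width_mult <= 0:
            raise InvalidParameterError("width_mult must be positive")


@dataclass(frozen=True)
class MultiChannelRppg:
    """A 6 x T multi-channel rPPG time series with its sampling rate."""

    signals: np.ndarray
    rate: float

    def __post_init__(self):
        signals = np.asarray(self.signals, dtype=np.float64)
        object.__setattr__(self, "signals", signals)
        if signals.ndim != 2 or signals.shape[0] != 6:
            raise ShapeError(f"signals must be (6, T), got {signals.shape}")
        if not np.all(np.isfinite(signals)):
            raise ShapeError("rPPG signals contain non-finite values")

    def channel_mean(self) -> np.ndarray:
        return self.signals.mean(axis=0)


def _width(base: int, mult: float) -> int:
    return max(4, int(round(base * mult)))


class RppgEstimator(nn.Module):
    def __init__(self, cfg: RppgEstimatorConfig):
        rng = np.random.default_rng(cfg.seed)
        w = cfg.width_mult
        c1, c2 = _width(32, w), _width(64, w)
        self.cfg = cfg
        self.conv1 = nn.Conv3d(3, c1, (1, 5, 5), rng=rng)
        self.norm1 = nn.InstanceNorm3d(c1, relu=True)
        self.conv2a = nn.Conv3d(c1, c2, (3, 3, 3), dilation_t=2, rng=rng)
        self.norm2a = nn.InstanceNorm3d(c2, relu=True)
        self.conv2b = nn.Conv3d(c2, c2, (3, 3, 3), dilation_t=2, rng=rng)
        self.norm2b = nn.InstanceNorm3d(c2, relu=True)
        self.conv3a = nn.Conv3d(c2, c2, (3, 3, 3), dilation_t=2, rng=rng)
        self.norm3a = nn.InstanceNorm3d(c2, relu=True)
        self.conv3b = nn.Conv3d(c2, c2, (3, 3, 3), dilation_t=2, rng=rng)
        self.norm3b = nn.InstanceNorm3d(c2, relu=True)
        self.conv4a = nn.Conv3d(c2, c2, (3, 3, 3), dilation_t=2, rng=rng)
        self.norm4a = nn.InstanceNorm3d(c2, relu=True)
        self.conv4b = nn.Conv3d(c2, c2, (3, 3, 3), dilation_t=2, rng=rng)
        self.norm4b = nn.InstanceNorm3d(c2, relu=True)
        self.conv5 = nn.Conv3d(c2, c2, (3, 3, 3), rng=rng)
        self.norm5 = nn.InstanceNorm3d(c2, relu=True)
        self.conv6 = nn.Conv3d(c2, cfg.out_channels, (3, 3, 3), rng=rng)

    # ------------------------------------------------------------------
    @property
    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        """(B, 3, T, H, W) -> (B, out_channels, T); input already standardized."""
        B, C, T, H, W = x.shape
        if C != 3:
            raise ShapeError(f"expected 3 input channels, got {C}")
        if T % 2:
            raise ShapeError(f"temporal length must be even, got {T}")
        if H != W or H not in (8, 16, 32, 64, 128):
            raise ShapeError(
                f"spatial size must be square 8/16/32/64/128 (use crop_resize), got {H}x{W}"
            )
        pool_sp = [H >= 128, H >= 64, H >= 32]

        h = self.norm1(self.conv1(x))
        if pool_sp[0]:
            h = nn.avgpool3d(h, (1, 2, 2), (1, 2, 2))
        h = self.norm2a(self.conv2a(h))
        h = self.norm2b(self.conv2b(h))
        h = nn.avgpool3d(h, (2, 2, 2) if pool_sp[1] else (2, 1, 1),
                         (2, 2, 2) if pool_sp[1] else (2, 1, 1))
        h = self.norm3a(self.conv3a(h))
        h = self.norm3b(self.conv3b(h))
        if pool_sp[2]:
            h = nn.avgpool3d(h, (2, 2, 2), (1, 2, 2))
        h = self.norm4a(self.conv4a(h))
        h = self.norm4b(self.conv4b(h))
        h = nn.time_interp(h, T)
        h = self.norm5(self.conv5(h))
        h = h.mean(axis=(3, 4), keepdims=True)          # global spatial average
        h = self.conv6(h)
        return h.reshape(B, self.cfg.out_channels, T)


def build_estimator(cfg: RppgEstimatorConfig) -> RppgEstimator:
    return RppgEstimator(cfg)


def standardize_clip(frames: np.ndarray) -> np.ndarray:
    """Per-clip, per-channel standardization of (B, 3, T, H, W) pixel data."""
    m = frames.mean(axis=(2, 3, 4), keepdims=True)
    s = frames.std(axis=(2, 3, 4), keepdims=True)
    return ((frames - m) / (s + 1e-6)).astype(np.float32)


def clip_to_input(clip: VideoClip) -> np.ndarray:
    """(T, H, W, 3) [0,1] frames -> standardized (1, 3, T, H, W) batch."""
    x = clip.frames.transpose(3, 0, 1, 2)[None]
    return standardize_clip(x)


def forward(estimator: RppgEstimator, clip: VideoClip) -> MultiChannelRppg:
    """Run the estimator on one clip (no gradient bookkeeping kept)."""
    H, W = clip.size
    if H != W or H not in (8, 16, 32, 64, 128):
        raise ShapeError(
            f"clip is {H}x{W}; crop_resize it to a square 8/16/32/64/128 first"
        )
    y = estimator(nn.Tensor(clip_to_input(clip)))
    return MultiChannelRppg(y.data[0], clip.rate)


# ----------------------------------------------------------------------
# checkpointing
# ----------------------------------------------------------------------

def save_checkpoint(path, estimator: RppgEstimator, extra: dict | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": asdict(estimator.cfg), "extra": extra or {}}
    np.savez(path, __meta__=json.dumps(meta), **estimator.state_dict())


def load_checkpoint(path) -> RppgEstimator:
    data = np.load(Path(path), allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    est = RppgEstimator(RppgEstimatorConfig(**meta["config"]))
    est.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return est
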