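"""SpO2 regression head: CNN-BiLSTM deep features, MFAM, and fusion.

Two branches produce one oxygen-saturation estimate per analysis window:

* deep branch (Mout1): a 1-D CNN over time followed by a bidirectional
  LSTM, applied to the 6-channel rPPG series from the 3DCNN concatenated
  with relative photometric traces of the ROI (the backbone normalizes its
  input and feature maps, so absolute AC/DC amplitude — which carries the
  SpO2 information — must reach the head through this un-normalized path).
  The concatenated final hidden states pass through a linear layer and a
  sigmoid, so Mout1 lives on a [0, 1] scale.
* manual branch (Mout2): the six handcrafted features C_w (per-channel
  pixel means and variances of the ROI clip) pass through a linear layer,
  ReLU and softmax; the resulting attention weights sum to one and Mout2
  is the attention-weighted feature sum.

Fusion is SpO2 = k1 * Mout1 + k2 * Mout2 with the constraint k1 + k2 = 100
enforced structurally: a single free parameter theta defines
k1 = 100 * sigmoid(theta), k2 = 100 - k1, initialized at the 50/50 split.
The end-to-end loss is the mean squared error on the percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .exceptions import (
    DataError,
    InsufficientLengthError,
    InvalidParameterError,
    ShapeError,
    StateError,
)
from .preprocess import VideoClip
from .rppg_net import RppgEstimator, standardize_clip

__all__ = [
    "ManualFeatureVector",
    "FusionWeights",
    "SpO2Estimate",
    "manual_features",
    "photometric_traces",
    "MFAM",
    "mfam_forward",
    "CnnBiLstm",
    "GenericLstmHead",
    "Fusion",
    "fuse",
    "end_to_end_loss",
    "Spo2Model",
    "train_stage3",
    "train_end_to_end",
    "predict_windows",
]

_MID_RANGE_LOGIT = float(np.log(0.965 / 0.035))  # output prior at 96.5%

#: Learning-rate multiplier for the single fusion gate parameter.  The gate
#: moves k1/k2 across a 0-100 scale through one sigmoid, so its useful
#: parameter range (several logits) is far wider than that of ordinary
#: weights; desk-scale step budgets need a proportionally larger step.
FUSION_LR_SCALE = 25.0


@dataclass(frozen=True)
class ManualFeatureVector:
    """C_w = [mean_R, mean_G, mean_B, var_R, var_G, var_B] of an ROI clip."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.shape != (6,):
            raise ShapeError(f"manual feature vector must have 6 entries, got {v.shape}")
        if np.any(v[:3] < 0) or np.any(v[:3] > 1) or np.any(v[3:] < 0):
            raise InvalidParameterError("means must lie in [0,1], variances must be >= 0")


@dataclass(frozen=True)
class FusionWeights:
    """Attention weights with the structural constraint k1 + k2 = 100."""

    k1: float
    k2: float

    def __post_init__(self):
        if self.k1 < 0 or self.k2 < 0 or self.k1 + self.k2 != 100.0:
            raise InvalidParameterError(
                f"fusion weights must be non-negative and sum to 100, got {self}"
            )


@dataclass(frozen=True)
class SpO2Estimate:
    """One SpO2 value in percent for a window of frames [start, stop)."""

    value: float
    window: tuple[int, int] = (0, 0)

    def __post_init__(self):
        object.__setattr__(self, "value", float(np.clip(self.value, 0.0, 100.0)))


def manual_features(clip: VideoClip) -> ManualFeatureVector:
    """Per-channel mean and variance over all pixels and frames of a clip."""
    if clip.frames.size == 0:
        raise DataError("empty clip")
    flat = clip.frames.reshape(-1, 3).astype(np.float64)
    return ManualFeatureVector(np.concatenate([flat.mean(axis=0), flat.var(axis=0)]))


def photometric_traces(clip: VideoClip) -> np.ndarray:
    """Relative channel-mean traces, percent units: 100*(m_c(t)/mean - 1)."""
    m = clip.channel_means()                                  # (3, T)
    base = m.mean(axis=1, keepdims=True)
    return (100.0 * (m / base - 1.0)).astype(np.float64)


def photometric_summary(photo: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Window-level AC amplitudes and log-ratios of the photometric traces.

    Per channel, the AC amplitude is the RMS of the linearly detrended
    relative trace; the three pairwise log-ratios are the classical
    ratio-of-ratios features of camera oximetry.  These scalars reach the
    deep head directly: every learned path normalizes amplitudes away, and
    recovering an RMS through conv/LSTM machinery from a few dozen labeled
    windows is not realistic, whereas the ratio features make the SpO2
    dependence almost linear.
    """
    t = np.arange(photo.shape[1])
    ac = np.empty(3)
    for c in range(3):
        coef = np.polyfit(t, photo[c], 1)
        ac[c] = np.sqrt(np.mean((photo[c] - np.polyval(coef, t)) ** 2))
    r, g, b = ac + eps
    return np.array([ac[0], ac[1], ac[2],
                     np.log(r / b), np.log(g / b), np.log(r / g)])


class MFAM(nn.Module):
    """Manual feature attention module."""

    def __init__(self, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = nn.Parameter(rng.normal(0.0, 0.3, size=(6, 6)))
        self.bias = nn.Parameter(np.zeros(6))

    def __call__(self, c: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """(B, 6) features -> (attention weights (B, 6), Mout2 (B,))."""
        c = nn.as_tensor(c)
        z = nn.relu(c @ self.weight.transpose(1, 0) + self.bias)
        a = nn.softmax(z, axis=1)
        m2 = (a * c).sum(axis=1)
        return a, m2


def mfam_forward(c, weight: np.ndarray, bias: np.ndarray) -> float:
    """Functional MFAM evaluation for a single feature vector."""
    if not (np.all(np.isfinite(weight)) and np.all(np.isfinite(bias))):
        raise InvalidParameterError("MFAM parameters must be finite")
    v = c.values if isinstance(c, ManualFeatureVector) else np.asarray(c, float)
    module = MFAM.__new__(MFAM)
    module.weight = nn.Parameter(np.asarray(weight, dtype=np.float64))
    module.bias = nn.Parameter(np.asarray(bias, dtype=np.float64))
    _, m2 = module(nn.Tensor(v[None]))
    return float(m2.data[0])


class CnnBiLstm(nn.Module):
    """1-D conv stack over time, BiLSTM, linear head, sigmoid output."""

    def __init__(self, in_channels: int = 9, conv_channels=(32, 64),
                 hidden: int = 64, extra_features: int = 6,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        c1, c2 = conv_channels
        self.conv1 = nn.Conv3d(in_channels, c1, (5, 1, 1), rng=rng)
        self.conv2 = nn.Conv3d(c1, c2, (5, 1, 1), rng=rng)
        self.lstm = nn.BiLSTM(c2, hidden, rng=rng)
        self.out = nn.Linear(2 * hidden + extra_features, 1, rng=rng,
                             bias_init=_MID_RANGE_LOGIT)
        self.receptive = 9

    def __call__(self, x: nn.Tensor, extra: nn.Tensor | None = None) -> nn.Tensor:
        """(B, C, T) time series plus (B, K) window scalars -> (B,) in (0, 1)."""
        B, C, T = x.shape
        if T < self.receptive:
            raise InsufficientLengthError(
                f"window of {T} frames is below the conv receptive field "
                f"({self.receptive})"
            )
        h = x.reshape(B, C, T, 1, 1)
        h = nn.relu(self.conv1(h))
        h = nn.relu(self.conv2(h))
        h = h.reshape(B, h.shape[1], T).transpose(0, 2, 1)    # (B, T, C)
        h = self.lstm(h)
        if extra is not None:
            h = nn.concat([h, nn.as_tensor(extra)], axis=1)
        return nn.sigmoid(self.out(h)).reshape(B)


class GenericLstmHead(nn.Module):
    """Plain LSTM regression head (the generic 3DCNN-LSTM ablation arm)."""

    def __init__(self, in_channels: int = 9, hidden: int = 64,
                 extra_features: int = 6, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.lstm = nn.LSTM(in_channels, hidden, rng=rng)
        self.out = nn.Linear(hidden + extra_features, 1, rng=rng,
                             bias_init=_MID_RANGE_LOGIT)

    def __call__(self, x: nn.Tensor, extra: nn.Tensor | None = None) -> nn.Tensor:
        B, C, T = x.shape
        h = self.lstm(x.transpose(0, 2, 1))
        if extra is not None:
            h = nn.concat([h, nn.as_tensor(extra)], axis=1)
        return nn.sigmoid(self.out(h)).reshape(B)


class Fusion(nn.Module):
    """Constrained fusion k1*Mout1 + k2*Mout2 with k1 + k2 = 100 structural.

    One free parameter theta gives k1 = 100*sigmoid(theta); theta = 0
    initializes the published 50/50 split.
    """

    def __init__(self):
        self.theta = nn.Parameter(np.zeros(1))

    def k1_tensor(self) -> nn.Tensor:
        return nn.sigmoid(self.theta) * 100.0

    def weights(self) -> FusionWeights:
        k1 = float(self.k1_tensor().data[0])
        return FusionWeights(k1=k1, k2=100.0 - k1)

    def __call__(self, m1: nn.Tensor, m2: nn.Tensor) -> nn.Tensor:
        k1 = self.k1_tensor()
        return k1 * m1 + (100.0 - k1) * m2


def fuse(m1: float, m2: float, w: FusionWeights,
         window: tuple[int, int] = (0, 0)) -> SpO2Estimate:
    """Combine branch outputs into a clipped SpO2 percentage."""
    return SpO2Estimate(w.k1 * m1 + w.k2 * m2, window)


def end_to_end_loss(pred, ref) -> float:
    """Mean squared error between SpO2 estimates and references (percent)."""
    p = np.asarray([e.value if isinstance(e, SpO2Estimate) else e for e in np.atleast_1d(pred)],
                   dtype=np.float64)
    r = np.asarray(ref, dtype=np.float64)
    if p.shape != r.shape:
        raise ShapeError(f"length mismatch: {p.shape} vs {r.shape}")
    return float(((p - r) ** 2).mean())


# ----------------------------------------------------------------------
# full model
# ----------------------------------------------------------------------

class Spo2Model(nn.Module):
    """Backbone + deep head (+ optional MFAM fusion) in one object."""

    def __init__(self, estimator: RppgEstimator, head: nn.Module,
                 mfam: MFAM | None = None, fusion: Fusion | None = None):
        self.estimator = estimator
        self.head = head
        self.mfam = mfam
        self.fusion = fusion if mfam is not None else None
        if mfam is not None and fusion is None:
            self.fusion = Fusion()
        # z-scoring constants for the window summary features, fitted on the
        # training windows of the SpO2 stage (buffers, not parameters)
        self.summary_mean = np.zeros(6)
        self.summary_sd = np.ones(6)

    def fit_summary_norm(self, summary: np.ndarray):
        self.summary_mean = summary.mean(axis=0)
        self.summary_sd = summary.std(axis=0) + 1e-8

    def norm_summary(self, summary: np.ndarray) -> np.ndarray:
        return (summary - self.summary_mean) / self.summary_sd

    def head_parameters(self) -> list[nn.Tensor]:
        params = self.head.parameters()
        if self.mfam is not None:
            params += self.mfam.parameters() + self.fusion.parameters()
        return params

    def lr_scales(self, params: list[nn.Tensor]) -> list[float]:
        theta = self.fusion.theta if self.fusion is not None else None
        return [FUSION_LR_SCALE if p is theta else 1.0 for p in params]

    def head_forward(self, signals: nn.Tensor, photo: np.ndarray,
                     feats: np.ndarray, summary: np.ndarray) -> nn.Tensor:
        """Branch outputs -> fused percent-scale prediction, (B,) tensor."""
        x = nn.concat([signals, nn.Tensor(photo.astype(np.float32))], axis=1)
        extra = self.norm_summary(summary).astype(np.float32)
        m1 = self.head(x, extra=nn.Tensor(extra))
        if self.mfam is None:
            return 100.0 * m1
        _, m2 = self.mfam(nn.Tensor(feats.astype(np.float64)))
        return self.fusion(m1, m2)

    def signals_for(self, face: np.ndarray) -> np.ndarray:
        """Frozen-backbone forward of (B, 3, T, H, W) raw clips -> (B, 6, T)."""
        y = self.estimator(nn.Tensor(standardize_clip(face)))
        return y.data


def _augment_series(arrays: list[np.ndarray], rng: np.random.Generator,
                    shift: bool, noise: float) -> list[np.ndarray]:
    """Joint circular time-shift + additive noise for (B, C, T) series."""
    outs = [a.copy() for a in arrays]
    B = outs[0].shape[0]
    T = outs[0].shape[-1]
    for j in range(B):
        if shift:
            r = int(rng.integers(T))
            for a in outs:
                a[j] = np.roll(a[j], r, axis=-1)
    if noise > 0:
        for a in outs:
            a += rng.normal(0.0, noise, size=a.shape)
    return outs


def _window_arrays(windows):
    face = np.stack([w.face for w in windows])
    photo = np.stack([w.photo for w in windows])
    feats = np.stack([w.features for w in windows])
    summary = np.stack([w.photo_summary for w in windows])
    labels = np.array([w.label for w in windows], dtype=np.float64)
    return face, photo, feats, summary, labels


def train_stage3(model: Spo2Model, data, cfg) -> list[dict[str, float]]:
    """End-to-end SpO2 training with the 3DCNN frozen.

    Backbone outputs are precomputed once; only head, MFAM and fusion
    parameters receive updates, so the estimator weights are bit-identical
    before and after.
    """
    from .contrastive import _as_windows  # shared manifest handling

    if model.estimator is None:
        raise StateError("stage 3 requires a trained estimator checkpoint")
    windows = _as_windows(data, cfg)
    face, photo, feats, summary, labels = _window_arrays(windows)
    model.fit_summary_norm(summary)
    signals = np.concatenate(
        [model.signals_for(face[i:i + 4]) for i in range(0, len(windows), 4)]
    )
    rng = np.random.default_rng(cfg.seed)
    params = model.head_parameters()
    # beta2 = 0.99: the fusion gate starts at 50/50, so early residuals are
    # tens of percent; a long second-moment memory would keep step sizes
    # throttled long after the offset is fixed
    opt = nn.Adam(params, lr=cfg.lr, betas=(0.9, 0.99),
                  lr_scales=model.lr_scales(params))
    history: list[dict[str, float]] = []
    for epoch in range(cfg.epochs):
        total = 0.0
        n_b = 0
        order = rng.permutation(len(windows))
        for i in range(0, len(windows), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            sig_b, photo_b = _augment_series(
                [signals[idx], photo[idx]], rng,
                cfg.augment_shift, cfg.augment_noise)
            pred = model.head_forward(nn.Tensor(sig_b.astype(np.float32)),
                                      photo_b, feats[idx], summary[idx])
            err = pred - nn.Tensor(labels[idx])
            loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data)
            n_b += 1
        history.append({"epoch": epoch, "mse": total / n_b})
    return history


def train_end_to_end(model: Spo2Model, data, cfg) -> list[dict[str, float]]:
    """Joint training of backbone and head with the MSE loss (ablation arms)."""
    from .contrastive import _as_windows

    windows = _as_windows(data, cfg)
    face, photo, feats, summary, labels = _window_arrays(windows)
    model.fit_summary_norm(summary)
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    opt = nn.Adam(params, lr=cfg.lr, betas=(0.9, 0.99),
                  lr_scales=model.lr_scales(params))
    history: list[dict[str, float]] = []
    for epoch in range(cfg.epochs):
        total = 0.0
        n_b = 0
        order = rng.permutation(len(windows))
        for i in range(0, len(windows), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            face_b, photo_b = face[idx].copy(), photo[idx].copy()
            if cfg.augment_shift:
                for j in range(len(idx)):
                    r = int(rng.integers(face_b.shape[2]))
                    face_b[j] = np.roll(face_b[j], r, axis=1)   # (3, T, H, W)
                    photo_b[j] = np.roll(photo_b[j], r, axis=-1)
            if cfg.augment_noise > 0:
                photo_b = photo_b + rng.normal(0.0, cfg.augment_noise,
                                               photo_b.shape)
            y = model.estimator(nn.Tensor(standardize_clip(face_b)))
            pred = model.head_forward(y, photo_b, feats[idx], summary[idx])
            err = pred - nn.Tensor(labels[idx])
            loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data)
            n_b += 1
        history.append({"epoch": epoch, "mse": total / n_b})
    return history


def predict_windows(model: Spo2Model, windows) -> np.ndarray:
    """Clipped percent-scale predictions for a list of training windows."""
    face, photo, feats, summary, _ = _window_arrays(windows)
    preds = []
    for i in range(0, len(windows), 8):
        sl = slice(i, i + 8)
        signals = model.signals_for(face[sl])
        p = model.head_forward(nn.Tensor(signals.astype(np.float32)),
                               photo[sl], feats[sl], summary[sl])
        preds.append(p.data)
    return np.clip(np.concatenate(preds), 0.0, 100.0)
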