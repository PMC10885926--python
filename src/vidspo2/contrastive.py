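"""PSD-similarity contrastive learning for the rPPG estimator.

Training tuples mirror the recording protocol: during the first half of a
window the subject is still and the camera sees face (x_a) and hand (x_b);
x_c is a pseudo clip built by freezing one augmented frame of x_a (so it
carries no pulse); x_d is the face during the second half of the window,
where rotation may occur.  All clips pass through the shared 3DCNN and are
compared in the power-spectral-density domain, which discards phase and
(after L1 normalization) amplitude:

* positive loss  L_p: quadrant sub-ROIs of the hand agree with each other,
  quadrant sub-ROIs of the face agree with each other (both double sums
  over all ordered region/batch pairs, divided by 16 N^2), and the
  whole-clip spectra satisfy |f_a - f_b|^2 + |f_a - f_d|^2 (spatial
  similarity and short-term invariance).
* negative loss  L_n = -mean_{n1,n2} |f_a - f_c|^2: the pulse-free pseudo
  clip must look spectrally different.  With L1-normalized spectra this
  term is bounded below by -4, so no margin is needed.
* supervised loss L_s = 2 - cos(y_a, y~1) - cos(y_d, y~2) for fine-tuning
  on the few windows that have contact-PPG references.

Stage 1 minimizes L_p + L_n on unlabeled windows; stage 2 minimizes L_s.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import nn
from .data import TrainingWindow, build_windows
from .exceptions import DataError, DegenerateSignalError, ShapeError
from .preprocess import VideoClip
from .rppg_net import MultiChannelRppg, RppgEstimator, standardize_clip
from .signalcore import CARDIAC_BAND, Waveform

__all__ = [
    "StageConfig",
    "ContrastiveBatch",
    "build_pseudo_sample",
    "psd_features",
    "positive_loss",
    "negative_loss",
    "supervised_loss",
    "train_stage1",
    "train_stage2",
    "mean_reference_similarity",
]


@dataclass(frozen=True)
class StageConfig:
    """Hyper-parameters of one training stage.

    Full-scale defaults follow the published schedule (stage 1: lr 1e-3,
    300 epochs; stage 2: lr 1e-4, 200 epochs); desk-scale runs override
    ``epochs`` downward.
    """

    lr: float = 1e-3
    epochs: int = 20
    seed: int = 0
    batch_size: int = 4
    window_frames: int = 60
    windows_per_subject: int = 1
    #: SpO2-stage augmentation: random circular time shifts and additive
    #: noise on the head's time-series inputs.  Labels and the window-level
    #: amplitude summaries are shift-invariant, so this suppresses
    #: memorization of individual windows without touching the signal that
    #: carries SpO2.
    augment_shift: bool = True
    augment_noise: float = 0.05

    def __post_init__(self):
        if self.lr <= 0 or self.epochs < 1:
            raise ShapeError("lr must be positive and epochs >= 1")


@dataclass
class ContrastiveBatch:
    """PSD features of one (x_a, x_b, x_c, x_d) training tuple batch.

    All fields are autodiff tensors (or arrays) of L1-normalized spectra on
    a shared frequency grid: whole-clip spectra are (N, F); the quadrant
    region sets are (N, 4, F), four sub-ROIs per body part per sample.
    """

    f_a: nn.Tensor
    f_b: nn.Tensor
    f_c: nn.Tensor
    f_d: nn.Tensor
    hand_regions: nn.Tensor
    face_regions: nn.Tensor

    def __post_init__(self):
        for name in ("f_a", "f_b", "f_c", "f_d", "hand_regions", "face_regions"):
            setattr(self, name, nn.as_tensor(getattr(self, name)))
        F = self.f_a.shape[-1]
        for name in ("f_b", "f_c", "f_d", "hand_regions", "face_regions"):
            if getattr(self, name).shape[-1] != F:
                raise ShapeError(f"{name} is not on the shared frequency grid")

    @property
    def n(self) -> int:
        return self.f_a.shape[0]


# ----------------------------------------------------------------------
# pseudo samples
# ----------------------------------------------------------------------

def _pseudo_array(clip: np.ndarray, rng: np.random.Generator,
                  gain_jitter: float = 0.15, offset_jitter: float = 0.05,
                  noise_sd: float = 0.01) -> np.ndarray:
    """Static pseudo clip from one chromatically augmented frame.

    ``clip`` is (3, T, H, W); the result has the same shape but every frame
    is the same jittered copy of one uniformly chosen source frame.
    """
    _, T, _, _ = clip.shape
    k = int(rng.integers(T))
    frame = clip[:, k].copy()
    gains = 1.0 + rng.uniform(-gain_jitter, gain_jitter, size=3)
    offsets = rng.uniform(-offset_jitter, offset_jitter, size=3)
    frame = frame * gains[:, None, None] + offsets[:, None, None]
    if noise_sd > 0:
        frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
    frame = np.clip(frame, 0.0, 1.0).astype(np.float32)
    return np.broadcast_to(frame[:, None], clip.shape).copy()


def build_pseudo_sample(x_a: VideoClip, seed: int, gain_jitter: float = 0.15,
                        offset_jitter: float = 0.05,
                        noise_sd: float = 0.01) -> VideoClip:
    """Public clip-level wrapper around the pseudo-sample construction."""
    rng = np.random.default_rng(seed)
    arr = x_a.frames.transpose(3, 0, 1, 2)
    out = _pseudo_array(arr, rng, gain_jitter, offset_jitter, noise_sd)
    return VideoClip(out.transpose(1, 2, 3, 0), x_a.rate)


# ----------------------------------------------------------------------
# differentiable PSD features
# ----------------------------------------------------------------------

@lru_cache(maxsize=32)
def _dft_matrices(n: int, rate: float, low: float, high: float):
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():
        raise ShapeError(f"no DFT bins inside [{low}, {high}] Hz for n={n}")
    k = np.nonzero(mask)[0]
    t = np.arange(n)
    ang = 2.0 * np.pi * np.outer(t, k) / n
    window = np.hanning(n)
    cosm = (np.cos(ang) * window[:, None]).astype(np.float32)
    sinm = (np.sin(ang) * window[:, None]).astype(np.float32)
    return freqs[mask], cosm, sinm


def psd_grid(n: int, rate: float, band=CARDIAC_BAND) -> np.ndarray:
    """Frequency grid (Hz) of the band-limited PSD features for length n."""
    return _dft_matrices(n, float(rate), *band)[0]


def psd_features(y: nn.Tensor, rate: float, band=CARDIAC_BAND,
                 eps: float = 1e-8) -> nn.Tensor:
    """Differentiable band-limited, L1-normalized PSD of (B, C, T) signals.

    Per-channel Hann periodograms are individually normalized and averaged
    over channels, so every row sums to one regardless of channel gains.
    """
    y = nn.as_tensor(y)
    B, C, T = y.shape
    _, cosm, sinm = _dft_matrices(T, float(rate), *band)
    if y.data.dtype == np.float64:
        cosm, sinm = cosm.astype(np.float64), sinm.astype(np.float64)
    yc = y - y.mean(axis=2, keepdims=True)
    re = yc @ nn.Tensor(cosm)
    im = yc @ nn.Tensor(sinm)
    p = re * re + im * im + eps
    p = p / p.sum(axis=2, keepdims=True)
    return p.mean(axis=1)


# ----------------------------------------------------------------------
# losses
# ----------------------------------------------------------------------

def _all_pairs_sqdist(x: nn.Tensor) -> nn.Tensor:
    """Sum of squared distances over all ordered pairs of rows of (M, F)."""
    M = x.shape[0]
    s = (x * x).sum(axis=1)
    gram_total = (x @ x.transpose(1, 0)).sum()
    return 2.0 * M * s.sum() - 2.0 * gram_total


def positive_loss(batch: ContrastiveBatch) -> nn.Tensor:
    """Positive (similarity) loss of the contrastive stage."""
    n = batch.n
    F = batch.f_a.shape[-1]
    hand = batch.hand_regions.reshape(4 * n, F)
    face = batch.face_regions.reshape(4 * n, F)
    region_term = (_all_pairs_sqdist(hand) + _all_pairs_sqdist(face)) * (
        1.0 / (16.0 * n * n)
    )
    dab = batch.f_a - batch.f_b
    dad = batch.f_a - batch.f_d
    st_term = (dab * dab).sum(axis=1).mean() + (dad * dad).sum(axis=1).mean()
    return region_term + st_term


def negative_loss(batch: ContrastiveBatch) -> nn.Tensor:
    """Negative (dissimilarity) loss: -mean_{n1,n2} ||f_a - f_c||^2."""
    n = batch.n
    a, c = batch.f_a, batch.f_c
    sa = (a * a).sum()
    sc = (c * c).sum()
    cross = (a @ c.transpose(1, 0)).sum()
    return (n * sa + n * sc - 2.0 * cross) * (-1.0 / (n * n))


def _channel_mean_cosine(y: nn.Tensor, ref: np.ndarray) -> nn.Tensor:
    """Cosine similarity between channel-mean predictions and references.

    ``y`` is (B, 6, T); ``ref`` is a constant (B, T) array.  Returns (B,).
    """
    ym = y.mean(axis=1)
    ref = np.asarray(ref, dtype=np.float64)
    ref_norm = np.linalg.norm(ref, axis=1)
    if np.any(ref_norm == 0):
        raise DegenerateSignalError("zero-norm reference signal")
    num = (ym * nn.Tensor(ref)).sum(axis=1)
    pred_norm = ((ym * ym).sum(axis=1) + 1e-24) ** 0.5
    return num / (pred_norm * nn.Tensor(ref_norm))


def supervised_loss(y_a, y_d, ref1, ref2) -> float:
    """Fine-tuning loss L_s = 2 - cos(y_a, y~1) - cos(y_d, y~2) in [0, 4]."""
    def as_batch(y):
        if isinstance(y, MultiChannelRppg):
            return nn.Tensor(y.signals[None])
        y = nn.as_tensor(y)
        return y if y.ndim == 3 else nn.Tensor(y.data[None])

    def as_ref(r):
        r = r.samples if isinstance(r, Waveform) else np.asarray(r, dtype=np.float64)
        return r[None] if r.ndim == 1 else r

    ya, yd = as_batch(y_a), as_batch(y_d)
    r1, r2 = as_ref(ref1), as_ref(ref2)
    if ya.shape[-1] != r1.shape[-1] or yd.shape[-1] != r2.shape[-1]:
        raise ShapeError("prediction/reference length mismatch")
    if np.all(ya.data.mean(axis=1) == 0) or np.all(yd.data.mean(axis=1) == 0):
        raise DegenerateSignalError("zero-norm channel-mean prediction")
    loss = _supervised_loss_t(ya, yd, r1, r2)
    return float(loss.data)


def _supervised_loss_t(ya: nn.Tensor, yd: nn.Tensor, r1: np.ndarray,
                       r2: np.ndarray) -> nn.Tensor:
    sim1 = _channel_mean_cosine(ya, r1)
    sim2 = _channel_mean_cosine(yd, r2)
    return (2.0 - sim1 - sim2).mean()


# ----------------------------------------------------------------------
# training stages
# ----------------------------------------------------------------------

def _standardized_tensor(stack: np.ndarray) -> nn.Tensor:
    return nn.Tensor(standardize_clip(stack))


def _quadrant_stack(stack: np.ndarray) -> np.ndarray:
    """(N, 3, T, H, W) -> (4N, 3, T, H/2, W/2), regions in fixed order."""
    N, C, T, H, W = stack.shape
    h, w = H // 2, W // 2
    quads = [stack[:, :, :, :h, :w], stack[:, :, :, :h, w:],
             stack[:, :, :, h:, :w], stack[:, :, :, h:, w:]]
    return np.concatenate(quads, axis=0)


def batch_psds(model: RppgEstimator, windows: list[TrainingWindow],
               rng: np.random.Generator, band=CARDIAC_BAND) -> ContrastiveBatch:
    """Forward a window batch through the shared estimator into PSD space."""
    N = len(windows)
    T = windows[0].face.shape[1]
    th = T // 2
    rate = windows[0].rate
    xa = np.stack([w.face[:, :th] for w in windows])
    xb = np.stack([w.hand[:, :th] for w in windows])
    xd = np.stack([w.face[:, th:] for w in windows])
    xc = np.stack([_pseudo_array(w.face[:, :th], rng) for w in windows])

    whole = _standardized_tensor(np.concatenate([xa, xb, xc, xd], axis=0))
    y_whole = model(whole)                                    # (4N, 6, th)
    f_whole = psd_features(y_whole, rate, band)
    F = f_whole.shape[-1]

    quads = np.concatenate([_quadrant_stack(xa), _quadrant_stack(xb)], axis=0)
    y_quads = model(_standardized_tensor(quads))              # (8N, 6, th)
    f_quads = psd_features(y_quads, rate, band)

    # quadrant stacking is region-major: reshape to (4, N, F) then put N first
    f_face = f_quads[0:4 * N].reshape(4, N, F).transpose(1, 0, 2)
    f_hand = f_quads[4 * N:8 * N].reshape(4, N, F).transpose(1, 0, 2)
    return ContrastiveBatch(
        f_a=f_whole[0:N], f_b=f_whole[N:2 * N], f_c=f_whole[2 * N:3 * N],
        f_d=f_whole[3 * N:4 * N], hand_regions=f_hand, face_regions=f_face,
    )


def _as_windows(data, cfg: StageConfig) -> list[TrainingWindow]:
    if not data:
        raise DataError("empty training manifest")
    if isinstance(data[0], TrainingWindow):
        return list(data)
    windows: list[TrainingWindow] = []
    for sample in data:
        windows.extend(build_windows(sample, cfg.window_frames,
                                     max_windows=cfg.windows_per_subject))
    if not windows:
        raise DataError("no full analysis window fits the provided clips")
    return windows


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train_stage1(model: RppgEstimator, data, cfg: StageConfig,
                 ) -> list[dict[str, float]]:
    """Contrastive pre-training: minimize L_p + L_n on unlabeled windows."""
    windows = _as_windows(data, cfg)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    history: list[dict[str, float]] = []
    for epoch in range(cfg.epochs):
        lp_sum = ln_sum = 0.0
        n_batches = 0
        for idx in _batches(len(windows), cfg.batch_size, rng):
            batch = batch_psds(model, [windows[i] for i in idx], rng)
            lp = positive_loss(batch)
            ln = negative_loss(batch)
            loss = lp + ln
            opt.zero_grad()
            loss.backward()
            opt.step()
            lp_sum += float(lp.data)
            ln_sum += float(ln.data)
            n_batches += 1
        history.append({"epoch": epoch, "positive": lp_sum / n_batches,
                        "negative": ln_sum / n_batches,
                        "total": (lp_sum + ln_sum) / n_batches})
    return history


def train_stage2(model: RppgEstimator, data, cfg: StageConfig,
                 ) -> list[dict[str, float]]:
    """Supervised rPPG fine-tuning: minimize L_s against contact PPG."""
    windows = _as_windows(data, cfg)
    if any(w.ppg is None for w in windows):
        raise DataError("stage 2 requires PPG references for every window")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    history: list[dict[str, float]] = []
    for epoch in range(cfg.epochs):
        ls_sum = 0.0
        n_batches = 0
        for idx in _batches(len(windows), cfg.batch_size, rng):
            ws = [windows[i] for i in idx]
            th = ws[0].face.shape[1] // 2
            xa = np.stack([w.face[:, :th] for w in ws])
            xd = np.stack([w.face[:, th:] for w in ws])
            y = model(_standardized_tensor(np.concatenate([xa, xd], axis=0)))
            r1 = np.stack([w.ppg[:th] for w in ws])
            r2 = np.stack([w.ppg[th:2 * th] for w in ws])
            loss = _supervised_loss_t(y[0:len(ws)], y[len(ws):2 * len(ws)], r1, r2)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ls_sum += float(loss.data)
            n_batches += 1
        history.append({"epoch": epoch, "supervised": ls_sum / n_batches})
    return history


def mean_reference_similarity(model: RppgEstimator, data,
                              cfg: StageConfig) -> float:
    """Mean cosine similarity of channel-mean predictions vs. PPG references."""
    windows = _as_windows(data, cfg)
    sims = []
    for w in windows:
        y = model(_standardized_tensor(w.face[None]))
        sim = _channel_mean_cosine(y, w.ppg[None][:, :w.face.shape[1]])
        sims.append(float(sim.data[0]))
    return float(np.mean(sims))
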