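"""Shared signal-processing primitives.

Waveform filtering, resampling and normalization follow the standard rPPG
pre-processing recipe: a zero-phase FIR band-pass over the cardiac band
(0.5-4 Hz, which covers 30-240 bpm plus the second harmonic of typical
resting heart rates), z-scoring, and resampling to the video frame rate.
Power spectra are single Hann-windowed periodograms restricted to the
cardiac band and L1-normalized, so that they are invariant to signal phase
and amplitude -- the property the contrastive losses rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy import stats

from .exceptions import (
    DegenerateSignalError,
    InsufficientLengthError,
    InvalidParameterError,
    ShapeError,
)

__all__ = [
    "Waveform",
    "PSDVector",
    "CARDIAC_BAND",
    "bandpass_fir",
    "resample",
    "normalize",
    "compute_psd",
    "cosine_similarity",
    "metrics",
    "waveform_to_csv",
    "waveform_from_csv",
    "psd_to_csv",
]

#: Analysis band in Hz used for filtering and for all PSD features.
CARDIAC_BAND = (0.5, 4.0)


@dataclass(frozen=True)
class Waveform:
    """A 1-D sampled signal with its sampling rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise InvalidParameterError(f"rate must be positive, got {self.rate}")
        if samples.ndim != 1 or samples.size < 2:
            raise InvalidParameterError("waveform needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise InvalidParameterError("waveform contains non-finite samples")

    def __len__(self):
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class PSDVector:
    """An L1-normalized band-limited power spectrum on its frequency grid."""

    power: np.ndarray
    freqs: np.ndarray

    def __post_init__(self):
        power = np.asarray(self.power, dtype=np.float64)
        freqs = np.asarray(self.freqs, dtype=np.float64)
        object.__setattr__(self, "power", power)
        object.__setattr__(self, "freqs", freqs)
        if power.shape != freqs.shape or power.ndim != 1:
            raise ShapeError("power and freqs must be matching 1-D arrays")
        if not (np.all(np.isfinite(power)) and np.all(np.isfinite(freqs))):
            raise InvalidParameterError("PSD entries must be finite")
        if np.any(power < 0):
            raise InvalidParameterError("PSD power must be non-negative")
        if np.any(np.diff(freqs) <= 0):
            raise InvalidParameterError("frequency grid must be strictly increasing")
        if abs(power.sum() - 1.0) > 1e-6:
            raise InvalidParameterError("PSD must be L1-normalized")

    @property
    def peak_freq(self) -> float:
        return float(self.freqs[int(np.argmax(self.power))])


def _default_numtaps(rate: float, low_hz: float) -> int:
    order = int(round(4.0 * rate / low_hz))
    return order + 1 if order % 2 == 0 else order


def bandpass_fir(w: Waveform, low_hz: float = CARDIAC_BAND[0],
                 high_hz: float = CARDIAC_BAND[1],
                 order: int | None = None) -> Waveform:
    """Zero-phase FIR band-pass (windowed-sinc, applied forward-backward).

    The default order is ``4 * rate / low_hz`` rounded to the nearest odd
    tap count, long enough to roll off sharply at the 0.5 Hz edge.
    """
    nyq = w.rate / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise InvalidParameterError(
            f"cutoffs must satisfy 0 < {low_hz} < {high_hz} < Nyquist {nyq}"
        )
    numtaps = _default_numtaps(w.rate, low_hz) if order is None else int(order) + 1
    if numtaps % 2 == 0:
        numtaps += 1
    if len(w) <= numtaps:
        raise InsufficientLengthError(
            f"waveform of {len(w)} samples is shorter than the {numtaps}-tap filter"
        )
    taps = sps.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=w.rate)
    padlen = min(3 * numtaps, len(w) - 1)
    filtered = sps.filtfilt(taps, [1.0], w.samples, padlen=padlen)
    return Waveform(filtered, w.rate)


def resample(w: Waveform, target_rate: float) -> Waveform:
    """Polyphase resampling to ``target_rate``; identity if rates match."""
    if target_rate <= 0:
        raise InvalidParameterError(f"target rate must be positive, got {target_rate}")
    if np.isclose(target_rate, w.rate):
        return Waveform(w.samples.copy(), w.rate)
    frac = Fraction(target_rate / w.rate).limit_denominator(1000)
    out = sps.resample_poly(w.samples, frac.numerator, frac.denominator)
    return Waveform(out, target_rate)


def normalize(w: Waveform) -> Waveform:
    """Standardize to zero mean and unit standard deviation."""
    sd = w.samples.std()
    if sd == 0:
        raise DegenerateSignalError("cannot normalize a constant waveform")
    return Waveform((w.samples - w.samples.mean()) / sd, w.rate)


def compute_psd(w: Waveform, band: tuple[float, float] = CARDIAC_BAND) -> PSDVector:
    """Hann-windowed periodogram restricted to ``band``, L1-normalized."""
    low, high = band
    nyq = w.rate / 2.0
    if not (0.0 < low < high <= nyq):
        raise InvalidParameterError(f"band {band} outside (0, Nyquist {nyq}]")
    if w.duration < 2.0 / low:
        raise InsufficientLengthError(
            f"need at least {2.0 / low:.1f} s of signal for band low {low} Hz"
        )
    if np.allclose(w.samples, 0.0):
        raise DegenerateSignalError("all-zero waveform has no spectrum")
    freqs, power = sps.periodogram(w.samples, fs=w.rate, window="hann",
                                   detrend="constant")
    mask = (freqs >= low) & (freqs <= high)
    power, freqs = power[mask], freqs[mask]
    total = power.sum()
    if total == 0:
        raise DegenerateSignalError("waveform has no power inside the band")
    return PSDVector(power / total, freqs)


def cosine_similarity(a, b) -> float:
    """Cosine similarity A.B / (||A|| ||B||) of two equal-length signals."""
    av = a.samples if isinstance(a, Waveform) else np.asarray(a, dtype=np.float64)
    bv = b.samples if isinstance(b, Waveform) else np.asarray(b, dtype=np.float64)
    if av.shape != bv.shape:
        raise ShapeError(f"length mismatch: {av.shape} vs {bv.shape}")
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na == 0 or nb == 0:
        raise DegenerateSignalError("cosine similarity undefined for zero signal")
    return float(np.dot(av, bv) / (na * nb))


def metrics(pred, ref, include_pearson: bool = True) -> dict[str, float]:
    """MAE, RMSE, and Pearson correlation between SpO2 series (percent).

    MAE and RMSE are defined for any pair; the correlation requires both
    series to be non-constant, so ``include_pearson=False`` skips it.
    """
    p = np.asarray(pred, dtype=np.float64)
    r = np.asarray(ref, dtype=np.float64)
    if p.shape != r.shape or p.ndim != 1 or p.size < 2:
        raise ShapeError(f"need matching 1-D series of length >= 2, got {p.shape}, {r.shape}")
    err = p - r
    out = {"mae": float(np.abs(err).mean()),
           "rmse": float(np.sqrt((err ** 2).mean()))}
    if include_pearson:
        if p.std() == 0 or r.std() == 0:
            raise DegenerateSignalError(
                "Pearson correlation undefined for constant series")
        out["pearson"] = float(stats.pearsonr(p, r).statistic)
    return out


# ----------------------------------------------------------------------
# plain-text interchange
# ----------------------------------------------------------------------

def waveform_to_csv(w: Waveform, path):
    t = np.arange(len(w)) / w.rate
    np.savetxt(path, np.column_stack([t, w.samples]), delimiter=",",
               header="time_s,value", comments="")


def waveform_from_csv(path) -> Waveform:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    dt = np.diff(arr[:, 0])
    rate = 1.0 / float(np.median(dt))
    return Waveform(arr[:, 1], rate)


def psd_to_csv(p: PSDVector, path):
    np.savetxt(path, np.column_stack([p.freqs, p.power]), delimiter=",",
               header="freq_hz,power", comments="")
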