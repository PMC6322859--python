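"""Signal conditioning applied before the similarity analyses.

Every operation is applied independently per trial and per sensor (or per
series); trials are never mixed. Defaults mirror the conditioning the RSA
stages assume: linear detrending, a 30 Hz zero-phase low-pass, decimation
to 300 Hz, and Gaussian temporal smoothing of correlation values with a
40 ms kernel support and 8 ms standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import EpochSet

__all__ = [
    "FilterSpec",
    "SmoothSpec",
    "detrend_linear",
    "lowpass",
    "resample",
    "gaussian_smooth",
    "gaussian_kernel",
]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth low-pass specification."""

    cutoff: float = 30.0  # Hz
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass(frozen=True)
class SmoothSpec:
    """Truncated Gaussian kernel: ``window`` is the full support length."""

    window: float = 0.040  # s
    sd: float = 0.008  # s

    def __post_init__(self) -> None:
        if self.window <= 0 or self.sd <= 0:
            raise ValueError("window and sd must be positive")
        if self.window < 2 * self.sd:
            raise ValueError("window must be >= 2 * sd")


def detrend_linear(epochs: EpochSet) -> EpochSet:
    """Remove the least-squares line from every trial x sensor series."""
    if epochs.n_times < 2:
        raise ValueError("detrending needs >= 2 time samples")
    out = signal.detrend(epochs.data, axis=-1, type="linear")
    return epochs.with_data(out)


def lowpass(epochs: EpochSet, spec: FilterSpec = FilterSpec()) -> EpochSet:
    """Low-pass filter along time (forward-backward by default, so the
    effective attenuation is the squared magnitude response)."""
    fs = epochs.sample_rate
    if spec.cutoff >= fs / 2:
        raise ValueError(
            f"cutoff {spec.cutoff} Hz must be below Nyquist {fs / 2} Hz"
        )
    sos = signal.butter(spec.order, spec.cutoff, btype="low", fs=fs, output="sos")
    if spec.zero_phase:
        out = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    else:
        out = signal.sosfilt(sos, epochs.data, axis=-1)
    return epochs.with_data(out)


def resample(epochs: EpochSet, target_rate: float) -> EpochSet:
    """Decimate to ``target_rate`` with polyphase anti-alias filtering.

    Upsampling is refused. The output grid keeps the half-open convention:
    sample k sits at ``times[0] + k / target_rate`` and the new axis spans
    the same window (``ceil(n * target / source)`` samples).
    """
    fs = epochs.sample_rate
    if target_rate > fs * (1 + 1e-9):
        raise ValueError("no upsampling: target rate exceeds source rate")
    if abs(target_rate - fs) <= 1e-9 * fs:
        return epochs.with_data(epochs.data.copy())
    frac = Fraction(target_rate / fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(epochs.data, up, down, axis=-1)
    n_new = out.shape[-1]
    new_times = epochs.times[0] + np.arange(n_new) / target_rate
    return epochs.with_data(out, times=new_times)


def gaussian_kernel(spec: SmoothSpec, rate: float) -> np.ndarray:
    """Truncated, renormalized Gaussian kernel sampled at ``rate``."""
    half = int(round(spec.window * rate / 2))
    t = np.arange(-half, half + 1) / rate
    k = np.exp(-0.5 * (t / spec.sd) ** 2)
    return k / k.sum()


def gaussian_smooth(
    series: np.ndarray, spec: SmoothSpec, rate: float, axis: int = -1
) -> np.ndarray:
    """Convolve with a truncated Gaussian; edges renormalize over the
    available support so a constant series is preserved exactly."""
    from scipy.ndimage import convolve1d

    series = np.asarray(series, dtype=float)
    k = gaussian_kernel(spec, rate)
    n = series.shape[axis]
    if k.size > n:
        raise ValueError(f"kernel ({k.size} samples) longer than series ({n})")
    # renormalize by the kernel mass actually inside the series at each edge
    norm = np.convolve(np.ones(n), k, mode="same")
    out = convolve1d(series, k, axis=axis, mode="constant", cval=0.0)
    shape = [1] * series.ndim
    shape[axis] = n
    return out / norm.reshape(shape)
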