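"""Sliding-window segmentation and per-window power spectra.

A time course of T samples at repeat time TR is cut into overlapping
windows of even length W shifted by ``step`` TRs.  The number of windows
follows the pipeline convention ``Tw = (T - W) // step`` — for the study
dimensions (T = 159, W = 50, step = 1) this gives 109 windows, with the
final timepoint left unused.  Each window is mean-subtracted (optionally
Hann-tapered), Fourier-transformed, and reduced to power at the W/2
positive-frequency bins (DC dropped, Nyquist kept), so a spectrogram is an
S x Tw matrix with S = W/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import ValidationError


class ConfigurationError(ValueError):
    """Raised for an invalid windowing configuration."""


@dataclass(frozen=True)
class WindowingScheme:
    """Sliding-window layout: window length W (TRs), step, derived window count."""

    window_length_tr: int
    step_tr: int
    n_timepoints: int
    n_windows: int

    @property
    def n_bins(self) -> int:
        """S = W/2 frequency bins per window."""
        return self.window_length_tr // 2


@dataclass
class Spectrogram:
    """Windowed power spectra of one component: ``power`` is S x Tw, >= 0."""

    power: np.ndarray
    freq_hz: np.ndarray


def make_scheme(n_timepoints: int, window_length: int = 50, step: int = 1) -> WindowingScheme:
    """Build a windowing scheme; ``n_windows = (T - W) // step``.

    Note the convention deliberately excludes the final window that the
    usual ``(T - W) // step + 1`` count would include; at T=159, W=50,
    step=1 it yields 109 windows.
    """
    if window_length <= 0 or window_length % 2 != 0:
        raise ConfigurationError(f"window_length must be a positive even integer, got {window_length}")
    if step <= 0:
        raise ConfigurationError(f"step must be positive, got {step}")
    if window_length >= n_timepoints:
        raise ConfigurationError(
            f"window_length {window_length} must be shorter than the time course ({n_timepoints})"
        )
    n_windows = (n_timepoints - window_length) // step
    if n_windows < 2:
        raise ConfigurationError(
            f"configuration yields {n_windows} window(s); at least 2 required"
        )
    return WindowingScheme(window_length, step, n_timepoints, n_windows)


def segment(timecourse: np.ndarray, scheme: WindowingScheme) -> np.ndarray:
    """Cut a T-vector into the scheme's windows; returns a Tw x W array.

    Window k covers timepoints ``[k*step, k*step + W)``.
    """
    x = np.asarray(timecourse, dtype=float)
    if x.ndim != 1 or x.shape[0] != scheme.n_timepoints:
        raise ValidationError(
            f"time course length {x.shape} does not match scheme ({scheme.n_timepoints})"
        )
    W, s = scheme.window_length_tr, scheme.step_tr
    starts = np.arange(scheme.n_windows) * s
    return np.stack([x[k : k + W] for k in starts])


def bin_frequencies(window_length: int, tr_seconds: float) -> np.ndarray:
    """Center frequencies (Hz) of bins k = 1..W/2; the last is Nyquist."""
    k = np.arange(1, window_length // 2 + 1)
    return k / (window_length * tr_seconds)


def window_psd(window: np.ndarray, tr_seconds: float, taper: str | None = None) -> np.ndarray:
    """Power spectrum of one demeaned window at bins 1..W/2.

    Power is the squared DFT magnitude (no density scaling); ``taper`` may
    be ``"hann"`` for a Hann taper, default is rectangular.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.shape[0] % 2 != 0:
        raise ValidationError("window must be a 1-D vector of even length")
    if not np.isfinite(w).all():
        raise ValidationError("non-finite values in window")
    w = w - w.mean()
    if taper == "hann":
        w = w * np.hanning(w.shape[0])
    elif taper is not None:
        raise ConfigurationError(f"unknown taper {taper!r} (supported: hann)")
    spec = np.fft.rfft(w)
    return np.abs(spec[1:]) ** 2  # drop DC, keep Nyquist


def spectrogram(
    timecourse: np.ndarray,
    scheme: WindowingScheme,
    tr_seconds: float,
    taper: str | None = None,
    log_power: bool = False,
    zscore: bool = False,
) -> Spectrogram:
    """Spectrogram of one time course: column k is the PSD of window k."""
    x = np.asarray(timecourse, dtype=float)
    if zscore:
        sd = x.std()
        if sd == 0:
            raise ValidationError("cannot z-score a constant time course")
        x = (x - x.mean()) / sd
    windows = segment(x, scheme)
    power = np.stack([window_psd(w, tr_seconds, taper=taper) for w in windows], axis=1)
    if log_power:
        power = np.log(power + np.finfo(float).tiny)
    return Spectrogram(power=power, freq_hz=bin_frequencies(scheme.window_length_tr, tr_seconds))


def spectrogram_stack(
    data: np.ndarray,
    scheme: WindowingScheme,
    tr_seconds: float,
    taper: str | None = None,
    log_power: bool = False,
    zscore: bool = False,
) -> np.ndarray:
    """Vectorized spectrograms for a (..., T) array; returns (..., S, Tw).

    Identical in output to calling :func:`spectrogram` on each time course;
    used by the pipeline for throughput.
    """
    x = np.asarray(data, dtype=float)
    if x.shape[-1] != scheme.n_timepoints:
        raise ValidationError("last axis does not match the windowing scheme")
    if not np.isfinite(x).all():
        raise ValidationError("non-finite values in time-course array")
    if zscore:
        sd = x.std(axis=-1, keepdims=True)
        if np.any(sd == 0):
            raise ValidationError("cannot z-score a constant time course")
        x = (x - x.mean(axis=-1, keepdims=True)) / sd
    W, s = scheme.window_length_tr, scheme.step_tr
    win = np.lib.stride_tricks.sliding_window_view(x, W, axis=-1)[..., ::s, :]
    win = win[..., : scheme.n_windows, :]  # (..., Tw, W)
    win = win - win.mean(axis=-1, keepdims=True)
    if taper == "hann":
        win = win * np.hanning(W)
    elif taper is not None:
        raise ConfigurationError(f"unknown taper {taper!r} (supported: hann)")
    power = np.abs(np.fft.rfft(win, axis=-1)[..., 1:]) ** 2  # (..., Tw, S)
    if log_power:
        power = np.log(power + np.finfo(float).tiny)
    return np.swapaxes(power, -1, -2)  # (..., S, Tw)
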