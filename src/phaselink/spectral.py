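"""FWHM-parameterized complex Morlet wavelet time-frequency decomposition.

Wavelets are complex sine waves tapered by a Gaussian whose width is given
directly as the full-width-at-half-maximum (FWHM) of the taper in the time
domain, the parameterization that makes the time-frequency trade-off
explicit: taper(t) = exp(-4 ln 2 * t^2 / FWHM^2). The default bank spans
2-40 Hz in 50 logarithmically spaced steps with FWHM shrinking log-linearly
from 400 ms at 2 Hz to 104 ms at 40 Hz. Kernels are normalized to unit
spectral peak gain so power is comparable across frequencies.

Phase comes from the argument of the complex convolution, power from the
squared magnitude; :func:`power_db` converts power to dB change relative to
a pre-cue baseline pooled over start trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft

LN2 = np.log(2.0)


@dataclass
class WaveletBank:
    center_freqs_hz: np.ndarray
    fwhm_ms: np.ndarray
    kernels: list  # complex arrays, odd length, unit spectral peak gain
    fs: float

    @property
    def n_freqs(self) -> int:
        return self.center_freqs_hz.size

    @property
    def max_half_length(self) -> int:
        return max(k.size // 2 for k in self.kernels)


@dataclass
class TFDecomposition:
    """Complex wavelet coefficients [trial, freq, time] plus metadata.

    ``edge_mask`` is True where the convolution kernel ran past the epoch
    border (half a kernel length at each end, per frequency); those samples
    must not enter any statistic, which is what the +/-2.5 s epoch padding
    around the analysis windows is for.
    """

    coefficients: np.ndarray
    freqs_hz: np.ndarray
    time_s: np.ndarray
    fs: float
    edge_mask: np.ndarray  # [freq, time], True = unreliable

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.coefficients)

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2


def fwhm_schedule(freqs_hz: np.ndarray, fmin: float, fmax: float,
                  fwhm_start_ms: float, fwhm_end_ms: float) -> np.ndarray:
    """FWHM per frequency, interpolated linearly in log-frequency."""
    lf = np.log(freqs_hz)
    w = (lf - np.log(fmin)) / (np.log(fmax) - np.log(fmin))
    return fwhm_start_ms + w * (fwhm_end_ms - fwhm_start_ms)


def design_bank(fmin: float = 2.0, fmax: float = 40.0, n: int = 50,
                fwhm_start_ms: float = 400.0, fwhm_end_ms: float = 104.0,
                fs: float = 250.0) -> WaveletBank:
    """Build the Morlet wavelet bank."""
    if not fmin < fmax:
        raise ValueError("fmin must be < fmax")
    if n < 2:
        raise ValueError("need at least 2 frequencies")
    if fs <= 2 * fmax:
        raise ValueError(f"fs={fs:g} Hz violates Nyquist for fmax={fmax:g} Hz")
    freqs = np.geomspace(fmin, fmax, n)
    fwhms = fwhm_schedule(freqs, fmin, fmax, fwhm_start_ms, fwhm_end_ms)
    kernels = []
    for f, fwhm in zip(freqs, fwhms):
        fwhm_s = fwhm / 1000.0
        half = int(np.ceil(3.0 * fwhm_s * fs))  # length 6*FWHM+1
        t = np.arange(-half, half + 1) / fs
        taper = np.exp(-4.0 * LN2 * t ** 2 / fwhm_s ** 2)
        kern = taper * np.exp(2j * np.pi * f * t)
        # unit spectral peak gain
        gain = np.max(np.abs(np.fft.fft(kern, 8 * kern.size)))
        kernels.append(kern / gain)
    return WaveletBank(center_freqs_hz=freqs, fwhm_ms=fwhms,
                       kernels=kernels, fs=fs)


def decompose(signal: np.ndarray, bank: WaveletBank,
              time_s: np.ndarray | None = None) -> TFDecomposition:
    """Convolve epoched signals [trial, time] with the wavelet bank.

    Convolution is centered ('same' length); the returned edge mask flags
    the half-kernel region at each epoch border per frequency.
    """
    sig = np.atleast_2d(np.asarray(signal, dtype=float))
    n_trials, n_time = sig.shape
    longest = 2 * bank.max_half_length + 1
    if n_time < longest:
        raise ValueError(f"signal length {n_time} shorter than the longest "
                         f"kernel ({longest} samples)")
    bad = np.where(~np.isfinite(sig).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"non-finite samples in trial(s) {bad.tolist()}")
    if time_s is None:
        time_s = np.arange(n_time) / bank.fs

    nfft = spfft.next_fast_len(n_time + longest - 1)
    sig_f = spfft.fft(sig, nfft, axis=-1)
    coeffs = np.empty((n_trials, bank.n_freqs, n_time), dtype=np.complex128)
    edge = np.zeros((bank.n_freqs, n_time), dtype=bool)
    for i, kern in enumerate(bank.kernels):
        half = kern.size // 2
        kf = spfft.fft(kern, nfft)
        full = spfft.ifft(sig_f * kf[None, :], axis=-1)
        coeffs[:, i, :] = full[:, half:half + n_time]
        edge[i, :half] = True
        edge[i, n_time - half:] = True
    return TFDecomposition(coefficients=coeffs,
                           freqs_hz=bank.center_freqs_hz,
                           time_s=np.asarray(time_s, dtype=float),
                           fs=bank.fs, edge_mask=edge)


def power_db(power: np.ndarray, time_s: np.ndarray,
             baseline_window_s: tuple = (-0.5, -0.2),
             baseline_power: np.ndarray | None = None) -> np.ndarray:
    """Convert power to dB change relative to a per-frequency baseline.

    ``power`` is [..., freq, time]. The baseline is the mean over the
    baseline window (pooled over the leading axes, i.e. over start trials),
    unless ``baseline_power`` [freq] is given explicitly.
    """
    power = np.asarray(power, dtype=float)
    if baseline_power is None:
        sel = (time_s >= baseline_window_s[0]) & (time_s <= baseline_window_s[1])
        if not sel.any():
            raise ValueError("baseline window outside the epoch")
        axes = tuple(range(power.ndim - 2)) + (power.ndim - 1,)
        baseline_power = power[..., sel].mean(axis=axes)
    baseline_power = np.asarray(baseline_power, dtype=float)
    if np.any(baseline_power <= 0):
        raise ValueError("degenerate baseline: zero power at some frequency")
    return 10.0 * np.log10(power / baseline_power[..., :, None])
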