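"""Morlet wavelet time-frequency decomposition and the two ASSR statistics.

The auditory steady-state response is quantified from the trial x frequency
x time complex wavelet coefficients ``W_n(f, t)`` by

* **mean trial power (MTP)** — ``mean_n |W_n(f, t)|^2``, the trial-averaged
  power surface, and
* **phase-locking factor (PLF)** — ``| mean_n W_n(f, t) / |W_n(f, t)| |``,
  the magnitude of the trial-averaged unit phasor (1 = perfect phase
  consistency across trials, ~N^(-1/2) for random phases; also known as
  inter-trial coherence).

The wavelet is a complex Morlet with a constant number of cycles, truncated
at +/-5 Gaussian widths and normalized in the frequency domain so that a
unit-amplitude sinusoid at the wavelet's centre frequency yields |W| = 1 at
every frequency: |W|^2 then reads directly as squared signal amplitude.
Samples closer to an epoch edge than half the wavelet support are flagged
invalid (NaN) and propagate through MTP/PLF and the band summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as _fft

from .io import EpochSet


@dataclass
class TFRSet:
    """Trial x frequency x time complex wavelet coefficients."""

    coeffs: np.ndarray        # (n_trials, n_freqs, n_times), complex
    freqs: np.ndarray         # Hz, strictly increasing
    times: np.ndarray         # s, aligned to the source EpochSet
    fs: float
    meta: dict

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]


@dataclass
class SpectralMap:
    """Frequency x time real-valued surface (MTP or PLF)."""

    values: np.ndarray        # (n_freqs, n_times); NaN = invalid edge cell
    kind: str                 # "MTP" or "PLF"
    freqs: np.ndarray
    times: np.ndarray
    n_trials: int

    def to_frame(self):
        """Long-format export (freq, time, value)."""
        import pandas as pd

        f, t = np.meshgrid(self.freqs, self.times, indexing="ij")
        return pd.DataFrame({"freq": f.ravel(), "time": t.ravel(),
                             "value": self.values.ravel()})


def morlet_wavelet(freq: float, fs: float, n_cycles: float = 7.0) -> np.ndarray:
    """Complex Morlet wavelet, amplitude-normalized (see module docstring).

    Support is +/-5 sigma_t where sigma_t = n_cycles / (2 pi f).
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-0.5 * (t / sigma_t) ** 2) * np.exp(2j * np.pi * freq * t)
    # convolution with cos(2 pi f t) yields 0.5 * S * e^{i 2 pi f t} with
    # S = sum_m w[m] e^{-i 2 pi f m / fs}; scale so that |W| = 1 there
    gain = np.sum(w * np.exp(-2j * np.pi * freq * t))
    return 2.0 * w / gain


def morlet_tfr(epochs: EpochSet, freq_grid: np.ndarray,
               n_cycles: float = 7.0) -> TFRSet:
    """Per-trial complex Morlet decomposition of an EpochSet.

    Edge samples within half the wavelet support of either epoch edge are
    NaN-flagged per frequency.  Frequencies at/above Nyquist are rejected.
    """
    freqs = np.asarray(freq_grid, dtype=float)
    if freqs.ndim != 1 or len(freqs) == 0 or np.any(np.diff(freqs) <= 0):
        raise ValueError("freq_grid must be a nonempty strictly increasing 1-D array")
    fs = epochs.fs
    if freqs.max() >= fs / 2:
        raise ValueError(
            f"frequency grid reaches {freqs.max()} Hz >= Nyquist ({fs / 2} Hz)")
    x = np.asarray(epochs.data, dtype=float)
    n_tr, n_t = x.shape
    halves = np.ceil(5.0 * (n_cycles / (2.0 * np.pi * freqs)) * fs).astype(int)
    coeffs = np.empty((n_tr, len(freqs), n_t), dtype=complex)
    fft_cache: dict[int, np.ndarray] = {}   # data FFTs per transform length
    for k, f in enumerate(freqs):
        h = int(halves[k])
        nfft = _fft.next_fast_len(n_t + 2 * h, real=False)
        X = fft_cache.get(nfft)
        if X is None:
            X = fft_cache[nfft] = _fft.fft(x, n=nfft, axis=1)
        w = morlet_wavelet(f, fs, n_cycles)
        W = _fft.fft(w, n=nfft)
        conv = _fft.ifft(X * W[None, :], axis=1)
        coeffs[:, k, :] = conv[:, h:h + n_t]          # centre of 'full' conv
        if h >= n_t:
            coeffs[:, k, :] = np.nan
        elif h > 0:
            coeffs[:, k, :h] = np.nan
            coeffs[:, k, n_t - h:] = np.nan
    meta = {key: getattr(epochs, key)
            for key in ("region", "condition", "stimulus", "session_id")}
    return TFRSet(coeffs=coeffs, freqs=freqs, times=epochs.times, fs=fs, meta=meta)


def mtp(tfr: TFRSet) -> SpectralMap:
    """Mean trial power: trial average of |W|^2 (invalid cells stay NaN)."""
    if tfr.n_trials < 1:
        raise ValueError("MTP needs at least one trial")
    mag = np.abs(tfr.coeffs)
    values = np.mean(mag * mag, axis=0)
    return SpectralMap(values, "MTP", tfr.freqs, tfr.times, tfr.n_trials)


def plf(tfr: TFRSet) -> SpectralMap:
    """Phase-locking factor: |trial mean of W/|W||, in [0, 1].

    Undefined for fewer than two trials; cells where any trial has |W| = 0
    are NaN.
    """
    if tfr.n_trials < 2:
        raise ValueError("PLF is undefined for fewer than two trials")
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = tfr.coeffs / np.abs(tfr.coeffs)   # 0/0 -> NaN where |W| = 0
    values = np.abs(np.mean(unit, axis=0))
    return SpectralMap(values, "PLF", tfr.freqs, tfr.times, tfr.n_trials)


def band_window_mean(spec: SpectralMap, band: tuple[float, float],
                     window: tuple[float, float]) -> float:
    """Arithmetic mean of the map over a closed band x window rectangle.

    The published ASSR summary uses the 35-45 Hz band and the 50-550 ms
    window.  NaN (edge-invalid) cells are excluded; an empty intersection or
    an all-invalid rectangle is an error.
    """
    f_lo, f_hi = band
    t_lo, t_hi = window
    fm = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    tm = (spec.times >= t_lo) & (spec.times <= t_hi)
    if not fm.any() or not tm.any():
        raise ValueError(
            f"band {band} Hz x window {window} s does not intersect the map grid")
    cells = spec.values[np.ix_(fm, tm)]
    if np.all(np.isnan(cells)):
        raise ValueError("all cells in the requested rectangle are edge-invalid")
    return float(np.nanmean(cells))
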