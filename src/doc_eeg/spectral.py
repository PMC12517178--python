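"""Multitaper spectral estimation and band/region power tables.

The PSD estimator is the classic sliding-window multitaper of Thomson:
orthonormal DPSS (Slepian) tapers with time-bandwidth product NW applied to
each window, eigenspectra averaged over tapers and windows. Defaults follow
the anesthesia-EEG convention used throughout this package: 5-s windows,
2.5-s overlap, NW = 3, K = 5 tapers.

Conventions: one-sided power spectral density in microvolts squared per Hz,
normalized so that the integral over [0, fs/2] equals the signal variance for
zero-mean stationary input; band power in dB is 10*log10 of the density
integrated over the band (reference 1 microvolt squared). Band edges follow
the half-open convention for assigning discrete frequencies, but integration
runs over the closed interval with interpolated endpoints so that adjacent
band integrals partition the total power exactly.

Default bands: delta 1-4, theta 4-7, alpha 7-12, beta 12-30, gamma 30-45 Hz.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss as _dpss

from .errors import LengthError, ParameterError
from .montage import Montage
from .recording import EEGRecording

#: Integrand floor, in microvolts squared per Hz, guarding log of zero power.
POWER_FLOOR = 1e-12


@dataclass(frozen=True)
class BandDef:
    """A frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_lo < self.f_hi:
            raise ParameterError(f"invalid band {self.name}: [{self.f_lo}, {self.f_hi})")


DEFAULT_BANDS = (
    BandDef("delta", 1.0, 4.0),
    BandDef("theta", 4.0, 7.0),
    BandDef("alpha", 7.0, 12.0),
    BandDef("beta", 12.0, 30.0),
    BandDef("gamma", 30.0, 45.0),
)


@dataclass(frozen=True)
class MultitaperParams:
    """Sliding-window multitaper settings."""

    window_s: float = 5.0
    overlap_s: float = 2.5
    time_bandwidth: float = 3.0
    n_tapers: int = 5

    def __post_init__(self) -> None:
        if self.overlap_s >= self.window_s:
            raise ParameterError("overlap must be shorter than the window")
        if not 1 <= self.n_tapers <= 2 * self.time_bandwidth - 1:
            raise ParameterError(
                f"taper count {self.n_tapers} outside 1..2*NW-1 "
                f"(= {int(2 * self.time_bandwidth - 1)})"
            )


@dataclass
class PSDEstimate:
    """One-sided multitaper PSD, microvolts squared per Hz, per channel."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    channels: list[str]
    params: MultitaperParams

    def __post_init__(self) -> None:
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(self.power < 0):
            raise ParameterError("PSD cannot be negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ParameterError("frequency grid must be strictly increasing")


def dpss_tapers(n_samples: int, nw: float, k: int) -> np.ndarray:
    """Return k orthonormal DPSS tapers of length n_samples (k x n matrix)."""
    if not 1 <= k <= 2 * nw - 1:
        raise ParameterError(f"need 1 <= k <= 2*NW-1 = {int(2 * nw - 1)}, got k={k}")
    if n_samples <= 2 * k:
        raise ParameterError(f"n_samples={n_samples} too short for {k} tapers")
    tapers = _dpss(n_samples, nw, Kmax=k)
    return np.atleast_2d(tapers)


def _window_starts(n: int, n_win: int, stride: int) -> np.ndarray:
    if n < n_win:
        raise LengthError(f"series length {n} shorter than one window ({n_win})")
    return np.arange(0, n - n_win + 1, stride)


def _eigenspectra(x: np.ndarray, fs: float, params: MultitaperParams,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window taper-averaged one-sided PSDs: (times, freqs, (n_win x n_f))."""
    x = np.asarray(x, dtype=float).ravel()
    n_win = int(round(params.window_s * fs))
    stride = max(1, int(round((params.window_s - params.overlap_s) * fs)))
    starts = _window_starts(len(x), n_win, stride)
    tapers = dpss_tapers(n_win, params.time_bandwidth, params.n_tapers)
    segs = np.stack([x[s:s + n_win] for s in starts])  # (W, n_win)
    tapered = segs[:, None, :] * tapers[None, :, :]  # (W, K, n_win)
    spec = np.abs(rfft(tapered, axis=-1)) ** 2 / fs  # two-sided density
    spec *= 2.0
    spec[..., 0] /= 2.0
    if n_win % 2 == 0:
        spec[..., -1] /= 2.0
    per_window = spec.mean(axis=1)  # average tapers
    freqs = rfftfreq(n_win, 1.0 / fs)
    times = (starts + n_win / 2) / fs
    return times, freqs, per_window


def multitaper_psd(x: np.ndarray, fs: float,
                   params: MultitaperParams = MultitaperParams(),
                   channel: str = "x") -> PSDEstimate:
    """Multitaper PSD of one series, averaged over tapers and sliding windows."""
    _, freqs, per_window = _eigenspectra(x, fs, params)
    return PSDEstimate(freqs, per_window.mean(axis=0)[None, :], [channel], params)


def multitaper_spectrogram(x: np.ndarray, fs: float,
                           params: MultitaperParams = MultitaperParams(),
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window multitaper PSDs: (window_centers_s, freqs, times x freqs power)."""
    times, freqs, per_window = _eigenspectra(x, fs, params)
    return times, freqs, per_window


def psd_of_recording(rec: EEGRecording,
                     params: MultitaperParams = MultitaperParams()) -> PSDEstimate:
    """Multitaper PSD of every channel of a recording."""
    rows = [multitaper_psd(ch_data, rec.fs, params).power[0] for ch_data in rec.data]
    freqs = multitaper_psd(rec.data[0], rec.fs, params).freqs
    return PSDEstimate(freqs, np.stack(rows), list(rec.channels), params)


def band_power_linear(psd: PSDEstimate, band: BandDef) -> np.ndarray:
    """Integrated band power in microvolts squared, per channel."""
    f = psd.freqs
    if band.f_lo < f[0] or band.f_hi > f[-1]:
        raise ParameterError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}) outside PSD grid "
            f"[{f[0]}, {f[-1]}]"
        )
    inner = (f > band.f_lo) & (f < band.f_hi)
    grid = np.concatenate([[band.f_lo], f[inner], [band.f_hi]])
    vals = []
    for row in psd.power:
        dens = np.concatenate([
            [np.interp(band.f_lo, f, row)], row[inner], [np.interp(band.f_hi, f, row)]
        ])
        vals.append(np.trapezoid(np.maximum(dens, POWER_FLOOR), grid))
    return np.asarray(vals)


def band_power_db(psd: PSDEstimate, band: BandDef) -> np.ndarray:
    """10*log10 of the integrated band power (dB re 1 microvolt squared)."""
    return 10.0 * np.log10(band_power_linear(psd, band))


def regional_band_power(psd: PSDEstimate, montage: Montage,
                        bands: tuple[BandDef, ...] = DEFAULT_BANDS,
                        average: str = "db") -> pd.DataFrame:
    """Region x band power table (tidy: region, band, power_db).

    The region value is the mean over member channels of the per-channel dB
    band power (``average="db"``, the default) or the dB of the mean linear
    power (``average="linear"``).
    """
    if average not in ("db", "linear"):
        raise ParameterError(f"unknown averaging mode {average!r}")
    index = {ch: i for i, ch in enumerate(psd.channels)}
    rows = []
    for region in montage.regions:
        members = montage.channels_of(region)
        missing = [ch for ch in members if ch not in index]
        if missing:
            raise ParameterError(f"region {region!r}: channel(s) {missing} missing")
        idx = [index[ch] for ch in members]
        for band in bands:
            if average == "db":
                value = float(np.mean(band_power_db(psd, band)[idx]))
            else:
                value = float(10 * np.log10(np.mean(band_power_linear(psd, band)[idx])))
            rows.append({"region": region, "band": band.name, "power_db": value})
    return pd.DataFrame(rows)


def channel_band_power(psd: PSDEstimate,
                       bands: tuple[BandDef, ...] = DEFAULT_BANDS) -> pd.DataFrame:
    """Channel x band power table (tidy: channel, band, power_db)."""
    rows = []
    for band in bands:
        db = band_power_db(psd, band)
        rows.extend(
            {"channel": ch, "band": band.name, "power_db": float(v)}
            for ch, v in zip(psd.channels, db)
        )
    return pd.DataFrame(rows)
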