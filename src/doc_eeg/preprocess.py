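"""Preprocessing chain for anesthesia EEG.

Fixed stage order: zero-phase high-pass (0.1 Hz FIR, Hamming, order 3,300) ->
zero-phase low-pass (45 Hz) -> downsampling (2,000 -> 100 Hz) -> bad-channel
interpolation -> artifact-segment rejection -> average re-referencing. Every
action is recorded in a :class:`PreprocessReport`.

Zero-phase filtering applies a symmetric (linear-phase) FIR forward and
backward, so the effective magnitude response is squared and the net group
delay is zero. The convolutions run in the frequency domain
(:func:`scipy.signal.oaconvolve`) because the 3,300-tap high-pass at 2 kHz
would be prohibitively slow time-domain; for a symmetric kernel the two are
numerically equivalent. Edges are odd-reflection padded, as in
:func:`scipy.signal.filtfilt`.

Artifact handling is deterministic by design: windows where any channel
exceeds an absolute-amplitude or sample-to-sample gradient threshold are
excised (with padding), in place of ICA-plus-manual-review which cannot be
reproduced without human raters.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import DataQualityError, ParameterError
from .montage import neighbor_table
from .recording import EEGRecording

logger = logging.getLogger("doc_eeg.preprocess")


@dataclass(frozen=True)
class FilterSpec:
    """Specification of one zero-phase FIR filter."""

    kind: str  # "highpass" or "lowpass"
    cutoff: float  # Hz
    order: int  # number of taps minus one
    window: str = "hamming"
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass"):
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        if self.cutoff <= 0:
            raise ParameterError(f"cutoff must be positive, got {self.cutoff}")
        if self.order < 1:
            raise ParameterError(f"order must be >= 1, got {self.order}")


@dataclass
class PreprocessReport:
    """Record of everything the preprocessing chain did to a recording."""

    bad_channels: list[str] = field(default_factory=list)
    interpolated: list[str] = field(default_factory=list)
    dropped_channels: list[str] = field(default_factory=list)
    rejected_segments: list[tuple[float, float, str]] = field(default_factory=list)
    #: sample offsets (in the concatenated output) where a new contiguous
    #: segment starts; analysis windows must not span these cuts.
    segment_starts: list[int] = field(default_factory=list)
    final_fs: float = 0.0
    actions: list[str] = field(default_factory=list)


def _design_fir(spec: FilterSpec, fs: float) -> np.ndarray:
    if spec.cutoff >= fs / 2:
        raise ParameterError(
            f"cutoff {spec.cutoff} Hz >= Nyquist {fs / 2} Hz"
        )
    numtaps = spec.order + 1
    if numtaps % 2 == 0:
        numtaps += 1  # symmetric type-I FIR: odd tap count, exact zero-phase
    taps = signal.firwin(
        numtaps, spec.cutoff, fs=fs, window=spec.window,
        pass_zero=(spec.kind == "lowpass"),
    )
    if spec.kind == "highpass":
        # force an exact DC null: with cutoffs far below the transition width
        # (0.1 Hz at 2 kHz) the windowed design leaves substantial DC leakage
        taps = taps - taps.mean()
    return taps


def _zero_phase_apply(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward FIR via centred FFT convolution, filtfilt-style edges."""
    n = data.shape[-1]
    pad = min(len(taps) - 1, n - 1)
    if pad > 0:
        left = 2.0 * data[..., :1] - data[..., pad:0:-1]
        right = 2.0 * data[..., -1:] - data[..., -2:-pad - 2:-1]
        padded = np.concatenate([left, data, right], axis=-1)
    else:
        padded = data
    kernel = taps[np.newaxis, :] if padded.ndim == 2 else taps
    out = signal.oaconvolve(padded, kernel, mode="same", axes=-1)
    out = signal.oaconvolve(out, kernel, mode="same", axes=-1)
    return out[..., pad:pad + n] if pad > 0 else out


def fir_filter(rec: EEGRecording, spec: FilterSpec) -> EEGRecording:
    """Apply a zero-phase FIR filter channel-wise."""
    taps = _design_fir(spec, rec.fs)
    if rec.n_samples <= 3 * spec.order:
        logger.warning(
            "recording length %d <= 3x filter order %d; edge padding dominates",
            rec.n_samples, spec.order,
        )
    return rec.with_data(_zero_phase_apply(rec.data, taps))


def downsample(rec: EEGRecording, target_fs: float,
               antialias_order: int | None = None) -> EEGRecording:
    """Resample to ``target_fs`` after an anti-alias low-pass at 0.45*target_fs."""
    if target_fs > rec.fs:
        raise ParameterError(f"target fs {target_fs} > recording fs {rec.fs}")
    if target_fs == rec.fs:
        logger.warning("target fs equals recording fs; downsample is a no-op")
        return rec.with_data(rec.data.copy())
    ratio = rec.fs / target_fs
    if antialias_order is None:
        # sharp transition (~5 Hz at 2 kHz -> 100 Hz) so analysis bands just
        # below the new Nyquist are not shaved
        antialias_order = int(60 * max(ratio, 1)) + 10
    spec = FilterSpec("lowpass", 0.45 * target_fs, antialias_order)
    filtered = _zero_phase_apply(rec.data, _design_fir(spec, rec.fs))
    if abs(ratio - round(ratio)) < 1e-9:
        out = filtered[:, ::int(round(ratio))]
    else:  # rational resampling; anti-alias already applied above
        from fractions import Fraction

        frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
        out = signal.resample_poly(filtered, frac.numerator, frac.denominator, axis=-1)
    return rec.with_data(out, fs=target_fs)


def detect_bad_channels(rec: EEGRecording, z_thresh: float = 3.0,
                        flat_thresh: float = 1e-3) -> list[str]:
    """Flag channels with outlying log-variance (robust z) or near-zero variance.

    Deterministic: robust z uses the median and MAD of per-channel
    log-variance; a channel is bad if |z| > ``z_thresh`` or its variance falls
    below ``flat_thresh`` (microvolts squared).
    """
    if rec.n_channels < 4:
        raise ParameterError("bad-channel detection needs >= 4 channels")
    # robust per-channel variance: median over one-second windows, so a short
    # artifact burst does not condemn a whole channel (segment rejection
    # handles transients); plain variance for very short recordings
    win = int(round(rec.fs))
    n_win = rec.n_samples // win if win > 0 else 0
    if n_win >= 4:
        trimmed = rec.data[:, :n_win * win].reshape(rec.n_channels, n_win, win)
        variances = np.median(trimmed.var(axis=2), axis=1)
    else:
        variances = rec.data.var(axis=1)
    flagged = set(np.asarray(rec.channels)[variances < flat_thresh])
    alive = variances >= flat_thresh
    if alive.sum() >= 4:
        logv = np.log(variances[alive])
        mad = np.median(np.abs(logv - np.median(logv)))
        # floor the scale so near-identical channels cannot be false-flagged:
        # a channel must deviate by at least ~x1.8 in variance to reach |z|=3
        scale = max(1.4826 * mad, 0.2)
        z = (logv - np.median(logv)) / scale
        flagged |= set(np.asarray(rec.channels)[alive][np.abs(z) > z_thresh])
    return [ch for ch in rec.channels if ch in flagged]


def interpolate_channels(rec: EEGRecording, bad: list[str],
                         neighbors: dict[str, list[str]] | None = None,
                         ) -> tuple[EEGRecording, list[str], list[str]]:
    """Replace bad channels by the unweighted mean of their good neighbours.

    Returns ``(recording, interpolated, dropped)``; a bad channel with fewer
    than two good neighbours is dropped with a warning instead.
    """
    unknown = set(bad) - set(rec.channels)
    if unknown:
        raise ParameterError(f"bad channels not in recording: {sorted(unknown)}")
    if not bad:
        return rec.with_data(rec.data.copy()), [], []
    if neighbors is None:
        neighbors = neighbor_table()
    good = [ch for ch in rec.channels if ch not in bad]
    data = rec.data.copy()
    interpolated, dropped = [], []
    for ch in bad:
        donors = [nb for nb in neighbors.get(ch, []) if nb in good]
        if len(donors) < 2:
            logger.warning("channel %s has <2 good neighbours; dropping it", ch)
            dropped.append(ch)
            continue
        data[rec.channels.index(ch)] = np.mean(
            [rec.data[rec.channels.index(nb)] for nb in donors], axis=0
        )
        interpolated.append(ch)
    if dropped:
        keep = [i for i, ch in enumerate(rec.channels) if ch not in dropped]
        data = data[keep]
        channels = [rec.channels[i] for i in keep]
        return rec.with_data(data, channels=channels), interpolated, dropped
    return rec.with_data(data), interpolated, dropped


def reject_artifact_segments(rec: EEGRecording, amp_thresh: float = 150.0,
                             grad_thresh: float = 50.0, pad: float = 0.5,
                             ) -> tuple[EEGRecording, PreprocessReport]:
    """Excise windows where any channel exceeds amplitude/gradient thresholds.

    Flagged samples are dilated by ``pad`` seconds on both sides, contiguous
    runs become rejected segments, and the survivors are concatenated. The
    report's ``segment_starts`` marks the cut positions in the output so that
    downstream windowed analyses can avoid spanning a cut.
    """
    amp_bad = np.abs(rec.data) > amp_thresh
    grad_bad = np.zeros_like(amp_bad)
    if rec.n_samples > 1:
        grad_bad[:, 1:] = np.abs(np.diff(rec.data, axis=1)) > grad_thresh
    bad = (amp_bad | grad_bad).any(axis=0)
    pad_n = int(round(pad * rec.fs))
    if pad_n > 0 and bad.any():
        kernel = np.ones(2 * pad_n + 1, dtype=bool)
        bad = np.convolve(bad, kernel, mode="same") > 0

    report = PreprocessReport(final_fs=rec.fs)
    if bad.all() or (rec.n_samples and bad.mean() > 0.80):
        raise DataQualityError(
            f"{bad.mean():.0%} of samples exceed artifact thresholds"
        )
    edges = np.flatnonzero(np.diff(np.concatenate([[0], bad.astype(int), [0]])))
    starts, ends = edges[::2], edges[1::2]
    for s, e in zip(starts, ends):
        reason = "amplitude" if amp_bad[:, s:e].any() else "gradient"
        report.rejected_segments.append((s / rec.fs, e / rec.fs, reason))

    keep = ~bad
    kept = rec.data[:, keep]
    # cut positions in concatenated coordinates: cumulative kept count at each
    # rejected-segment start (interior cuts only)
    kept_before = np.concatenate([[0], np.cumsum(keep)])
    for s in starts:
        pos = int(kept_before[s])
        if 0 < pos < kept.shape[1]:
            report.segment_starts.append(pos)
    out = rec.with_data(kept)
    report.actions.append(
        f"rejected {len(report.rejected_segments)} segment(s), "
        f"{rec.n_samples - kept.shape[1]} samples"
    )
    return out, report


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference so the instantaneous mean across channels is zero."""
    if rec.n_channels < 2:
        raise ParameterError("average reference needs >= 2 channels")
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable thresholds of the chain (all stated in the units of the data)."""

    highpass_cutoff: float = 0.1  # Hz
    highpass_order: int = 3300
    lowpass_cutoff: float = 45.0  # Hz
    lowpass_order: int = 1500
    target_fs: float = 100.0  # Hz
    amp_thresh: float = 150.0  # microvolts
    grad_thresh: float = 50.0  # microvolts per sample
    artifact_pad: float = 0.5  # seconds
    badchan_z: float = 3.0
    flat_thresh: float = 1e-3  # microvolts squared


def preprocess(rec: EEGRecording, config: PreprocessConfig = PreprocessConfig(),
               ) -> tuple[EEGRecording, PreprocessReport]:
    """Run the full fixed-order chain and return the cleaned recording + report."""
    out = fir_filter(rec, FilterSpec("highpass", config.highpass_cutoff,
                                     config.highpass_order))
    out = fir_filter(out, FilterSpec("lowpass", config.lowpass_cutoff,
                                     config.lowpass_order))
    # discard filter edge transients (reflection padding cannot fully suppress
    # them for a cascade of long kernels); the analysis segment is interior
    edge = config.highpass_order + config.lowpass_order
    if out.n_samples > 4 * edge:
        out = out.with_data(out.data[:, edge:-edge])
    if config.target_fs < out.fs:
        out = downsample(out, config.target_fs)
    bad = detect_bad_channels(out, config.badchan_z, config.flat_thresh)
    out, interpolated, dropped = interpolate_channels(out, bad)
    out, report = reject_artifact_segments(
        out, config.amp_thresh, config.grad_thresh, config.artifact_pad
    )
    out = average_reference(out)
    report.bad_channels = bad
    report.interpolated = interpolated
    report.dropped_channels = dropped
    report.final_fs = out.fs
    report.actions = [
        f"highpass {config.highpass_cutoff} Hz (order {config.highpass_order})",
        f"lowpass {config.lowpass_cutoff} Hz (order {config.lowpass_order})",
        f"downsample -> {out.fs} Hz",
        f"bad channels {bad or 'none'} (interpolated {interpolated or 'none'}, "
        f"dropped {dropped or 'none'})",
        *report.actions,
        "average reference",
    ]
    return out, report
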