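"""Normalized permutation entropy (PE) of EEG time series.

PE quantifies signal complexity through the distribution of ordinal (rank
order) patterns. A series x is embedded into vectors
``X_i = [x(i), x(i+tau), ..., x(i+(m-1)tau)]``; each vector is reduced to the
permutation that sorts it ascending (ties broken by earlier index first,
i.e. a stable sort); and the Shannon entropy of the pattern distribution,

    H = -sum_j P_j ln P_j,   P_j = count_j / n_vectors,

is normalized by ln(m!) so 0 <= H <= 1: 0 for a fully regular (monotone)
series, 1 for one visiting all m! patterns equally. Defaults m = 6, tau = 1,
the usual choice for 100 Hz anesthesia EEG.

Patterns are encoded by the Lehmer code of the stable argsort — an internal
detail, but fixed so that reported ``pattern_counts`` are reproducible.
Unobserved patterns contribute zero (0 ln 0 := 0); normalization is always by
ln(m!), never by the number of observed patterns.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DataQualityError, LengthError, ParameterError
from .montage import Montage
from .recording import EEGRecording

logger = logging.getLogger("doc_eeg.entropy")


@dataclass(frozen=True)
class PEParams:
    """Embedding dimension m and time delay tau (samples)."""

    m: int = 6
    tau: int = 1

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ParameterError(f"embedding dimension m must be >= 2, got {self.m}")
        if self.tau < 1:
            raise ParameterError(f"time delay tau must be >= 1, got {self.tau}")

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.m)


@dataclass
class PEResult:
    """Normalized permutation entropy with its pattern histogram."""

    value: float
    n_vectors: int
    pattern_counts: np.ndarray  # length m!, indexed by Lehmer code
    params: PEParams

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ParameterError(f"PE {self.value} outside [0, 1]")
        if int(self.pattern_counts.sum()) != self.n_vectors:
            raise ParameterError("pattern counts do not sum to n_vectors")


@dataclass(frozen=True)
class DeltaPE:
    """PE(anesthesia) - PE(baseline) for one region/subject."""

    value: float
    region: str
    subject_id: str
    states: tuple[str, str] = ("steady_state", "baseline")


def _lehmer_codes(perms: np.ndarray) -> np.ndarray:
    """Lehmer code of each permutation row (vectorized over rows)."""
    n, m = perms.shape
    codes = np.zeros(n, dtype=np.int64)
    for i in range(m - 1):
        smaller_later = (perms[:, i + 1:] < perms[:, i:i + 1]).sum(axis=1)
        codes += smaller_later * math.factorial(m - 1 - i)
    return codes


def ordinal_pattern(window: np.ndarray, m: int | None = None) -> int:
    """Lehmer-code id in [0, m!) of one window's ordinal pattern.

    Ties are broken by earlier index first (stable ascending sort), so e.g.
    (2, 2) yields the ascending pattern.
    """
    window = np.asarray(window, dtype=float)
    if m is not None and len(window) != m:
        raise ParameterError(f"window length {len(window)} != m = {m}")
    if not np.all(np.isfinite(window)):
        raise DataQualityError("non-finite value in window")
    perm = np.argsort(window, kind="stable")
    return int(_lehmer_codes(perm[None, :])[0])


def permutation_entropy(x: np.ndarray, params: PEParams = PEParams()) -> PEResult:
    """Normalized permutation entropy of one series."""
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise DataQualityError("non-finite value in series")
    m, tau = params.m, params.tau
    span = (m - 1) * tau + 1
    if len(x) < span + 1:
        raise LengthError(
            f"need at least {(m - 1) * tau + 2} samples for m={m}, tau={tau}; "
            f"got {len(x)}"
        )
    counts = _pattern_counts(x, params)
    return _result_from_counts(counts, params)


def _pattern_counts(x: np.ndarray, params: PEParams) -> np.ndarray:
    m, tau = params.m, params.tau
    span = (m - 1) * tau + 1
    windows = sliding_window_view(x, span)[:, ::tau]  # (n_vectors, m)
    perms = np.argsort(windows, axis=1, kind="stable")
    codes = _lehmer_codes(perms)
    return np.bincount(codes, minlength=params.n_patterns)


def _result_from_counts(counts: np.ndarray, params: PEParams) -> PEResult:
    n_vectors = int(counts.sum())
    if n_vectors < 10 * params.n_patterns:
        # severe undersampling is worth a warning; mild gets debug level
        level = logging.WARNING if n_vectors < 5 * params.n_patterns else logging.DEBUG
        logger.log(
            level,
            "only %d pattern vectors for m=%d (%d patterns); "
            "PE estimate may be biased low", n_vectors, params.m, params.n_patterns,
        )
    p = counts[counts > 0] / n_vectors
    h = float(-(p * np.log(p)).sum() / math.log(params.n_patterns))
    h = 0.0 if h <= 0.0 else min(h, 1.0)  # clamp; avoids -0.0 for 1 pattern
    return PEResult(h, n_vectors, counts, params)


def permutation_entropy_segments(x: np.ndarray, segment_starts: list[int],
                                 params: PEParams = PEParams()) -> PEResult:
    """PE with pattern counts pooled across contiguous segments.

    ``segment_starts`` are sample offsets where artifact-rejection cuts fall;
    no embedding vector spans a cut. Segments too short to embed are skipped.
    """
    x = np.asarray(x, dtype=float).ravel()
    bounds = [0, *sorted(segment_starts), len(x)]
    counts = np.zeros(params.n_patterns, dtype=np.int64)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo >= (params.m - 1) * params.tau + 2:
            counts += _pattern_counts(x[lo:hi], params)
    if counts.sum() == 0:
        raise LengthError("no segment long enough to embed")
    return _result_from_counts(counts, params)


def channel_pe(rec: EEGRecording, params: PEParams = PEParams(),
               segment_starts: list[int] | None = None) -> pd.DataFrame:
    """Per-channel PE of a (preprocessed) recording: channel, pe, n_vectors."""
    rows = []
    for ch in rec.channels:
        res = permutation_entropy_segments(
            rec.channel(ch), segment_starts or [], params
        )
        rows.append({"channel": ch, "pe": res.value, "n_vectors": res.n_vectors})
    return pd.DataFrame(rows)


def regional_pe(rec: EEGRecording, montage: Montage,
                params: PEParams = PEParams(),
                segment_starts: list[int] | None = None) -> pd.DataFrame:
    """Region-level PE: mean over member channels of per-channel PE."""
    per_channel = channel_pe(rec, params, segment_starts)
    lookup = dict(zip(per_channel["channel"], per_channel["pe"]))
    rows = []
    for region in montage.regions:
        members = [ch for ch in montage.channels_of(region) if ch in lookup]
        if not members:
            raise ParameterError(f"region {region!r} has no usable channels")
        rows.append({"region": region,
                     "pe": float(np.mean([lookup[ch] for ch in members]))})
    return pd.DataFrame(rows)


def delta_pe(pe_anes: PEResult, pe_base: PEResult, region: str = "",
             subject_id: str = "") -> DeltaPE:
    """PE(anesthesia) - PE(baseline); sign convention: negative = lost complexity."""
    if pe_anes.params != pe_base.params:
        raise ParameterError(
            f"PE parameter mismatch: {pe_anes.params} vs {pe_base.params}"
        )
    return DeltaPE(pe_anes.value - pe_base.value, region, subject_id)
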