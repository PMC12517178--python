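"""Synthetic EEG and cohort generator.

This module emulates the *structure* of an anesthesia-EEG study in disorders
of consciousness so that every pipeline stage can be exercised without
patient data: 19-channel recordings at 2,000 Hz whose band powers and signal
complexity differ between anesthesia states with group-specific profiles, and
a CRS-R cohort whose change scores couple to the entropy change with
group-specific strength.

Signal model, per channel::

    x(t) = sum_b gain_b * s_b(t) + background(t)
    s_b(t) = normalize[(1 - lambda) * sin(2 pi f_b t + phi) + lambda * nb(t)]

where ``nb`` is Gaussian noise band-limited to band b (synthesized in the
frequency domain), ``phi`` is a channel-specific random phase, and the
mixture is renormalized to unit RMS so that ``gain_b`` *is* the band's RMS
amplitude in microvolts regardless of the complexity knob ``lambda``. The
oscillation frequencies ``f_b`` are in-band harmonics of a channel-specific
fundamental (~2.5 Hz, snapped to an integer period at the 100 Hz analysis
rate and fixed across states): at ``lambda = 0`` each channel is an exactly
periodic waveform with a small ordinal-pattern vocabulary, so permutation
entropy is genuinely low, and it rises monotonically as ``lambda`` trades the
harmonics for band noise (saturating above ``lambda ~ 0.5``). The background
is 1/f noise 20 dB below baseline oscillatory power, rolled off steeply above
the alpha range so that beta/gamma band contrasts are carried entirely by the
injected gains.

Determinism: all draws come from PCG64 streams keyed on
(seed, crc32(subject_id), state, channel), so outputs are bit-reproducible
and independent of cohort size or generation order.

Cohort model: ``dPE`` is drawn per subject from a group-specific normal
(TBI/CVA mean -0.21, SD 0.08; AIE mean -0.05, SD 0.05); the continuous CRS-R
change is ``intercept + slope * dPE + noise`` with per-group lines
(TBI 3.16 - 9.86x, CVA 1.03 - 6.67x, AIE 0.84 - 0.7x) and noise SDs chosen so
the regression R-squared is about 0.45 for TBI/CVA and near 0 for AIE. The
integer CRS-R change is distributed over subscales respecting their ranges.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crsr
from .errors import ParameterError
from .montage import CHANNELS_19
from .recording import GROUPS, STATES, EEGRecording
from .spectral import DEFAULT_BANDS, BandDef

logger = logging.getLogger("doc_eeg.synthetic")

#: Baseline band RMS amplitudes in microvolts (delta-dominated 1/f-ish EEG).
BASELINE_GAINS = {"delta": 20.0, "theta": 10.0, "alpha": 8.0, "beta": 5.0,
                  "gamma": 3.0}

#: Group-specific multiplicative gain changes under steady-state anesthesia:
#: beta/gamma suppression everywhere; AIE also loses alpha; AIE/TBI gain
#: slow-wave power; CVA keeps slow waves and alpha unchanged.
STEADY_MULTIPLIERS = {
    "AIE": {"delta": 1.3, "theta": 1.2, "alpha": 0.7, "beta": 0.5, "gamma": 0.5},
    "TBI": {"delta": 1.4, "theta": 1.3, "alpha": 0.8, "beta": 0.45, "gamma": 0.4},
    "CVA": {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 0.6, "gamma": 0.5},
}

#: Complexity knob per state: AIE barely loses complexity under anesthesia,
#: TBI/CVA lose a lot. Values sit in the responsive part of the PE(lambda)
#: curve (PE saturates above lambda ~ 0.5).
COMPLEXITY = {
    "AIE": {"baseline": 0.32, "induction": 0.29, "steady_state": 0.26,
            "recovery": 0.30},
    "TBI": {"baseline": 0.32, "induction": 0.18, "steady_state": 0.05,
            "recovery": 0.26},
    "CVA": {"baseline": 0.32, "induction": 0.19, "steady_state": 0.07,
            "recovery": 0.26},
}


@dataclass(frozen=True)
class GroupProfile:
    """Per-state band gains (microvolt RMS) and complexity for one group."""

    band_gain: dict[str, dict[str, float]]  # state -> band -> uV RMS
    complexity: dict[str, float]  # state -> lambda in [0, 1]
    pe_target: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for state, gains in self.band_gain.items():
            if any(g < 0 for g in gains.values()):
                raise ParameterError(f"negative band gain in state {state!r}")
        if any(not 0 <= lam <= 1 for lam in self.complexity.values()):
            raise ParameterError("complexity lambda must lie in [0, 1]")


def default_profile(group: str) -> GroupProfile:
    """The study-condition profile for one etiology group."""
    if group not in GROUPS:
        raise ParameterError(f"unknown group {group!r}")
    mult = STEADY_MULTIPLIERS[group]
    gains = {}
    for state in STATES:
        if state == "baseline":
            m = {b: 1.0 for b in BASELINE_GAINS}
        elif state == "steady_state":
            m = mult
        else:  # induction/recovery sit between the extremes
            w = 0.6 if state == "induction" else 0.25
            m = {b: 1.0 + w * (mult[b] - 1.0) for b in BASELINE_GAINS}
        gains[state] = {b: BASELINE_GAINS[b] * m[b] for b in BASELINE_GAINS}
    return GroupProfile(band_gain=gains, complexity=dict(COMPLEXITY[group]))


def _stream(seed: int, subject_id: str, state: str, channel: str) -> np.random.Generator:
    key = [int(seed), zlib.crc32(subject_id.encode()), STATES.index(state),
           zlib.crc32(channel.encode())]
    return np.random.default_rng(key)


#: Per-channel fundamental periods in samples at the 100 Hz analysis rate.
#: Each channel's oscillations are harmonics of fs/period, so the lambda = 0
#: waveform repeats exactly with a small ordinal-pattern vocabulary (low
#: permutation entropy). Distinct primes guarantee that no two channels share
#: any harmonic frequency below 100 Hz (m1/p1 = m2/p2 with p1 != p2 prime
#: forces m2 >= p2, i.e. >= 100 Hz), so channels stay uncorrelated and the
#: average reference cannot subtract a shared component. Fixed per channel
#: and across states, so filter roll-off at band edges cancels exactly in
#: state contrasts.
_CHANNEL_PERIODS = dict(zip(CHANNELS_19, (
    31, 37, 41, 43, 47, 53, 59, 61, 67, 71,
    73, 79, 83, 89, 97, 101, 103, 107, 109)))


def _fundamental(channel: str) -> float:
    return 100.0 / _CHANNEL_PERIODS.get(channel, 40)


def _harmonic_frequency(f0: float, band: BandDef) -> float:
    """In-band harmonic of the fundamental f0 closest to the band centre.

    Falls back to the band centre when no harmonic lands inside the band
    (cannot happen for the default bands with f0 in [2.25, 2.75]).
    """
    center = 0.5 * (band.f_lo + band.f_hi)
    k = max(1, int(round(center / f0)))
    for cand in (k, k - 1, k + 1):
        if cand >= 1 and band.f_lo <= cand * f0 < band.f_hi:
            return cand * f0
    return center


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                f_lo: float, f_hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [f_lo, f_hi] (frequency domain)."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = np.zeros(len(freqs), dtype=complex)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    k = int(band.sum())
    spec[band] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                f_floor: float = 0.5, f_knee: float = 12.0) -> np.ndarray:
    """Unit-RMS 1/f background (flat below ``f_floor``, steep above ``f_knee``).

    The extra roll-off above the alpha range keeps the background out of the
    beta/gamma bands: rhythmic content there is carried entirely by the band
    components, so injected gain contrasts stay analytically exact.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, f_floor))
    above = freqs > f_knee
    amp[above] *= (f_knee / freqs[above]) ** 2
    amp[0] = 0.0
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n)
    return x / np.sqrt(np.mean(x**2))


def generate_eeg(subject_id: str, group: str, state: str,
                 profile: GroupProfile | None = None, duration_s: float = 300.0,
                 fs: float = 2000.0, seed: int = 0,
                 bands: tuple[BandDef, ...] = DEFAULT_BANDS,
                 channels: tuple[str, ...] = CHANNELS_19) -> EEGRecording:
    """Generate one synthetic recording (channels x samples, microvolts)."""
    if duration_s < 60:
        logger.warning("duration %.0f s < 60 s: spectral/PE estimates unstable",
                       duration_s)
    if profile is None:
        profile = default_profile(group)
    gains = profile.band_gain[state]
    lam = profile.complexity[state]
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    data = np.empty((len(channels), n))
    # background anchored to the *baseline* oscillatory power (the noise floor
    # does not change with anesthesia state), 20 dB below it
    base_power = sum(g**2 for g in profile.band_gain["baseline"].values())
    bg_rms = np.sqrt(base_power) * 10 ** (-20 / 20)
    for ci, ch in enumerate(channels):
        rng = _stream(seed, subject_id, state, ch)
        f0 = _fundamental(ch)
        x = np.zeros(n)
        for band in bands:
            gain = gains.get(band.name, 0.0)
            if gain == 0.0:
                continue
            f_c = _harmonic_frequency(f0, band)
            phi = rng.uniform(0, 2 * np.pi)
            sine = np.sqrt(2.0) * np.sin(2 * np.pi * f_c * t + phi)  # unit RMS
            noise = _band_noise(rng, n, fs, band.f_lo, band.f_hi)
            mix = (1 - lam) * sine + lam * noise
            mix /= np.sqrt(np.mean(mix**2))
            x += gain * mix
        x += bg_rms * _pink_noise(rng, n, fs)
        data[ci] = x
    return EEGRecording(subject_id=subject_id, group=group, state=state,
                        fs=fs, channels=list(channels), data=data)


def calibrate_lambda(pe_target: float, params=None, band_gains: dict | None = None,
                     seed: int = 0, tol: float = 0.02, n_seeds: int = 5,
                     duration_s: float = 60.0) -> float:
    """Bisection on the complexity knob so measured PE hits ``pe_target``.

    PE is measured on a generated signal preprocessed to the analysis rate
    (100 Hz), averaged over ``n_seeds`` seeds. PE is empirically monotone
    increasing in lambda; a target outside [PE(0), PE(1)] raises a range
    error reporting the achievable interval.
    """
    from .entropy import PEParams, permutation_entropy
    from .preprocess import downsample

    params = params or PEParams()
    gains = band_gains or BASELINE_GAINS

    def measure(lam: float) -> float:
        profile = GroupProfile(
            band_gain={s: dict(gains) for s in STATES},
            complexity={s: lam for s in STATES},
        )
        vals = []
        for k in range(n_seeds):
            rec = generate_eeg("cal", "AIE", "baseline", profile,
                               duration_s=duration_s, seed=seed + k,
                               channels=("Cz",))
            rec = downsample(rec, 100.0)
            vals.append(permutation_entropy(rec.data[0], params).value)
        return float(np.mean(vals))

    lo, hi = 0.0, 1.0
    pe_lo, pe_hi = measure(lo), measure(hi)
    if not pe_lo - tol <= pe_target <= pe_hi + tol:
        raise ParameterError(
            f"PE target {pe_target} outside achievable range "
            f"[{pe_lo:.3f}, {pe_hi:.3f}]"
        )
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        pe_mid = measure(mid)
        if abs(pe_mid - pe_target) < tol:
            return mid
        if pe_mid < pe_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition cohort parameters (defaults mirror the study design)."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"AIE": 11, "CVA": 14, "TBI": 15})
    #: group -> (intercept, slope) of continuous dCRS-R on dPE
    regression: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"TBI": (3.16, -9.86), "CVA": (1.03, -6.67),
                                 "AIE": (0.84, -0.7)})
    #: group -> residual SD of the continuous dCRS-R (calibrated so R^2 ~ 0.45
    #: for TBI/CVA at the default slopes, ~0.01 for AIE)
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"TBI": 0.872, "CVA": 0.590, "AIE": 0.348})
    #: group -> (mean, SD) of dPE
    delta_pe: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"TBI": (-0.21, 0.08), "CVA": (-0.21, 0.08),
                                 "AIE": (-0.05, 0.05)})
    #: fraction of non-AIE subjects starting at MCS- (AIE start all UWS)
    mcs_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group.values()):
            raise ParameterError("need n >= 2 per group")


_UWS_PROFILE = dict(auditory=1, visual=1, motor=2, oromotor=1,
                    communication=0, arousal=2)
_MCS_MINUS_PROFILE = dict(auditory=1, visual=2, motor=2, oromotor=1,
                          communication=0, arousal=2)

#: Order in which integer CRS-R gains are assigned to subscales; motor and
#: visual first, mirroring where post-operative recovery concentrates.
_GAIN_ORDER = ("motor", "visual", "auditory", "arousal", "oromotor",
               "communication")


def _distribute_gain(pre: dict[str, int], total_gain: int) -> dict[str, int]:
    post = dict(pre)
    remaining = total_gain
    while remaining > 0:
        progressed = False
        for sub in _GAIN_ORDER:
            if remaining == 0:
                break
            if post[sub] < crsr.SUBSCALE_MAX[sub]:
                post[sub] += 1
                remaining -= 1
                progressed = True
        if not progressed:  # every subscale at ceiling
            break
    return post


def generate_cohort(config: CohortConfig = CohortConfig()) -> pd.DataFrame:
    """Generate the synthetic cohort table (one row per subject).

    Columns: subject_id, group, delta_pe, delta_crsr_cont (the continuous
    model value used by regression recovery tests), pre_/post_ subscales and
    totals, diagnoses, delta_crsr (integer) and the improvement flag.
    """
    rows = []
    for group in sorted(config.n_per_group):
        n = config.n_per_group[group]
        intercept, slope = config.regression[group]
        mu, sd = config.delta_pe[group]
        n_mcs = 0 if group == "AIE" else int(round(config.mcs_fraction * n))
        for i in range(n):
            sid = f"{group}{i + 1:03d}"
            rng = np.random.default_rng([config.seed, zlib.crc32(sid.encode())])
            dpe = mu + sd * rng.standard_normal()
            noise = config.noise_sd[group] * rng.standard_normal()
            dcrs_cont = intercept + slope * dpe + noise
            pre_profile = _MCS_MINUS_PROFILE if i < n_mcs else _UWS_PROFILE
            gain = int(round(dcrs_cont))
            if gain < 0:
                logger.warning("%s: continuous dCRS-R %.2f < 0 clipped to 0",
                               sid, dcrs_cont)
                gain = 0
            post_profile = _distribute_gain(pre_profile, gain)
            pre = crsr.CRSRAssessment(**pre_profile, timepoint="pre_op")
            post = crsr.CRSRAssessment(**post_profile, timepoint="month3")
            row = {
                "subject_id": sid, "group": group,
                "delta_pe": dpe, "delta_crsr_cont": dcrs_cont,
                **{f"pre_{k}": v for k, v in pre_profile.items()},
                **{f"post_{k}": v for k, v in post_profile.items()},
                "pre_total": crsr.total_score(pre),
                "post_total": crsr.total_score(post),
                "pre_diagnosis": str(crsr.classify(pre)),
                "post_diagnosis": str(crsr.classify(post)),
                "improved": crsr.improved(crsr.classify(pre), crsr.classify(post)),
            }
            row["delta_crsr"] = row["post_total"] - row["pre_total"]
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# long-format entropy tables for mixed-model recovery


@dataclass(frozen=True)
class LMMTruth:
    """Ground-truth parameters of the entropy linear mixed model."""

    beta_intercept: float = 0.72
    beta_group: float = -0.21  # TBI/CVA vs AIE
    beta_state: float = -0.15  # anesthesia vs baseline
    beta_interaction: float = 0.18
    sigma_u: float = 0.25  # random-intercept SD
    sigma_e: float = 0.12  # residual SD
    n_tbicva: int = 29
    n_aie: int = 11


def generate_entropy_long_table(truth: LMMTruth = LMMTruth(),
                                seed: int = 0) -> pd.DataFrame:
    """Simulate rows (subject, group, state, entropy) from the LMM truth."""
    rng = np.random.default_rng(seed)
    rows = []
    subjects = [("TBI/CVA", f"S{i:03d}") for i in range(truth.n_tbicva)] + [
        ("AIE", f"S{i + truth.n_tbicva:03d}") for i in range(truth.n_aie)]
    if len(subjects) < 2:
        raise ParameterError("need at least 2 subjects")
    if truth.n_tbicva + truth.n_aie == 1:
        logger.warning("single subject: variance components unidentifiable")
    for group, sid in subjects:
        g = 1.0 if group == "TBI/CVA" else 0.0
        u = truth.sigma_u * rng.standard_normal()
        for state, s in (("baseline", 0.0), ("anesthesia", 1.0)):
            mean = (truth.beta_intercept + truth.beta_group * g
                    + truth.beta_state * s + truth.beta_interaction * g * s)
            rows.append({
                "subject": sid, "group": group, "state": state,
                "entropy": mean + u + truth.sigma_e * rng.standard_normal(),
            })
    return pd.DataFrame(rows)
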