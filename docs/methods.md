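# Methods

`doc-eeg` implements an EEG analysis pipeline for studying how low-dose
propofol anesthesia modulates brain activity in patients with disorders of
consciousness (DoC), and how that modulation relates to behavioural outcome.
This note documents the models, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Data model

A recording is a channels × samples matrix in microvolts with a sampling
rate and 10–20 electrode labels drawn from the 19-channel legacy set
(FP1 … O2, with T3/T4/T5/T6 rather than T7/T8/P7/P8; modern names are
aliased on read). Each subject contributes up to four anesthesia states:
`baseline`, `induction`, `steady_state` (stable maintenance) and `recovery`.
All between-state contrasts ("Δ" quantities) are **steady_state − baseline**;
induction and recovery are carried descriptively when present. Channels are
grouped into six scalp regions: prefrontal (FP1, FP2), frontal (F3, Fz, F4),
central (C3, Cz, C4), parietal (P3, Pz, P4), occipital (O1, O2) and
temporal (T3, T4).

## Preprocessing

Fixed stage order: zero-phase high-pass → zero-phase low-pass → edge trim →
downsampling → bad-channel interpolation → artifact-segment rejection →
average re-referencing. Defaults:

| parameter | default | unit | note |
|---|---|---|---|
| high-pass cutoff / order | 0.1 / 3300 | Hz / taps | Hamming window |
| low-pass cutoff / order | 45 / 1500 | Hz / taps | removes line noise too |
| target rate | 100 | Hz | polyphase-free integer decimation |
| artifact amplitude / gradient | 150 / 50 | µV / µV·sample⁻¹ | rejection thresholds |
| rejection padding | 0.5 | s | around flagged samples |
| bad-channel robust z | 3.0 | – | on log-variance |
| flat threshold | 1e-3 | µV² | dead-channel variance floor |

Numerical choices worth knowing:

* **Zero-phase filtering** applies a symmetric FIR forward and backward
  (magnitude response squared, zero net group delay). The convolutions run
  in the frequency domain (`scipy.signal.oaconvolve`) with odd-reflection
  edge padding; for a symmetric kernel this is numerically equivalent to
  `filtfilt` but O(n log n), which matters for a 3,300-tap kernel at 2 kHz.
* The windowed high-pass design leaves measurable DC leakage when the cutoff
  (0.1 Hz) is far below the achievable transition width; the kernel is
  therefore shifted to have an exact zero at DC (taps minus their mean).
* A cascade of long zero-phase kernels leaves edge transients that reflection
  padding cannot fully suppress; the chain trims `highpass_order +
  lowpass_order` samples from each end (2.4 s at 2 kHz) before analysis.
* Downsampling applies an anti-alias low-pass at 0.45 × target rate with a
  sharp transition (~5 Hz for 2000 → 100) before integer decimation, so
  analysis bands just below the new Nyquist are not shaved.
* **Bad channels** are flagged from the robust z-score of log-variance across
  channels. The variance estimate per channel is the median over one-second
  windows (so a short burst does not condemn a channel), and the MAD scale is
  floored at 0.2 log-units so statistically identical channels can never be
  false-flagged. Flagged channels are replaced by the unweighted mean of
  their good neighbours in a shipped 10–20 adjacency table (no electrode
  coordinates are assumed, so spherical-spline interpolation is out of
  scope). Channels with fewer than two good neighbours are dropped.
* **Artifact rejection is deterministic** (amplitude/gradient thresholds with
  padding) rather than ICA with manual component review: reproducibility was
  prioritized over artifact-class specificity, and the rejected-segment
  boundaries are recorded so no downstream analysis window spans a cut.
  More than 80 % rejected raises a quality error instead of returning data.

## Spectral analysis

Multitaper PSD (Thomson): DPSS tapers with time–bandwidth NW = 3, K = 5
tapers, 5-s windows, 2.5-s overlap; eigenspectra averaged over tapers and
windows. The one-sided density in µV²/Hz is normalized so its integral over
[0, fs/2] equals the signal variance for zero-mean stationary input.

Frequency bands: δ 1–4, θ 4–7, α 7–12, β 12–30, γ 30–45 Hz. Band edges are
half-open `[lo, hi)` for assigning discrete frequencies, but band *power*
integrates the density over the closed interval by trapezoid with
interpolated endpoint values — shared endpoints are the only way band
integrals partition the total power exactly. Band power in dB is
10·log₁₀(∫ band density), reference 1 µV², with the integrand floored at
1e-12 µV²/Hz to keep logs finite. Regional values average member-channel dB
values (a linear-domain average is available via `average="linear"`).

## Permutation entropy

For embedding dimension m and delay τ, each vector
`[x(i), x(i+τ), …, x(i+(m−1)τ)]` is reduced to the permutation that sorts it
ascending, ties broken by earlier index (stable sort). With pattern
probabilities `P_j = count_j / n_vectors`,

    H = −Σ_j P_j ln P_j / ln(m!) ∈ [0, 1].

Defaults m = 6, τ = 1 at the 100 Hz analysis rate. Unobserved patterns
contribute zero; normalization is always by ln(m!), never by the number of
observed patterns. Patterns are encoded by the Lehmer code of the stable
argsort — an internal detail fixed for reproducibility of the histogram
output. PE is computed per channel over the full artifact-free segment
(pattern counts pooled across contiguous segments, no vector spanning a
rejection cut), then averaged per region; averaging signals before embedding
would cancel phase-incoherent activity and was rejected. ΔPE is
PE(steady_state) − PE(baseline). For the clinical correlation a band-limited
variant is also computed after a zero-phase 7–12 Hz band-pass (`pe_band`),
since entropy–outcome coupling is assessed in the alpha range. A 60-s segment
at 100 Hz yields ~6,000 vectors against 720 patterns for m = 6, which biases
PE slightly low but identically across states; the package warns below
10·m! vectors.

## CRS-R model

Six subscales — auditory 0–4, visual 0–5, motor 0–6, oromotor/verbal 0–3,
communication 0–2, arousal 0–3 — total 0–23. Diagnosis follows standard
CRS-R conventions (the source cohort tables report only labels, not
item-level rules, so the published convention is adopted explicitly):

* **EMCS**: functional communication (communication = 2) or functional
  object use (motor = 6);
* **MCS+**: command following (auditory ≥ 3), intelligible verbalization
  (oromotor = 3) or intentional communication (communication = 1);
* **MCS−**: visual fixation/pursuit (visual ≥ 2), localization/object
  manipulation (motor 3–5) or sound localization (auditory = 2);
* otherwise **UWS**. Arousal never enters the diagnosis.

Improvement is strictly diagnosis-level: post > pre on
UWS < MCS− < MCS+ < EMCS; a higher total at the same diagnosis does not
count. Standardized subscores divide each raw score by its subscale maximum.

## Statistics

Two-sided tests, α = 0.05 throughout. Wilcoxon signed-rank (exact below
n = 26 without ties, else normal approximation with continuity correction)
for within-group pre/post contrasts; Mann–Whitney U (exact for pooled
n ≤ 12 without ties) and Kruskal–Wallis for between-group contrasts;
rank-biserial r as the rank-test effect size and Cohen's d for parametric
contrasts. Benjamini–Hochberg FDR is applied within one family per
(contrast × band) across regions. Diagnosis tables get Pearson chi-square
**without** continuity correction — this convention exactly reproduces the
published statistics for the cohort tables — and Fisher's exact test
alongside (hypergeometric for 2×2; full enumeration over tables with fixed
margins for r×c with N ≤ 60, seeded Monte-Carlo beyond). Normality screening
uses the Lilliefors variant of the Kolmogorov–Smirnov test.

The entropy model is a random-intercept LMM,
`entropy ~ group * state + (1 | subject)`, with TBI/CVA pooled against AIE
as reference and anesthesia against baseline. It is fitted by REML profiled
down to the variance ratio θ = σ²ᵤ/σ²ₑ (for a single random intercept the
GLS step is closed-form per subject), with θ found by a bounded 1-D search
(tolerance 1e-8) and a θ = 0 boundary check. Fixed-effect inference is Wald
t with df = n_obs − 4 (the source reports plain t and CI without naming a
df method; Satterthwaite is out of scope). The test suite cross-checks the
fit against `statsmodels` MixedLM and against paired-OLS algebra on
within-subject differences. One observation per subject is flagged as a
boundary fit (intercept variance unidentifiable).

## Synthetic data generator

The generator defines the study conditions for all recovery tests; it
emulates structure, not biophysics.

**EEG**: each channel is a sum over the five bands of
`gain_b · normalize[(1−λ)·sine + λ·band-noise]` plus a 1/f background. Band
gains are µV RMS (baseline defaults δ 20, θ 10, α 8, β 5, γ 3 — a realistic
delta-dominated DoC spectrum in the 10–50 µV range), and the per-band
mixture is renormalized to unit RMS so the gain is exact regardless of λ.
The oscillations are harmonics of a channel-specific fundamental whose
period is a distinct **prime** number of samples (31–109) at 100 Hz: at
λ = 0 the waveform repeats exactly (small ordinal vocabulary, PE ≈ 0.63–0.71
by channel), and distinct primes guarantee no two channels share a harmonic
below 100 Hz, so the average reference cannot subtract a shared component.
Oscillation frequencies are fixed across states so filter roll-off at band
edges cancels exactly in state contrasts. PE rises monotonically in λ and
saturates near 0.83 above λ ≈ 0.5; `calibrate_lambda` bisects the curve to
hit a PE target (±0.02 over 5 seeds), e.g. 0.72 for a typical DoC baseline.
The background is 1/f noise 20 dB below baseline oscillatory power, rolled
off steeply above the alpha range: rhythmic β/γ content is carried entirely
by the injected gains, keeping gain contrasts analytically exact; the
background is state-independent, as a noise floor should be. Group profiles
encode the study contrasts: β/γ suppression in all groups under steady-state
anesthesia (γ ×0.5 for AIE/CVA, ×0.4 for TBI), slow-wave increase in
AIE/TBI, α preserved in CVA and reduced in AIE, and a large complexity drop
(λ 0.32 → ~0.05) for TBI/CVA against a minimal one for AIE. All draws come
from PCG64 streams keyed on (seed, CRC32(subject), state, channel), so
output is bit-reproducible and independent of cohort size or ordering.

**Cohort**: per-subject ΔPE is drawn from a group-specific normal (TBI/CVA
mean −0.21, SD 0.08; AIE mean −0.05, SD 0.05); the continuous CRS-R change
is `intercept + slope·ΔPE + noise` with group lines TBI 3.16 − 9.86x,
CVA 1.03 − 6.67x, AIE 0.84 − 0.7x. The residual SDs (0.872 / 0.590 / 0.348)
are a calibration choice: no within-group scatter is published, so they are
set to make R² ≈ 0.45 for TBI/CVA (r ≈ −0.67) and ≈ 0.01 for AIE at the
given slopes. The integer CRS-R change (continuous value rounded, floored at
0 with a warning) is distributed over subscales in a fixed priority order
(motor, visual, auditory, arousal, oromotor, communication — where recovery
concentrates clinically) respecting subscale maxima. Pre-op profiles are
UWS for all AIE subjects and ~80 % UWS / 20 % MCS− for CVA/TBI, matching
the cohort's marginal diagnosis mix. Long-format entropy tables for
mixed-model recovery are generated directly from the LMM with truth values
(intercept 0.72; group −0.21; state −0.15; interaction +0.18; σᵤ 0.25,
σₑ 0.12) for 29 + 11 subjects × 2 states.

**What passing tests do not show**: the generator has no eye-blink/EMG
artifact structure beyond injected threshold-crossing bursts, no volume
conduction or spatial correlation between electrodes, no non-stationarity
within a state, and its entropy floor (~0.63) is higher than deeply
suppressed clinical EEG can reach. Recovery of injected contrasts therefore
validates the estimators and the pipeline plumbing, not clinical
sensitivity or artifact robustness on real recordings.

## Problem sizes

The shipped demo study is 3 groups × 5 subjects × 2 states × 60 s of
19-channel EEG at 2 kHz (about half a minute of compute); regression
recovery uses 200 subjects per group and mixed-model coverage uses 200
replicates of 40 subjects — sizes chosen so every stochastic check has
comfortable Monte-Carlo margin while a full run stays in the minutes range.

## Known limitations

* The EDF writer is minimal (plain EDF, 16-bit, one-second records,
  zero-padded tail); it exists for fixtures and simulator output, not
  clinical archiving. CSV is the lossless interchange format.
* r×c Fisher enumeration is exponential in principle; beyond N = 60 it
  switches to seeded Monte-Carlo.
* The LMM supports exactly one random intercept — the model the analysis
  needs — not general random-effects structures.
* Diagnosis rules are a published convention, not the source cohort's
  (unreported) item-level rules; contingency analyses on synthetic cohorts
  depend on that convention.
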