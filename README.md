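# doc-eeg

EEG band power and permutation entropy analysis of propofol anesthesia in
disorders of consciousness (DoC), with Coma Recovery Scale-Revised (CRS-R)
outcome modelling.

Patients with DoC — unresponsive wakefulness syndrome (UWS) and minimally
conscious states (MCS) after severe brain injury — sometimes undergo surgery
(e.g. spinal cord stimulator implantation) under general anesthesia. How
their injured brains react to a standard anesthetic is itself informative:
the EEG response to propofol differs by etiology (traumatic brain injury,
stroke, anoxic encephalopathy) and may carry prognostic signal for later
recovery. This package provides a tested, reproducible pipeline for that
kind of study, for clinical neurophysiologists and biostatisticians:

* **Preprocessing** — zero-phase FIR filtering (0.1 Hz high-pass, 45 Hz
  low-pass, Hamming), downsampling 2,000 → 100 Hz, bad-channel
  interpolation on the 10–20 montage, deterministic amplitude/gradient
  artifact rejection, average re-referencing.
* **Spectral analysis** — multitaper PSD (DPSS tapers, 5 s windows, 2.5 s
  overlap, NW = 3, K = 5) and region × band power tables in dB for
  δ (1–4), θ (4–7), α (7–12), β (12–30) and γ (30–45 Hz).
* **Permutation entropy (PE)** — normalized ordinal-pattern entropy
  H = −Σ Pⱼ ln Pⱼ / ln(m!) with m = 6, τ = 1, per channel and region, and
  its anesthesia contrast ΔPE = PE(steady state) − PE(baseline).
* **CRS-R** — validation of the six subscales, totals, UWS/MCS−/MCS+/EMCS
  diagnosis, diagnosis-level improvement, and 0–1 standardized subscores.
* **Statistics** — Wilcoxon / Mann–Whitney / Kruskal–Wallis with
  rank-biserial effect sizes, Pearson chi-square and Fisher's exact test
  (r×c by enumeration), Benjamini–Hochberg FDR, Pearson/OLS regression of
  ΔCRS-R on ΔPE, and a random-intercept linear mixed model
  `entropy ~ group * state + (1 | subject)` fitted by profiled REML.
* **Synthetic data** — a seeded generator producing 19-channel EEG whose
  band powers and complexity differ by group and anesthesia state, plus
  CRS-R cohorts with group-specific ΔPE–ΔCRS-R coupling, so the entire
  pipeline is testable end to end without patient data.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Simulate one traumatic-brain-injury subject at baseline and under
steady-state anesthesia, and run the subject-level pipeline:

```python
from doc_eeg.synthetic import generate_eeg, default_profile
from doc_eeg.pipeline import run_subject, RunConfig

profile = default_profile("TBI")
recordings = {
    state: generate_eeg("TBI001", "TBI", state, profile, duration_s=60, seed=7)
    for state in ("baseline", "steady_state")
}
features = run_subject(recordings, RunConfig())
print(features.band_delta[features.band_delta.band == "gamma"].to_string(index=False))
print(features.pe_delta[features.pe_delta.variant == "broadband"].to_string(index=False))
```

```
    region  band  delta_db
   central gamma -7.758023
   frontal gamma -7.588018
 occipital gamma -8.068945
  parietal gamma -7.778148
prefrontal gamma -7.673130
  temporal gamma -7.623520
    region   variant  delta_pe
   central broadband -0.260341
   frontal broadband -0.239482
 occipital broadband -0.225287
  parietal broadband -0.266543
prefrontal broadband -0.191302
  temporal broadband -0.236653
```

The TBI profile halves-and-more the γ amplitude under anesthesia
(gain × 0.4 ⇒ 20·log₁₀ 0.4 ≈ −7.96 dB): the pipeline recovers that drop in
every region to within half a dB. The complexity knob drops from λ = 0.32
to 0.05, and regional PE falls by 0.19–0.27 everywhere — the suppression of
signal complexity that, in TBI/stroke patients, tracks later CRS-R
improvement.

A full cohort run (simulate → preprocess → spectra → entropy → statistics):

```bash
doc-eeg run-all --config configs/demo.yaml --out demo_out/
```

writes per-subject feature tables plus six result families under
`demo_out/results/`: within-group Wilcoxon with FDR, between-group
Kruskal–Wallis, diagnosis contingency tables (chi-square + Fisher),
per-group ΔCRS-R-on-ΔPE regression, the entropy mixed model, and
standardized CRS-R subscores. `doc-eeg simulate/preprocess/spectra/entropy/
features/stats` expose the individual stages.

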