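"""Subject- and cohort-level orchestration.

A subject run takes one recording per anesthesia state through the fixed
chain (preprocess -> multitaper band power -> permutation entropy) and forms
state contrasts; the "post-anesthesia" state for all deltas is
``steady_state`` (the stable maintenance segment), with induction/recovery
carried descriptively when present. A cohort run assembles the six result
families: within-group pre/post Wilcoxon with BH-FDR, between-group
Kruskal-Wallis / Mann-Whitney, diagnosis contingency tables with chi-square
and Fisher tests, per-group regression of CRS-R change on entropy change,
the random-intercept mixed model on regional entropy, and the standardized
CRS-R subscore table.

FDR families are one family per (contrast x band) across regions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crsr
from .entropy import PEParams, regional_pe
from .errors import ParameterError
from .montage import Montage
from .preprocess import FilterSpec, PreprocessConfig, fir_filter, preprocess
from .recording import EEGRecording
from .spectral import DEFAULT_BANDS, BandDef, MultitaperParams, psd_of_recording, \
    regional_band_power
from .stats import ContingencyTable, bh_fdr, chi_square, fisher_exact, \
    fit_random_intercept_lmm, kruskal_wallis, mann_whitney_u, pearson_regression, \
    wilcoxon_signed_rank

logger = logging.getLogger("doc_eeg.pipeline")

CONTRAST = ("steady_state", "baseline")  # (post, pre) for all deltas


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings for a full run."""

    preprocess: PreprocessConfig = PreprocessConfig()
    multitaper: MultitaperParams = MultitaperParams()
    pe: PEParams = PEParams()
    #: band limits for the band-limited PE used in the clinical correlation
    pe_band: tuple[float, float] = (7.0, 12.0)
    pe_band_order: int = 100
    bands: tuple[BandDef, ...] = DEFAULT_BANDS
    montage: Montage = field(default_factory=Montage)
    lmm_region: str = "prefrontal"
    alpha: float = 0.05


@dataclass
class SubjectFeatures:
    """Per-subject feature tables (tidy DataFrames)."""

    subject_id: str
    group: str | None
    band_power: pd.DataFrame  # state, region, band, power_db
    band_delta: pd.DataFrame  # region, band, delta_db
    pe: pd.DataFrame  # state, region, variant, pe
    pe_delta: pd.DataFrame  # region, variant, delta_pe


def _band_limited(rec: EEGRecording, lo: float, hi: float, order: int) -> EEGRecording:
    out = fir_filter(rec, FilterSpec("highpass", lo, order))
    return fir_filter(out, FilterSpec("lowpass", hi, order))


def run_subject(recordings: dict[str, EEGRecording],
                config: RunConfig = RunConfig()) -> SubjectFeatures:
    """Compute band-power and PE features for one subject across states."""
    missing = [s for s in CONTRAST if s not in recordings]
    if missing:
        raise ParameterError(f"missing required state recording(s): {missing}")
    any_rec = next(iter(recordings.values()))
    bp_rows, pe_rows = [], []
    for state, rec in recordings.items():
        clean, report = preprocess(rec, config.preprocess)
        psd = psd_of_recording(clean, config.multitaper)
        bp = regional_band_power(psd, config.montage, config.bands)
        bp.insert(0, "state", state)
        bp_rows.append(bp)
        broad = regional_pe(clean, config.montage, config.pe, report.segment_starts)
        broad.insert(0, "state", state)
        broad["variant"] = "broadband"
        pe_rows.append(broad)
        lo, hi = config.pe_band
        narrow_rec = _band_limited(clean, lo, hi, config.pe_band_order)
        narrow = regional_pe(narrow_rec, config.montage, config.pe,
                             report.segment_starts)
        narrow.insert(0, "state", state)
        narrow["variant"] = "band_limited"
        pe_rows.append(narrow)

    band_power = pd.concat(bp_rows, ignore_index=True)
    pe = pd.concat(pe_rows, ignore_index=True)

    post, pre = CONTRAST
    bp_wide = band_power.pivot_table(index=["region", "band"], columns="state",
                                     values="power_db")
    band_delta = (bp_wide[post] - bp_wide[pre]).rename("delta_db").reset_index()
    pe_wide = pe.pivot_table(index=["region", "variant"], columns="state",
                             values="pe")
    pe_delta = (pe_wide[post] - pe_wide[pre]).rename("delta_pe").reset_index()
    return SubjectFeatures(any_rec.subject_id, any_rec.group, band_power,
                           band_delta, pe, pe_delta)


def features_table(features: list[SubjectFeatures]) -> pd.DataFrame:
    """Stack per-subject band-power tables into one tidy frame."""
    frames = []
    for f in features:
        df = f.band_power.copy()
        df.insert(0, "subject_id", f.subject_id)
        df.insert(1, "group", f.group)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _within_group_tests(features: list[SubjectFeatures], alpha: float) -> pd.DataFrame:
    rows = []
    groups = sorted({f.group for f in features})
    for group in groups:
        members = [f for f in features if f.group == group]
        if len(members) < 3:
            logger.warning("group %s has n=%d < 3: skipped in within-group tests",
                           group, len(members))
            continue
        deltas = pd.concat(
            [m.band_delta.assign(subject_id=m.subject_id) for m in members]
        )
        for band, band_df in deltas.groupby("band"):  # one FDR family per band
            fam = []
            for region, region_df in band_df.groupby("region"):
                d = region_df["delta_db"].to_numpy()
                try:
                    res = wilcoxon_signed_rank(d)
                except Exception as exc:
                    logger.warning("wilcoxon %s/%s/%s failed: %s",
                                   group, band, region, exc)
                    continue
                fam.append({
                    "group": group, "band": band, "region": region,
                    "method": res.method, "n": res.n,
                    "statistic": res.statistic, "p": res.p_value,
                    "effect_size": res.effect_size,
                })
            if fam:
                adj = bh_fdr([r["p"] for r in fam], alpha)
                for r, pa, rej in zip(fam, adj.adjusted, adj.rejected):
                    r["p_adjusted"] = float(pa)
                    r["significant"] = bool(rej)
                rows.extend(fam)
    return pd.DataFrame(rows)


def _between_group_tests(features: list[SubjectFeatures], alpha: float) -> pd.DataFrame:
    rows = []
    groups = sorted({f.group for f in features})
    eligible = [g for g in groups
                if sum(f.group == g for f in features) >= 3]
    if len(eligible) < 2:
        logger.warning("fewer than 2 groups with n >= 3: between-group tests skipped")
        return pd.DataFrame(rows)
    deltas = pd.concat(
        [f.band_delta.assign(group=f.group) for f in features if f.group in eligible]
    )
    for band, band_df in deltas.groupby("band"):
        fam = []
        for region, region_df in band_df.groupby("region"):
            samples = [region_df.loc[region_df["group"] == g, "delta_db"].to_numpy()
                       for g in eligible]
            try:
                if len(eligible) >= 3:
                    res = kruskal_wallis(*samples)
                else:
                    res = mann_whitney_u(samples[0], samples[1])
            except Exception as exc:
                logger.warning("between-group %s/%s failed: %s", band, region, exc)
                continue
            fam.append({
                "band": band, "region": region, "method": res.method,
                "n": res.n, "statistic": res.statistic, "p": res.p_value,
                "effect_size": res.effect_size,
            })
        if fam:
            adj = bh_fdr([r["p"] for r in fam], alpha)
            for r, pa, rej in zip(fam, adj.adjusted, adj.rejected):
                r["p_adjusted"] = float(pa)
                r["significant"] = bool(rej)
            rows.extend(fam)
    return pd.DataFrame(rows)


def _diagnosis_tables(cohort: pd.DataFrame) -> pd.DataFrame:
    rows = []
    groups = sorted(cohort["group"].unique())
    if len(groups) < 2:
        logger.warning("single group: contingency tests skipped")
        return pd.DataFrame(rows)
    for when in ("pre", "post"):
        col = f"{when}_diagnosis"
        cats = sorted(cohort[col].unique())
        counts = np.array([
            [(cohort[(cohort["group"] == g) & (cohort[col] == c)]).shape[0]
             for c in cats] for g in groups
        ])
        if min(counts.shape) < 2:
            logger.warning("%s diagnosis table degenerate (one category); skipped",
                           when)
            continue
        table = ContingencyTable(counts, list(groups), list(cats))
        chi = chi_square(table)
        fish = fisher_exact(table)
        for res, label in ((chi, "chi_square"), (fish, fish.method)):
            rows.append({
                "timepoint": when, "method": label, "n": res.n,
                "statistic": res.statistic, "df": res.df, "p": res.p_value,
                "categories": "|".join(cats),
                "counts": ";".join(",".join(map(str, r)) for r in counts),
            })
    return pd.DataFrame(rows)


def _group_regressions(cohort: pd.DataFrame) -> pd.DataFrame:
    ycol = "delta_crsr_cont" if "delta_crsr_cont" in cohort.columns else "delta_crsr"
    rows = []
    for group, df in cohort.groupby("group"):
        if len(df) < 3:
            logger.warning("group %s has n < 3: regression skipped", group)
            continue
        try:
            fit, test = pearson_regression(df["delta_pe"], df[ycol])
        except Exception as exc:
            logger.warning("regression for group %s failed: %s", group, exc)
            continue
        rows.append({
            "group": group, "n": fit.n, "intercept": fit.intercept,
            "slope": fit.slopes["x"], "r": test.effect_size,
            "r_squared": fit.r_squared, "p": test.p_value,
        })
    return pd.DataFrame(rows)


def _entropy_lmm(features: list[SubjectFeatures], region: str) -> pd.DataFrame:
    rows = []
    for f in features:
        sub = f.pe[(f.pe["region"] == region) & (f.pe["variant"] == "broadband")]
        for state in CONTRAST:
            val = sub.loc[sub["state"] == state, "pe"]
            if val.empty:
                continue
            rows.append({
                "subject": f.subject_id,
                "group": "AIE" if f.group == "AIE" else "TBI/CVA",
                "state": "anesthesia" if state == "steady_state" else "baseline",
                "entropy": float(val.iloc[0]),
            })
    obs = pd.DataFrame(rows)
    fit = fit_random_intercept_lmm(obs)
    out = fit.fixed_effects.copy()
    out["random_intercept_sd"] = fit.random_intercept_sd
    out["residual_sd"] = fit.residual_sd
    out["n_subjects"] = fit.n_subjects
    out["n_obs"] = fit.n_obs
    out["region"] = region
    return out


def _standardized_scores(cohort: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, r in cohort.iterrows():
        for when, tp in (("pre", "pre_op"), ("post", "month3")):
            a = crsr.CRSRAssessment(
                **{s: int(r[f"{when}_{s}"]) for s in crsr.SUBSCALES}, timepoint=tp)
            for sub, val in crsr.standardize(a).items():
                rows.append({"group": r["group"], "timepoint": when,
                             "subscale": sub, "score": val})
    df = pd.DataFrame(rows)
    return (df.groupby(["group", "timepoint", "subscale"], sort=True)["score"]
            .mean().reset_index())


def run_cohort(features: list[SubjectFeatures], cohort: pd.DataFrame,
               config: RunConfig = RunConfig()) -> dict[str, pd.DataFrame]:
    """Assemble the six cohort-level result families.

    Returns a dict of tidy DataFrames keyed ``within_group``, ``between_group``,
    ``diagnosis_contingency``, ``pe_crsr_regression``, ``entropy_lmm`` and
    ``crsr_standardized``.
    """
    results = {
        "within_group": _within_group_tests(features, config.alpha),
        "between_group": _between_group_tests(features, config.alpha),
        "diagnosis_contingency": _diagnosis_tables(cohort),
        "pe_crsr_regression": _group_regressions(cohort),
        "crsr_standardized": _standardized_scores(cohort),
    }
    try:
        results["entropy_lmm"] = _entropy_lmm(features, config.lmm_region)
    except Exception as exc:
        logger.warning("entropy LMM skipped: %s", exc)
        results["entropy_lmm"] = pd.DataFrame()
    return results
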