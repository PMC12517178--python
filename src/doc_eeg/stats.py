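"""Statistical layer: nonparametric tests, contingency analysis, FDR,
correlation/regression, effect sizes, and the random-intercept linear mixed
model used for group x anesthesia-state entropy contrasts.

Conventions: two-sided tests, alpha = 0.05, Pearson chi-square without
continuity correction for r x c tables (Fisher's exact test is provided
alongside), Benjamini-Hochberg step-up FDR within named test families, and
effect sizes as Cohen's d (parametric) or rank-biserial r (rank tests).

The mixed model is a random-intercept LMM fitted by REML, profiling out the
fixed effects and the residual variance so that only the variance ratio
theta = sigma_u^2 / sigma_e^2 remains; theta is found by a bracketed 1-D
search. Inference on fixed effects is Wald t with df = n_obs - n_fixed.
Standard scipy/statsmodels routines back the classical tests; the r x c exact
test and the LMM are implemented here (scipy's Fisher test is 2 x 2 only, and
the profiled-REML route gives exact boundary behaviour, cross-checked against
statsmodels MixedLM in the test suite).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.special import gammaln

from .errors import ConvergenceError, DegenerateDataError, LengthError, ParameterError

logger = logging.getLogger("doc_eeg.stats")


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    p_value: float
    df: float | None = None
    effect_size: float | None = None
    effect_size_name: str | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ParameterError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class ContingencyTable:
    """Non-negative integer counts with row (group) and column labels."""

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ParameterError("contingency table must be at least 2 x 2")
        if np.any(self.counts < 0) or not np.allclose(self.counts, self.counts.round()):
            raise ParameterError("counts must be non-negative integers")
        self.counts = self.counts.round().astype(int)
        if not self.row_labels:
            self.row_labels = [f"r{i}" for i in range(self.counts.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"c{j}" for j in range(self.counts.shape[1])]


@dataclass
class RegressionFit:
    """OLS fit summary."""

    intercept: float
    slopes: dict[str, float]
    r_squared: float
    p_values: dict[str, float]
    n: int
    stderr: dict[str, float] = field(default_factory=dict)


@dataclass
class FDRResult:
    """Benjamini-Hochberg adjustment of a family of p-values."""

    raw: np.ndarray
    adjusted: np.ndarray
    rejected: np.ndarray
    alpha: float


@dataclass
class LMMFit:
    """Random-intercept linear mixed model fit (REML)."""

    fixed_effects: pd.DataFrame  # term, estimate, se, t, p, ci_lo, ci_hi
    random_intercept_sd: float
    residual_sd: float
    n_subjects: int
    n_obs: int
    variance_ratio: float
    boundary: bool = False

    def effect(self, term: str) -> pd.Series:
        row = self.fixed_effects[self.fixed_effects["term"] == term]
        if row.empty:
            raise ParameterError(f"no fixed effect {term!r}")
        return row.iloc[0]


# --------------------------------------------------------------------------
# rank tests


def _rank_biserial_paired(diffs: np.ndarray) -> float:
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = ranks[diffs > 0].sum()
    w_minus = ranks[diffs < 0].sum()
    return float((w_plus - w_minus) / (w_plus + w_minus))


def wilcoxon_signed_rank(differences: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; the p-value is exact (enumeration) below
    n = 26 when there are no ties in |differences|, else a normal
    approximation with continuity correction. Effect size: matched-pairs
    rank-biserial correlation.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    if n < 2:
        raise LengthError("need at least 2 non-zero differences")
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n < 26 and not has_ties) else "approx"
    stat, p = sps.wilcoxon(d, alternative="two-sided", correction=True,
                           method=method, zero_method="wilcox")
    return TestResult("wilcoxon_signed_rank", float(stat), float(p),
                      effect_size=_rank_biserial_paired(d),
                      effect_size_name="rank_biserial", n=n)


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided Mann-Whitney U; exact for n_a + n_b <= 12 without ties.

    Effect size: rank-biserial r = 1 - 2U/(n_a n_b).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateDataError("empty sample")
    pooled = np.concatenate([a, b])
    exact = len(pooled) <= 12 and len(np.unique(pooled)) == len(pooled)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    r = 1.0 - 2.0 * float(res.statistic) / (len(a) * len(b))
    return TestResult("mann_whitney_u", float(res.statistic), float(res.pvalue),
                      effect_size=r, effect_size_name="rank_biserial",
                      n=len(pooled))


def kruskal_wallis(*samples: np.ndarray) -> TestResult:
    """Kruskal-Wallis H with tie correction, chi-square approximation."""
    if len(samples) < 3:
        raise ParameterError("Kruskal-Wallis needs >= 3 groups")
    try:
        with np.errstate(invalid="ignore"):
            stat, p = sps.kruskal(*samples)
    except ValueError as exc:  # all values identical
        raise DegenerateDataError(str(exc)) from exc
    if np.isnan(stat) or np.isnan(p):  # complete-tie degeneracy
        raise DegenerateDataError("all values identical across groups")
    return TestResult("kruskal_wallis", float(stat), float(p),
                      df=len(samples) - 1, n=sum(len(s) for s in samples))


# --------------------------------------------------------------------------
# contingency


def chi_square(table: ContingencyTable) -> TestResult:
    """Pearson chi-square, no continuity correction, df = (r-1)(c-1)."""
    obs = table.counts
    expected = sps.contingency.expected_freq(obs)
    zero = np.argwhere(expected == 0)
    if zero.size:
        i, j = zero[0]
        raise DegenerateDataError(
            f"expected count 0 in cell ({table.row_labels[i]}, {table.col_labels[j]})"
        )
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return TestResult("chi_square", float(stat), float(p), df=float(dof),
                      n=int(obs.sum()))


def _log_table_prob(counts: np.ndarray, log_margin_term: float) -> float:
    return log_margin_term - gammaln(counts + 1).sum()


def _enumerate_tables(row_sums: list[int], col_rem: np.ndarray):
    """Yield all tables (as flat cell lists) with the given margins."""
    c = len(col_rem)

    def rows(i: int, col_rem: tuple[int, ...], acc: list[int]):
        if i == len(row_sums) - 1:
            yield acc + list(col_rem)
            return
        for comp in _compositions(row_sums[i], col_rem):
            yield from rows(
                i + 1, tuple(r - x for r, x in zip(col_rem, comp)), acc + list(comp)
            )

    def _compositions(total: int, caps: tuple[int, ...]):
        if len(caps) == 1:
            if total <= caps[0]:
                yield (total,)
            return
        tail_cap = sum(caps[1:])
        for first in range(max(0, total - tail_cap), min(total, caps[0]) + 1):
            for rest in _compositions(total - first, caps[1:]):
                yield (first, *rest)

    yield from rows(0, tuple(int(v) for v in col_rem), [])


def fisher_exact(table: ContingencyTable, seed: int = 0,
                 n_mc: int = 200_000, force_enumeration: bool = False) -> TestResult:
    """Fisher's exact test: hypergeometric for 2 x 2, enumeration over all
    tables with fixed margins for r x c with N <= 60, Monte Carlo beyond.

    ``force_enumeration`` routes a 2 x 2 table through the general r x c
    enumeration (used to cross-check the two code paths).
    """
    obs = table.counts
    if obs.shape == (2, 2) and not force_enumeration:
        stat, p = sps.fisher_exact(obs, alternative="two-sided")
        return TestResult("fisher_exact", float(stat), float(p), n=int(obs.sum()))
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    n = int(obs.sum())
    log_margin = (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
                  - gammaln(n + 1))
    logp_obs = _log_table_prob(obs, log_margin)
    if n <= 60:
        p = 0.0
        for flat in _enumerate_tables(list(rows), cols):
            lp = _log_table_prob(np.asarray(flat, dtype=float), log_margin)
            if lp <= logp_obs + 1e-9:
                p += math.exp(lp)
        method = "fisher_exact_enumeration"
    else:
        rng = np.random.default_rng(seed)
        dist = sps.random_table(rows, cols)
        draws = dist.rvs(n_mc, random_state=rng)
        lps = log_margin - gammaln(draws + 1).sum(axis=(1, 2))
        p = float(np.mean(lps <= logp_obs + 1e-9))
        method = "fisher_exact_montecarlo"
    return TestResult(method, float(math.exp(logp_obs)), min(float(p), 1.0), n=n)


def bh_fdr(p_values, alpha: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up FDR adjustment."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return FDRResult(p, p.copy(), np.zeros(0, dtype=bool), alpha)
    rejected, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return FDRResult(p, adjusted, rejected, alpha)


# --------------------------------------------------------------------------
# correlation / regression


def pearson_regression(x, y) -> tuple[RegressionFit, TestResult]:
    """Pearson r with two-sided t-test (df = n - 2) and the simple OLS line."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise LengthError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for a constant variable")
    lr = sps.linregress(x, y)
    fit = RegressionFit(
        intercept=float(lr.intercept), slopes={"x": float(lr.slope)},
        r_squared=float(lr.rvalue) ** 2, p_values={"x": float(lr.pvalue)},
        n=len(x), stderr={"x": float(lr.stderr)},
    )
    test = TestResult("pearson", float(lr.rvalue), float(lr.pvalue),
                      df=len(x) - 2, effect_size=float(lr.rvalue),
                      effect_size_name="pearson_r", n=len(x))
    return fit, test


def multiple_regression(y, covariates: pd.DataFrame, predictor: str) -> RegressionFit:
    """OLS of y on covariates; returns the adjusted coefficient per column.

    ``predictor`` names the column of interest (present in ``covariates``);
    a rank-deficient design raises a parameter error.
    """
    import statsmodels.api as sm

    X = pd.DataFrame(covariates).astype(float)
    if predictor not in X.columns:
        raise ParameterError(f"predictor {predictor!r} not among covariates")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ParameterError("rank-deficient (collinear) design matrix")
    res = sm.OLS(np.asarray(y, float), design).fit()
    return RegressionFit(
        intercept=float(res.params["const"]),
        slopes={c: float(res.params[c]) for c in X.columns},
        r_squared=float(res.rsquared),
        p_values={c: float(res.pvalues[c]) for c in X.columns},
        n=int(res.nobs),
        stderr={c: float(res.bse[c]) for c in X.columns},
    )


# --------------------------------------------------------------------------
# random-intercept LMM (profiled REML)


def _lmm_design(obs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary-code group (TBI/CVA vs AIE) and state (anesthesia vs baseline)."""
    def binarize(col: pd.Series, positive: set[str], name: str) -> np.ndarray:
        vals = col.to_numpy()
        if np.issubdtype(np.asarray(vals).dtype, np.number):
            out = np.asarray(vals, dtype=float)
            if not set(np.unique(out)) <= {0.0, 1.0}:
                raise ParameterError(f"numeric {name} column must be 0/1 coded")
            return out
        return np.array([1.0 if str(v) in positive else 0.0 for v in vals])

    g = binarize(obs["group"], {"TBI", "CVA", "TBI/CVA"}, "group")
    s = binarize(obs["state"], {"anesthesia", "steady_state"}, "state")
    X = np.column_stack([np.ones(len(obs)), g, s, g * s])
    y = obs["entropy"].to_numpy(dtype=float)
    subjects = obs["subject"].to_numpy()
    return X, y, subjects


_LMM_TERMS = ("intercept", "group", "state", "group:state")


def fit_random_intercept_lmm(obs: pd.DataFrame) -> LMMFit:
    """REML fit of entropy ~ group * state + (1 | subject).

    ``obs`` needs columns subject, group, state, entropy; group is coded
    TBI/CVA = 1 vs AIE = 0 and state anesthesia/steady_state = 1 vs
    baseline = 0 (0/1 columns pass through). The REML criterion is profiled
    down to the variance ratio theta = sigma_u^2/sigma_e^2 and minimized by a
    bracketed 1-D search (tolerance 1e-8). Wald t inference with
    df = n_obs - 4.
    """
    X, y, subjects = _lmm_design(obs)
    n, p = X.shape
    uniq, inv = np.unique(subjects, return_inverse=True)
    if len(uniq) < 5:
        raise ParameterError("need >= 5 subjects")
    counts = np.bincount(inv)
    if n - p < 1:
        raise LengthError("too few observations")
    boundary = bool(counts.max() == 1)
    if boundary:
        logger.warning("one observation per subject: random-intercept variance "
                       "is confounded with the residual (boundary fit likely)")

    # per-subject sufficient statistics
    Sx = np.zeros((len(uniq), p))
    Sy = np.zeros(len(uniq))
    np.add.at(Sx, inv, X)
    np.add.at(Sy, inv, y)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def profiled(theta: float):
        w = theta / (1.0 + counts * theta)  # per-subject shrinkage
        XtWX = XtX - (Sx * w[:, None]).T @ Sx
        XtWy = Xty - Sx.T @ (w * Sy)
        ytWy = yty - float(w @ Sy**2)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = ytWy - float(beta @ XtWy)
        sigma_e2 = rss / (n - p)
        sign, logdet = np.linalg.slogdet(XtWX)
        crit = (np.log1p(counts * theta).sum() + (n - p) * np.log(sigma_e2)
                + logdet)
        return crit, beta, sigma_e2, XtWX

    res = optimize.minimize_scalar(
        lambda t: profiled(t)[0], bounds=(0.0, 1e6), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise ConvergenceError(f"REML search failed: {res.message}")
    theta = float(res.x)
    crit0 = profiled(0.0)[0]
    if crit0 <= res.fun:  # boundary optimum at theta = 0
        theta = 0.0
    _, beta, sigma_e2, XtWX = profiled(theta)
    se = np.sqrt(np.diag(sigma_e2 * np.linalg.inv(XtWX)))
    df = n - p
    t_vals = beta / se
    p_vals = 2 * sps.t.sf(np.abs(t_vals), df)
    t_crit = sps.t.ppf(0.975, df)
    table = pd.DataFrame({
        "term": _LMM_TERMS,
        "estimate": beta,
        "se": se,
        "t": t_vals,
        "p": p_vals,
        "ci_lo": beta - t_crit * se,
        "ci_hi": beta + t_crit * se,
    })
    return LMMFit(
        fixed_effects=table,
        random_intercept_sd=float(np.sqrt(theta * sigma_e2)),
        residual_sd=float(np.sqrt(sigma_e2)),
        n_subjects=len(uniq),
        n_obs=n,
        variance_ratio=theta,
        boundary=boundary or theta == 0.0,
    )


# --------------------------------------------------------------------------
# normality and effect size


def normality_check(sample) -> TestResult:
    """Lilliefors variant of the Kolmogorov-Smirnov test against a fitted normal."""
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(sample, dtype=float)
    if len(x) < 5:
        raise LengthError("normality check needs n >= 5")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant sample")
    stat, p = lilliefors(x, dist="norm")
    return TestResult("lilliefors_ks", float(stat), float(np.clip(p, 0, 1)), n=len(x))


def cohens_d(a, b) -> float:
    """Cohen's d with the pooled (n-1 weighted) standard deviation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise LengthError("Cohen's d needs >= 2 values per group")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise DegenerateDataError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))
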