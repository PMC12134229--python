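"""Statistical battery for subject-level tables.

Implements the study-style analyses: non-parametric behavioural contrasts
(Wilcoxon signed-rank / Mann-Whitney U), skipped Spearman correlations robust
to bivariate outliers, influence-screened OLS with normality/specification
diagnostics, MAD-filtered linear mixed models with a per-subject random
intercept, and Holm-Bonferroni multiplicity adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.covariance import MinCovDet
from statsmodels.stats.diagnostic import het_white, spec_white
from statsmodels.stats.stattools import jarque_bera

__all__ = [
    "TermResult",
    "ModelResult",
    "CorrelationResult",
    "behavioural_metrics",
    "rank_tests",
    "skipped_spearman",
    "fit_baseline_model",
    "fit_mixed_model",
    "medication_model",
    "holm_adjust",
    "delta_metabolites",
    "percent_task_effect",
]


@dataclass
class TermResult:
    name: str
    estimate: float
    ci95_lo: float
    ci95_hi: float
    p: float


@dataclass
class ModelResult:
    terms: list[TermResult]
    n_used: int
    dropped: list[tuple[object, str]]
    diagnostics: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"term {name!r} not in model; have {[t.name for t in self.terms]}")

    def __getitem__(self, name: str) -> TermResult:
        return self.term(name)


@dataclass
class CorrelationResult:
    r: float
    ci95: tuple[float, float]
    p: float
    n_outliers_removed: int
    n_used: int
    reliable: bool = True
    p_holm: float | None = None
    outlier_mask: np.ndarray | None = None  # over the complete pairs


# --- behavioural -------------------------------------------------------------


def behavioural_metrics(log: pd.DataFrame) -> dict[str, float]:
    """Per-subject task performance summary from a trial log.

    RA = fraction correct; RT = median over correct responses; RA/RT their
    ratio; RT_slowing = median incongruent RT minus median congruent RT
    (correct responses only). Conditions without correct responses yield NaN
    metrics and ``flagged=True``.
    """
    if len(log) == 0:
        raise ValueError("empty trial log")
    ra = float(log["correct"].mean())
    ok = log[log["correct"] & log["rt_s"].notna()]
    flagged = False
    rt = float(ok["rt_s"].median()) if len(ok) else np.nan
    rt_c = float(ok.loc[ok["congruent"], "rt_s"].median()) if (ok["congruent"]).any() else np.nan
    rt_i = float(ok.loc[~ok["congruent"], "rt_s"].median()) if (~ok["congruent"]).any() else np.nan
    if not (np.isfinite(rt) and np.isfinite(rt_c) and np.isfinite(rt_i)):
        flagged = True
    return {
        "ra": ra,
        "rt_s": rt,
        "ra_over_rt": ra / rt if np.isfinite(rt) and rt > 0 else np.nan,
        "rt_slowing_s": rt_i - rt_c,
        "flagged": flagged,
    }


def rank_tests(a, b, paired: bool) -> tuple[float, float]:
    """Two-sided rank test: Wilcoxon signed-rank (paired) or Mann-Whitney U.

    All-tied paired differences are degenerate: returns p = 1 with a warning
    rather than raising.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        d = a - b
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; degenerate test, p = 1",
                          stacklevel=2)
            return 0.0, 1.0
        res = scipy.stats.wilcoxon(a, b, alternative="two-sided")
    else:
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# --- skipped Spearman --------------------------------------------------------


def _skipped_outliers(xy: np.ndarray, seed: int | None = 0) -> np.ndarray:
    """Flag bivariate outliers by projection onto directions through the
    minimum-covariance-determinant centre, with a box-plot rule per direction."""
    n = xy.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        centre = MinCovDet(random_state=seed).fit(xy).location_
    b = xy - centre
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        d = b[i]
        norm = np.hypot(*d)
        if norm == 0:
            continue
        proj = b @ (d / norm)
        q1, q3 = np.percentile(proj, [25, 75])
        iqr = q3 - q1
        if iqr == 0:
            continue
        out |= (proj < q1 - 1.5 * iqr) | (proj > q3 + 1.5 * iqr)
    return out


def skipped_spearman(
    x, y, n_boot: int = 1000, seed: int = 0, min_retained: int = 5
) -> CorrelationResult:
    """Spearman correlation after removing bivariate outliers.

    Outliers are flagged by projecting all points onto every direction through
    the robust (MCD) centre and a point, and applying the 1.5-IQR box-plot
    rule to the projections; the rank correlation and its percentile-bootstrap
    CI (fixed seed) are computed over the retained points. Reduces exactly to
    classical Spearman when nothing is flagged.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 10:
        raise ValueError(f"need >= 10 complete pairs, have {x.size}")
    xy = np.column_stack([x, y])
    out = _skipped_outliers(xy, seed=seed)
    xr, yr = x[~out], y[~out]
    n_ret = xr.size
    if n_ret < min_retained:
        return CorrelationResult(np.nan, (np.nan, np.nan), np.nan,
                                 int(out.sum()), n_ret, reliable=False,
                                 outlier_mask=out)
    r, p = scipy.stats.spearmanr(xr, yr)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n_ret, n_ret)
        if np.unique(xr[idx]).size < 2 or np.unique(yr[idx]).size < 2:
            boots[i] = np.nan
            continue
        boots[i] = scipy.stats.spearmanr(xr[idx], yr[idx]).statistic
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return CorrelationResult(float(r), (float(lo), float(hi)), float(p),
                             int(out.sum()), n_ret, outlier_mask=out)


# --- OLS with influence screen and diagnostics -------------------------------


def _terms_from_fit(fit) -> list[TermResult]:
    ci = fit.conf_int()
    ci = np.asarray(ci)
    return [
        TermResult(name, float(fit.params.iloc[i]), float(ci[i, 0]),
                   float(ci[i, 1]), float(fit.pvalues.iloc[i]))
        for i, name in enumerate(fit.params.index)
    ]


def _ols_with_influence(formula: str, data: pd.DataFrame) -> ModelResult:
    """OLS fit, single-pass DFFITS screen at 2*sqrt(k/n), refit, diagnostics."""
    data = data.dropna(subset=_formula_columns(formula, data)).copy()
    fit = smf.ols(formula, data=data).fit()
    k = fit.df_model + 1
    n = int(fit.nobs)
    dffits, _ = fit.get_influence().dffits
    thresh = 2.0 * np.sqrt(k / n)
    bad = np.abs(dffits) > thresh
    dropped = [
        (idx, f"|DFFITS| {abs(d):.3f} > {thresh:.3f}")
        for idx, d, b in zip(data.index, dffits, bad)
        if b
    ]
    if bad.any():
        data2 = data.loc[~bad]
        fit = smf.ols(formula, data=data2).fit()
    warns: list[str] = []
    resid = fit.resid
    exog = fit.model.exog
    jb_p = float(jarque_bera(resid)[1])
    try:
        white_lm_p = float(het_white(resid, exog)[1])
    except (np.linalg.LinAlgError, ValueError):
        white_lm_p, warns = np.nan, warns + ["White LM test failed"]
    try:
        white_spec_p = float(spec_white(resid, exog)[1])
    except (np.linalg.LinAlgError, ValueError):
        white_spec_p = np.nan
        warns.append("White two-moment specification test failed")
    diags = {
        "jarque_bera_p": jb_p,
        "white_lm_p": white_lm_p,
        "white_spec_p": white_spec_p,
    }
    for nm, p in diags.items():
        if np.isfinite(p) and p < 0.05:
            warns.append(f"model-suitability: {nm} = {p:.4f} < 0.05")
    return ModelResult(
        terms=_terms_from_fit(fit),
        n_used=int(fit.nobs),
        dropped=dropped,
        diagnostics=diags,
        warnings=warns,
    )


def _formula_columns(formula: str, data: pd.DataFrame) -> list[str]:
    return [c for c in data.columns if c in formula]


def fit_baseline_model(
    table: pd.DataFrame, response: str = "glx_off_iu", bold_source: str = "fmri"
) -> ModelResult:
    """Baseline metabolite ~ C(group) * BOLD + fGM + age, influence-screened.

    ``bold_source`` selects the BOLD covariate: the external fMRI median-Z
    (``bold_fmri_z``) or the spectroscopic linewidth change (``bold_fmrs``).
    Baseline means the task-OFF estimate.
    """
    bold_col = {"fmri": "bold_fmri_z", "fmrs": "bold_fmrs"}[bold_source]
    for col in (response, bold_col, "group", "fgm", "age_y"):
        if col not in table.columns:
            raise ValueError(f"required column {col!r} missing")
    formula = f"{response} ~ C(group) * {bold_col} + fgm + age_y"
    return _ols_with_influence(formula, table)


def medication_model(table: pd.DataFrame, response: str = "gaba_off_iu") -> ModelResult:
    """GABA+ ~ C(is_active) * DDD + fGM + age + PANSS-positive, patients only."""
    pat = table[table["group"] == "patient"].copy()
    if len(pat) == 0:
        raise ValueError("no patient rows")
    if (pat["ddd"].fillna(0) == 0).all():
        raise ValueError("column 'ddd' is all zero: DDD slope inestimable")
    if pat["is_active"].nunique() < 2:
        warnings.warn("is_active is constant; interaction dropped", stacklevel=2)
        formula = f"{response} ~ ddd + fgm + age_y + panss_pos"
    else:
        formula = f"{response} ~ C(is_active) * ddd + fgm + age_y + panss_pos"
    return _ols_with_influence(formula, pat)


# --- mixed model with MAD residual filter ------------------------------------


def fit_mixed_model(
    long_table: pd.DataFrame,
    response: str = "value_iu",
    factor: str = "task_state",
    mad_factor: float = 2.5,
    group_col: str = "subject_id",
) -> ModelResult:
    """Random-intercept mixed model with one MAD-based residual-filter refit.

    Model: ``response ~ C(group) * C(factor) + fgm + age_y`` with a random
    intercept per subject. After an initial fit, observations whose marginal
    residual (observation minus the fixed-effects prediction) deviates from
    the median residual by more than ``mad_factor`` times the unscaled MAD are
    excluded and the model is refitted once. Falls back to OLS with a warning
    if the random-effects fit is singular.
    """
    cols = [response, "group", factor, "fgm", "age_y", group_col]
    data = long_table.dropna(subset=[c for c in cols if c in long_table.columns]).copy()
    counts = data.groupby(group_col).size()
    if (counts < 2).all():
        raise ValueError("need >= 2 observations per subject for a mixed model")
    formula = f"{response} ~ C(group) * C({factor}) + fgm + age_y"
    warns: list[str] = []

    def _fit(d: pd.DataFrame):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                m = smf.mixedlm(formula, d, groups=d[group_col]).fit(reml=True)
                if not np.all(np.isfinite(np.asarray(m.bse_fe))):
                    raise np.linalg.LinAlgError("non-finite fixed-effect SEs")
                return m, False
            except (np.linalg.LinAlgError, ValueError):
                return smf.ols(formula, d).fit(), True

    def _marginal_resid(fit, d: pd.DataFrame) -> np.ndarray:
        if hasattr(fit, "fe_params"):  # mixed model: fixed-effects prediction
            return np.asarray(d[response]) - np.asarray(
                fit.model.exog @ np.asarray(fit.fe_params)
            )
        return np.asarray(fit.resid)

    fit0, fell_back = _fit(data)
    resid = _marginal_resid(fit0, data)
    med = np.median(resid)
    mad = float(np.median(np.abs(resid - med)))
    dropped: list[tuple[object, str]] = []
    # a MAD at numerical-noise level (noiseless data) must not trigger filtering
    scale = max(float(np.std(data[response])), 1.0)
    if mad > 1e-6 * scale:
        bad = np.abs(resid - med) > mad_factor * mad
        if bad.any():
            dropped = [
                (idx, f"|resid - median| > {mad_factor} x MAD {mad:.3g}")
                for idx, b in zip(data.index, bad)
                if b
            ]
            data = data.loc[~bad]
            fit0, fell_back = _fit(data)
    if fell_back:
        warns.append("singular random-effects fit; fell back to OLS")

    if hasattr(fit0, "fe_params"):
        names = list(fit0.fe_params.index)
        ci = np.asarray(fit0.conf_int().loc[names])
        terms = [
            TermResult(nm, float(fit0.fe_params.iloc[i]), float(ci[i, 0]),
                       float(ci[i, 1]), float(fit0.pvalues.loc[nm]))
            for i, nm in enumerate(names)
        ]
    else:
        terms = _terms_from_fit(fit0)
    diags = {
        "fgm_mean": float(data["fgm"].mean()) if "fgm" in data else np.nan,
        "age_y_mean": float(data["age_y"].mean()) if "age_y" in data else np.nan,
    }
    return ModelResult(
        terms=terms, n_used=int(fit0.nobs), dropped=dropped,
        diagnostics=diags, warnings=warns,
    )


def percent_task_effect(result: ModelResult, factor: str = "task_state",
                        level: str = "ON") -> float:
    """Task coefficient as a percentage of the reference (task-OFF) level.

    The reference level is the model intercept evaluated at the sample means
    of the continuous covariates (fGM, age), i.e. the fitted task-OFF mean of
    the reference group, not the raw intercept extrapolated to fgm = age = 0.
    """
    task = result.term(f"C({factor})[T.{level}]").estimate
    ref = result.term("Intercept").estimate
    for cov, key in (("fgm", "fgm_mean"), ("age_y", "age_y_mean")):
        mean = result.diagnostics.get(key, np.nan)
        try:
            coef = result.term(cov).estimate
        except KeyError:
            continue
        if np.isfinite(mean):
            ref += coef * mean
    return 100.0 * task / ref


# --- Holm and deltas ---------------------------------------------------------


def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm-Bonferroni adjustment with monotonicity, capped at 1."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def delta_metabolites(
    table: pd.DataFrame,
    on_col: str = "glx_on_iu",
    off_col: str = "glx_off_iu",
    usable_on: str | None = None,
    usable_off: str | None = None,
) -> pd.Series:
    """Task-ON minus task-OFF metabolite estimate per subject.

    A missing or unusable condition yields a missing delta, never zero.
    """
    on = table[on_col]
    off = table[off_col]
    delta = on - off
    if usable_on is not None:
        delta = delta.where(table[usable_on].astype(bool))
    if usable_off is not None:
        delta = delta.where(table[usable_off].astype(bool))
    return delta
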