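"""Cross-stock meta-analysis of the partitioned variance fractions.

Works on a "meta table": one row per stock with the (clamped, table-style)
variance fractions, permutation p-values, selected lag, region/habitat labels,
life-history traits and the long-term fishing (mean, CV of F/M) and
temperature (mean, CV) indices.

Three families of questions are answered here:

* Do the three effect fractions differ across stocks, overall and within
  region / habitat groups?  The published p-values derive from a one-way
  ANOVA with Tukey's HSD over the three effect columns, which is the default
  here; pairwise paired t-tests are available as an alternative reading.
* Which covariates explain the per-stock fishing / temperature fractions?
  Simple univariate OLS per covariate, then a linear mixed model with the
  same fixed effect and a random intercept by habitat (REML, Satterthwaite
  degrees of freedom).
* Is the multivariate partition more efficient than univariate indicator
  regressions at rejecting the null?  Matched p-value pairs scored by strict
  inequality and an exact one-sided binomial test against 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import DegenerateInputError, InsufficientDataError, ValidationError

EFFECT_COLUMNS = {
    "fishing": "frac_fishing",
    "shared": "frac_shared",
    "temperature": "frac_temperature",
}
EFFECT_PAIRS = (
    ("fishing", "temperature"),
    ("fishing", "shared"),
    ("temperature", "shared"),
)
COVARIATES = ("A_50", "L_50", "L_inf", "K", "mean_FM", "cv_FM", "mean_temp", "cv_temp")


@dataclass(frozen=True)
class PairedComparison:
    group_label: str
    effect_pair: str
    n: int
    statistic: float  # mean difference (first minus second effect)
    p_value: float
    method: str


def summarize_fraction_table(meta: pd.DataFrame) -> dict:
    """Column summaries of a per-stock fraction table (percent scale for the
    means/maximum, significance counted at P < 0.05)."""
    return {
        "n_stocks": int(len(meta)),
        "mean_fishing_pct": float(100 * meta["frac_fishing"].mean()),
        "mean_shared_pct": float(100 * meta["frac_shared"].mean()),
        "mean_temperature_pct": float(100 * meta["frac_temperature"].mean()),
        "max_total_adj_r2_pct": float(100 * meta["total_adj_r2"].max()),
        "n_fishing_significant": int(_significant(meta, "fishing").sum()),
        "n_temperature_significant": int(_significant(meta, "temperature").sum()),
    }


def _significant(meta: pd.DataFrame, effect: str, alpha: float = 0.05):
    """Significance mask from either permutation p-values or printed classes."""
    pcol, scol = f"p_{effect}", f"sig_{effect}"
    if pcol in meta.columns and meta[pcol].notna().any():
        return meta[pcol] < alpha
    if scol in meta.columns:
        return meta[scol] > 0
    raise ValidationError(f"meta table has neither {pcol} nor {scol}")


def paired_effect_comparisons(
    meta: pd.DataFrame,
    group_by: str | None = None,
    method: str = "tukey",
    min_group: int = 3,
) -> list[PairedComparison]:
    """Compare the three effect fractions, overall or within groups.

    ``method="tukey"`` (default) runs a one-way ANOVA across the three effect
    columns and reports Tukey-HSD adjusted p-values — the construction behind
    the published figure captions.  ``method="paired_t"`` reports two-sided
    paired t-tests per pair, with p = 1 when the paired differences have zero
    variance.  Groups smaller than ``min_group`` stocks are skipped with a
    warning.
    """
    if method not in ("tukey", "paired_t"):
        raise ValidationError("method must be 'tukey' or 'paired_t'")
    if group_by is None:
        groups = [("all", meta)]
    else:
        groups = [(str(k), g) for k, g in meta.groupby(group_by, sort=True)]
    out: list[PairedComparison] = []
    for label, g in groups:
        if len(g) < min_group:
            warnings.warn(
                f"group {label!r}: only {len(g)} stocks (< {min_group}); skipped",
                stacklevel=2,
            )
            continue
        cols = {e: g[c].to_numpy(float) for e, c in EFFECT_COLUMNS.items()}
        if method == "tukey":
            res = stats.tukey_hsd(cols["fishing"], cols["temperature"], cols["shared"])
            idx = {"fishing": 0, "temperature": 1, "shared": 2}
            for e1, e2 in EFFECT_PAIRS:
                out.append(
                    PairedComparison(
                        group_label=label,
                        effect_pair=f"{e1}-vs-{e2}",
                        n=len(g),
                        statistic=float(cols[e1].mean() - cols[e2].mean()),
                        p_value=float(res.pvalue[idx[e1], idx[e2]]),
                        method="tukey",
                    )
                )
        else:
            for e1, e2 in EFFECT_PAIRS:
                d = cols[e1] - cols[e2]
                if np.allclose(d, d[0]) and np.isclose(d[0], 0):
                    t, p = float("nan"), 1.0
                else:
                    t, p = stats.ttest_rel(cols[e1], cols[e2])
                    t, p = float(t), float(p)
                out.append(
                    PairedComparison(
                        group_label=label,
                        effect_pair=f"{e1}-vs-{e2}",
                        n=len(g),
                        statistic=t,
                        p_value=p,
                        method="paired_t",
                    )
                )
    return out


def repeated_measures_anova(meta: pd.DataFrame) -> tuple[float, float]:
    """One-way repeated-measures ANOVA over the three effect fractions
    (stock as block); provided for completeness, not the reporting path."""
    X = meta[list(EFFECT_COLUMNS.values())].to_numpy(float)
    n, k = X.shape
    grand = X.mean()
    ss_effect = n * ((X.mean(0) - grand) ** 2).sum()
    ss_block = k * ((X.mean(1) - grand) ** 2).sum()
    ss_err = ((X - grand) ** 2).sum() - ss_effect - ss_block
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = (ss_effect / df1) / (ss_err / df2)
    return float(F), float(stats.f.sf(F, df1, df2))


# ---------------------------------------------------------------------------
# covariate models


def fraction_regression(
    meta: pd.DataFrame, response: str, covariate: str
) -> tuple[float, float]:
    """Univariate OLS of an explained fraction on one covariate.

    Returns (slope, two-sided p).  A constant response gives (0, 1); a
    constant covariate is an error.
    """
    y = meta[EFFECT_COLUMNS[response]].to_numpy(float)
    x = meta[covariate].to_numpy(float)
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"covariate {covariate} has missing values")
    if np.ptp(x) == 0:
        raise DegenerateInputError(f"covariate {covariate} has zero variance")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


@dataclass(frozen=True)
class LMMResult:
    fixed_coef: float
    p_value: float
    se: float
    df: float
    sigma2: float
    tau2: float
    method: str  # "lmm-satterthwaite" or "ols-fallback"


def _reml_loglik(theta, y, X, Z):
    """REML log-likelihood of a random-intercept model.

    theta = (residual variance σ², intercept variance τ²); Z is the n×g
    group-indicator matrix.
    """
    s2, t2 = theta
    n, p = X.shape
    V = s2 * np.eye(n) + t2 * (Z @ Z.T)
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign2, logdetX = np.linalg.slogdet(XtViX)
    if sign2 <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (logdetV + logdetX + r @ Vi @ r)


def _satterthwaite_df(theta, y, X, Z, c):
    """Satterthwaite df for contrast c at REML estimate theta.

    df = 2 f² / (gᵀ A g) with f(θ) = cᵀ(XᵀV⁻¹X)⁻¹c, g its finite-difference
    gradient and A the inverse observed REML information in θ.
    """
    def f(th):
        s2, t2 = max(th[0], 1e-12), max(th[1], 0.0)
        V = s2 * np.eye(len(y)) + t2 * (Z @ Z.T)
        XtViX = X.T @ np.linalg.solve(V, X)
        return float(c @ np.linalg.solve(XtViX, c))

    theta = np.asarray(theta, float)
    h = np.maximum(1e-6, 1e-4 * np.abs(theta))
    g = np.empty(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = h[i]
        g[i] = (f(theta + e) - f(theta - e)) / (2 * h[i])
    H = np.empty((2, 2))
    ll = lambda th: _reml_loglik(th, y, X, Z)
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2); ei[i] = h[i]
            ej = np.zeros(2); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                ll(theta + ei + ej) - ll(theta + ei - ej)
                - ll(theta - ei + ej) + ll(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    fhat = f(theta)
    try:
        A = np.linalg.inv(-H)
        denom = float(g @ A @ g)
    except np.linalg.LinAlgError:
        denom = np.nan
    if not np.isfinite(denom) or denom <= 0:
        return float(len(y) - X.shape[1])  # fall back to residual df
    return float(2 * fhat**2 / denom)


def fraction_lmm(meta: pd.DataFrame, response: str, covariate: str) -> LMMResult:
    """Mixed model: fraction ~ covariate with a random intercept by habitat.

    REML fit via statsmodels MixedLM; the fixed-slope p-value uses a t
    distribution with Satterthwaite degrees of freedom computed from the
    closed-form REML likelihood of the random-intercept model.  If the
    random-intercept variance collapses to (numerically) zero, or only one
    habitat is present, the fit falls back to OLS with a flag.
    """
    y = meta[EFFECT_COLUMNS[response]].to_numpy(float)
    x = meta[covariate].to_numpy(float)
    hab = meta["habitat"].astype(str).to_numpy()
    if np.ptp(x) == 0:
        raise DegenerateInputError(f"covariate {covariate} has zero variance")
    X = np.column_stack([np.ones_like(x), x])
    levels, gidx = np.unique(hab, return_inverse=True)

    def ols_fallback():
        fit = sm.OLS(y, X).fit()
        return LMMResult(
            fixed_coef=float(fit.params[1]),
            p_value=float(fit.pvalues[1]),
            se=float(fit.bse[1]),
            df=float(fit.df_resid),
            sigma2=float(fit.scale),
            tau2=0.0,
            method="ols-fallback",
        )

    if len(levels) < 2:
        return ols_fallback()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = MixedLM(y, X, groups=gidx).fit(reml=True, method="lbfgs")
        except Exception:
            return ols_fallback()
    sigma2 = float(fit.scale)
    tau2 = float(np.asarray(fit.cov_re)[0, 0])
    if not np.isfinite(tau2) or tau2 <= 1e-10 * max(sigma2, 1e-12):
        return ols_fallback()
    Z = np.eye(len(levels))[gidx]
    c = np.array([0.0, 1.0])
    df = _satterthwaite_df((sigma2, tau2), y, X, Z, c)
    df = float(np.clip(df, 1.0, len(y) - 2))
    slope = float(fit.fe_params[1])
    se = float(fit.bse_fe[1])
    p = float(2 * stats.t.sf(abs(slope / se), df))
    return LMMResult(slope, p, se, df, sigma2, tau2, "lmm-satterthwaite")


# ---------------------------------------------------------------------------
# variation partitioning vs univariate indicators


@dataclass(frozen=True)
class EfficiencyComparison:
    prob_success: float
    binom_p: float
    n_pairs: int
    n_success: int


def pvalue_efficiency_comparison(
    varpart_p: pd.DataFrame, sbi_p: pd.DataFrame
) -> EfficiencyComparison:
    """Score how often the partition's permutation p beats the matching
    indicator-regression p.

    ``varpart_p`` needs columns (stock_id, effect, p); ``sbi_p`` needs
    (stock_id, effect, sbi, p).  Pairs are matched on (stock_id, effect), one
    per indicator; success is *strict* inequality (ties score zero).  The
    binomial test is one-sided (alternative: success probability > 0.5).
    """
    merged = sbi_p.merge(varpart_p, on=["stock_id", "effect"], suffixes=("_sbi", "_vp"))
    merged = merged.dropna(subset=["p_sbi", "p_vp"])
    n = len(merged)
    if n == 0:
        raise InsufficientDataError("no matched (stock, effect) p-value pairs")
    wins = int((merged["p_vp"] < merged["p_sbi"]).sum())
    binom = stats.binomtest(wins, n, p=0.5, alternative="greater")
    return EfficiencyComparison(
        prob_success=wins / n, binom_p=float(binom.pvalue), n_pairs=n, n_success=wins
    )
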