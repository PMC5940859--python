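"""Univariate size-based indicators (SBIs) and their forcing regressions.

Five indicators summarize each year's length-frequency distribution:

* ``L95`` — upper 95th percentile of length, linearly interpolated inside the
  containing bin (tracks the large-fish tail that size-selective fishing
  truncates first);
* ``mean_length`` — proportion-weighted mean of bin midpoints;
* ``shannon_H`` — Shannon diversity of length classes, in nats;
* ``pielou_J`` — evenness H / ln(S), with S the number of length classes
  occupied at the stock level (held constant across years so J is comparable
  through time);
* ``skewness`` — population-moment skewness of the weighted distribution.

Each indicator is then regressed on temperature, fishing and their product
(``SBI ~ T + F + T:F``); predictors are z-scored before the product is formed
so the interaction term is not an artefact of measurement scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import LengthComposition, drop_empty_bins, to_proportions
from .errors import CollinearityError, InsufficientDataError, ValidationError

SBI_NAMES = ("L95", "mean_length", "shannon_H", "pielou_J", "skewness")
TERM_NAMES = ("intercept", "temperature", "fishing", "interaction")


def weighted_percentile(proportions, bin_edges, pct: float = 0.95) -> float:
    """Percentile of a binned distribution, interpolating within the bin where
    the cumulative proportion crosses ``pct``."""
    p = np.asarray(proportions, float)
    edges = np.asarray(bin_edges, float)
    cum = np.cumsum(p)
    j = int(np.searchsorted(cum, pct * (1 - 1e-12)))
    j = min(j, p.size - 1)
    below = cum[j - 1] if j > 0 else 0.0
    width = edges[j + 1] - edges[j]
    if p[j] <= 0:  # crossing sits exactly on an earlier edge
        return float(edges[j])
    return float(edges[j] + (pct - below) / p[j] * width)


def compute_sbi_table(comp: LengthComposition) -> pd.DataFrame:
    """Per-year indicator table (index: year; columns: the five SBIs).

    Degenerate years (all mass in one class) get ``H = 0`` and missing
    skewness, with a warning; ``pielou_J`` is missing when only one length
    class is occupied at the stock level.
    """
    comp = drop_empty_bins(comp)
    props = to_proportions(comp).counts
    mids = comp.midpoints
    S = comp.n_bins  # occupied classes at stock level (post bin-drop)
    out = {name: np.empty(comp.n_years) for name in SBI_NAMES}
    for i in range(comp.n_years):
        p = props[i]
        mean = float(p @ mids)
        var = float(p @ (mids - mean) ** 2)
        out["mean_length"][i] = mean
        out["L95"][i] = weighted_percentile(p, comp.bin_edges, 0.95)
        nz = p[p > 0]
        H = float(-(nz * np.log(nz)).sum())
        out["shannon_H"][i] = H
        out["pielou_J"][i] = H / np.log(S) if S > 1 else np.nan
        if var > 0:
            out["skewness"][i] = float(p @ (mids - mean) ** 3) / var**1.5
        else:
            warnings.warn(
                f"year {comp.years[i]}: all mass in one length class; "
                "skewness undefined",
                stacklevel=2,
            )
            out["skewness"][i] = np.nan
    return pd.DataFrame(out, index=pd.Index(comp.years, name="year"))


@dataclass(frozen=True)
class SBIRegressionResult:
    """OLS fit of one indicator on temperature, fishing and their product."""

    sbi_name: str
    coefficients: dict
    p_values: dict
    n: int


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise CollinearityError("constant predictor cannot be z-scored")
    return (x - x.mean()) / sd


def sbi_regression(sbi, x_fish, x_temp, name: str = "sbi") -> SBIRegressionResult:
    """Fit ``SBI ~ temperature + fishing + temperature×fishing`` by OLS.

    Predictors are z-scored before the product term.  A constant response is
    reported with zero slopes and p = 1 (nothing to explain); a rank-deficient
    design raises :class:`CollinearityError`.
    """
    y = np.asarray(sbi, float)
    xf = np.asarray(x_fish, float)
    xt = np.asarray(x_temp, float)
    if not (y.size == xf.size == xt.size):
        raise ValidationError("sbi and predictors must be aligned")
    ok = np.isfinite(y)
    y, xf, xt = y[ok], xf[ok], xt[ok]
    n = y.size
    if n < 8:
        raise InsufficientDataError(f"{name}: only {n} usable years (< 8)")
    zt, zf = _zscore(xt), _zscore(xf)
    X = np.column_stack([np.ones(n), zt, zf, zt * zf])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(f"{name}: design matrix is rank deficient")
    if y.std(ddof=1) == 0:
        coefs = dict(zip(TERM_NAMES, [float(y[0]), 0.0, 0.0, 0.0]))
        pvals = dict(zip(TERM_NAMES, [1.0, 1.0, 1.0, 1.0]))
        return SBIRegressionResult(name, coefs, pvals, n)
    fit = sm.OLS(y, X).fit()
    coefs = dict(zip(TERM_NAMES, map(float, fit.params)))
    pvals = dict(zip(TERM_NAMES, map(float, fit.pvalues)))
    return SBIRegressionResult(name, coefs, pvals, n)


def all_sbi_regressions(sbi_table: pd.DataFrame, x_fish, x_temp) -> dict:
    """Regress every indicator column of ``sbi_table`` on the aligned forcing."""
    return {
        name: sbi_regression(sbi_table[name].to_numpy(), x_fish, x_temp, name=name)
        for name in sbi_table.columns
    }
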