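"""Redundancy analysis and two-set variation partitioning, from scratch.

Redundancy analysis (RDA) is the multivariate extension of ordinary
regression: the response is a whole matrix Y (here, a stock's yearly length
composition) and the summary statistic is the fraction of Y's total
(column-centered) sum of squares captured by the projection of Y onto the
predictor column space.  With two single-variable predictor sets — annual
fishing mortality and (possibly lagged) temperature — the explained variance
decomposes into a pure fishing fraction [a], a shared fraction [b] and a pure
temperature fraction [c] by differencing Ezekiel-adjusted R² values:

    a = adjR²(f+t) − adjR²(t),   c = adjR²(f+t) − adjR²(f),
    b = adjR²(f) + adjR²(t) − adjR²(f+t),
    residual = 1 − adjR²(f+t).

The shared fraction (labelled "interaction" in report tables, following the
field's convention for this column) is not
an interaction term and has no test; the pure fractions are tested by
permuting the residuals of the reduced model (Freedman–Lane scheme) with the
partial pseudo-F as statistic.  The temperature lag is chosen, per stock, as
the candidate maximizing the total adjusted R², ties going to the smaller lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DEFAULT_MIN_YEARS, StockSeries, align_years
from .errors import (
    CollinearityError,
    DegenerateInputError,
    InsufficientDataError,
    ValidationError,
)

#: Temperature-lag candidates (years): annual surveys test contemporaneous,
#: 1- and 3-year lags; stocks sampled every 2–3 years test 0/2/3 by default.
LAGS_ANNUAL = (0, 1, 3)
LAGS_MULTIYEAR = (0, 2, 3)


@dataclass(frozen=True)
class RDAFit:
    """Summary of one (possibly partial) redundancy analysis."""

    r2: float
    adj_r2: float
    n: int
    p: int
    q: int
    pseudo_F: float


@dataclass(frozen=True)
class PartitionResult:
    """Two-set partition of a stock's size-structure variance.

    Fractions are kept unclamped (the shared fraction, and occasionally a
    pure fraction, can legitimately be negative under the adjusted
    decomposition); ``*_reported`` properties clamp at zero for table output.
    """

    frac_fishing: float
    frac_shared: float
    frac_temperature: float
    frac_residual: float
    total_adj_r2: float
    p_fishing: float | None
    p_temperature: float | None
    lag: int
    n_years: int

    @property
    def frac_fishing_reported(self) -> float:
        return max(self.frac_fishing, 0.0)

    @property
    def frac_shared_reported(self) -> float:
        return max(self.frac_shared, 0.0)

    @property
    def frac_temperature_reported(self) -> float:
        return max(self.frac_temperature, 0.0)

    @property
    def total_reported(self) -> float:
        return max(self.total_adj_r2, 0.0)


def _center(A: np.ndarray) -> np.ndarray:
    return A - A.mean(axis=0, keepdims=True)


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _project(Y: np.ndarray, X: np.ndarray, rtol: float = 1e-10):
    """Orthogonal projection of Y onto col(X) via thin SVD; returns
    (projection, rank)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > rtol * (s[0] if s.size else 0.0)))
    U = U[:, :rank]
    return U @ (U.T @ Y), rank


def rda_r2(Y, X, W=None, allow_collinear: bool = False) -> RDAFit:
    """RDA of Y on X, optionally conditioning on (partialling out) W.

    All matrices are column-centered first.  With W present, both Y and X are
    residualized on W and the explained sum of squares of the residual fit is
    reported as a fraction of the *total* centered SS of Y, so that partial
    and marginal fractions share a common denominator.

    pseudo_F = (SS_explained / p) / (SS_residual / (n − p − q − 1)), the
    standard constrained-ordination statistic.
    """
    Y = _center(np.asarray(Y, float))
    X = _center(_as_matrix(X))
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValidationError("Y and X row counts differ")
    q = 0
    ss_total = float(np.sum(Y * Y))
    if ss_total <= 0:
        raise DegenerateInputError("Y has zero variance after centering")
    if W is not None:
        W = _center(_as_matrix(W))
        q = W.shape[1]
        pre_norms = np.linalg.norm(X, axis=0)
        Y = Y - _project(Y, W)[0]
        X = X - _project(X, W)[0]
        # a column absorbed by W leaves only float noise: zero it out instead
        # of projecting onto a meaningless direction
        gone = np.linalg.norm(X, axis=0) <= 1e-8 * np.maximum(pre_norms, 1e-300)
        X[:, gone] = 0.0
    if n <= p + q + 1:
        raise InsufficientDataError(f"n={n} too small for p={p}, q={q} predictors")
    proj, rank = _project(Y, X)
    if rank < p and not allow_collinear:
        raise CollinearityError(f"X rank {rank} < {p} after residualization")
    ss_exp = float(np.sum(proj * proj))
    ss_res = float(np.sum((Y - proj) ** 2))
    r2 = ss_exp / ss_total
    df_res = n - p - q - 1
    pseudo_F = (ss_exp / p) / (ss_res / df_res) if ss_res > 0 else np.inf
    return RDAFit(
        r2=r2, adj_r2=adjust_r2(r2, n, p + q), n=n, p=p, q=q, pseudo_F=pseudo_F
    )


def adjust_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjusted R²: 1 − (1 − R²)(n − 1)/(n − p − 1).

    Unbiased at zero under random predictors; may be negative.
    """
    if n - p - 1 < 1:
        raise InsufficientDataError(f"n={n}, p={p}: no residual degrees of freedom")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def permutation_test_fraction(
    Y,
    x_focal,
    x_cond=None,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for the (partial) fraction explained by ``x_focal``.

    The observed statistic is the partial pseudo-F of ``Y ~ x_focal | x_cond``.
    Null replicates follow the Freedman–Lane scheme: fitted values of the
    reduced model (``Y ~ x_cond``, or the column means when unconditioned) are
    kept fixed and the reduced-model residual rows are permuted, after which
    the partial pseudo-F is recomputed.  p = (#{F* ≥ F_obs} + 1)/(n_perm + 1).

    Deterministic given ``seed``; permutations are vectorized so the default
    1000 draws cost a few milliseconds at survey-series sizes.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99 for usable resolution")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    Y = _center(np.asarray(Y, float))
    n, m = Y.shape
    if float(np.sum(Y * Y)) <= 0:
        raise DegenerateInputError("Y has zero variance after centering")

    def unit(v):
        nv = np.linalg.norm(v)
        if nv <= 1e-12 * max(1.0, np.abs(v).max(initial=0.0)):
            raise CollinearityError("focal predictor has no variance left")
        return v / nv

    q = 0
    if x_cond is not None:
        w = _center(_as_matrix(x_cond))
        # a constant conditioning variable spans nothing beyond the intercept
        keep = np.linalg.norm(w, axis=0) > 1e-12
        w = w[:, keep] if keep.any() else None
    if x_cond is not None and w is not None:
        q = w.shape[1]
        w, _ = np.linalg.qr(w)
        # orthonormal basis of the conditioning space (beyond the intercept)
        R = Y - w @ (w.T @ Y)  # reduced-model residuals
        xf = _center(_as_matrix(x_focal))[:, 0]
        u = unit(xf - w @ (w.T @ xf))
    else:
        w = None
        R = Y
        u = unit(_center(_as_matrix(x_focal))[:, 0])
    n_perm = int(n_perm)
    df_res = n - 1 - q - 1
    if df_res < 1:
        raise InsufficientDataError("no residual degrees of freedom")

    def pseudo_F(ss_exp, ss_after_cond):
        return ss_exp / np.maximum(ss_after_cond - ss_exp, 1e-300) * df_res

    ss_R = float(np.sum(R * R))
    f_obs = pseudo_F(float(np.sum((u @ R) ** 2)), ss_R)

    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    Rp = R[perms]  # (n_perm, n, m): permuted reduced-model residual rows
    ss_exp = np.einsum("n,bnm->bm", u, Rp)
    ss_exp = np.sum(ss_exp**2, axis=1)
    if w is not None:
        wPR = np.einsum("nq,bnm->bqm", w, Rp)
        ss_after = ss_R - np.sum(wPR**2, axis=(1, 2))
    else:
        # rows of R are centered, so permutation leaves column means at zero
        ss_after = np.full(n_perm, ss_R)
    f_null = pseudo_F(ss_exp, ss_after)
    return float((np.sum(f_null >= f_obs - 1e-12) + 1) / (n_perm + 1))


def partition2(
    Y,
    x_fish,
    x_temp,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    lag: int = 0,
    do_tests: bool = True,
) -> PartitionResult:
    """Two-set adjusted variation partition of Y on fishing and temperature.

    The joint model is fitted allowing collinear predictors (identical fishing
    and temperature series collapse onto one axis; the projection is still
    well defined and the whole overlap lands in the shared fraction).
    """
    Y = np.asarray(Y, float)
    fit_f = rda_r2(Y, x_fish, allow_collinear=True)
    fit_t = rda_r2(Y, x_temp, allow_collinear=True)
    fit_ft = rda_r2(Y, np.column_stack([x_fish, x_temp]), allow_collinear=True)
    a = fit_ft.adj_r2 - fit_t.adj_r2
    c = fit_ft.adj_r2 - fit_f.adj_r2
    b = fit_f.adj_r2 + fit_t.adj_r2 - fit_ft.adj_r2
    p_f = p_t = None
    if do_tests:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        # a predictor with no variance (or one collinear with the other set)
        # has no testable pure fraction; its p stays None
        try:
            p_f = permutation_test_fraction(Y, x_fish, x_temp, n_perm=n_perm, seed=rng)
        except CollinearityError:
            p_f = None
        try:
            p_t = permutation_test_fraction(Y, x_temp, x_fish, n_perm=n_perm, seed=rng)
        except CollinearityError:
            p_t = None
    return PartitionResult(
        frac_fishing=a,
        frac_shared=b,
        frac_temperature=c,
        frac_residual=1.0 - fit_ft.adj_r2,
        total_adj_r2=fit_ft.adj_r2,
        p_fishing=p_f,
        p_temperature=p_t,
        lag=lag,
        n_years=Y.shape[0],
    )


def default_lag_candidates(sampling_interval_years: int, include_lag0: bool = True):
    """Lag candidates by survey cadence; ``include_lag0=False`` restricts
    multi-year surveys to the {2, 3} set."""
    if sampling_interval_years > 1:
        return LAGS_MULTIYEAR if include_lag0 else (2, 3)
    return LAGS_ANNUAL


def select_lag_model(
    stock: StockSeries,
    lag_candidates=None,
    min_years: int = DEFAULT_MIN_YEARS,
    n_perm: int = 1000,
    seed: int = 0,
    transform: str = "proportions",
) -> PartitionResult:
    """Fit the partition at each candidate temperature lag and keep the one
    with the largest total adjusted R² (ties → smaller lag).

    Permutation tests are run only for the winning lag, on its alignment.
    """
    if lag_candidates is None:
        lag_candidates = default_lag_candidates(stock.meta.sampling_interval_years)
    if not len(lag_candidates):
        raise ValidationError("lag_candidates must be non-empty")
    best = None
    errors = []
    for lag in sorted(set(int(l) for l in lag_candidates)):
        try:
            Y, xf, xt, _ = align_years(stock, lag, min_years=min_years, transform=transform)
            res = partition2(Y, xf, xt, do_tests=False, lag=lag)
        except (InsufficientDataError, DegenerateInputError, CollinearityError) as e:
            errors.append(f"lag {lag}: {e}")
            continue
        if best is None or res.total_adj_r2 > best.total_adj_r2 + 1e-12:
            best = res
    if best is None:
        raise InsufficientDataError(
            f"{stock.meta.stock_id}: no candidate lag could be fitted "
            f"({'; '.join(errors)})"
        )
    Y, xf, xt, _ = align_years(stock, best.lag, min_years=min_years, transform=transform)
    return partition2(Y, xf, xt, n_perm=n_perm, seed=seed, lag=best.lag)
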