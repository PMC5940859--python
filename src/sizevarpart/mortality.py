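"""Exploitation rate ↔ instantaneous fishing mortality, and fishing-pressure indices.

West-coast US assessments report the annual exploitation rate μ (the fraction
of the stock removed by fishing over the year) rather than the instantaneous
fishing mortality F.  Under a type II fishery — fishing and natural mortality
operating concurrently through the year (Ricker's classification) — the two
are linked through

    Z = F + M,      A = 1 − e^(−Z),      μ = F · A / Z,

so μ = F (1 − e^(−(F+M))) / (F + M).  Given μ and the natural mortality M the
relation is inverted numerically to recover F.  Cross-stock fishing pressure
is expressed as the mortality ratio F/M (management commonly sets target F
proportional to M, so F/M is the comparable scale), summarized by its
long-term mean and coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .data import ForcingSeries
from .errors import DegenerateInputError, ValidationError


def mu_from_F(F: float, M: float) -> float:
    """Annual exploitation rate for instantaneous rates ``F`` and ``M``.

    Strictly increasing in F, 0 at F=0, approaching 1 as F → ∞, and always
    below the actual total mortality fraction A = 1 − e^(−(F+M)).
    """
    if F < 0 or M <= 0:
        raise ValidationError("need F >= 0 and M > 0")
    if F == 0:
        return 0.0
    Z = F + M
    return F * -np.expm1(-Z) / Z


def exploitation_to_F(mu: float, M: float, tol: float = 1e-10) -> float:
    """Invert :func:`mu_from_F`: the unique F ≥ 0 with ``mu_from_F(F, M) = mu``.

    Brent's method on an upper bracket doubled until it encloses the root.
    """
    if M <= 0:
        raise ValidationError("M must be > 0")
    if mu < 0:
        raise ValidationError("mu must be >= 0")
    if mu >= 1:
        raise ValidationError(f"mu={mu} >= 1 is infeasible under a type II fishery")
    if mu == 0:
        return 0.0
    hi = 1.0
    while mu_from_F(hi, M) < mu:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - mu >= 1 already rejected
            raise ValidationError(f"could not bracket F for mu={mu}")
    return brentq(lambda F: mu_from_F(F, M) - mu, 0.0, hi, xtol=tol)


def fill_fishing_mortality(forcing: ForcingSeries, M: float) -> ForcingSeries:
    """Return a forcing series whose F column is complete, converting from μ
    where F is missing.  Years with F already present are left untouched."""
    F = forcing.F.copy()
    need = ~np.isfinite(F)
    if not need.any():
        return forcing
    for i in np.flatnonzero(need):
        F[i] = exploitation_to_F(float(forcing.mu[i]), M)
    return replace(forcing, F=F)


def mortality_ratio_series(F, M: float) -> np.ndarray:
    """Elementwise mortality ratio F_t / M."""
    if M <= 0:
        raise ValidationError("M must be > 0")
    return np.asarray(F, float) / M


@dataclass(frozen=True)
class FishingIndices:
    """Long-term summary of the annual F/M series."""

    ratio_series: np.ndarray
    mean_FM: float
    cv_FM: float


def long_term_indices(series) -> tuple[float, float]:
    """Arithmetic mean and CV (sample sd / mean) of a series."""
    x = np.asarray(series, float)
    if x.size < 2:
        raise ValidationError("need at least 2 values for mean/CV")
    mean = float(x.mean())
    if mean == 0:
        raise DegenerateInputError("CV undefined: series mean is zero")
    return mean, float(x.std(ddof=1) / mean)


def fishing_indices(F, M: float) -> FishingIndices:
    ratios = mortality_ratio_series(F, M)
    mean, cv = long_term_indices(ratios)
    return FishingIndices(ratio_series=ratios, mean_FM=mean, cv_FM=cv)
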