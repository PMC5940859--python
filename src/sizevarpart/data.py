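"""Data model and I/O for annual length compositions, forcing series and stock metadata.

The unit of analysis is a :class:`StockSeries`: one stock's years × length-bins
count matrix together with the annual fishing-mortality / temperature forcing
and the life-history metadata needed downstream.  Length bins are half-open
``[lower, upper)`` intervals in centimetres.  Years may be irregular (some
surveys run every 2–3 years); alignment against the forcing series, including
a lagged temperature, is handled by :func:`align_years`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DegenerateInputError,
    FormatError,
    InsufficientDataError,
    ValidationError,
)

REGIONS = ("WestUS", "Alaska", "NorthSea", "other")
HABITATS = ("pelagic", "demersal", "benthic")

#: Minimum aligned years required for a per-stock analysis.
DEFAULT_MIN_YEARS = 8


def _as_1d(x, dtype=float) -> np.ndarray:
    return np.asarray(x, dtype=dtype).reshape(-1)


@dataclass(frozen=True)
class LengthComposition:
    """Annual length-frequency matrix.

    Parameters
    ----------
    years
        Strictly increasing calendar years (gaps allowed).
    bin_edges
        Strictly increasing edges; ``len(bin_edges) - 1`` length classes.
    counts
        ``(n_years, n_bins)`` nonnegative frequencies; every row must have a
        positive total (an all-zero survey year carries no information and is
        rejected at load).
    """

    years: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "years", _as_1d(self.years, int))
        object.__setattr__(self, "bin_edges", _as_1d(self.bin_edges))
        object.__setattr__(self, "counts", np.asarray(self.counts, float))
        years, edges, counts = self.years, self.bin_edges, self.counts
        if edges.size < 3:
            raise ValidationError("need at least 2 length bins (3 edges)")
        if np.any(np.diff(edges) <= 0):
            raise ValidationError("bin_edges must be strictly increasing")
        if np.any(np.diff(years) <= 0):
            raise ValidationError("years must be strictly increasing")
        if counts.ndim != 2 or counts.shape != (years.size, edges.size - 1):
            raise ValidationError(
                f"counts shape {counts.shape} != (n_years={years.size}, "
                f"n_bins={edges.size - 1})"
            )
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValidationError("counts must be finite and nonnegative")
        if np.any(counts.sum(axis=1) <= 0):
            bad = years[counts.sum(axis=1) <= 0]
            raise ValidationError(f"all-zero year(s) in composition: {bad.tolist()}")

    @property
    def n_years(self) -> int:
        return self.years.size

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LengthComposition):
            return NotImplemented
        return (
            np.array_equal(self.years, other.years)
            and np.array_equal(self.bin_edges, other.bin_edges)
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class ForcingSeries:
    """Annual forcing: fishing mortality ``F`` (yr⁻¹) or exploitation rate
    ``mu`` (fraction of the stock removed per year), plus temperature ``T``
    (°C).  Missing entries are NaN; every year must carry at least one of
    ``F`` / ``mu``."""

    years: np.ndarray
    F: np.ndarray | None = None
    mu: np.ndarray | None = None
    T: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "years", _as_1d(self.years, int))
        n = self.years.size
        for name in ("F", "mu", "T"):
            v = getattr(self, name)
            v = np.full(n, np.nan) if v is None else _as_1d(v)
            if v.size != n:
                raise ValidationError(f"{name} length {v.size} != n_years {n}")
            object.__setattr__(self, name, v)
        if np.any(np.diff(self.years) <= 0):
            raise ValidationError("forcing years must be strictly increasing")
        if np.any(self.F[np.isfinite(self.F)] < 0):
            raise ValidationError("F must be >= 0 where present")
        mu = self.mu[np.isfinite(self.mu)]
        if np.any((mu < 0) | (mu >= 1)):
            raise ValidationError("mu must lie in [0, 1) where present")
        if np.any(~np.isfinite(self.F) & ~np.isfinite(self.mu)):
            raise ValidationError("every forcing year needs F or mu")

    def __eq__(self, other) -> bool:
        if not isinstance(other, ForcingSeries):
            return NotImplemented
        same = np.array_equal(self.years, other.years)
        for name in ("F", "mu", "T"):
            a, b = getattr(self, name), getattr(other, name)
            same = same and np.array_equal(a, b, equal_nan=True)
        return same


@dataclass(frozen=True)
class StockMeta:
    """Per-stock metadata: region/habitat vocabulary, natural mortality ``M``
    and the von Bertalanffy / maturation traits used by the meta-analysis."""

    stock_id: str
    region: str
    habitat: str
    M: float
    K: float
    L_inf: float
    A_50: float
    L_50: float
    sampling_interval_years: int = 1
    bin_terminal_edge: float | None = None

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValidationError(f"region {self.region!r} not in {REGIONS}")
        if self.habitat not in HABITATS:
            raise ValidationError(f"habitat {self.habitat!r} not in {HABITATS}")
        if not self.M > 0:
            raise ValidationError("M must be > 0")
        if not (self.K > 0 and self.L_inf > 0):
            raise ValidationError("K and L_inf must be > 0")
        if not self.L_50 < self.L_inf:
            raise ValidationError("L_50 must be < L_inf")
        if int(self.sampling_interval_years) < 1:
            raise ValidationError("sampling_interval_years must be >= 1")


@dataclass(frozen=True)
class StockSeries:
    """One stock's composition + forcing + metadata (the unit of analysis)."""

    meta: StockMeta
    composition: LengthComposition
    forcing: ForcingSeries

    def __post_init__(self):
        common = np.intersect1d(self.composition.years, self.forcing.years)
        if common.size == 0:
            raise ValidationError(
                f"{self.meta.stock_id}: composition and forcing share no years"
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, StockSeries):
            return NotImplemented
        return (
            self.meta == other.meta
            and self.composition == other.composition
            and self.forcing == other.forcing
        )


# ---------------------------------------------------------------------------
# transforms


def to_proportions(comp: LengthComposition) -> LengthComposition:
    """Normalize each year's counts to proportions (rows sum to 1)."""
    totals = comp.counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise DegenerateInputError("zero-total row: cannot form proportions")
    return replace(comp, counts=comp.counts / totals)


def hellinger(comp: LengthComposition) -> LengthComposition:
    """Hellinger transform: square root of row proportions."""
    return replace(to_proportions(comp), counts=np.sqrt(to_proportions(comp).counts))


def drop_empty_bins(comp: LengthComposition) -> LengthComposition:
    """Drop length classes whose total count over all years is zero.

    Empty classes contribute no variance and would only distort evenness
    denominators and column centering downstream.  Edges are pruned so the
    remaining bins keep their original intervals; interior gaps are closed by
    keeping the lower edge of each retained bin plus the final upper edge.
    """
    keep = comp.counts.sum(axis=0) > 0
    if keep.all():
        return comp
    if keep.sum() < 2:
        raise DegenerateInputError("fewer than 2 occupied length classes")
    lowers = comp.bin_edges[:-1][keep]
    upper = comp.bin_edges[1:][keep][-1]
    return LengthComposition(
        years=comp.years,
        bin_edges=np.append(lowers, upper),
        counts=comp.counts[:, keep],
    )


_TRANSFORMS = ("proportions", "hellinger")


def align_years(
    stock: StockSeries,
    temp_lag: int,
    min_years: int = DEFAULT_MIN_YEARS,
    transform: str = "proportions",
):
    """Align composition rows with same-year fishing and lag-year temperature.

    For each composition year ``t`` the retained observation is the response
    row at ``t``, fishing mortality ``F(t)`` (fishing is never lagged: it acts
    on the standing stock immediately) and temperature ``T(t - temp_lag)``
    (temperature acts through recruitment with a delay).  Years missing any of
    the three are dropped, order is preserved.

    Returns
    -------
    (Y, x_fish, x_temp, years)
        ``Y`` is the transformed response matrix (row proportions by default,
        Hellinger optionally); vectors are aligned to ``years``.

    Raises
    ------
    InsufficientDataError
        If fewer than ``min_years`` rows survive alignment.
    """
    if temp_lag < 0:
        raise ValidationError("temp_lag must be >= 0")
    if transform not in _TRANSFORMS:
        raise ValidationError(f"transform must be one of {_TRANSFORMS}")
    comp = drop_empty_bins(stock.composition)
    comp = to_proportions(comp) if transform == "proportions" else hellinger(comp)

    fyears = stock.forcing.years
    f_at = dict(zip(fyears.tolist(), stock.forcing.F))
    t_at = dict(zip(fyears.tolist(), stock.forcing.T))

    rows, xf, xt, years = [], [], [], []
    for i, yr in enumerate(comp.years.tolist()):
        F = f_at.get(yr, np.nan)
        T = t_at.get(yr - temp_lag, np.nan)
        if np.isfinite(F) and np.isfinite(T):
            rows.append(comp.counts[i])
            xf.append(F)
            xt.append(T)
            years.append(yr)
    if len(years) < min_years:
        raise InsufficientDataError(
            f"{stock.meta.stock_id}: {len(years)} aligned years at lag "
            f"{temp_lag} (< {min_years}). Forcing F may need conversion from mu."
        )
    return np.array(rows), np.array(xf), np.array(xt), years


# ---------------------------------------------------------------------------
# I/O — tidy composition CSV (year, bin_lower, count), forcing CSV
# (year, F and/or mu, T) and a key:value metadata YAML.


def _read_meta_yaml(meta_path) -> StockMeta:
    with open(meta_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FormatError(f"{meta_path}: expected a mapping of StockMeta fields")
    fields = {
        "stock_id", "region", "habitat", "M", "K", "L_inf", "A_50", "L_50",
        "sampling_interval_years", "bin_terminal_edge",
    }
    unknown = set(raw) - fields
    if unknown:
        raise FormatError(f"{meta_path}: unknown metadata keys {sorted(unknown)}")
    missing = fields - set(raw) - {"sampling_interval_years", "bin_terminal_edge"}
    if missing:
        raise FormatError(f"{meta_path}: missing metadata keys {sorted(missing)}")
    return StockMeta(**raw)


def read_composition_csv(path, terminal_edge: float | None = None) -> LengthComposition:
    """Read a tidy (year, bin_lower, count) file into a LengthComposition.

    Bins are assembled from the sorted distinct ``bin_lower`` values plus a
    terminal upper edge — declared by the caller (usually via the metadata
    file) or, failing that, extrapolated with the median bin width.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"year", "bin_lower", "count"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
    if df["count"].lt(0).any():
        raise ValidationError(f"{path}: negative counts")
    if df.duplicated(subset=["year", "bin_lower"]).any():
        raise ValidationError(f"{path}: duplicate (year, bin_lower) entries")
    grid = df.pivot(index="year", columns="bin_lower", values="count")
    grid = grid.sort_index().sort_index(axis=1).fillna(0.0)
    lowers = grid.columns.to_numpy(float)
    if terminal_edge is None:
        width = float(np.median(np.diff(lowers))) if lowers.size > 1 else 1.0
        terminal_edge = float(lowers[-1]) + width
    edges = np.append(lowers, terminal_edge)
    return LengthComposition(grid.index.to_numpy(int), edges, grid.to_numpy(float))


def read_forcing_csv(path) -> ForcingSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    if "year" not in df.columns or not ({"F", "mu"} & set(df.columns)):
        raise FormatError(f"{path}: need columns year and F and/or mu")
    df = df.sort_values("year")
    get = lambda c: df[c].to_numpy(float) if c in df.columns else None
    return ForcingSeries(df["year"].to_numpy(int), F=get("F"), mu=get("mu"), T=get("T"))


def read_stock_csv(path, meta_path, forcing_path=None) -> StockSeries:
    """Load a validated StockSeries from a composition CSV + metadata YAML.

    The forcing CSV defaults to ``forcing.csv`` next to the metadata file.
    """
    meta = _read_meta_yaml(meta_path)
    comp = read_composition_csv(path, terminal_edge=meta.bin_terminal_edge)
    # pin the resolved edge so loaded objects round-trip exactly
    meta = replace(meta, bin_terminal_edge=float(comp.bin_edges[-1]))
    if forcing_path is None:
        forcing_path = Path(meta_path).with_name("forcing.csv")
    forcing = read_forcing_csv(forcing_path)
    return StockSeries(meta=meta, composition=comp, forcing=forcing)


def write_stock_csv(stock: StockSeries, directory) -> dict:
    """Write composition.csv / forcing.csv / meta.yaml; returns the paths.

    The files round-trip: ``read_stock_csv`` on the output reproduces an
    equal StockSeries.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    comp = stock.composition
    tidy = pd.DataFrame(
        {
            "year": np.repeat(comp.years, comp.n_bins),
            "bin_lower": np.tile(comp.bin_edges[:-1], comp.n_years),
            "count": comp.counts.ravel(),
        }
    )
    paths = {
        "composition": directory / "composition.csv",
        "forcing": directory / "forcing.csv",
        "meta": directory / "meta.yaml",
    }
    tidy.to_csv(paths["composition"], index=False, float_format="%.17g")
    fr = pd.DataFrame({"year": stock.forcing.years})
    for name in ("F", "mu", "T"):
        v = getattr(stock.forcing, name)
        if np.any(np.isfinite(v)):
            fr[name] = v
    fr.to_csv(paths["forcing"], index=False, float_format="%.17g")
    meta = {
        "stock_id": stock.meta.stock_id,
        "region": stock.meta.region,
        "habitat": stock.meta.habitat,
        "sampling_interval_years": int(stock.meta.sampling_interval_years),
        "M": float(stock.meta.M),
        "K": float(stock.meta.K),
        "L_inf": float(stock.meta.L_inf),
        "A_50": float(stock.meta.A_50),
        "L_50": float(stock.meta.L_50),
        "bin_terminal_edge": float(comp.bin_edges[-1]),
    }
    with open(paths["meta"], "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return paths
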