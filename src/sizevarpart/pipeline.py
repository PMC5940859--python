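"""End-to-end orchestration: per-stock analysis, cross-stock meta-analysis,
and reproduction of the embedded published tables.

The per-stock stage converts exploitation rates to fishing mortality where
needed, selects the temperature lag by total adjusted R², runs the
permutation tests, and computes the univariate indicators and their forcing
regressions on the lag-0 alignment.  The meta stage assembles the per-stock
rows into a meta table and runs the cross-stock comparisons, covariate
models and the partition-vs-indicator efficiency comparison.  All outputs
are plain CSV with a JSON provenance sidecar; re-running with the same
config and seed reproduces the CSVs byte for byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import DEFAULT_MIN_YEARS, StockSeries, align_years, read_stock_csv
from .errors import InsufficientDataError, SizeVarPartError
from .fixtures import published_fractions_frame, published_regressions_frame
from .indicators import all_sbi_regressions, compute_sbi_table
from .meta import (
    COVARIATES,
    fraction_lmm,
    fraction_regression,
    paired_effect_comparisons,
    pvalue_efficiency_comparison,
    summarize_fraction_table,
)
from .mortality import fill_fishing_mortality, fishing_indices, long_term_indices
from .varpart import PartitionResult, default_lag_candidates, select_lag_model

PARTITION_COLUMNS = (
    "stock_id", "frac_fishing", "frac_shared", "frac_temperature",
    "total_adj_r2", "p_fishing", "p_temperature", "lag", "n_years",
)


@dataclass(frozen=True)
class RunConfig:
    """Knobs of a pipeline run (seeded, hence reproducible)."""

    n_perm: int = 1000
    seed: int = 0
    transform: str = "proportions"   # or "hellinger"
    min_years: int = DEFAULT_MIN_YEARS
    lag_candidates: tuple | None = None   # None -> per-stock defaults
    include_lag0_multiyear: bool = True

    def __post_init__(self):
        if self.n_perm < 99:
            raise SizeVarPartError("n_perm must be >= 99")


@dataclass
class StockResult:
    stock_id: str
    partition: PartitionResult
    sbi_table: pd.DataFrame
    sbi_regressions: dict
    stock: StockSeries
    mean_FM: float
    cv_FM: float
    mean_temp: float
    cv_temp: float


def _stock_seed(cfg: RunConfig, stock_id: str) -> int:
    # stable per-stock stream independent of batch order
    return int(np.random.SeedSequence(
        [cfg.seed, zlib.crc32(stock_id.encode())]
    ).generate_state(1)[0] % (2**31))


def run_single_stock(stock: StockSeries, cfg: RunConfig = RunConfig()) -> StockResult:
    """Partition + indicators for one stock.

    Raises package errors (insufficient aligned years, degenerate input);
    batch callers catch and record them per stock.
    """
    forcing = fill_fishing_mortality(stock.forcing, stock.meta.M)
    stock = replace(stock, forcing=forcing)
    lags = cfg.lag_candidates or default_lag_candidates(
        stock.meta.sampling_interval_years, cfg.include_lag0_multiyear
    )
    part = select_lag_model(
        stock,
        lag_candidates=lags,
        min_years=cfg.min_years,
        n_perm=cfg.n_perm,
        seed=_stock_seed(cfg, stock.meta.stock_id),
        transform=cfg.transform,
    )
    sbi_table = compute_sbi_table(stock.composition)
    _, xf, xt, years = align_years(stock, 0, min_years=cfg.min_years)
    regs = all_sbi_regressions(sbi_table.loc[years], xf, xt)

    # long-term forcing indices over the years covered by the composition
    yrs = stock.forcing.years
    span = (yrs >= stock.composition.years.min()) & (yrs <= stock.composition.years.max())
    F = stock.forcing.F[span]
    T = stock.forcing.T[span]
    fi = fishing_indices(F[np.isfinite(F)], stock.meta.M)
    mean_T, cv_T = long_term_indices(T[np.isfinite(T)])
    return StockResult(
        stock_id=stock.meta.stock_id,
        partition=part,
        sbi_table=sbi_table,
        sbi_regressions=regs,
        stock=stock,
        mean_FM=fi.mean_FM,
        cv_FM=fi.cv_FM,
        mean_temp=mean_T,
        cv_temp=cv_T,
    )


def partition_row(res: StockResult) -> dict:
    """One published-table-style row (fractions clamped at zero)."""
    p = res.partition
    return {
        "stock_id": res.stock_id,
        "frac_fishing": p.frac_fishing_reported,
        "frac_shared": p.frac_shared_reported,
        "frac_temperature": p.frac_temperature_reported,
        "total_adj_r2": p.total_reported,
        "p_fishing": p.p_fishing,
        "p_temperature": p.p_temperature,
        "lag": p.lag,
        "n_years": p.n_years,
    }


def build_meta_table(results: list[StockResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = partition_row(r)
        m = r.stock.meta
        row.update(
            region=m.region, habitat=m.habitat,
            K=m.K, L_inf=m.L_inf, A_50=m.A_50, L_50=m.L_50,
            mean_FM=r.mean_FM, cv_FM=r.cv_FM,
            mean_temp=r.mean_temp, cv_temp=r.cv_temp,
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class MetaOutputs:
    meta_table: pd.DataFrame
    comparisons: pd.DataFrame
    regressions: pd.DataFrame
    mixed_models: pd.DataFrame
    efficiency: pd.DataFrame
    summary: dict
    failures: dict = field(default_factory=dict)


def run_meta(results: list[StockResult], cfg: RunConfig = RunConfig()) -> MetaOutputs:
    """Cross-stock stage on successfully analyzed stocks (needs >= 3)."""
    if len(results) < 3:
        raise InsufficientDataError(f"meta-analysis needs >= 3 stocks, got {len(results)}")
    meta = build_meta_table(results)

    comps = []
    for group_by in (None, "region", "habitat"):
        for c in paired_effect_comparisons(meta, group_by=group_by, method="tukey"):
            comps.append({
                "grouping": group_by or "overall", "group": c.group_label,
                "pair": c.effect_pair, "n": c.n,
                "mean_difference": c.statistic, "p": c.p_value,
            })
    comparisons = pd.DataFrame(comps)

    regs, lmms = [], []
    for response in ("fishing", "temperature"):
        for cov in COVARIATES:
            coef, p = fraction_regression(meta, response, cov)
            regs.append({"response": response, "covariate": cov, "coef": coef, "p": p})
            lr = fraction_lmm(meta, response, cov)
            lmms.append({
                "response": response, "covariate": cov,
                "coef": lr.fixed_coef, "p": lr.p_value, "df": lr.df,
                "tau2": lr.tau2, "method": lr.method,
            })

    vp_rows, sbi_rows = [], []
    for r in results:
        for effect, p in (("fishing", r.partition.p_fishing),
                          ("temperature", r.partition.p_temperature)):
            vp_rows.append({"stock_id": r.stock_id, "effect": effect, "p": p})
            for name, reg in r.sbi_regressions.items():
                sbi_rows.append({
                    "stock_id": r.stock_id, "effect": effect, "sbi": name,
                    "p": reg.p_values[effect],
                })
    eff_rows = []
    for effect in ("fishing", "temperature"):
        vp = pd.DataFrame([r for r in vp_rows if r["effect"] == effect])
        sp = pd.DataFrame([r for r in sbi_rows if r["effect"] == effect])
        e = pvalue_efficiency_comparison(vp, sp)
        eff_rows.append({
            "effect": effect, "prob_success": e.prob_success,
            "binom_p": e.binom_p, "n_pairs": e.n_pairs, "n_success": e.n_success,
        })

    return MetaOutputs(
        meta_table=meta,
        comparisons=comparisons,
        regressions=pd.DataFrame(regs),
        mixed_models=pd.DataFrame(lmms),
        efficiency=pd.DataFrame(eff_rows),
        summary=summarize_fraction_table(meta),
    )


# ---------------------------------------------------------------------------
# batch over a directory of stocks, and output writing


def load_stock_dir(directory) -> list[StockSeries]:
    """Load every stock subdirectory (composition.csv + meta.yaml [+ forcing.csv])."""
    directory = Path(directory)
    stocks = []
    for meta_path in sorted(directory.glob("*/meta.yaml")):
        stocks.append(read_stock_csv(meta_path.parent / "composition.csv", meta_path))
    if not stocks:
        raise SizeVarPartError(f"no stock subdirectories under {directory}")
    return stocks


def analyze_stocks(stocks: list[StockSeries], cfg: RunConfig = RunConfig()):
    """Per-stock stage over a batch; failures are recorded, not fatal."""
    results, failures = [], {}
    for stock in stocks:
        try:
            results.append(run_single_stock(stock, cfg))
        except SizeVarPartError as e:
            failures[stock.meta.stock_id] = str(e)
    return results, failures


def write_outputs(out_dir, cfg: RunConfig, results=None, meta_out: MetaOutputs | None = None):
    """Write per-stock and meta CSVs plus a JSON provenance sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if results:
        part = pd.DataFrame([partition_row(r) for r in results])
        part.to_csv(out_dir / "partition.csv", index=False)
        written.append("partition.csv")
        sbi = pd.concat(
            [r.sbi_table.assign(stock_id=r.stock_id) for r in results]
        ).reset_index()
        sbi.to_csv(out_dir / "sbi.csv", index=False)
        written.append("sbi.csv")
        reg_rows = [
            {"stock_id": r.stock_id, "sbi": name, "term": term,
             "coef": reg.coefficients[term], "p": reg.p_values[term]}
            for r in results
            for name, reg in r.sbi_regressions.items()
            for term in reg.coefficients
        ]
        pd.DataFrame(reg_rows).to_csv(out_dir / "sbi_regressions.csv", index=False)
        written.append("sbi_regressions.csv")
    if meta_out is not None:
        for name, df in (
            ("meta_table", meta_out.meta_table),
            ("effect_comparisons", meta_out.comparisons),
            ("fraction_regressions", meta_out.regressions),
            ("fraction_mixed_models", meta_out.mixed_models),
            ("efficiency", meta_out.efficiency),
        ):
            df.to_csv(out_dir / f"{name}.csv", index=False)
            written.append(f"{name}.csv")
    sidecar = {
        "package": f"sizevarpart {__version__}",
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "transform": cfg.transform,
        "min_years": cfg.min_years,
        "files": written,
    }
    if meta_out is not None:
        sidecar["summary"] = meta_out.summary
        sidecar["failures"] = meta_out.failures
    (out_dir / "run.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir


# ---------------------------------------------------------------------------
# fixture mode: statistics of the embedded published tables


def run_fixture(out_dir=None) -> dict:
    """Recompute the published summary statistics from the embedded tables.

    Returns the column summaries plus the ANOVA/Tukey effect comparisons
    (overall and by region) computed from the printed per-stock fractions,
    and echoes the published covariate-regression table for reference.
    """
    meta = published_fractions_frame()
    summary = summarize_fraction_table(meta)
    comps = []
    for group_by in (None, "region"):
        for c in paired_effect_comparisons(meta, group_by=group_by, method="tukey"):
            comps.append({
                "grouping": group_by or "overall", "group": c.group_label,
                "pair": c.effect_pair, "n": c.n,
                "mean_difference": c.statistic, "p": c.p_value,
            })
    comparisons = pd.DataFrame(comps)
    out = {"summary": summary,
           "comparisons": comparisons,
           "published_regressions": published_regressions_frame()}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta.to_csv(out_dir / "published_fractions.csv", index=False)
        comparisons.to_csv(out_dir / "fixture_comparisons.csv", index=False)
        (out_dir / "fixture_summary.json").write_text(json.dumps(summary, indent=2))
    return out
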