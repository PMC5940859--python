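"""Seeded age-structured stock simulator for end-to-end testing.

The generator produces a :class:`~sizevarpart.data.StockSeries` with the two
causal pathways the analysis is designed to detect:

* **size-selective fishing** — a logistic (in length) selectivity removes
  large individuals at the annual fishing mortality ``F_t``, truncating the
  upper part of the observed length composition as ``F`` rises;
* **temperature-forced recruitment** — log-normal recruitment whose mean
  responds to the temperature anomaly ``rec_lag`` years earlier, perturbing
  the small-length classes with exactly that delay.

Population dynamics are a deterministic cohort model: mean length-at-age from
the von Bertalanffy curve, survival ``exp(−(M + s(L̄_a) F_t))``, recruitment
``R0·exp(β_T (T_{t−ℓ} − T̄) − σ_R²/2 + η_t)`` (the −σ²/2 term keeps mean
recruitment stationary when β_T = 0).  The survey observes abundance through
a logistic vulnerability curve (the fishing selectivity unless a separate
survey curve is configured), spreads each age over lengths as a normal with
CV·L̄_a spread, and draws ``N_sample`` individuals multinomially into
``bin_width``-cm classes — a survey catch-at-length proxy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .data import ForcingSeries, LengthComposition, StockMeta, StockSeries, write_stock_csv
from .errors import SimulationError, ValidationError


@dataclass(frozen=True)
class SimConfig:
    """All parameters of the synthetic stock generator (units in comments)."""

    n_years: int = 35
    first_year: int = 1980
    # von Bertalanffy growth
    L_inf: float = 60.0       # cm
    K: float = 0.35           # yr^-1
    a0: float = -0.5          # yr
    cv_length: float = 0.12   # spread of length-at-age
    # mortality
    M: float = 0.25           # yr^-1
    a_max: int | None = None  # default: exp(-M*a_max) < 0.01, capped at 40
    # fishing selectivity, logistic in length
    sel_l50: float = 32.0     # cm
    sel_slope: float = 0.25   # cm^-1
    # survey vulnerability (None -> reuse fishing selectivity)
    survey_l50: float | None = None
    survey_slope: float | None = None
    # recruitment
    R0: float = 1e6
    beta_T: float = 0.25      # per deg C
    sigma_R: float = 0.3      # lognormal sd
    rec_lag: int = 1          # years
    # temperature AR(1)
    T_mean: float = 8.0       # deg C
    T_rho: float = 0.6
    T_sd: float = 0.6         # innovation sd, deg C
    # fishing trajectory
    F_start: float = 0.1      # yr^-1
    F_end: float = 0.6        # yr^-1
    F_rw_sd: float = 0.03     # random-walk sd
    # survey sampling
    N_sample: int = 5000
    bin_width: float = 2.0    # cm
    seed: int = 0
    stock_id: str = "sim"
    region: str = "other"
    habitat: str = "demersal"

    def __post_init__(self):
        if self.n_years < 2 or self.N_sample < 100:
            raise ValidationError("need n_years >= 2 and N_sample >= 100")
        if not (-1 < self.T_rho < 1):
            raise ValidationError("T_rho must lie in (-1, 1)")
        for name in ("L_inf", "K", "M", "cv_length", "bin_width"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.rec_lag < 0 or min(self.F_start, self.F_end) < 0:
            raise ValidationError("rec_lag and F must be nonnegative")

    @property
    def ages(self) -> np.ndarray:
        amax = self.a_max
        if amax is None:
            amax = int(min(np.ceil(-np.log(0.01) / self.M), 40))
        return np.arange(amax + 1)

    @property
    def pad_years(self) -> int:
        # temperature history needed for lagged recruitment and lag-3 alignment
        return max(self.rec_lag, 3)


def _logistic(L, l50, slope):
    return 1.0 / (1.0 + np.exp(-slope * (L - l50)))


def mean_length_at_age(cfg: SimConfig) -> np.ndarray:
    return cfg.L_inf * (1.0 - np.exp(-cfg.K * (cfg.ages - cfg.a0)))


def simulate_temperature(cfg: SimConfig, n: int | None = None, rng=None) -> np.ndarray:
    """AR(1) temperature series, started from its stationary distribution."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_years if n is None else n
    T = np.empty(n)
    stat_sd = cfg.T_sd / np.sqrt(1.0 - cfg.T_rho**2) if cfg.T_sd > 0 else 0.0
    T[0] = cfg.T_mean + stat_sd * rng.standard_normal()
    eps = cfg.T_sd * rng.standard_normal(n - 1)
    for t in range(1, n):
        T[t] = cfg.T_mean + cfg.T_rho * (T[t - 1] - cfg.T_mean) + eps[t - 1]
    return T


def simulate_fishing(cfg: SimConfig, rng=None) -> np.ndarray:
    """Linear F ramp plus a Gaussian random walk, reflected at zero."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    ramp = np.linspace(cfg.F_start, cfg.F_end, cfg.n_years)
    walk = np.cumsum(cfg.F_rw_sd * rng.standard_normal(cfg.n_years)) if cfg.F_rw_sd > 0 else 0.0
    return np.abs(ramp + walk)


def simulate_stock(cfg: SimConfig) -> StockSeries:
    """Run the cohort model and return an observed StockSeries.

    The forcing series starts ``cfg.pad_years`` before the first composition
    year (temperature history for lagged alignment; F pinned at ``F_start``
    in the pre-years), so every lag candidate retains all survey years.
    Identical configs (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    pad = cfg.pad_years
    T_full = simulate_temperature(cfg, n=pad + cfg.n_years, rng=rng)
    F_comp = simulate_fishing(cfg, rng=rng)
    rec_noise = cfg.sigma_R * rng.standard_normal(cfg.n_years) if cfg.sigma_R > 0 else np.zeros(cfg.n_years)

    La = mean_length_at_age(cfg)
    sel = _logistic(La, cfg.sel_l50, cfg.sel_slope)
    if cfg.survey_l50 is not None:
        vul = _logistic(La, cfg.survey_l50, cfg.survey_slope or cfg.sel_slope)
    else:
        vul = sel

    # survey length bins covering the plausible length range
    upper = np.ceil(cfg.L_inf * (1 + 4 * cfg.cv_length) / cfg.bin_width) * cfg.bin_width
    edges = np.arange(0.0, upper + cfg.bin_width / 2, cfg.bin_width)
    # per-age bin probabilities: normal around mean length-at-age
    cdf = norm.cdf(edges[None, :], loc=La[:, None], scale=np.maximum(cfg.cv_length * La, 1e-6)[:, None])
    age_bin = np.diff(cdf, axis=1)  # (n_ages, n_bins)

    # equilibrium start at F_start
    N = np.empty(La.size)
    N[0] = cfg.R0
    Z0 = cfg.M + sel * cfg.F_start
    for a in range(La.size - 1):
        N[a + 1] = N[a] * np.exp(-Z0[a])

    counts = np.empty((cfg.n_years, edges.size - 1))
    for t in range(cfg.n_years):
        anomaly = T_full[pad + t - cfg.rec_lag] - cfg.T_mean
        N[0] = cfg.R0 * np.exp(cfg.beta_T * anomaly - cfg.sigma_R**2 / 2 + rec_noise[t])
        w = N * vul
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise SimulationError(
                f"{cfg.stock_id}: vulnerable population collapsed in year {t} "
                f"(total={total!r})"
            )
        probs = w @ age_bin
        probs = np.maximum(probs, 0)
        probs /= probs.sum()
        counts[t] = rng.multinomial(cfg.N_sample, probs)
        Z = cfg.M + sel * F_comp[t]
        N[1:] = N[:-1] * np.exp(-Z[:-1])

    years = cfg.first_year + np.arange(cfg.n_years)
    keep = counts.sum(axis=0) > 0  # survey never sees the far tail bins
    comp = LengthComposition(years, np.append(edges[:-1][keep], edges[1:][keep][-1]), counts[:, keep])
    f_years = cfg.first_year - pad + np.arange(pad + cfg.n_years)
    F_full = np.concatenate([np.full(pad, cfg.F_start), F_comp])
    forcing = ForcingSeries(f_years, F=F_full, T=T_full)
    L50 = 0.5 * cfg.L_inf
    meta = StockMeta(
        stock_id=cfg.stock_id,
        region=cfg.region,
        habitat=cfg.habitat,
        M=cfg.M,
        K=cfg.K,
        L_inf=cfg.L_inf,
        A_50=float(cfg.a0 - np.log(1 - L50 / cfg.L_inf) / cfg.K),
        L_50=L50,
    )
    return StockSeries(meta=meta, composition=comp, forcing=forcing)


def simulate_fleet(
    n_stocks: int,
    seed: int = 0,
    base: SimConfig | None = None,
    out_dir=None,
) -> list[StockSeries]:
    """Generate a batch of stocks with varied traits and forcing regimes.

    Traits (K, L_inf, M), the fishing ramp, the recruitment sensitivity and
    the thermal regime are jittered across stocks (uniform ranges around the
    base config) so the cross-stock meta-analysis has covariate contrast;
    habitats cycle through the controlled vocabulary.  With ``out_dir`` set,
    each stock is written in the package CSV/YAML layout plus a manifest.
    """
    base = base or SimConfig()
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_stocks)
    rng = np.random.default_rng(ss.spawn(1)[0])
    habitats = ("demersal", "benthic", "pelagic")
    stocks = []
    for i in range(n_stocks):
        L_inf = float(rng.uniform(40, 100))
        cfg = replace(
            base,
            stock_id=f"sim{i:03d}",
            habitat=habitats[i % 3],
            L_inf=L_inf,
            K=float(rng.uniform(0.15, 0.5)),
            M=float(rng.uniform(0.15, 0.4)),
            sel_l50=float(0.5 * L_inf),
            F_start=float(rng.uniform(0.05, 0.2)),
            F_end=float(rng.uniform(0.2, 0.8)),
            beta_T=float(rng.uniform(0.0, 0.5)),
            T_mean=float(rng.uniform(5, 12)),
            seed=int(child[i].generate_state(1)[0] % (2**31)),
        )
        stocks.append(simulate_stock(cfg))
    if out_dir is not None:
        out_dir = Path(out_dir)
        manifest = []
        for stock, cfg_stock in zip(stocks, stocks):
            d = out_dir / stock.meta.stock_id
            write_stock_csv(stock, d)
            manifest.append(stock.meta.stock_id)
        (out_dir / "manifest.json").write_text(
            json.dumps({"seed": seed, "stocks": manifest}, indent=2)
        )
    return stocks


def config_to_yaml_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)


# ---------------------------------------------------------------------------
# documented study scenarios (used by the validation suite)


def scenario_fishing_ramp(seed: int = 0) -> SimConfig:
    """Strong exploitation build-up (F 0.1 → 0.8 over 35 years) with no
    temperature pathway: the positive control for detecting the fishing
    fraction."""
    return SimConfig(n_years=35, F_start=0.1, F_end=0.8, beta_T=0.0,
                     N_sample=5000, seed=seed)


def scenario_temperature_null(seed: int = 0) -> SimConfig:
    """Constant fishing, no recruitment forcing and no recruitment noise:
    temperature varies but cannot influence the stock, so any detected
    temperature fraction is a false positive."""
    return SimConfig(n_years=35, F_start=0.3, F_end=0.3, F_rw_sd=0.0,
                     beta_T=0.0, sigma_R=0.0, N_sample=5000, seed=seed)


def scenario_lag_recovery(true_lag: int, seed: int = 0) -> SimConfig:
    """Recruitment driven hard (β_T = 0.8 per °C) by white-noise temperature
    with delay ``true_lag``, and a survey that sees age-0 fish (low survey
    L50), so the size structure echoes temperature at exactly that lag."""
    return SimConfig(
        n_years=35, K=0.35, L_inf=60.0, a0=-0.5,
        survey_l50=8.0, survey_slope=0.5,
        beta_T=0.8, sigma_R=0.1, rec_lag=true_lag,
        T_rho=0.0, T_sd=1.0,
        F_start=0.3, F_end=0.3, F_rw_sd=0.05,
        N_sample=5000, seed=seed,
    )
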