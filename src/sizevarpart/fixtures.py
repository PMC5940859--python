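"""Embedded published per-stock results used as desk-scale fixtures.

``PUBLISHED_FRACTIONS`` carries, for each of the 28 exploited stocks (West US, Alaska,
North Sea), the printed three-decimal variance fractions from the best-lag
variation partition: pure fishing, shared ("interaction"), pure temperature
and total adjusted R², together with the printed significance class of the
two testable fractions (0 = n.s., 1 = P < 0.05, 2 = P < 0.01) and the lag of
the best model (years).  Printed fractions are clamped at zero, so column
arithmetic on them reproduces the published summary statistics exactly.

``PUBLISHED_REGRESSIONS`` carries the published univariate regression coefficients / p-values
of the explained fractions on each cross-stock covariate.

Habitat labels are not part of the published table (they come from a
supplement that is not embedded); the labels below are assigned from standard
species classifications — clupeids and mackerel pelagic, flatfishes benthic,
gadoids/rockfishes/sablefish-like demersal — and should be treated as a
synthetic reconstruction.  No published summary statistic recomputed here
depends on them.
"""

from __future__ import annotations

import pandas as pd

PUBLISHED_FRACTIONS_COLUMNS = (
    "stock_id",
    "region",
    "habitat",
    "frac_fishing",
    "frac_shared",
    "frac_temperature",
    "total_adj_r2",
    "sig_fishing",
    "sig_temperature",
    "lag",
)

# (stock, region, habitat, fishing, shared, temperature, total, sigF, sigT, lag)
PUBLISHED_FRACTIONS = [
    ("WestUS/arrowtooth_flounder", "WestUS", "benthic", 0.211, 0.000, 0.070, 0.262, 2, 1, 3),
    ("WestUS/chilipepper_rockfish", "WestUS", "demersal", 0.176, 0.000, 0.000, 0.173, 2, 0, 0),
    ("WestUS/darkblotched_rockfish", "WestUS", "demersal", 0.012, 0.000, 0.030, 0.029, 0, 0, 3),
    ("WestUS/dover_sole", "WestUS", "benthic", 0.038, 0.001, 0.094, 0.134, 0, 1, 0),
    ("WestUS/english_sole", "WestUS", "benthic", 0.000, 0.005, 0.021, 0.009, 0, 0, 1),
    ("WestUS/lingcod", "WestUS", "demersal", 0.214, 0.000, 0.058, 0.253, 2, 2, 3),
    ("WestUS/longspine_thornyhead", "WestUS", "demersal", 0.391, 0.000, 0.006, 0.392, 2, 0, 3),
    ("WestUS/petrale_sole", "WestUS", "benthic", 0.093, 0.000, 0.005, 0.093, 2, 0, 0),
    ("WestUS/sardine", "WestUS", "pelagic", 0.033, 0.000, 0.035, 0.057, 0, 0, 1),
    ("WestUS/splitnose_rockfish", "WestUS", "demersal", 0.122, 0.000, 0.015, 0.110, 1, 0, 0),
    ("WestUS/yelloweye_rockfish", "WestUS", "demersal", 0.312, 0.045, 0.040, 0.398, 2, 0, 1),
    ("Alaska/AI_walleye_pollock", "Alaska", "pelagic", 0.000, 0.000, 0.368, 0.266, 0, 0, 0),
    ("Alaska/GOA_walleye_pollock", "Alaska", "pelagic", 0.000, 0.042, 0.000, 0.000, 0, 0, 0),
    ("Alaska/EBS_flathead_sole", "Alaska", "benthic", 0.000, 0.000, 0.064, 0.025, 0, 0, 3),
    ("Alaska/GOA_flathead_sole", "Alaska", "benthic", 0.134, 0.000, 0.000, 0.109, 1, 0, 1),
    ("Alaska/EBS_pacific_cod", "Alaska", "demersal", 0.071, 0.000, 0.034, 0.104, 1, 0, 1),
    ("Alaska/GOA_pacific_cod", "Alaska", "demersal", 0.003, 0.022, 0.000, 0.000, 0, 0, 0),
    ("Alaska/GOA_rex_sole", "Alaska", "benthic", 0.312, 0.000, 0.059, 0.226, 0, 0, 0),
    ("NorthSea/cod", "NorthSea", "demersal", 0.067, 0.078, 0.094, 0.239, 1, 2, 1),
    ("NorthSea/haddock", "NorthSea", "demersal", 0.139, 0.000, 0.011, 0.116, 2, 0, 3),
    ("NorthSea/herring", "NorthSea", "pelagic", 0.003, 0.009, 0.001, 0.013, 0, 0, 1),
    ("NorthSea/mackerel", "NorthSea", "pelagic", 0.000, 0.011, 0.000, 0.000, 0, 0, 0),
    ("NorthSea/norway_pout", "NorthSea", "demersal", 0.000, 0.000, 0.001, 0.000, 0, 0, 0),
    ("NorthSea/plaice", "NorthSea", "benthic", 0.292, 0.112, 0.037, 0.440, 2, 1, 0),
    ("NorthSea/saithe", "NorthSea", "demersal", 0.027, 0.042, 0.037, 0.106, 0, 0, 0),
    ("NorthSea/sole", "NorthSea", "benthic", 0.000, 0.012, 0.072, 0.078, 0, 1, 3),
    ("NorthSea/sprat", "NorthSea", "pelagic", 0.025, 0.000, 0.102, 0.108, 0, 2, 0),
    ("NorthSea/whiting", "NorthSea", "demersal", 0.372, 0.000, 0.001, 0.351, 0, 0, 1),
]

#: covariate -> (coef on fishing fraction, p; coef on temperature fraction, p)
PUBLISHED_REGRESSIONS = {
    "A_50": (0.014, 0.125, 0.000, 0.975),
    "L_50": (-0.001, 0.622, 0.001, 0.523),
    "L_inf": (0.000, 0.596, 0.000, 0.927),
    "K": (-0.089, 0.509, 0.040, 0.599),
    "mean_FM": (-0.004, 0.840, 0.004, 0.673),
    "cv_FM": (0.075, 0.511, 0.122, 0.048),
    "mean_temp": (0.009, 0.163, -0.003, 0.343),
    "cv_temp": (-0.022, 0.459, -0.017, 0.308),
}


def published_fractions_frame() -> pd.DataFrame:
    """The embedded per-stock fraction table as a DataFrame."""
    return pd.DataFrame(PUBLISHED_FRACTIONS, columns=PUBLISHED_FRACTIONS_COLUMNS)


def published_regressions_frame() -> pd.DataFrame:
    rows = [
        {"covariate": cov, "coef_fishing": cf, "p_fishing": pf,
         "coef_temperature": ct, "p_temperature": pt}
        for cov, (cf, pf, ct, pt) in PUBLISHED_REGRESSIONS.items()
    ]
    return pd.DataFrame(rows)
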