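"""Cross-stock comparisons, covariate models and the efficiency comparison."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sizevarpart import (
    fraction_lmm,
    fraction_regression,
    paired_effect_comparisons,
    pvalue_efficiency_comparison,
)
from sizevarpart.errors import DegenerateInputError, InsufficientDataError
from sizevarpart.fixtures import published_fractions_frame
from sizevarpart.meta import repeated_measures_anova


def frame_of(f, s, t, habitat=None):
    df = pd.DataFrame(
        {"frac_fishing": f, "frac_shared": s, "frac_temperature": t}
    )
    if habitat is not None:
        df["habitat"] = habitat
    return df


class TestEffectComparisons:
    def test_tukey_matches_scipy_direct(self, rng):
        f, s, t = rng.normal(size=(3, 10))
        res = {
            c.effect_pair: c.p_value
            for c in paired_effect_comparisons(frame_of(f, s, t), method="tukey")
        }
        ref = stats.tukey_hsd(f, t, s)
        assert res["fishing-vs-temperature"] == pytest.approx(ref.pvalue[0, 1])
        assert res["temperature-vs-shared"] == pytest.approx(ref.pvalue[1, 2])

    def test_paired_t_identical_columns_p_one(self):
        x = np.linspace(0, 1, 8)
        res = paired_effect_comparisons(frame_of(x, x, x), method="paired_t")
        assert all(c.p_value == 1.0 for c in res)

    def test_paired_t_power_grows_with_shift(self, rng):
        noise = rng.normal(scale=0.05, size=30)
        base = rng.uniform(0, 0.3, size=30)
        ps = []
        for delta in (0.01, 0.05, 0.2):
            res = paired_effect_comparisons(
                frame_of(base + delta + noise, base, base * 0), method="paired_t"
            )
            ps.append({c.effect_pair: c.p_value for c in res}["fishing-vs-shared"])
        assert ps[0] > ps[1] > ps[2]

    def test_small_groups_skipped_with_warning(self):
        df = frame_of([0.1, 0.2, 0.3, 0.1], [0] * 4, [0.05] * 4, habitat=["a", "a", "a", "b"])
        with pytest.warns(UserWarning, match="skipped"):
            res = paired_effect_comparisons(df, group_by="habitat")
        assert {c.group_label for c in res} == {"a"}

    def test_repeated_measures_anova_detects_effect(self):
        meta = published_fractions_frame()
        F, p = repeated_measures_anova(meta)
        assert F > 1 and p < 0.05


class TestFractionRegression:
    def test_exact_slope_recovery(self, rng):
        cv = rng.uniform(0.1, 1.0, size=28)
        df = frame_of(0 * cv, 0 * cv, 0.1 + 0.122 * cv)
        df["cv_FM"] = cv
        coef, p = fraction_regression(df, "temperature", "cv_FM")
        assert coef == pytest.approx(0.122, abs=1e-10)
        assert p < 1e-10

    def test_permuted_covariate_uniform_p(self, rng):
        # under the null, p-values should be roughly uniform
        ps = []
        for _ in range(200):
            y = rng.uniform(0, 0.4, size=25)
            x = rng.normal(size=25)
            df = frame_of(y, 0 * y, 0 * y)
            df["K"] = x
            ps.append(fraction_regression(df, "fishing", "K")[1])
        assert 0.01 <= np.mean(np.array(ps) < 0.05) <= 0.12
        assert abs(np.mean(ps) - 0.5) < 0.08

    def test_constant_response_and_covariate_rules(self):
        df = frame_of([0.1] * 5, [0] * 5, [0] * 5)
        df["K"] = [1, 2, 3, 4, 5]
        assert fraction_regression(df, "fishing", "K") == (0.0, 1.0)
        df["L_inf"] = 50.0
        with pytest.raises(DegenerateInputError):
            fraction_regression(df, "fishing", "L_inf")


def lmm_frame(rng, n_per=20, slope=0.2, offsets=(0.1, -0.1, 0.0), noise=0.05):
    rows = []
    for off, hab in zip(offsets, ("demersal", "benthic", "pelagic")):
        x = rng.uniform(0, 1, n_per)
        y = 0.1 + off + slope * x + noise * rng.normal(size=n_per)
        for xi, yi in zip(x, y):
            rows.append(
                {"habitat": hab, "cv_FM": xi, "frac_temperature": yi,
                 "frac_fishing": 0.0, "frac_shared": 0.0}
            )
    return pd.DataFrame(rows)


class TestFractionLMM:
    def test_single_habitat_collapses_to_ols(self, rng):
        df = lmm_frame(rng, offsets=(0.0,))
        df = df[df.habitat == "demersal"]
        res = fraction_lmm(df, "temperature", "cv_FM")
        assert res.method == "ols-fallback"
        coef, p = fraction_regression(df, "temperature", "cv_FM")
        assert res.fixed_coef == pytest.approx(coef, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_orthogonal_covariate_matches_ols_slope(self, rng):
        df = lmm_frame(rng)
        # center the covariate within habitat: orthogonal to the random
        # intercepts, so LMM and OLS slopes coincide
        df["cv_FM"] -= df.groupby("habitat")["cv_FM"].transform("mean")
        res = fraction_lmm(df, "temperature", "cv_FM")
        coef, _ = fraction_regression(df, "temperature", "cv_FM")
        assert res.fixed_coef == pytest.approx(coef, abs=1e-6)

    def test_slope_recovery_coverage(self):
        # true slope inside the Satterthwaite CI in >= 90% of replicates
        root = np.random.SeedSequence(2024)
        hits = 0
        N = 150
        for ss in root.spawn(N):
            g = np.random.default_rng(ss)
            res = fraction_lmm(lmm_frame(g), "temperature", "cv_FM")
            tcrit = stats.t.ppf(0.975, res.df)
            hits += abs(res.fixed_coef - 0.2) <= tcrit * res.se
        assert hits / N >= 0.90

    def test_matches_lmer_satterthwaite(self, tmp_path, rng):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not on PATH; lmerTest oracle unavailable")
        df = lmm_frame(rng, n_per=12)
        df.to_csv(tmp_path / "d.csv", index=False)
        rcode = textwrap.dedent(
            f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{tmp_path}/d.csv")
            m <- lmer(frac_temperature ~ cv_FM + (1|habitat), data=d, REML=TRUE)
            s <- summary(m)$coefficients
            cat(sprintf("%.10f,%.6f,%.10g\\n", s[2,1], s[2,3], s[2,5]))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        slope_r, df_r, p_r = (float(v) for v in out.stdout.strip().split(","))
        res = fraction_lmm(df, "temperature", "cv_FM")
        assert res.method == "lmm-satterthwaite"
        assert res.fixed_coef == pytest.approx(slope_r, abs=1e-6)
        assert res.df == pytest.approx(df_r, rel=0.02)
        assert res.p_value == pytest.approx(p_r, rel=0.05, abs=1e-12)


class TestEfficiencyComparison:
    def pair_frames(self, vp_p, sbi_p):
        n = len(vp_p)
        vp = pd.DataFrame(
            {"stock_id": [f"s{i}" for i in range(n)], "effect": "fishing", "p": vp_p}
        )
        sp = pd.DataFrame(
            {"stock_id": [f"s{i}" for i in range(n)], "effect": "fishing",
             "sbi": "L95", "p": sbi_p}
        )
        return vp, sp

    def test_exact_binomial_example(self):
        # 8 wins of 10: one-sided tail = (45 + 10 + 1)/1024
        vp = [0.01] * 8 + [0.5] * 2
        sp = [0.02] * 8 + [0.1] * 2
        res = pvalue_efficiency_comparison(*self.pair_frames(vp, sp))
        assert res.prob_success == pytest.approx(0.8)
        assert res.binom_p == pytest.approx(56 / 1024, abs=1e-12)

    def test_all_ties_count_zero(self):
        res = pvalue_efficiency_comparison(*self.pair_frames([0.1] * 6, [0.1] * 6))
        assert res.prob_success == 0.0

    def test_always_smaller_closed_form(self):
        res = pvalue_efficiency_comparison(
            *self.pair_frames([0.01] * 12, [0.02] * 12)
        )
        assert res.prob_success == 1.0
        assert res.binom_p == pytest.approx(0.5**12, rel=1e-12)

    def test_no_pairs_errors(self):
        vp, sp = self.pair_frames([0.1], [0.2])
        sp["effect"] = "temperature"
        with pytest.raises(InsufficientDataError):
            pvalue_efficiency_comparison(vp, sp)
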