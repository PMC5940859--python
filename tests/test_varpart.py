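"""RDA, adjusted two-set partition, permutation test and lag selection."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from sizevarpart import (
    SimConfig,
    adjust_r2,
    partition2,
    permutation_test_fraction,
    rda_r2,
    select_lag_model,
    simulate_stock,
)
from sizevarpart.errors import (
    CollinearityError,
    DegenerateInputError,
    InsufficientDataError,
)
from sizevarpart.simulate import scenario_lag_recovery


def ols_r2_oracle(Y, x):
    """Brute-force oracle: per-column simple-regression explained SS over
    total centered SS."""
    Y = Y - Y.mean(axis=0)
    x = x - x.mean()
    ss_exp = sum(
        (float(x @ Y[:, j]) / float(x @ x)) ** 2 * float(x @ x)
        for j in range(Y.shape[1])
    )
    return ss_exp / float(np.sum(Y * Y))


class TestRdaR2:
    def test_perfect_fit(self, rng):
        x = rng.normal(size=12)
        Y = np.outer(x, rng.normal(size=5))
        assert rda_r2(Y, x).r2 == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_response(self):
        x = np.array([1.0, 2, 3, 4])
        Y = np.array([[1.0], [-1], [-1], [1]])  # orthogonal to centered x
        assert rda_r2(Y, x).r2 == pytest.approx(0.0, abs=1e-12)

    def test_two_column_example(self):
        x = np.array([1.0, 2, 3, 4])
        Y = np.column_stack([x - x.mean(), [1.0, -1, -1, 1]])
        fit = rda_r2(Y, x)
        assert fit.r2 == pytest.approx(5 / 9, abs=1e-12)
        assert fit.adj_r2 == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("n,m", [(10, 3), (25, 8), (15, 30)])
    def test_matches_percolumn_ols_oracle(self, rng, n, m):
        for _ in range(20):
            Y = rng.normal(size=(n, m))
            x = rng.normal(size=n)
            assert rda_r2(Y, x).r2 == pytest.approx(ols_r2_oracle(Y, x), abs=1e-10)

    def test_zero_variance_response(self):
        with pytest.raises(DegenerateInputError):
            rda_r2(np.ones((8, 3)), np.arange(8.0))

    def test_collinear_predictors_raise_unless_allowed(self, rng):
        x = rng.normal(size=10)
        Y = rng.normal(size=(10, 3))
        X = np.column_stack([x, 2 * x])
        with pytest.raises(CollinearityError):
            rda_r2(Y, X)
        fit = rda_r2(Y, X, allow_collinear=True)
        assert fit.r2 == pytest.approx(rda_r2(Y, x).r2, abs=1e-12)

    def test_partial_rda_focal_absorbed_by_conditioning(self, rng):
        # conditioning on x itself leaves no focal direction: rank deficient
        # in strict mode, explains exactly nothing when allowed
        x = rng.normal(size=15)
        Y = np.outer(x, rng.normal(size=4)) + 0.1 * rng.normal(size=(15, 4))
        with pytest.raises(CollinearityError):
            rda_r2(Y, x, W=x)
        fit = rda_r2(Y, x, W=x, allow_collinear=True)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_partial_rda_reported_on_total_ss(self, rng):
        # marginal fractions of two orthogonal predictors share the total
        # denominator, so partial(f | t) equals marginal(f) exactly
        n = 24
        f, t = rng.normal(size=n), rng.normal(size=n)
        f, t = f - f.mean(), t - t.mean()
        t -= (t @ f) / (f @ f) * f
        Y = np.outer(f, [1.0, -2.0]) + np.outer(t, [0.5, 1.0]) + rng.normal(size=(n, 2))
        assert rda_r2(Y, f, W=t).r2 == pytest.approx(rda_r2(Y, f).r2, abs=1e-10)


class TestAdjustR2:
    def test_examples(self):
        assert adjust_r2(1.0, 20, 2) == 1.0
        assert adjust_r2(0.0, 10, 1) == pytest.approx(-0.125)
        assert adjust_r2(5 / 9, 4, 1) == pytest.approx(1 / 3)

    def test_insufficient_df(self):
        with pytest.raises(InsufficientDataError):
            adjust_r2(0.5, 3, 2)


class TestPartition2:
    def test_identity_on_random_inputs(self, rng):
        for _ in range(30):
            Y = rng.normal(size=(16, 5))
            f, t = rng.normal(size=16), rng.normal(size=16)
            pr = partition2(Y, f, t, do_tests=False)
            assert (
                pr.frac_fishing + pr.frac_shared + pr.frac_temperature
                == pytest.approx(pr.total_adj_r2, abs=1e-10)
            )
            assert pr.frac_residual == pytest.approx(1 - pr.total_adj_r2, abs=1e-12)

    def test_identical_predictors_all_shared(self, rng):
        x = rng.normal(size=20)
        Y = np.outer(x, rng.normal(size=4)) + 0.5 * rng.normal(size=(20, 4))
        A_f = rda_r2(Y, x).adj_r2
        pr = partition2(Y, x, x.copy(), do_tests=False)
        assert pr.frac_fishing == pytest.approx(0.0, abs=0.06)
        assert pr.frac_temperature == pytest.approx(0.0, abs=0.06)
        assert pr.frac_shared == pytest.approx(A_f, abs=0.06)

    def test_orthogonal_design_separates_cleanly(self, rng):
        n = 40
        f = np.sin(np.arange(n))  # deterministic, then orthogonalized
        t = rng.normal(size=n)
        f = f - f.mean()
        t = t - t.mean()
        t = t - (t @ f) / (f @ f) * f  # exactly orthogonal
        Y = np.outer(f, [1.0, 0.5, 0.0]) + np.outer(t, [0.0, -0.5, 1.0])
        A_f, A_t = rda_r2(Y, f).adj_r2, rda_r2(Y, t).adj_r2
        pr = partition2(Y, f, t, do_tests=False)
        assert pr.frac_shared == pytest.approx(0.0, abs=0.03)
        assert pr.frac_fishing == pytest.approx(A_f, abs=0.03)
        assert pr.frac_temperature == pytest.approx(A_t, abs=0.03)

    def test_reported_values_clamped_but_totals_not(self, rng):
        Y = rng.normal(size=(12, 4))
        f, t = rng.normal(size=12), rng.normal(size=12)
        pr = partition2(Y, f, t, do_tests=False)
        assert pr.frac_fishing_reported >= 0
        assert pr.frac_shared_reported >= 0
        assert pr.frac_temperature_reported >= 0


class TestPermutationTest:
    def test_perfect_signal_minimum_p(self, rng):
        x = rng.normal(size=25)
        Y = np.outer(x, [1.0, 2.0, -1.0]) + 1e-9 * rng.normal(size=(25, 3))
        p = permutation_test_fraction(Y, x, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_deterministic_given_seed(self, rng):
        Y = rng.normal(size=(20, 4))
        f, t = rng.normal(size=20), rng.normal(size=20)
        p1 = permutation_test_fraction(Y, f, t, n_perm=199, seed=42)
        p2 = permutation_test_fraction(Y, f, t, n_perm=199, seed=42)
        assert p1 == p2

    def test_type1_error_rate_quick(self):
        # smaller replicate of the calibration run (full version in the
        # acceptance suite): null focal predictor, nominal alpha 0.05
        root = np.random.SeedSequence(7)
        rej = 0
        N = 300
        for ss in root.spawn(N):
            g = np.random.default_rng(ss)
            Y = g.normal(size=(30, 4))
            p = permutation_test_fraction(
                Y, g.normal(size=30), g.normal(size=30), n_perm=200, seed=g
            )
            rej += p < 0.05
        assert 0.02 <= rej / N <= 0.08

    def test_small_n_perm_rejected(self, rng):
        Y = rng.normal(size=(10, 3))
        with pytest.raises(Exception):
            permutation_test_fraction(Y, rng.normal(size=10), n_perm=50, seed=0)


class TestSelectLag:
    def test_single_candidate(self, small_stock):
        res = select_lag_model(small_stock, lag_candidates=(0,), n_perm=99, seed=0)
        assert res.lag == 0

    def test_constant_temperature_tie_breaks_to_lag0(self, small_stock):
        from dataclasses import replace

        forcing = replace(
            small_stock.forcing, T=np.full(small_stock.forcing.years.size, 8.0)
        )
        stock = replace(small_stock, forcing=forcing)
        res = select_lag_model(stock, lag_candidates=(0, 1, 3), n_perm=99, seed=0)
        assert res.lag == 0

    @pytest.mark.parametrize("true_lag", [1, 3])
    def test_lag_recovery_plurality_quick(self, true_lag):
        # 12 seeds here; the 50-seed version runs in the acceptance suite
        picks = [
            select_lag_model(
                simulate_stock(scenario_lag_recovery(true_lag, seed=300 + i)),
                lag_candidates=(0, 1, 3),
                n_perm=99,
                seed=i,
            ).lag
            for i in range(12)
        ]
        values, counts = np.unique(picks, return_counts=True)
        assert values[np.argmax(counts)] == true_lag


class TestVeganCrossCheck:
    def test_fractions_match_vegan_varpart(self, tmp_path, rng):
        """Independent oracle: R vegan::varpart on the same small dataset."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not on PATH; vegan oracle unavailable")
        n, m = 18, 5
        f = np.linspace(0, 1, n) + 0.1 * rng.normal(size=n)
        t = rng.normal(size=n)
        Y = (
            np.outer(f, rng.normal(size=m))
            + 0.5 * np.outer(t, rng.normal(size=m))
            + 0.3 * rng.normal(size=(n, m))
        )
        np.savetxt(tmp_path / "Y.csv", Y, delimiter=",")
        np.savetxt(tmp_path / "x.csv", np.column_stack([f, t]), delimiter=",")
        rcode = textwrap.dedent(
            f"""
            suppressMessages(library(vegan))
            Y <- as.matrix(read.csv("{tmp_path}/Y.csv", header=FALSE))
            X <- read.csv("{tmp_path}/x.csv", header=FALSE)
            vp <- varpart(Y, ~V1, ~V2, data=X)
            ind <- vp$part$indfract
            cat(sprintf("%.12f,%.12f,%.12f,%.12f\\n",
                ind$Adj.R.squared[1], ind$Adj.R.squared[2],
                ind$Adj.R.squared[3], vp$part$fract$Adj.R.squared[3]))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        got = [float(v) for v in out.stdout.strip().splitlines()[-1].split(",")]
        pr = partition2(Y, f, t, do_tests=False)
        ours = sorted([pr.frac_fishing, pr.frac_shared, pr.frac_temperature])
        assert sorted(got[:3]) == pytest.approx(ours, abs=1e-8)
        assert got[3] == pytest.approx(pr.total_adj_r2, abs=1e-8)
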