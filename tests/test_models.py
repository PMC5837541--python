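"""Swap-model fitting: symmetry, closed-form agreement, recovery, errors."""
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from actibigram import (
    CollinearityError,
    DegenerateFeatureError,
    SwapModelSpec,
    fit_bigram_swap,
    fit_cpm_models,
    fit_state_transfer,
    run_full_grid,
)


def spec(kind="ubigram_swap", baseline="[SS]", comparison="[MV]", **kw):
    return SwapModelSpec(kind=kind, baseline=baseline, comparison=comparison, **kw)


class TestSpecValidation:
    def test_baseline_equals_comparison_rejected(self):
        with pytest.raises(ValueError):
            spec(baseline="[MV]", comparison="[MV]")

    def test_transfer_with_duration_adjustment_rejected(self):
        with pytest.raises(ValueError):
            spec(kind="state_transfer", baseline="S", comparison="M",
                 adjustment="model3")

    @pytest.mark.parametrize("kind,key", [
        ("state_transfer", "X"), ("bigram_swap", "SX"), ("ubigram_swap", "[XY]"),
    ])
    def test_alphabet_checked(self, kind, key):
        with pytest.raises(ValueError):
            spec(kind=kind, baseline=key, comparison="SS" if kind != "state_transfer" else "S")

    def test_ubigram_key_canonicalized(self):
        s = spec(baseline="VM", comparison="LS")
        assert s.baseline == "[MV]" and s.comparison == "[SL]"


class TestReciprocalSymmetry:
    def test_transfer_negates_exactly(self, cohort_table):
        """Exchanging baseline and comparison states negates the estimate and
        preserves the CI width, because the swap is a reparametrization."""
        for adj in ("model1", "model2"):
            a = fit_state_transfer(cohort_table, spec(
                kind="state_transfer", baseline="S", comparison="M",
                adjustment=adj, covariates=("z", "female")))
            b = fit_state_transfer(cohort_table, spec(
                kind="state_transfer", baseline="M", comparison="S",
                adjustment=adj, covariates=("z", "female")))
            assert b.raw_beta == pytest.approx(-a.raw_beta, rel=1e-10)
            assert b.raw_se == pytest.approx(a.raw_se, rel=1e-10)
            width_a = a.ci_high - a.ci_low
            width_b = b.ci_high - b.ci_low
            assert width_b == pytest.approx(width_a, rel=1e-10)

    def test_ubigram_swap_negates_exactly(self, cohort_table):
        for adj in ("model1", "model3", "model4"):
            a = fit_bigram_swap(cohort_table, spec(
                baseline="[SS]", comparison="[MV]", adjustment=adj,
                covariates=("z", "female")))
            b = fit_bigram_swap(cohort_table, spec(
                baseline="[MV]", comparison="[SS]", adjustment=adj,
                covariates=("z", "female")))
            assert b.raw_beta == pytest.approx(-a.raw_beta, rel=1e-10)
            assert (b.ci_high - b.ci_low) == pytest.approx(
                a.ci_high - a.ci_low, rel=1e-10)


class TestAgainstClosedForm:
    def test_unadjusted_fit_matches_normal_equations(self, cohort_table):
        """With no covariates the fit must equal the two-predictor OLS
        solution computed independently from the normal equations."""
        r = fit_bigram_swap(cohort_table, spec())
        x1 = cohort_table["[MV]"].to_numpy(float)
        x2 = 1439.0 - x1 - cohort_table["[SS]"].to_numpy(float)
        y = cohort_table["BMI"].to_numpy(float)
        X = np.column_stack([np.ones_like(x1), x1, x2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        df = len(y) - 3
        sigma2 = resid @ resid / df
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(cov[1, 1])
        tq = scipy.stats.t.ppf(0.975, df)
        assert r.raw_beta == pytest.approx(beta[1], rel=1e-9)
        assert r.raw_se == pytest.approx(se, rel=1e-9)
        assert r.ci_low == pytest.approx(10 * (beta[1] - tq * se), rel=1e-9)
        assert r.ci_high == pytest.approx(10 * (beta[1] + tq * se), rel=1e-9)
        assert r.beta_scaled == pytest.approx(10 * beta[1], rel=1e-12)


class TestRecovery:
    def test_transfer_model_recovers_known_coefficients(self):
        """outcome = c1*Md + c2*r + noise is recovered within sampling error."""
        rng = np.random.default_rng(3)
        n = 600
        Md = rng.normal(100, 25, n)
        Sd = rng.normal(650, 60, n)
        r_col = 1440.0 - (Md + Sd)
        c1, c2 = -0.03, 0.01
        table = pd.DataFrame({
            "Md": Md, "Sd": Sd,
            "BMI": 19 + c1 * Md + c2 * r_col + rng.normal(0, 1.5, n),
        })
        res = fit_state_transfer(
            table, spec(kind="state_transfer", baseline="S", comparison="M"))
        assert abs(res.raw_beta - c1) < 4 * res.raw_se
        assert res.ci_low / 10 <= c1 <= res.ci_high / 10

    def test_constant_outcome_gives_null_effect(self, cohort_table):
        table = cohort_table.copy()
        table["BMI"] = 21.0
        res = fit_bigram_swap(table, spec())
        assert res.beta_scaled == pytest.approx(0, abs=1e-8)
        assert res.ci_low <= 0 <= res.ci_high


class TestScaling:
    def test_per_sd_uses_baseline_sd(self, cohort_table):
        res = fit_bigram_swap(cohort_table, spec(scale="per_sd"))
        sd = cohort_table["[SS]"].std(ddof=1)
        assert res.sd_of_baseline == pytest.approx(sd)
        assert res.beta_scaled == pytest.approx(res.raw_beta * sd)

    def test_mcpm_reported_per_100_counts(self):
        rng = np.random.default_rng(5)
        n = 500
        mcpm = rng.normal(800, 120, n)
        sdcpm = rng.normal(400, 60, n)
        a = -0.004
        table = pd.DataFrame({
            "mCPM": mcpm, "sdCPM": sdcpm,
            "BMI": 21 + a * mcpm + rng.normal(0, 0.05, n),
        })
        res_m, res_sd = fit_cpm_models(table)
        assert res_m.beta_scaled == pytest.approx(100 * a, rel=0.02)
        assert res_sd.beta_scaled == pytest.approx(
            res_sd.raw_beta * sdcpm.std(ddof=1))

    def test_mutual_adjustment_with_identical_columns_fails(self):
        rng = np.random.default_rng(6)
        x = rng.normal(800, 100, 50)
        table = pd.DataFrame({"mCPM": x, "sdCPM": x,
                              "BMI": rng.normal(19, 3, 50)})
        with pytest.raises(CollinearityError):
            fit_cpm_models(table, mutual=True)


class TestDegeneracy:
    def test_zero_variance_comparison_flagged(self, cohort_table):
        table = cohort_table.copy()
        table["[MV]"] = 1.0
        with pytest.raises(DegenerateFeatureError):
            fit_bigram_swap(table, spec())

    def test_collinear_covariate_named(self, cohort_table):
        table = cohort_table.copy()
        table["dup"] = 2.0 * table["[MV]"]
        with pytest.raises(CollinearityError) as err:
            fit_bigram_swap(table, spec(adjustment="model2",
                                        covariates=("dup",)))
        assert "dup" in str(err.value) or "comparison" in str(err.value)


class TestGrid:
    def test_contrast_counts_per_family(self, cohort_table):
        grid = run_full_grid(cohort_table, adjustments=("model1",))
        transfer = grid[grid.kind == "state_transfer"]
        ubi = grid[grid.kind == "ubigram_swap"]
        assert len(transfer) == 6       # C(4,2) state pairs
        assert len(ubi) == 45           # C(10,2) u-bigram pairs
        assert (grid["error"] == "").all()
        # one orientation per unordered pair
        pairs = set(map(tuple, ubi[["baseline", "comparison"]].to_numpy()))
        assert all((b, a) not in pairs for a, b in pairs)

    def test_grid_is_deterministic(self, cohort_table):
        g1 = run_full_grid(cohort_table, kinds=("state_transfer",),
                           adjustments=("model1",))
        g2 = run_full_grid(cohort_table, kinds=("state_transfer",),
                           adjustments=("model1",))
        pd.testing.assert_frame_equal(g1, g2)

    def test_per_fit_failures_become_flagged_rows(self, cohort_table):
        table = cohort_table.copy()
        table["[SV]"] = 0.0  # degenerate comparison for any [SV] contrast
        grid = run_full_grid(table, kinds=("ubigram_swap",),
                             adjustments=("model1",))
        flagged = grid[grid["error"] != ""]
        assert len(flagged) > 0 and len(grid) == 45
        assert flagged["beta"].isna().all()
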