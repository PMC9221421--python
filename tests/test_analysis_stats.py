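"""Descriptives, Pearson screen, OLS, and backward elimination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from audbattery import analysis_stats as an
from audbattery import virtual_listener as vl


# ---------------------------------------------------------------------------
# independent oracles


def pearson_bruteforce(x, y):
    """Covariance/SD formula plus the explicit t-transform p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def ols_normal_equations(y, X):
    """Coefficients from (X'X)^-1 X'y with an explicit intercept column."""
    design = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    return np.linalg.solve(design.T @ design, design.T @ np.asarray(y, float))


# ---------------------------------------------------------------------------


class TestDescribe:
    def test_constant_column_has_zero_sd(self):
        frame = pd.DataFrame({"CO": [3.0, 3.0, 3.0], "SEP": [1.0, 2.0, 3.0]})
        out = an.describe(frame)
        assert out.loc["CO", "Std. Deviation"] == 0.0

    def test_two_row_hand_arithmetic(self):
        frame = pd.DataFrame({"CO": [0.0, 10.0]})
        out = an.describe(frame)
        assert out.loc["CO", "Mean"] == 5.0
        assert out.loc["CO", "Std. Deviation"] == pytest.approx(np.sqrt(50.0))

    def test_simulated_cohort_schema_has_11_variables(self, study_results):
        out = an.describe(study_results)
        assert list(out.index) == list(vl.RESULT_COLUMNS)
        assert list(out.columns) == ["Minimum", "Maximum", "Mean", "Std. Deviation"]

    def test_single_row_is_usage_error(self):
        with pytest.raises(an.UsageError):
            an.describe(pd.DataFrame({"CO": [1.0]}))


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert an.pearson(x, x)[0] == pytest.approx(1.0)
        assert an.pearson(x, -x)[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_to_1e12(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=35)
        y = 0.4 * x + rng.normal(size=35)
        r, p = an.pearson(x, y)
        r2, p2 = pearson_bruteforce(x, y)
        assert r == pytest.approx(r2, abs=1e-12)
        assert p == pytest.approx(p2, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(an.UndefinedCorrelationError):
            an.pearson(np.ones(10), np.arange(10.0))

    @pytest.mark.parametrize(
        "r,expected_p",
        [(0.381, 0.014), (0.467, 0.002), (0.500, 0.001)],
    )
    def test_printed_r_values_reproduce_printed_p_at_n41(self, r, expected_p):
        # invert: p from the t transform at n=41 must round to the published p
        t = r * np.sqrt((41 - 2) / (1 - r**2))
        p = 2 * stats.t.sf(t, df=39)
        assert round(p, 3) == expected_p


class TestCorrelationScreen:
    def test_duplicated_column_always_flagged(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"CO": rng.normal(size=30)})
        frame["SEP"] = frame["CO"]
        out = an.correlation_screen(frame)
        assert ((out["Variable 1"] == "CO") & (out["Variable 2"] == "SEP")).any()
        assert out["Pearson Correlation"].iloc[0] == pytest.approx(1.0)

    def test_type_i_rate_near_alpha_for_independent_noise(self):
        rng = np.random.default_rng(7)
        n_pairs = 0
        n_hits = 0
        for _ in range(40):
            frame = pd.DataFrame(rng.normal(size=(200, 6)),
                                 columns=["CO", "SEP", "SRM", "Age", "PTA", "TGap"])
            out = an.correlation_screen(frame, alpha=0.05)
            n_hits += len(out)
            n_pairs += 15
        rate = n_hits / n_pairs
        assert 0.02 < rate < 0.09  # ~5% of pairs pass by chance

    def test_planted_structure_detected(self, study_results):
        out = an.correlation_screen(study_results)
        pairs = set(map(tuple, out[["Variable 1", "Variable 2"]].to_numpy()))
        assert ("SEP", "SRM") in pairs
        row = out[(out["Variable 1"] == "SEP") & (out["Variable 2"] == "SRM")]
        assert row["Pearson Correlation"].iloc[0] < -0.7

    def test_bonferroni_flag_tightens_criterion(self, study_results):
        plain = an.correlation_screen(study_results, alpha=0.05)
        strict = an.correlation_screen(study_results, alpha=0.05, bonferroni=True)
        assert len(strict) <= len(plain)


class TestFitOLS:
    def test_exact_linear_relationship(self):
        x = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        y = 2.0 * x["x"] + 1.0
        model = an.fit_ols(y, x)
        assert model.coefficients["const"] == pytest.approx(1.0)
        assert model.coefficients["x"] == pytest.approx(2.0)
        assert model.r2 == pytest.approx(1.0)
        assert model.adjusted_r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = X @ [1.0, -2.0, 0.5, 0.0] + rng.normal(size=60)
        model = an.fit_ols(y, X)
        expected = ols_normal_equations(y, X)
        assert np.allclose(model.coefficients.to_numpy(), expected, atol=1e-8)

    def test_null_coefficient_p_is_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(400):
            x = pd.DataFrame({"x": rng.normal(size=25)})
            y = rng.normal(size=25)
            ps.append(an.fit_ols(y, x).p_values["x"])
        # Kolmogorov-Smirnov against Uniform(0, 1)
        d, p = stats.kstest(ps, "uniform")
        assert p > 0.01

    def test_adjusted_r2_closed_form(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = X["a"] + rng.normal(size=40)
        m = an.fit_ols(y, X)
        n, k = 40, 3
        assert m.adjusted_r2 == pytest.approx(1 - (1 - m.r2) * (n - 1) / (n - k - 1))

    def test_noise_predictor_does_not_inflate_adjusted_r2_on_average(self):
        rng = np.random.default_rng(21)
        deltas = []
        for _ in range(200):
            X = pd.DataFrame({"x": rng.normal(size=30)})
            y = X["x"] + rng.normal(size=30)
            base = an.fit_ols(y, X).adjusted_r2
            X2 = X.assign(noise=rng.normal(size=30))
            deltas.append(an.fit_ols(y, X2).adjusted_r2 - base)
        assert np.mean(deltas) < 0.005

    def test_rank_deficient_design_raises(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0]})
        X["b"] = 2 * X["a"]
        with pytest.raises(np.linalg.LinAlgError):
            an.fit_ols(np.arange(5.0), X)

    def test_too_few_rows_is_usage_error(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(an.UsageError):
            an.fit_ols([0.0, 1.0], X)


class TestBackwardElimination:
    def test_single_noise_predictor_yields_no_model(self):
        rng = np.random.default_rng(40)
        # a predictor with a clearly null p is removed, leaving no model
        for attempt in range(5):
            X = pd.DataFrame({"x": rng.normal(size=50)})
            y = rng.normal(size=50)
            model = an.backward_eliminate(y, X)
            if model.no_model:
                break
        assert model.no_model
        assert model.elimination_trace and model.elimination_trace[0][0] == "x"

    def test_strong_predictors_retained(self):
        rng = np.random.default_rng(41)
        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        y = 2 * X["a"] - 1.5 * X["b"] + rng.normal(size=80)
        model = an.backward_eliminate(y, X)
        assert set(model.predictors) == {"a", "b"}
        assert all(p <= 0.10 for p in model.p_values.drop("const"))

    def test_looser_criterion_retains_superset(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            X = pd.DataFrame(rng.normal(size=(41, 6)), columns=list("abcdef"))
            y = X["a"] + 0.4 * X["b"] + rng.normal(size=41)
            strict = an.backward_eliminate(y, X, p_remove=0.10)
            loose = an.backward_eliminate(y, X, p_remove=0.20)
            assert set(strict.predictors) <= set(loose.predictors)

    def test_order_invariance_on_generic_input(self):
        rng = np.random.default_rng(43)
        X = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        y = X["a"] - X["c"] + rng.normal(size=50)
        forward = an.backward_eliminate(y, X)
        shuffled = an.backward_eliminate(y, X[["e", "c", "a", "d", "b"]])
        assert set(forward.predictors) == set(shuffled.predictors)
        assert forward.adjusted_r2 == pytest.approx(shuffled.adjusted_r2)


class TestAnalysisReport:
    def test_report_contains_three_model_sections(self, study_results):
        report = an.analysis_report(study_results)
        assert set(report.models) == {"CO", "SEP", "SRM"}
        table = report.model_table()
        assert list(table["Condition"]) == ["CO", "SEP", "SRM"]

    def test_report_rendering_deterministic(self, study_results, tmp_path):
        r1 = an.analysis_report(study_results)
        r2 = an.analysis_report(study_results)
        assert r1.render_text() == r2.render_text()
        p1 = r1.to_csv(tmp_path / "a")
        p2 = r2.to_csv(tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_missing_columns_rejected(self):
        with pytest.raises(an.UsageError):
            an.analysis_report(pd.DataFrame({"CO": [1.0, 2.0, 3.0]}))


@pytest.fixture(scope="module")
def study_results():
    cohort = vl.generate_cohort(vl.CohortConfig(n=41), seed=2022)
    return vl.run_study(cohort, seed=2022)
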