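"""GLM battery and ICC against independent linear-algebra and ANOVA oracles."""

import numpy as np
import pandas as pd
import pytest

from flowpulse import (
    DomainError,
    ModelSpec,
    SingularDesignError,
    ValidationError,
    fit_glm,
    icc_2_1,
    run_model_battery,
    simulate_rater_pair,
)


@pytest.fixture(scope="module")
def fixed_table():
    """A small deterministic cohort-like table with no missing values."""
    rng = np.random.default_rng(99)
    n = 12
    table = pd.DataFrame(
        {
            "age": rng.uniform(55, 85, n),
            "female": rng.integers(0, 2, n),
            "map": rng.uniform(85, 115, n),
            "hypertension": rng.integers(0, 2, n),
            "tcbf": rng.uniform(8, 14, n),
            "ica_pi": rng.uniform(0.8, 2.0, n),
            "ica_fvp": rng.uniform(0.2, 0.8, n),
            "m1_pi": rng.uniform(0.8, 2.0, n),
            "m1_fvp": rng.uniform(0.1, 0.5, n),
        }
    )
    table["tbv_pct_icv"] = (
        80 - 0.2 * table.age + 3 * table.female + rng.normal(0, 2, n)
    )
    table["wmh_pct_icv"] = np.exp(rng.normal(-1.0, 0.8, n))
    table["aggregate_z"] = rng.normal(0, 3, n)
    table["svd"] = rng.integers(0, 2, n)
    return table


class TestModelSpec:
    def test_m3_terms_excluded(self):
        with pytest.raises(ValidationError):
            ModelSpec("wmh_pct_icv", "M3_PI")

    def test_cognition_excluded_from_subgroup(self):
        with pytest.raises(ValidationError):
            ModelSpec("cognition", "M1_PI", subgroup="svd_only")

    def test_family_follows_outcome(self):
        assert ModelSpec("wmh_pct_icv", "ICA_FVP").family_link == "gamma_log"
        assert ModelSpec("tbv_pct_icv", "ICA_FVP").family_link == "gaussian_identity"
        assert ModelSpec("cognition", "M1_PI").family_link == "gaussian_identity"


class TestFitGLM:
    def test_intercept_only_gamma_log_closed_form(self, fixed_table):
        spec = ModelSpec("wmh_pct_icv", None, base_covariates=())
        fit = fit_glm(spec, fixed_table)
        assert fit.coef("intercept") == pytest.approx(
            np.log(fixed_table.wmh_pct_icv.mean()), abs=1e-8
        )

    def test_gaussian_identity_matches_normal_equations(self, fixed_table):
        spec = ModelSpec("tbv_pct_icv", "ICA_PI")
        fit = fit_glm(spec, fixed_table)
        cols = list(spec.design_columns())
        X = np.column_stack([np.ones(len(fixed_table))] + [fixed_table[c] for c in cols])
        y = fixed_table.tbv_pct_icv.to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coefficients, beta, atol=1e-8)
        # Wald CI geometry
        assert np.all(fit.ci_lower <= fit.coefficients)
        assert np.all(fit.coefficients <= fit.ci_upper)

    def test_gamma_log_rescaling_shifts_only_intercept(self, fixed_table):
        spec = ModelSpec("wmh_pct_icv", "ICA_FVP")
        base = fit_glm(spec, fixed_table)
        scaled_table = fixed_table.assign(wmh_pct_icv=fixed_table.wmh_pct_icv * 7.5)
        scaled = fit_glm(spec, scaled_table)
        assert scaled.coef("intercept") == pytest.approx(
            base.coef("intercept") + np.log(7.5), abs=1e-8
        )
        assert np.allclose(scaled.coefficients[1:], base.coefficients[1:], atol=1e-8)

    def test_nonpositive_gamma_outcome_rejected(self, fixed_table):
        bad = fixed_table.copy()
        bad.loc[0, "wmh_pct_icv"] = 0.0
        with pytest.raises(ValidationError):
            fit_glm(ModelSpec("wmh_pct_icv", "ICA_FVP"), bad)

    def test_collinear_design_names_columns(self, fixed_table):
        bad = fixed_table.assign(ica_pi=2.0 * fixed_table.tcbf)
        with pytest.raises(SingularDesignError) as err:
            fit_glm(ModelSpec("tbv_pct_icv", "ICA_PI"), bad)
        assert any(c in err.value.collinear_columns for c in ("ica_pi", "tcbf"))

    def test_complete_case_count_is_exact(self, small_cohort):
        frame, _ = small_cohort
        spec = ModelSpec("wmh_pct_icv", "ICA_FVP")
        fit = fit_glm(spec, frame)
        cols = ["wmh_pct_icv"] + spec.design_columns()
        assert fit.n_used == len(frame[cols].dropna())

    def test_too_few_complete_cases_rejected(self, fixed_table):
        with pytest.raises(ValidationError):
            fit_glm(ModelSpec("tbv_pct_icv", "ICA_PI"), fixed_table.head(8))


class TestModelBattery:
    def test_basic_battery_has_twelve_models(self, small_cohort):
        frame, _ = small_cohort
        res = run_model_battery(frame, include_extended=False, include_subgroup=False)
        assert len(res) == 12
        assert set(res.outcome) == {"wmh_pct_icv", "tbv_pct_icv", "cognition"}
        assert res.groupby("pulsatility_term").size().eq(3).all()

    def test_subgroup_excludes_cognition(self, small_cohort):
        frame, _ = small_cohort
        res = run_model_battery(frame)
        sub = res[res.variant == "svd_subgroup"]
        assert len(sub) == 8
        assert "cognition" not in set(sub.outcome)

    def test_no_svd_subjects_skips_subgroup_quietly(self, small_cohort):
        frame, _ = small_cohort
        no_svd = frame.assign(svd=0)
        res = run_model_battery(no_svd, include_extended=False)
        assert (res.variant == "basic").all()
        assert len(res) == 12

    def test_gamma_family_used_for_wmh(self, small_cohort):
        frame, _ = small_cohort
        res = run_model_battery(frame, include_extended=False, include_subgroup=False)
        fam = res.set_index("outcome").family_link
        assert (fam.loc["wmh_pct_icv"] == "gamma_log").all()
        assert (fam.loc["tbv_pct_icv"] == "gaussian_identity").all()


def icc_anova_oracle(a, b):
    """Brute-force two-way ANOVA mean squares via explicit sums of squares."""
    x = np.column_stack([a, b]).astype(float)
    n, k = x.shape
    grand = x.mean()
    msr = k / (n - 1) * sum((x[i].mean() - grand) ** 2 for i in range(n))
    msc = n / (k - 1) * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestICC:
    def test_perfect_agreement(self):
        a = np.array([0, 1, 2, 3, 4, 5, 6], dtype=float)
        assert icc_2_1(a, a) == pytest.approx(1.0)

    def test_matches_anova_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            a = rng.integers(0, 7, 30)
            b = np.clip(a + rng.integers(-2, 3, 30), 0, 6)
            assert icc_2_1(a, b) == pytest.approx(icc_anova_oracle(a, b), abs=1e-12)

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(31)
        a = rng.normal(3, 1.5, 40)
        b = a + rng.normal(0.2, 0.7, 40)
        long = pd.DataFrame(
            {
                "subject": np.tile(np.arange(40), 2),
                "rater": np.repeat(["A", "B"], 40),
                "score": np.concatenate([a, b]),
            }
        )
        ref = pingouin.intraclass_corr(long, "subject", "rater", "score")
        # absolute-agreement single-measure ICC (McGraw-Wong A,1 == Shrout-Fleiss 2,1)
        icc2 = ref.set_index("Type").loc["ICC(A,1)", "ICC"]
        assert icc_2_1(a, b) == pytest.approx(icc2, abs=1e-9)

    def test_simulated_raters_match_variance_components(self):
        rng = np.random.default_rng(41)
        sigma_s, sigma_e = 1.5, 0.5
        latent = rng.normal(3.0, sigma_s, 500)
        a, b = simulate_rater_pair(latent, rater_sd=sigma_e, seed=13)
        # rounding to integer grades adds ~1/12 of noise variance
        expected = sigma_s**2 / (sigma_s**2 + sigma_e**2 + 1 / 12)
        assert icc_2_1(a, b) == pytest.approx(expected, abs=0.05)

    def test_zero_variance_undefined(self):
        with pytest.raises(DomainError):
            icc_2_1([3, 3, 3, 3], [3, 3, 3, 3])
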