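"""Regression-model contracts: design construction, IRLS fits against
closed forms and an independent reference implementation, and Wald
effect reports."""

import math

import numpy as np
import pandas as pd
import pytest

from myoquant import (
    DesignError, GLMFit, ModelSpec, SeparationError, ValidationError,
    build_design, effect_report, fit_binomial_glm, fit_linear_model,
    fit_quasipoisson_glm,
)


def logit(p):
    return math.log(p / (1 - p))


# ---------------------------------------------------------------------------
# design construction

def test_design_two_factor_interaction_layout():
    data = pd.DataFrame(
        {"A": [0, 1, 0, 1], "B": [0, 0, 1, 1], "s": [1, 2, 3, 4], "n": [10] * 4}
    )
    spec = ModelSpec("binomial-grouped", ("s", "n"), factors=["A", "B"],
                     interactions=[("A", "B")])
    d = build_design(spec, data)
    assert list(d.X.columns) == ["(Intercept)", "A[1]", "B[1]", "A[1]:B[1]"]
    assert np.linalg.matrix_rank(d.X.to_numpy()) == 4


def test_design_dose_only():
    data = pd.DataFrame({"dose": [0.0, 1.0, 2.0], "y": [1.0, 2.0, 3.0]})
    spec = ModelSpec("continuous", "y", dose_term="dose")
    d = build_design(spec, data)
    assert list(d.X.columns) == ["(Intercept)", "dose"]


def test_design_aliased_column_reported():
    data = pd.DataFrame({"A": [0, 1, 0, 1], "A2": [0, 1, 0, 1],
                         "y": [1.0, 2.0, 3.0, 4.0]})
    spec = ModelSpec("continuous", "y", factors=["A", "A2"])
    with pytest.raises(DesignError) as err:
        build_design(spec, data)
    assert err.value.aliased


def test_design_validates_binomial_response():
    data = pd.DataFrame({"A": [0, 1], "s": [5, 3], "n": [10, 0]})
    spec = ModelSpec("binomial-grouped", ("s", "n"), factors=["A"])
    with pytest.raises(ValidationError, match="trials"):
        build_design(spec, data)


# ---------------------------------------------------------------------------
# binomial GLM

def test_binomial_saturated_closed_form():
    data = pd.DataFrame(
        {"A": [0, 1, 0, 1], "B": [0, 0, 1, 1],
         "s": [50, 25, 50, 75], "n": [100] * 4}
    )
    spec = ModelSpec("binomial-grouped", ("s", "n"), factors=["A", "B"],
                     interactions=[("A", "B")])
    d = build_design(spec, data)
    fit = fit_binomial_glm(d.X, d.y, d.trials)
    expected = {
        "(Intercept)": 0.0,
        "A[1]": logit(0.25) - logit(0.5),
        "B[1]": 0.0,
        "A[1]:B[1]": logit(0.75) - logit(0.25),
    }
    for name, val in expected.items():
        assert fit.params[name] == pytest.approx(val, abs=1e-8)


def test_binomial_symmetric_cells_give_zero_effects():
    X = np.column_stack([np.ones(4), np.eye(4)[:, 1:]])
    fit = fit_binomial_glm(X, np.full(4, 50.0), np.full(4, 100.0))
    assert np.allclose(fit.params, 0.0, atol=1e-10)


def test_binomial_separation_detected():
    X = np.column_stack([np.ones(2), [0.0, 1.0]])
    with pytest.raises(SeparationError):
        fit_binomial_glm(X, np.array([50.0, 100.0]), np.array([100.0, 100.0]))


def test_binomial_grouped_equals_bernoulli():
    rng = np.random.default_rng(3)
    data = pd.DataFrame({"A": [0, 0, 1, 1], "s": [3, 5, 7, 2], "n": [10] * 4})
    spec = ModelSpec("binomial-grouped", ("s", "n"), factors=["A"])
    d = build_design(spec, data)
    grouped = fit_binomial_glm(d.X, d.y, d.trials)
    rows = []
    for _, r in data.iterrows():
        rows += [{"A": r.A, "y": 1}] * int(r.s) + [{"A": r.A, "y": 0}] * int(r.n - r.s)
    bern = pd.DataFrame(rows)
    spec_b = ModelSpec("binomial-bernoulli", "y", factors=["A"])
    db = build_design(spec_b, bern)
    single = fit_binomial_glm(db.X, db.y)
    assert np.allclose(grouped.params, single.params, atol=1e-10)


# ---------------------------------------------------------------------------
# quasi-Poisson

def test_quasipoisson_two_condition_log_means():
    df = pd.DataFrame({"g": [0] * 6 + [1] * 6,
                       "count": [9, 10, 11, 10, 9, 11, 19, 20, 21, 20, 19, 21]})
    spec = ModelSpec("count", "count", factors=["g"])
    d = build_design(spec, df)
    fit = fit_quasipoisson_glm(d.X, d.y)
    m0 = df.loc[df.g == 0, "count"].mean()
    m1 = df.loc[df.g == 1, "count"].mean()
    assert fit.params["(Intercept)"] == pytest.approx(math.log(m0), abs=1e-8)
    assert fit.params["g[1]"] == pytest.approx(math.log(m1 / m0), abs=1e-8)


def test_quasipoisson_intercept_is_log_sample_mean():
    fit = fit_quasipoisson_glm(np.ones((2, 1)), np.array([4.0, 6.0]))
    assert fit.params.iloc[0] == pytest.approx(math.log(5.0), abs=1e-12)


def test_quasipoisson_dispersion_near_one_for_poisson_data():
    rng = np.random.default_rng(1)
    y = rng.poisson(10.0, 10_000).astype(float)
    fit = fit_quasipoisson_glm(np.ones((y.size, 1)), y)
    assert 0.9 <= fit.dispersion <= 1.1


def test_quasipoisson_rejects_degenerate_input():
    with pytest.raises(ValidationError):
        fit_quasipoisson_glm(np.ones((3, 1)), np.zeros(3))
    with pytest.raises(ValidationError):
        fit_quasipoisson_glm(np.ones((3, 1)), np.array([1.0, -2.0, 3.0]))


# ---------------------------------------------------------------------------
# linear model

def test_linear_exact_fit():
    x = np.arange(10.0)
    X = np.column_stack([np.ones(10), x])
    fit = fit_linear_model(X, 2 * x + 1)
    assert fit.params.iloc[0] == pytest.approx(1.0, abs=1e-10)
    assert fit.params.iloc[1] == pytest.approx(2.0, abs=1e-10)
    assert fit.dispersion == pytest.approx(0.0, abs=1e-18)


def test_linear_mean_only_model():
    y = np.array([3.0, 5.0, 7.0, 9.0])
    fit = fit_linear_model(np.ones((4, 1)), y)
    assert fit.params.iloc[0] == pytest.approx(y.mean())


def test_linear_interaction_recovery_within_two_se():
    """Cell line × dose interaction on simulated eccentricity data.

    A single replicate misses its 2-SE band ~5% of the time by
    construction, so the property is asserted over five replicates.
    """
    truth = 0.05
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 400
        line = rng.integers(0, 2, n).astype(float)
        dose = rng.choice([0.0, 1.0, 2.0, 4.0], n)
        y = 0.55 + 0.02 * line + 0.01 * dose + truth * line * dose \
            + rng.normal(0, 0.08, n)
        X = np.column_stack([np.ones(n), line, dose, line * dose])
        fit = fit_linear_model(X, y)
        est, se = fit.params.iloc[3], fit.se.iloc[3]
        hits += abs(est - truth) < 2 * se
    assert hits >= 4


# ---------------------------------------------------------------------------
# invariants and cross-checks

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_saturated_oracle_equivalence(seed):
    """Saturated factorial fits equal direct cell contrasts."""
    rng = np.random.default_rng(seed)
    data = pd.DataFrame({"A": [0, 1, 0, 1], "B": [0, 0, 1, 1]})
    data["n"] = 200
    data["s"] = rng.integers(20, 180, 4)
    spec = ModelSpec("binomial-grouped", ("s", "n"), factors=["A", "B"],
                     interactions=[("A", "B")])
    d = build_design(spec, data)
    fit = fit_binomial_glm(d.X, d.y, d.trials)
    p = (data["s"] / data["n"]).to_numpy()
    cell_logits = np.log(p / (1 - p))
    contrast = np.array(
        [cell_logits[0], cell_logits[1] - cell_logits[0],
         cell_logits[2] - cell_logits[0],
         cell_logits[3] - cell_logits[2] - cell_logits[1] + cell_logits[0]]
    )
    assert np.allclose(fit.params, contrast, atol=1e-8)


def test_crosscheck_against_statsmodels():
    from myoquant.validation import glm_crosscheck

    assert glm_crosscheck(seed=0, n_problems=10)["max_abs_diff"] < 1e-6


# ---------------------------------------------------------------------------
# effect reports

def test_effect_report_wald_interval_closed_form():
    idx = pd.Index(["(Intercept)", "trt[1]"])
    fit = GLMFit(
        params=pd.Series([0.3, 0.0], index=idx),
        vcov=pd.DataFrame(np.diag([0.04, 0.25]), index=idx, columns=idx),
        dispersion=1.0, loglik=None, df_resid=10, n_obs=12,
        kind="binomial", link="logit",
    )
    rep = effect_report(fit)
    row = rep.terms.loc["trt[1]"]
    assert row["odds_ratio"] == pytest.approx(1.0)
    assert row["ci_low"] == pytest.approx(math.exp(-0.98), rel=1e-9)
    assert row["ci_high"] == pytest.approx(math.exp(0.98), rel=1e-9)


def test_effect_report_intercept_omission_narrower_when_cov_nonneg():
    idx = pd.Index(["(Intercept)", "trt[1]"])
    vcov = pd.DataFrame([[0.3, 0.1], [0.1, 0.2]], index=idx, columns=idx)
    fit = GLMFit(
        params=pd.Series([-0.5, 1.0], index=idx), vcov=vcov, dispersion=1.0,
        loglik=None, df_resid=10, n_obs=12, kind="binomial", link="logit",
    )
    conditions = pd.DataFrame(
        [[1.0, 0.0], [1.0, 1.0]], columns=idx, index=["baseline", "trt"]
    )
    full = effect_report(fit, conditions, omit_intercept_error=False)
    flagged = effect_report(fit, conditions, omit_intercept_error=True)
    width = lambda t, c: t.loc[c, "ci_high"] - t.loc[c, "ci_low"]
    assert width(flagged.conditions, "trt") < width(full.conditions, "trt")
    # baseline keeps the full interval: the intercept is its only term
    assert flagged.conditions.loc["baseline", "se_eta"] == \
        pytest.approx(full.conditions.loc["baseline", "se_eta"])


def test_effect_report_identity_link_refuses_ratios():
    fit = fit_linear_model(np.ones((3, 1)), np.array([1.0, 2.0, 3.0]))
    with pytest.raises(ValidationError):
        effect_report(fit)
    rep = effect_report(fit, ratios=False)
    assert "odds_ratio" not in rep.terms.columns
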