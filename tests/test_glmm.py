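"""Three-level mixed logistic model: oracles, invariances, inference."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from notelex.glmm import (
    GlmmSpec,
    NestedLogisticRegression,
    fit_glmm,
    fit_patient_count_model,
    marginal_loglik,
    or_table,
)

TOY = pd.DataFrame(
    {
        "patient_id": ["a", "a", "a", "b", "b", "c"],
        "encounter_id": ["a1", "a1", "a2", "b1", "b2", "c1"],
        "outcome": [1, 0, 1, 0, 0, 1],
        "x": [0.5, -0.2, 0.1, 0.3, -1.0, 0.7],
    }
)
TOY_SPEC = GlmmSpec(fixed_effects=("x",))


def dense_integration_loglik(rows, beta, s2p, s2e, grid=601, half_width=7.0):
    """Brute-force marginal log-likelihood by nested trapezoid
    integration over both random effects (independent oracle)."""
    total = 0.0
    for _, dfp in rows.groupby("patient_id"):
        ug = np.linspace(-half_width * np.sqrt(s2p), half_width * np.sqrt(s2p), grid)
        phi_u = np.exp(-(ug**2) / (2 * s2p)) / np.sqrt(2 * np.pi * s2p)
        enc_int = np.ones_like(ug)
        for _, dfe in dfp.groupby("encounter_id"):
            wg = np.linspace(-half_width * np.sqrt(s2e), half_width * np.sqrt(s2e), grid)
            phi_w = np.exp(-(wg**2) / (2 * s2e)) / np.sqrt(2 * np.pi * s2e)
            lik = np.ones((grid, grid))
            for _, r in dfe.iterrows():
                eta = beta[0] + beta[1] * r["x"] + ug[:, None] + wg[None, :]
                p = expit(eta)
                lik *= p if r["outcome"] == 1 else 1 - p
            enc_int *= np.trapezoid(lik * phi_w[None, :], wg, axis=1)
        total += np.log(np.trapezoid(enc_int * phi_u, ug))
    return total


def test_marginal_loglik_matches_dense_integration_oracle():
    """Quadrature evaluation of the marginal likelihood agrees with a
    dense two-level trapezoid integration on a 3-patient toy."""
    beta, s2p, s2e = [-0.3, 0.6], 0.8, 0.4
    oracle = dense_integration_loglik(TOY, beta, s2p, s2e)
    ll = marginal_loglik(TOY, TOY_SPEC, beta, s2p, s2e, method="agq", order=15)
    assert ll == pytest.approx(oracle, abs=1e-4)
    # the Laplace value is close but not exact on binary toy data
    lap = marginal_loglik(TOY, TOY_SPEC, beta, s2p, s2e, method="laplace")
    assert lap == pytest.approx(oracle, abs=0.2)


def test_marginal_loglik_invariant_to_row_order():
    beta, s2p, s2e = [0.2, -0.4], 0.5, 0.3
    base = marginal_loglik(TOY, TOY_SPEC, beta, s2p, s2e, method="agq", order=9)
    rng = np.random.default_rng(0)
    for _ in range(3):
        shuffled = TOY.sample(frac=1.0, random_state=rng.integers(1 << 31)).reset_index(drop=True)
        assert marginal_loglik(shuffled, TOY_SPEC, beta, s2p, s2e, method="agq", order=9) == pytest.approx(
            base, abs=1e-10
        )


def _simulate_independent(n, seed, beta0=-1.0, beta1=0.8):
    """Data with zero random-effect variances: one note per encounter
    per patient, outcome from a plain logistic model."""
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float)
    y = rng.binomial(1, expit(beta0 + beta1 * x)).astype(float)
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "encounter_id": [f"e{i}" for i in range(n)],
            "outcome": y,
            "x": x,
        }
    )


def test_reduces_to_plain_logistic_when_variances_are_zero():
    """With clustered data generated at zero random-effect variances the
    mixed model's fixed effects match the IRLS logistic solution to 1e-3
    (the variances themselves shrink to the boundary).

    Note the clusters: with singleton clusters the variances would sit
    on an exactly flat likelihood ridge and the comparison would be
    meaningless (see the degenerate-cluster test below)."""
    import statsmodels.api as sm

    rows = _simulate_nested(1250, seed=42, beta1=0.8, s2p=0.0, s2e=0.0, intercept=-1.0)
    assert len(rows) > 3500
    fit = fit_glmm(rows, GlmmSpec(fixed_effects=("x",), compute_se=False))
    X = sm.add_constant(rows[["x"]].to_numpy())
    oracle = sm.GLM(rows["outcome"].to_numpy(), X, family=sm.families.Binomial()).fit()
    assert np.allclose(fit.beta.to_numpy(), oracle.params, atol=1e-3)
    assert fit.sigma2_patient < 0.05 and fit.sigma2_encounter < 0.05


def test_degenerate_single_note_clusters_terminate():
    """One note per encounter per patient leaves the two variances
    jointly unidentified; the fit must still terminate with finite
    estimates (boundary values tolerated)."""
    rows = _simulate_independent(300, seed=7)
    fit = fit_glmm(rows, GlmmSpec(fixed_effects=("x",), compute_se=False, max_iter=80))
    assert np.isfinite(fit.loglik)
    assert np.isfinite(fit.sigma2_patient) and np.isfinite(fit.sigma2_encounter)
    assert isinstance(fit.converged, bool)


def test_errors_on_constant_outcome_and_collinear_design():
    rows = _simulate_independent(50, seed=1)
    rows["outcome"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        fit_glmm(rows, GlmmSpec(fixed_effects=("x",)))
    rows2 = _simulate_independent(50, seed=2)
    rows2["x2"] = rows2["x"]
    with pytest.raises(ValueError, match="collinear"):
        fit_glmm(rows2, GlmmSpec(fixed_effects=("x", "x2")))
    with pytest.raises(ValueError, match="2 patients"):
        one = rows2.iloc[:1]
        fit_glmm(one, GlmmSpec(fixed_effects=("x",)))


def _simulate_nested(n_pat, seed, beta1=0.9, s2p=0.5, s2e=0.3, intercept=-1.5):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pat):
        x = float(rng.binomial(1, 0.5))
        u = rng.normal(0, np.sqrt(s2p))
        for j in range(1 + rng.poisson(1.0)):
            w = rng.normal(0, np.sqrt(s2e))
            for k in range(1 + rng.poisson(0.8)):
                p = expit(intercept + beta1 * x + u + w)
                rows.append(
                    {
                        "patient_id": f"p{i}",
                        "encounter_id": f"p{i}e{j}",
                        "outcome": int(rng.random() < p),
                        "x": x,
                    }
                )
    return pd.DataFrame(rows)


def test_recovers_generating_effect_on_nested_data():
    rows = _simulate_nested(1500, seed=11)
    fit = fit_glmm(rows, GlmmSpec(fixed_effects=("x",), compute_se=False))
    assert fit.beta["x"] == pytest.approx(0.9, abs=0.3)
    assert 0.0 <= fit.sigma2_patient < 2.0


def test_cluster_doubling_keeps_beta_and_shrinks_se():
    """Exact replication of every patient (new ids) leaves the fixed
    effects essentially unchanged and scales Wald SEs by ~1/sqrt(2)."""
    rows = _simulate_nested(250, seed=23)
    doubled = pd.concat(
        [rows, rows.assign(
            patient_id=rows.patient_id + "_dup", encounter_id=rows.encounter_id + "_dup"
        )],
        ignore_index=True,
    )
    spec = GlmmSpec(fixed_effects=("x",))
    fit1 = fit_glmm(rows, spec)
    fit2 = fit_glmm(doubled, spec)
    assert fit2.n_patients == 2 * fit1.n_patients
    assert fit2.beta["x"] == pytest.approx(fit1.beta["x"], abs=0.05)
    ratio = fit2.se["x"] / fit1.se["x"]
    assert ratio == pytest.approx(1 / np.sqrt(2), abs=0.12)


def test_or_table_definitions():
    rows = _simulate_nested(400, seed=5)
    fit = fit_glmm(rows, GlmmSpec(fixed_effects=("x",)))
    tab = or_table(fit).set_index("term")
    x = tab.loc["x"]
    assert x["odds_ratio"] == pytest.approx(np.exp(fit.beta["x"]))
    assert x["ci_low"] == pytest.approx(np.exp(fit.beta["x"] - 1.959963984540054 * fit.se["x"]))
    assert x["ci_low"] < x["odds_ratio"] < x["ci_high"]


def test_or_is_reciprocal_under_reference_swap():
    """Swapping the indicator's reference group inverts the odds ratio
    in a two-group unadjusted fit."""
    rows = _simulate_nested(400, seed=9)
    fit_a = fit_glmm(rows, GlmmSpec(fixed_effects=("x",), compute_se=False))
    swapped = rows.assign(x=1.0 - rows["x"])
    fit_b = fit_glmm(swapped, GlmmSpec(fixed_effects=("x",), compute_se=False))
    assert np.exp(fit_a.beta["x"]) == pytest.approx(1.0 / np.exp(fit_b.beta["x"]), rel=5e-3)


def test_estimator_surface():
    est = NestedLogisticRegression(GlmmSpec(fixed_effects=("x",), compute_se=False))
    assert "spec" in est.get_params()
    est.fit(_simulate_nested(150, seed=3))
    assert hasattr(est, "beta_") and hasattr(est, "sigma2_patient_")
    assert est.result_.n_patients == 150


def test_patient_count_model_two_group_closed_form():
    rng = np.random.default_rng(0)
    g = rng.binomial(1, 0.5, 500)
    counts = pd.Series(rng.poisson(0.1 + 0.056 * g), name="n")
    cov = pd.DataFrame({"g": g.astype(float)})
    tab = fit_patient_count_model(counts, cov)
    m1 = counts[g == 1].mean()
    m0 = counts[g == 0].mean()
    assert tab.loc["g", "coef"] == pytest.approx(m1 - m0, abs=1e-10)
    assert tab.loc["g", "coef_per_100"] == pytest.approx(100 * (m1 - m0), abs=1e-8)


def test_patient_count_model_zero_counts_give_zero_slopes():
    counts = pd.Series(np.zeros(100))
    cov = pd.DataFrame({"g": np.r_[np.zeros(50), np.ones(50)]})
    tab = fit_patient_count_model(counts, cov)
    assert tab.loc["g", "coef"] == pytest.approx(0.0, abs=1e-12)


def test_patient_count_model_recovers_simulated_difference():
    """Monte-Carlo check of the per-100-patients race coefficient."""
    rng = np.random.default_rng(77)
    n = 5000
    g = rng.binomial(1, 0.6, n)
    counts = pd.Series(rng.poisson(0.08 + 0.056 * g))
    tab = fit_patient_count_model(counts, pd.DataFrame({"g": g.astype(float)}))
    assert tab.loc["g", "coef"] == pytest.approx(0.056, abs=0.02)
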