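import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from riskbeliefs.regression import average_marginal_effects, fit_quasibinomial

from irls_oracle import irls_quasibinomial_logit


def binary_frame(n0=25, n1=25, p0=0.2, p1=0.6, weight=1.0):
    return pd.DataFrame(
        {
            "y": [p0] * n0 + [p1] * n1,
            "g": ["a"] * n0 + ["b"] * n1,
            "weight": weight,
        }
    )


def random_frame(n=50, seed=0):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    p = expit(-0.3 + 0.8 * x1 - 0.5 * x2)
    y = np.clip(rng.beta(p * 5, (1 - p) * 5), 1e-6, 1 - 1e-6)
    w = rng.uniform(0.5, 2.0, n)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2, "weight": w})


class TestFit:
    def test_saturated_binary_model_is_closed_form(self):
        fit = fit_quasibinomial(binary_frame(), "y", ["g"], outcome_scale=1.0)
        mu = fit.predict()
        assert np.allclose(np.sort(np.unique(mu.round(12))), [0.2, 0.6])
        assert fit.params["Intercept"] == pytest.approx(logit(0.2), abs=1e-8)

    def test_constant_weights_match_unweighted_fit(self):
        df = random_frame()
        unw = fit_quasibinomial(df, "y", ["x1", "x2"], use_weights=False, outcome_scale=1.0)
        df["weight"] = 3.7
        wtd = fit_quasibinomial(df, "y", ["x1", "x2"], use_weights=True, outcome_scale=1.0)
        assert np.allclose(unw.params, wtd.params, atol=1e-10)

    def test_matches_independent_irls_oracle(self):
        df = random_frame()
        fit = fit_quasibinomial(df, "y", ["x1", "x2"], outcome_scale=1.0)
        X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
        oracle = irls_quasibinomial_logit(X, df["y"], df["weight"])
        assert np.allclose(fit.params.to_numpy(), oracle, atol=1e-6)

    def test_reparameterized_design_gives_identical_probabilities(self):
        df = random_frame()
        df["x1_flipped"] = -df["x1"]
        f1 = fit_quasibinomial(df, "y", ["x1", "x2"], outcome_scale=1.0)
        f2 = fit_quasibinomial(df, "y", ["x1_flipped", "x2"], outcome_scale=1.0)
        assert np.allclose(f1.predict(), f2.predict(), atol=1e-10)

    def test_dispersion_near_one_for_binomial_data(self):
        rng = np.random.default_rng(5)
        n = 4000
        x = rng.normal(size=n)
        y = rng.binomial(1, expit(0.2 + 0.7 * x)).astype(float)
        fit = fit_quasibinomial(
            pd.DataFrame({"y": y, "x": x}), "y", ["x"], use_weights=False, outcome_scale=1.0
        )
        assert fit.dispersion == pytest.approx(1.0, abs=0.1)

    def test_listwise_deletion_counts(self):
        df = random_frame(n=40)
        df.loc[:4, "x1"] = np.nan
        fit = fit_quasibinomial(df, "y", ["x1", "x2"], outcome_scale=1.0)
        assert fit.n_used == 35

    def test_outcome_outside_unit_interval_rejected(self):
        df = pd.DataFrame({"y": [0.1, 1.4, 0.2, 0.5], "x": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="outside"):
            fit_quasibinomial(df, "y", ["x"], use_weights=False, outcome_scale=1.0)

    def test_too_few_records_rejected(self):
        df = pd.DataFrame({"y": [0.1, 0.4], "x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="complete records"):
            fit_quasibinomial(df, "y", ["x"], use_weights=False, outcome_scale=1.0)


class TestMarginalEffects:
    def test_binary_covariate_ame_equals_group_probability_difference(self):
        fit = fit_quasibinomial(binary_frame(), "y", ["g"], outcome_scale=1.0)
        ame = average_marginal_effects(fit).set_index("level")
        assert ame.loc["b", "ame"] == pytest.approx(0.6 - 0.2, abs=1e-8)

    def test_recovers_generated_gender_gap(self):
        rng = np.random.default_rng(6)
        n = 5000
        male = rng.random(n) < 0.5
        p = np.where(male, 0.30, 0.35)  # -0.05 on the probability scale
        y = np.clip(rng.beta(p * 8, (1 - p) * 8), 1e-9, 1 - 1e-9)
        df = pd.DataFrame({"y": y, "gender": np.where(male, "male", "female")})
        fit = fit_quasibinomial(df, "y", ["gender"], use_weights=False, outcome_scale=1.0)
        ame = average_marginal_effects(fit).set_index("level")
        se = ame.loc["male", "se"]
        assert ame.loc["male", "ame"] == pytest.approx(-0.05, abs=3 * se)

    def test_delta_method_se_close_to_bootstrap(self):
        df = random_frame(n=300, seed=7)
        df["g"] = np.where(df["x1"] > 0, "hi", "lo")
        fit = fit_quasibinomial(df, "y", ["g", "x2"], outcome_scale=1.0)
        ame = average_marginal_effects(fit).set_index("level")
        rng = np.random.default_rng(8)
        boots = []
        for _ in range(200):
            bs = df.sample(len(df), replace=True, random_state=rng.integers(2**31))
            bfit = fit_quasibinomial(bs, "y", ["g", "x2"], outcome_scale=1.0)
            boots.append(
                average_marginal_effects(bfit).set_index("level").loc["lo", "ame"]
            )
        assert ame.loc["lo", "se"] == pytest.approx(np.std(boots, ddof=1), rel=0.2)

    def test_unknown_reference_handling_is_stable(self):
        # relabeling which level is reference leaves the contrast magnitude
        df = binary_frame()
        fit = fit_quasibinomial(df, "y", ["g"], outcome_scale=1.0)
        df2 = df.assign(g=df["g"].map({"a": "z_ref", "b": "a_other"}))
        fit2 = fit_quasibinomial(df2, "y", ["g"], outcome_scale=1.0)
        a1 = average_marginal_effects(fit)["ame"].iloc[0]
        a2 = average_marginal_effects(fit2)["ame"].iloc[0]
        assert a1 == pytest.approx(-a2, abs=1e-8)

    def test_non_converged_fit_rejected(self):
        fit = fit_quasibinomial(binary_frame(), "y", ["g"], outcome_scale=1.0)
        fit.converged = False
        with pytest.raises(ValueError, match="non-converged"):
            average_marginal_effects(fit)


def test_weighted_fit_from_survey_table(default_table):
    fit = fit_quasibinomial(default_table, "q2_own_risk", ["gender", "region_tier"])
    assert fit.converged
    assert fit.cov.to_numpy() == pytest.approx(fit.cov.to_numpy().T)
    ame = average_marginal_effects(fit)
    # the generator gives men lower own-risk beliefs
    assert ame.set_index("level").loc["male", "ame"] < 0
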