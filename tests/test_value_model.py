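"""Value-model tests: closed forms, monotonicity, fitting vs brute-force oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from rewardtask.value_model import (NonIdentifiableError, RewardSizeErrorModel,
                                    SatiationErrorModel, ValueModelParams,
                                    fit_by_group, fit_reward_size_model,
                                    fit_satiation_model, predict_error_rate,
                                    predict_error_rate_satiation,
                                    satiation_factor)

REWARDS = np.array([1.0, 2.0, 4.0, 8.0])
QUARTILE_RCUM = np.array([0.125, 0.375, 0.625, 0.875])


def _quartile_table(params: ValueModelParams, noise_sd: float = 0.0,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    R, Q = np.meshgrid(REWARDS, QUARTILE_RCUM, indexing="ij")
    y = predict_error_rate_satiation(params, R.ravel(), Q.ravel())
    if noise_sd:
        y = np.clip(y + rng.normal(0, noise_sd, y.size), 0, 1)
    return pd.DataFrame({"reward_size": R.ravel(), "quartile_rcum": Q.ravel(),
                         "error_rate": y})


def grid_min_sse(table: pd.DataFrame, c_grid, b_grid, lambda_grid) -> float:
    """Independent brute-force SSE oracle (plain loops over the grid)."""
    R = table["reward_size"].to_numpy(float)
    rcum = (table["quartile_rcum"].to_numpy(float)
            if "quartile_rcum" in table else np.zeros(len(table)))
    y = table["error_rate"].to_numpy(float)
    best = np.inf
    for c in c_grid:
        for lam in lambda_grid:
            pred_no_b = c / (R * np.exp(-lam * rcum))
            for b in b_grid:
                sse = float(np.sum((np.clip(pred_no_b + b, 0, 1) - y) ** 2))
                best = min(best, sse)
    return best


class TestClosedForms:
    def test_inverse_reward_examples(self):
        p = ValueModelParams(c=0.0, b=0.2)
        for R in (1, 2, 4, 8):
            assert predict_error_rate(p, R) == 0.2
        p = ValueModelParams(c=0.4, b=0.05)
        assert predict_error_rate(p, 1) == pytest.approx(0.45)
        assert predict_error_rate(p, 8) == pytest.approx(0.10)

    def test_satiation_factor_closed_forms(self):
        assert satiation_factor(3.7, 0.0) == 1.0
        assert satiation_factor(0.0, 0.8) == 1.0
        assert satiation_factor(math.log(2), 1.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            satiation_factor(-1.0, 0.5)

    def test_satiation_prediction_direct_evaluation(self):
        p = ValueModelParams(c=0.1, b=0.0, lambda_=1.0)
        expected = 0.1 * math.exp(0.875) / 4  # independent scalar computation
        assert predict_error_rate_satiation(p, 4, 0.875) == pytest.approx(
            expected, abs=1e-15)

    def test_lambda_zero_reduces_to_reward_size_model(self):
        for c in (0.0, 0.1, 0.5, 2.0):
            for b in (0.0, 0.3, 1.0):
                p = ValueModelParams(c=c, b=b, lambda_=0.0)
                for rcum in (0.0, 0.5, 1.0):
                    e2 = predict_error_rate_satiation(p, REWARDS, rcum)
                    e1 = predict_error_rate(p, REWARDS)
                    np.testing.assert_array_equal(e2, e1)

    def test_invalid_inputs_rejected(self):
        p = ValueModelParams(c=0.1, b=0.1)
        with pytest.raises(ValueError):
            predict_error_rate(p, 0)
        with pytest.raises(ValueError):
            predict_error_rate_satiation(p, 4, 1.5)
        with pytest.raises(ValueError):
            ValueModelParams(c=-0.1, b=0.1)
        with pytest.raises(ValueError):
            ValueModelParams(c=0.1, b=1.5)


class TestMonotonicity:
    @settings(deadline=None, max_examples=100)
    @given(c=st.floats(0, 5), b=st.floats(0, 1),
           lam=st.floats(0, 10), rcum=st.floats(0, 1))
    def test_error_rate_nonincreasing_in_reward(self, c, b, lam, rcum):
        p = ValueModelParams(c=c, b=b, lambda_=lam)
        e = predict_error_rate_satiation(p, REWARDS, rcum)
        assert (np.diff(e) <= 1e-15).all()

    @settings(deadline=None, max_examples=100)
    @given(c=st.floats(1e-6, 5), b=st.floats(0, 1), lam=st.floats(1e-3, 10))
    def test_error_rate_nondecreasing_in_satiation(self, c, b, lam):
        p = ValueModelParams(c=c, b=b, lambda_=lam)
        e = predict_error_rate_satiation(p, 4.0, np.linspace(0, 1, 9))
        assert (np.diff(e) >= -1e-15).all()


class TestFitting:
    def test_noiseless_reward_size_recovery(self):
        true = ValueModelParams(c=0.3, b=0.08)
        table = pd.DataFrame({"reward_size": REWARDS,
                              "error_rate": predict_error_rate(true, REWARDS)})
        res = fit_reward_size_model(table)
        assert res.sse < 1e-6
        assert res.params.c == pytest.approx(0.3, abs=1e-3)
        assert res.params.b == pytest.approx(0.08, abs=1e-3)
        assert res.params.lambda_ == 0.0

    def test_noiseless_satiation_recovery(self):
        true = ValueModelParams(c=0.15, b=0.05, lambda_=0.8)
        res = fit_satiation_model(_quartile_table(true))
        assert res.sse < 1e-10
        assert res.params.c == pytest.approx(0.15, abs=1e-3)
        assert res.params.b == pytest.approx(0.05, abs=1e-3)
        assert res.params.lambda_ == pytest.approx(0.8, abs=1e-3)

    def test_constant_table_gives_pure_baseline(self):
        table = pd.DataFrame({"reward_size": REWARDS,
                              "error_rate": np.full(4, 0.3)})
        res = fit_reward_size_model(table)
        assert res.params.c == pytest.approx(0.0, abs=1e-6)
        assert res.params.b == pytest.approx(0.3, abs=1e-6)
        assert res.sse == pytest.approx(0.0, abs=1e-12)

    def test_fit_beats_brute_force_grid(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            true = ValueModelParams(c=rng.uniform(0.05, 0.5),
                                    b=rng.uniform(0, 0.3),
                                    lambda_=rng.uniform(0, 3))
            table = _quartile_table(true, noise_sd=0.05, rng=rng)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                res = fit_satiation_model(table)
            oracle = grid_min_sse(table, np.linspace(0, 2, 30),
                                  np.linspace(0, 0.6, 30), np.linspace(0, 6, 30))
            assert res.sse <= oracle + 1e-12

    def test_nesting_satiation_sse_never_worse_than_fixed_lambda(self):
        rng = np.random.default_rng(5)
        true = ValueModelParams(c=0.2, b=0.05, lambda_=1.2)
        table = _quartile_table(true, noise_sd=0.08, rng=rng)
        free = fit_satiation_model(table)
        fixed = fit_satiation_model(table, fix_lambda=0.0)
        assert free.sse <= fixed.sse + 1e-12

    def test_fixed_lambda_matches_reward_model_on_collapsed_table(self):
        rng = np.random.default_rng(9)
        table = _quartile_table(ValueModelParams(0.25, 0.1, 0.9),
                                noise_sd=0.05, rng=rng)
        fixed = fit_satiation_model(table, fix_lambda=0.0)
        collapsed = (table.groupby("reward_size", as_index=False)["error_rate"]
                     .mean())
        flat = fit_reward_size_model(collapsed)
        # balanced quartile layout: the (c, b) optimum is shared
        assert fixed.params.c == pytest.approx(flat.params.c, abs=1e-6)
        assert fixed.params.b == pytest.approx(flat.params.b, abs=1e-6)

    def test_non_identifiable_layouts_signalled(self):
        single_R = pd.DataFrame({"reward_size": [4.0] * 4,
                                 "error_rate": [0.1, 0.2, 0.15, 0.12]})
        with pytest.raises(NonIdentifiableError):
            fit_reward_size_model(single_R)
        single_q = pd.DataFrame({"reward_size": REWARDS,
                                 "quartile_rcum": [0.125] * 4,
                                 "error_rate": [0.4, 0.2, 0.15, 0.1]})
        with pytest.raises(NonIdentifiableError):
            fit_satiation_model(single_q)

    def test_heavy_clipping_emits_warning(self):
        table = _quartile_table(ValueModelParams(0.2, 0.05, 1.0))
        table["error_rate"] = 1.0  # saturated data force clipped predictions
        with pytest.warns(UserWarning, match="clipped"):
            fit_satiation_model(table)

    def test_deterministic_given_inputs(self):
        rng = np.random.default_rng(2)
        table = _quartile_table(ValueModelParams(0.2, 0.05, 1.0),
                                noise_sd=0.05, rng=rng)
        a = fit_satiation_model(table)
        b = fit_satiation_model(table)
        assert (a.params, a.sse) == (b.params, b.sse)

    def test_fit_by_group_defaults_to_subject_by_treatment(self):
        tables = []
        for subj in ("m1", "m2"):
            for treat in ("vehicle", "agonist"):
                t = _quartile_table(ValueModelParams(0.2, 0.05, 1.0))
                t["subject_id"], t["treatment"] = subj, treat
                tables.append(t)
        fits = fit_by_group(pd.concat(tables, ignore_index=True))
        assert set(fits) == {("m1", "vehicle"), ("m1", "agonist"),
                             ("m2", "vehicle"), ("m2", "agonist")}

    def test_recovery_unbiased_on_binomial_cell_sampling(self):
        """Estimator-level parameter recovery: cells sampled binomially at the
        model's own rates show no significant bias in c-hat or b-hat (3 SE)."""
        true = ValueModelParams(c=0.2, b=0.05, lambda_=1.0)
        rng = np.random.default_rng(17)
        n_per_cell = 80
        est = {"c": [], "b": [], "lambda": []}
        for _ in range(60):
            table = _quartile_table(true)
            k = rng.binomial(n_per_cell, table["error_rate"])
            table["error_rate"] = k / n_per_cell
            res = fit_satiation_model(table)
            est["c"].append(res.params.c)
            est["b"].append(res.params.b)
            est["lambda"].append(res.params.lambda_)
        for name, truth in (("c", true.c), ("b", true.b)):
            vals = np.asarray(est[name])
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - truth) <= 3 * se, name


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        est = SatiationErrorModel(n_starts=3)
        assert clone(est).get_params()["n_starts"] == 3
        est.set_params(n_starts=7)
        assert est.n_starts == 7
        flat = RewardSizeErrorModel(n_grid_c=30)
        assert clone(flat).get_params()["n_grid_c"] == 30

    def test_fit_predict_round_trip(self):
        true = ValueModelParams(c=0.2, b=0.05, lambda_=1.0)
        table = _quartile_table(true)
        est = SatiationErrorModel().fit(table, table["error_rate"])
        pred = est.predict(table)
        np.testing.assert_allclose(pred, table["error_rate"], atol=1e-4)
        assert est.score(table, table["error_rate"]) > 0.999

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            SatiationErrorModel().predict(np.array([[4.0, 0.5]]))

    def test_array_input_equivalent_to_frame(self):
        true = ValueModelParams(c=0.2, b=0.05, lambda_=1.0)
        table = _quartile_table(true)
        X = table[["reward_size", "quartile_rcum"]].to_numpy()
        a = SatiationErrorModel().fit(X, table["error_rate"].to_numpy())
        b = SatiationErrorModel().fit(table, table["error_rate"])
        assert a.c_ == b.c_ and a.lambda_ == b.lambda_
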