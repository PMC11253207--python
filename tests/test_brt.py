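"""Boosted-tree model: staged CV selection, importance, partial dependence."""

import numpy as np
import pandas as pd
import pytest

from nocmig.brt import BoostedTreesModel

FAST = dict(learning_rate=0.1, tree_complexity=4, cv_folds=5, step_size=25,
            max_trees=500, plateau_steps=2)


def _frame(n=400, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"x{i}" for i in range(6)])
    y = 2.0 * X["x0"] if signal else pd.Series(np.zeros(n))
    X["y"] = y + 0.0
    return X


class TestFitting:
    def test_strong_signal_gives_high_cv_correlation(self):
        df = _frame(n=500, seed=1)
        df["y"] = 2.0 * df["x0"] + np.random.default_rng(2).normal(0, 0.1, len(df))
        res = BoostedTreesModel.from_dataframe(
            df, "y", [f"x{i}" for i in range(6)], **FAST
        ).fit(seed=3)
        assert res.cv_correlation > 0.95

    def test_seed_determinism(self):
        df = _frame(n=300, seed=4)
        make = lambda: BoostedTreesModel.from_dataframe(
            df, "y", [f"x{i}" for i in range(6)], **FAST
        ).fit(seed=9)
        a, b = make(), make()
        assert a.n_trees_selected == b.n_trees_selected
        np.testing.assert_array_equal(a.predict(a.model.X), b.predict(b.model.X))
        np.testing.assert_array_equal(a.cv_deviance_trace, b.cv_deviance_trace)

    def test_constant_response_predicts_constant_with_zero_importance(self):
        df = _frame(n=100, seed=5)
        df["y"] = 3.14
        res = BoostedTreesModel.from_dataframe(
            df, "y", [f"x{i}" for i in range(6)], **FAST
        ).fit(seed=0)
        np.testing.assert_allclose(res.predict(res.model.X), 3.14, atol=1e-9)
        with pytest.warns(UserWarning, match="no informative splits"):
            imp = res.relative_importance()
        assert (imp.relative_importance == 0).all()

    def test_train_deviance_nonincreasing_per_step(self):
        df = _frame(n=300, seed=6)
        df["y"] = df["x0"] ** 2 + np.random.default_rng(7).normal(0, 0.3, len(df))
        res = BoostedTreesModel.from_dataframe(
            df, "y", [f"x{i}" for i in range(6)], **FAST
        ).fit(seed=1)
        trace = res.train_deviance_trace
        assert np.all(np.diff(trace) <= 1e-10)

    def test_selected_trees_multiple_of_step_size(self):
        df = _frame(n=200, seed=8)
        df["y"] = df["x1"] + np.random.default_rng(8).normal(0, 0.5, len(df))
        res = BoostedTreesModel.from_dataframe(
            df, "y", [f"x{i}" for i in range(6)], **FAST
        ).fit(seed=2)
        assert res.n_trees_selected % FAST["step_size"] == 0
        assert res.n_trees_selected >= FAST["step_size"]
        assert -1.0 <= res.cv_correlation <= 1.0

    def test_nonfinite_response_rejected_with_rows(self):
        df = _frame(n=100, seed=9)
        df.loc[7, "y"] = np.nan
        with pytest.raises(ValueError, match=r"non-finite response.*7"):
            BoostedTreesModel.from_dataframe(df, "y", ["x0", "x1"], **FAST)

    def test_too_few_rows_rejected(self):
        df = _frame(n=8, seed=10)
        with pytest.raises(ValueError, match="fold"):
            BoostedTreesModel.from_dataframe(df, "y", ["x0"], **FAST)

    def test_missing_covariate_values_handled_without_imputation(self):
        df = _frame(n=200, seed=11)
        df["y"] = df["x0"] + np.random.default_rng(3).normal(0, 0.2, len(df))
        df.loc[:10, "x3"] = np.nan  # e.g. first-night deltas
        model = BoostedTreesModel.from_dataframe(df, "y", [f"x{i}" for i in range(6)], **FAST)
        assert np.isnan(model.X[:11, 3]).all()
        res = model.fit(seed=0)
        assert res.cv_correlation > 0.8

    def test_categorical_covariate_ordinal_encoded(self):
        df = _frame(n=200, seed=12)
        df["radar_type"] = np.where(df["x5"] > 0, "weather", "vertical-looking")
        model = BoostedTreesModel.from_dataframe(
            df, "y", ["x0", "radar_type"], **FAST
        )
        assert model.categorical_levels["radar_type"] == ["vertical-looking", "weather"]
        assert set(np.unique(model.X[:, 1])) == {0.0, 1.0}


class TestImportance:
    def test_sums_to_hundred_with_rank_permutation(self):
        df = _frame(n=300, seed=13)
        df["y"] = df["x0"] + 0.5 * df["x1"] + np.random.default_rng(5).normal(0, 0.2, len(df))
        res = BoostedTreesModel.from_dataframe(
            df, "y", [f"x{i}" for i in range(6)], **FAST
        ).fit(seed=4)
        imp = res.relative_importance()
        assert imp.relative_importance.sum() == pytest.approx(100.0, abs=1e-6)
        assert (imp.relative_importance >= 0).all()
        assert sorted(imp["rank"]) == list(range(1, 7))

    def test_single_covariate_gets_everything(self):
        df = _frame(n=200, seed=14)
        df["y"] = df["x0"] + np.random.default_rng(6).normal(0, 0.1, len(df))
        res = BoostedTreesModel.from_dataframe(df, "y", ["x0"], **FAST).fit(seed=0)
        imp = res.relative_importance()
        assert imp.relative_importance.iloc[0] == pytest.approx(100.0)

    def test_dominant_variable_ranked_first(self):
        df = _frame(n=400, seed=15)
        df["y"] = 3.0 * df["x2"] + 0.3 * df["x4"] + np.random.default_rng(7).normal(
            0, 0.3, len(df)
        )
        res = BoostedTreesModel.from_dataframe(
            df, "y", [f"x{i}" for i in range(6)], **FAST
        ).fit(seed=5)
        imp = res.relative_importance()
        assert imp.iloc[0].variable == "x2"


class TestMarginalResponse:
    def test_additive_component_recovered(self):
        rng = np.random.default_rng(16)
        n = 600
        df = pd.DataFrame({"x0": rng.uniform(-2, 2, n), "x1": rng.uniform(-2, 2, n)})
        f0 = lambda x: np.sin(1.5 * x)
        df["y"] = f0(df.x0) + 0.8 * df.x1 + rng.normal(0, 0.05, n)
        res = BoostedTreesModel.from_dataframe(
            df, "y", ["x0", "x1"],
            learning_rate=0.05, tree_complexity=4, cv_folds=5,
            step_size=50, max_trees=2000, plateau_steps=3,
        ).fit(seed=0)
        grid = np.linspace(-1.8, 1.8, 25)
        m = res.marginal_response("x0", grid=grid)
        got = m.response - m.response.mean()
        want = f0(grid) - f0(grid).mean()
        rmse = float(np.sqrt(np.mean((got - want) ** 2)))
        assert rmse < 0.1

    def test_constant_model_gives_flat_curve(self):
        df = _frame(n=100, seed=17)
        df["y"] = 1.0
        res = BoostedTreesModel.from_dataframe(df, "y", ["x0", "x1"], **FAST).fit(seed=0)
        m = res.marginal_response("x0")
        assert m.response.std() == pytest.approx(0.0, abs=1e-12)

    def test_extrapolation_flagged(self):
        df = _frame(n=120, seed=18)
        df["y"] = df["x0"]
        res = BoostedTreesModel.from_dataframe(df, "y", ["x0", "x1"], **FAST).fit(seed=0)
        lo = df.x0.min()
        m = res.marginal_response("x0", grid=[lo - 1.0, 0.0])
        assert list(m.extrapolation) == [True, False]

    def test_back_transform_is_expm1(self):
        df = _frame(n=120, seed=19)
        df["y"] = np.abs(df["x0"])
        res = BoostedTreesModel.from_dataframe(df, "y", ["x0", "x1"], **FAST).fit(seed=0)
        raw = res.marginal_response("x0", grid=[0.0, 1.0])
        back = res.marginal_response("x0", grid=[0.0, 1.0], back_transform=True)
        np.testing.assert_allclose(back.response, np.expm1(raw.response))


def test_plot_marginal_response_draws_curve():
    import matplotlib
    matplotlib.use("Agg")
    df = _frame(n=120, seed=21)
    df["y"] = df["x0"]
    res = BoostedTreesModel.from_dataframe(df, "y", ["x0", "x1"], **FAST).fit(seed=0)
    ax = res.plot_marginal_response("x0", n_grid=10)
    (line,) = ax.get_lines()
    assert len(line.get_xdata()) == 10
    assert ax.get_xlabel() == "x0"


def test_summary_renders_key_quantities():
    df = _frame(n=150, seed=20)
    df["y"] = df["x0"] + np.random.default_rng(1).normal(0, 0.3, len(df))
    res = BoostedTreesModel.from_dataframe(df, "y", ["x0", "x1"], **FAST).fit(seed=1)
    text = res.summary()
    assert "trees selected" in text and "CV correlation" in text and "x0" in text
    d = res.to_dict()
    assert d["n_trees_selected"] == res.n_trees_selected
    assert set(d["importance"]) == {"x0", "x1"}
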