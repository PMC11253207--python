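"""Boosted regression trees for nightly migration intensity.

Models log(directional MTR + 1) as a Gaussian (squared-error) stagewise
boosted ensemble of depth-limited regression trees, with the staged
cross-validated tree-count selection popularised by gbm.step: trees are
added in fixed steps (default 25) to ten cross-validation fold models in
parallel, held-out deviance is tracked per step, growth stops once the mean
held-out deviance has failed to improve for a plateau of consecutive steps,
and the selected tree count — the step minimising held-out deviance — is
used to refit the final ensemble on all data.

"Tree complexity" is the gbm interaction depth: the number of splits per
tree, implemented as best-first growth to ``tree_complexity + 1`` leaves.
Relative importance follows the classic definition — the number of times a
variable is selected for splitting, weighted by the squared improvement of
the model, averaged over all trees and scaled so the sum adds to 100 — and
marginal (partial-dependence) responses average the ensemble prediction
over the data with one covariate pinned to grid values.

The ensemble, selection loop, importance and partial dependence are
implemented here; scikit-learn supplies only the base tree learner.
Usage follows the Model / Results pattern::

    model = BoostedTreesModel.from_dataframe(df, response="log_mtr",
                                             covariates=PREDICTORS)
    res = model.fit(seed=7)
    print(res.summary())
    res.relative_importance()
    res.marginal_response("wind_speed")
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = ["BoostedTreesModel", "BoostedTreesResults", "DEFAULT_HYPERPARAMS"]

#: The study's tuned hyperparameters.
DEFAULT_HYPERPARAMS = dict(
    learning_rate=0.001,
    tree_complexity=10,
    bag_fraction=0.5,
    cv_folds=10,
    step_size=25,
    max_trees=10_000,
    plateau_steps=3,
)


@dataclass
class BoostedTreesModel:
    """Gaussian boosted-tree model specification bound to data."""

    y: np.ndarray
    X: np.ndarray
    var_names: list[str]
    learning_rate: float = 0.001
    tree_complexity: int = 10
    bag_fraction: float = 0.5
    cv_folds: int = 10
    step_size: int = 25
    max_trees: int = 10_000
    plateau_steps: int = 3
    categorical_levels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        self.X = np.asarray(self.X, float)
        bad = ~np.isfinite(self.y)
        if bad.any():
            raise ValueError(
                f"non-finite response values at rows {np.flatnonzero(bad).tolist()}"
            )
        if len(self.y) < 2 * self.cv_folds:
            raise ValueError(
                f"need at least {2 * self.cv_folds} rows for {self.cv_folds}-fold "
                f"cross-validation, got {len(self.y)}"
            )
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y row counts differ")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        covariates: list[str],
        **hyperparams,
    ) -> "BoostedTreesModel":
        """Build from a modelling table.  Non-numeric covariates (e.g. the
        radar-type factor) are ordinal-encoded; the level order is recorded
        for reporting.  Missing covariate values are kept as NaN and handled
        natively by the tree splitter (no imputation)."""
        X = np.empty((len(data), len(covariates)))
        cat_levels: dict = {}
        for j, c in enumerate(covariates):
            col = data[c]
            if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                codes, levels = pd.factorize(col, sort=True)
                X[:, j] = np.where(codes < 0, np.nan, codes)
                cat_levels[c] = list(levels)
            else:
                X[:, j] = pd.to_numeric(col).to_numpy(float)
        return cls(
            y=data[response].to_numpy(float),
            X=X,
            var_names=list(covariates),
            categorical_levels=cat_levels,
            **hyperparams,
        )

    # -- fitting ------------------------------------------------------------

    def _grow_step(self, rng, X, y, current, trees):
        """Add ``step_size`` trees to one boosting state in place."""
        n = len(y)
        n_bag = max(2, int(round(self.bag_fraction * n)))
        for _ in range(self.step_size):
            resid = y - current
            bag = rng.choice(n, size=n_bag, replace=False)
            tree = DecisionTreeRegressor(
                max_leaf_nodes=self.tree_complexity + 1,
                # the conventional boosting minimum of 10 obs per terminal
                # node, relaxed only when the bag itself is tiny
                min_samples_leaf=min(10, max(1, n_bag // 5)),
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[bag], resid[bag])
            current += self.learning_rate * tree.predict(X)
            trees.append(tree)

    def fit(self, seed: int = 0) -> "BoostedTreesResults":
        """Run the staged CV tree selection, then refit on all data with the
        selected tree count.  Fully deterministic for a given seed."""
        rng = np.random.default_rng([seed, 0])
        n = len(self.y)
        order = rng.permutation(n)
        folds = [order[k :: self.cv_folds] for k in range(self.cv_folds)]

        fold_state = []
        for k, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(order, test_idx)
            init = float(self.y[train_idx].mean())
            fold_state.append(
                dict(
                    rng=np.random.default_rng([seed, 1, k]),
                    train=train_idx,
                    test=test_idx,
                    f_train=np.full(len(train_idx), init),
                    f_test=np.full(len(test_idx), init),
                    trees=[],
                )
            )

        cv_trace: list[float] = []
        oof_snapshots: list[np.ndarray] = []
        n_steps_max = max(1, self.max_trees // self.step_size)
        for step in range(n_steps_max):
            oof = np.empty(n)
            sq = 0.0
            for st in fold_state:
                # grow the fold's training ensemble; track its held-out fit
                self._grow_step(
                    st["rng"],
                    self.X[st["train"]],
                    self.y[st["train"]],
                    st["f_train"],
                    st["trees"],
                )
                # extend held-out predictions with the newly added trees
                new = st["trees"][-self.step_size :]
                for t in new:
                    st["f_test"] += self.learning_rate * t.predict(self.X[st["test"]])
                oof[st["test"]] = st["f_test"]
                sq += float(((self.y[st["test"]] - st["f_test"]) ** 2).sum())
            cv_trace.append(sq / n)
            oof_snapshots.append(oof)
            best = int(np.argmin(cv_trace))
            if step - best >= self.plateau_steps:
                break

        best = int(np.argmin(cv_trace))
        n_trees = self.step_size * (best + 1)
        oof_best = oof_snapshots[best]
        if np.std(oof_best) == 0 or np.std(self.y) == 0:
            cv_corr = np.nan
        else:
            cv_corr = float(np.corrcoef(oof_best, self.y)[0, 1])

        # final refit on all data
        final_rng = np.random.default_rng([seed, 2])
        init = float(self.y.mean())
        current = np.full(n, init)
        trees: list[DecisionTreeRegressor] = []
        train_trace = []
        for _ in range(n_trees // self.step_size):
            self._grow_step(final_rng, self.X, self.y, current, trees)
            train_trace.append(float(np.mean((self.y - current) ** 2)))

        return BoostedTreesResults(
            model=self,
            init_value=init,
            trees=trees,
            n_trees_selected=n_trees,
            cv_deviance_trace=np.asarray(cv_trace),
            train_deviance_trace=np.asarray(train_trace),
            cv_correlation=cv_corr,
            seed=seed,
        )


@dataclass
class BoostedTreesResults:
    """Fitted ensemble with its tree-selection trace and diagnostics."""

    model: BoostedTreesModel
    init_value: float
    trees: list
    n_trees_selected: int
    cv_deviance_trace: np.ndarray  # mean held-out deviance per step
    train_deviance_trace: np.ndarray  # training deviance per step (final fit)
    cv_correlation: float  # Pearson r, out-of-fold predictions vs response
    seed: int

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        out = np.full(X.shape[0], self.init_value)
        lr = self.model.learning_rate
        for t in self.trees:
            out += lr * t.predict(X)
        return out

    def relative_importance(self) -> pd.DataFrame:
        """Squared-improvement importance scaled to sum to 100, with ranks.

        Per variable: the summed squared-error improvement of every split it
        makes, accumulated over all trees; a model with zero splits returns
        an all-zero table with a warning.
        """
        raw = np.zeros(len(self.model.var_names))
        for t in self.trees:
            tr = t.tree_
            for node in range(tr.node_count):
                left, right = tr.children_left[node], tr.children_right[node]
                if left == -1:  # leaf
                    continue
                w = tr.weighted_n_node_samples
                improvement = (
                    w[node] * tr.impurity[node]
                    - w[left] * tr.impurity[left]
                    - w[right] * tr.impurity[right]
                )
                raw[tr.feature[node]] += max(improvement, 0.0)
        total = raw.sum()
        if total <= 0:
            warnings.warn("model has no informative splits; importances are all zero")
            pct = raw
        else:
            pct = 100.0 * raw / total
        order = np.argsort(-pct, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(1, len(order) + 1)
        return pd.DataFrame(
            {"variable": self.model.var_names, "relative_importance": pct, "rank": rank}
        ).sort_values("rank").reset_index(drop=True)

    def marginal_response(
        self,
        covariate: str,
        grid=None,
        n_grid: int = 50,
        back_transform: bool = False,
    ) -> pd.DataFrame:
        """Partial dependence of the response on one covariate.

        The ensemble prediction is averaged over the data with the covariate
        pinned to each grid value; grid points outside the observed range are
        computed but flagged as extrapolation.  ``back_transform`` maps the
        log-scale response through exp(x) - 1 to the MTR scale.
        """
        j = self.model.var_names.index(covariate)
        col = self.model.X[:, j]
        lo, hi = np.nanmin(col), np.nanmax(col)
        if grid is None:
            grid = np.linspace(lo, hi, n_grid)
        grid = np.asarray(grid, float)
        # stack the data once per grid value so the ensemble walks the trees
        # a single time over the whole block
        n = self.model.X.shape[0]
        Xstack = np.tile(self.model.X, (len(grid), 1))
        Xstack[:, j] = np.repeat(grid, n)
        values = self.predict(Xstack).reshape(len(grid), n).mean(axis=1)
        if back_transform:
            values = np.expm1(values)
        return pd.DataFrame(
            {
                "covariate": covariate,
                "grid_value": grid,
                "response": values,
                "extrapolation": (grid < lo) | (grid > hi),
            }
        )

    def plot_marginal_response(self, covariate: str, ax=None, n_grid: int = 50,
                               back_transform: bool = False):
        """Plot the partial-dependence curve of one covariate; returns the
        matplotlib Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.marginal_response(covariate, n_grid=n_grid,
                                   back_transform=back_transform)
        ax.plot(m.grid_value, m.response, lw=1.5)
        ax.set_xlabel(covariate)
        ax.set_ylabel("MTR (birds km$^{-1}$ h$^{-1}$)" if back_transform
                      else "log(directional MTR + 1)")
        return ax

    def summary(self) -> str:
        m = self.model
        imp = self.relative_importance()
        lines = [
            "Boosted regression trees — Gaussian deviance",
            "=" * 52,
            f"n obs:              {len(m.y)}",
            f"covariates:         {len(m.var_names)}",
            f"learning rate:      {m.learning_rate}",
            f"tree complexity:    {m.tree_complexity}",
            f"bag fraction:       {m.bag_fraction}",
            f"CV folds:           {m.cv_folds} (steps of {m.step_size} trees)",
            f"trees selected:     {self.n_trees_selected}",
            f"CV correlation:     {self.cv_correlation:.3f}",
            f"CV deviance (best): {float(np.min(self.cv_deviance_trace)):.4f}",
            "-" * 52,
            f"{'variable':<24}{'rel. importance':>16}{'rank':>8}",
        ]
        for _, r in imp.iterrows():
            lines.append(
                f"{r['variable']:<24}{r['relative_importance']:>15.2f}%{int(r['rank']):>7}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        imp = self.relative_importance()
        return {
            "hyperparams": {
                k: getattr(self.model, k)
                for k in DEFAULT_HYPERPARAMS
            },
            "n_obs": int(len(self.model.y)),
            "n_trees_selected": int(self.n_trees_selected),
            "cv_correlation": None if np.isnan(self.cv_correlation) else float(self.cv_correlation),
            "cv_deviance_trace": [float(x) for x in self.cv_deviance_trace],
            "seed": self.seed,
            "importance": {
                r["variable"]: float(r["relative_importance"]) for _, r in imp.iterrows()
            },
        }
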