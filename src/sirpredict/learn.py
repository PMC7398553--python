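"""Regression protocol: how well do centralities predict outbreak size?

For a fixed graph size N, transmission rate beta, and feature combination,
the protocol is:

1. project the record table onto the selected features and Omega(beta) and
   drop exact duplicates (see :mod:`sirpredict.dataset`);
2. split into development and test data — the development size is itself a
   tunable quantity, chosen from a ten-point learning curve as the smallest
   size where the cross-validated score has levelled off near the training
   score (defaults to a 75% split when tuning is skipped, appropriate at
   desk-scale N where data is not abundant);
3. grid-search hyperparameters with ten-fold cross-validation on the
   development data (random-forest or support-vector regression, both from
   scikit-learn), refit the best model on all development data;
4. score on the held-out test data with the coefficient of determination
   R^2 = 1 - S_res/S_tot;
5. optionally attach a permutation p-value: the cross-validated score is
   compared against scores obtained after permuting the targets, with
   p = (1 + #{permuted >= observed}) / (1 + n_permutations).

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import (
    GridSearchCV,
    KFold,
    cross_validate,
    permutation_test_score,
    train_test_split,
)
from sklearn.svm import SVR

from .centrality import FEATURE_NAMES
from .dataset import ExperimentView, project_and_dedup

__all__ = [
    "RegressionConfig",
    "ExperimentResult",
    "LearningCurve",
    "PermutationTestResult",
    "r_squared",
    "tune_dev_size",
    "run_experiment",
    "permutation_test",
    "sweep",
    "min_over_beta",
    "feature_combinations",
]


def r_squared(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """Coefficient of determination 1 - S_res / S_tot.

    S_res is the residual sum of squares and S_tot the total sum of squares
    about the mean of ``y_true``.  Equals 1 for a perfect prediction, 0 for
    the constant mean predictor, and is unbounded below.  Undefined (raises)
    when the true targets are constant.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size == 0:
        raise ValueError("need two equal-length non-empty 1-d arrays")
    s_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if s_tot == 0.0:
        raise ValueError("R^2 undefined: true targets are constant")
    s_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - s_res / s_tot


@dataclass(frozen=True)
class RegressionConfig:
    """Regressor kind, hyperparameter grids and cross-validation settings.

    The forest grid spans up to 20 trees and minimum-leaf fractions from 1%
    down to 0.01% of the training size; the SVR grid spans linear and RBF
    kernels with regularisation C from 0.1 to 100, a fixed epsilon-tube of
    0.01 and the kernel coefficient gamma scaled automatically from the
    feature count and variance.  Grids are ordered simple-to-complex so that
    score ties resolve toward the simpler model.
    """

    kind: str = "forest"  # "forest" | "svm"
    forest_trees: tuple[int, ...] = (5, 10, 15, 20)
    forest_leaf_fractions: tuple[float, ...] = (1e-2, 3e-3, 1e-3, 3e-4, 1e-4)
    svm_c: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svm_kernels: tuple[str, ...] = ("linear", "rbf")
    svm_epsilon: float = 0.01
    cv_folds: int = 10
    # learning-curve plateau thresholds (see tune_dev_size)
    plateau_val_tol: float = 0.005
    plateau_gap_tol: float = 0.02

    def __post_init__(self) -> None:
        if self.kind not in ("forest", "svm"):
            raise ValueError("kind must be 'forest' or 'svm'")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not (self.forest_trees and self.forest_leaf_fractions and self.svm_c):
            raise ValueError("hyperparameter grids must be non-empty")

    def make_estimator(self, seed: int | None = 0):
        if self.kind == "forest":
            return RandomForestRegressor(
                n_estimators=self.forest_trees[-1] // 2 or 1,
                min_samples_leaf=self.forest_leaf_fractions[0],
                random_state=seed,
            )
        return SVR(kernel="rbf", C=1.0, epsilon=self.svm_epsilon, gamma="scale")

    def param_grid(self) -> list[dict]:
        """Explicit grid, one entry per combination, simple models first."""
        if self.kind == "forest":
            return [
                {"n_estimators": [t], "min_samples_leaf": [f]}
                for t in self.forest_trees
                for f in self.forest_leaf_fractions
            ]
        return [
            {"kernel": [k], "C": [c]}
            for k in self.svm_kernels  # linear listed before rbf
            for c in self.svm_c
        ]


@dataclass(frozen=True)
class LearningCurve:
    """Training/validation score vs development-data size, ten sizes."""

    sizes: tuple[int, ...]
    train_scores: tuple[float, ...]
    validation_scores: tuple[float, ...]


@dataclass(frozen=True)
class PermutationTestResult:
    p_value: float
    score: float
    permuted_scores: tuple[float, ...]


@dataclass
class ExperimentResult:
    """Outcome of one (N, beta, feature combination, regressor) cell."""

    n_nodes: int | None
    beta: float
    feature_names: tuple[str, ...]
    kind: str
    dev_size: int
    best_params: dict
    test_r2: float
    p_value: float | None = None
    learning_curve: LearningCurve | None = None
    dev_size_warning: bool = False
    model: object = field(default=None, repr=False)


def _subseeds(seed: int, k: int) -> list[int]:
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(k)]


def tune_dev_size(
    view: ExperimentView, config: RegressionConfig, seed: int = 0
) -> tuple[int, LearningCurve, bool]:
    """Choose the development-data size from a learning curve.

    Ten candidate sizes on a linear scale up to 80% of the data; at each, a
    default-configuration regressor is cross-validated (ten folds) on a
    random subsample and mean training/validation R^2 recorded.  The chosen
    size is the smallest at which the validation score is within
    ``plateau_val_tol`` of its maximum over the curve *and* the
    training-validation gap is below ``plateau_gap_tol`` — i.e. the curve
    has levelled off close to the training curve.  If no size qualifies the
    maximum size is returned with a warning flag.
    """
    n = len(view)
    max_size = int(math.floor(0.8 * n))
    sizes = sorted({int(round(max_size * k / 10)) for k in range(1, 11)})
    if len(sizes) < 10 or sizes[0] < config.cv_folds:
        raise ValueError(
            f"dataset of {n} rows is too small for a ten-point learning curve "
            f"with {config.cv_folds}-fold validation"
        )
    s_sub, s_cv, s_est = _subseeds(seed, 3)
    rng = np.random.default_rng(s_sub)
    x_all, y_all = view.X, view.y
    train_means, val_means = [], []
    for size in sizes:
        idx = rng.choice(n, size=size, replace=False)
        cv = KFold(config.cv_folds, shuffle=True, random_state=s_cv)
        scores = cross_validate(
            config.make_estimator(s_est),
            x_all[idx],
            y_all[idx],
            cv=cv,
            scoring="r2",
            return_train_score=True,
        )
        train_means.append(float(np.mean(scores["train_score"])))
        val_means.append(float(np.mean(scores["test_score"])))
    curve = LearningCurve(tuple(sizes), tuple(train_means), tuple(val_means))
    best_val = max(val_means)
    for size, tr, va in zip(sizes, train_means, val_means):
        if va >= best_val - config.plateau_val_tol and tr - va < config.plateau_gap_tol:
            return size, curve, False
    return sizes[-1], curve, True


def run_experiment(
    view: ExperimentView,
    config: RegressionConfig | None = None,
    seed: int = 0,
    *,
    dev_fraction: float = 0.75,
    tune_size: bool = False,
    n_permutations: int | None = None,
) -> ExperimentResult:
    """Full protocol on one deduplicated view: split, tune, test.

    With ``tune_size`` the development size comes from the learning curve;
    otherwise ``dev_fraction`` of the rows form the development data.  The
    split is uniform random without replacement, the hyperparameter search
    is a ten-fold cross-validated grid search on the development data only,
    and the reported R^2 is computed on the untouched test rows.  Identical
    seeds give identical results (to numerical tolerance for the SVR).
    """
    config = config or RegressionConfig()
    n = len(view)
    if n <= 20:
        raise ValueError(f"view has only {n} rows; too degenerate to split and tune")
    s_split, s_cv, s_est, s_tune, s_perm = _subseeds(seed, 5)
    curve = None
    warn = False
    if tune_size:
        dev_size, curve, warn = tune_dev_size(view, config, seed=s_tune)
    else:
        dev_size = int(round(dev_fraction * n))
    dev_size = min(max(dev_size, config.cv_folds), n - 1)
    x_dev, x_test, y_dev, y_test = train_test_split(
        view.X, view.y, train_size=dev_size, random_state=s_split, shuffle=True
    )
    cv = KFold(config.cv_folds, shuffle=True, random_state=s_cv)
    search = GridSearchCV(
        config.make_estimator(s_est),
        config.param_grid(),
        scoring="r2",
        cv=cv,
        refit=True,
    )
    search.fit(x_dev, y_dev)
    test_r2 = r_squared(y_test, search.best_estimator_.predict(x_test))
    p_value = None
    if n_permutations is not None:
        p_value = _permutation_p(
            search.best_estimator_, x_dev, y_dev, config, n_permutations, s_perm
        )
    return ExperimentResult(
        n_nodes=view.n_nodes,
        beta=view.beta,
        feature_names=view.feature_names,
        kind=config.kind,
        dev_size=dev_size,
        best_params=dict(search.best_params_),
        test_r2=float(test_r2),
        p_value=p_value,
        learning_curve=curve,
        dev_size_warning=warn,
        model=search.best_estimator_,
    )


def _permutation_p(estimator, x, y, config, n_permutations, seed) -> float:
    _, _, p = permutation_test_score(
        estimator,
        x,
        y,
        cv=KFold(config.cv_folds, shuffle=True, random_state=seed),
        n_permutations=n_permutations,
        scoring="r2",
        random_state=seed,
    )
    return float(p)


def permutation_test(
    view: ExperimentView,
    config: RegressionConfig | None = None,
    n_permutations: int = 100,
    seed: int = 0,
    *,
    dev_fraction: float = 0.75,
) -> PermutationTestResult:
    """Permutation significance of the feature-target relationship.

    The targets of the development data are permuted so any structural
    dependence on the features is destroyed; a ten-fold cross-validated
    score is computed for the true targets and for each permutation, and

        p = (1 + #{permuted score >= true score}) / (1 + n_permutations),

    so the smallest attainable p with 100 permutations is 1/101.  Under a
    genuine dependence the true score beats every permutation and the
    minimum is attained; under the null p is approximately uniform.
    """
    config = config or RegressionConfig()
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    s_split, s_cv, s_est, s_perm = _subseeds(seed, 4)
    x, y = view.X, view.y
    if dev_fraction < 1.0:
        x, _, y, _ = train_test_split(
            x, y, train_size=dev_fraction, random_state=s_split, shuffle=True
        )
    score, perm_scores, p = permutation_test_score(
        config.make_estimator(s_est),
        x,
        y,
        cv=KFold(config.cv_folds, shuffle=True, random_state=s_cv),
        n_permutations=n_permutations,
        scoring="r2",
        random_state=s_perm,
    )
    return PermutationTestResult(
        p_value=float(p), score=float(score), permuted_scores=tuple(map(float, perm_scores))
    )


def feature_combinations(max_size: int, features: Sequence[str] = FEATURE_NAMES):
    """All feature combinations of size 1..max_size, deterministic order."""
    out = []
    for k in range(1, max_size + 1):
        out.extend(itertools.combinations(features, k))
    return out


def sweep(
    records: pd.DataFrame,
    combos: Iterable[Sequence[str]],
    betas: Iterable[float],
    config: RegressionConfig | None = None,
    seed: int = 0,
    on_error: str = "record",
    **experiment_kwargs,
) -> pd.DataFrame:
    """One experiment per (feature combination, beta); heatmap-ready table.

    Every cell gets its own seed derived deterministically from ``seed`` and
    the cell index, so a sweep is reproducible as a whole and per cell.
    Cells whose view is too degenerate to run (e.g. at very small N) are
    recorded with a NaN score and the error message when
    ``on_error='record'`` (the default), or abort the sweep with
    ``on_error='raise'``.

    Columns: n, beta, combo ("+"-joined), n_features, kind, dev_size,
    best_params (repr), test_r2, error.
    """
    config = config or RegressionConfig()
    combos = [tuple(c) for c in combos]
    betas = list(betas)
    rows = []
    for i, (combo, beta) in enumerate(itertools.product(combos, betas)):
        view = project_and_dedup(records, combo, beta)
        cell_seed = int(
            np.random.SeedSequence((seed, i)).generate_state(1)[0]
        ) % (2**31)
        try:
            res = run_experiment(view, config, seed=cell_seed, **experiment_kwargs)
            cell = {
                "dev_size": res.dev_size,
                "best_params": repr(res.best_params),
                "test_r2": res.test_r2,
                "error": "",
            }
        except ValueError as exc:
            if on_error == "raise":
                raise
            cell = {
                "dev_size": 0,
                "best_params": "",
                "test_r2": float("nan"),
                "error": str(exc),
            }
        rows.append(
            {
                "n": view.n_nodes,
                "beta": beta,
                "combo": "+".join(combo),
                "n_features": len(combo),
                "kind": config.kind,
                **cell,
            }
        )
    return pd.DataFrame(rows)


def min_over_beta(results: pd.DataFrame) -> pd.DataFrame:
    """Per-combination worst case: the minimum test R^2 across betas.

    This is the summary the heatmap captions rank combinations by — a
    combination is only as good as its hardest transmission rate.
    """
    out = (
        results.groupby(["combo", "n_features"], as_index=False)["test_r2"]
        .min()
        .rename(columns={"test_r2": "min_r2"})
    )
    return out.sort_values("min_r2", ascending=False, ignore_index=True)
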