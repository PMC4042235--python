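"""Internal/external model validation and Y-randomization.

Statistics follow the conventions of grid-field QSAR reporting:

* ``q2`` — leave-one-out cross-validated coefficient of determination on the
  training set, ``1 - sum(y - y_loo)^2 / sum(y - ybar_train)^2``;
* ``pred_r2`` — the external analogue on the test set.  Its denominator sums
  test-set deviations *from the training mean*, not the test mean;
* ``r2``, standard error and the F statistic of the fitted model;
* Y-randomization — refit on permuted activities, summarize the true
  statistic's outlyingness as ``Z = (h - mu)/sigma`` and convert Z to a
  standard-normal curve area.

A model is conventionally accepted when r2, q2 > 0.6 and pred_r2 > 0.5.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .fields import DescriptorMatrix
from .qsar import (PLSQSARRegressor, QSARModel, SplitSpec,
                   StepwiseForwardSelector)

logger = logging.getLogger(__name__)


@dataclass
class PredictionSet:
    """Actual vs predicted activities, plus the reference (training) mean."""

    actual: np.ndarray
    predicted: np.ndarray
    reference_mean: float

    def __post_init__(self) -> None:
        self.actual = np.asarray(self.actual, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.actual.shape != self.predicted.shape:
            raise ValueError("actual/predicted length mismatch")
        if not (np.all(np.isfinite(self.actual))
                and np.all(np.isfinite(self.predicted))
                and math.isfinite(self.reference_mean)):
            raise ValueError("non-finite values in prediction set")


def q_squared(actual, predicted, reference_mean: float) -> float:
    """``1 - sum(y - yhat)^2 / sum(y - reference_mean)^2``.

    The same formula serves LOO q2 (reference_mean = training mean, predictions
    from leave-one-out refits) and pred_r2 (test-set predictions against the
    training mean).
    """
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    denom = float(np.sum((y - reference_mean) ** 2))
    if denom <= 0:
        raise ValueError("zero denominator: activities equal the reference mean")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / denom


@dataclass(frozen=True)
class ModelRecipe:
    """Settings that reproduce a model fit: selection size, PLS components and
    whether LOO refits re-run descriptor selection per fold (strict mode) or
    keep the full-training selection frozen (default)."""

    max_descriptors: int = 4
    n_components: int | None = None
    max_components: int | None = None
    reselect_per_fold: bool = False


def _fit_on(
    m: DescriptorMatrix, ids: Sequence[str], selected: Sequence[str],
    recipe: ModelRecipe,
) -> QSARModel:
    sub = m.subset(list(ids))
    k = recipe.n_components
    if k is not None:
        k = min(k, len(selected))  # selection may return fewer descriptors
    reg = PLSQSARRegressor(n_components=k,
                           max_components=recipe.max_components)
    reg.fit(sub.X[list(selected)], sub.y)
    return reg.to_qsar_model()


def q_squared_loo(
    m: DescriptorMatrix,
    train: SplitSpec,
    selected: Sequence[str],
    recipe: ModelRecipe = ModelRecipe(),
) -> float:
    """Leave-one-out q2 on the training set.

    Each training compound is held out in turn and the model refitted on the
    remainder (coefficients only by default; per-fold reselection in strict
    mode), then the held-out activity is predicted.  The denominator uses the
    full training mean.
    """
    ids = list(train.train_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 training compounds for LOO")
    sub = m.subset(ids)
    y = sub.y.to_numpy()
    ybar = float(y.mean())
    # pin the component count so every fold refits the same model shape
    full = _fit_on(m, ids, selected, recipe)
    fold_recipe = ModelRecipe(recipe.max_descriptors, full.n_components,
                              recipe.max_components, recipe.reselect_per_fold)
    preds = np.empty(len(ids))
    for i, held in enumerate(ids):
        rest = [c for c in ids if c != held]
        fold_selected = list(selected)
        if recipe.reselect_per_fold:
            rest_sub = m.subset(rest)
            sel = StepwiseForwardSelector(max_descriptors=recipe.max_descriptors)
            sel.fit(rest_sub.X, rest_sub.y)
            fold_selected = sel.selected_
        fold_model = _fit_on(m, rest, fold_selected, fold_recipe)
        preds[i] = fold_model.predict(m.X.loc[[held]])[0]
    return q_squared(y, preds, ybar)


def pred_r_squared(
    model: QSARModel,
    m: DescriptorMatrix,
    test: SplitSpec | Sequence[str],
) -> float:
    """External-validation pred_r2 on the test set, with the training-set mean
    in the denominator (so beating "always predict the training mean" gives a
    positive value)."""
    test_ids = list(test.test_ids) if isinstance(test, SplitSpec) else list(test)
    if not test_ids:
        raise ValueError("test set is empty")
    sub = m.subset(test_ids)
    preds = model.predict(sub.X)
    if not math.isfinite(model.training_mean_activity):
        raise ValueError("model lacks a training mean for the denominator")
    return q_squared(sub.y.to_numpy(), preds, model.training_mean_activity)


@dataclass(frozen=True)
class FitStatistics:
    r2: float
    se: float
    f_test: float
    degrees_of_freedom: int


def fit_statistics(p: PredictionSet, k: int) -> FitStatistics:
    """r2, standard error of estimate, and the F statistic of a fitted model
    with k regressors (n must exceed k + 1)."""
    n = len(p.actual)
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (got n={n}, k={k})")
    ybar = float(p.actual.mean())
    sse = float(np.sum((p.actual - p.predicted) ** 2))
    sst = float(np.sum((p.actual - ybar) ** 2))
    if sst <= 0:
        raise ValueError("constant activities: r2 undefined")
    ssr = sst - sse
    df = n - k - 1
    r2 = 1.0 - sse / sst
    se = math.sqrt(sse / df)
    f = math.inf if sse <= 0 else (ssr / k) / (sse / df)
    return FitStatistics(r2, se, f, df)


def normal_area_percent(z: float, decimals: int | None = 2) -> float:
    """Percent area under the standard normal curve to the left of z
    (``100 * Phi(z)``), rounded to 2 decimals by default."""
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    area = 100.0 * float(norm.cdf(z))
    return area if decimals is None else round(area, decimals)


# ---------------------------------------------------------------------------
# Y-randomization
# ---------------------------------------------------------------------------

@dataclass
class RandomizationResult:
    """Z-score summary of one statistic against its permutation distribution."""

    statistic: str
    h: float
    mu: float
    sigma: float
    z_score: float
    best_random: float
    p_empirical: float
    n_permutations: int
    seed: int


def _permuted_matrix(m: DescriptorMatrix, ids: list[str],
                     rng: np.random.Generator) -> DescriptorMatrix:
    y = m.y.copy()
    perm = rng.permutation(len(ids))
    y.loc[ids] = y.loc[ids].to_numpy()[perm]
    return DescriptorMatrix(m.X, y, m.descriptors)


def _model_statistics(
    m: DescriptorMatrix, split: SplitSpec, recipe: ModelRecipe,
) -> dict[str, float]:
    sub = m.subset(list(split.train_ids))
    sel = StepwiseForwardSelector(max_descriptors=recipe.max_descriptors)
    sel.fit(sub.X, sub.y)
    selected = sel.selected_
    model = _fit_on(m, list(split.train_ids), selected, recipe)
    preds = model.predict(sub.X)
    sst = float(np.sum((sub.y - sub.y.mean()) ** 2))
    sse = float(np.sum((sub.y.to_numpy() - preds) ** 2))
    # q2 in nested (reselect-per-fold) mode: the frozen-selection LOO q2 is
    # the very criterion selection maximized, so on permuted activities it
    # measures selection bias rather than chance correlation.  Nested LOO is
    # the selection-bias-free estimate and is used consistently for the
    # actual statistic and every permutation.
    nested = ModelRecipe(recipe.max_descriptors, recipe.n_components,
                         recipe.max_components, reselect_per_fold=True)
    out = {"r2": 1.0 - sse / sst,
           "q2": q_squared_loo(m, SplitSpec.from_lists(split.train_ids, ()),
                               selected, nested)}
    if split.test_ids:
        out["pred_r2"] = pred_r_squared(model, m, list(split.test_ids))
    return out


def y_randomization(
    m: DescriptorMatrix,
    split: SplitSpec,
    recipe: ModelRecipe = ModelRecipe(),
    n_permutations: int = 100,
    seed: int = 42,
) -> dict[str, RandomizationResult]:
    """Chance-correlation control: rebuild the model on activity-permuted
    training sets and express the true statistics as Z-scores against the
    permutation distribution.

    Each permutation shuffles training activities, re-runs descriptor
    selection and the PLS fit, and records r2 / q2 (and pred_r2 when a test
    set is present).  Also reports the best random value and an empirical
    one-sided p-value ``(#random >= h + 1) / (n_permutations + 1)``.
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    ids = list(split.train_ids)
    h = _model_statistics(m, split, recipe)
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {k: [] for k in h}
    for _ in range(n_permutations):
        perm_m = _permuted_matrix(m, ids, rng)
        try:
            stats = _model_statistics(perm_m, split, recipe)
        except (ValueError, FloatingPointError) as exc:  # degenerate permutation
            logger.warning("skipping degenerate permutation: %s", exc)
            continue
        for k in draws:
            if k in stats:
                draws[k].append(stats[k])
    results: dict[str, RandomizationResult] = {}
    for stat, values in draws.items():
        arr = np.asarray(values)
        mu = float(arr.mean())
        sigma = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        if sigma > 0:
            z = (h[stat] - mu) / sigma
        else:
            z = math.inf
            logger.warning("zero spread in randomized %s; Z reported as inf", stat)
        p_emp = (int(np.sum(arr >= h[stat])) + 1) / (len(arr) + 1)
        results[stat] = RandomizationResult(
            statistic=stat, h=h[stat], mu=mu, sigma=sigma, z_score=z,
            best_random=float(arr.max()), p_empirical=p_emp,
            n_permutations=len(arr), seed=seed)
    return results


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Full statistical account of one fitted model."""

    n: int
    k: int
    degrees_of_freedom: int
    n_components: int
    r2: float
    q2: float
    pred_r2: float | None
    r2_se: float
    q2_se: float
    pred_r2_se: float | None
    f_test: float
    randomization: dict[str, RandomizationResult] = field(default_factory=dict)

    def normal_areas(self) -> dict[str, float]:
        return {stat: normal_area_percent(res.z_score)
                for stat, res in self.randomization.items()
                if math.isfinite(res.z_score)}

    def to_json(self) -> str:
        d = asdict(self)
        d["normal_areas"] = self.normal_areas()
        d["f_test"] = None if math.isinf(self.f_test) else self.f_test
        for res in d["randomization"].values():
            if math.isinf(res["z_score"]):
                res["z_score"] = None
        return json.dumps(d, indent=2)

    def to_table(self) -> pd.DataFrame:
        """Flat one-row table in the style of published randomization summaries."""
        row: dict[str, float] = {}
        for stat, res in self.randomization.items():
            label = {"r2": "r2", "q2": "q2", "pred_r2": "Pred r2"}[stat]
            row[f"ZScore {label}"] = res.z_score
            row[f"Best Rand {label}"] = res.best_random
            row[f"p Rand {label}"] = res.p_empirical
        return pd.DataFrame([row])


def _se_of_errors(errors: np.ndarray, df: int) -> float:
    return math.sqrt(float(np.sum(errors ** 2)) / df)


def validate_model(
    m: DescriptorMatrix,
    split: SplitSpec,
    model: QSARModel,
    recipe: ModelRecipe = ModelRecipe(),
    n_permutations: int = 100,
    seed: int = 42,
    run_randomization: bool = True,
) -> ValidationReport:
    """Compute the full validation report for a fitted model on a split."""
    train_sub = m.subset(list(split.train_ids))
    n, k = len(train_sub.y), len(model.descriptor_names)
    preds = model.predict(train_sub.X)
    pset = PredictionSet(train_sub.y.to_numpy(), preds,
                         model.training_mean_activity)
    fit = fit_statistics(pset, k)
    # LOO predictions for q2 and its standard error
    recipe_fixed = ModelRecipe(recipe.max_descriptors, model.n_components,
                               recipe.max_components, recipe.reselect_per_fold)
    q2 = q_squared_loo(m, SplitSpec.from_lists(split.train_ids, ()),
                       model.descriptor_names, recipe_fixed)
    y = train_sub.y.to_numpy()
    sst = float(np.sum((y - y.mean()) ** 2))
    q2_se = math.sqrt(max(0.0, (1.0 - q2) * sst) / fit.degrees_of_freedom)
    pred_r2 = pred_r2_se = None
    if split.test_ids:
        pred_r2 = pred_r_squared(model, m, split)
        test_sub = m.subset(list(split.test_ids))
        errs = test_sub.y.to_numpy() - model.predict(test_sub.X)
        pred_r2_se = _se_of_errors(errs, max(1, len(errs) - 1))
    randomization = {}
    if run_randomization:
        randomization = y_randomization(m, split, recipe_fixed,
                                        n_permutations=n_permutations, seed=seed)
    return ValidationReport(
        n=n, k=k, degrees_of_freedom=fit.degrees_of_freedom,
        n_components=model.n_components,
        r2=fit.r2, q2=q2, pred_r2=pred_r2,
        r2_se=fit.se, q2_se=q2_se, pred_r2_se=pred_r2_se,
        f_test=fit.f_test, randomization=randomization)
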