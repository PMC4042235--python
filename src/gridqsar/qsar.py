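"""Dataset splitting, stepwise-forward descriptor selection and PLS modelling.

The modelling core follows scikit-learn estimator conventions:

* :class:`StepwiseForwardSelector` — greedy forward descriptor selection,
  scored by leave-one-out cross-validated q2 on the training set;
* :class:`PLSQSARRegressor` — partial least squares on mean-centered (not
  autoscaled) descriptors, with the latent-component count chosen by LOO q2,
  exported as an equivalent linear equation on the original descriptor scale.

Field descriptors share kcal/mol units, which is why centering without
autoscaling is the default: column variances carry physical meaning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_is_fitted

from .fields import DescriptorMatrix


# ---------------------------------------------------------------------------
# Splits and unicolumn statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnicolumnStats:
    """Per-set summary of the dependent variable (pIC50)."""

    average: float
    max: float
    min: float
    std_dev: float
    sum: float

    def as_row(self) -> dict[str, float]:
        return {"Average": self.average, "Max": self.max, "Min": self.min,
                "Std Dev": self.std_dev, "Sum": self.sum}


def unicolumn_stats(values: Sequence[float]) -> UnicolumnStats:
    """Average, max, min, sample standard deviation and sum of a value set."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute unicolumn statistics of an empty set")
    std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return UnicolumnStats(float(arr.mean()), float(arr.max()),
                          float(arr.min()), std, float(arr.sum()))


def check_split_interpolative(
    train: Sequence[float], test: Sequence[float]
) -> tuple[bool, list[str]]:
    """Check that the test set lies strictly inside the training activity
    range (max(train) > max(test) and min(test) > min(train)), the usual
    requirement for an interpolative external test set."""
    if len(train) == 0 or len(test) == 0:
        raise ValueError("train and test must both be nonempty")
    messages: list[str] = []
    if not max(train) > max(test):
        messages.append(
            f"max(train)={max(train):g} is not greater than max(test)={max(test):g}")
    if not min(test) > min(train):
        messages.append(
            f"min(test)={min(test):g} is not greater than min(train)={min(train):g}")
    return (not messages), messages


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint training / external-test compound id lists."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)}")
        if not self.train_ids:
            raise ValueError("training set is empty")

    @classmethod
    def from_lists(cls, train_ids: Sequence[str], test_ids: Sequence[str]) -> "SplitSpec":
        return cls(tuple(train_ids), tuple(test_ids))


def split_interpolative(
    m: DescriptorMatrix, n_test: int, seed: int = 42
) -> SplitSpec:
    """Automated stand-in for manual test-set selection.

    Picks ``n_test`` compounds at activity quantiles strictly inside the
    range, so the resulting split passes :func:`check_split_interpolative`.
    Deterministic for a fixed matrix and seed (the seed only breaks ties
    among equal activities).
    """
    ids = np.array(m.compound_ids)
    y = m.y.to_numpy()
    if n_test < 1 or n_test > len(ids) - 2:
        raise ValueError("n_test must leave at least two training compounds")
    rng = np.random.default_rng(seed)
    order = np.lexsort((rng.random(len(y)), y))
    # interior quantile positions, never the global min or max
    interior = order[1:-1]
    pos = np.linspace(0, len(interior) - 1, n_test).round().astype(int)
    test_idx = sorted(set(interior[pos].tolist()))
    test = [str(ids[i]) for i in test_idx]
    train = [str(i) for i in ids if i not in set(test)]
    return SplitSpec.from_lists(train, test)


def split_sphere_exclusion(
    m: DescriptorMatrix, radius_factor: float = 1.0, seed: int = 42
) -> SplitSpec:
    """Sphere-exclusion split in standardized descriptor space: greedily pick
    training representatives, excluding neighbours within a data-scaled
    radius; excluded compounds form the test set."""
    X = m.X.to_numpy()
    sd = X.std(axis=0, ddof=1)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n = len(m.compound_ids)
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(Z))
    radius = radius_factor * np.median(D[D > 0]) if n > 1 else 1.0
    rng = np.random.default_rng(seed)
    remaining = list(rng.permutation(n))
    train_idx: list[int] = []
    test_idx: list[int] = []
    while remaining:
        i = remaining.pop(0)
        train_idx.append(i)
        near = [j for j in remaining if D[i, j] < radius]
        test_idx.extend(near)
        remaining = [j for j in remaining if j not in set(near)]
    ids = m.compound_ids
    return SplitSpec.from_lists([ids[i] for i in sorted(train_idx)],
                                [ids[i] for i in sorted(test_idx)])


# ---------------------------------------------------------------------------
# LOO q2 helpers (shared with validation)
# ---------------------------------------------------------------------------

def _ols_loo_q2(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out q2 of an OLS fit, via the PRESS identity
    ``e_loo = e / (1 - h_ii)`` (exact, no refitting)."""
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    Q, _ = np.linalg.qr(A)
    h = np.sum(Q * Q, axis=1)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    denom_h = 1.0 - h
    if np.any(denom_h < 1e-10):
        return -np.inf
    press = float(np.sum((resid / denom_h) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise ValueError("constant activities: q2 undefined")
    return 1.0 - press / sst


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class StepwiseForwardSelector(TransformerMixin, BaseEstimator):
    """Greedy forward descriptor selection scored by LOO cross-validated q2.

    Starting from the empty set, each step adds the candidate descriptor that
    maximizes the LOO q2 of a full-rank linear fit on the selected columns
    plus the candidate; selection stops at ``max_descriptors`` or when no
    addition improves q2.  With ``refine=True`` (default) a replacement pass
    follows: each selected descriptor is tentatively swapped against every
    remaining candidate and the best strictly improving swap applied, until
    stable — the usual escape from greedy local optima when grid columns are
    collinear.  Ties are broken toward the lower column index, so selection
    is deterministic for a fixed matrix.

    Attributes
    ----------
    selected_ : list of str
        Names of the selected columns, in selection order.
    support_ : ndarray of bool
        Mask of selected columns.
    q2_path_ : list of float
        LOO q2 after each accepted addition.
    q2_ : float
        LOO q2 of the final selection.
    """

    def __init__(self, max_descriptors: int = 4, min_improvement: float = 0.0,
                 refine: bool = True, max_refine_sweeps: int = 10):
        self.max_descriptors = max_descriptors
        self.min_improvement = min_improvement
        self.refine = refine
        self.max_refine_sweeps = max_refine_sweeps

    def fit(self, X, y):
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        Xv = X_df.to_numpy(dtype=float)
        yv = np.asarray(y, dtype=float)
        n, p = Xv.shape
        if p < 1:
            raise ValueError("need at least one candidate descriptor")
        if self.max_descriptors < 1:
            raise ValueError("max_descriptors must be >= 1")
        if n < self.max_descriptors + 2:
            raise ValueError(
                f"need at least max_descriptors + 2 = {self.max_descriptors + 2} "
                f"training rows, got {n}")
        selected: list[int] = []
        q2_path: list[float] = []
        current = -np.inf
        while len(selected) < self.max_descriptors:
            best_j, best_q2 = -1, -np.inf
            for j in range(p):
                if j in selected:
                    continue
                q2 = _ols_loo_q2(Xv[:, selected + [j]], yv)
                if q2 > best_q2 + 1e-12:  # strict improvement; ties keep lower j
                    best_j, best_q2 = j, q2
            if best_j < 0:
                if selected:
                    break
                raise ValueError("no candidate descriptor admits a LOO fit")
            if selected and best_q2 <= current + self.min_improvement:
                break
            selected.append(best_j)
            q2_path.append(best_q2)
            current = best_q2
        if self.refine and len(selected) > 1:
            for _ in range(self.max_refine_sweeps):
                improved = False
                for pos in range(len(selected)):
                    best_j, best_q2 = -1, current
                    for j in range(p):
                        if j in selected:
                            continue
                        cand = selected.copy()
                        cand[pos] = j
                        q2 = _ols_loo_q2(Xv[:, cand], yv)
                        if q2 > best_q2 + 1e-9:
                            best_j, best_q2 = j, q2
                    if best_j >= 0:
                        selected[pos] = best_j
                        current = best_q2
                        improved = True
                if not improved:
                    break
        self.q2_ = current
        self.n_features_in_ = p
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[selected] = True
        self.selected_idx_ = list(selected)
        self.selected_ = [str(X_df.columns[j]) for j in selected]
        self.q2_path_ = q2_path
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X[self.selected_]
        return np.asarray(X)[:, self.selected_idx_]


class PLSQSARRegressor(RegressorMixin, BaseEstimator):
    """Partial least squares QSAR regressor on mean-centered descriptors.

    ``n_components=None`` selects the component count in ``1..max_components``
    that maximizes LOO q2 ("optimum component").  After fitting, the model is
    available as an equivalent linear equation on the original descriptor
    scale (``coef_``, ``intercept_``), which is how grid-field QSAR equations
    are conventionally reported.
    """

    def __init__(self, n_components: int | None = None,
                 max_components: int | None = None):
        self.n_components = n_components
        self.max_components = max_components

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _fit_pls(X: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, float]:
        """Fit centered PLS with k components; return (coef, intercept)."""
        if np.ptp(y) == 0.0:
            return np.zeros(X.shape[1]), float(y[0])
        pls = PLSRegression(n_components=k, scale=False)
        pls.fit(X, y)
        coef = np.asarray(pls.coef_).reshape(-1)
        intercept = float(y.mean() - X.mean(axis=0) @ coef)
        return coef, intercept

    @classmethod
    def _loo_q2(cls, X: np.ndarray, y: np.ndarray, k: int) -> float:
        n = len(y)
        press = 0.0
        for i in range(n):
            mask = np.arange(n) != i
            coef, intercept = cls._fit_pls(X[mask], y[mask], k)
            press += (y[i] - (X[i] @ coef + intercept)) ** 2
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst <= 0:
            raise ValueError("constant activities: q2 undefined")
        return 1.0 - press / sst

    def fit(self, X, y):
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        Xv = X_df.to_numpy(dtype=float)
        yv = np.asarray(y, dtype=float)
        n, p = Xv.shape
        if p < 1:
            raise ValueError("no descriptors to fit")
        cap = min(p, n - 1)
        if self.max_components is not None:
            cap = min(cap, self.max_components)
        if self.n_components is not None:
            if not 1 <= self.n_components <= p:
                raise ValueError("n_components must be in 1..n_descriptors")
            k = self.n_components
            self.component_q2_path_ = None
        elif np.ptp(yv) == 0.0 or cap == 1:
            k = 1
            self.component_q2_path_ = None
        else:
            path = [(kk, self._loo_q2(Xv, yv, kk)) for kk in range(1, cap + 1)]
            k = max(path, key=lambda t: t[1])[0]
            self.component_q2_path_ = path
        coef, intercept = self._fit_pls(Xv, yv, k)
        if not np.all(np.isfinite(coef)) or not math.isfinite(intercept):
            raise FloatingPointError(
                "PLS produced non-finite coefficients (rank-deficient or "
                "degenerate descriptor block)")
        self.n_features_in_ = p
        self.feature_names_in_ = np.array([str(c) for c in X_df.columns])
        self.coef_ = coef
        self.intercept_ = intercept
        self.n_components_ = k
        self.training_mean_activity_ = float(yv.mean())
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names_in_)]
        Xv = np.asarray(X, dtype=float)
        return Xv @ self.coef_ + self.intercept_

    def to_qsar_model(self) -> "QSARModel":
        check_is_fitted(self, "coef_")
        return QSARModel(
            descriptor_names=[str(n) for n in self.feature_names_in_],
            coefficients=[float(c) for c in self.coef_],
            intercept=float(self.intercept_),
            n_components=int(self.n_components_),
            training_mean_activity=float(self.training_mean_activity_),
        )


# ---------------------------------------------------------------------------
# Model equation
# ---------------------------------------------------------------------------

@dataclass
class QSARModel:
    """A fitted grid-field QSAR model as a linear equation.

    ``pIC50 = intercept + sum_i coefficient_i * descriptor_i`` with
    descriptors on their original (kcal/mol) scale.
    """

    descriptor_names: list[str]
    coefficients: list[float]
    intercept: float
    n_components: int
    training_mean_activity: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.descriptor_names) != len(self.coefficients):
            raise ValueError("descriptor_names and coefficients length mismatch")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        vals = list(self.coefficients) + [self.intercept]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("model has non-finite values")

    def predict(self, values: Mapping[str, float] | pd.DataFrame | pd.Series):
        """Evaluate the equation; raises KeyError naming any missing descriptor."""
        if isinstance(values, pd.DataFrame):
            missing = [n for n in self.descriptor_names if n not in values.columns]
            if missing:
                raise KeyError(f"missing descriptor(s): {missing}")
            X = values[self.descriptor_names].to_numpy(dtype=float)
            return X @ np.asarray(self.coefficients) + self.intercept
        missing = [n for n in self.descriptor_names if n not in values]
        if missing:
            raise KeyError(f"missing descriptor(s): {missing}")
        return float(self.intercept + sum(
            c * float(values[n]) for n, c in zip(self.descriptor_names,
                                                 self.coefficients)))

    def to_json(self) -> str:
        return json.dumps({
            "descriptors": [{"name": n, "coefficient": c}
                            for n, c in zip(self.descriptor_names, self.coefficients)],
            "intercept": self.intercept,
            "n_components": self.n_components,
            "training_mean": self.training_mean_activity,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "QSARModel":
        d = json.loads(text)
        return cls(
            descriptor_names=[e["name"] for e in d["descriptors"]],
            coefficients=[float(e["coefficient"]) for e in d["descriptors"]],
            intercept=float(d["intercept"]),
            n_components=int(d.get("n_components", 1)),
            training_mean_activity=float(d.get("training_mean", float("nan"))),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "QSARModel":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Functional wrappers (thin, over the estimators)
# ---------------------------------------------------------------------------

def stepwise_forward_select(
    m: DescriptorMatrix,
    train: SplitSpec,
    max_descriptors: int = 4,
) -> list[str]:
    """Greedy forward selection of descriptors on the training rows."""
    sub = m.subset(train.train_ids)
    sel = StepwiseForwardSelector(max_descriptors=max_descriptors)
    sel.fit(sub.X, sub.y)
    return sel.selected_


def fit_pls(
    m: DescriptorMatrix,
    train: SplitSpec,
    selected: Sequence[str],
    max_components: int | None = None,
    n_components: int | None = None,
) -> QSARModel:
    """Fit centered PLS on the selected descriptors of the training rows and
    export the equivalent linear equation."""
    if not selected:
        raise ValueError("no descriptors selected")
    sub = m.subset(train.train_ids)
    reg = PLSQSARRegressor(n_components=n_components, max_components=max_components)
    reg.fit(sub.X[list(selected)], sub.y)
    return reg.to_qsar_model()


def predict(model: QSARModel, descriptor_values: Mapping[str, float]) -> float:
    """Evaluate a QSAR equation at named descriptor values."""
    return model.predict(descriptor_values)


def contribution_percentages(
    model: QSARModel,
    m: DescriptorMatrix,
    train_ids: Sequence[str] | None = None,
) -> dict[str, float]:
    """Signed contribution of each model descriptor.

    ``contribution_i = 100 * c_i * range_i / sum_j |c_j * range_j|`` where
    ``range_i`` is the descriptor's training-set range; absolute values sum
    to 100.
    """
    X = m.X if train_ids is None else m.subset(list(train_ids)).X
    missing = [n for n in model.descriptor_names if n not in X.columns]
    if missing:
        raise KeyError(f"model descriptor(s) not in matrix: {missing}")
    products = {}
    for name, c in zip(model.descriptor_names, model.coefficients):
        rng = float(X[name].max() - X[name].min())
        products[name] = c * rng
    total = sum(abs(v) for v in products.values())
    if total <= 0:
        raise ValueError("all coefficient x range products are zero")
    return {n: 100.0 * v / total for n, v in products.items()}
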