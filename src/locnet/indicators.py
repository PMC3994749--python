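"""One-vs-rest indicator estimators.

Every Bayesian network classifier conditions on hard 0/1 estimates of the
*other* locations' indicators.  Those estimates come from q binary SVMs
(RBF kernel by default), one per location, each trained to separate
proteins localizing to that compartment from the rest.

The fitted decision rule is stored explicitly (support vectors, dual
coefficients, intercept, standardization constants) so that predictions
are a pure deterministic function of the stored numbers and survive a
plain-text model round-trip exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import EstimatorConfig
from .dataset import MultiLocDataset

__all__ = [
    "SvmIndicator",
    "ConstantIndicator",
    "IndicatorEstimatorSet",
    "fit_indicator_estimators",
    "estimate_indicators",
]


@dataclass
class SvmIndicator:
    """A trained margin classifier in explicit form.

    predict(X) = 1 iff  sum_s dual_s * exp(-gamma ||x' - sv_s||^2) + b > 0
    (linear kernel: dual . (x' . sv_s) instead), with x' the standardized
    feature row.
    """

    mean: np.ndarray
    scale: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    kernel: str = "rbf"

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.mean) / self.scale
        sv = self.support_vectors
        if self.kernel == "rbf":
            d2 = (
                (Xs**2).sum(axis=1)[:, None]
                + (sv**2).sum(axis=1)[None, :]
                - 2.0 * Xs @ sv.T
            )
            K = np.exp(-self.gamma * np.maximum(d2, 0.0))
        elif self.kernel == "linear":
            K = Xs @ sv.T
        else:  # pragma: no cover - rejected at fit time
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        return K @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(np.int8)


@dataclass
class ConstantIndicator:
    """Degenerate estimator for a location with a single training class."""

    value: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.value, dtype=np.int8)


@dataclass
class IndicatorEstimatorSet:
    """q fitted estimators, ordered as the location vocabulary."""

    estimators: list
    config: EstimatorConfig
    feature_dim: int

    def __len__(self) -> int:
        return len(self.estimators)


def _fit_one(X: np.ndarray, y: np.ndarray, config: EstimatorConfig, name: str):
    classes = np.unique(y)
    if len(classes) < 2:
        value = int(classes[0])
        warnings.warn(
            f"location {name!r} has a single training class ({value}); "
            "its estimator degenerates to that constant",
            stacklevel=3,
        )
        return ConstantIndicator(value)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    svc = SVC(
        kernel=config.kernel,
        C=config.C,
        gamma=config.gamma,
        class_weight=config.class_weight,
        random_state=config.seed,
    ).fit(Xs, y)
    return SvmIndicator(
        mean=scaler.mean_.copy(),
        scale=scaler.scale_.copy(),
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        gamma=float(svc._gamma) if config.kernel == "rbf" else 0.0,
        kernel=config.kernel,
    )


def fit_indicator_estimators(
    dataset: MultiLocDataset, config: EstimatorConfig | None = None
) -> IndicatorEstimatorSet:
    """Train one binary estimator per location on the dataset's features."""
    config = config or EstimatorConfig()
    if not dataset.is_labeled:
        raise ValueError("fitting indicator estimators requires labels")
    if config.kernel not in ("rbf", "linear"):
        raise ValueError(f"unsupported kernel {config.kernel!r}")
    estimators = [
        _fit_one(dataset.X, dataset.Y[:, i], config, dataset.vocabulary.names[i])
        for i in range(dataset.q)
    ]
    return IndicatorEstimatorSet(estimators, config, dataset.d)


def estimate_indicators(estimators: IndicatorEstimatorSet, X) -> np.ndarray:
    """Hard 0/1 indicator estimates, one q-vector per feature row."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature rows must form a 2-d array")
    if X.shape[1] != estimators.feature_dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the "
            f"estimators' training dimension {estimators.feature_dim}"
        )
    if len(X) == 0:
        return np.zeros((0, len(estimators)), dtype=np.int8)
    return np.column_stack([e.predict(X) for e in estimators.estimators])


def cross_fit_estimates(
    dataset: MultiLocDataset, config: EstimatorConfig, n_splits: int = 5
) -> np.ndarray:
    """Out-of-fold training-set indicator estimates (optional mode)."""
    out = np.zeros((dataset.m, dataset.q), dtype=np.int8)
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
    for train_idx, test_idx in kf.split(dataset.X):
        est = fit_indicator_estimators(dataset.subset(train_idx), config)
        out[test_idx] = estimate_indicators(est, dataset.X[test_idx])
    return out
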