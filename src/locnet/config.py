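"""Configuration dataclasses and YAML round-trip.

Sections mirror the pipeline stages: ``estimator`` (the one-vs-rest SVM
indicator estimators), ``search`` (CLL hill climbing), and ``cv``
(cross-validation harness).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["EstimatorConfig", "SearchConfig", "CVConfig", "TrainConfig"]


@dataclass(frozen=True)
class EstimatorConfig:
    """Settings for the per-location indicator estimators.

    kernel : 'rbf' or 'linear'
    C : SVM regularization constant
    gamma : RBF width; 'scale' uses sklearn's 1/(d * Var(X)) rule
    class_weight : None or 'balanced'
    features : 'raw' (standardized continuous features, default) or
        'discrete' (integer codes from the fitted discretizer)
    cross_fit : if True, training-set indicator estimates are produced
        out-of-fold by an internal 5-fold split instead of in-sample
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"
    class_weight: str | None = None
    features: str = "raw"
    cross_fit: bool = False
    seed: int = 0


@dataclass(frozen=True)
class SearchConfig:
    """Settings for the greedy CLL structure search.

    alpha : pseudo-count added to every CPT cell
    epsilon : minimum score improvement to apply a move (numerical guard)
    max_iters : hard cap on hill-climbing iterations
    max_parents : optional cap on any node's parent count (CPT memory guard)
    penalty : 'bic' (default) subtracts (log m / 2) * k from the CLL, with
        k the free-parameter count of the factors entering the target's
        conditional; 'none' climbs the raw CLL, which in-sample accepts
        almost every edge and overfits
    location_cpts_from : 'true' fits location-node CPTs from true labels
        (default); 'estimated' fits them from the SVM indicator estimates
    """

    alpha: float = 1.0
    epsilon: float = 1e-9
    max_iters: int = 500
    max_parents: int | None = None
    penalty: str = "bic"
    location_cpts_from: str = "true"


@dataclass(frozen=True)
class CVConfig:
    runs: int = 5
    folds: int = 5


@dataclass(frozen=True)
class TrainConfig:
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "TrainConfig":
        data = dict(data or {})
        est = EstimatorConfig(**(data.pop("estimator", {}) or {}))
        search = SearchConfig(**(data.pop("search", {}) or {}))
        cv = CVConfig(**(data.pop("cv", {}) or {}))
        return cls(estimator=est, search=search, cv=cv, **data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def with_seed(self, seed: int) -> "TrainConfig":
        return dataclasses.replace(
            self,
            seed=seed,
            estimator=dataclasses.replace(self.estimator, seed=seed),
        )
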