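"""End-to-end training and multi-location prediction pipeline.

Training runs the stages in order: fit the MDLP discretizer, code the
features, train the q one-vs-rest indicator SVMs, produce training-set
indicator estimates, and hill-climb one Bayesian network classifier per
location.  Prediction estimates the indicators for a query protein with
the SVMs, then lets every per-location network compute
Pr(L_i = 1 | features, other-location estimates) and thresholds at 0.5
(strictly greater predicts 1; the all-zero prediction is legal output).
"""

from __future__ import annotations

import json
import logging

import numpy as np

from .bayesnet import BNClassifier, CPT, CPTSet, NetworkStructure, target_posterior
from .config import TrainConfig
from .dataset import LocationVocabulary, MultiLocDataset
from .discretize import CutpointMap, apply_discretizer, fit_discretizer
from .indicators import (
    ConstantIndicator,
    IndicatorEstimatorSet,
    SvmIndicator,
    cross_fit_estimates,
    estimate_indicators,
    fit_indicator_estimators,
)
from .search import SearchTrace, hill_climb

__all__ = ["MultiLocModel", "train", "predict", "predict_proba",
           "save_model", "load_model"]

MODEL_FORMAT_VERSION = "locnet-model-v1"

logger = logging.getLogger("locnet")


class MultiLocModel:
    """A trained multi-location predictor: discretizer + SVMs + q networks."""

    def __init__(self, vocabulary, feature_names, cutpoints, estimators,
                 classifiers, config, traces=None):
        self.vocabulary = vocabulary
        self.feature_names = list(feature_names)
        self.cutpoints: CutpointMap = cutpoints
        self.estimators: IndicatorEstimatorSet = estimators
        self.classifiers: list[BNClassifier] = classifiers
        self.config: TrainConfig = config
        self.traces: list[SearchTrace] | None = traces
        targets = sorted(c.target for c in classifiers)
        if targets != list(range(len(vocabulary))):
            raise ValueError("need exactly one classifier per location")

    @property
    def q(self) -> int:
        return len(self.vocabulary)

    @property
    def d(self) -> int:
        return len(self.feature_names)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        def est_obj(e):
            if isinstance(e, ConstantIndicator):
                return {"type": "constant", "value": int(e.value)}
            return {
                "type": "svm",
                "kernel": e.kernel,
                "mean": e.mean.tolist(),
                "scale": e.scale.tolist(),
                "support_vectors": e.support_vectors.tolist(),
                "dual_coef": e.dual_coef.tolist(),
                "intercept": e.intercept,
                "gamma": e.gamma,
            }

        def clf_obj(c: BNClassifier):
            st = c.structure
            return {
                "target": c.target,
                "edges": [
                    [st.node_name(u), st.node_name(v)] for u, v in st.edges()
                ],
                "alpha": c.cpts.alpha,
                "arities": list(c.cpts.arities),
                "cpts": {
                    st.node_name(v): {
                        "parents": [st.node_name(p) for p in cpt.parents],
                        "shape": list(cpt.table.shape),
                        "table": cpt.table.ravel().tolist(),
                    }
                    for v, cpt in sorted(c.cpts.tables.items())
                },
            }

        obj = {
            "format": MODEL_FORMAT_VERSION,
            "locations": list(self.vocabulary.names),
            "feature_names": self.feature_names,
            "cutpoints": {
                "boundaries": [b.tolist() for b in self.cutpoints.boundaries],
                "ranges": [list(r) for r in self.cutpoints.ranges],
            },
            "estimators": [est_obj(e) for e in self.estimators.estimators],
            "classifiers": [clf_obj(c) for c in
                            sorted(self.classifiers, key=lambda c: c.target)],
            "config": self.config.to_dict(),
        }
        return json.dumps(obj, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "MultiLocModel":
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupt model file: {exc}") from exc
        if not isinstance(obj, dict) or "format" not in obj:
            raise ValueError("corrupt model file: missing format tag")
        if obj["format"] != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format {obj['format']!r}; "
                f"this build reads {MODEL_FORMAT_VERSION!r}"
            )
        vocab = LocationVocabulary(tuple(obj["locations"]))
        feature_names = list(obj["feature_names"])
        cutpoints = CutpointMap(
            feature_names,
            [np.array(b, dtype=float) for b in obj["cutpoints"]["boundaries"]],
            [tuple(r) for r in obj["cutpoints"]["ranges"]],
        )
        config = TrainConfig.from_dict(obj["config"])

        def est_from(o):
            if o["type"] == "constant":
                return ConstantIndicator(o["value"])
            return SvmIndicator(
                mean=np.array(o["mean"], dtype=float),
                scale=np.array(o["scale"], dtype=float),
                support_vectors=np.array(o["support_vectors"], dtype=float),
                dual_coef=np.array(o["dual_coef"], dtype=float),
                intercept=float(o["intercept"]),
                gamma=float(o["gamma"]),
                kernel=o["kernel"],
            )

        estimators = IndicatorEstimatorSet(
            [est_from(o) for o in obj["estimators"]],
            config.estimator,
            len(feature_names),
        )

        def clf_from(o):
            st = NetworkStructure(feature_names, list(vocab.names))
            parents = [[] for _ in range(st.n_nodes)]
            for u_name, v_name in o["edges"]:
                parents[st.node_index(v_name)].append(st.node_index(u_name))
            st = NetworkStructure(feature_names, list(vocab.names), parents)
            tables = {}
            for name, t in o["cpts"].items():
                v = st.node_index(name)
                tables[v] = CPT(
                    tuple(st.node_index(p) for p in t["parents"]),
                    np.array(t["table"], dtype=float).reshape(t["shape"]),
                )
            cpts = CPTSet(tables, o["alpha"], tuple(o["arities"]))
            return BNClassifier(o["target"], st, cpts)

        classifiers = [clf_from(o) for o in obj["classifiers"]]
        return cls(vocab, feature_names, cutpoints, estimators, classifiers, config)


def train(dataset: MultiLocDataset, config: TrainConfig | None = None) -> MultiLocModel:
    """Train the full multi-location model on a labeled dataset."""
    config = config or TrainConfig()
    if not dataset.is_labeled:
        raise ValueError("training requires a labeled dataset")

    logger.info("fitting discretizer on %d records, %d features",
                dataset.m, dataset.d)
    cutpoints = fit_discretizer(dataset)
    coded = apply_discretizer(cutpoints, dataset)

    est_input = coded if config.estimator.features == "discrete" else dataset
    logger.info("fitting %d indicator estimators (%s features)",
                dataset.q, config.estimator.features)
    estimators = fit_indicator_estimators(est_input, config.estimator)
    if config.estimator.cross_fit:
        estimates = cross_fit_estimates(est_input, config.estimator)
    else:
        estimates = estimate_indicators(estimators, est_input.X)

    classifiers, traces = [], []
    for i in range(dataset.q):
        clf, trace = hill_climb(coded, estimates, i, config.search)
        logger.info(
            "target %s: %d moves, final CLL %.3f",
            dataset.vocabulary.names[i], trace.iterations, trace.final_cll,
        )
        classifiers.append(clf)
        traces.append(trace)
    return MultiLocModel(dataset.vocabulary, dataset.feature_names, cutpoints,
                         estimators, classifiers, config, traces)


def _query_matrices(model: MultiLocModel, proteins) -> tuple[np.ndarray, np.ndarray]:
    X = proteins.X if isinstance(proteins, MultiLocDataset) else np.asarray(
        proteins, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.d:
        raise ValueError(
            f"query features must be (n, {model.d}); got {X.shape}"
        )
    codes = model.cutpoints.transform(X)
    est_X = codes if model.config.estimator.features == "discrete" else X
    estimates = estimate_indicators(model.estimators, est_X)
    return codes, estimates


def predict_proba(model: MultiLocModel, proteins) -> np.ndarray:
    """Per protein, the q per-location posterior probabilities."""
    codes, estimates = _query_matrices(model, proteins)
    proba = np.empty((len(codes), model.q))
    for clf in sorted(model.classifiers, key=lambda c: c.target):
        proba[:, clf.target] = target_posterior(clf, codes, estimates)
    return proba


def predict(model: MultiLocModel, proteins) -> np.ndarray:
    """Per protein, the hard q-vector of 0/1 location indicators."""
    return (predict_proba(model, proteins) > 0.5).astype(np.int8)


def baseline_predict(model: MultiLocModel, proteins) -> np.ndarray:
    """Indicator-estimator (SVM-only) predictions, for baseline comparisons."""
    _, estimates = _query_matrices(model, proteins)
    return estimates


def save_model(model: MultiLocModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(model.to_json())
        fh.write("\n")


def load_model(path) -> MultiLocModel:
    with open(path, "r", encoding="utf-8") as fh:
        return MultiLocModel.from_json(fh.read())
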