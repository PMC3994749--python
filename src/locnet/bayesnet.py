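"""Bayesian network classifier core: structure, CPTs, inference, CLL.

A classifier for target location L_i is a DAG over the d (discretized)
feature variables F_1..F_d and the q location variables L_1..L_q, with no
edges between two feature nodes, plus one conditional probability table
per node.  The joint factorizes as

    Pr(F_1..F_d, L_1..L_q) = prod_v Pr(v | Pa(v)),

and the quantity the classifier computes for a query protein is

    Pr(L_i = 1 | features, estimated other indicators)
        = J(1) / (J(0) + J(1)),

where J(z) is the joint with L_i = z and everything else fixed.  Since
exactly one variable is free, the ratio depends only on the factors that
contain L_i (its own CPT and those of its children); both the reduced and
the full-factorization computation are implemented and must agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import MultiLocDataset

__all__ = [
    "NetworkStructure",
    "CPT",
    "CPTSet",
    "BNClassifier",
    "fit_parameters",
    "joint_log_prob",
    "conditional_prob_target",
    "cll_score",
]

_LOG_FLOOR = np.log(1e-300)


class NetworkStructure:
    """DAG over feature and location nodes with per-node parent sets.

    Nodes are integers: 0..d-1 are features, d..d+q-1 are locations.
    Feature-feature edges are forbidden in either direction.
    """

    def __init__(self, feature_names, location_names, parents=None):
        self.feature_names = list(feature_names)
        self.location_names = list(location_names)
        self.d = len(self.feature_names)
        self.q = len(self.location_names)
        self.n_nodes = self.d + self.q
        if parents is None:
            parents = [() for _ in range(self.n_nodes)]
        self.parents = [tuple(sorted(p)) for p in parents]
        if len(self.parents) != self.n_nodes:
            raise ValueError("one parent tuple per node is required")
        self.validate()

    # -- naming --------------------------------------------------------------

    def is_feature(self, v: int) -> bool:
        return v < self.d

    def node_name(self, v: int) -> str:
        return (
            f"F:{self.feature_names[v]}"
            if v < self.d
            else f"L:{self.location_names[v - self.d]}"
        )

    def node_index(self, name: str) -> int:
        kind, _, rest = name.partition(":")
        if kind == "F":
            return self.feature_names.index(rest)
        if kind == "L":
            return self.d + self.location_names.index(rest)
        raise ValueError(f"malformed node name {name!r}")

    # -- graph queries --------------------------------------------------------

    def edges(self) -> list[tuple[int, int]]:
        return sorted((u, v) for v, ps in enumerate(self.parents) for u in ps)

    def has_edge(self, u: int, v: int) -> bool:
        return u in self.parents[v]

    def children(self, u: int) -> list[int]:
        return [v for v in range(self.n_nodes) if u in self.parents[v]]

    def path_exists(self, src: int, dst: int) -> bool:
        """Directed path src -> ... -> dst (length >= 1)."""
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v, ps in enumerate(self.parents):
            for u in ps:
                adj[u].append(v)
        stack, seen = [src], set()
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w == dst:
                    return True
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def validate(self) -> None:
        for v, ps in enumerate(self.parents):
            for u in ps:
                if not (0 <= u < self.n_nodes) or u == v:
                    raise ValueError(f"invalid parent {u} of node {v}")
                if self.is_feature(u) and self.is_feature(v):
                    raise ValueError(
                        "feature-feature edge "
                        f"{self.node_name(u)} -> {self.node_name(v)} is forbidden"
                    )
        # Kahn's algorithm for acyclicity
        indeg = [len(p) for p in self.parents]
        queue = [v for v, k in enumerate(indeg) if k == 0]
        seen = 0
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v, ps in enumerate(self.parents):
            for u in ps:
                adj[u].append(v)
        while queue:
            u = queue.pop()
            seen += 1
            for w in adj[u]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        if seen != self.n_nodes:
            raise ValueError("graph contains a directed cycle")

    # -- copies under edits ----------------------------------------------------

    def with_parents(self, new_parents) -> "NetworkStructure":
        return NetworkStructure(self.feature_names, self.location_names, new_parents)

    def add_edge(self, u: int, v: int) -> "NetworkStructure":
        ps = list(self.parents)
        ps[v] = tuple(sorted(ps[v] + (u,)))
        return self.with_parents(ps)

    def remove_edge(self, u: int, v: int) -> "NetworkStructure":
        ps = list(self.parents)
        ps[v] = tuple(x for x in ps[v] if x != u)
        return self.with_parents(ps)

    def reverse_edge(self, u: int, v: int) -> "NetworkStructure":
        ps = list(self.parents)
        ps[v] = tuple(x for x in ps[v] if x != u)
        ps[u] = tuple(sorted(ps[u] + (v,)))
        return self.with_parents(ps)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, NetworkStructure)
            and self.feature_names == other.feature_names
            and self.location_names == other.location_names
            and self.parents == other.parents
        )

    def __repr__(self) -> str:
        es = ", ".join(
            f"{self.node_name(u)}->{self.node_name(v)}" for u, v in self.edges()
        )
        return f"NetworkStructure(d={self.d}, q={self.q}, edges=[{es}])"


@dataclass
class CPT:
    """Conditional probability table of one node.

    ``table`` has shape (*parent_arities, arity): indexing by the parent
    values yields the conditional distribution over the node's values.
    """

    parents: tuple[int, ...]
    table: np.ndarray

    @property
    def arity(self) -> int:
        return self.table.shape[-1]

    def logp(self, values: np.ndarray, assignment: np.ndarray) -> np.ndarray:
        """log Pr(node = values | parent columns of assignment), vectorized."""
        idx = tuple(assignment[:, p] for p in self.parents) + (values,)
        return np.log(self.table[idx])


@dataclass
class CPTSet:
    """All node CPTs of one network plus the smoothing pseudo-count."""

    tables: dict[int, CPT]
    alpha: float = 1.0
    arities: tuple[int, ...] = field(default_factory=tuple)

    def __getitem__(self, v: int) -> CPT:
        return self.tables[v]


@dataclass
class BNClassifier:
    """One per-location classifier: target index, DAG, CPTs."""

    target: int  # location index (0-based within the vocabulary)
    structure: NetworkStructure
    cpts: CPTSet

    @property
    def target_node(self) -> int:
        return self.structure.d + self.target


# -- parameter learning ----------------------------------------------------


def _data_matrix(dataset: MultiLocDataset) -> np.ndarray:
    if not dataset.is_labeled:
        raise ValueError("parameter fitting requires labels")
    X = dataset.X
    codes = X.astype(np.int64)
    if not np.array_equal(codes, X):
        raise ValueError("features must be integer-coded; run the discretizer first")
    return np.column_stack([codes, dataset.Y.astype(np.int64)])


def _infer_arities(V: np.ndarray, d: int) -> tuple[int, ...]:
    ar = V.max(axis=0) + 1
    ar[d:] = np.maximum(ar[d:], 2)  # locations are always binary
    return tuple(int(a) for a in np.maximum(ar, 1))


def _fit_family(V: np.ndarray, v: int, parents: tuple[int, ...],
                arities, alpha: float) -> CPT:
    shape = tuple(arities[p] for p in parents) + (arities[v],)
    flat_idx = np.ravel_multi_index(
        tuple(V[:, p] for p in parents) + (V[:, v],), shape
    )
    counts = np.bincount(flat_idx, minlength=int(np.prod(shape))).reshape(shape)
    row_tot = counts.sum(axis=-1, keepdims=True)
    if alpha > 0:
        table = (counts + alpha) / (row_tot + alpha * arities[v])
    else:
        empty = row_tot == 0
        if empty.any():
            warnings.warn(
                "unseen parent configuration with alpha=0; "
                "the affected CPT rows are set to uniform",
                stacklevel=3,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            table = counts / row_tot
        table = np.where(empty, 1.0 / arities[v], table)
    return CPT(parents, table)


def fit_parameters(
    structure: NetworkStructure,
    discrete_dataset: MultiLocDataset,
    alpha: float = 1.0,
    arities=None,
) -> CPTSet:
    """Maximum-likelihood CPTs with a uniform pseudo-count alpha per cell.

    theta_v(x | y..) = (n_joint + alpha) / (n_marginal + alpha * arity(v)),
    counted over the training records (locations from the true labels).
    ``arities`` may be supplied (e.g. from the discretizer) so that codes
    unseen in this subset still get table rows; otherwise they are inferred
    as max code + 1 per column.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    V = _data_matrix(discrete_dataset)
    if arities is None:
        arities = _infer_arities(V, discrete_dataset.d)
    arities = tuple(int(a) for a in arities)
    tables = {
        v: _fit_family(V, v, structure.parents[v], arities, alpha)
        for v in range(structure.n_nodes)
    }
    return CPTSet(tables, alpha, arities)


# -- inference -------------------------------------------------------------


def joint_log_prob(classifier: BNClassifier, assignment) -> float:
    """log of the fully factorized joint (Eq. of the model) at a full
    assignment, given as a dict {node name or index: value} or a vector."""
    st = classifier.structure
    if isinstance(assignment, dict):
        vec = np.empty(st.n_nodes, dtype=np.int64)
        filled = np.zeros(st.n_nodes, dtype=bool)
        for key, val in assignment.items():
            v = key if isinstance(key, (int, np.integer)) else st.node_index(key)
            vec[v] = val
            filled[v] = True
        if not filled.all():
            missing = [st.node_name(v) for v in np.where(~filled)[0]]
            raise ValueError(f"assignment misses variables: {', '.join(missing)}")
    else:
        vec = np.asarray(assignment, dtype=np.int64)
        if vec.shape != (st.n_nodes,):
            raise ValueError(f"assignment must cover all {st.n_nodes} variables")
    A = vec[None, :]
    return float(
        sum(
            classifier.cpts[v].logp(np.array([vec[v]]), A)[0]
            for v in range(st.n_nodes)
        )
    )


def _target_log_odds(
    structure: NetworkStructure,
    cpts: CPTSet,
    target_node: int,
    W: np.ndarray,
    reduced: bool = True,
) -> np.ndarray:
    """log J(1) - log J(0) per row of W (target column is overwritten)."""
    nodes = (
        [target_node] + structure.children(target_node)
        if reduced
        else list(range(structure.n_nodes))
    )
    W0 = W.copy()
    W0[:, target_node] = 0
    W1 = W.copy()
    W1[:, target_node] = 1
    delta = np.zeros(len(W), dtype=float)
    for v in nodes:
        cpt = cpts[v]
        delta += cpt.logp(W1[:, v], W1) - cpt.logp(W0[:, v], W0)
    return delta


def target_posterior(
    classifier: BNClassifier,
    feature_codes: np.ndarray,
    estimates: np.ndarray,
    reduced: bool = True,
) -> np.ndarray:
    """Pr(L_target = 1 | features, other-location estimates), vectorized.

    ``estimates`` is an (n, q) 0/1 matrix; its target column is ignored
    (the classifier conditions only on the other locations).
    """
    st = classifier.structure
    feature_codes = np.asarray(feature_codes, dtype=np.int64)
    estimates = np.asarray(estimates, dtype=np.int64)
    if feature_codes.shape[1] != st.d or estimates.shape[1] != st.q:
        raise ValueError("feature/estimate dimensions do not match the network")
    W = np.column_stack([feature_codes, estimates])
    delta = _target_log_odds(st, classifier.cpts, classifier.target_node, W, reduced)
    # p1 = sigmoid(delta), in a form stable for large |delta|; delta is NaN
    # exactly when both joints vanish (possible only with alpha = 0)
    p1 = np.exp(-np.logaddexp(0.0, -delta))
    both_zero = np.isnan(delta)
    if both_zero.any():
        warnings.warn("zero joint probability on both target values; returning 0.5")
        p1 = np.where(both_zero, 0.5, p1)
    return p1


def conditional_prob_target(
    classifier: BNClassifier, features, estimates, reduced: bool = True
) -> float:
    """Single-query convenience wrapper around :func:`target_posterior`."""
    features = np.atleast_2d(np.asarray(features, dtype=np.int64))
    estimates = np.atleast_2d(np.asarray(estimates, dtype=np.int64))
    return float(target_posterior(classifier, features, estimates, reduced)[0])


def cll_score(
    classifier: BNClassifier,
    discrete_dataset: MultiLocDataset,
    estimates: np.ndarray,
    reduced: bool = True,
) -> float:
    """Conditional log likelihood of the true target indicators.

    Sum over records of log Pr(L_i = true value | features, estimated
    other indicators).  Zero-probability terms (possible only with
    alpha = 0) are floored at log(1e-300).
    """
    st = classifier.structure
    V = _data_matrix(discrete_dataset)
    feature_codes = V[:, : st.d]
    y = discrete_dataset.Y[:, classifier.target].astype(np.int64)
    W = np.column_stack([feature_codes, np.asarray(estimates, dtype=np.int64)])
    delta = _target_log_odds(st, classifier.cpts, classifier.target_node, W, reduced)
    # log sigmoid(+-delta), stable
    log_p1 = -np.logaddexp(0.0, -delta)
    log_p0 = -np.logaddexp(0.0, delta)
    terms = np.where(y == 1, log_p1, log_p0)
    if np.isneginf(terms).any():
        warnings.warn("zero-probability CLL terms floored at log(1e-300)")
        terms = np.maximum(terms, _LOG_FLOOR)
    return float(terms.sum())
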