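"""Synthetic multi-location datasets with controllable label dependencies.

No sufficiently large public corpus of single- and multi-localized
proteins with precomputed feature tables is bundled, so every stage of the
package is exercised on generated data.  The generator draws each
protein's location-indicator vector by ancestral sampling from a DAG over
the label variables (all-zero vectors are rejection-resampled, since real
corpora contain none), then emits continuous features whose means shift
with the label configuration — a stand-in for sequence-derived numeric
features, without modeling sequences.

``dependency_strength`` interpolates every child-label CPT between
independence (0: the CPT collapses to a constant marginal) and
near-determinism (1: the CPT equals a hard boolean rule of the parents).
The dependency fixture places part of the label signal *only* in the
inter-label CPTs: two of the five labels carry no feature signal at all
and are driven by their parent labels, so a dependency-blind per-label
baseline is structurally handicapped there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .bayesnet import CPT, CPTSet, NetworkStructure
from .dataset import LocationVocabulary, MultiLocDataset

__all__ = [
    "GeneratorSpec",
    "sample_dataset",
    "dependency_fixture_spec",
    "independence_fixture_spec",
    "paper_shape_fixture",
    "tiny_oracle_network",
    "sample_network",
]


@dataclass
class GeneratorSpec:
    """Full description of one synthetic corpus.

    label_parents[i] lists the parent label indices of label i;
    label_cpts[i] is an array of shape (2,) * n_parents giving
    Pr(L_i = 1 | parent values).  Feature i is Normal with mean
    base_mean[i] + sum_j weights[i, j] * l_j and SD sigma[i].  Features
    flagged in ``bimodal`` get a per-protein random sign on their label
    contribution, producing a symmetric two-band signature when active —
    the shape of non-monotone sequence scores (e.g. a sorting-signal score
    that is extreme in either direction for targeted proteins).
    """

    q: int
    d: int
    n: int
    label_parents: tuple[tuple[int, ...], ...]
    label_cpts: tuple[np.ndarray, ...]
    base_mean: np.ndarray
    weights: np.ndarray  # (d, q)
    sigma: np.ndarray  # (d,)
    seed: int = 0
    dependency_strength: float = field(default=0.0)
    bimodal: np.ndarray | None = None  # (d,) bool
    location_names: tuple[str, ...] | None = None
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.label_parents) != self.q or len(self.label_cpts) != self.q:
            raise ValueError("need parent list and CPT for each of the q labels")
        for i, (ps, cpt) in enumerate(zip(self.label_parents, self.label_cpts)):
            cpt = np.asarray(cpt, dtype=float)
            if cpt.shape != (2,) * len(ps):
                raise ValueError(
                    f"label {i}: CPT shape {cpt.shape} does not match "
                    f"{len(ps)} parents"
                )
            if ((cpt < 0) | (cpt > 1)).any():
                raise ValueError(f"label {i}: CPT entries must lie in [0, 1]")
        g = nx.DiGraph()
        g.add_nodes_from(range(self.q))
        for i, ps in enumerate(self.label_parents):
            g.add_edges_from((p, i) for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("label dependency graph must be acyclic")
        self._topo_order = list(nx.topological_sort(g))
        self.base_mean = np.asarray(self.base_mean, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.weights.shape != (self.d, self.q):
            raise ValueError(
                f"weights must be (d={self.d}, q={self.q}); got {self.weights.shape}"
            )
        if self.base_mean.shape != (self.d,) or self.sigma.shape != (self.d,):
            raise ValueError("base_mean and sigma must have length d")
        if self.bimodal is not None:
            self.bimodal = np.asarray(self.bimodal, dtype=bool)
            if self.bimodal.shape != (self.d,):
                raise ValueError("bimodal flags must have length d")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _sample_labels(spec: GeneratorSpec, rng: np.random.Generator, n: int):
    L = np.zeros((n, spec.q), dtype=np.int8)
    for i in spec._topo_order:
        ps = spec.label_parents[i]
        cpt = np.asarray(spec.label_cpts[i], dtype=float)
        p = cpt[tuple(L[:, list(ps)].T)] if ps else np.full(n, float(cpt))
        L[:, i] = rng.random(n) < p
    return L


def sample_dataset(spec: GeneratorSpec) -> MultiLocDataset:
    """Draw a labeled dataset; all-zero label vectors are resampled."""
    rng = np.random.default_rng(spec.seed)
    L = _sample_labels(spec, rng, spec.n)
    for _ in range(1000):
        zero = np.where(L.sum(axis=1) == 0)[0]
        if zero.size == 0:
            break
        L[zero] = _sample_labels(spec, rng, len(zero))
    else:
        raise RuntimeError(
            "could not draw label vectors with >= 1 positive label; "
            "the label CPTs concentrate on the all-zero configuration"
        )
    shift = L @ spec.weights.T
    if spec.bimodal is not None and spec.bimodal.any():
        cols = np.where(spec.bimodal)[0]
        signs = rng.choice([-1.0, 1.0], size=(spec.n, len(cols)))
        shift[:, cols] *= signs
    X = spec.base_mean + shift + rng.normal(size=(spec.n, spec.d)) * spec.sigma
    loc_names = spec.location_names or tuple(f"loc{i + 1}" for i in range(spec.q))
    feat_names = spec.feature_names or tuple(f"f{i + 1:02d}" for i in range(spec.d))
    ids = [f"P{i + 1:05d}" for i in range(spec.n)]
    return MultiLocDataset(LocationVocabulary(loc_names), ids, X, L, feat_names)


def _interp_cpt(rule: np.ndarray, marginal: float, strength: float) -> np.ndarray:
    """CPT = (1 - s) * marginal + s * boolean rule."""
    rule = np.asarray(rule, dtype=float)
    return (1.0 - strength) * marginal + strength * rule


def dependency_fixture_spec(
    n: int = 2000, dependency_strength: float = 0.95, seed: int = 0
) -> GeneratorSpec:
    """The q=5, d=10 corpus used to probe the value of label dependencies.

    Three "driver" compartments cyt, ex, nuc are independent roots, each
    signalled by one dedicated two-band signature feature: proteins in the
    compartment score at +-3.2 (SD 0.58) on it, others near 0 — the shape
    of a sorting-signal score that is extreme in either direction for
    targeted proteins.  Both learners resolve the drivers almost
    perfectly, so driver prediction cannot contribute to any gap between
    them.

    The two remaining compartments carry no feature signal of their own
    and are driven purely by the label DAG: mem holds proteins found in
    exactly two of the three driver compartments (an interface compartment
    for dually-shuttling proteins), and mi co-occurs with the ex AND nuc
    combination.  ``dependency_strength`` interpolates these rules between
    independence (0: the CPTs collapse to a constant 0.75 marginal, so
    both systems degenerate to the same constant majority prediction) and
    near-determinism (1).  The remaining seven features are pure noise.
    All predictive signal for mem and mi therefore lives in the
    inter-label dependencies.
    """
    q, d = 5, 10
    s = dependency_strength
    base = 0.75
    two_of_three = np.zeros((2, 2, 2))
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                two_of_three[a, b, c] = 1.0 if a + b + c == 2 else 0.0
    and_rule = np.array([[0.0, 0.0], [0.0, 1.0]])
    label_parents = ((), (), (), (0, 1, 2), (1, 2))
    label_cpts = (
        np.array(0.55),
        np.array(0.50),
        np.array(0.45),
        _interp_cpt(two_of_three, base, s),
        _interp_cpt(and_rule, base, s),
    )
    weights = np.zeros((d, q))
    sigma = np.ones(d)
    bimodal = np.zeros(d, dtype=bool)
    for lab in range(3):  # driver label j -> signature feature j
        weights[lab, lab] = 3.2
        sigma[lab] = 0.58
        bimodal[lab] = True
    return GeneratorSpec(
        q=q, d=d, n=n,
        label_parents=label_parents,
        label_cpts=label_cpts,
        base_mean=np.zeros(d),
        weights=weights,
        sigma=sigma,
        seed=seed,
        dependency_strength=s,
        bimodal=bimodal,
        location_names=("cyt", "ex", "nuc", "mem", "mi"),
    )


def independence_fixture_spec(n: int = 2000, seed: int = 0) -> GeneratorSpec:
    """The same corpus with all label CPTs collapsed to their marginals."""
    return dependency_fixture_spec(n=n, dependency_strength=0.0, seed=seed)


# location-combination template loosely shaped like a real mixed corpus of
# single- and double-localized proteins: 9 compartments, singles ~64%,
# doubles ~36%, dominated by a few combinations, strong class imbalance
_SHAPE_LOCATIONS = ("cyt", "ER", "ex", "gol", "lys", "mi", "nuc", "mem", "per")
_SHAPE_COMBOS = (
    (("cyt",), 1411), (("ER",), 198), (("ex",), 843), (("gol",), 150),
    (("lys",), 103), (("mi",), 510), (("nuc",), 837), (("mem",), 1238),
    (("per",), 157),
    (("cyt", "nuc"), 1882), (("ex", "mem"), 334), (("cyt", "mem"), 252),
    (("cyt", "mi"), 240), (("nuc", "mi"), 120), (("ER", "ex"), 115),
    (("ex", "nuc"), 113),
)


def paper_shape_fixture(seed: int, n: int = 1500) -> MultiLocDataset:
    """Scaled-down synthetic corpus mimicking a mixed single/multi corpus.

    q = 9 compartments, d = 30 features, label combinations drawn from a
    fixed template dominated by a few single and double combinations.
    Qualitative shape only; no claim of distributional identity with any
    real corpus.
    """
    rng = np.random.default_rng(seed)
    vocab = LocationVocabulary(_SHAPE_LOCATIONS)
    counts = np.array([c for _, c in _SHAPE_COMBOS], dtype=float)
    probs = counts / counts.sum()
    picks = rng.choice(len(_SHAPE_COMBOS), size=n, p=probs)
    Y = np.zeros((n, len(vocab)), dtype=np.int8)
    for i, c in enumerate(picks):
        Y[i] = vocab.encode(_SHAPE_COMBOS[c][0])
    d = 30
    weights = np.zeros((d, len(vocab)))
    feat_pool = rng.permutation(d)
    for j in range(len(vocab)):  # three dedicated features per compartment
        for f in feat_pool[3 * j: 3 * j + 3]:
            weights[f, j] = rng.normal(1.8, 0.3)
    remaining = feat_pool[3 * len(vocab):]
    for f in remaining:  # weakly mixed features
        weights[f] = rng.normal(0.0, 0.4, size=len(vocab))
    X = Y @ weights.T + rng.normal(size=(n, d))
    ids = [f"P{i + 1:05d}" for i in range(n)]
    feat_names = tuple(f"f{i + 1:02d}" for i in range(d))
    return MultiLocDataset(vocab, ids, X, Y, feat_names)


# -- tiny hand-specified oracle network ------------------------------------


def tiny_oracle_network() -> tuple[NetworkStructure, CPTSet]:
    """Fixed 4-node binary network (2 features, 2 locations) with known CPTs.

    Structure: F:g1 -> L:cyt, F:g2 -> L:nuc, L:cyt -> L:nuc.
    Node order: 0 = F:g1, 1 = F:g2, 2 = L:cyt, 3 = L:nuc.

    Pr(F1=1) = 0.3            Pr(F2=1) = 0.6
    Pr(L1=1 | F1)      = [0.2, 0.8]
    Pr(L2=1 | F2, L1)  = [[0.1, 0.7], [0.4, 0.9]]
    """
    st = NetworkStructure(
        ["g1", "g2"], ["cyt", "nuc"], [(), (), (0,), (1, 2)]
    )
    t_f1 = CPT((), np.array([0.7, 0.3]))
    t_f2 = CPT((), np.array([0.4, 0.6]))
    t_l1 = CPT((0,), np.array([[0.8, 0.2], [0.2, 0.8]]))
    p_l2 = np.array([[0.1, 0.7], [0.4, 0.9]])  # indexed [f2, l1]
    t_l2 = CPT((1, 2), np.stack([1.0 - p_l2, p_l2], axis=-1))
    cpts = CPTSet({0: t_f1, 1: t_f2, 2: t_l1, 3: t_l2}, alpha=0.0,
                  arities=(2, 2, 2, 2))
    return st, cpts


def sample_network(
    structure: NetworkStructure, cpts: CPTSet, n: int, seed: int
) -> np.ndarray:
    """Ancestral samples (n, n_nodes) from an arbitrary discrete network."""
    g = nx.DiGraph()
    g.add_nodes_from(range(structure.n_nodes))
    for v, ps in enumerate(structure.parents):
        g.add_edges_from((p, v) for p in ps)
    rng = np.random.default_rng(seed)
    V = np.zeros((n, structure.n_nodes), dtype=np.int64)
    for v in nx.topological_sort(g):
        cpt = cpts[v]
        if cpt.parents:
            probs = cpt.table[tuple(V[:, p] for p in cpt.parents)]  # (n, arity)
        else:
            probs = np.broadcast_to(cpt.table, (n, cpt.arity))
        u = rng.random(n)
        V[:, v] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return V
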