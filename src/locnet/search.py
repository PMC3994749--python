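"""Greedy hill-climbing structure search on a conditional-log-likelihood score.

One search is run per target location.  Starting from the empty graph,
each iteration enumerates every legal move (edge addition, deletion, or
reversal that keeps the graph acyclic and never connects two feature
nodes), scores the resulting network, and applies the best move while it
improves the score by more than a small tolerance.

The score is the conditional log likelihood (CLL) of the target indicator
minus, by default, a BIC-style complexity penalty (log m / 2) * k, where
k counts the free parameters of the factors that enter the target's
conditional (the target's CPT and its children's CPTs).  The penalty
matters: the in-sample CLL of maximum-likelihood CPTs increases almost
surely when any parent is added, so climbing the raw CLL connects the
target to noise; the penalized score accepts an edge only when its fit
gain exceeds the chance level for the parameters it introduces.  Set
``penalty='none'`` for raw-CLL climbing.

Because the CLL of target L_i depends only on the factors containing L_i,
moves that change no such family leave the score exactly unchanged; the
default scorer skips them and refits only the affected families.
``full_refit=True`` scores every move by refitting the complete network —
a slower, independent path used to validate the incremental one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bayesnet import (
    BNClassifier,
    CPTSet,
    NetworkStructure,
    _data_matrix,
    _fit_family,
    _infer_arities,
    cll_score,
)
from .config import SearchConfig
from .dataset import MultiLocDataset

__all__ = ["SearchMove", "SearchTrace", "legal_moves", "hill_climb"]

_LOG_FLOOR = np.log(1e-300)


@dataclass(frozen=True)
class SearchMove:
    """One hill-climbing step: add/delete/reverse the edge u -> v."""

    kind: str  # 'add' | 'delete' | 'reverse'
    u: int
    v: int

    def __str__(self) -> str:
        return f"{self.kind}({self.u}->{self.v})"


@dataclass
class SearchTrace:
    """Audit record of one hill climb: applied moves and the score path.

    ``objective`` names what the scores are ('cll' or 'cll-bic'); the raw
    CLL at each step is recorded alongside the objective values.
    """

    objective: str = "cll-bic"
    rows: list = field(default_factory=list)
    # each row: (iteration, SearchMove, score_before, score_after, cll_after)
    final_score: float = np.nan
    final_cll: float = np.nan
    iterations: int = 0
    converged: bool = True

    def append(self, iteration, move, before, after, cll_after) -> None:
        self.rows.append((iteration, move, before, after, cll_after))

    def score_sequence(self) -> list[float]:
        seq = [self.rows[0][2]] if self.rows else [self.final_score]
        seq.extend(r[3] for r in self.rows)
        return seq

    def to_tsv(self) -> str:
        lines = ["iteration\tmove\tscore_before\tscore_after\tcll_after"]
        for it, mv, before, after, cll in self.rows:
            lines.append(f"{it}\t{mv}\t{before!r}\t{after!r}\t{cll!r}")
        return "\n".join(lines) + "\n"


def legal_moves(structure: NetworkStructure, max_parents: int | None = None):
    """All moves whose result is acyclic and free of feature-feature edges.

    Deterministic order: kind ('add' < 'delete' < 'reverse'), then the
    ordered node pair.
    """
    moves: list[SearchMove] = []
    n = structure.n_nodes
    for u in range(n):
        for v in range(n):
            if u == v or structure.has_edge(u, v):
                continue
            if structure.is_feature(u) and structure.is_feature(v):
                continue
            if max_parents is not None and len(structure.parents[v]) >= max_parents:
                continue
            if structure.path_exists(v, u):  # adding u->v would close a cycle
                continue
            moves.append(SearchMove("add", u, v))
    for u, v in structure.edges():
        moves.append(SearchMove("delete", u, v))
    for u, v in structure.edges():
        if max_parents is not None and len(structure.parents[u]) >= max_parents:
            continue
        if structure.remove_edge(u, v).path_exists(u, v):
            continue  # another u->..->v path exists; reversal closes a cycle
        moves.append(SearchMove("reverse", u, v))
    order = {"add": 0, "delete": 1, "reverse": 2}
    moves.sort(key=lambda m: (order[m.kind], m.u, m.v))
    return moves


def _apply_to_parents(parents: list, move: SearchMove) -> list:
    parents = list(parents)
    if move.kind == "add":
        parents[move.v] = tuple(sorted(parents[move.v] + (move.u,)))
    elif move.kind == "delete":
        parents[move.v] = tuple(x for x in parents[move.v] if x != move.u)
    elif move.kind == "reverse":
        parents[move.v] = tuple(x for x in parents[move.v] if x != move.u)
        parents[move.u] = tuple(sorted(parents[move.u] + (move.v,)))
    else:  # pragma: no cover
        raise ValueError(f"unknown move kind {move.kind!r}")
    return parents


def _changed_families(parents: list, move: SearchMove) -> list[int]:
    return [move.v] if move.kind in ("add", "delete") else [move.u, move.v]


class _CLLScorer:
    """Incremental CLL evaluation with family-level caching."""

    def __init__(self, dataset, estimates, target, config):
        self.d, self.q = dataset.d, dataset.q
        self.tnode = self.d + target
        self.alpha = config.alpha
        V_true = _data_matrix(dataset)
        if config.location_cpts_from == "estimated":
            # alternative reading: location-node CPTs counted from the SVM
            # estimates (the target's own column stays true)
            V = np.column_stack(
                [V_true[:, : self.d], np.asarray(estimates, dtype=np.int64)]
            )
            V[:, self.tnode] = V_true[:, self.tnode]
            self.V = V
        elif config.location_cpts_from == "true":
            self.V = V_true
        else:
            raise ValueError(
                f"unknown location_cpts_from {config.location_cpts_from!r}"
            )
        self.arities = _infer_arities(V_true, self.d)
        self.y = V_true[:, self.tnode]
        W = np.column_stack(
            [V_true[:, : self.d], np.asarray(estimates, dtype=np.int64)]
        )
        self.W0 = W.copy()
        self.W0[:, self.tnode] = 0
        self.W1 = W.copy()
        self.W1[:, self.tnode] = 1
        if config.penalty not in ("bic", "none"):
            raise ValueError(f"unknown penalty {config.penalty!r}")
        self.bic = config.penalty == "bic"
        self.half_log_m = 0.5 * float(np.log(len(self.y)))
        self._terms: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

    def family_terms(self, v: int, parents: tuple[int, ...]):
        key = (v, parents)
        hit = self._terms.get(key)
        if hit is None:
            cpt = _fit_family(self.V, v, parents, self.arities, self.alpha)
            lp0 = cpt.logp(self.W0[:, v], self.W0)
            lp1 = cpt.logp(self.W1[:, v], self.W1)
            hit = self._terms[key] = (lp0, lp1)
        return hit

    def relevant_families(self, parents: list) -> list[tuple[int, tuple[int, ...]]]:
        fams = [(self.tnode, parents[self.tnode])]
        fams.extend(
            (v, ps) for v, ps in enumerate(parents) if self.tnode in ps
        )
        return fams

    def cll(self, parents: list) -> float:
        delta = np.zeros(len(self.y))
        for v, ps in self.relevant_families(parents):
            lp0, lp1 = self.family_terms(v, ps)
            delta = delta + (lp1 - lp0)
        terms = np.where(
            self.y == 1,
            -np.logaddexp(0.0, -delta),
            -np.logaddexp(0.0, delta),
        )
        if np.isneginf(terms).any():
            terms = np.maximum(terms, _LOG_FLOOR)
        return float(terms.sum())

    def param_count(self, parents: list) -> int:
        """Free parameters of the factors entering the target conditional."""
        k = 0
        for v, ps in self.relevant_families(parents):
            rows = 1
            for p in ps:
                rows *= self.arities[p]
            k += rows * (self.arities[v] - 1)
        return k

    def score(self, parents: list) -> float:
        """CLL minus the BIC complexity penalty (if enabled)."""
        s = self.cll(parents)
        if self.bic:
            s -= self.half_log_m * self.param_count(parents)
        return s

    def move_is_relevant(self, parents: list, move: SearchMove) -> bool:
        """Does the move change any factor containing the target?"""
        new_parents = _apply_to_parents(parents, move)
        for w in _changed_families(parents, move):
            if (
                w == self.tnode
                or self.tnode in parents[w]
                or self.tnode in new_parents[w]
            ):
                return True
        return False


def hill_climb(
    discrete_dataset: MultiLocDataset,
    estimates: np.ndarray,
    target: int,
    config: SearchConfig | None = None,
    full_refit: bool = False,
) -> tuple[BNClassifier, SearchTrace]:
    """Steepest-ascent CLL search for one target location.

    Parameters
    ----------
    discrete_dataset : dataset with integer-coded features and true labels
    estimates : (m, q) hard indicator estimates for every record
    target : location index the learned classifier predicts
    config : search settings (pseudo-count, tolerance, iteration cap)
    full_refit : score every candidate by refitting the complete network
        (slow; exists to validate the incremental scorer against)

    Ties between equal-scoring moves resolve to the earliest move in the
    deterministic enumeration order.
    """
    config = config or SearchConfig()
    if not 0 <= target < discrete_dataset.q:
        raise ValueError(f"target {target} out of range for q={discrete_dataset.q}")
    scorer = _CLLScorer(discrete_dataset, estimates, target, config)
    structure = NetworkStructure(
        discrete_dataset.feature_names, list(discrete_dataset.vocabulary.names)
    )

    def fit_all(st: NetworkStructure) -> CPTSet:
        # counts come from the scorer's matrix so that the alternative
        # location_cpts_from='estimated' mode stays consistent throughout
        tables = {
            v: _fit_family(scorer.V, v, st.parents[v], scorer.arities, config.alpha)
            for v in range(st.n_nodes)
        }
        return CPTSet(tables, config.alpha, scorer.arities)

    def full_score(st: NetworkStructure) -> float:
        cls = BNClassifier(target, st, fit_all(st))
        s = cll_score(cls, discrete_dataset, estimates, reduced=False)
        if scorer.bic:
            s -= scorer.half_log_m * scorer.param_count(st.parents)
        return s

    cur_score = full_score(structure) if full_refit else scorer.score(structure.parents)
    trace = SearchTrace(objective="cll-bic" if scorer.bic else "cll")
    for iteration in range(config.max_iters):
        best_move, best_score = None, -np.inf
        for move in legal_moves(structure, config.max_parents):
            if full_refit:
                cand_score = full_score(_apply_move(structure, move))
            else:
                if not scorer.move_is_relevant(structure.parents, move):
                    continue  # score provably unchanged; cannot beat epsilon
                cand_score = scorer.score(_apply_to_parents(structure.parents, move))
            if cand_score > best_score:
                best_move, best_score = move, cand_score
        if best_move is None or best_score - cur_score <= config.epsilon:
            trace.converged = True
            break
        structure = _apply_move(structure, best_move)
        structure.validate()  # acyclic + no feature-feature edge, every step
        trace.append(iteration, best_move, cur_score, best_score,
                     scorer.cll(structure.parents))
        cur_score = best_score
    else:
        trace.converged = False
        warnings.warn(
            f"hill climb for target {target} hit the iteration cap "
            f"({config.max_iters}) before converging"
        )
    trace.final_score = cur_score
    trace.final_cll = scorer.cll(structure.parents)
    trace.iterations = len(trace.rows)
    return BNClassifier(target, structure, fit_all(structure)), trace


def _apply_move(structure: NetworkStructure, move: SearchMove) -> NetworkStructure:
    if move.kind == "add":
        return structure.add_edge(move.u, move.v)
    if move.kind == "delete":
        return structure.remove_edge(move.u, move.v)
    if move.kind == "reverse":
        return structure.reverse_edge(move.u, move.v)
    raise ValueError(f"unknown move kind {move.kind!r}")
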