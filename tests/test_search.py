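"""Greedy hill-climbing structure search: moves, optimality, determinism."""

import numpy as np
import pytest

import oracles
from locnet.bayesnet import (
    BNClassifier,
    CPT,
    CPTSet,
    NetworkStructure,
    cll_score,
    fit_parameters,
)
from locnet.config import SearchConfig
from locnet.dataset import LocationVocabulary, MultiLocDataset
from locnet.search import hill_climb, legal_moves
from locnet.simulate import sample_network


def _dataset(V, d, q, feature_names=None):
    vocab = LocationVocabulary(tuple(f"loc{i}" for i in range(q)))
    Y = V[:, d:].copy()
    return MultiLocDataset(
        vocab, [f"P{i}" for i in range(len(V))], V[:, :d].astype(float), Y,
        feature_names or [f"f{i}" for i in range(d)],
    )


class TestLegalMoves:
    def test_empty_graph_has_only_feature_location_adds(self):
        st = NetworkStructure(["a", "b"], ["x", "y"])
        moves = legal_moves(st)
        assert all(m.kind == "add" for m in moves)
        assert len(moves) == 10  # 12 ordered pairs minus 2 feature-feature

    def test_existing_edge_enables_delete_and_reverse(self):
        st = NetworkStructure(["a"], ["x", "y"], [(), (0,), ()])
        kinds = {(m.kind, m.u, m.v) for m in legal_moves(st)}
        assert ("delete", 0, 1) in kinds
        assert ("reverse", 0, 1) in kinds
        assert ("add", 0, 1) not in kinds
        assert ("add", 1, 0) not in kinds  # would duplicate/close a 2-cycle

    def test_cycle_creating_reversal_excluded(self):
        # A->B, B->C, A->C: reversing A->C would close A->B->C->A
        st = NetworkStructure([], ["A", "B", "C"], [(), (0,), (0, 1)])
        moves = {(m.kind, m.u, m.v) for m in legal_moves(st)}
        assert ("reverse", 0, 2) not in moves
        assert ("reverse", 1, 2) in moves

    def test_cycle_creating_add_excluded(self):
        st = NetworkStructure([], ["A", "B", "C"], [(), (0,), (1,)])
        moves = {(m.kind, m.u, m.v) for m in legal_moves(st)}
        assert ("add", 2, 0) not in moves

    def test_max_parents_guard(self):
        st = NetworkStructure([], ["A", "B", "C"], [(), (0,), ()])
        moves = legal_moves(st, max_parents=1)
        assert ("add", 2, 1) not in {(m.kind, m.u, m.v) for m in moves}

    def test_deterministic_enumeration_order(self):
        st = NetworkStructure(["a"], ["x", "y"], [(), (0,), (1,)])
        assert legal_moves(st) == legal_moves(st)


def _simulated_instance(seed, n=5000, strong=True):
    """4-node instance (2 features, 2 locations) sampled from a known net."""
    st = NetworkStructure(["g1", "g2"], ["locA", "locB"],
                          [(), (), (0,), (2,)] if strong else [(), (), (), ()])
    rng = np.random.default_rng(seed)
    tables = {}
    for v in range(4):
        shape = tuple(2 for _ in st.parents[v]) + (2,)
        if strong and v == 2:
            t = np.array([[0.92, 0.08], [0.10, 0.90]])
        elif strong and v == 3:
            t = np.array([[0.85, 0.15], [0.20, 0.80]])
        else:
            t = rng.dirichlet((3.0, 3.0), size=int(np.prod(shape[:-1]))).reshape(shape)
        tables[v] = CPT(tuple(st.parents[v]), t)
    cpts = CPTSet(tables, 1.0, (2, 2, 2, 2))
    V = sample_network(st, cpts, n=n, seed=seed + 500)
    V[V[:, 2:].sum(axis=1) == 0, 3] = 1  # labeled rows need >= 1 positive
    return _dataset(V, 2, 2, ["g1", "g2"])


def _exhaustive_best_score(ds, est, target, config):
    """Max search objective over every legal DAG on the 4 nodes."""
    best = -np.inf
    m = ds.m
    half_log_m = 0.5 * np.log(m)
    for edges in oracles.all_legal_edge_sets(2, 2):
        parents = [[] for _ in range(4)]
        for u, v in edges:
            parents[v].append(u)
        st = NetworkStructure(ds.feature_names, list(ds.vocabulary.names), parents)
        cpts = fit_parameters(st, ds, alpha=config.alpha, arities=(2, 2, 2, 2))
        clf = BNClassifier(target, st, cpts)
        score = cll_score(clf, ds, est, reduced=False)
        if config.penalty == "bic":
            tnode = 2 + target
            k = 0
            for v in range(4):
                if v == tnode or tnode in st.parents[v]:
                    k += 2 ** len(st.parents[v])
            score -= half_log_m * k
        best = max(best, score)
    return best


class TestHillClimb:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_attains_exhaustive_optimum_on_4_nodes(self, seed):
        ds = _simulated_instance(seed)
        rng = np.random.default_rng(seed)
        est = ds.Y.copy()
        flip = rng.random(ds.Y.shape) < 0.1  # imperfect indicator estimates
        est = np.where(flip, 1 - est, est)
        config = SearchConfig()
        clf, trace = hill_climb(ds, est, 0, config)
        best = _exhaustive_best_score(ds, est, 0, config)
        assert trace.final_score == pytest.approx(best, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_raw_cll_climb_bounded_by_exhaustive_optimum(self, seed):
        # without the complexity penalty greedy ascent can stall in a local
        # optimum, so the exhaustive maximum is an upper bound, not equality
        ds = _simulated_instance(seed)
        est = ds.Y
        config = SearchConfig(penalty="none")
        clf, trace = hill_climb(ds, est, 0, config)
        best = _exhaustive_best_score(ds, est, 0, config)
        assert trace.final_score <= best + 1e-9

    def test_independent_target_stays_unconnected(self):
        unconnected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 2000
            X = rng.integers(0, 2, size=(n, 2))
            y = rng.integers(0, 2, n)
            other = np.ones(n, dtype=int)
            ds = _dataset(np.column_stack([X, y, other]), 2, 2)
            est = np.column_stack([y, other])
            clf, trace = hill_climb(ds, est, 0, SearchConfig())
            tn = clf.target_node
            touching = [e for e in clf.structure.edges() if tn in e]
            unconnected += not touching
            assert abs(trace.final_score - trace.score_sequence()[0]) < 10.0
        assert unconnected >= 18

    def test_score_sequence_monotone_and_structures_legal(self):
        ds = _simulated_instance(7, n=1500)
        est = ds.Y
        clf, trace = hill_climb(ds, est, 1, SearchConfig())
        seq = trace.score_sequence()
        assert all(b - a > 0 for a, b in zip(seq, seq[1:]))
        clf.structure.validate()  # acyclic, no feature-feature edges

    def test_full_refit_equals_incremental_scoring(self):
        ds = _simulated_instance(11, n=800)
        rng = np.random.default_rng(11)
        est = np.where(rng.random(ds.Y.shape) < 0.1, 1 - ds.Y, ds.Y)
        for penalty in ("bic", "none"):
            cfg = SearchConfig(penalty=penalty)
            clf_a, tr_a = hill_climb(ds, est, 0, cfg, full_refit=False)
            clf_b, tr_b = hill_climb(ds, est, 0, cfg, full_refit=True)
            assert clf_a.structure == clf_b.structure
            assert [r[1] for r in tr_a.rows] == [r[1] for r in tr_b.rows]
            assert tr_a.final_score == pytest.approx(tr_b.final_score, abs=1e-9)

    def test_deterministic_given_inputs(self):
        ds = _simulated_instance(21, n=1000)
        est = ds.Y
        a = hill_climb(ds, est, 0, SearchConfig())[0]
        b = hill_climb(ds, est, 0, SearchConfig())[0]
        assert a.structure == b.structure
        assert all(
            np.array_equal(a.cpts[v].table, b.cpts[v].table)
            for v in range(a.structure.n_nodes)
        )

    def test_iteration_cap_warns_and_returns(self):
        ds = _simulated_instance(5, n=1200)
        with pytest.warns(UserWarning, match="iteration cap"):
            clf, trace = hill_climb(ds, ds.Y, 0, SearchConfig(max_iters=1))
        assert not trace.converged
        assert trace.iterations == 1

    def test_invalid_target_rejected(self):
        ds = _simulated_instance(1, n=100)
        with pytest.raises(ValueError):
            hill_climb(ds, ds.Y, 5, SearchConfig())


class TestEstimatedLabelCounts:
    def test_alternative_cpt_counting_mode_runs_and_is_deterministic(self):
        ds = _simulated_instance(9, n=800)
        rng = np.random.default_rng(9)
        est = np.where(rng.random(ds.Y.shape) < 0.15, 1 - ds.Y, ds.Y)
        cfg = SearchConfig(location_cpts_from="estimated")
        a, _ = hill_climb(ds, est, 0, cfg)
        b, _ = hill_climb(ds, est, 0, cfg)
        assert a.structure == b.structure
        with pytest.raises(ValueError, match="location_cpts_from"):
            hill_climb(ds, est, 0, SearchConfig(location_cpts_from="wat"))
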