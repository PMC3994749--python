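"""Network structure, CPT fitting, and target-conditional inference."""

import numpy as np
import pytest

import oracles
from conftest import random_discrete_dataset
from locnet.bayesnet import (
    BNClassifier,
    CPT,
    CPTSet,
    NetworkStructure,
    cll_score,
    conditional_prob_target,
    fit_parameters,
    joint_log_prob,
    target_posterior,
)
from locnet.dataset import LocationVocabulary, MultiLocDataset
from locnet.simulate import sample_network, tiny_oracle_network


def _dataset_from_matrix(V, d, q):
    vocab = LocationVocabulary(tuple(f"loc{i}" for i in range(q)))
    Y = V[:, d:].copy()
    Y[Y.sum(axis=1) == 0, 0] = 1  # labeled datasets need >= 1 positive
    return MultiLocDataset(
        vocab, [f"P{i}" for i in range(len(V))], V[:, :d].astype(float), Y,
        [f"f{i}" for i in range(d)],
    )


def random_network(rng, max_nodes=12):
    """Random legal structure + Dirichlet CPTs over binary nodes."""
    d = int(rng.integers(1, 5))
    q = int(rng.integers(2, max_nodes - d + 1))
    n = d + q
    st = NetworkStructure([f"f{i}" for i in range(d)],
                          [f"l{i}" for i in range(q)])
    order = rng.permutation(n)
    parents = [[] for _ in range(n)]
    for pos, v in enumerate(order):
        for u in order[:pos]:
            if v < d and u < d:
                continue
            if rng.random() < 0.4:
                parents[v].append(int(u))
    st = st.with_parents(parents)
    arities = (2,) * n
    tables = {}
    for v in range(n):
        shape = tuple(arities[p] for p in st.parents[v]) + (2,)
        t = rng.dirichlet((1.0, 1.0), size=int(np.prod(shape[:-1]))).reshape(shape)
        tables[v] = CPT(tuple(st.parents[v]), t)
    return st, CPTSet(tables, alpha=1.0, arities=arities)


class TestStructure:
    def test_feature_feature_edge_rejected(self):
        with pytest.raises(ValueError, match="feature-feature"):
            NetworkStructure(["a", "b"], ["x", "y"], [(), (0,), (), ()])

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            NetworkStructure([], ["x", "y", "z"], [(2,), (0,), (1,)])

    def test_children_and_path_queries(self):
        st = NetworkStructure(["a"], ["x", "y"], [(), (0,), (1,)])
        assert st.children(0) == [1]
        assert st.path_exists(0, 2)
        assert not st.path_exists(2, 0)


class TestFitParameters:
    def test_parentless_node_is_count_ratio(self):
        V = np.array([[1], [1], [1], [0]])
        ds = _dataset_from_matrix(
            np.column_stack([V, np.ones((4, 1), dtype=int), V * 0 + 1]), 1, 2
        )
        st = NetworkStructure(["f0"], ["loc0", "loc1"])
        cpts = fit_parameters(st, ds, alpha=0.0)
        assert cpts[0].table[1] == pytest.approx(0.75)

    def test_smoothing_formula(self):
        # value 1 in 0 of 2 records, alpha=1 -> (0+1)/(2+2) = 0.25
        ds = _dataset_from_matrix(np.array([[0, 1, 1], [0, 1, 1]]), 1, 2)
        st = NetworkStructure(["f0"], ["loc0", "loc1"])
        cpts = fit_parameters(st, ds, alpha=1.0, arities=(2, 2, 2))
        assert cpts[0].table[1] == pytest.approx(0.25)

    def test_rows_normalize(self):
        rng = np.random.default_rng(0)
        ds = random_discrete_dataset(rng, 60, 3, 3, arity=3)
        st = NetworkStructure(ds.feature_names, list(ds.vocabulary.names),
                              [(), (3,), (4, 3), (), (3,), (0, 1)])
        cpts = fit_parameters(st, ds, alpha=0.7)
        for v in range(st.n_nodes):
            rows = cpts[v].table.sum(axis=-1)
            assert np.allclose(rows, 1.0, atol=1e-9)

    def test_unseen_parent_config_uniform_with_warning(self):
        ds = _dataset_from_matrix(np.array([[0, 1, 0], [0, 1, 1]]), 1, 2)
        st = NetworkStructure(["f0"], ["loc0", "loc1"], [(), (0,), ()])
        with pytest.warns(UserWarning, match="unseen parent"):
            cpts = fit_parameters(st, ds, alpha=0.0, arities=(2, 2, 2))
        assert np.allclose(cpts[1].table[1], [0.5, 0.5])

    def test_non_integer_features_rejected(self, small_dataset):
        st = NetworkStructure(small_dataset.feature_names,
                              list(small_dataset.vocabulary.names))
        with pytest.raises(ValueError, match="integer-coded"):
            fit_parameters(st, small_dataset)


class TestJointLogProb:
    def test_independent_uniform_product(self):
        st = NetworkStructure(["a"], ["x", "y", "z", "w"])
        tables = {v: CPT((), np.array([0.5, 0.5])) for v in range(5)}
        clf = BNClassifier(0, st, CPTSet(tables, 1.0, (2,) * 5))
        lp = joint_log_prob(clf, np.array([0, 1, 0, 1, 1]))
        assert lp == pytest.approx(5 * np.log(0.5))

    def test_chain_matches_hand_product(self):
        st = NetworkStructure([], ["x", "y", "z"], [(), (0,), (1,)])
        tables = {
            0: CPT((), np.array([0.3, 0.7])),
            1: CPT((0,), np.array([[0.9, 0.1], [0.2, 0.8]])),
            2: CPT((1,), np.array([[0.6, 0.4], [0.5, 0.5]])),
        }
        clf = BNClassifier(0, st, CPTSet(tables, 0.0, (2, 2, 2)))
        lp = joint_log_prob(clf, {"L:x": 1, "L:y": 1, "L:z": 0})
        assert lp == pytest.approx(np.log(0.7 * 0.8 * 0.5))

    def test_missing_variable_rejected(self):
        st = NetworkStructure([], ["x", "y"])
        tables = {v: CPT((), np.array([0.5, 0.5])) for v in range(2)}
        clf = BNClassifier(0, st, CPTSet(tables, 1.0, (2, 2)))
        with pytest.raises(ValueError, match="misses"):
            joint_log_prob(clf, {"L:x": 1})


class TestConditionalProbTarget:
    def test_isolated_target_returns_its_prior(self):
        st = NetworkStructure(["a"], ["x", "y"])
        tables = {
            0: CPT((), np.array([0.5, 0.5])),
            1: CPT((), np.array([0.3, 0.7])),
            2: CPT((), np.array([0.6, 0.4])),
        }
        clf = BNClassifier(0, st, CPTSet(tables, 1.0, (2, 2, 2)))
        p = conditional_prob_target(clf, [1], [0, 1])
        assert p == pytest.approx(0.7)

    def test_uniform_network_gives_half(self):
        st = NetworkStructure(["a"], ["x", "y"], [(), (0,), (1,)])
        tables = {
            0: CPT((), np.array([0.5, 0.5])),
            1: CPT((0,), np.full((2, 2), 0.5)),
            2: CPT((1,), np.full((2, 2), 0.5)),
        }
        clf = BNClassifier(0, st, CPTSet(tables, 1.0, (2, 2, 2)))
        assert conditional_prob_target(clf, [0], [0, 1]) == pytest.approx(0.5)

    def test_tiny_network_hand_values(self):
        st, cpts = tiny_oracle_network()
        # target cyt: J(1) ~ 0.8*0.7, J(0) ~ 0.2*0.1 given F1=1, F2=0, nuc=1
        clf = BNClassifier(0, st, cpts)
        p = conditional_prob_target(clf, [1, 0], [0, 1])
        assert p == pytest.approx(0.56 / 0.58)
        # target nuc is a leaf: posterior is its CPT entry directly
        clf = BNClassifier(1, st, cpts)
        p = conditional_prob_target(clf, [0, 1], [0, 0])
        assert p == pytest.approx(0.4)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_full_joint_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        st, cpts = random_network(rng)
        joint = oracles.enumerate_joint(
            [st.parents[v] for v in range(st.n_nodes)],
            {v: _indexable(cpts[v]) for v in range(st.n_nodes)},
            cpts.arities,
        )
        assert sum(joint.values()) == pytest.approx(1.0)
        target = int(rng.integers(0, st.q))
        clf = BNClassifier(target, st, cpts)
        for _ in range(4):
            assign = rng.integers(0, 2, st.n_nodes)
            p = conditional_prob_target(clf, assign[: st.d], assign[st.d:])
            expected = oracles.conditional_from_joint(
                joint, st.d + target, tuple(assign)
            )
            assert p == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_markov_blanket_equals_full_factorization(self, seed):
        rng = np.random.default_rng(300 + seed)
        st, cpts = random_network(rng)
        target = int(rng.integers(0, st.q))
        clf = BNClassifier(target, st, cpts)
        X = rng.integers(0, 2, size=(20, st.d))
        E = rng.integers(0, 2, size=(20, st.q))
        p_red = target_posterior(clf, X, E, reduced=True)
        p_full = target_posterior(clf, X, E, reduced=False)
        assert np.allclose(np.log(p_red), np.log(p_full), atol=1e-12)


def _indexable(cpt):
    class _T:
        def __getitem__(self, pa_vals):
            return cpt.table[pa_vals]

    return _T()


class TestCllScore:
    def test_isolated_uniform_target(self):
        rng = np.random.default_rng(1)
        ds = random_discrete_dataset(rng, 10, 1, 2)
        st = NetworkStructure(ds.feature_names, list(ds.vocabulary.names))
        tables = {v: CPT((), np.array([0.5, 0.5])) for v in range(3)}
        clf = BNClassifier(0, st, CPTSet(tables, 1.0, (2, 2, 2)))
        est = rng.integers(0, 2, size=(10, 2))
        assert cll_score(clf, ds, est) == pytest.approx(10 * np.log(0.5))

    def test_near_deterministic_edge_gives_near_zero_cll(self):
        # target copies the estimate of the other location via a 0.99 CPT
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 10)
        V = np.column_stack([np.zeros(10, dtype=int), y, np.ones(10, dtype=int)])
        ds = _dataset_from_matrix(V, 1, 2)
        st = NetworkStructure(["f0"], ["loc0", "loc1"], [(), (2,), ()])
        tables = {
            0: CPT((), np.array([1.0, 0.0])),
            1: CPT((2,), np.array([[0.99, 0.01], [0.01, 0.99]])),
            2: CPT((), np.array([0.5, 0.5])),
        }
        clf = BNClassifier(0, st, CPTSet(tables, 0.0, (2, 2, 2)))
        est = np.column_stack([y, y])  # l-hat of loc1 equals the target
        assert cll_score(clf, ds, est) == pytest.approx(10 * np.log(0.99))

    def test_cll_is_nonpositive(self):
        rng = np.random.default_rng(3)
        ds = random_discrete_dataset(rng, 40, 2, 3)
        st = NetworkStructure(ds.feature_names, list(ds.vocabulary.names),
                              [(), (), (0, 3), (), (2,)])
        cpts = fit_parameters(st, ds, alpha=1.0)
        est = rng.integers(0, 2, size=(40, 3))
        assert cll_score(BNClassifier(0, st, cpts), ds, est) <= 0


def _with_background_location(st, V):
    """Wrap network samples into a dataset via an always-on extra location.

    Sampled label vectors may be all-zero, which a labeled dataset rejects;
    an isolated constant location keeps every row valid without touching
    the counts of the original families.
    """
    st_bg = NetworkStructure(
        st.feature_names, st.location_names + ["bg"],
        [tuple(p) for p in st.parents] + [()],
    )
    vocab = LocationVocabulary(tuple(st_bg.location_names))
    Y = np.column_stack([V[:, st.d:], np.ones(len(V), dtype=int)])
    ds = MultiLocDataset(
        vocab, [f"P{i}" for i in range(len(V))], V[:, : st.d].astype(float),
        Y, st.feature_names,
    )
    return st_bg, ds


class TestParameterRecovery:
    def test_tiny_network_recovered_from_samples(self):
        st, cpts = tiny_oracle_network()
        V = sample_network(st, cpts, n=20000, seed=11)
        st_bg, ds = _with_background_location(st, V)
        refit = fit_parameters(st_bg, ds, alpha=1.0, arities=(2,) * 5)
        worst = max(
            np.abs(refit[v].table - cpts[v].table).max() for v in range(4)
        )
        assert worst < 0.02

    def test_ml_estimates_converge_with_n(self):
        st, cpts = tiny_oracle_network()
        errs = []
        for n in (1000, 10000):
            V = sample_network(st, cpts, n=n, seed=13)
            st_bg, ds = _with_background_location(st, V)
            refit = fit_parameters(st_bg, ds, alpha=0.0, arities=(2,) * 5)
            errs.append(max(
                np.abs(refit[v].table - cpts[v].table).max() for v in range(4)
            ))
        assert errs[1] < errs[0]
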