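"""Independent reference implementations used as test oracles.

Everything here is deliberately naive and written against the underlying
definitions (plain Python loops, Counter, fractions of counts), sharing no
code path with the package implementations it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


# -- full-joint enumeration for Bayesian network inference ------------------


def enumerate_joint(parents, tables, arities):
    """Explicit full joint: {assignment tuple: probability}.

    parents[v] is the ordered parent tuple of node v, tables[v] a nested
    indexable with tables[v][parent values tuple][value] = Pr(v | pa).
    """
    n = len(parents)
    joint = {}
    for assignment in itertools.product(*(range(a) for a in arities)):
        p = 1.0
        for v in range(n):
            pa_vals = tuple(assignment[u] for u in parents[v])
            p *= float(tables[v][pa_vals][assignment[v]])
        joint[assignment] = p
    return joint


def conditional_from_joint(joint, target, assignment):
    """Pr(node target = 1 | everything else) from an enumerated joint."""
    a0 = list(assignment)
    a0[target] = 0
    a1 = list(assignment)
    a1[target] = 1
    j0 = joint[tuple(a0)]
    j1 = joint[tuple(a1)]
    return j1 / (j0 + j1)


# -- exhaustive recursive MDLP discretization --------------------------------


def _entropy_counter(labels) -> float:
    n = len(labels)
    h = 0.0
    for _, c in sorted(Counter(labels).items()):
        p = c / n
        h -= p * math.log2(p)
    return h


def _mdl_threshold(n, k, k1, k2, h, h1, h2) -> float:
    delta = math.log2(3.0**k - 2.0) - (k * h - k1 * h1 - k2 * h2)
    return (math.log2(n - 1) + delta) / n


def mdlp_boundaries(values, labels, tie_tol=1e-12):
    """All MDL-accepted cut boundaries of one feature, naive recursion.

    ``values``/``labels`` are aligned flat lists of (value, single label)
    pairs (multi-labeled instances must be expanded by the caller).
    """
    pairs = sorted(zip(values, labels), key=lambda t: t[0])
    out = []
    _mdlp_recurse(pairs, out, tie_tol)
    return sorted(out)


def _mdlp_recurse(pairs, out, tie_tol):
    n = len(pairs)
    distinct = sorted({v for v, _ in pairs})
    if len(distinct) < 2:
        return
    best = None  # (entropy, boundary, left, right)
    for lo, hi in zip(distinct, distinct[1:]):
        t = (lo + hi) / 2.0
        left = [(v, l) for v, l in pairs if v <= t]
        right = [(v, l) for v, l in pairs if v > t]
        h = (
            len(left) * _entropy_counter([l for _, l in left])
            + len(right) * _entropy_counter([l for _, l in right])
        ) / n
        if best is None or h < best[0] - tie_tol:
            best = (h, t, left, right)
    _, t, left, right = best
    labs = [l for _, l in pairs]
    h_parent = _entropy_counter(labs)
    h1 = _entropy_counter([l for _, l in left])
    h2 = _entropy_counter([l for _, l in right])
    k = len(set(labs))
    k1 = len({l for _, l in left})
    k2 = len({l for _, l in right})
    gain = h_parent - (len(left) / n) * h1 - (len(right) / n) * h2
    if gain <= _mdl_threshold(n, k, k1, k2, h_parent, h1, h2):
        return
    out.append(t)
    _mdlp_recurse(left, out, tie_tol)
    _mdlp_recurse(right, out, tie_tol)


# -- naive multi-label metrics on label-set pairs ---------------------------


def naive_accuracy(pairs):
    return sum(len(m & p) / len(m | p) for m, p in pairs) / len(pairs)


def naive_f1(pairs):
    return sum(2 * len(m & p) / (len(m) + len(p)) for m, p in pairs) / len(pairs)


def naive_pre_rec(pairs, loc):
    pred = [(m, p) for m, p in pairs if loc in p]
    true = [(m, p) for m, p in pairs if loc in m]
    pre = sum(len(m & p) / len(p) for m, p in pred) / len(pred) if pred else None
    rec = sum(len(m & p) / len(m) for m, p in true) / len(true) if true else None
    return pre, rec


def naive_f1_label(pairs, vocabulary):
    present = [s for s in vocabulary if any(s in m for m, _ in pairs)]
    terms = []
    for s in present:
        pre, rec = naive_pre_rec(pairs, s)
        if pre is None or rec is None or pre + rec == 0:
            terms.append(0.0)
        else:
            terms.append(2 * pre * rec / (pre + rec))
    return sum(terms) / len(terms)


def naive_std_pre_rec(pairs, loc):
    tp = sum(1 for m, p in pairs if loc in m and loc in p)
    fp = sum(1 for m, p in pairs if loc not in m and loc in p)
    fn = sum(1 for m, p in pairs if loc in m and loc not in p)
    pre = tp / (tp + fp) if tp + fp else None
    rec = tp / (tp + fn) if tp + fn else None
    return pre, rec, tp, fp, fn


# -- exhaustive DAG enumeration for the 4-node search oracle ----------------


def all_legal_edge_sets(n_features, n_locations):
    """Every acyclic edge set over the nodes with no feature-feature edge."""
    n = n_features + n_locations
    candidates = [
        (u, v)
        for u in range(n)
        for v in range(n)
        if u != v and not (u < n_features and v < n_features)
    ]
    legal = []
    for bits in itertools.product((0, 1), repeat=len(candidates)):
        edges = [e for e, b in zip(candidates, bits) if b]
        if _is_acyclic(edges, n):
            legal.append(edges)
    return legal


def _is_acyclic(edges, n) -> bool:
    adj = {v: [] for v in range(n)}
    for u, v in edges:
        if (v, u) in edges:
            return False
        adj[u].append(v)
    seen, done = set(), set()

    def visit(u):
        if u in done:
            return True
        if u in seen:
            return False
        seen.add(u)
        for w in adj[u]:
            if not visit(w):
                return False
        done.add(u)
        return True

    return all(visit(v) for v in range(n))
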