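"""Recursive minimal-entropy (MDLP) discretization of continuous features.

Each continuous feature is cut recursively at the boundary minimizing the
class-conditional entropy of the location variable, and a split is kept
only while it passes the Minimum Description Length acceptance test of
Fayyad and Irani.  Multi-localized proteins are handled by expanding every
protein into one (instance, location) pair per positive label, so the
class variable has a proper distribution; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import MultiLocDataset

__all__ = [
    "CutpointMap",
    "conditional_entropy",
    "find_best_boundary",
    "mdlp_accept",
    "fit_discretizer",
    "apply_discretizer",
]

# two candidate cuts whose conditional entropies differ by no more than this
# are treated as tied (ties resolve toward the smaller boundary)
_TIE_TOL = 1e-12


@dataclass
class CutpointMap:
    """Per-feature cut boundaries and the value -> integer-code mapping.

    Intervals follow the half-open convention: a value v gets code c where
    c is the number of boundaries strictly below v (v <= T goes left, i.e.
    v == T maps to the interval ending at T).  Values outside the training
    range clamp to the extreme codes.
    """

    feature_names: list[str]
    boundaries: list[np.ndarray]
    ranges: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.boundaries = [np.asarray(b, dtype=float) for b in self.boundaries]
        if len(self.boundaries) != len(self.feature_names):
            raise ValueError("one boundary list per feature is required")
        for name, b, (lo, hi) in zip(self.feature_names, self.boundaries, self.ranges):
            if b.size and (np.diff(b) <= 0).any():
                raise ValueError(f"boundaries for {name!r} must be strictly increasing")
            if b.size and not ((b > lo).all() and (b < hi).all()):
                raise ValueError(
                    f"boundaries for {name!r} must lie strictly inside ({lo}, {hi})"
                )

    @property
    def d(self) -> int:
        return len(self.feature_names)

    def n_codes(self, i: int) -> int:
        return len(self.boundaries[i]) + 1

    def arities(self) -> list[int]:
        return [self.n_codes(i) for i in range(self.d)]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.d:
            raise ValueError(
                f"feature matrix has {X.shape[-1] if X.ndim == 2 else '?'} columns, "
                f"discretizer was fitted on {self.d}"
            )
        codes = np.empty(X.shape, dtype=np.int64)
        for i in range(self.d):
            # side='left': v == T falls in the interval ending at T
            codes[:, i] = np.searchsorted(self.boundaries[i], X[:, i], side="left")
        return codes

    # plain-text serialization ------------------------------------------------

    def to_text(self) -> str:
        lines = ["#locnet-cutpoints-v1"]
        for name, b, (lo, hi) in zip(self.feature_names, self.boundaries, self.ranges):
            cuts = ",".join(repr(float(x)) for x in b)
            lines.append(f"{name}\t{lo!r}\t{hi!r}\t{cuts}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "CutpointMap":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or lines[0] != "#locnet-cutpoints-v1":
            raise ValueError("not a recognized cutpoint file")
        names, bounds, ranges = [], [], []
        for ln in lines[1:]:
            name, lo, hi, cuts = ln.split("\t")
            names.append(name)
            ranges.append((float(lo), float(hi)))
            bounds.append(
                np.array([float(x) for x in cuts.split(",") if x], dtype=float)
            )
        return cls(names, bounds, ranges)


# -- label expansion -------------------------------------------------------


def _expand_pairs(values, label_rows):
    """Expand multi-labeled instances into (value, single-location) pairs."""
    vals, labs = [], []
    for v, row in zip(values, label_rows):
        row = list(row)
        if not row:
            raise ValueError("every instance needs at least one label")
        vals.extend([v] * len(row))
        labs.extend(row)
    index = {lab: i for i, lab in enumerate(sorted(set(labs)))}
    return np.asarray(vals, dtype=float), np.array([index[l] for l in labs])


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of a count vector, summed in class order."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


# -- spec operations -------------------------------------------------------


def conditional_entropy(values, label_rows, boundary) -> float:
    """Class entropy of the location variable given a two-sided cut (bits).

    Returns Pr(f<=T) H(S | f<=T) + Pr(f>T) H(S | f>T) with all proportions
    taken over expanded (instance, location) pairs.
    """
    vals, labs = _expand_pairs(values, label_rows)
    left = vals <= boundary
    if not left.any() or left.all():
        raise ValueError(
            f"boundary {boundary} leaves no instance on one side of the cut"
        )
    k = labs.max() + 1
    n = len(vals)
    cl = np.bincount(labs[left], minlength=k)
    cr = np.bincount(labs[~left], minlength=k)
    nl = int(cl.sum())
    return (nl * _entropy(cl) + (n - nl) * _entropy(cr)) / n


def _scan_cuts(vals_sorted, labs_sorted, k):
    """All candidate midpoint cuts with per-side class counts.

    Returns (boundaries, left_counts, right_counts) where row j of the count
    arrays corresponds to boundary j.  Candidates are midpoints between
    consecutive distinct sorted values.
    """
    n = len(vals_sorted)
    onehot = np.zeros((n, k), dtype=np.int64)
    onehot[np.arange(n), labs_sorted] = 1
    cum = np.cumsum(onehot, axis=0)
    change = np.where(np.diff(vals_sorted) > 0)[0]  # cut after position j
    if change.size == 0:
        return None
    boundaries = (vals_sorted[change] + vals_sorted[change + 1]) / 2.0
    left = cum[change]
    right = cum[-1] - left
    return boundaries, left, right


def find_best_boundary(values, label_rows):
    """Entropy-minimizing midpoint cut, or None if < 2 distinct values.

    Ties break toward the smallest boundary.
    """
    vals, labs = _expand_pairs(values, label_rows)
    order = np.argsort(vals, kind="stable")
    best = _best_cut_expanded(vals[order], labs[order], int(labs.max()) + 1)
    return None if best is None else best[0]


def _best_cut_expanded(vals_sorted, labs_sorted, k):
    """(boundary, H_cond, left_counts, right_counts) of the best cut."""
    scan = _scan_cuts(vals_sorted, labs_sorted, k)
    if scan is None:
        return None
    boundaries, left, right = scan
    n = len(vals_sorted)
    best = None
    for j in range(len(boundaries)):
        nl = int(left[j].sum())
        h = (nl * _entropy(left[j]) + (n - nl) * _entropy(right[j])) / n
        if best is None or h < best[1] - _TIE_TOL:
            best = (float(boundaries[j]), h, left[j], right[j])
    return best


def mdlp_accept(n, entropy_parent, entropy_left, entropy_right,
                k, k1, k2, n_left, n_right) -> bool:
    """Fayyad–Irani MDL acceptance test for a binary split.

    Accepts iff Gain > log2(n-1)/n + Delta/n with
    Gain  = H(S) - (n_left/n) H(S_left) - (n_right/n) H(S_right)
    Delta = log2(3^k - 2) - [k H(S) - k1 H(S_left) - k2 H(S_right)].
    """
    if n < 2:
        return False
    if n_left + n_right != n:
        raise ValueError("n_left + n_right must equal n")
    gain = entropy_parent - (n_left / n) * entropy_left - (n_right / n) * entropy_right
    delta = np.log2(3.0**k - 2.0) - (
        k * entropy_parent - k1 * entropy_left - k2 * entropy_right
    )
    return bool(gain > (np.log2(n - 1) + delta) / n)


def _recurse(vals_sorted, labs_sorted, q, out, use_mdl=True):
    k = int(len(np.unique(labs_sorted)))
    best = _best_cut_expanded(vals_sorted, labs_sorted, q)
    if best is None:
        return
    boundary, _, cl, cr = best
    n = len(vals_sorted)
    nl, nr = int(cl.sum()), int(cr.sum())
    if use_mdl:
        h_parent = _entropy(np.bincount(labs_sorted, minlength=q))
        hl, hr = _entropy(cl), _entropy(cr)
        k1 = int((cl > 0).sum())
        k2 = int((cr > 0).sum())
        if not mdlp_accept(n, h_parent, hl, hr, k, k1, k2, nl, nr):
            return
    out.append(boundary)
    left = vals_sorted <= boundary
    _recurse(vals_sorted[left], labs_sorted[left], q, out, use_mdl)
    _recurse(vals_sorted[~left], labs_sorted[~left], q, out, use_mdl)


def fit_discretizer(dataset: MultiLocDataset, use_mdl: bool = True) -> CutpointMap:
    """Fit per-feature MDLP cut boundaries on a labeled training set.

    Each feature is partitioned independently.  Features where no cut
    passes the MDL test get zero boundaries (a single code 0).  Setting
    ``use_mdl=False`` disables the stopping rule and splits down to single
    distinct values (useful only for diagnostics).
    """
    if not dataset.is_labeled:
        raise ValueError("discretization requires a labeled dataset")
    # expansion indices shared by all features
    reps = dataset.Y.sum(axis=1).astype(int)
    row_idx = np.repeat(np.arange(dataset.m), reps)
    labs = np.concatenate([np.where(row)[0] for row in dataset.Y])
    q = dataset.q

    bounds, ranges = [], []
    for i in range(dataset.d):
        vals = dataset.X[row_idx, i]
        order = np.argsort(vals, kind="stable")
        out: list[float] = []
        _recurse(vals[order], labs[order], q, out, use_mdl)
        bounds.append(np.array(sorted(out), dtype=float))
        ranges.append((float(dataset.X[:, i].min()), float(dataset.X[:, i].max())))
    return CutpointMap(list(dataset.feature_names), bounds, ranges)


def apply_discretizer(cmap: CutpointMap, dataset: MultiLocDataset) -> MultiLocDataset:
    """Map every feature value to its integer interval code."""
    if dataset.d != cmap.d:
        raise ValueError(
            f"dataset has d={dataset.d} features, discretizer was fitted on {cmap.d}"
        )
    return dataset.replace_features(cmap.transform(dataset.X))
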