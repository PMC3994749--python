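"""Dataset representation, tabular I/O and multi-label-aware fold splitting.

A dataset holds ``m`` proteins, each represented by a ``d``-dimensional
numeric feature vector and (for labeled data) a ``q``-dimensional binary
location-indicator vector over a fixed vocabulary of subcellular
compartments.  Multi-localized proteins simply have more than one positive
indicator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocationVocabulary",
    "ProteinRecord",
    "MultiLocDataset",
    "load_dataset",
    "write_dataset",
    "split_stratified",
]


@dataclass(frozen=True)
class LocationVocabulary:
    """Ordered set of subcellular compartment names.

    The order is fixed and defines the positions of location-indicator
    vectors throughout the package.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        if len(self.names) < 2:
            raise ValueError("a location vocabulary needs at least 2 compartments")
        if len(set(self.names)) != len(self.names):
            raise ValueError("location names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown location name: {name!r}") from None

    def encode(self, positives: Iterable[str]) -> np.ndarray:
        """Indicator vector with 1s at the named compartments."""
        vec = np.zeros(len(self.names), dtype=np.int8)
        for name in positives:
            vec[self.index(name)] = 1
        return vec

    def decode(self, indicator: Sequence[int]) -> tuple[str, ...]:
        return tuple(n for n, v in zip(self.names, indicator) if v)


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein: id, feature vector, optional indicator vector."""

    id: str
    features: np.ndarray
    labels: np.ndarray | None = None


class MultiLocDataset:
    """Feature matrix plus (optional) 0/1 location-indicator matrix.

    Parameters
    ----------
    vocabulary : LocationVocabulary
    ids : sequence of str, length m
    X : array (m, d) of numeric feature values
    Y : array (m, q) of 0/1 indicators, or None for unlabeled queries
    feature_names : sequence of d strings
    """

    def __init__(self, vocabulary, ids, X, Y, feature_names):
        self.vocabulary = vocabulary
        self.ids = list(map(str, ids))
        self.X = np.asarray(X, dtype=float)
        self.feature_names = list(map(str, feature_names))
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        if self.X.shape[0] != len(self.ids):
            raise ValueError("id list and feature matrix disagree on m")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature names and feature matrix disagree on d")
        if len(self.ids) < 1:
            raise ValueError("a dataset needs at least one record")
        if Y is None:
            self.Y = None
        else:
            Y = np.asarray(Y)
            if Y.shape != (len(self.ids), len(vocabulary)):
                raise ValueError(
                    f"label matrix shape {Y.shape} does not match "
                    f"(m={len(self.ids)}, q={len(vocabulary)})"
                )
            if not np.isin(Y, (0, 1)).all():
                raise ValueError("label entries must be 0/1")
            self.Y = Y.astype(np.int8)
            zero = np.where(self.Y.sum(axis=1) == 0)[0]
            if zero.size:
                bad = ", ".join(self.ids[i] for i in zero[:10])
                raise ValueError(
                    "labeled records must have at least one positive location; "
                    f"offending ids: {bad}"
                )

    # -- convenience -------------------------------------------------------

    @property
    def m(self) -> int:
        return len(self.ids)

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return len(self.vocabulary)

    @property
    def is_labeled(self) -> bool:
        return self.Y is not None

    @property
    def records(self) -> list[ProteinRecord]:
        return [
            ProteinRecord(
                self.ids[i],
                self.X[i],
                None if self.Y is None else self.Y[i],
            )
            for i in range(self.m)
        ]

    def label_sets(self) -> list[frozenset[str]]:
        if self.Y is None:
            raise ValueError("dataset is unlabeled")
        return [frozenset(self.vocabulary.decode(row)) for row in self.Y]

    def subset(self, indices) -> "MultiLocDataset":
        idx = np.asarray(indices, dtype=int)
        return MultiLocDataset(
            self.vocabulary,
            [self.ids[i] for i in idx],
            self.X[idx],
            None if self.Y is None else self.Y[idx],
            self.feature_names,
        )

    def replace_features(self, X, feature_names=None) -> "MultiLocDataset":
        return MultiLocDataset(
            self.vocabulary,
            self.ids,
            X,
            self.Y,
            self.feature_names if feature_names is None else feature_names,
        )

    def __repr__(self) -> str:
        lab = "labeled" if self.is_labeled else "unlabeled"
        return f"MultiLocDataset(m={self.m}, d={self.d}, q={self.q}, {lab})"


# -- I/O -------------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    """Read a CSV or TSV file with a header row (delimiter sniffed)."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def load_dataset(features_path, labels_path=None, vocabulary=None) -> MultiLocDataset:
    """Load a dataset from delimited text files.

    The features file has an ``id`` column followed by d numeric columns.
    The labels file has an ``id`` column followed either by q 0/1 columns
    (one per location) or by a single ``locations`` column of
    comma-separated location names.  Records are joined on id; record order
    follows the features file.
    """
    feat = _read_table(features_path)
    if feat.columns[0] != "id":
        raise ValueError("features file must start with an 'id' column")
    ids = feat["id"].astype(str).tolist()
    feature_names = list(feat.columns[1:])
    X = np.empty((len(ids), len(feature_names)))
    for j, col in enumerate(feature_names):
        try:
            X[:, j] = pd.to_numeric(feat[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(feat[col], errors="coerce")
            row = int(np.where(bad.isna() & feat[col].notna())[0][0])
            raise ValueError(
                f"non-numeric feature value {feat[col].iloc[row]!r} "
                f"at row {row} (id={ids[row]}), column {col!r}"
            ) from None

    if labels_path is None:
        if vocabulary is None:
            raise ValueError("unlabeled datasets require an explicit vocabulary")
        return MultiLocDataset(vocabulary, ids, X, None, feature_names)

    lab = _read_table(labels_path)
    if lab.columns[0] != "id":
        raise ValueError("labels file must start with an 'id' column")
    lab_ids = lab["id"].astype(str).tolist()
    missing = sorted(set(ids) - set(lab_ids))
    extra = sorted(set(lab_ids) - set(ids))
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"ids only in features file: {', '.join(missing[:10])}")
        if extra:
            parts.append(f"ids only in labels file: {', '.join(extra[:10])}")
        raise ValueError("feature/label id mismatch — " + "; ".join(parts))
    lab = lab.set_index("id").loc[ids]

    if list(lab.columns) == ["locations"]:
        names_seen: list[list[str]] = [
            [t.strip() for t in str(cell).split(",") if t.strip()]
            for cell in lab["locations"]
        ]
        if vocabulary is None:
            ordered: list[str] = []
            for row in names_seen:
                for name in row:
                    if name not in ordered:
                        ordered.append(name)
            vocabulary = LocationVocabulary(tuple(sorted(ordered)))
        Y = np.zeros((len(ids), len(vocabulary)), dtype=np.int8)
        for i, row in enumerate(names_seen):
            Y[i] = vocabulary.encode(row)  # raises KeyError on unknown names
    else:
        file_vocab = LocationVocabulary(tuple(lab.columns))
        if vocabulary is None:
            vocabulary = file_vocab
        elif vocabulary.names != file_vocab.names:
            raise ValueError(
                f"labels file columns {file_vocab.names} do not match the "
                f"supplied vocabulary {vocabulary.names}"
            )
        Y = lab.to_numpy(dtype=float)
        if not np.isin(Y, (0.0, 1.0)).all():
            raise ValueError("wide-format label cells must all be 0 or 1")
        Y = Y.astype(np.int8)
    return MultiLocDataset(vocabulary, ids, X, Y, feature_names)


def write_dataset(dataset, features_path, labels_path=None, sep="\t",
                  label_format="wide") -> None:
    """Write a dataset back to delimited text (full float precision)."""
    feat = pd.DataFrame(dataset.X, columns=dataset.feature_names)
    feat.insert(0, "id", dataset.ids)
    # default float formatting is repr(), which round-trips exactly
    feat.to_csv(features_path, sep=sep, index=False)
    if labels_path is None:
        return
    if dataset.Y is None:
        raise ValueError("dataset has no labels to write")
    if label_format == "wide":
        lab = pd.DataFrame(dataset.Y, columns=dataset.vocabulary.names)
        lab.insert(0, "id", dataset.ids)
    elif label_format == "names":
        lab = pd.DataFrame(
            {
                "id": dataset.ids,
                "locations": [
                    ",".join(dataset.vocabulary.decode(row)) for row in dataset.Y
                ],
            }
        )
    else:
        raise ValueError(f"unknown label_format {label_format!r}")
    lab.to_csv(labels_path, sep=sep, index=False)


# -- fold splitting --------------------------------------------------------


def split_stratified(dataset: MultiLocDataset, k: int, seed: int) -> list[np.ndarray]:
    """Split into k disjoint folds, stratified by exact label combination.

    Every group of records sharing the same label combination is spread as
    evenly as possible across folds (per-combination counts differ by at
    most 1), and overall fold sizes differ by at most 1.  Fully determined
    by (record order, k, seed).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if not dataset.is_labeled:
        raise ValueError("stratified splitting requires labels")
    if k > dataset.m:
        raise ValueError(f"cannot split m={dataset.m} records into k={k} folds")

    combos: dict[tuple, list[int]] = {}
    for i, row in enumerate(dataset.Y):
        combos.setdefault(tuple(int(v) for v in row), []).append(i)

    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    # iterate groups largest first (ties by combination key) so small strata
    # land in the currently emptiest folds
    for key in sorted(combos, key=lambda c: (-len(combos[c]), c)):
        members = np.array(combos[key])
        rng.shuffle(members)
        order = sorted(range(k), key=lambda f: (len(folds[f]), f))
        for pos, idx in enumerate(members):
            folds[order[pos % k]].append(int(idx))
    return [np.array(sorted(f), dtype=int) for f in folds]
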