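"""Discrete Function Learning: minimal-subset selection and classification.

DFL treats the class attribute Y as a (possibly noisy) function of a
small subset X of discretized features.  It searches for the smallest
subset whose empirical mutual information with Y nearly exhausts the
class entropy:

    H(Y) - I(X; Y) < epsilon * H(Y)

with epsilon a noise-tolerance parameter in [0, 1).  The search visits
subsets in cardinality-increasing order (1, 2, ..., K); within a
cardinality, candidates are generated from evaluated parents ranked by
descending I(parent; Y) (ties by feature index), each extended by one
feature (features ranked by descending single-feature information, ties
by index).  The first subset satisfying the criterion is returned; if
none does by cardinality K, the best-scoring evaluated subset of size K
is returned with ``converged=False``.

The classifier built on the selected subset is a function table: the
distinct training value-vectors x, each mapped to the majority class of
its supporting samples.  Prediction looks the query up in the table;
for unseen vectors the Hamming-nearest entry wins, equidistant entries
are resolved by the largest supporting count, remaining ties by the
lexicographically smallest key.

Continuous features enter through per-feature equal-frequency binning
(default 3 bins) with edges learned on training data only; test values
are clipped into the end bins.

Entropy and mutual information are plug-in (empirical) estimates in
bits.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class DFLError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class DFLConfig:
    epsilon: float = 0.3  # tolerated fraction of H(Y) left unexplained
    max_cardinality: int = 5  # K: largest subset size searched
    n_bins: int = 3  # B: equal-frequency bins per feature
    max_evals_per_cardinality: int | None = None  # beam cap; None = exhaustive

    def __post_init__(self) -> None:
        if not 0 <= self.epsilon < 1:
            raise DFLError("epsilon must be in [0, 1)")
        if self.max_cardinality < 1:
            raise DFLError("max_cardinality must be >= 1")
        if self.n_bins < 2:
            raise DFLError("n_bins must be >= 2")


def entropy(labels: Sequence) -> float:
    """Plug-in Shannon entropy in bits."""
    arr = np.asarray(labels)
    if arr.size == 0:
        raise DFLError("entropy of an empty label vector is undefined")
    _, counts = np.unique(arr, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _codes(columns: np.ndarray) -> np.ndarray:
    """Collapse rows of a discrete matrix into integer codes."""
    if columns.ndim == 1:
        columns = columns[:, None]
    _, codes = np.unique(columns, axis=0, return_inverse=True)
    return codes


def mutual_information(columns: np.ndarray, labels: Sequence) -> float:
    """Plug-in I(X; Y) in bits over the empirical joint distribution."""
    y = np.asarray(labels)
    x = np.asarray(columns)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != y.shape[0]:
        raise DFLError("columns and labels must have the same length")
    xc = _codes(x)
    _, yc = np.unique(y, return_inverse=True)
    return _mi_codes(xc, yc, int(yc.max()) + 1)


def _mi_codes(xcodes: np.ndarray, ycodes: np.ndarray, n_y: int) -> float:
    joint = xcodes.astype(np.int64) * n_y + ycodes
    n = joint.size

    def _h(codes: np.ndarray) -> float:
        counts = np.bincount(codes)
        counts = counts[counts > 0]
        p = counts / n
        return float(-(p * np.log2(p)).sum())

    return _h(xcodes) + _h(ycodes) - _h(joint)


@dataclasses.dataclass
class EqualFrequencyDiscretizer:
    """Per-feature equal-frequency binning learned on training data."""

    n_bins: int = 3
    edges_: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    feature_ids_: list[str] = dataclasses.field(default_factory=list)

    def fit(self, matrix: pd.DataFrame) -> "EqualFrequencyDiscretizer":
        if self.n_bins < 2:
            raise DFLError("n_bins must be >= 2")
        self.feature_ids_ = list(matrix.columns)
        self.edges_ = {}
        qs = np.arange(1, self.n_bins) / self.n_bins
        for f in self.feature_ids_:
            col = matrix[f].to_numpy(dtype=float)
            edges = np.unique(np.quantile(col, qs))
            edges = edges[(edges > col.min()) & (edges <= col.max())]
            if edges.size == 0 and np.unique(col).size == 1:
                warnings.warn(f"feature {f!r} is constant; using a single bin", stacklevel=2)
            self.edges_[f] = edges
        return self

    def transform(self, matrix: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_ids_ if f not in matrix.columns]
        if missing:
            raise DFLError(f"matrix lacks fitted features {missing[:3]}")
        out = np.empty((matrix.shape[0], len(self.feature_ids_)), dtype=np.int64)
        for j, f in enumerate(self.feature_ids_):
            col = matrix[f].to_numpy(dtype=float)
            # out-of-range values clip into the end bins by construction
            out[:, j] = np.searchsorted(self.edges_[f], col, side="right")
        return out

    def fit_transform(self, matrix: pd.DataFrame) -> np.ndarray:
        return self.fit(matrix).transform(matrix)


@dataclasses.dataclass
class DiscreteDataset:
    """Discretized samples x features matrix with class labels."""

    x: np.ndarray  # bin indices, samples x features
    y: np.ndarray  # class labels
    feature_ids: list[str]
    discretizer: EqualFrequencyDiscretizer | None = None

    @classmethod
    def from_continuous(
        cls, matrix: pd.DataFrame, labels: Sequence, n_bins: int = 3
    ) -> "DiscreteDataset":
        disc = EqualFrequencyDiscretizer(n_bins=n_bins)
        x = disc.fit_transform(matrix)
        return cls(
            x=x,
            y=np.asarray(labels),
            feature_ids=list(matrix.columns),
            discretizer=disc,
        )


@dataclasses.dataclass
class DFLSelection:
    features: list[str]
    indices: list[int]
    mi: float
    h_y: float
    converged: bool


def dfl_select(dataset: DiscreteDataset, cfg: DFLConfig | None = None) -> DFLSelection:
    """Find the first subset satisfying H(Y) - I(X;Y) < epsilon * H(Y).

    Subsets are visited in cardinality-increasing order with the
    deterministic within-cardinality ordering described in the module
    docstring.  ``cfg.max_evals_per_cardinality`` optionally caps how
    many subsets are scored per cardinality (a beam limit for very wide
    matrices); with the cap unset the scan over a cardinality is
    exhaustive.
    """
    cfg = cfg or DFLConfig()
    x, y = dataset.x, dataset.y
    n_features = x.shape[1]
    k_max = cfg.max_cardinality
    if k_max > n_features:
        warnings.warn(
            f"max_cardinality {k_max} exceeds {n_features} features; clipping",
            stacklevel=2,
        )
        k_max = n_features

    h_y = entropy(y)
    _, ycodes = np.unique(y, return_inverse=True)
    n_y = int(ycodes.max()) + 1

    if h_y == 0.0:
        return DFLSelection(features=[], indices=[], mi=0.0, h_y=0.0, converged=True)

    def satisfied(mi: float) -> bool:
        # H(Y) - I < eps*H(Y); at eps=0 accept numerically exact functions
        return (h_y - mi) < cfg.epsilon * h_y or bool(np.isclose(mi, h_y))

    # radix-encode subsets of bin columns for fast repeated MI evaluation;
    # bin indices are small so codes stay within bincount range
    xi = x.astype(np.int64)
    radix = int(xi.max()) + 1 if xi.size else 1

    def mi_of(subset: tuple[int, ...]) -> float:
        code = xi[:, subset[0]].copy()
        for j in subset[1:]:
            code = code * radix + xi[:, j]
        if radix ** len(subset) > 8 * code.size:
            _, code = np.unique(code, return_inverse=True)
        return _mi_codes(code, ycodes, n_y)

    def found(subset: tuple[int, ...], mi: float, converged: bool) -> DFLSelection:
        return DFLSelection(
            features=[dataset.feature_ids[i] for i in subset],
            indices=list(subset),
            mi=float(mi),
            h_y=h_y,
            converged=converged,
        )

    # singletons, ranked by descending information then feature index
    single_mi = np.array([mi_of((j,)) for j in range(n_features)])
    feature_order = sorted(range(n_features), key=lambda j: (-single_mi[j], j))

    # parents for the next cardinality: (subset, mi) in evaluation order
    parents: list[tuple[tuple[int, ...], float]] = []
    for j in feature_order:
        mi = float(single_mi[j])
        if satisfied(mi):
            return found((j,), mi, True)
        parents.append(((j,), mi))

    for _card in range(2, k_max + 1):
        parents.sort(key=lambda item: (-item[1], item[0]))
        seen: set[tuple[int, ...]] = set()
        evaluated: list[tuple[tuple[int, ...], float]] = []
        n_evals = 0
        capped = False
        for parent, _pmi in parents:
            for j in feature_order:
                if j in parent:
                    continue
                child = tuple(sorted(parent + (j,)))
                if child in seen:
                    continue
                seen.add(child)
                mi = mi_of(child)
                n_evals += 1
                if satisfied(mi):
                    return found(child, mi, True)
                evaluated.append((child, mi))
                if (
                    cfg.max_evals_per_cardinality is not None
                    and n_evals >= cfg.max_evals_per_cardinality
                ):
                    capped = True
                    break
            if capped:
                break
        parents = evaluated

    # no subset satisfied the criterion: best-scoring subset of size K
    best_subset, best_mi = min(parents, key=lambda item: (-item[1], item[0]))
    return found(best_subset, best_mi, False)


@dataclasses.dataclass(frozen=True)
class TableEntry:
    label: object
    count: int  # supporting samples of the majority class
    total: int  # all samples sharing the key
    class_counts: Mapping[object, int]


@dataclasses.dataclass
class FunctionTable:
    """The learned mapping from discrete value-vectors to classes."""

    entries: dict[tuple[int, ...], TableEntry]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        for key, entry in self.entries.items():
            if entry.count < 1:
                raise DFLError(f"entry {key} has no supporting samples")


def build_function_table(
    x: np.ndarray, y: Sequence, selected: Sequence[int], feature_ids: Sequence[str]
) -> FunctionTable:
    """Merge duplicate (x, y) training pairs into a function table.

    Each distinct value-vector maps to the majority class among its
    supporting samples; ties go to the smallest class label.
    """
    y_arr = np.asarray(y)
    cols = np.asarray(x)[:, list(selected)]
    entries: dict[tuple[int, ...], TableEntry] = {}
    grouped: dict[tuple[int, ...], dict[object, int]] = {}
    for row, label in zip(map(tuple, cols.tolist()), y_arr.tolist()):
        grouped.setdefault(row, {})
        grouped[row][label] = grouped[row].get(label, 0) + 1
    for key, class_counts in grouped.items():
        best = min(class_counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
        entries[key] = TableEntry(
            label=best[0],
            count=best[1],
            total=sum(class_counts.values()),
            class_counts=dict(class_counts),
        )
    return FunctionTable(
        entries=entries, feature_ids=[feature_ids[i] for i in selected]
    )


def dfl_predict(table: FunctionTable, query: Sequence[int]) -> object:
    """Predict via exact lookup, else the count-weighted Hamming 1-NN rule."""
    if not table.entries:
        raise DFLError("empty function table")
    key = tuple(int(v) for v in query)
    hit = table.entries.get(key)
    if hit is not None:
        return hit.label
    keys = np.array(list(table.entries.keys()))
    dists = (keys != np.asarray(key)).sum(axis=1)
    best = None  # (distance, -count, key)
    for k_tuple, dist in zip(table.entries.keys(), dists.tolist()):
        entry = table.entries[k_tuple]
        cand = (dist, -entry.count, k_tuple)
        if best is None or cand < best:
            best = cand
    return table.entries[best[2]].label


def dfl_predict_score(table: FunctionTable, query: Sequence[int], positive) -> float:
    """Score for ROC: fraction of the positive class among the supporting
    samples of the matched (or nearest) table entry."""
    if not table.entries:
        raise DFLError("empty function table")
    key = tuple(int(v) for v in query)
    entry = table.entries.get(key)
    if entry is None:
        keys = list(table.entries.keys())
        dists = (np.array(keys) != np.asarray(key)).sum(axis=1)
        best = min(
            zip(keys, dists.tolist()),
            key=lambda kd: (kd[1], -table.entries[kd[0]].count, kd[0]),
        )
        entry = table.entries[best[0]]
    return entry.class_counts.get(positive, 0) / entry.total


@dataclasses.dataclass
class DFLClassifier:
    """End-to-end DFL model: discretize, select, tabulate, predict.

    ``fit`` learns bin edges on the training matrix only, runs the
    subset search and builds the function table.  ``predict_score``
    returns the positive-class support fraction of the matched table
    entry, usable as an ROC score.
    """

    config: DFLConfig = dataclasses.field(default_factory=DFLConfig)
    selection_: DFLSelection | None = None
    table_: FunctionTable | None = None
    dataset_: DiscreteDataset | None = None

    def fit(self, matrix: pd.DataFrame, labels: Sequence) -> "DFLClassifier":
        ds = DiscreteDataset.from_continuous(matrix, labels, n_bins=self.config.n_bins)
        self.dataset_ = ds
        self.selection_ = dfl_select(ds, self.config)
        indices = self.selection_.indices
        if not indices:
            # degenerate single-class training data: constant predictor
            indices = [0] if ds.x.shape[1] else []
        self.table_ = build_function_table(ds.x, ds.y, indices, ds.feature_ids)
        self._indices = indices
        return self

    def _discretize(self, matrix: pd.DataFrame) -> np.ndarray:
        if self.dataset_ is None or self.dataset_.discretizer is None:
            raise DFLError("classifier is not fitted")
        return self.dataset_.discretizer.transform(matrix)[:, self._indices]

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        assert self.table_ is not None
        binned = self._discretize(matrix)
        return np.array([dfl_predict(self.table_, row) for row in binned])

    def predict_score(self, matrix: pd.DataFrame, positive) -> np.ndarray:
        assert self.table_ is not None
        binned = self._discretize(matrix)
        return np.array(
            [dfl_predict_score(self.table_, row, positive) for row in binned]
        )


def exhaustive_minimal_subsets(
    dataset: DiscreteDataset, cfg: DFLConfig
) -> tuple[int | None, list[tuple[int, ...]]]:
    """All satisfying subsets at the minimal satisfying cardinality.

    Brute-force reference search over every subset up to the configured
    cardinality, independent of the ordered search in
    :func:`dfl_select`.  Returns (cardinality, subsets) or (None, []).
    """
    x, y = dataset.x, dataset.y
    h_y = entropy(y)
    n = x.shape[1]

    def satisfied(mi: float) -> bool:
        return (h_y - mi) < cfg.epsilon * h_y or bool(np.isclose(mi, h_y))

    for card in range(1, min(cfg.max_cardinality, n) + 1):
        hits = [
            subset
            for subset in itertools.combinations(range(n), card)
            if satisfied(mutual_information(x[:, list(subset)], y))
        ]
        if hits:
            return card, hits
    return None, []
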