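"""Splitting, cross-validation, baseline feature selection and evaluation.

The classifier contract is a :class:`ClassifierSpec`: ``fit(X, y)``
returns an opaque model, ``predict(model, X)`` returns labels, and an
optional ``score(model, X)`` returns positive-class scores for ROC
curves.  Reference implementations ship for kNN (Euclidean, majority
vote, deterministic tie rules) and the DFL table classifier; any
scikit-learn estimator plugs in through :func:`sklearn_spec`.

Feature selection baselines:

* CFS — correlation-based selection maximizing the merit
  ``m * r_cf / sqrt(m + m*(m-1) * r_ff)`` where ``r_cf`` is the mean
  symmetrical uncertainty between subset features and the class and
  ``r_ff`` the mean pairwise SU within the subset, searched by
  best-first (with a non-improving expansion limit) or greedy-stepwise
  forward selection;
* wrapper selection — the same searches scored by a classifier's
  cross-validated accuracy.

ROC curves are threshold staircases over the scores with simultaneous
steps on ties; the trapezoid AUC equals the Mann-Whitney statistic
divided by ``n1 * n0``.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dfl import (
    DFLClassifier,
    DFLConfig,
    EqualFrequencyDiscretizer,
    entropy,
    mutual_information,
)


class ModelError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratify_by_batch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ModelError("train_fraction must be in (0, 1)")


@dataclasses.dataclass
class ClassifierSpec:
    """fit/predict(/score) triple identifying one classification algorithm."""

    name: str
    fit: Callable[[pd.DataFrame, np.ndarray], object]
    predict: Callable[[object, pd.DataFrame], np.ndarray]
    score: Callable[[object, pd.DataFrame], np.ndarray] | None = None


@dataclasses.dataclass
class EvalReport:
    accuracy: float  # percent
    n: int
    confusion: dict[str, int]  # tp, fp, tn, fn w.r.t. the positive class
    positive: object
    roc_points: np.ndarray | None = None  # (fpr, tpr) staircase
    auc: float | None = None


def stratified_split(
    metadata: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[list[str], list[str]]:
    """Split sample ids into train/test, stratified by class.

    The train side gets ``round(fraction * n)`` samples overall, with
    per-class counts allocated by largest remainder so that class
    proportions are preserved to within one sample.  Optionally the
    allocation is refined within class x batch strata.
    """
    spec = spec or SplitSpec()
    labels = metadata["class"]
    if spec.stratify_by_batch:
        strata = metadata["class"].astype(str) + "\x00" + metadata["batch"].astype(str)
    else:
        strata = labels.astype(str)
    counts = strata.value_counts().sort_index()
    if (labels.value_counts() < 2).any():
        raise ModelError("need at least 2 samples per class")
    n = len(metadata)
    n_train = int(round(spec.train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ModelError("split fraction leaves one side empty")

    raw = counts.to_numpy() * spec.train_fraction
    base = np.floor(raw).astype(int)
    rem = n_train - base.sum()
    if rem < 0:
        order = np.argsort(raw - base, kind="stable")
        for idx in order[: -rem]:
            base[idx] -= 1
    else:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:rem]] += 1

    rng = np.random.default_rng(spec.seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for stratum, take in zip(counts.index, base):
        members = sorted(strata.index[strata == stratum])
        perm = rng.permutation(len(members))
        chosen = set(np.asarray(members, dtype=object)[perm[:take]])
        train_ids.extend(m for m in members if m in chosen)
        test_ids.extend(m for m in members if m not in chosen)
    if not train_ids or not test_ids:
        raise ModelError("split fraction leaves one side empty")
    return train_ids, test_ids


def loocv(
    spec: ClassifierSpec, matrix: pd.DataFrame, labels: pd.Series | np.ndarray
) -> float:
    """Leave-one-out cross-validated accuracy (fraction in [0, 1])."""
    y = np.asarray(labels)
    n = len(matrix)
    if n < 2:
        raise ModelError("LOOCV needs at least two samples")
    correct = 0
    for i in range(n):
        keep = np.arange(n) != i
        try:
            model = spec.fit(matrix.iloc[keep], y[keep])
            pred = spec.predict(model, matrix.iloc[[i]])
        except Exception as exc:  # pragma: no cover - classifier contract breach
            raise ModelError(f"classifier {spec.name!r} failed in fold {i}") from exc
        correct += int(np.asarray(pred)[0] == y[i])
    return correct / n


def knn_classify(
    train: np.ndarray | pd.DataFrame,
    labels: Sequence,
    queries: np.ndarray | pd.DataFrame,
    k: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """k-nearest-neighbour labels and positive-class vote fractions.

    Euclidean metric, majority vote; vote ties resolved by the smaller
    mean neighbour distance, then by the smaller class label.  The
    returned score is the vote fraction of the largest class label
    (positive class by convention).
    """
    x = np.asarray(train, dtype=float)
    y = np.asarray(labels)
    q = np.asarray(queries, dtype=float)
    if k <= 0:
        raise ModelError("k must be positive")
    if k > x.shape[0]:
        raise ModelError(f"k={k} exceeds {x.shape[0]} training samples")
    classes = np.unique(y)
    positive = classes[-1]  # np.unique output is sorted
    d = np.sqrt(((q[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    preds = np.empty(q.shape[0], dtype=y.dtype)
    scores = np.empty(q.shape[0])
    for i in range(q.shape[0]):
        order = np.argsort(d[i], kind="stable")[:k]
        votes = y[order]
        dists = d[i][order]
        cand: list[tuple[int, float, object]] = []
        for cls in classes:
            mask = votes == cls
            if mask.any():
                cand.append((int(mask.sum()), float(dists[mask].mean()), cls))
        cand.sort(key=lambda t: (-t[0], t[1], str(t[2])))
        preds[i] = cand[0][2]
        scores[i] = (votes == positive).mean()
    return preds, scores


def make_knn_spec(k: int = 6) -> ClassifierSpec:
    def fit(matrix: pd.DataFrame, y: np.ndarray) -> tuple:
        return (matrix.to_numpy(dtype=float), np.asarray(y), list(matrix.columns))

    def predict(model: tuple, matrix: pd.DataFrame) -> np.ndarray:
        x, y, cols = model
        return knn_classify(x, y, matrix[cols].to_numpy(dtype=float), k=k)[0]

    def score(model: tuple, matrix: pd.DataFrame) -> np.ndarray:
        x, y, cols = model
        return knn_classify(x, y, matrix[cols].to_numpy(dtype=float), k=k)[1]

    return ClassifierSpec(name=f"kNN(k={k})", fit=fit, predict=predict, score=score)


def make_dfl_spec(config: DFLConfig | None = None) -> ClassifierSpec:
    cfg = config or DFLConfig()

    def fit(matrix: pd.DataFrame, y: np.ndarray) -> DFLClassifier:
        return DFLClassifier(config=cfg).fit(matrix, y)

    def predict(model: DFLClassifier, matrix: pd.DataFrame) -> np.ndarray:
        return model.predict(matrix)

    def score(model: DFLClassifier, matrix: pd.DataFrame) -> np.ndarray:
        positive = np.unique(model.dataset_.y)[-1]
        return model.predict_score(matrix, positive)

    return ClassifierSpec(name="DFL", fit=fit, predict=predict, score=score)


def sklearn_spec(estimator, name: str | None = None) -> ClassifierSpec:
    """Adapt a scikit-learn classifier to the ClassifierSpec contract."""
    from sklearn.base import clone

    def fit(matrix: pd.DataFrame, y: np.ndarray):
        model = clone(estimator)
        model.fit(matrix.to_numpy(dtype=float), y)
        return model

    def predict(model, matrix: pd.DataFrame) -> np.ndarray:
        return model.predict(matrix.to_numpy(dtype=float))

    def score(model, matrix: pd.DataFrame) -> np.ndarray:
        proba = model.predict_proba(matrix.to_numpy(dtype=float))
        positive_idx = len(model.classes_) - 1  # classes_ is sorted
        return proba[:, positive_idx]

    has_proba = hasattr(estimator, "predict_proba")
    return ClassifierSpec(
        name=name or type(estimator).__name__,
        fit=fit,
        predict=predict,
        score=score if has_proba else None,
    )


# ---------------------------------------------------------------------------
# feature-selection baselines


def _symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    ha, hb = entropy(a), entropy(b)
    if ha + hb == 0:
        return 0.0
    return 2.0 * mutual_information(a, b) / (ha + hb)


def _cfs_merit(su_fc: np.ndarray, su_ff: np.ndarray, subset: tuple[int, ...]) -> float:
    m = len(subset)
    if m == 0:
        return 0.0
    r_cf = su_fc[list(subset)].mean()
    if m == 1:
        return float(r_cf)
    idx = np.array(subset)
    pair_sum = su_ff[np.ix_(idx, idx)].sum() - np.trace(su_ff[np.ix_(idx, idx)])
    r_ff = pair_sum / (m * (m - 1))
    return float(m * r_cf / np.sqrt(m + m * (m - 1) * r_ff))


def cfs_select(
    matrix: pd.DataFrame,
    labels: Sequence,
    strategy: str = "best-first",
    n_bins: int = 3,
    max_nonimproving: int = 5,
) -> list[str]:
    """Correlation-based feature selection on symmetrical uncertainty.

    Continuous inputs are equal-frequency discretized first.  Both
    search strategies are deterministic, breaking ties by feature index.
    """
    if strategy not in ("best-first", "greedy-stepwise"):
        raise ModelError(f"unknown strategy {strategy!r}")
    y = np.asarray(labels)
    disc = EqualFrequencyDiscretizer(n_bins=n_bins)
    x = disc.fit_transform(matrix)
    p = x.shape[1]
    su_fc = np.array([_symmetrical_uncertainty(x[:, j], y) for j in range(p)])
    su_ff = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            su_ff[i, j] = su_ff[j, i] = _symmetrical_uncertainty(x[:, i], x[:, j])

    def merit(subset: tuple[int, ...]) -> float:
        return _cfs_merit(su_fc, su_ff, subset)

    if strategy == "greedy-stepwise":
        subset: tuple[int, ...] = ()
        current = 0.0
        while len(subset) < p:
            best = max(
                ((merit(tuple(sorted(subset + (j,)))), -j, j) for j in range(p) if j not in subset),
            )
            if best[0] <= current:
                break
            subset = tuple(sorted(subset + (best[2],)))
            current = best[0]
        selected = subset
    else:
        # best-first with a limit on consecutive non-improving expansions
        start: tuple[int, ...] = ()
        frontier: list[tuple[float, tuple[int, ...]]] = [(0.0, start)]
        visited = {start}
        best_merit, best_subset = 0.0, start
        nonimproving = 0
        while frontier and nonimproving < max_nonimproving:
            frontier.sort(key=lambda t: (-t[0], t[1]))
            node_merit, node = frontier.pop(0)
            improved = False
            for j in range(p):
                if j in node:
                    continue
                child = tuple(sorted(node + (j,)))
                if child in visited:
                    continue
                visited.add(child)
                m = merit(child)
                frontier.append((m, child))
                if m > best_merit:
                    best_merit, best_subset = m, child
                    improved = True
            nonimproving = 0 if improved else nonimproving + 1
        selected = best_subset
    if not selected and p:
        # degenerate data: nothing correlates with the class
        return []
    return [matrix.columns[j] for j in selected]


def _cv_accuracy(
    spec: ClassifierSpec,
    matrix: pd.DataFrame,
    y: np.ndarray,
    folds: int,
    seed: int,
) -> float:
    """Stratified k-fold accuracy with a fixed shuffle."""
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(matrix, y):
        model = spec.fit(matrix.iloc[train_idx], y[train_idx])
        pred = spec.predict(model, matrix.iloc[test_idx])
        correct += int((np.asarray(pred) == y[test_idx]).sum())
    return correct / len(y)


def wrapper_select(
    matrix: pd.DataFrame,
    labels: Sequence,
    spec: ClassifierSpec,
    strategy: str = "greedy-stepwise",
    folds: int = 5,
    seed: int = 0,
    max_nonimproving: int = 5,
) -> list[str]:
    """Wrapper feature selection scored by cross-validated accuracy."""
    if strategy not in ("best-first", "greedy-stepwise"):
        raise ModelError(f"unknown strategy {strategy!r}")
    y = np.asarray(labels)
    p = matrix.shape[1]
    cache: dict[tuple[int, ...], float] = {}

    def cv_score(subset: tuple[int, ...]) -> float:
        if not subset:
            return 0.0
        if subset not in cache:
            cols = [matrix.columns[j] for j in subset]
            cache[subset] = _cv_accuracy(spec, matrix[cols], y, folds, seed)
        return cache[subset]

    if strategy == "greedy-stepwise":
        subset: tuple[int, ...] = ()
        current = 0.0
        while len(subset) < p:
            best = max(
                ((cv_score(tuple(sorted(subset + (j,)))), -j, j) for j in range(p) if j not in subset)
            )
            if best[0] <= current:
                break
            subset = tuple(sorted(subset + (best[2],)))
            current = best[0]
        return [matrix.columns[j] for j in subset]

    start: tuple[int, ...] = ()
    frontier: list[tuple[float, tuple[int, ...]]] = [(0.0, start)]
    visited = {start}
    best_score, best_subset = 0.0, start
    nonimproving = 0
    while frontier and nonimproving < max_nonimproving:
        frontier.sort(key=lambda t: (-t[0], t[1]))
        _, node = frontier.pop(0)
        improved = False
        for j in range(p):
            if j in node:
                continue
            child = tuple(sorted(node + (j,)))
            if child in visited:
                continue
            visited.add(child)
            s = cv_score(child)
            frontier.append((s, child))
            if s > best_score:
                best_score, best_subset = s, child
                improved = True
        nonimproving = 0 if improved else nonimproving + 1
    return [matrix.columns[j] for j in best_subset]


def roc_auc(
    scores: Sequence[float], labels: Sequence, positive=None
) -> tuple[np.ndarray, float]:
    """ROC staircase and trapezoid AUC; ties step simultaneously."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ModelError("AUC is undefined without exactly two classes")
    positive = classes[-1] if positive is None else positive
    pos = y == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ModelError("AUC is undefined without both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_sorted = pos[order].astype(int)
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(1 - pos_sorted)
    # keep only the last point of each tied-score run (simultaneous step)
    keep = np.append(s_sorted[1:] != s_sorted[:-1], True)
    tpr = np.concatenate([[0.0], tps[keep] / n1])
    fpr = np.concatenate([[0.0], fps[keep] / n0])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def evaluate_on_test(
    model: object,
    spec: ClassifierSpec,
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    positive=None,
) -> EvalReport:
    """Accuracy (percent), confusion counts and ROC/AUC on held-out data."""
    y = np.asarray(labels)
    classes = np.unique(y)
    positive = classes[-1] if positive is None else positive
    pred = np.asarray(spec.predict(model, matrix))
    if pred.shape[0] != y.shape[0]:
        raise ModelError("prediction length mismatch")
    acc = float((pred == y).mean() * 100.0)
    confusion = {
        "tp": int(((pred == positive) & (y == positive)).sum()),
        "fp": int(((pred == positive) & (y != positive)).sum()),
        "tn": int(((pred != positive) & (y != positive)).sum()),
        "fn": int(((pred != positive) & (y == positive)).sum()),
    }
    roc_points = auc = None
    if spec.score is not None and classes.size == 2:
        scores = np.asarray(spec.score(model, matrix))
        roc_points, auc = roc_auc(scores, y, positive=positive)
    return EvalReport(
        accuracy=acc,
        n=len(y),
        confusion=confusion,
        positive=positive,
        roc_points=roc_points,
        auc=auc,
    )


class LabelGuard:
    """Access wrapper preventing training-time reads of test labels.

    The pipeline hands stages a guard instead of the raw label vector;
    looking up a held-out sample before :meth:`release` raises.
    """

    def __init__(self, labels: pd.Series, train_ids: Sequence[str]):
        self._labels = labels
        self._train = set(train_ids)
        self._released = False

    def training_labels(self, ids: Sequence[str]) -> pd.Series:
        bad = [i for i in ids if i not in self._train]
        if bad and not self._released:
            raise ModelError(
                f"training-time access to held-out label {bad[0]!r} is forbidden"
            )
        return self._labels.loc[list(ids)]

    def release(self) -> None:
        """Open the guard for the final evaluation stage."""
        self._released = True

    def test_labels(self, ids: Sequence[str]) -> pd.Series:
        if not self._released:
            raise ModelError("test labels requested before evaluation stage")
        return self._labels.loc[list(ids)]
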