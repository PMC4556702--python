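"""Ranking feature subsets with the thresholding bandit.

Each candidate feature subset is one arm of an EXP3 bandit; pulling an arm
draws a fresh stratified train/test split, fits a classifier on the training
rows restricted to the subset's columns, and feeds the test accuracy back as
the reward.  The bandit's probability vector over subsets is the ranking;
pruning it with the ``t**alpha / t`` threshold yields a sparse ensemble of
surviving subsets.  A univariate two-sample t-test ranking is included as the
standard stability baseline.

The default classifier is an in-package ridge-penalised logistic regression
fitted by iteratively reweighted least squares (IRLS): the bandit experiments
require on the order of a million fits on tiny design matrices, so the fit
path is a few dense numpy solves with no estimator-object overhead.  Any
object with sklearn-style ``fit(X, y)`` / ``predict(X)`` methods can be
passed instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bandit import exp3_init, exp3_probabilities, exp3_step, threshold_distribution

__all__ = [
    "LabeledTable",
    "FeatureSubset",
    "SubsetEnsemble",
    "TTestRanking",
    "sample_subsets",
    "evaluate_subset",
    "rank_subsets",
    "ttest_rank",
    "accuracy_curve",
    "fit_ridge_logistic",
]


@dataclass
class LabeledTable:
    """n samples x p features with binary class labels.

    ``labels`` are stored as 0/1 (``classes_`` keeps the original two label
    values, sorted).  Rows with missing values are dropped at construction
    and counted in ``n_dropped``.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    classes_: tuple = (0, 1)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        n, p = self.values.shape
        if self.labels.shape != (n,):
            raise ValueError(f"labels length {self.labels.shape} != n={n}")
        if len(self.feature_ids) != p or len(self.sample_ids) != n:
            raise ValueError("identifier lists do not match the matrix shape")
        keep = np.isfinite(self.values).all(axis=1)
        if not keep.all():
            self.n_dropped += int((~keep).sum())
            self.values = self.values[keep]
            self.labels = self.labels[keep]
            self.sample_ids = [s for s, k in zip(self.sample_ids, keep) if k]
        uniq = np.unique(self.labels)
        if len(uniq) != 2:
            raise ValueError(f"need exactly two classes, found {list(uniq)}")
        self.classes_ = tuple(uniq)
        self.labels = (self.labels == uniq[1]).astype(np.int8)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str) -> "LabeledTable":
        if label_col not in df.columns:
            raise ValueError(f"label column {label_col!r} not in table")
        feats = df.drop(columns=[label_col])
        dup = feats.columns[feats.columns.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate feature IDs: {sorted(set(dup))}")
        bad = feats.columns[
            [not np.issubdtype(dt, np.number) for dt in feats.dtypes]
        ]
        if len(bad):
            raise ValueError(f"non-numeric feature column(s): {list(bad)}")
        return cls(
            values=feats.to_numpy(dtype=float),
            labels=df[label_col].to_numpy(),
            feature_ids=[str(c) for c in feats.columns],
            sample_ids=[str(i) for i in df.index],
        )

    def to_dataframe(self, label_col: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_ids,
                          index=self.sample_ids)
        df[label_col] = np.asarray(self.classes_)[self.labels]
        return df


@dataclass(frozen=True)
class FeatureSubset:
    """An ordered list of feature positions; repeats are allowed."""

    indices: tuple[int, ...]

    def __init__(self, indices: Sequence[int]):
        object.__setattr__(self, "indices", tuple(int(i) for i in indices))
        if any(i < 0 for i in self.indices):
            raise ValueError("feature positions must be non-negative")

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, p: int) -> None:
        if any(i >= p for i in self.indices):
            raise ValueError(f"subset index out of range for p={p}")

    def feature_ids(self, table: LabeledTable) -> list[str]:
        return [table.feature_ids[i] for i in self.indices]


@dataclass
class SubsetEnsemble:
    """Candidate subsets with the bandit's raw and thresholded distributions."""

    subsets: list[FeatureSubset]
    probs: np.ndarray
    thresholded: np.ndarray
    iterations_used: int
    alpha: float

    def ranked_indices(self) -> np.ndarray:
        """Subset order by decreasing raw probability (stable on ties)."""
        return np.argsort(-self.probs, kind="stable")

    def top_subset(self) -> FeatureSubset:
        return self.subsets[int(self.ranked_indices()[0])]

    def selected_features(self, table: LabeledTable, thresholded: bool = True):
        """Union of the features of the surviving (or top) subsets.

        With ``thresholded=True``: all subsets with non-zero thresholded
        probability; otherwise just the top-ranked subset.
        """
        if thresholded:
            live = np.flatnonzero(self.thresholded > 0)
        else:
            live = [int(self.ranked_indices()[0])]
        out: set[str] = set()
        for i in live:
            out.update(self.subsets[i].feature_ids(table))
        return frozenset(out)

    def to_records(self, table: LabeledTable) -> list[dict]:
        order = self.ranked_indices()
        return [
            {
                "subset_id": int(i),
                "rank": rank,
                "feature_ids": self.subsets[i].feature_ids(table),
                "raw_prob": float(self.probs[i]),
                "thresholded_prob": float(self.thresholded[i]),
            }
            for rank, i in enumerate(order)
        ]


def sample_subsets(
    p: int,
    n_subsets: int,
    subset_size: int,
    replacement: bool = False,
    seed: "int | np.random.Generator | None" = None,
) -> list[FeatureSubset]:
    """Draw ``n_subsets`` uniform random subsets of ``subset_size`` features.

    Without replacement (the default) a subset never repeats a feature and
    requires ``subset_size <= p``.
    """
    if subset_size > p and not replacement:
        raise ValueError(
            f"cannot draw {subset_size} distinct features from p={p}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [
        FeatureSubset(rng.choice(p, size=subset_size, replace=replacement))
        for _ in range(n_subsets)
    ]


def fit_ridge_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1.0,
    max_iter: int = 30,
    tol: float = 1e-8,
) -> np.ndarray:
    """Ridge-penalised logistic regression by IRLS (Newton) iterations.

    Returns coefficients ``(intercept, beta_1..beta_p)``; the intercept is
    unpenalised.  The ridge term keeps the Newton system well-posed under
    collinear or separable designs (p >= n is routine here).
    """
    n, p = X.shape
    Z = np.empty((n, p + 1))
    Z[:, 0] = 1.0
    Z[:, 1:] = X
    pen = np.full(p + 1, float(ridge))
    pen[0] = 0.0
    beta = np.zeros(p + 1)
    for _ in range(max_iter):
        eta = Z @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu) + 1e-10
        g = Z.T @ (y - mu) - pen * beta
        H = (Z * w[:, None]).T @ Z
        H[np.diag_indices_from(H)] += pen + 1e-12
        step = np.linalg.solve(H, g)
        beta += step
        if np.abs(step).max() < tol:
            break
    return beta


def _logistic_accuracy(Xtr, ytr, Xte, yte, ridge) -> float:
    beta = fit_ridge_logistic(Xtr, ytr, ridge=ridge)
    pred = (beta[0] + Xte @ beta[1:]) > 0
    return float((pred == (yte == 1)).mean())


def _stratified_split(labels: np.ndarray, split_fraction: float,
                      rng: np.random.Generator):
    """Index split keeping >= 1 training and >= 1 test sample per class."""
    train, test = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(
                f"class {cls} has {len(idx)} sample(s); need >= 2 for a split"
            )
        rng.shuffle(idx)
        n_tr = int(round(split_fraction * len(idx)))
        n_tr = min(max(n_tr, 1), len(idx) - 1)
        train.extend(idx[:n_tr])
        test.extend(idx[n_tr:])
    return np.array(train), np.array(test)


def evaluate_subset(
    table: LabeledTable,
    subset: FeatureSubset,
    split_fraction: float = 0.5,
    classifier: "str | object" = "logistic",
    rng: "np.random.Generator | None" = None,
    ridge: float = 1.0,
) -> float:
    """Test accuracy of a classifier fitted on the subset's columns.

    One fresh stratified split per call (``split_fraction`` of each class in
    the training part); the returned accuracy in [0, 1] is the bandit reward.
    """
    if rng is None:
        rng = np.random.default_rng()
    subset.validate(table.p)
    tr, te = _stratified_split(table.labels, split_fraction, rng)
    cols = list(subset.indices)
    Xtr, Xte = table.values[np.ix_(tr, cols)], table.values[np.ix_(te, cols)]
    ytr, yte = table.labels[tr], table.labels[te]
    if classifier == "logistic":
        return _logistic_accuracy(Xtr, ytr, Xte, yte, ridge)
    clf = classifier
    clf.fit(Xtr, ytr)
    return float((np.asarray(clf.predict(Xte)) == yte).mean())


def rank_subsets(
    table: LabeledTable,
    subsets: Sequence[FeatureSubset],
    T: int,
    gamma_schedule="log",
    alpha: float = 0.75,
    seed: "int | np.random.Generator | None" = None,
    split_fraction: float = 0.5,
    classifier: "str | object" = "logistic",
    ridge: float = 1.0,
    average: bool = False,
) -> SubsetEnsemble:
    """Rank candidate subsets by EXP3 with test-accuracy rewards.

    Runs ``T`` bandit rounds (fresh random split at every pull) and returns
    the ensemble with the final probability vector and its thresholded
    version at ``T**alpha / T``.  ``average=True`` ranks by the time-average
    of the played distributions instead of the final round.
    """
    if len(subsets) < 1:
        raise ValueError("need at least one candidate subset")
    if T < 1:
        raise ValueError(f"need at least one bandit round, got T={T}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for s in subsets:
        s.validate(table.p)

    def oracle(arm: int) -> float:
        return evaluate_subset(
            table, subsets[arm], split_fraction, classifier, rng, ridge
        )

    state = exp3_init(len(subsets), gamma_schedule, rng)
    acc = np.zeros(len(subsets)) if average else None
    for _ in range(T):
        if acc is not None:
            acc += exp3_probabilities(state)
        exp3_step(state, oracle)
    probs = acc / T if acc is not None else exp3_probabilities(state)
    return SubsetEnsemble(
        subsets=list(subsets),
        probs=probs,
        thresholded=threshold_distribution(probs, T, alpha),
        iterations_used=T,
        alpha=alpha,
    )


@dataclass
class TTestRanking:
    """Features ordered by decreasing |t| with the selected top-k set."""

    order: np.ndarray
    tstats: np.ndarray
    k: int

    @property
    def top_indices(self) -> np.ndarray:
        return self.order[: self.k]

    def top_feature_ids(self, table: LabeledTable) -> frozenset:
        return frozenset(table.feature_ids[i] for i in self.top_indices)


def ttest_rank(table: LabeledTable, k: int, equal_var: bool = False) -> TTestRanking:
    """Univariate two-sample t ranking (Welch by default).

    The per-feature statistic is ``(mean1 - mean0) / sqrt(s1^2/n1 + s0^2/n0)``
    (or its pooled-variance variant); a small additive guard in the
    denominator keeps zero-variance features finite.  Features are ordered by
    decreasing |t| and the top ``k`` form the selected set.
    """
    if not 1 <= k <= table.p:
        raise ValueError(f"k must lie in [1, p={table.p}], got {k}")
    X, y = table.values, table.labels
    g1, g0 = X[y == 1], X[y == 0]
    n1, n0 = len(g1), len(g0)
    if min(n1, n0) < 2:
        raise ValueError("need >= 2 samples per class for a t statistic")
    m1, m0 = g1.mean(axis=0), g0.mean(axis=0)
    v1, v0 = g1.var(axis=0, ddof=1), g0.var(axis=0, ddof=1)
    if equal_var:
        sp = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        denom = np.sqrt(sp * (1 / n1 + 1 / n0))
    else:
        denom = np.sqrt(v1 / n1 + v0 / n0)
    t = (m1 - m0) / (denom + 1e-300)
    order = np.argsort(-np.abs(t), kind="stable")
    return TTestRanking(order=order, tstats=t, k=k)


def accuracy_curve(
    table: LabeledTable,
    ensemble: SubsetEnsemble,
    repetitions: int,
    rng: "np.random.Generator | None" = None,
    split_fraction: float = 0.5,
    classifier: "str | object" = "logistic",
    ridge: float = 1.0,
) -> np.ndarray:
    """Mean test accuracy per ranked subset, best-ranked first.

    For each subset in ranking order, averages ``repetitions`` independent
    splits; the decreasing trend of this curve is the visual check that the
    bandit's ranking tracks predictive value.
    """
    if repetitions < 1:
        raise ValueError(f"repetitions must be >= 1, got {repetitions}")
    if rng is None:
        rng = np.random.default_rng()
    means = []
    for i in ensemble.ranked_indices():
        accs = [
            evaluate_subset(
                table, ensemble.subsets[int(i)], split_fraction, classifier,
                rng, ridge,
            )
            for _ in range(repetitions)
        ]
        means.append(float(np.mean(accs)))
    return np.array(means)
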