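"""Synthetic data generators for the two simulation studies and toy games.

Two designs are emulated:

* **Small-n-large-p** — a binary classification problem with n = 10
  observations and p = 100 features.  Class ``+`` is drawn from
  ``N(+mu**g, sigma^2 I)`` and class ``-`` from ``N(-mu**g, sigma^2 I)``
  with the shape exponent ``g = 0.9`` applied elementwise to a nonnegative
  mean vector mu (the exponent makes the two densities non-mirror-identical
  in form).  mu itself is unspecified by the design; the default draws it
  once as Uniform(0, 1) from a seed stored in the config, so every feature
  carries weak, heterogeneous signal and the vector is reproducible.

* **Functional categories** — features arranged in functional categories of
  redundant copies: each category has one latent standard-normal covariate
  and its features are noisy copies of it, and labels follow a well-specified
  logistic model on one representative feature per category.  Candidate
  subsets of 3 features are built so the first three cover all categories
  (optimal) and the rest miss one or two (suboptimal), with repeats allowed
  within a subset.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .games import MatrixGame, exact_nash_lp
from .ranking import FeatureSubset, LabeledTable, fit_ridge_logistic
from .stability import CategoryMap

__all__ = [
    "GaussianTwoClassConfig",
    "FunctionalSimConfig",
    "gen_small_n_large_p",
    "gen_functional_data",
    "gen_functional_subsets",
    "fit_logistic_error",
    "toy_games",
    "planted_support_game",
]


@dataclass
class GaussianTwoClassConfig:
    """Configuration of the small-n-large-p two-Gaussian generator.

    ``mu_base=None`` draws the mean vector once as Uniform(0, 1) with
    ``mu_seed`` so that all replicates of a study share one data-generating
    distribution.  ``sparse_signal`` builds the alternative preset with k
    informative features and the rest exactly null.
    """

    n: int = 10
    p: int = 100
    mu_base: Optional[np.ndarray] = None
    mu_seed: int = 20150831
    sigma2: float = 1.0
    shape_gamma: float = 0.9
    class_balance: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.shape_gamma <= 1.0:
            raise ValueError("shape exponent must lie in (0, 1]")
        if self.sigma2 <= 0:
            raise ValueError("variance must be positive")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class balance must lie in (0, 1)")

    def resolved_mu(self) -> np.ndarray:
        if self.mu_base is not None:
            mu = np.asarray(self.mu_base, dtype=float)
            if mu.shape != (self.p,):
                raise ValueError(f"mu_base must have length p={self.p}")
            if (mu < 0).any():
                raise ValueError(
                    "negative mean entries are invalid under a fractional "
                    "shape exponent"
                )
            return mu
        return np.random.default_rng(self.mu_seed).uniform(0.0, 1.0, self.p)

    @classmethod
    def sparse_signal(cls, k: int, magnitude: float = 1.0, **kwargs):
        """Preset with k informative features of fixed magnitude, rest null."""
        cfg = cls(**kwargs)
        mu = np.zeros(cfg.p)
        mu[:k] = magnitude
        cfg.mu_base = mu
        return cfg

    @property
    def n_over_p(self) -> float:
        return self.n / self.p


def gen_small_n_large_p(
    config: GaussianTwoClassConfig, seed: "int | np.random.Generator | None"
) -> LabeledTable:
    """Draw one small-n-large-p two-class Gaussian table."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = config.resolved_mu() ** config.shape_gamma
    n_pos = int(round(config.class_balance * config.n))
    n_pos = min(max(n_pos, 1), config.n - 1)
    signs = np.r_[np.ones(n_pos), -np.ones(config.n - n_pos)]
    values = signs[:, None] * mu[None, :] + rng.normal(
        0.0, np.sqrt(config.sigma2), size=(config.n, config.p)
    )
    return LabeledTable(
        values=values,
        labels=(signs > 0).astype(int),
        feature_ids=[f"f{j + 1}" for j in range(config.p)],
        sample_ids=[f"s{i + 1}" for i in range(config.n)],
    )


@dataclass
class FunctionalSimConfig:
    """Configuration of the functional-category generator.

    ``theta_star`` holds the true logistic coefficients, one per category
    (default magnitudes 2.0-2.8 with mixed signs: every category contributes
    real predictive signal, and dropping any one costs roughly ten accuracy
    points, so optimal and suboptimal subsets are separated well beyond the
    reward noise of a test split).  ``within_category_noise`` is the s.d.
    of the redundant copies around their category's latent covariate.
    """

    n_categories: int = 3
    features_per_category: int = 3
    theta_star: Optional[np.ndarray] = None
    n_samples: int = 200
    within_category_noise: float = 0.01
    n_subsets: int = 15
    subset_size: int = 3
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.n_categories < 1 or self.features_per_category < 1:
            raise ValueError("need >= 1 category and >= 1 feature per category")
        if self.within_category_noise < 0:
            raise ValueError("noise s.d. must be non-negative")

    @property
    def p(self) -> int:
        return self.n_categories * self.features_per_category

    def resolved_theta(self) -> np.ndarray:
        if self.theta_star is not None:
            th = np.asarray(self.theta_star, dtype=float)
            if th.shape != (self.n_categories,):
                raise ValueError(
                    f"theta_star must have one coefficient per category "
                    f"({self.n_categories})"
                )
            return th
        signs = np.where(np.arange(self.n_categories) % 2 == 0, 1.0, -1.0)
        return signs * np.linspace(2.0, 2.8, self.n_categories)


def gen_functional_data(
    config: FunctionalSimConfig, seed: "int | np.random.Generator | None"
) -> tuple[LabeledTable, CategoryMap, np.ndarray]:
    """Draw one functional-category dataset.

    Returns the labeled table, the feature -> category map, and the true
    coefficient vector (one entry per category).  Labels are Bernoulli with
    logit ``intercept + sum_c theta_c * x_rep(c)`` where ``x_rep(c)`` is the
    first feature of category c, so fitting a logistic regression on one
    representative per category is exactly well-specified.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = config.resolved_theta()
    n, C, fpc = config.n_samples, config.n_categories, config.features_per_category
    latent = rng.normal(size=(n, C))
    noise = rng.normal(0.0, 1.0, size=(n, C * fpc))
    values = np.repeat(latent, fpc, axis=1) + config.within_category_noise * noise
    reps = values[:, ::fpc]  # first feature of each category
    logits = config.intercept + reps @ theta
    labels = (rng.random(n) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    if labels.min() == labels.max():  # all one class: flip the most extreme sample
        labels[int(np.argmax(np.abs(logits)))] ^= 1
    feature_ids = [f"C{c + 1}_f{j + 1}" for c in range(C) for j in range(fpc)]
    table = LabeledTable(
        values=values,
        labels=labels,
        feature_ids=feature_ids,
        sample_ids=[f"s{i + 1}" for i in range(n)],
    )
    cmap = CategoryMap(
        {f"C{c + 1}_f{j + 1}": f"C{c + 1}" for c in range(C) for j in range(fpc)}
    )
    return table, cmap, theta


def gen_functional_subsets(
    config: FunctionalSimConfig, seed: "int | np.random.Generator | None"
) -> list[FeatureSubset]:
    """Candidate subsets for the functional design (repeats allowed).

    Subsets 1-3 contain one feature from every category (optimal); of the
    remaining ones, half draw all features from a single category (two
    categories missing) and half from exactly two categories (one missing).
    """
    if config.subset_size != config.n_categories:
        raise ValueError(
            "the functional design assumes subset_size == n_categories"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C, fpc = config.n_categories, config.features_per_category

    def feat(cat: int) -> int:
        return cat * fpc + int(rng.integers(fpc))

    subsets: list[FeatureSubset] = []
    for _ in range(3):
        subsets.append(FeatureSubset([feat(c) for c in range(C)]))
    n_rest = config.n_subsets - 3
    for i in range(n_rest):
        if i < n_rest // 2:  # single-category subset: two categories missing
            cat = int(rng.integers(C))
            cats = [cat] * config.subset_size
        else:  # exactly two categories present: one missing
            pair = rng.choice(C, size=2, replace=False)
            cats = [int(pair[0]), int(pair[1])]
            cats += [int(pair[rng.integers(2)]) for _ in range(config.subset_size - 2)]
        subsets.append(FeatureSubset([feat(c) for c in cats]))
    return subsets


def fit_logistic_error(
    table: LabeledTable,
    subset: FeatureSubset,
    theta_star: np.ndarray,
    cmap: CategoryMap,
    rng: "np.random.Generator | None" = None,
    ridge: float = 1e-3,
) -> float:
    """Euclidean distance between fitted and true logistic coefficients.

    The logistic model is fitted (ridge-stabilised, so separable or
    collinear designs stay finite) on the subset's columns over the whole
    table.  Each selected feature inherits the true coefficient of its
    category; the intercept is excluded from the norm.  Subsets missing a
    category cannot recover its coefficient and keep an error bounded away
    from zero.
    """
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    subset.validate(table.p)
    cats = sorted({str(c) for c in cmap.mapping.values()})
    if len(cats) != len(theta_star):
        raise ValueError("theta_star length must equal the number of categories")
    theta_by_cat = dict(zip(cats, np.asarray(theta_star, dtype=float)))
    X = table.values[:, list(subset.indices)]
    beta = fit_ridge_logistic(X, table.labels, ridge=ridge)
    truth = np.array(
        [
            theta_by_cat[str(cmap.category_of(table.feature_ids[i]))]
            for i in subset.indices
        ]
    )
    return float(np.linalg.norm(beta[1:] - truth))


def toy_games() -> dict[str, MatrixGame]:
    """Named small game fixtures with known equilibria."""
    return {
        # unique mixed equilibrium (1/2, 1/2), value 1/2
        "matching_pennies": MatrixGame([[1.0, 0.0], [0.0, 1.0]]),
        # rock-paper-scissors rescaled to [0, 1]: uniform equilibrium, value 1/2
        "rps": MatrixGame(
            [[0.5, 1.0, 0.0], [0.0, 0.5, 1.0], [1.0, 0.0, 0.5]]
        ),
        # row 1 dominates; the column player best-responds with the 0.9 column
        "dominated_2x2": MatrixGame([[1.0, 0.9], [0.1, 0.0]]),
    }


_BASE_BLOCKS = {
    1: np.array([[0.5]]),
    2: np.array([[0.75, 0.25], [0.25, 0.75]]),
    3: np.array([[0.5, 1.0, 0.0], [0.0, 0.5, 1.0], [1.0, 0.0, 0.5]]),
}


def planted_support_game(
    k_prime: int,
    K: int = 10,
    seed: "int | np.random.Generator | None" = None,
    margin: float = 0.2,
    verify: bool = False,
) -> MatrixGame:
    """Random K x K game with a unique equilibrium of support size k_prime.

    A k' x k' block with a unique fully-mixed equilibrium of value 1/2 is
    embedded at random row/column positions; every other row pays strictly
    below the value against the block columns (so the row player shuns it)
    and every other column strictly above it (so the column player does),
    with margins jittered around ``margin``.  ``verify=True`` re-derives the
    support with the LP oracle and asserts it matches the construction.
    """
    if k_prime not in _BASE_BLOCKS:
        raise ValueError("supported planted support sizes are 1, 2, 3")
    if K < k_prime:
        raise ValueError(f"K={K} smaller than planted support {k_prime}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    jitter = lambda size: margin + rng.uniform(-0.05, 0.05, size=size)
    M = np.empty((K, K))
    M[:, :] = 0.5 - jitter((K, K))          # dominated rows (low payoff)
    M[:k_prime, :] = 0.5 + jitter((k_prime, K))  # dominated columns (high payoff)
    M[:k_prime, :k_prime] = _BASE_BLOCKS[k_prime]
    row_order = rng.permutation(K)  # new row r holds old row row_order[r]
    col_order = rng.permutation(K)
    M = M[row_order][:, col_order]
    game = MatrixGame(np.clip(M, 0.0, 1.0))
    if verify:
        eq = exact_nash_lp(game)
        assert set(np.flatnonzero(eq.x > 0)) == set(
            np.flatnonzero(row_order < k_prime)
        )
        assert set(np.flatnonzero(eq.y > 0)) == set(
            np.flatnonzero(col_order < k_prime)
        )
    return game
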