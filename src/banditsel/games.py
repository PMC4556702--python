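"""Zero-sum matrix games: exact equilibria by LP, epsilon-Nash certification,
and approximate sparse solving by EXP3 self-play with thresholding.

A matrix game is given by a payoff matrix ``M`` of shape ``(k1, k2)`` with
entries in [0, 1]; the row player receives ``M[i, j]`` and the column player
``-M[i, j]``.  A Nash equilibrium is a pair of mixed strategies that are
mutual best responses; its exploitability (the smallest epsilon for which the
pair is an epsilon-Nash equilibrium) is

    max( max_i (M y)_i - x' M y,  x' M y - min_j (x' M)_j ),

zero exactly at equilibria.  Exact equilibria are computed by linear
programming; the sparse approximate solver runs two independent EXP3 learners
in self-play (the column player maximises ``1 - M[i, j]`` so both rewards stay
in EXP3's [0, 1] domain) and then prunes the resulting distributions with the
``t**alpha / t`` threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import linprog

from .bandit import (
    ThresholdRule,
    exp3_draw,
    exp3_init,
    exp3_probabilities,
    exp3_update,
    threshold_distribution,
)

__all__ = [
    "MatrixGame",
    "EquilibriumApprox",
    "payoff_draw",
    "exact_nash_lp",
    "exploitability",
    "solve_game_exp3",
]

_SUPPORT_TOL = 1e-9


@dataclass
class MatrixGame:
    """A two-player zero-sum game in strategic form.

    ``payoffs[i, j]`` is the row player's (expected) reward, in [0, 1].  An
    optional ``stochastic_sampler(i, j, rng)`` draws a random reward in
    [0, 1] whose expectation is ``payoffs[i, j]``; when absent the game is
    deterministic.  Strategy indices are 0-based in code (1-based in prose).
    """

    payoffs: np.ndarray
    stochastic_sampler: Optional[
        Callable[[int, int, np.random.Generator], float]
    ] = None

    def __post_init__(self) -> None:
        self.payoffs = np.asarray(self.payoffs, dtype=float)
        if self.payoffs.ndim != 2 or min(self.payoffs.shape) < 1:
            raise ValueError("payoff matrix must be 2-D with k1, k2 >= 1")
        if not np.isfinite(self.payoffs).all():
            raise ValueError("payoff matrix must be finite")
        if self.payoffs.min() < 0.0 or self.payoffs.max() > 1.0:
            raise ValueError("payoffs must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.payoffs.shape

    @classmethod
    def from_csv(cls, path) -> "MatrixGame":
        """Read a headerless CSV of reals as a deterministic game."""
        m = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls(m)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.payoffs, delimiter=",", fmt="%.17g")


@dataclass
class EquilibriumApprox:
    """An (approximate) equilibrium: strategies, value, and certificate.

    ``epsilon`` is the exploitability of ``(x, y)``; ``support_sizes`` counts
    the strictly positive entries of each strategy.
    """

    x: np.ndarray
    y: np.ndarray
    value: float
    epsilon: float
    support_sizes: tuple[int, int]
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "x": list(self.x),
                "y": list(self.y),
                "value": self.value,
                "epsilon": self.epsilon,
                "support_sizes": list(self.support_sizes),
                **self.meta,
            }
        )


def payoff_draw(
    game: MatrixGame, i: int, j: int, rng: "np.random.Generator | None" = None
) -> float:
    """Reward of the pure-strategy pair ``(i, j)`` (0-based).

    Deterministic games return the matrix cell exactly; stochastic games draw
    from the cell's reward distribution (mean ``payoffs[i, j]``).
    """
    k1, k2 = game.shape
    if not (0 <= i < k1 and 0 <= j < k2):
        raise IndexError(f"strategy pair ({i}, {j}) out of range for {k1}x{k2} game")
    if game.stochastic_sampler is None:
        return float(game.payoffs[i, j])
    if rng is None:
        rng = np.random.default_rng()
    r = float(game.stochastic_sampler(i, j, rng))
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"stochastic payoff {r} outside [0, 1] at ({i}, {j})")
    return r


def exploitability(game: MatrixGame, x: np.ndarray, y: np.ndarray) -> float:
    """Smallest epsilon for which ``(x, y)`` is an epsilon-Nash pair.

    Computed by enumerating pure best responses; always >= 0, and 0 iff the
    pair is an exact equilibrium.
    """
    M = game.payoffs
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != (M.shape[0],) or y.shape != (M.shape[1],):
        raise ValueError(
            f"strategy shapes {x.shape}/{y.shape} do not match game {M.shape}"
        )
    My = M @ y
    xM = x @ M
    v = float(x @ My)
    return max(float(My.max()) - v, v - float(xM.min()), 0.0)


def _clean_distribution(p: np.ndarray) -> np.ndarray:
    p = np.where(p > _SUPPORT_TOL, p, 0.0)
    return p / p.sum()


def _lp_best_strategy(M: np.ndarray) -> tuple[np.ndarray, float]:
    """Row player's maximin strategy of ``M`` and the game value, by LP.

    Variables (x, v): maximise v subject to M' x >= v 1, sum x = 1, x >= 0.
    """
    k1, k2 = M.shape
    c = np.zeros(k1 + 1)
    c[-1] = -1.0  # maximise v
    A_ub = np.hstack([-M.T, np.ones((k2, 1))])
    b_ub = np.zeros(k2)
    A_eq = np.hstack([np.ones((1, k1)), np.zeros((1, 1))])
    b_eq = np.ones(1)
    bounds = [(0.0, None)] * k1 + [(None, None)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                  method="highs")
    if not res.success:  # cannot happen for a bounded finite game
        raise RuntimeError(f"LP solver failed: {res.message}")
    return _clean_distribution(res.x[:k1]), float(res.x[-1])


def exact_nash_lp(game: MatrixGame) -> EquilibriumApprox:
    """Exact Nash equilibrium of a deterministic game by linear programming.

    Solves the row player's maximin LP and the column player's minimax LP
    (the row maximin LP of ``1 - M.T``); the value is unique even when the
    equilibrium is not.
    """
    M = game.payoffs
    x, value = _lp_best_strategy(M)
    y, _ = _lp_best_strategy(1.0 - M.T)
    eps = exploitability(game, x, y)
    return EquilibriumApprox(
        x=x,
        y=y,
        value=float(x @ M @ y),
        epsilon=eps,
        support_sizes=(int((x > 0).sum()), int((y > 0).sum())),
        meta={"method": "lp"},
    )


def solve_game_exp3(
    game: MatrixGame,
    iterations: int,
    gamma_schedule="log",
    alpha: float = 0.75,
    seed: "int | None" = 0,
    refine: bool = False,
    keep_equal: bool = False,
    average: bool = True,
) -> EquilibriumApprox:
    """Approximate sparse equilibrium by EXP3 self-play plus thresholding.

    Both players run independent EXP3 instances and draw simultaneously each
    round; the row player's reward is the (possibly stochastic) payoff, the
    column player's is its complement ``1 - r``.  After ``iterations`` rounds
    each player's distribution is pruned at ``iterations**alpha / iterations``
    and renormalised.

    The equilibrium estimate defaults to the time-average of the played
    distributions: in self-play the last iterate of exponential-weights
    dynamics cycles around interior equilibria (measurably so on matching
    pennies) while averaged play carries the classical no-regret guarantee;
    ``average=False`` returns the final-round distributions instead.

    With ``refine=True`` a second self-play pass is run on the sub-game
    restricted to the surviving supports and thresholded again (re-optimising
    the probabilities of the retained strategies).
    """
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    k1, k2 = game.shape
    ss = np.random.SeedSequence(seed)
    s_row, s_col, s_pay = ss.spawn(3)
    rng_pay = np.random.default_rng(s_pay)

    x, y = _selfplay(game, iterations, gamma_schedule, s_row, s_col, rng_pay, average)
    rule = ThresholdRule(alpha=alpha, keep_equal=keep_equal)
    x = threshold_distribution(x, iterations, rule)
    y = threshold_distribution(y, iterations, rule)

    if refine:
        rows = np.flatnonzero(x > 0)
        cols = np.flatnonzero(y > 0)
        sub = MatrixGame(
            game.payoffs[np.ix_(rows, cols)],
            stochastic_sampler=(
                None
                if game.stochastic_sampler is None
                else lambda i, j, rng: game.stochastic_sampler(
                    int(rows[i]), int(cols[j]), rng
                )
            ),
        )
        s_row2, s_col2, s_pay2 = ss.spawn(3)
        xs, ys = _selfplay(
            sub, iterations, gamma_schedule, s_row2, s_col2,
            np.random.default_rng(s_pay2), average,
        )
        xs = threshold_distribution(xs, iterations, rule)
        ys = threshold_distribution(ys, iterations, rule)
        x = np.zeros(k1)
        x[rows] = xs
        y = np.zeros(k2)
        y[cols] = ys

    eps = exploitability(game, x, y)
    return EquilibriumApprox(
        x=x,
        y=y,
        value=float(x @ game.payoffs @ y),
        epsilon=eps,
        support_sizes=(int((x > 0).sum()), int((y > 0).sum())),
        meta={
            "method": "exp3",
            "iterations": iterations,
            "alpha": alpha,
            "seed": seed,
            "refine": refine,
            "average": average,
        },
    )


def _selfplay(game, iterations, gamma_schedule, s_row, s_col, rng_pay, average):
    k1, k2 = game.shape
    row = exp3_init(k1, gamma_schedule, np.random.default_rng(s_row))
    col = exp3_init(k2, gamma_schedule, np.random.default_rng(s_col))
    acc_x = np.zeros(k1) if average else None
    acc_y = np.zeros(k2) if average else None
    for _ in range(iterations):
        if average:
            acc_x += exp3_probabilities(row)
            acc_y += exp3_probabilities(col)
        i = exp3_draw(row)
        j = exp3_draw(col)
        r = payoff_draw(game, i, j, rng_pay)
        exp3_update(row, i, r)
        exp3_update(col, j, 1.0 - r)
    if average:
        return acc_x / iterations, acc_y / iterations
    return exp3_probabilities(row), exp3_probabilities(col)
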