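"""EXP3 adversarial bandit and the ``t**alpha / t`` thresholding rule.

The EXP3 (exponential-weights exploration/exploitation) algorithm maintains one
positive weight per arm and plays the mixture

    x_i = (1 - gamma) * w_i / sum_j w_j + gamma / K,

so every arm keeps an exploration floor of ``gamma / K``.  After drawing arm
``i_t`` and observing a reward ``r`` in [0, 1], the importance-weighted
estimate ``r / x_{i_t}`` updates only the drawn arm:

    w_{i_t} <- w_{i_t} * exp(gamma * (r / x_{i_t}) / K).

Sparsity is induced afterwards by zeroing every probability at or below
``t**alpha / t`` (``alpha`` in (0, 1)) and renormalising the survivors; the
threshold decays to zero as the number of rounds ``t`` grows, so only arms
whose probability stays bounded away from zero survive asymptotically.

Weights are stored as logarithms internally so that long runs cannot overflow;
the public ``weights`` view is only rebased (a common rescaling, which leaves
the played distribution unchanged) once the leading log-weight exceeds a large
cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GammaSchedule",
    "resolve_gamma_schedule",
    "Exp3State",
    "ThresholdRule",
    "exp3_init",
    "exp3_probabilities",
    "exp3_draw",
    "exp3_update",
    "exp3_step",
    "exp3_run",
    "threshold_distribution",
]

GammaSchedule = Callable[[int], float]

# Rebase log-weights once the leader exceeds this, to keep exp() finite.
_LOG_REBASE = 500.0


def resolve_gamma_schedule(spec: "float | str | GammaSchedule") -> GammaSchedule:
    """Turn a schedule spec into a callable ``t -> gamma``.

    Accepted specs:

    * a float ``g`` in (0, 1]: constant exploration rate;
    * the string ``"log"``: ``gamma_t = min(1, 1 / log(t + 1))``, the
      schedule used by the simulation studies (capped at 1 for t = 1, where
      ``1/log 2 > 1`` would not be a valid mixing coefficient);
    * any callable ``t -> gamma``.
    """
    if callable(spec):
        return spec
    if isinstance(spec, str):
        if spec == "log":
            return lambda t: min(1.0, 1.0 / math.log(t + 1))
        raise ValueError(f"unknown gamma schedule {spec!r}")
    g = float(spec)
    if not 0.0 < g <= 1.0:
        raise ValueError(f"constant gamma must lie in (0, 1], got {g}")
    return lambda t: g


@dataclass
class Exp3State:
    """Mutable state of one EXP3 learner over ``K`` arms."""

    K: int
    log_w: np.ndarray
    gamma_schedule: GammaSchedule
    rng: np.random.Generator
    t: int = 1

    @property
    def gamma(self) -> float:
        """Exploration rate in effect at the current round."""
        return self.gamma_schedule(self.t)

    @property
    def weights(self) -> np.ndarray:
        """The (possibly rebased) positive weight vector."""
        return np.exp(self.log_w)

    def to_dict(self) -> dict:
        """JSON-serialisable snapshot (schedules serialise only by name)."""
        return {"K": self.K, "log_w": self.log_w.tolist(), "t": self.t}


def exp3_init(
    K: int,
    gamma_schedule: "float | str | GammaSchedule" = "log",
    seed: "int | np.random.Generator | None" = None,
) -> Exp3State:
    """Fresh EXP3 state: unit weights, round counter at 1.

    At t = 1 the played distribution is uniform regardless of gamma.
    """
    if K < 1:
        raise ValueError(f"need at least one arm, got K={K}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return Exp3State(
        K=K,
        log_w=np.zeros(K),
        gamma_schedule=resolve_gamma_schedule(gamma_schedule),
        rng=rng,
    )


def exp3_probabilities(state: Exp3State) -> np.ndarray:
    """Current mixture ``(1-gamma) w_i / sum w + gamma / K``."""
    v = state.log_w - state.log_w.max()
    w = np.exp(v)
    gamma = state.gamma
    return (1.0 - gamma) * w / w.sum() + gamma / state.K


def exp3_draw(state: Exp3State) -> int:
    """Draw an arm from the current mixture (advances the state's rng)."""
    p = exp3_probabilities(state)
    # inverse-CDF draw; cheaper and bit-stable compared to rng.choice
    u = state.rng.random()
    return int(np.searchsorted(np.cumsum(p), u, side="right").clip(0, state.K - 1))


def exp3_update(state: Exp3State, arm: int, reward: float) -> Exp3State:
    """Apply the importance-weighted update for ``arm`` and advance the round.

    Only the drawn arm's weight changes.  Rewards outside [0, 1] raise; they
    are never clipped silently.
    """
    if not 0 <= arm < state.K:
        raise IndexError(f"arm {arm} out of range for K={state.K}")
    if not 0.0 <= reward <= 1.0:
        raise ValueError(f"reward must lie in [0, 1], got {reward}")
    p = exp3_probabilities(state)
    gamma = state.gamma
    rhat = reward / p[arm]
    state.log_w[arm] += gamma * rhat / state.K
    m = state.log_w.max()
    if m > _LOG_REBASE:
        state.log_w -= m
    state.t += 1
    return state


def exp3_step(
    state: Exp3State, reward_oracle: Callable[[int], float]
) -> tuple[Exp3State, int, float]:
    """One full round: draw an arm, query its reward, update."""
    arm = exp3_draw(state)
    reward = float(reward_oracle(arm))
    exp3_update(state, arm, reward)
    return state, arm, reward


def exp3_run(
    K: int,
    reward_oracle: Callable[[int], float],
    T: int,
    gamma_schedule: "float | str | GammaSchedule" = "log",
    seed: "int | np.random.Generator | None" = None,
    average: bool = False,
) -> tuple[np.ndarray, list[tuple[int, float]]]:
    """Run EXP3 for ``T`` rounds against a per-arm reward oracle.

    Returns the final-round played distribution (or the running average of the
    played distributions when ``average`` is set) and the per-round history of
    ``(arm, reward)`` pairs.  Deterministic given the seed.
    """
    if T < 1:
        raise ValueError(f"need at least one round, got T={T}")
    state = exp3_init(K, gamma_schedule, seed)
    history: list[tuple[int, float]] = []
    acc = np.zeros(K) if average else None
    for _ in range(T):
        if acc is not None:
            acc += exp3_probabilities(state)
        _, arm, reward = exp3_step(state, reward_oracle)
        history.append((arm, reward))
    if acc is not None:
        return acc / T, history
    return exp3_probabilities(state), history


@dataclass(frozen=True)
class ThresholdRule:
    """Elimination rule zeroing probabilities at or below ``t**alpha / t``.

    For fixed ``alpha`` in (0, 1) the threshold ``t**(alpha-1)`` is strictly
    decreasing in the number of rounds ``t``; for fixed ``t > 1`` it is
    increasing in ``alpha``, so larger ``alpha`` prunes more aggressively.

    ``keep_equal`` keeps entries exactly equal to the threshold (strict-``<``
    elimination) instead of zeroing them; the two conventions differ only on
    exact ties.
    """

    alpha: float = 0.75
    keep_equal: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")

    def threshold(self, t: int) -> float:
        if t < 1:
            raise ValueError(f"round count must be >= 1, got t={t}")
        return t**self.alpha / t


def threshold_distribution(
    x: Sequence[float],
    t: int,
    rule: "ThresholdRule | float" = 0.75,
    keep_equal: "bool | None" = None,
) -> np.ndarray:
    """Sparsify a probability vector by the ``t**alpha / t`` rule.

    Entries at or below the threshold are set to zero and the survivors are
    renormalised to sum to one.  If every entry falls below the threshold the
    single largest entry is kept with probability one (purification-style
    fallback: a player must always retain a playable strategy; ties resolve
    to the lowest index).  Idempotent at fixed ``(t, alpha)``.
    """
    if not isinstance(rule, ThresholdRule):
        rule = ThresholdRule(alpha=float(rule))
    if keep_equal is not None:
        rule = ThresholdRule(alpha=rule.alpha, keep_equal=keep_equal)
    x = np.asarray(x, dtype=float)
    thr = rule.threshold(t)
    keep = x >= thr if rule.keep_equal else x > thr
    if not keep.any():
        out = np.zeros_like(x)
        out[int(np.argmax(x))] = 1.0
        return out
    out = np.where(keep, x, 0.0)
    return out / out.sum()
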