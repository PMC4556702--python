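"""End-to-end drivers for the two simulation studies.

``run_smallnp_experiment`` replays the small-n-large-p stability study: over
Monte-Carlo replicates it generates a fresh 10 x 100 two-Gaussian table,
selects features by three methods — univariate t-test (top-k), EXP3 subset
ranking (features of the top-ranked subset of size k) and the thresholding
bandit (union of the features of the subsets surviving the ``t**alpha / t``
prune) — and summarises the cross-replicate stability of each method with
the relative weighted consistency CW_rel, at several feature counts.

``run_functional_experiment`` replays the functional-category study: per
replicate it generates the redundant-category data and the 15 candidate
subsets, ranks the subsets with EXP3 (accuracy rewards, gamma = 1/log(t+1)),
and records each subset's probability together with the coefficient-recovery
error of a logistic fit on the subset.

Replicates derive their seeds from the master seed by a counter, so results
are independent of any parallel execution order; every run is deterministic
given its seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .ranking import (
    LabeledTable,
    accuracy_curve,
    rank_subsets,
    sample_subsets,
    ttest_rank,
)
from .stability import SelectionCollection, cw_rel, functional_collection, i_overlap
from .synthdata import (
    FunctionalSimConfig,
    GaussianTwoClassConfig,
    fit_logistic_error,
    gen_functional_data,
    gen_functional_subsets,
    gen_small_n_large_p,
)

__all__ = [
    "SmallNPConfig",
    "FunctionalConfig",
    "StabilityReport",
    "FunctionalResult",
    "run_smallnp_experiment",
    "run_functional_experiment",
]

logger = logging.getLogger("banditsel")

METHODS = ("ttest", "exp3", "exp3_threshold")


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    # counter-based derivation: independent of worker scheduling
    return np.random.default_rng(np.random.SeedSequence([seed, rep]))


@dataclass
class SmallNPConfig:
    """Study conditions of the small-n-large-p stability experiment."""

    reps: int = 200
    data: GaussianTwoClassConfig = field(default_factory=GaussianTwoClassConfig)
    feature_counts: tuple[int, ...] = (5, 7, 10)
    n_subsets: int = 50
    iterations: int = 2000
    alpha: float = 0.75
    gamma_schedule: "float | str" = "log"
    split_fraction: float = 0.5
    ridge: float = 1.0
    accuracy_curve_reps: int = 0  # per-rank accuracy repetitions (0 = skip)
    # The candidate subsets are part of the study design: by default they are
    # drawn once (from the master seed) and shared by all data replicates, so
    # cross-replicate stability measures how consistently the methods pick
    # among one fixed menu of subsets.  Resampling them per replicate bounds
    # every subset-based method's stability near the random-selection level.
    resample_subsets_per_rep: bool = False


@dataclass
class StabilityReport:
    """Per-method, per-feature-count stability of repeated selection."""

    cw_rel: pd.DataFrame
    i_overlap: pd.DataFrame
    selections: dict
    accuracy_curves: dict
    config: SmallNPConfig
    seed: int
    failed_reps: int = 0

    def to_dict(self) -> dict:
        return {
            "cw_rel": {m: dict(self.cw_rel.loc[m]) for m in self.cw_rel.index},
            "i_overlap": {
                m: dict(self.i_overlap.loc[m]) for m in self.i_overlap.index
            },
            "seed": self.seed,
            "reps": self.config.reps,
            "failed_reps": self.failed_reps,
        }


def run_smallnp_experiment(config: SmallNPConfig, seed: int = 0) -> StabilityReport:
    """Run the small-n-large-p stability study.

    Returns a report with CW_rel and I-overlap per method and feature count,
    plus the raw selected sets for any further stability analysis.
    """
    selections = {
        (m, k): [] for m in METHODS for k in config.feature_counts
    }
    design_rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
    fixed_subsets = {
        k: sample_subsets(config.data.p, config.n_subsets, k, seed=design_rng)
        for k in config.feature_counts
    }
    curves: dict = {}
    failed = 0
    t0 = time.perf_counter()
    for rep in range(config.reps):
        rng = _rep_rng(seed, rep)
        table = gen_small_n_large_p(config.data, rng)
        try:
            for k in config.feature_counts:
                sel_t = ttest_rank(table, k).top_feature_ids(table)
                selections[("ttest", k)].append(sel_t)
                if config.resample_subsets_per_rep:
                    subsets = sample_subsets(table.p, config.n_subsets, k, seed=rng)
                else:
                    subsets = fixed_subsets[k]
                ens = rank_subsets(
                    table,
                    subsets,
                    T=config.iterations,
                    gamma_schedule=config.gamma_schedule,
                    alpha=config.alpha,
                    seed=rng,
                    split_fraction=config.split_fraction,
                    ridge=config.ridge,
                )
                selections[("exp3", k)].append(
                    ens.selected_features(table, thresholded=False)
                )
                selections[("exp3_threshold", k)].append(
                    ens.selected_features(table, thresholded=True)
                )
                if rep == 0 and config.accuracy_curve_reps > 0:
                    curves[k] = accuracy_curve(
                        table, ens, config.accuracy_curve_reps, rng
                    )
        except ValueError as exc:  # degenerate replicate: record and skip
            logger.warning("rep %d failed: %s", rep, exc)
            failed += 1
            continue
        logger.debug("rep %d done (%.2fs)", rep, time.perf_counter() - t0)

    universe = [f"f{j + 1}" for j in range(config.data.p)]
    cw_tab = pd.DataFrame(index=list(METHODS), columns=list(config.feature_counts),
                          dtype=float)
    io_tab = cw_tab.copy()
    for (m, k), sets in selections.items():
        coll = SelectionCollection(sets, universe)
        cw_tab.loc[m, k] = cw_rel(coll)
        io_tab.loc[m, k] = i_overlap(coll)
    logger.info(
        "small-n-large-p experiment: %d reps (%d failed) in %.1fs",
        config.reps, failed, time.perf_counter() - t0,
    )
    return StabilityReport(
        cw_rel=cw_tab,
        i_overlap=io_tab,
        selections=selections,
        accuracy_curves=curves,
        config=config,
        seed=seed,
        failed_reps=failed,
    )


@dataclass
class FunctionalConfig:
    """Study conditions of the functional-category ranking experiment."""

    reps: int = 200
    data: FunctionalSimConfig = field(default_factory=FunctionalSimConfig)
    iterations: int = 5000
    alpha: float = 0.75
    gamma_schedule: "float | str" = "log"
    split_fraction: float = 0.5
    ridge: float = 1.0
    error_ridge: float = 1e-3


@dataclass
class FunctionalResult:
    """Per-replicate subset probabilities and coefficient-recovery errors."""

    probs: np.ndarray  # (reps, n_subsets) raw final distributions
    thresholded: np.ndarray  # (reps, n_subsets) after the t**alpha/t prune
    errors: np.ndarray  # (reps, n_subsets) ||theta_star - theta_hat||
    config: FunctionalConfig
    seed: int

    @property
    def n_optimal(self) -> int:
        return 3

    def optimal_mass(self, thresholded: bool = True) -> np.ndarray:
        """Per-replicate total probability on the optimal subsets (1-3)."""
        dist = self.thresholded if thresholded else self.probs
        return dist[:, : self.n_optimal].sum(axis=1)

    def median_optimal_mass(self, thresholded: bool = True) -> float:
        return float(np.median(self.optimal_mass(thresholded)))

    def error_separation_rate(self) -> float:
        """Fraction of replicates where every suboptimal subset has a larger
        coefficient error than every optimal one."""
        opt = self.errors[:, : self.n_optimal].max(axis=1)
        sub = self.errors[:, self.n_optimal:].min(axis=1)
        return float((sub > opt).mean())

    def summary(self) -> dict:
        return {
            "median_optimal_mass_raw": self.median_optimal_mass(False),
            "median_optimal_mass_thresholded": self.median_optimal_mass(True),
            "error_separation_rate": self.error_separation_rate(),
            "mean_probs": self.probs.mean(axis=0).tolist(),
            "mean_errors": self.errors.mean(axis=0).tolist(),
            "reps": self.config.reps,
            "seed": self.seed,
        }


def run_functional_experiment(
    config: FunctionalConfig, seed: int = 0
) -> FunctionalResult:
    """Run the functional-category ranking study."""
    n_sub = config.data.n_subsets
    probs = np.zeros((config.reps, n_sub))
    thr = np.zeros((config.reps, n_sub))
    errs = np.zeros((config.reps, n_sub))
    t0 = time.perf_counter()
    for rep in range(config.reps):
        rng = _rep_rng(seed, rep)
        table, cmap, theta = gen_functional_data(config.data, rng)
        subsets = gen_functional_subsets(config.data, rng)
        ens = rank_subsets(
            table,
            subsets,
            T=config.iterations,
            gamma_schedule=config.gamma_schedule,
            alpha=config.alpha,
            seed=rng,
            split_fraction=config.split_fraction,
            ridge=config.ridge,
        )
        probs[rep] = ens.probs
        thr[rep] = ens.thresholded
        errs[rep] = [
            fit_logistic_error(table, s, theta, cmap, ridge=config.error_ridge)
            for s in subsets
        ]
        logger.debug("functional rep %d done (%.2fs)", rep, time.perf_counter() - t0)
    logger.info(
        "functional experiment: %d reps in %.1fs", config.reps,
        time.perf_counter() - t0,
    )
    return FunctionalResult(
        probs=probs, thresholded=thr, errors=errs, config=config, seed=seed
    )
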