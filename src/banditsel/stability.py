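"""Similarity and stability statistics for repeated feature selection.

Given omega selected feature sets S_1..S_omega over a universe F, with
Omega = sum_i |S_i| and F_f the number of sets containing feature f:

* **I-overlap** — the mean intersection-over-union over all unordered pairs
  of sets; 1 for identical selections, 0 for pairwise disjoint ones.

* **CW (weighted consistency)** — ``sum_f (F_f/Omega) * (F_f-1)/(omega-1)``,
  equivalently ``(sum_f F_f**2 - Omega) / (Omega*(omega-1))``; 1 when all
  runs select one identical set, 0 when no feature is ever re-selected.

* **CW_rel (relative weighted consistency)** — CW rescaled by its minimum and
  maximum over all collections with the same totals (Omega, omega, |F|),
  which removes the subset-size bias of raw CW.

The extremes CWmin/CWmax follow from CW being monotone in ``sum_f F_f**2``
under the constraints ``sum_f F_f = Omega`` and ``0 <= F_f <= omega`` (any
such count vector is realisable as a collection): the minimum spreads counts
as evenly as possible over the universe, the maximum concentrates them on as
few features as possible.  The closed forms are gate-checked against an
exhaustive enumeration oracle in the test suite.

Functional stability applies the same statistics after mapping each selected
set to the set of *distinct* functional categories (e.g. GO terms) its
features hit — two disjoint gene sets drawn from the same pathway are
functionally identical even though their feature-level overlap is zero.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Iterable, Mapping

__all__ = [
    "SelectionCollection",
    "CategoryMap",
    "UNCATEGORIZED",
    "i_overlap",
    "cw",
    "cw_bounds",
    "cw_rel",
    "functional_collection",
]

UNCATEGORIZED = "uncategorized"


@dataclass
class SelectionCollection:
    """omega selected feature sets over a common universe."""

    sets: list[frozenset]
    universe: frozenset

    def __init__(self, sets: Iterable[Iterable[Hashable]], universe: Iterable[Hashable]):
        self.sets = [frozenset(s) for s in sets]
        self.universe = frozenset(universe)
        stray = frozenset().union(*self.sets, frozenset()) - self.universe
        if stray:
            raise ValueError(
                f"{len(stray)} selected feature(s) outside the universe, "
                f"e.g. {sorted(map(str, stray))[:3]}"
            )

    @property
    def omega(self) -> int:
        """Number of selection runs."""
        return len(self.sets)

    @property
    def Omega(self) -> int:
        """Total number of selections, sum of set cardinalities."""
        return sum(len(s) for s in self.sets)

    @property
    def counts(self) -> Counter:
        """F_f: per-feature occurrence counts across the runs."""
        c: Counter = Counter()
        for s in self.sets:
            c.update(s)
        return c


def i_overlap(collection: SelectionCollection) -> float:
    """Mean pairwise intersection-over-union similarity.

    Convention for degenerate pairs: two empty sets count as fully similar
    (1); one empty and one non-empty set count as fully dissimilar (0).
    """
    if collection.omega < 2:
        raise ValueError("need at least two selection runs")
    total = 0.0
    npairs = 0
    for a, b in combinations(collection.sets, 2):
        union = len(a | b)
        total += 1.0 if union == 0 else len(a & b) / union
        npairs += 1
    return total / npairs


def cw(collection: SelectionCollection) -> float:
    """Weighted consistency ``sum_f (F_f/Omega) (F_f-1)/(omega-1)``."""
    omega = collection.omega
    Omega = collection.Omega
    if omega < 2:
        raise ValueError("need at least two selection runs")
    if Omega == 0:
        raise ValueError("weighted consistency undefined for all-empty runs")
    sum_sq = sum(f * f for f in collection.counts.values())
    return (sum_sq - Omega) / (Omega * (omega - 1))


def cw_bounds(Omega: int, omega: int, universe_size: int) -> tuple[float, float]:
    """(CWmin, CWmax): extremes of CW over collections with matched totals.

    With ``D = Omega mod universe_size`` the minimum spreads the Omega
    selections as evenly as possible over the universe; with
    ``H = Omega mod omega`` the maximum places full count omega on
    ``Omega // omega`` features and the remainder H on one more.
    """
    if omega < 2:
        raise ValueError("need omega >= 2 runs")
    if Omega < 1:
        raise ValueError("need at least one selection in total")
    if universe_size < 1:
        raise ValueError("universe must be non-empty")
    if Omega > omega * universe_size:
        raise ValueError(
            f"infeasible totals: Omega={Omega} exceeds omega*|F|="
            f"{omega * universe_size}"
        )
    m = universe_size
    k, D = divmod(Omega, m)
    sum_sq_min = D * (k + 1) ** 2 + (m - D) * k * k
    q, H = divmod(Omega, omega)
    sum_sq_max = q * omega * omega + H * H
    denom = Omega * (omega - 1)
    return (sum_sq_min - Omega) / denom, (sum_sq_max - Omega) / denom


def cw_rel(collection: SelectionCollection) -> float:
    """Relative weighted consistency ``(CW - CWmin) / (CWmax - CWmin)``.

    Clipped to [0, 1] against floating error.  When the bounds coincide
    (a fully constrained collection, e.g. every run forced to select the
    whole universe) the statistic carries no information: NaN is returned
    with a warning rather than a silent number.
    """
    lo, hi = cw_bounds(collection.Omega, collection.omega, len(collection.universe))
    if hi - lo <= 1e-15:
        warnings.warn(
            "CWmax equals CWmin for these totals; relative weighted "
            "consistency is undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    val = (cw(collection) - lo) / (hi - lo)
    return min(1.0, max(0.0, val))


class CategoryMap:
    """Many-to-one map from feature IDs to functional category IDs.

    Features absent from the mapping fall into an explicit
    ``"uncategorized"`` bucket; lookups of such features are counted in
    ``n_unmapped_lookups``.
    """

    def __init__(self, mapping: Mapping[Hashable, Hashable]):
        self.mapping = dict(mapping)
        self.n_unmapped_lookups = 0

    def category_of(self, feature: Hashable) -> Hashable:
        try:
            return self.mapping[feature]
        except KeyError:
            self.n_unmapped_lookups += 1
            return UNCATEGORIZED

    def categories(self, features: Iterable[Hashable]) -> frozenset:
        """Distinct categories hit by a feature set."""
        return frozenset(self.category_of(f) for f in features)

    @classmethod
    def from_tsv(cls, path) -> "CategoryMap":
        """Read a 2-column (feature_id, category_id) TSV; IDs are opaque."""
        mapping = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, "
                        f"got {len(parts)}"
                    )
                mapping[parts[0]] = parts[1]
        return cls(mapping)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for feat, cat in self.mapping.items():
                fh.write(f"{feat}\t{cat}\n")


def functional_collection(
    collection: SelectionCollection, cmap: CategoryMap
) -> SelectionCollection:
    """Lift a feature-level collection to the functional-category level.

    Each selected set becomes the set of distinct categories its features
    hit (deduplicated: hitting a category twice is not more stable), and the
    universe becomes the set of categories reachable from the feature
    universe.  ``cw_rel`` of the result is the functional stability.
    """
    cat_universe = cmap.categories(collection.universe)
    return SelectionCollection(
        [cmap.categories(s) for s in collection.sets], cat_universe
    )
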