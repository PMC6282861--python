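"""Population structure, treatment effects, and information arithmetic.

The full trial population is partitioned into J disjoint subgroups with
known prevalences.  Candidate populations for selection are unions of
subgroups (typically a nested chain such as S1 < S1+2 < F).  Test
statistics follow ``Z_s ~ N(I_s * theta_s, 1)`` where ``I_s`` is the
*information level*: the reciprocal standard error of the treatment
difference estimate, ``1/(sigma*sqrt(1/n_T + 1/n_C))``.  With 1:1
allocation this is ``sqrt(n)/(2*sigma)``.  Squared information levels
add across independent stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationSet",
    "EffectConfig",
    "InformationSchedule",
    "information_level",
    "composite_effect",
    "correlation_matrix",
    "round_to_subgroup_integer",
]

_PREV_TOL = 1e-12


@dataclass(frozen=True)
class PopulationSet:
    """Disjoint subgroups plus the ordered candidate populations.

    Parameters
    ----------
    prevalences
        Per-subgroup prevalences ``lambda_1..lambda_J``; must sum to 1.
    members
        Candidate populations in selection-priority order, each a set of
        subgroup indices in ``1..J`` (1-based, as in standard subgroup
        notation).  Defaults to the nested chain ``{1}, {1,2}, ..., F``.
    """

    prevalences: tuple[float, ...]
    members: tuple[frozenset[int], ...] = ()

    def __post_init__(self) -> None:
        prev = tuple(float(p) for p in self.prevalences)
        object.__setattr__(self, "prevalences", prev)
        if any(p <= 0 for p in prev):
            raise ValueError("every subgroup prevalence must be positive")
        if abs(sum(prev) - 1.0) > 1e-9:
            raise ValueError(f"prevalences must sum to 1, got {sum(prev)!r}")
        if not self.members:
            members = tuple(
                frozenset(range(1, k + 1)) for k in range(1, self.n_subgroups + 1)
            )
            object.__setattr__(self, "members", members)
        else:
            members = tuple(frozenset(int(i) for i in m) for m in self.members)
            object.__setattr__(self, "members", members)
        seen = set()
        full = set(range(1, self.n_subgroups + 1))
        for m in self.members:
            if not m:
                raise ValueError("candidate population labels must be nonempty")
            if not m <= full:
                raise ValueError(f"label {set(m)} is not a subset of 1..J")
            if m in seen:
                raise ValueError(f"duplicate candidate population {set(m)}")
            seen.add(m)

    # -- constructors ---------------------------------------------------
    @classmethod
    def two_population(cls, lambda1: float) -> "PopulationSet":
        """Subgroup-versus-full candidate set {S1, F} with prev(S1)=lambda1."""
        return cls((lambda1, 1.0 - lambda1), (frozenset({1}), frozenset({1, 2})))

    @classmethod
    def nested_chain(cls, prevalences) -> "PopulationSet":
        """The chain {1}, {1,2}, ..., {1..J} over the given prevalences."""
        return cls(tuple(prevalences))

    # -- basic accessors ------------------------------------------------
    @property
    def n_subgroups(self) -> int:
        return len(self.prevalences)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_prevalence(self, member: frozenset[int] | int) -> float:
        m = self.members[member] if isinstance(member, int) else frozenset(member)
        if not m:
            raise ValueError("empty population label")
        return sum(self.prevalences[j - 1] for j in m)

    @property
    def member_prevalences(self) -> np.ndarray:
        return np.array([self.member_prevalence(m) for m in self.members])

    def member_label(self, w: int) -> str:
        m = self.members[w]
        if m == frozenset(range(1, self.n_subgroups + 1)):
            return "F"
        return "S" + "+".join(str(j) for j in sorted(m))

    @property
    def member_labels(self) -> tuple[str, ...]:
        return tuple(self.member_label(w) for w in range(self.n_members))

    def member_index(self, label: str) -> int:
        try:
            return self.member_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown population label {label!r}") from None


@dataclass(frozen=True)
class EffectConfig:
    """True per-subgroup treatment differences and the common outcome SD."""

    thetas: tuple[float, ...]
    sigma: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "thetas", tuple(float(t) for t in self.thetas))
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @classmethod
    def single_effect(cls, n_subgroups: int, delta: float, sigma: float = 1.0,
                      which: int = 1) -> "EffectConfig":
        """Exactly one subgroup carries the effect delta, all others zero."""
        th = [0.0] * n_subgroups
        th[which - 1] = delta
        return cls(tuple(th), sigma)


def information_level(n_total: float, sigma: float, allocation: float = 1.0) -> float:
    """Reciprocal standard error of the treatment-difference estimate.

    ``allocation`` is the treatment:control ratio; for 1:1 the result is
    ``sqrt(n_total)/(2*sigma)``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_total < 2:
        raise ValueError("need at least one patient per arm")
    if allocation <= 0:
        raise ValueError("allocation ratio must be positive")
    n_t = n_total * allocation / (1.0 + allocation)
    n_c = n_total - n_t
    if n_t <= 0 or n_c <= 0:
        raise ValueError("both arms must be nonempty")
    return 1.0 / (sigma * math.sqrt(1.0 / n_t + 1.0 / n_c))


def composite_effect(population_set: PopulationSet, effect_config: EffectConfig,
                     member) -> float:
    """Prevalence-weighted effect of a union of subgroups.

    ``theta_L = sum_{j in L} lambda_j theta_j / sum_{j in L} lambda_j``.
    """
    if isinstance(member, int):
        m = population_set.members[member]
    else:
        m = frozenset(member)
    if not m:
        raise ValueError("empty population label")
    lam = population_set.prevalences
    th = effect_config.thetas
    num = sum(lam[j - 1] * th[j - 1] for j in m)
    den = sum(lam[j - 1] for j in m)
    return num / den


def _pair_correlation(a: frozenset[int], b: frozenset[int],
                      population_set: PopulationSet) -> float:
    if a == b:
        return 1.0
    if not (a & b):
        return 0.0
    if a < b or b < a:
        small, big = (a, b) if a < b else (b, a)
        return math.sqrt(population_set.member_prevalence(small)
                         / population_set.member_prevalence(big))
    raise ValueError(
        f"populations {set(a)} and {set(b)} partially overlap; only nested "
        "or disjoint candidate populations are supported"
    )


def correlation_matrix(population_set: PopulationSet) -> np.ndarray:
    """Stage-wise correlation matrix of the candidate test statistics.

    For nested U < V the shared patients give ``corr = sqrt(n_U/n_V) =
    sqrt(prev(U)/prev(V))``; disjoint populations are independent.
    """
    m = population_set.n_members
    R = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            R[i, j] = R[j, i] = _pair_correlation(
                population_set.members[i], population_set.members[j],
                population_set)
    return R


def round_to_subgroup_integer(n: float, population_set: PopulationSet,
                              max_scan: int = 10000) -> int:
    """Smallest integer total >= n for which every subgroup count is integral.

    Subgroup sample sizes are fixed as ``lambda_j * n``; final reported
    totals are rounded up until each of those products is a whole number
    (e.g. a multiple of 2 for prevalences 0.5/0.5, of 3 for thirds).
    Falls back to the plain ceiling when no such total exists nearby
    (irrational prevalences).
    """
    start = math.ceil(n - 1e-9)
    lam = np.asarray(population_set.prevalences)
    for total in range(start, start + max_scan):
        counts = lam * total
        if np.all(np.abs(counts - np.round(counts)) < 1e-6):
            return total
    return start


@dataclass(frozen=True)
class InformationSchedule:
    """Per-stage accumulated sample sizes and information for one population.

    ``stage_totals`` are the patients accrued to this population per stage
    (both arms combined; may be fractional during sample-size searches).
    """

    stage_totals: tuple[float, ...]
    sigma: float = 1.0
    allocation: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage_totals",
                           tuple(float(n) for n in self.stage_totals))
        if any(n < 0 for n in self.stage_totals):
            raise ValueError("stage sample sizes must be nonnegative")

    @property
    def cumulative_totals(self) -> np.ndarray:
        return np.cumsum(self.stage_totals)

    def information(self, stage: int) -> float:
        """Accumulated information level through ``stage`` (1-based)."""
        n = float(self.cumulative_totals[stage - 1])
        return information_level(n, self.sigma, self.allocation)
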