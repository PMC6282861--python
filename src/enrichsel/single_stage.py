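"""Single-stage design calibration: critical value, power, sample size.

The shared critical value ``C_alpha`` solves

    sum_w  P(select w, Z_w >= C) = alpha     under the global null,

which controls the family-wise error rate in the weak sense; because
the global null maximizes the error probability under maximum-statistic
selection, weak control implies strong control.  Two power definitions
are supported: rejecting the null of a prespecified target population
after having selected it ("select-target-and-reject"), and rejecting
any null among an interest set ("reject-any").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .density import SelectionDensity
from .populations import (EffectConfig, PopulationSet,
                          round_to_subgroup_integer)

__all__ = ["DesignSpec", "SingleStageDesign", "critical_value", "power",
           "required_sample_size"]

#: tolerance on the FWER scale for the critical-value root
FWER_TOL = 1e-6
#: bisection tolerance on the critical value itself
C_TOL = 1e-8
#: sample-size search cap
N_MAX = 1e7


@dataclass(frozen=True)
class DesignSpec:
    """Error rates and decision rules for a selection design."""

    population_set: PopulationSet
    alpha: float = 0.025
    beta: float = 0.2
    stages: int = 1
    selection_rule: str = "max"
    power_definition: str = "select-target-and-reject"
    target: int | None = None          # member index for the target definition
    interest_set: tuple[int, ...] | None = None  # members for reject-any
    allocation: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")
        if self.stages < 1:
            raise ValueError("need at least one stage")
        if self.power_definition not in ("select-target-and-reject", "reject-any"):
            raise ValueError(f"unknown power definition {self.power_definition!r}")
        if self.power_definition == "select-target-and-reject" and self.target is None:
            raise ValueError("target population required for this power definition")


@dataclass(frozen=True)
class SingleStageDesign:
    """Calibrated single-stage design: critical value and total sample size."""

    spec: DesignSpec
    effect_config: EffectConfig
    critical_value: float
    n_full: int
    achieved_power: float


def critical_value(population_set: PopulationSet, alpha: float,
                   allocation: float = 1.0) -> float:
    """Solve for the shared critical value at one-sided FWER ``alpha``.

    Bracketed between the single-test quantile (no selection penalty)
    and the Bonferroni quantile plus margin.  The value does not depend
    on the sample size: under the global null every candidate statistic
    is standard normal and only the correlation structure matters.
    """
    m = population_set.n_members
    null = EffectConfig((0.0,) * population_set.n_subgroups, 1.0)
    dens = SelectionDensity(population_set, null, n_full=100.0,
                            allocation=allocation)

    def excess(c: float) -> float:
        return dens.total_tail_probability(c) - alpha

    lo = norm.ppf(1 - alpha) - 1e-9
    hi = norm.ppf(1 - alpha / m) + 0.5
    if excess(lo) < -FWER_TOL:
        return float(norm.ppf(1 - alpha))
    if excess(hi) > 0:
        raise RuntimeError("critical value not bracketed; check the population set")
    return float(brentq(excess, lo, hi, xtol=C_TOL))


def power(spec: DesignSpec, effect_config: EffectConfig, n_full: float,
          c_alpha: float) -> float:
    """Probability of the powered event at sample size ``n_full``."""
    dens = SelectionDensity(spec.population_set, effect_config, n_full,
                            spec.allocation)
    if spec.power_definition == "select-target-and-reject":
        return dens.tail_probability(spec.target, c_alpha)
    members = (spec.interest_set if spec.interest_set is not None
               else range(spec.population_set.n_members))
    return sum(dens.tail_probability(w, c_alpha) for w in members)


def required_sample_size(spec: DesignSpec, effect_config: EffectConfig,
                         c_alpha: float | None = None) -> SingleStageDesign:
    """Smallest full-population total meeting the power requirement.

    The search runs on a continuous sample size (subgroup sizes
    ``lambda_j * n`` stay fractional inside the information formulas)
    and the result is rounded up to the nearest total that gives every
    subgroup a whole number of patients.
    """
    if c_alpha is None:
        c_alpha = critical_value(spec.population_set, spec.alpha, spec.allocation)
    goal = 1.0 - spec.beta

    def gap(n: float) -> float:
        return power(spec, effect_config, n, c_alpha) - goal

    lo, hi = 4.0, 64.0
    while gap(hi) < 0:
        lo, hi = hi, hi * 2
        if hi > N_MAX:
            raise RuntimeError(f"power {goal} unattainable below n={N_MAX:g}")
    n_star = brentq(gap, lo, hi, xtol=1e-6)
    n_int = round_to_subgroup_integer(n_star, spec.population_set)
    return SingleStageDesign(spec, effect_config, c_alpha, n_int,
                             power(spec, effect_config, n_int, c_alpha))
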