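"""Multistage (group-sequential) calibration with interim selection.

One population is selected at the first interim analysis; afterwards
all recruitment is enriched to the selected population (deselected
subgroups' allocation is reabsorbed), and the accumulated statistic
``Z_w^{1:k}`` is monitored against upper (efficacy) and lower
(futility) boundaries.  Stopping probabilities are computed by
propagating the stage-1 joint selection density through the
independent-increment Gaussian transition law on a quadrature grid,
stage by stage.  A single free boundary constant (e.g. the
O'Brien-Fleming constant) is tuned so the summed efficacy-crossing
probabilities under the global null equal the FWER level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .density import QUAD_NODES, Z_RANGE, SelectionDensity
from .populations import (EffectConfig, InformationSchedule, PopulationSet,
                          composite_effect, information_level,
                          round_to_subgroup_integer)
from .single_stage import DesignSpec, critical_value as _single_stage_c

__all__ = ["Boundaries", "MultistageDesign", "obf_boundaries",
           "transition_density", "stagewise_probabilities",
           "stagewise_probability", "calibrate_boundaries",
           "error_spending_boundaries", "required_stagewise_sample_size",
           "enrichment_information_update"]

#: tolerance on the FWER scale for boundary calibration
BOUNDARY_TOL = 1e-5
N_MAX = 1e7


@dataclass(frozen=True)
class Boundaries:
    """Per-stage stopping boundaries.

    ``lower[K-1] == upper[K-1]`` so the final analysis forces a
    decision.  ``binding`` records whether the futility bounds were
    enforced during error-rate calibration.
    """

    upper: tuple[float, ...]
    lower: tuple[float, ...]
    binding: bool = True
    family: str = "obf"

    def __post_init__(self) -> None:
        object.__setattr__(self, "upper", tuple(float(c) for c in self.upper))
        object.__setattr__(self, "lower", tuple(float(c) for c in self.lower))
        if len(self.upper) != len(self.lower):
            raise ValueError("upper and lower boundaries must align per stage")
        K = len(self.upper)
        for k in range(K - 1):
            if self.lower[k] > self.upper[k]:
                raise ValueError(f"lower bound exceeds upper bound at stage {k + 1}")
        if K and not math.isclose(self.lower[-1], self.upper[-1],
                                  rel_tol=0, abs_tol=1e-9):
            raise ValueError("final-stage bounds must coincide")

    @property
    def n_stages(self) -> int:
        return len(self.upper)


def obf_boundaries(constant: float, n_stages: int,
                   lower_bound: float = 0.0, binding: bool = True) -> Boundaries:
    """O'Brien-Fleming family: ``C_u^k = C * sqrt(K/k)``, fixed lower bound."""
    upper = tuple(constant * math.sqrt(n_stages / k)
                  for k in range(1, n_stages + 1))
    lower = tuple(min(lower_bound, upper[k]) for k in range(n_stages - 1))
    return Boundaries(upper, lower + (upper[-1],), binding, "obf")


def transition_density(z_curr, z_prev, i_curr: float, i_prev: float,
                       theta: float):
    """Conditional density of ``Z^{1:k}`` given ``Z^{1:(k-1)} = z_prev``.

    The unique Gaussian law consistent with the accumulated statistic
    being the information-weighted combination of independent stage
    increments with unit-variance margins:

        mean = z_prev * I_prev/I_curr + theta * (I_curr^2 - I_prev^2)/I_curr
        var  = (I_curr^2 - I_prev^2)/I_curr^2
    """
    if not i_curr > i_prev > 0:
        raise ValueError("information must be positive and strictly increasing")
    mean = (np.asarray(z_prev) * i_prev / i_curr
            + theta * (i_curr ** 2 - i_prev ** 2) / i_curr)
    sd = math.sqrt(i_curr ** 2 - i_prev ** 2) / i_curr
    return norm.pdf((np.asarray(z_curr) - mean) / sd) / sd


def _transition_params(z_prev: np.ndarray, i_curr: float, i_prev: float,
                       theta: float) -> tuple[np.ndarray, float]:
    mean = z_prev * i_prev / i_curr + theta * (i_curr ** 2 - i_prev ** 2) / i_curr
    sd = math.sqrt(i_curr ** 2 - i_prev ** 2) / i_curr
    return mean, sd


def enrichment_information_update(population_set: PopulationSet, selected: int,
                                  stage_sizes, sigma: float,
                                  allocation: float = 1.0,
                                  enrichment: bool = True
                                  ) -> list[InformationSchedule]:
    """Per-population accrual schedules after enriching to ``selected``.

    Stage-1 recruitment is prevalence-proportional; from stage 2 on all
    recruits come from the selected population (so a population ``s``
    accrues ``n_k * prev(s & w)/prev(w)`` patients at stage ``k``).
    Selecting F leaves recruitment prevalence-proportional.  With
    ``enrichment=False`` every stage stays prevalence-proportional.
    """
    stage_sizes = [float(n) for n in stage_sizes]
    w_set = population_set.members[selected]
    prev_w = population_set.member_prevalence(selected)
    schedules = []
    for s in range(population_set.n_members):
        s_set = population_set.members[s]
        prev_s = population_set.member_prevalence(s)
        totals = [prev_s * stage_sizes[0]]
        for n_k in stage_sizes[1:]:
            if enrichment:
                inter = s_set & w_set
                prev_inter = (sum(population_set.prevalences[j - 1] for j in inter)
                              if inter else 0.0)
                totals.append(n_k * prev_inter / prev_w)
            else:
                totals.append(n_k * prev_s)
        schedules.append(InformationSchedule(tuple(totals), sigma, allocation))
    return schedules


def stagewise_probabilities(population_set: PopulationSet,
                            effect_config: EffectConfig,
                            stage_sizes, boundaries: Boundaries,
                            w: int, allocation: float = 1.0,
                            enrichment: bool = True,
                            enforce_lower: bool | None = None,
                            n_nodes: int = QUAD_NODES
                            ) -> list[dict[str, float]]:
    """Efficacy/futility stopping probabilities per stage for selection w.

    Returns one ``{"efficacy": ., "futility": ., "continue": .}`` dict
    per stage; the stage-``k`` entries are the probabilities of
    selecting ``w`` at the interim, surviving the continuation regions
    of stages ``1..k-1``, and crossing the respective boundary at
    stage ``k``.  ``enforce_lower=False`` integrates the continuation
    regions down to the lower truncation instead of the futility bound
    (used for nonbinding calibration); by default ``boundaries.binding``
    decides.
    """
    K = boundaries.n_stages
    if len(list(stage_sizes)) != K:
        raise ValueError("need one stage size per boundary stage")
    if enforce_lower is None:
        enforce_lower = boundaries.binding
    sched = enrichment_information_update(population_set, w, stage_sizes,
                                          effect_config.sigma, allocation,
                                          enrichment)[w]
    theta_w = composite_effect(population_set, effect_config, w)
    info = [sched.information(k) for k in range(1, K + 1)]

    dens = SelectionDensity(population_set, effect_config,
                            float(list(stage_sizes)[0]), allocation)
    out = []
    if K == 1:
        eff = dens.tail_probability(w, boundaries.upper[0])
        fut = dens.selection_probability(w) - eff
        out.append({"efficacy": eff, "futility": max(fut, 0.0), "continue": 0.0})
        return out

    eff1 = dens.tail_probability(w, boundaries.upper[0])
    lower1 = boundaries.lower[0] if enforce_lower else -np.inf
    fut1 = dens.integral(w, -np.inf, lower1) if np.isfinite(lower1) else 0.0
    grid, gw = dens.continuation_grid(w, lower1, boundaries.upper[0], n_nodes)
    cont1 = float(np.sum(gw))
    out.append({"efficacy": eff1, "futility": fut1, "continue": cont1})

    dens_w = gw  # density * quadrature weight at the grid nodes
    for k in range(2, K + 1):
        drift = theta_w * info[k - 1]
        mean, sd = _transition_params(grid, info[k - 1], info[k - 2], theta_w)
        cu = boundaries.upper[k - 1]
        cl = boundaries.lower[k - 1] if (enforce_lower or k == K) else -np.inf
        eff_k = float(np.sum(dens_w * norm.sf((cu - mean) / sd)))
        if k == K:
            fut_k = float(np.sum(dens_w * norm.cdf((cu - mean) / sd)))
            out.append({"efficacy": eff_k, "futility": fut_k, "continue": 0.0})
            break
        fut_k = (float(np.sum(dens_w * norm.cdf((cl - mean) / sd)))
                 if np.isfinite(cl) else 0.0)
        lo = max(cl, drift - Z_RANGE, -Z_RANGE)
        hi = min(cu, drift + Z_RANGE)
        if hi <= lo:
            out.append({"efficacy": eff_k, "futility": fut_k, "continue": 0.0})
            dens_w = np.zeros(1)
            grid = np.array([lo])
            continue
        x, wt = np.polynomial.legendre.leggauss(n_nodes)
        new_grid = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
        new_w = 0.5 * (hi - lo) * wt
        pdfs = norm.pdf((new_grid[:, None] - mean[None, :]) / sd) / sd
        new_dens = new_w * (pdfs @ dens_w)
        cont_k = float(np.sum(new_dens))
        out.append({"efficacy": eff_k, "futility": fut_k, "continue": cont_k})
        grid, dens_w = new_grid, new_dens
    return out


def stagewise_probability(population_set: PopulationSet,
                          effect_config: EffectConfig, stage_sizes,
                          boundaries: Boundaries, w: int, k: int,
                          decision: str, **kwargs) -> float:
    """One stagewise probability; ``decision`` is efficacy|futility|continue."""
    if decision not in ("efficacy", "futility", "continue"):
        raise ValueError(f"unknown decision {decision!r}")
    probs = stagewise_probabilities(population_set, effect_config, stage_sizes,
                                    boundaries, w, **kwargs)
    if not 1 <= k <= len(probs):
        raise ValueError(f"stage {k} outside 1..{len(probs)}")
    return probs[k - 1][decision]


def _total_efficacy(population_set, effect_config, stage_sizes, boundaries,
                    members=None, allocation=1.0, enrichment=True,
                    enforce_lower=None, n_nodes=QUAD_NODES) -> float:
    if members is None:
        members = range(population_set.n_members)
    total = 0.0
    for w in members:
        probs = stagewise_probabilities(population_set, effect_config,
                                        stage_sizes, boundaries, w,
                                        allocation, enrichment,
                                        enforce_lower, n_nodes)
        total += sum(p["efficacy"] for p in probs)
    return total


def calibrate_boundaries(population_set: PopulationSet, alpha: float,
                         n_stages: int, stage_sizes=None,
                         lower_bound: float = 0.0, binding: bool = True,
                         allocation: float = 1.0, enrichment: bool = True
                         ) -> Boundaries:
    """Tune the O'Brien-Fleming constant for FWER ``alpha``.

    With nonbinding futility the lower bounds are ignored (set to
    ``-inf``) during calibration but retained in the returned object
    for trial conduct.  With equal stage sizes the calibration does not
    depend on the absolute sample size, only on prevalences and the
    stage-size ratios.
    """
    if stage_sizes is None:
        stage_sizes = [100.0] * n_stages
    null = EffectConfig((0.0,) * population_set.n_subgroups, 1.0)

    if n_stages == 1:
        c = _single_stage_c(population_set, alpha, allocation)
        return Boundaries((c,), (c,), binding, "obf")

    def excess(c: float) -> float:
        b = obf_boundaries(c, n_stages, lower_bound, binding)
        return _total_efficacy(population_set, null, stage_sizes, b,
                               allocation=allocation, enrichment=enrichment,
                               enforce_lower=binding) - alpha

    lo = norm.ppf(1 - alpha) - 0.3
    hi = norm.ppf(1 - alpha / population_set.n_members) + 1.0
    c = brentq(excess, lo, hi, xtol=1e-7)
    return obf_boundaries(float(c), n_stages, lower_bound, binding)


def error_spending_boundaries(population_set: PopulationSet, alpha_schedule,
                              stage_sizes=None, lower_bound: float = -np.inf,
                              allocation: float = 1.0,
                              enrichment: bool = True) -> Boundaries:
    """Upper bounds from a per-stage error-spending schedule.

    The stage-``k`` bound is solved forward so the cumulative
    efficacy-crossing probability under the global null equals
    ``alpha_1 + ... + alpha_k``, holding the earlier bounds fixed.  A
    zero increment yields an infinite bound at that stage (no early
    stopping for efficacy there); spending everything at stage 1
    reproduces the single-stage critical value.
    """
    alphas = [float(a) for a in alpha_schedule]
    if any(a < 0 for a in alphas):
        raise ValueError("spending increments must be nonnegative")
    if sum(alphas) <= 0:
        raise ValueError("total spend must be positive")
    K = len(alphas)
    if stage_sizes is None:
        stage_sizes = [100.0] * K
    null = EffectConfig((0.0,) * population_set.n_subgroups, 1.0)
    upper: list[float] = []
    binding = np.isfinite(lower_bound)
    for k in range(1, K + 1):
        target = sum(alphas[:k])
        if alphas[k - 1] == 0.0:
            # no efficacy spend at this stage: the bound is never crossed
            upper.append(np.inf)
            continue

        def excess(c: float) -> float:
            trial_upper = tuple(upper) + (c,) * (K - k + 1)
            low = tuple(min(lower_bound, trial_upper[i]) for i in range(K - 1))
            b = Boundaries(trial_upper, low + (trial_upper[-1],), binding,
                           "error-spending")
            tot = 0.0
            for w in range(population_set.n_members):
                probs = stagewise_probabilities(
                    population_set, null, stage_sizes, b, w, allocation,
                    enrichment, enforce_lower=binding)
                tot += sum(p["efficacy"] for p in probs[:k])
            return tot - target

        lo, hi = norm.ppf(1 - target) - 0.5, 9.0
        if excess(hi) > 0:
            raise ValueError(f"spending schedule infeasible at stage {k}")
        upper.append(float(brentq(excess, lo, hi, xtol=1e-7)))
    low = tuple(min(lower_bound, upper[i]) for i in range(K - 1))
    return Boundaries(tuple(upper), low + (upper[-1],), binding,
                      "error-spending")


@dataclass(frozen=True)
class MultistageDesign:
    """Calibrated multistage design with equal per-stage sample sizes."""

    spec: DesignSpec
    effect_config: EffectConfig
    boundaries: Boundaries
    stage_n: tuple[int, ...]
    achieved_power: float

    @property
    def total_n(self) -> int:
        return int(sum(self.stage_n))


def _powered_probability(spec: DesignSpec, effect_config: EffectConfig,
                         stage_sizes, boundaries: Boundaries,
                         enrichment: bool = True) -> float:
    if spec.power_definition == "select-target-and-reject":
        members = [spec.target]
    else:
        members = (list(spec.interest_set) if spec.interest_set is not None
                   else range(spec.population_set.n_members))
    return _total_efficacy(spec.population_set, effect_config, stage_sizes,
                           boundaries, members, spec.allocation, enrichment,
                           enforce_lower=True)


def required_stagewise_sample_size(spec: DesignSpec,
                                   effect_config: EffectConfig,
                                   lower_bound: float = 0.0,
                                   binding: bool = True,
                                   enrichment: bool = True,
                                   boundaries: Boundaries | None = None
                                   ) -> MultistageDesign:
    """Smallest equal per-stage full-population size meeting the power goal.

    Boundaries are calibrated once (they do not depend on the absolute
    size under an equal split); the power search then runs on a
    continuous per-stage size, rounded up to integral subgroup counts.
    Futility bounds are always respected in the power computation.
    """
    K = spec.stages
    if boundaries is None:
        boundaries = calibrate_boundaries(spec.population_set, spec.alpha, K,
                                          lower_bound=lower_bound,
                                          binding=binding,
                                          allocation=spec.allocation,
                                          enrichment=enrichment)
    goal = 1.0 - spec.beta

    def gap(n_stage: float) -> float:
        return _powered_probability(spec, effect_config, [n_stage] * K,
                                    boundaries, enrichment) - goal

    lo, hi = 4.0, 64.0
    while gap(hi) < 0:
        lo, hi = hi, hi * 2
        if hi > N_MAX:
            raise RuntimeError(f"power {goal} unattainable below n={N_MAX:g}")
    n_star = brentq(gap, lo, hi, xtol=1e-6)
    n_int = round_to_subgroup_integer(n_star, spec.population_set)
    achieved = _powered_probability(spec, effect_config, [n_int] * K,
                                    boundaries, enrichment)
    return MultistageDesign(spec, effect_config, boundaries, (n_int,) * K,
                            achieved)
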