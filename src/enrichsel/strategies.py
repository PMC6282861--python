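"""Comparison of evaluation strategies for a two-subgroup question.

Three ways to test a treatment that may only work in a biomarker
subgroup: (i) separate per-subgroup studies (optionally Bonferroni
corrected), (ii) a single-stage selection design over {subgroup, full},
and (iii) a two-stage enrichment design selecting at the halfway point
with O'Brien-Fleming efficacy bounds.  Each plan reports total sample
size, maximum family-wise error rate, the share of patients studied in
the truly superior subgroup, and the trial duration under a constant
recruitment rate.

Duration model: patients accrue at ``rate`` per month from a single
stream; after enrichment to a subgroup only its fraction of screened
patients enrolls, so recruitment slows to ``rate * prevalence``.  The
endpoint delay is added once at the end (the last recruit must be
followed up); interim-analysis time is absorbed into continued
recruitment and does not extend the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .multistage import required_stagewise_sample_size
from .populations import EffectConfig, PopulationSet
from .single_stage import DesignSpec, required_sample_size

__all__ = ["StrategyPlan", "separate_studies_plan", "single_stage_plan",
           "two_stage_plan", "trial_duration", "percent_superior",
           "compare_strategies"]


@dataclass(frozen=True)
class StrategyPlan:
    name: str
    total_n: int
    max_fwer: float
    stage_n: tuple[int, ...]            # recruitment segments, in order
    superior_prevalence: float          # prevalence of the truly better subgroup
    percent_superior: dict[str, float]  # per selection path
    selection_prevalences: dict[str, float]  # recruitment pool prevalence per path


def separate_studies_plan(delta: float, sigma: float, alpha: float,
                          power: float, n_groups: int = 2,
                          multiplicity: str = "none") -> StrategyPlan:
    """Independent two-arm studies, one per subgroup.

    Per-arm size is the standard normal-endpoint formula
    ``ceil(2*sigma^2*(z_{1-a'} + z_{1-b})^2 / delta^2)`` with
    ``a' = alpha`` or ``alpha/n_groups`` under Bonferroni; without
    correction the family-wise error across the studies reaches
    ``1 - (1-alpha)^n_groups``.
    """
    if multiplicity not in ("none", "bonferroni"):
        raise ValueError(f"unknown multiplicity adjustment {multiplicity!r}")
    a = alpha / n_groups if multiplicity == "bonferroni" else alpha
    per_arm = math.ceil(2 * sigma ** 2 * (norm.ppf(1 - a) + norm.ppf(power)) ** 2
                        / delta ** 2)
    total = 2 * per_arm * n_groups
    max_fwer = 1.0 - (1.0 - a) ** n_groups
    return StrategyPlan(f"separate-studies[{multiplicity}]", total, max_fwer,
                        (total,), 0.5, {"all": 100.0 / n_groups},
                        {"all": 1.0})


def single_stage_plan(lambda1: float, delta: float, sigma: float,
                      alpha: float, power: float) -> StrategyPlan:
    """Single-stage selection design over {S1, F}, reject-any power."""
    ps = PopulationSet.two_population(lambda1)
    spec = DesignSpec(ps, alpha=alpha, beta=1 - power,
                      power_definition="reject-any")
    eff = EffectConfig.single_effect(2, delta, sigma)
    design = required_sample_size(spec, eff)
    n = design.n_full
    return StrategyPlan("single-stage", n, alpha, (n,), lambda1,
                        {"all": 100.0 * lambda1}, {"all": 1.0})


def two_stage_plan(lambda1: float, delta: float, sigma: float, alpha: float,
                   power: float, lower_bound: float = 0.0,
                   binding: bool = True) -> StrategyPlan:
    """Two-stage enrichment design over {S1, F}, selection at halfway."""
    ps = PopulationSet.two_population(lambda1)
    spec = DesignSpec(ps, alpha=alpha, beta=1 - power, stages=2,
                      power_definition="reject-any")
    eff = EffectConfig.single_effect(2, delta, sigma)
    design = required_stagewise_sample_size(spec, eff, lower_bound=lower_bound,
                                            binding=binding)
    n1, n2 = design.stage_n
    total = n1 + n2
    pct = {
        "S1": 100.0 * (lambda1 * n1 + n2) / total,
        "F": 100.0 * lambda1,
    }
    return StrategyPlan("two-stage", total, alpha, (n1, n2), lambda1, pct,
                        {"S1": lambda1, "F": 1.0})


def trial_duration(plan: StrategyPlan, recruitment_rate: float,
                   endpoint_delay: float, selected_path: str | None = None
                   ) -> float:
    """Months from first recruit until the last endpoint is observed.

    Each recruitment segment of ``n`` patients from a pool of
    prevalence ``p`` takes ``n / (rate * p)`` months; the endpoint
    delay is appended once.
    """
    if recruitment_rate <= 0:
        raise ValueError("recruitment rate must be positive")
    if selected_path is None:
        selected_path = next(iter(plan.selection_prevalences))
    pool = plan.selection_prevalences[selected_path]
    months = 0.0
    for i, n in enumerate(plan.stage_n):
        p = 1.0 if i == 0 else pool
        months += n / (recruitment_rate * p)
    return months + endpoint_delay


def percent_superior(plan: StrategyPlan, selected_path: str | None = None
                     ) -> float:
    """Share of all recruited patients in the truly superior subgroup."""
    if selected_path is None:
        selected_path = next(iter(plan.percent_superior))
    return plan.percent_superior[selected_path]


def compare_strategies(delta: float, sigma: float, alpha: float = 0.025,
                       power: float = 0.8, lambda1: float = 0.5,
                       recruitment_rate: float = 25.0,
                       endpoint_delay: float = 3.0):
    """Side-by-side table of the three strategies (plus Bonferroni variant).

    Returns a pandas DataFrame with one row per strategy: max FWER,
    total N, percent of patients in the superior subgroup, and the
    duration(s) — for the two-stage design one per selection path.
    """
    import pandas as pd

    rows = []
    sep = separate_studies_plan(delta, sigma, alpha, power)
    bon = separate_studies_plan(delta, sigma, alpha, power,
                                multiplicity="bonferroni")
    single = single_stage_plan(lambda1, delta, sigma, alpha, power)
    two = two_stage_plan(lambda1, delta, sigma, alpha, power)
    for plan in (sep, bon, single):
        rows.append({
            "strategy": plan.name,
            "max_fwer": round(plan.max_fwer, 4),
            "total_n": plan.total_n,
            "percent_superior": percent_superior(plan),
            "duration_months": round(
                trial_duration(plan, recruitment_rate, endpoint_delay), 2),
        })
    dur = {path: round(trial_duration(two, recruitment_rate, endpoint_delay,
                                      path), 2)
           for path in ("F", "S1")}
    rows.append({
        "strategy": two.name,
        "max_fwer": round(two.max_fwer, 4),
        "total_n": two.total_n,
        "percent_superior": percent_superior(two, "S1"),
        "duration_months": dur["F"],
        "duration_months_subgroup": dur["S1"],
    })
    return pd.DataFrame(rows)
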