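"""Standardized bias and root-MSE of the naive MLE under selection.

Because the required sample size changes with prevalence, accuracy is
reported on a standardized scale: each replicate contributes the
z-scored residual

    r = (theta_hat_s - theta_s) * I_s^{1:M}

i.e. the estimation error divided by the estimator's nominal standard
error ``1/I`` at the stopping-stage information.  ``bias/SE`` is the
cell mean of ``r`` and ``sqrt(MSE)/SE`` the cell root-mean-square; an
unconditional single-stage MLE therefore has bias 0 and root-MSE 1.

Three conditioning situations are supported: none (all replicates),
selection (only replicates that picked the population), and
selection-plus-rejection (only "published" significant trials,
capturing reporting bias).  Family-wise rows pool the selected
population's residual over every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .populations import EffectConfig, PopulationSet, composite_effect

__all__ = ["AssessmentRow", "standardized_assessment",
           "familywise_assessment", "assessment_table"]

CONDITIONINGS = ("none", "selected", "selected-rejected")


@dataclass(frozen=True)
class AssessmentRow:
    population: str            # member label, or "FW" for family-wise rows
    conditioning: str
    stage: int | None          # stopping stage scope; None = overall
    bias_over_se: float        # NaN when the cell is empty
    rmse_over_se: float
    proportion_pct: float      # share of all replicates in the cell
    n_cell: int


def _cell_mask(records: pd.DataFrame, w: int | None, conditioning: str,
               stage: int | None) -> np.ndarray:
    if conditioning not in CONDITIONINGS:
        raise ValueError(f"unknown conditioning {conditioning!r}")
    mask = np.ones(len(records), dtype=bool)
    if stage is not None:
        mask &= (records["M"].to_numpy() == stage)
    if conditioning != "none" and w is not None:
        mask &= (records["W"].to_numpy() == w)
    if conditioning == "selected-rejected":
        mask &= records["rejected"].to_numpy()
    return mask


def _summarize(r: np.ndarray, mask: np.ndarray, total: int, population: str,
               conditioning: str, stage: int | None) -> AssessmentRow:
    n_cell = int(mask.sum())
    if n_cell == 0:
        return AssessmentRow(population, conditioning, stage,
                             float("nan"), float("nan"), 0.0, 0)
    cell = r[mask]
    return AssessmentRow(population, conditioning, stage,
                         float(cell.mean()),
                         float(np.sqrt(np.mean(cell ** 2))),
                         100.0 * n_cell / total, n_cell)


def standardized_assessment(records: pd.DataFrame,
                            population_set: PopulationSet,
                            effect_config: EffectConfig, label: str,
                            conditioning: str = "none",
                            stage: int | None = None) -> AssessmentRow:
    """Standardized bias and root-MSE of one population's MLE."""
    if conditioning not in CONDITIONINGS:
        raise ValueError(f"unknown conditioning {conditioning!r}")
    w = population_set.member_index(label)
    theta = composite_effect(population_set, effect_config, w)
    r = ((records[f"mle_{label}"].to_numpy() - theta)
         * records[f"info_{label}"].to_numpy())
    mask = _cell_mask(records, w, conditioning, stage)
    return _summarize(r, mask, len(records), label, conditioning, stage)


def familywise_assessment(records: pd.DataFrame,
                          population_set: PopulationSet,
                          effect_config: EffectConfig,
                          conditioning: str = "selected",
                          stage: int | None = None) -> AssessmentRow:
    """Bias/MSE of the selected population's MLE, pooled over selections.

    Under ``conditioning="none"`` there is no selected estimator to
    follow, so the family average pools every candidate population's
    residual with equal weight (which is symmetric, hence unbiased,
    under the global null); the proportion then refers to replicates,
    not population-replicate pairs.
    """
    thetas = np.array([composite_effect(population_set, effect_config, w)
                       for w in range(population_set.n_members)])
    mask = _cell_mask(records, None, conditioning, stage)
    if conditioning == "none":
        labels = population_set.member_labels
        r = np.concatenate([
            ((records[f"mle_{lab}"].to_numpy() - thetas[s])
             * records[f"info_{lab}"].to_numpy())[mask]
            for s, lab in enumerate(labels)])
        n_cell = int(mask.sum())
        if n_cell == 0:
            return AssessmentRow("FW", conditioning, stage, float("nan"),
                                 float("nan"), 0.0, 0)
        return AssessmentRow("FW", conditioning, stage, float(r.mean()),
                             float(np.sqrt(np.mean(r ** 2))),
                             100.0 * n_cell / len(records), n_cell)
    W = records["W"].to_numpy()
    r = (records["mle"].to_numpy() - thetas[W]) * records["info_final"].to_numpy()
    return _summarize(r, mask, len(records), "FW", conditioning, stage)


def assessment_table(records: pd.DataFrame, population_set: PopulationSet,
                     effect_config: EffectConfig,
                     stages: tuple[int | None, ...] | None = None
                     ) -> pd.DataFrame:
    """Full report: per-population and family-wise rows, per stage scope.

    Row order follows the reporting convention of the simulation study
    (per population: unconditional, selected, selected+rejected; then
    the two family-wise rows); for multistage records the stage scopes
    are stage 1..K followed by overall.
    """
    if stages is None:
        K = int(records["M"].max()) if len(records) else 1
        stages = tuple(range(1, K + 1)) + (None,) if K > 1 else (None,)
    rows = []
    for label in population_set.member_labels:
        for conditioning in CONDITIONINGS:
            for stage in stages:
                row = standardized_assessment(records, population_set,
                                              effect_config, label,
                                              conditioning, stage)
                rows.append(row)
    for conditioning in ("selected", "selected-rejected"):
        for stage in stages:
            rows.append(familywise_assessment(records, population_set,
                                              effect_config, conditioning,
                                              stage))
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["stage"] = pd.array(
        ["overall" if r.stage is None else r.stage for r in rows],
        dtype=object)
    return out
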