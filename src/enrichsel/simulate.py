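"""Monte-Carlo engine for selection designs.

Trials are generated on per-subgroup sufficient statistics: at each
stage the observed mean treatment difference of subgroup ``j`` is drawn
as ``N(theta_j, 4*sigma^2/n_j)`` (1:1 allocation), and every candidate
population's statistic is the sample-size-weighted pool of its
subgroups.  This reproduces the exact joint Gaussian law of the
statistics — including the nested correlation structure and the
enrichment bookkeeping — without simulating individual patients.  A
patient-level mode draws individual outcomes instead and serves as an
end-to-end check of the sufficient-statistics shortcut.

Naive maximum-likelihood estimates are the pooled mean differences at
the stopping stage; after enrichment the pool for a population that
strictly contains the selected one mixes in stage-2+ patients drawn
only from the selected population, exactly as a naive analysis of the
accumulated data would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .multistage import Boundaries
from .populations import EffectConfig, PopulationSet
from .rules import vectorized_rule

__all__ = ["SimulationConfig", "simulate_trials", "mle",
           "UnavailableEstimateError"]


class UnavailableEstimateError(KeyError):
    """Raised when an estimate is requested for a deselected population
    that accrued no data after stage 1."""


@dataclass
class SimulationConfig:
    """One simulation scenario: design, truth, and engine settings."""

    population_set: PopulationSet
    effect_config: EffectConfig
    boundaries: Boundaries
    stage_sizes: tuple[float, ...]
    selection_rule: object = "max"   # "max" | "sequential3" | vectorized callable
    n_reps: int = 100_000
    seed: int = 0
    mode: str = "sufficient"         # "sufficient" | "patient"
    enrichment: bool = True
    random_subgroup_counts: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("sufficient", "patient"):
            raise ValueError(f"unknown simulation mode {self.mode!r}")
        if len(self.stage_sizes) != self.boundaries.n_stages:
            raise ValueError("stage sizes must match the boundary stages")
        if self.random_subgroup_counts and self.mode != "sufficient":
            raise ValueError("random subgroup counts only supported in "
                             "sufficient-statistics mode")


def _draw_stage_means(rng, counts, thetas, sigma, mode):
    """Observed mean differences per subgroup given per-rep counts.

    ``counts`` has shape (reps, J).  In patient-level mode counts are
    rounded to even integers (1:1 allocation) and individual normal
    outcomes are drawn and averaged.
    """
    if mode == "sufficient":
        sd = 2.0 * sigma / np.sqrt(counts)
        return rng.normal(thetas[None, :], sd)
    reps, J = counts.shape
    out = np.empty((reps, J))
    for j in range(J):
        per_arm = int(round(counts[0, j] / 2.0))
        if not np.allclose(counts[:, j], counts[0, j]):
            raise ValueError("patient-level mode requires fixed counts")
        if per_arm < 1:
            raise ValueError("patient-level mode needs at least 1 per arm")
        treat = rng.normal(thetas[j], sigma, size=(reps, per_arm)).mean(axis=1)
        ctrl = rng.normal(0.0, sigma, size=(reps, per_arm)).mean(axis=1)
        out[:, j] = treat - ctrl
        counts[:, j] = 2 * per_arm
    return out


def simulate_trials(config: SimulationConfig) -> pd.DataFrame:
    """Simulate trials; one row per replicate.

    Columns: ``rep, W, M, rejected``, the selected population's final
    statistic/information/estimate (``z_final, info_final, mle``), and
    per-population ``mle_<label>, info_<label>, frozen_<label>`` where
    ``frozen`` marks estimates stuck at their stage-1 value because the
    population was deselected and disjoint from the selected one.
    """
    ps, eff = config.population_set, config.effect_config
    J, m = ps.n_subgroups, ps.n_members
    K = config.boundaries.n_stages
    R = int(config.n_reps)
    lam = np.asarray(ps.prevalences)
    thetas = np.asarray(eff.thetas)
    sigma = eff.sigma
    upper, lower = config.boundaries.upper, config.boundaries.lower
    member_masks = np.zeros((m, J), dtype=bool)
    for w, mem in enumerate(ps.members):
        for j in mem:
            member_masks[w, j - 1] = True
    prev_members = ps.member_prevalences

    rng = np.random.default_rng(config.seed)

    # stage 1 ---------------------------------------------------------
    n1 = float(config.stage_sizes[0])
    if config.random_subgroup_counts:
        counts1 = rng.multinomial(int(round(n1)), lam, size=R).astype(float)
        counts1 = np.maximum(counts1, 2.0)
    else:
        counts1 = np.broadcast_to(lam * n1, (R, J)).copy()
    d1 = _draw_stage_means(rng, counts1, thetas, sigma, config.mode)

    n_acc = counts1.copy()               # per-subgroup accumulated counts
    s_acc = counts1 * d1                 # per-subgroup accumulated sums

    def member_stats(mask_rows=None):
        nA = n_acc if mask_rows is None else n_acc[mask_rows]
        sA = s_acc if mask_rows is None else s_acc[mask_rows]
        n_mem = nA @ member_masks.T
        est = (sA @ member_masks.T) / n_mem
        info = np.sqrt(n_mem) / (2.0 * sigma)
        return est, info, n_mem

    est1, info1, _ = member_stats()
    z1 = est1 * info1
    select = vectorized_rule(config.selection_rule)
    W = select(z1)

    M = np.full(R, 1, dtype=np.int64)
    rejected = np.zeros(R, dtype=bool)
    z_sel = z1[np.arange(R), W]

    if K == 1:
        rejected = z_sel >= upper[0]
        active = np.zeros(R, dtype=bool)
    else:
        rejected = z_sel >= upper[0]
        stopped = rejected | (np.isfinite(lower[0]) & (z_sel <= lower[0]))
        active = ~stopped

    for k in range(2, K + 1):
        n_k = float(config.stage_sizes[k - 1])
        for w in range(m):
            rows = active & (W == w)
            if not rows.any():
                continue
            if config.enrichment:
                sub = np.where(member_masks[w])[0]
                counts = np.broadcast_to(
                    n_k * lam[sub] / prev_members[w],
                    (int(rows.sum()), len(sub))).copy()
            else:
                sub = np.arange(J)
                counts = np.broadcast_to(n_k * lam, (int(rows.sum()), J)).copy()
            d = _draw_stage_means(rng, counts, thetas[sub], sigma, config.mode)
            n_acc[np.ix_(rows, sub)] += counts
            s_acc[np.ix_(rows, sub)] += counts * d
        est_k, info_k, _ = member_stats(active)
        zk = (est_k * info_k)[np.arange(int(active.sum())), W[active]]
        idx = np.where(active)[0]
        M[idx] = k
        z_sel[idx] = zk
        if k == K:
            rejected[idx] = zk >= upper[k - 1]
            active[:] = False
        else:
            rej_k = zk >= upper[k - 1]
            fut_k = np.isfinite(lower[k - 1]) & (zk <= lower[k - 1])
            rejected[idx[rej_k]] = True
            active[idx[rej_k | fut_k]] = False

    est, info, n_mem = member_stats()
    frozen = np.zeros((R, m), dtype=bool)
    if K > 1 and config.enrichment:
        for w in range(m):
            for s in range(m):
                if not (ps.members[s] & ps.members[w]) and K > 1:
                    frozen[(W == w) & (M > 1), s] = True

    data = {
        "rep": np.arange(R),
        "W": W,
        "M": M,
        "rejected": rejected,
        "z_final": z_sel,
        "info_final": info[np.arange(R), W],
        "mle": est[np.arange(R), W],
    }
    for s, lab in enumerate(ps.member_labels):
        data[f"mle_{lab}"] = est[:, s]
        data[f"info_{lab}"] = info[:, s]
        data[f"frozen_{lab}"] = frozen[:, s]
    return pd.DataFrame(data)


def mle(records: pd.DataFrame, label: str, strict: bool = False) -> pd.Series:
    """Naive MLE series for one population: ``Z^{1:M}/I^{1:M}``.

    With ``strict=True`` an :class:`UnavailableEstimateError` is raised
    if any requested estimate is frozen at its stage-1 value because
    the population was deselected and received no later data.
    """
    col = f"mle_{label}"
    if col not in records.columns:
        raise UnavailableEstimateError(f"no estimates recorded for {label!r}")
    if strict and records[f"frozen_{label}"].any():
        raise UnavailableEstimateError(
            f"population {label!r} accrued no post-selection data in some "
            "replicates; its estimate is frozen at stage 1")
    return records[col]
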