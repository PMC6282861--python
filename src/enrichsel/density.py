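"""Joint density of the selected statistic and the selection index.

Under selection by the maximum statistic, the joint density of the
selected stage-1 statistic ``Z_W`` and the selection index ``W`` is

    p(z, w) = phi(z - theta_w * I_w) * Psi_{S \\ w}(z, ..., z)

where ``phi`` is the standard normal density and ``Psi`` is the CDF of
the (|S|-1)-dimensional conditional normal distribution of the
remaining candidate statistics given ``Z_w = z``, evaluated at the
all-``z`` point (the event that every rival statistic falls below the
selected one).  Tail integrals of ``p(z, w)`` give joint
selection-and-rejection probabilities; full integrals give selection
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal, norm

from .populations import (EffectConfig, PopulationSet, composite_effect,
                          correlation_matrix, information_level)

__all__ = ["SelectionDensity"]

#: half-width of the outer integration window around the drifted mean
Z_RANGE = 8.5
#: Gauss-Legendre nodes used for outer integrals
QUAD_NODES = 256


@dataclass
class _ConditionalParams:
    slope: np.ndarray        # regression of rivals on Z_w (= correlation column)
    base_mean: np.ndarray    # rival means minus slope * mu_w
    cov: np.ndarray          # conditional covariance (positive semidefinite)


class SelectionDensity:
    """Precomputed stage-1 joint-density context for one design.

    Parameters
    ----------
    population_set, effect_config
        Structure and true effects.
    n_full
        Full-population stage-1 sample size (both arms; may be
        fractional during searches).
    allocation
        Treatment:control allocation ratio.
    """

    def __init__(self, population_set: PopulationSet,
                 effect_config: EffectConfig, n_full: float,
                 allocation: float = 1.0) -> None:
        self.population_set = population_set
        self.effect_config = effect_config
        self.n_full = float(n_full)
        self.allocation = allocation
        self.corr = correlation_matrix(population_set)

        prev = population_set.member_prevalences
        self.info = np.array([
            information_level(self.n_full * p, effect_config.sigma, allocation)
            for p in prev
        ])
        self.effects = np.array([
            composite_effect(population_set, effect_config, w)
            for w in range(population_set.n_members)
        ])
        self.means = self.effects * self.info

        self._cond: list[_ConditionalParams | None] = []
        m = population_set.n_members
        for w in range(m):
            if m == 1:
                self._cond.append(None)
                continue
            idx = [i for i in range(m) if i != w]
            slope = self.corr[idx, w]
            cov = self.corr[np.ix_(idx, idx)] - np.outer(slope, slope)
            base = self.means[idx] - slope * self.means[w]
            self._cond.append(_ConditionalParams(slope, base, cov))

    # -- density --------------------------------------------------------
    def _rival_cdf(self, z: np.ndarray, w: int) -> np.ndarray:
        """P(all rival statistics <= z | Z_w = z), vectorized over z."""
        cp = self._cond[w]
        if cp is None:
            return np.ones_like(z)
        cmean = cp.base_mean[None, :] + np.outer(z, cp.slope)
        resid = z[:, None] - cmean
        if cp.cov.shape[0] == 1:
            sd = np.sqrt(max(cp.cov[0, 0], 0.0))
            if sd == 0.0:
                return (resid[:, 0] >= 0).astype(float)
            return norm.cdf(resid[:, 0] / sd)
        mvn = multivariate_normal(mean=np.zeros(cp.cov.shape[0]), cov=cp.cov,
                                  allow_singular=True)
        return np.atleast_1d(mvn.cdf(resid))

    def joint_density(self, z, w: int) -> np.ndarray | float:
        """p(z, w): density of selecting population w at statistic value z."""
        if not 0 <= w < self.population_set.n_members:
            raise KeyError(f"no candidate population with index {w}")
        z_arr = np.atleast_1d(np.asarray(z, dtype=float))
        out = norm.pdf(z_arr - self.means[w]) * self._rival_cdf(z_arr, w)
        return float(out[0]) if np.isscalar(z) or np.ndim(z) == 0 else out

    # -- integrals ------------------------------------------------------
    def integral(self, w: int, lower: float, upper: float | None = None,
                 n_nodes: int = QUAD_NODES) -> float:
        """``int_lower^upper p(z, w) dz`` by Gauss-Legendre quadrature.

        Infinite limits are truncated at ``theta_w * I_w +/- 8.5``;
        mass beyond is negligible at the tolerances used downstream.
        """
        mu = self.means[w]
        lo = max(lower, mu - Z_RANGE)
        hi = mu + Z_RANGE if upper is None else min(upper, mu + Z_RANGE)
        if hi <= lo:
            return 0.0
        x, wt = np.polynomial.legendre.leggauss(n_nodes)
        zz = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
        ww = 0.5 * (hi - lo) * wt
        return float(np.sum(ww * self.joint_density(zz, w)))

    def tail_probability(self, w: int, critical_value: float) -> float:
        """P(select w and Z_w >= critical_value)."""
        return self.integral(w, critical_value)

    def selection_probability(self, w: int) -> float:
        """P(select population w) = full integral of p(z, w)."""
        return self.integral(w, -np.inf)

    def selection_probabilities(self) -> np.ndarray:
        return np.array([self.selection_probability(w)
                         for w in range(self.population_set.n_members)])

    def total_tail_probability(self, critical_value: float) -> float:
        """Sum over w of P(select w, Z_w >= c); the FWER when c=C_alpha
        and all effects are zero."""
        return sum(self.tail_probability(w, critical_value)
                   for w in range(self.population_set.n_members))

    # -- quadrature grid handoff for multistage recursion --------------
    def continuation_grid(self, w: int, lower: float, upper: float,
                          n_nodes: int = QUAD_NODES
                          ) -> tuple[np.ndarray, np.ndarray]:
        """Nodes and density*weight values of p(z, w) on [lower, upper]."""
        mu = self.means[w]
        lo = max(lower, mu - Z_RANGE)
        hi = min(upper, mu + Z_RANGE)
        if hi <= lo:
            return np.empty(0), np.empty(0)
        x, wt = np.polynomial.legendre.leggauss(n_nodes)
        zz = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
        ww = 0.5 * (hi - lo) * wt
        return zz, ww * self.joint_density(zz, w)
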