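"""Population-selection rules applied to stage-1 test statistics.

Selection by the maximum statistic is the worst case for both the
family-wise error rate and selection bias, so designs are calibrated
under it; the sequential three-population variant decides S1, then
S1+2, then F by pairwise comparisons and coincides with the maximum
rule except on ties (which have probability zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .populations import PopulationSet

__all__ = ["SelectionOutcome", "select_max", "select_sequential_three",
           "get_rule", "vectorized_rule"]


@dataclass(frozen=True)
class SelectionOutcome:
    selected_index: int
    selected_label: str
    rule_name: str


def _check_finite(values) -> np.ndarray:
    z = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("selection requires one finite statistic per population")
    return z


def select_max(z_values, population_set: PopulationSet) -> SelectionOutcome:
    """Select the candidate with the largest statistic.

    ``z_values`` may be a sequence ordered as ``population_set.members``
    or a mapping from member label to value.  Exact ties go to the
    first-listed (higher-priority) population.
    """
    if isinstance(z_values, Mapping):
        try:
            z = [z_values[lab] for lab in population_set.member_labels]
        except KeyError as e:
            raise ValueError(f"missing statistic for population {e}") from None
    else:
        z = list(z_values)
    if len(z) != population_set.n_members:
        raise ValueError("need exactly one statistic per candidate population")
    z = _check_finite(z)
    w = int(np.argmax(z))  # argmax returns the first maximum: priority order
    return SelectionOutcome(w, population_set.member_label(w), "max")


def select_sequential_three(z1: float, z12: float, zf: float,
                            population_set: PopulationSet | None = None
                            ) -> SelectionOutcome:
    """Sequential rule for the nested chain S1 < S1+2 < F.

    S1 if its statistic strictly exceeds both others; otherwise S1+2 if
    it strictly exceeds F's; otherwise F.  The boundary case
    ``z12 == zf`` resolves to F: ties have probability zero and the
    larger population is the ethically conservative default.
    """
    z = _check_finite([z1, z12, zf])
    if population_set is None:
        population_set = PopulationSet.nested_chain((1 / 3, 1 / 3, 1 / 3))
    if population_set.n_members != 3:
        raise ValueError("sequential rule requires exactly three candidates")
    if z[0] > max(z[1], z[2]):
        w = 0
    elif z[1] > z[2]:
        w = 1
    else:
        w = 2
    return SelectionOutcome(w, population_set.member_label(w), "sequential3")


def _max_vec(z: np.ndarray) -> np.ndarray:
    return np.argmax(z, axis=1)


def _sequential3_vec(z: np.ndarray) -> np.ndarray:
    if z.shape[1] != 3:
        raise ValueError("sequential rule requires exactly three candidates")
    first = z[:, 0] > np.maximum(z[:, 1], z[:, 2])
    second = z[:, 1] > z[:, 2]
    return np.where(first, 0, np.where(second, 1, 2))


def vectorized_rule(rule) -> Callable[[np.ndarray], np.ndarray]:
    """Map an (n_reps, n_members) statistic matrix to selected indices.

    ``rule`` is ``"max"``, ``"sequential3"``, or a callable with the
    vectorized signature already.
    """
    if callable(rule):
        return rule
    try:
        return {"max": _max_vec, "sequential3": _sequential3_vec}[rule]
    except KeyError:
        raise ValueError(f"unknown selection rule {rule!r}") from None


def get_rule(name: str):
    """Scalar rule by configuration name ("max" | "sequential3")."""
    if name == "max":
        return select_max
    if name == "sequential3":
        return lambda z, ps: select_sequential_three(z[0], z[1], z[2], ps)
    raise ValueError(f"unknown selection rule {name!r}")
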