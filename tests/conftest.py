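"""Shared fixtures: canonical designs calibrated once per session."""

from __future__ import annotations

import numpy as np
import pytest

import enrichsel as es


@pytest.fixture(scope="session")
def ps2():
    """Two candidates {S1, F}, subgroup prevalence one half."""
    return es.PopulationSet.two_population(0.5)


@pytest.fixture(scope="session")
def ps3():
    """Nested chain {S1, S1+2, F} over three equal subgroups."""
    return es.PopulationSet.nested_chain((1 / 3, 1 / 3, 1 / 3))


@pytest.fixture(scope="session")
def eff_asthma():
    """Minimum clinically relevant FEV1 effect in subgroup 1 only."""
    return es.EffectConfig.single_effect(2, 0.23, 0.72)


@pytest.fixture(scope="session")
def eff3():
    """Unit-variance outcome, effect 0.5 in subgroup 1 only."""
    return es.EffectConfig.single_effect(3, 0.5, 1.0)


@pytest.fixture(scope="session")
def c_alpha_2pop(ps2):
    return es.critical_value(ps2, 0.025)


@pytest.fixture(scope="session")
def design2(ps3, eff3):
    """Single-stage three-candidate design powered to select-and-reject S1."""
    spec = es.DesignSpec(ps3, power_definition="select-target-and-reject",
                         target=0)
    return es.required_sample_size(spec, eff3)


@pytest.fixture(scope="session")
def design4(ps3, eff3):
    """Two-stage counterpart of design2: OBF upper bounds, lower bound 0."""
    spec = es.DesignSpec(ps3, stages=2,
                         power_definition="select-target-and-reject", target=0)
    return es.required_stagewise_sample_size(spec, eff3)


@pytest.fixture(scope="session")
def design2_records(ps3, eff3, design2):
    """One million simulated trials of the calibrated single-stage design."""
    b = es.Boundaries((design2.critical_value,), (design2.critical_value,))
    cfg = es.SimulationConfig(ps3, eff3, b, (design2.n_full,),
                              selection_rule="sequential3",
                              n_reps=1_000_000, seed=20240901)
    return es.simulate_trials(cfg)


@pytest.fixture(scope="session")
def design4_records(ps3, eff3, design4):
    """One million simulated trials of the calibrated two-stage design."""
    cfg = es.SimulationConfig(ps3, eff3, design4.boundaries, design4.stage_n,
                              selection_rule="sequential3",
                              n_reps=1_000_000, seed=20240902)
    return es.simulate_trials(cfg)


def mc_band(values: np.ndarray, n_factor: float = 2.0) -> float:
    """3-sigma Monte-Carlo band for comparing two independent estimates.

    ``n_factor=2`` doubles the variance because the reference value is
    itself a simulation of the same size.
    """
    values = np.asarray(values, float)
    return 3.0 * np.sqrt(n_factor * values.var() / len(values))
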