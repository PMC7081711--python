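"""Shared fixtures: seeded synthetic scenarios and fitted pipelines.

Scenario fixtures are session-scoped because generation plus trajectory
fitting is the expensive part of the suite; every test treats them as
read-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from methylcoom.io import BetaMatrix, SampleSheet, filter_probes
from methylcoom.synthetic import SimulationConfig, Scenario, simulate_scenario
from methylcoom.trajectory import refit_with_linear_cpgs
from methylcoom.coo import place_samples


@dataclass
class FittedScenario:
    scenario: Scenario
    ref: BetaMatrix
    sheet: SampleSheet
    axis: object
    model: object
    table: object
    linear_dynamic: list
    assignments: object


def _fit(scenario: Scenario) -> FittedScenario:
    ref = filter_probes(scenario.ref, scenario.annotation)
    axis, model, table = refit_with_linear_cpgs(ref, scenario.sheet)
    linear_dynamic = list(table.index[table["linear"]])
    assignments = place_samples(
        scenario.tumors, ref, scenario.sheet, axis, linear_dynamic
    )
    return FittedScenario(
        scenario=scenario,
        ref=ref,
        sheet=scenario.sheet,
        axis=axis,
        model=model,
        table=table,
        linear_dynamic=linear_dynamic,
        assignments=assignments,
    )


@pytest.fixture(scope="session")
def small_scenario() -> Scenario:
    """3k-probe scenario with planted aberrations and tumor noise sd 0.05."""
    cfg = SimulationConfig(
        n_probes=3000,
        planted_counts={"A": 100, "B": 20, "C": 80, "D": 20},
        tumor_noise_sd=0.05,
        seed=11,
    )
    return simulate_scenario(cfg)


@pytest.fixture(scope="session")
def small_fitted(small_scenario) -> FittedScenario:
    return _fit(small_scenario)


@pytest.fixture(scope="session")
def clean_scenario() -> Scenario:
    """Noiseless, aberration-free continuum: every probe sits on its program."""
    cfg = SimulationConfig(
        n_probes=1500,
        noise_sd=0.0,
        tumor_noise_sd=0.0,
        fraction_nonlinear=0.0,
        planted_counts={"A": 0, "B": 0, "C": 0, "D": 0},
        n_correlated_genes=0,
        n_null_genes=10,
        n_mirnas=4,
        n_planted_mirnas=0,
        seed=7,
    )
    return simulate_scenario(cfg)


@pytest.fixture(scope="session")
def clean_fitted(clean_scenario) -> FittedScenario:
    return _fit(clean_scenario)


# full-size conditions used by the acceptance tests

@pytest.fixture(scope="session")
def default_scenario() -> Scenario:
    """The default study conditions: 20k probes, 6x3 reference at noise sd
    0.02, 34 tumors at noise sd 0.05 carrying planted events of magnitude
    0.30."""
    return simulate_scenario(SimulationConfig(tumor_noise_sd=0.05, seed=101))


@pytest.fixture(scope="session")
def default_fitted(default_scenario) -> FittedScenario:
    return _fit(default_scenario)
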