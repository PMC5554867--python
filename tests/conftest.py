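"""Shared fixtures: tiny hand-built registries and a simulated stand."""

from __future__ import annotations

import pytest

from forestdyn.census import CensusRegistry, Observation, Status, TreeRecord
from forestdyn.simulate import SimulationParams, simulate_stand


def build_registry(
    tree_specs: list[tuple[str, str, list[float | str | None]]],
    censuses: dict[str, int],
    stand_id: str = "T",
    n_plots: int = 2,
    plot_area_m2: float = 300.0,
) -> CensusRegistry:
    """Build a registry from per-tree DBH trajectories.

    Each spec is (tree_id, species, values) with one value per census:
    a float DBH means alive, the string "dead" means dead, None means
    not yet recruited.
    """
    registry = CensusRegistry(
        stand_id=stand_id, censuses=dict(censuses), n_plots=n_plots, plot_area_m2=plot_area_m2
    )
    labels = list(censuses)
    for tree_id, species, values in tree_specs:
        record = TreeRecord(tree_id, species, "P1", stand_id)
        for label, value in zip(labels, values):
            if value is None:
                record.observations[label] = Observation(Status.NOT_YET_RECRUITED)
            elif value == "dead":
                record.observations[label] = Observation(Status.DEAD)
            else:
                record.observations[label] = Observation(Status.ALIVE, float(value))
        registry.add(record)
    registry.validate()
    return registry


@pytest.fixture(scope="session")
def toy_registry() -> CensusRegistry:
    """10 trees over 2 censuses: 2 deaths, 3 recruits, known growth.

    Survivor basal-area components are hand-enumerable: tree T05 shrinks
    (decrement), the other survivors grow or stay.
    """
    specs = [
        ("T01", "Alpha one", [6.0, 7.0]),
        ("T02", "Alpha one", [8.0, 8.5]),
        ("T03", "Beta two", [5.5, "dead"]),
        ("T04", "Beta two", [12.0, 13.0]),
        ("T05", "Gamma three", [9.0, 8.0]),  # shrinkage
        ("T06", "Gamma three", [25.0, 26.0]),
        ("T07", "Delta four", [6.5, "dead"]),
        ("T08", "Alpha one", [None, 5.2]),
        ("T09", "Beta two", [None, 5.0]),
        ("T10", "Epsilon five", [None, 6.0]),
    ]
    return build_registry(specs, {"c0": 2000, "c1": 2005})


@pytest.fixture(scope="session")
def sim_registry() -> CensusRegistry:
    """Mid-sized simulated stand shared across tests (3 censuses)."""
    return simulate_stand(
        SimulationParams(n_initial_trees=600, n_plots=10, seed=20260918 % 2**31)
    )
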