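"""Shared fixtures: small synthetic wing datasets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from wingmorph import (
    SimulationSpec,
    SpeciesSpec,
    average_replicates,
    build_dataset,
    generate_dataset,
    gpa,
    parse_tps,
)

# small non-degenerate 6-point template for cheap simulations
SMALL_TEMPLATE = np.array(
    [[0.0, 0.0], [1.0, 0.2], [2.0, 0.0], [1.8, 0.8], [1.0, 1.1], [0.2, 0.8]]
)


def simulate_aligned(spec: SimulationSpec):
    """Generate, parse, superimpose and replicate-average a simulation."""
    data = generate_dataset(spec)
    table = build_dataset(parse_tps(data.tps), data.metadata)
    aligned = gpa(table.coordinate_array(), meta=table.frame)
    return average_replicates(aligned), data


def two_species_spec(
    seed: int,
    n: int = 30,
    offset: float = 0.03,
    shape_sd: float = 0.005,
    **kwargs,
) -> SimulationSpec:
    """Two-species design with a controllable mean-shape separation."""
    common = dict(
        shape_sd=shape_sd,
        sex_shape_offset=0.0,
        allometry=0.0,
    )
    common.update(kwargs)
    species = [
        SpeciesSpec(name="A", genus="G", n_males=n // 2, n_females=n - n // 2,
                    shape_offset=offset, **common),
        SpeciesSpec(name="B", genus="G", n_males=n // 2, n_females=n - n // 2,
                    shape_offset=offset, **common),
    ]
    return SimulationSpec(
        species=species,
        genus_shape_offset=0.0,
        digitization_sd=0.0,
        replicates=1,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_study():
    """A 4-species, ~60-specimen study with replicates: one GPA for many tests."""
    species = [
        SpeciesSpec(name="AA", genus="G1", n_males=8, n_females=8),
        SpeciesSpec(name="AB", genus="G1", n_males=6, n_females=9),
        SpeciesSpec(name="BA", genus="G2", n_males=7, n_females=7),
        SpeciesSpec(name="BB", genus="G2", n_males=8, n_females=7),
    ]
    spec = SimulationSpec(species=species, seed=42)
    aligned, data = simulate_aligned(spec)
    return aligned, data, spec
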