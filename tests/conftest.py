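"""Shared fixtures: one synthetic study (grid, species, occurrence design)
is built per session and reused by the evaluation and fitting tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ttrsdm import background, synthetic


@pytest.fixture(scope="session")
def grid():
    return synthetic.generate_environment(60, 40, novelty_strength=2.0, seed=7)


@pytest.fixture(scope="session")
def flat_grid():
    """No-novelty control grid."""
    return synthetic.generate_environment(60, 40, novelty_strength=0.0, seed=7)


@pytest.fixture(scope="session")
def true_params(grid):
    return synthetic.default_true_params(grid)


@pytest.fixture(scope="session")
def species(grid, true_params):
    return synthetic.make_virtual_species(grid, true_params, name="vsp")


@pytest.fixture(scope="session")
def zone_model(grid):
    return background.cluster_environments(grid.env_table(), k=24, seed=7)


@pytest.fixture(scope="session")
def occurrence_design(grid, species, zone_model):
    """Presences, pseudoabsences and the stacked fitting table."""
    presences = synthetic.sample_occurrences(species, grid, 150, seed=7)
    pseudo = background.sample_pseudoabsences(grid, zone_model,
                                              n_total=len(presences), seed=7)
    table = pd.concat([presences, pseudo.drop(columns="zone")],
                      ignore_index=True)
    return {
        "presences": presences,
        "pseudo": pseudo,
        "table": table,
        "X": grid.forcing(table["cell"].to_numpy()),
        "y": table["presence"].to_numpy(),
        "is_training": (table["region"] == "training").to_numpy(),
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
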