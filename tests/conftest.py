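import numpy as np
import pandas as pd
import pytest

from mangrovesdm import synthetic as syn
from mangrovesdm.grids import EnvStack, GridDefinition
from mangrovesdm.occurrences import OccurrenceSet


@pytest.fixture(scope="session")
def small_config():
    return syn.LandscapeConfig(n_rows=30, n_cols=30, seed=42)


@pytest.fixture(scope="session")
def small_stack(small_config):
    return syn.generate_env_stack(small_config)


@pytest.fixture(scope="session")
def truths(small_config):
    return syn.default_species_truths(small_config)


@pytest.fixture
def grid10():
    return GridDefinition(10, 10)


def make_occurrences(records, grid, **kw):
    """Build an OccurrenceSet from (species, x, y, source) tuples."""
    df = pd.DataFrame(records, columns=["species_code", "x", "y", "source"])
    return OccurrenceSet(df, grid, validate_registry=False, **kw)


def stack_from_layers(grid, **layers):
    return EnvStack(grid, {k: np.asarray(v, dtype=float) for k, v in layers.items()})


@pytest.fixture
def make_occ():
    return make_occurrences


@pytest.fixture
def make_stack():
    return stack_from_layers
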