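import numpy as np
import pandas as pd
import pytest

from sipnet.otu import OtuTable
from sipnet.synthetic import SimConfig, generate_dataset


def make_table(
    counts: pd.DataFrame,
    taxonomy: dict[str, str] | None = None,
    meta: pd.DataFrame | None = None,
) -> OtuTable:
    """Build an OtuTable with placeholder metadata where none is given."""
    if taxonomy is None:
        taxonomy = {}
    if meta is None:
        meta = pd.DataFrame(
            {
                "species": "SP",
                "strategy": "none",
                "compartment": "light",
                "replicate": range(1, len(counts.index) + 1),
            },
            index=counts.index,
        )
    return OtuTable(
        counts=counts,
        taxonomy=pd.Series(taxonomy, dtype=object),
        sample_meta=meta,
    )


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=11, n_otus=200)


@pytest.fixture(scope="session")
def dataset(sim_config):
    """One full synthetic experiment shared across the session."""
    return generate_dataset(sim_config)


@pytest.fixture()
def small_table() -> OtuTable:
    """3 samples x 4 OTUs with mixed strategies and compartments."""
    counts = pd.DataFrame(
        {
            "otu1": [10, 0, 3],
            "otu2": [30, 5, 0],
            "otu3": [60, 5, 7],
            "otu4": [0, 0, 0],
        },
        index=["s1", "s2", "s3"],
    )
    meta = pd.DataFrame(
        {
            "species": ["A", "A", "B"],
            "strategy": ["exploitative", "exploitative", "conservative"],
            "compartment": ["light", "heavy", "light"],
            "replicate": [1, 2, 1],
        },
        index=["s1", "s2", "s3"],
    )
    taxonomy = {
        "otu1": "Bacteria;Proteobacteria",
        "otu2": "Bacteria;Firmicutes",
        "otu3": "Bacteria;Proteobacteria",
        "otu4": "",
    }
    return make_table(counts, taxonomy, meta)
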