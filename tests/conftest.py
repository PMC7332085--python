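import dataclasses

import numpy as np
import pandas as pd
import pytest

from polityscale.io import COLUMNS, SocietyTable
from polityscale.synth import GeneratorConfig, generate_societies, reference_config


def make_table(
    pop_sizes, areas, levels, languages=None, families=None, continents=None,
    lons=None, lats=None,
) -> SocietyTable:
    """Hand-build a small valid society table (nesting trivially satisfied)."""
    n = len(pop_sizes)
    df = pd.DataFrame(
        {
            "society_id": [f"s{i}" for i in range(n)],
            "language": languages or [f"lang{i}" for i in range(n)],
            "family": families or [f"fam{i}" for i in range(n)],
            "continent": continents or ["africa"] * n,
            "longitude": lons if lons is not None else np.linspace(-20, 40, n),
            "latitude": lats if lats is not None else np.linspace(-10, 10, n),
            "pop_size": pop_sizes,
            "range_area_km2": areas,
            "level": levels,
        },
        columns=list(COLUMNS),
    )
    if families is None and languages is None:
        # default: one family per language, nesting holds
        df["family"] = ["fam" + str(i) for i in range(n)]
    return SocietyTable(df, provenance="test fixture")


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Study-default structure at ~quarter sample sizes, for fast fits."""
    return dataclasses.replace(
        reference_config(seed=11),
        n_per_level=(103, 88, 47, 35, 10),
    )


@pytest.fixture(scope="session")
def small_table(small_config) -> SocietyTable:
    return generate_societies(small_config)


@pytest.fixture(scope="session")
def reference_table() -> SocietyTable:
    """One full-size replicate at the study-sample defaults."""
    return generate_societies(reference_config(seed=5))
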