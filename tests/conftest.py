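import numpy as np
import pandas as pd
import pytest

from alepanel import (
    AssociationSpec,
    EventCatalog,
    PanelDataset,
    australian_catalog,
    swiss_catalog,
)


@pytest.fixture(scope="session")
def swiss():
    return swiss_catalog()


@pytest.fixture(scope="session")
def australian():
    return australian_catalog()


@pytest.fixture
def tiny_catalog():
    return EventCatalog(events=("a", "b", "c"))


@pytest.fixture
def tiny_panel(tiny_catalog):
    """Hand-built 5-person-year panel with one masked cell."""
    df = pd.DataFrame(
        {
            "id": [1, 1, 1, 2, 2],
            "hh_id": [10, 10, 10, 11, 11],
            "year": [2000, 2001, 2002, 2000, 2001],
            "age": [30, 31, 32, 17, 18],
            "a": [1.0, 0.0, 1.0, 0.0, 1.0],
            "b": [0.0, np.nan, 1.0, 0.0, 0.0],
            "c": [0.0, 0.0, 0.0, 1.0, 0.0],
        }
    )
    return PanelDataset(data=df, catalog=tiny_catalog, provenance="fixture")


def random_typed_panel(catalog, n=300, years=6, seed=0, **assoc_kwargs):
    assoc = AssociationSpec.from_rates(catalog, **assoc_kwargs)
    from alepanel import simulate_typed_panel

    return simulate_typed_panel(assoc, catalog, n, years, seed)
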