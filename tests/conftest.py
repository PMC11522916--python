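import numpy as np
import pandas as pd
import pytest

from reeftraits.survey import Segment, TransectRecord
from reeftraits.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture
def simple_transect():
    """One 10-m tape: 2.5 m coral, 7.5 m bare reef."""
    return TransectRecord(
        "S1", 2006, True, "T1", 10.0,
        [
            Segment("reef-building coral", "Porites sp01", 2.5),
            Segment("bare reef", None, 7.5),
        ],
    )


@pytest.fixture
def two_site_transects():
    """Two equal-length sites with one shared taxon at 10% and 30%."""
    def tape(site, frac):
        return TransectRecord(
            site, 2006, False, "T1", 10.0,
            [
                Segment("reef-building coral", "Porites sp01", frac * 10.0),
                Segment("rock", None, (1 - frac) * 10.0),
            ],
        )

    return [tape("S1", 0.1), tape("S2", 0.3)]


@pytest.fixture
def mini_trait_table():
    """Six taxa, two genera/forms, complete raw traits."""
    rng = np.random.default_rng(7)
    taxa = [f"Acropora sp{i}" for i in range(3)] + [f"Porites sp{i}" for i in range(3)]
    table = pd.DataFrame(
        {
            "genus": ["Acropora"] * 3 + ["Porites"] * 3,
            "growth_form": ["corymbose"] * 3 + ["massive"] * 3,
        },
        index=pd.Index(taxa, name="taxon"),
    )
    from reeftraits.traitspace import TRAIT_NAMES

    for t in TRAIT_NAMES:
        table[t] = np.exp(rng.normal(1.0, 0.5, size=6))
    return table


@pytest.fixture(scope="session")
def default_scenario():
    """One full synthetic scenario shared across read-only tests."""
    return generate_scenario(ScenarioConfig(seed=11))
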