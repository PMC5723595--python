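import warnings

import numpy as np
import pandas as pd
import pytest

from lepmon import SimulationSpec, simulate_bundle


@pytest.fixture(scope="session")
def bundle():
    """One mid-sized synthetic monitoring bundle shared across tests."""
    spec = SimulationSpec(n_sites=6, n_years=8, n_species=12, trend=1.03)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_bundle(spec, seed=7)


@pytest.fixture(scope="session")
def records(bundle):
    return bundle["records"]


@pytest.fixture
def toy_records():
    """Hand-written records: 2 sites, 2 years, explicit survey structure."""
    rows = []
    for site in ("A", "B"):
        for year in (2009, 2010):
            for t, month in enumerate((3, 5, 9, 11), start=1):
                rows.append({
                    "site_id": site,
                    "date": pd.Timestamp(year=year, month=month, day=15),
                    "year": year, "survey_index": t,
                    "species_id": "sp1", "count": t,
                })
    return pd.DataFrame(rows)
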