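import numpy as np
import pytest

import spatrisk as sp


@pytest.fixture(scope="session")
def table1():
    return sp.load_table1_fixture()


@pytest.fixture(scope="session")
def iran_adj():
    return sp.load_iran_adjacency_fixture()


@pytest.fixture(scope="session")
def chain3():
    """Three areas on a path graph with moderate counts."""
    adj = sp.AdjacencyStructure.from_pairs(
        ["A", "B", "C"], [("A", "B"), ("B", "C")]
    )
    recs = [
        sp.ProvinceRecord("A", "both", 55, 50.0),
        sp.ProvinceRecord("B", "both", 70, 80.0),
        sp.ProvinceRecord("C", "both", 75, 60.0),
    ]
    return sp.StudyDataset(records=recs, adjacency=adj)


@pytest.fixture(scope="session")
def short_male_sample(table1):
    """One short chain on the male fixture, shared across tests."""
    cfg = sp.BymConfig(n_iterations=3000, burn_in=600, seed=42)
    return sp.fit_bym(table1, covariates=(), config=cfg, sex="male")


def make_dataset(y, E, adjacency=None, uer=None):
    recs = []
    for k in range(len(y)):
        recs.append(
            sp.ProvinceRecord(
                area_id=f"a{k}",
                sex="both",
                observed=int(y[k]),
                expected=float(E[k]),
                uer=None if uer is None else float(uer[k]),
            )
        )
    return sp.StudyDataset(records=recs, adjacency=adjacency)


@pytest.fixture
def rng():
    return np.random.default_rng(20080101)
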