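import numpy as np
import pandas as pd
import pytest

from herbnet.network import ComponentRecord, build_ct_network
from herbnet.simulate import MetaboSimSpec, gen_metabolites


@pytest.fixture(scope="session")
def toy_net():
    """Two-component, three-edge bipartite network used for hand-worked
    contribution-index arithmetic: X (herb A) -> {t1, t2}, Y (herb B) -> {t2}."""
    records = [
        ComponentRecord("X", frozenset("A"), ob=40.0, dl=0.3),
        ComponentRecord("Y", frozenset("B"), ob=40.0, dl=0.3),
    ]
    return build_ct_network(records, [("X", "t1"), ("X", "t2"), ("Y", "t2")])


@pytest.fixture(scope="session")
def single_edge_net():
    rec = [ComponentRecord("X", frozenset("A"), ob=40.0, dl=0.3)]
    return build_ct_network(rec, [("X", "t1")])


@pytest.fixture(scope="session")
def planted_metabolites():
    """Default treated-vs-control intensity simulation with 10 planted
    metabolites of 200, at the generator's default seed."""
    spec = MetaboSimSpec(seed=0)
    X, groups, truth = gen_metabolites(spec)
    return X, groups, truth


def random_network(rng, max_components=10, max_targets=20):
    """Small random bipartite network for oracle/property tests."""
    n_comp = rng.integers(1, max_components + 1)
    n_targ = rng.integers(1, max_targets + 1)
    records = []
    edges = []
    for i in range(n_comp):
        herbs = rng.choice(["A", "B", "AB"])
        records.append(
            ComponentRecord(f"c{i:02d}", frozenset(herbs), ob=50.0, dl=0.5)
        )
        deg = rng.integers(1, n_targ + 1)
        for t in rng.choice(n_targ, size=deg, replace=False):
            edges.append((f"c{i:02d}", f"t{t:02d}"))
    return build_ct_network(records, edges)
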