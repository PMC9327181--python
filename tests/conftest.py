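import numpy as np
import pandas as pd
import pytest

from simvec.kg_store import load_kg
from simvec.synthetic_data import SynthSpec, make_benchmark


@pytest.fixture
def toy_tables():
    """A hand-checkable graph: 3 drugs, 2 proteins, 2 side-effect types.

    Drug-drug degrees: a=1 (one triple), b=2, c=5 would need more edges; here
    a-b (se1), b-c (se1), a? no — kept minimal: a:1, b:2, c:1.
    """
    combo = pd.DataFrame(
        [("a", "b", "se1"), ("b", "c", "se2")],
        columns=["drug1", "drug2", "side_effect_id"],
    )
    ppi = pd.DataFrame([("g1", "g2")], columns=["gene1", "gene2"])
    targets = pd.DataFrame([("a", "g1"), ("c", "g2")], columns=["drug", "gene"])
    mono = pd.DataFrame(
        [("a", "m1"), ("a", "m2"), ("b", "m1"), ("c", "m3")],
        columns=["drug", "mono_side_effect_id"],
    )
    return combo, ppi, targets, mono


@pytest.fixture
def toy_kg(toy_tables):
    return load_kg(*toy_tables)


def random_toy_kg(rng, n_drugs=8, n_proteins=4, n_rels=3, n_edges=15):
    """A random small KG built through the public loader."""
    drugs = [f"d{i}" for i in range(n_drugs)]
    rows = set()
    while len(rows) < n_edges:
        i, j = rng.choice(n_drugs, size=2, replace=False)
        r = rng.integers(n_rels)
        rows.add((drugs[min(i, j)], drugs[max(i, j)], f"se{r}"))
    combo = pd.DataFrame(sorted(rows), columns=["drug1", "drug2", "side_effect_id"])
    prots = [f"g{i}" for i in range(n_proteins)]
    ppi = pd.DataFrame([(prots[0], prots[1]), (prots[2], prots[3])],
                       columns=["gene1", "gene2"])
    targets = pd.DataFrame([(drugs[0], prots[0])], columns=["drug", "gene"])
    return load_kg(combo, ppi, targets)


@pytest.fixture(scope="session")
def bench():
    """The default desk-scale synthetic benchmark (60 drugs, planted signal)."""
    return make_benchmark(SynthSpec(seed=1), n_weak=10)
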