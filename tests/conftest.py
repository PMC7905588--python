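import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")

from fatiguenet.containers import BinaryCohortMatrix, Feature
from fatiguenet.conet import WeightedCooccurrenceNetwork


def make_network(edges, isolated=(), blocks=None):
    """Build a network from {('A','B'): w} plus optional isolated node codes."""
    blocks = blocks or {}
    codes = sorted({c for pair in edges for c in pair} | set(isolated))
    nodes = [Feature(c, c, blocks.get(c, "symptom")) for c in codes]
    triples = [(a, b, float(w)) for (a, b), w in edges.items()]
    return WeightedCooccurrenceNetwork(nodes, triples)


def make_matrix(rows, codes=None, blocks=None):
    """Binary cohort matrix from a list of 0/1 row strings or sequences."""
    arr = np.array([[int(x) for x in row] for row in rows], dtype=np.int8)
    n_feat = arr.shape[1]
    codes = codes or [chr(ord("A") + j) for j in range(n_feat)]
    blocks = blocks or {}
    feats = [Feature(c, c, blocks.get(c, "symptom")) for c in codes]
    return BinaryCohortMatrix(pd.DataFrame(arr, columns=codes), feats)


@pytest.fixture
def unit_triangle():
    return make_network({("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 1})


@pytest.fixture
def unit_path():
    return make_network({("A", "B"): 1, ("B", "C"): 1})


@pytest.fixture
def toy_weighted_graph():
    """5 nodes, 6 weighted edges; connected, not vertex-transitive."""
    return make_network({
        ("A", "B"): 3, ("A", "C"): 1, ("B", "C"): 2,
        ("B", "D"): 5, ("C", "E"): 4, ("D", "E"): 1,
    })


def random_network(rng, n_nodes=None, labelled=False):
    """Random connected-ish weighted network, possibly with isolated vertices."""
    n = int(n_nodes or rng.integers(2, 10))
    codes = [f"N{i}" for i in range(n)]
    labels = {}
    if labelled:
        words = ["white coating", "yellow coating", "wiry pulse", "uric acid",
                 "blood pressure", "platelet width"]
        labels = {c: f"{rng.choice(words)} {i}" for i, c in enumerate(codes)}
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                edges[(codes[i], codes[j])] = int(rng.integers(1, 50))
    nodes = [Feature(c, labels.get(c, c), "symptom" if i % 2 else "index")
             for i, c in enumerate(codes)]
    triples = [(a, b, float(w)) for (a, b), w in edges.items()]
    return WeightedCooccurrenceNetwork(nodes, triples)
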