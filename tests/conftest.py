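import numpy as np
import pytest

from flone.data import DDTTriple, TripleStore
from flone.synthetic import SynthConfig, generate_features, generate_network


@pytest.fixture(scope="session")
def tiny_store():
    """Hand-built 8-triple store over 4 drugs / 5 targets / 2 diseases."""
    triples = [
        DDTTriple("d1", "k1", "t1"), DDTTriple("d1", "k1", "t2"),
        DDTTriple("d2", "k1", "t2"), DDTTriple("d2", "k2", "t3"),
        DDTTriple("d3", "k2", "t3"), DDTTriple("d3", "k2", "t4"),
        DDTTriple("d4", "k1", "t5"), DDTTriple("d4", "k2", "t1"),
    ]
    return TripleStore(triples)


@pytest.fixture(scope="session")
def small_network():
    """A small generated network (fast: 20 drugs / 15 targets / 8 diseases)."""
    cfg = SynthConfig(n_drugs=20, n_targets=15, n_diseases=8,
                      mean_triangles_per_disease=6.0, fingerprint_width=64,
                      n_families=4, seed=0)
    return generate_network(cfg)


@pytest.fixture(scope="session")
def small_features(small_network):
    return generate_features(small_network)


@pytest.fixture(scope="session")
def default_network():
    """The default study fixture network (60 / 50 / 25, seed 0)."""
    return generate_network(SynthConfig())


def random_toy_edges(rng, n_drugs=8, n_targets=6, n_diseases=5,
                     p_dd=0.3, p_dt=0.3, p_kt=0.3):
    """Random typed edge list with known entity roles, plus the role sets."""
    drugs = [f"d{i}" for i in range(n_drugs)]
    targets = [f"t{i}" for i in range(n_targets)]
    diseases = [f"k{i}" for i in range(n_diseases)]
    edges = []
    for d in drugs:
        for k in diseases:
            if rng.random() < p_dd:
                pair = (d, k) if rng.random() < 0.5 else (k, d)
                edges.append((*pair, "drug_disease"))
        for t in targets:
            if rng.random() < p_dt:
                pair = (d, t) if rng.random() < 0.5 else (t, d)
                edges.append((*pair, "drug_target"))
    for k in diseases:
        for t in targets:
            if rng.random() < p_kt:
                pair = (k, t) if rng.random() < 0.5 else (t, k)
                edges.append((*pair, "disease_target"))
    rng.shuffle(edges)
    return edges, drugs, targets, diseases


def brute_force_triples(edges, drugs, targets, diseases):
    """O(n^3) oracle: enumerate all (drug, disease, target) combinations."""
    undirected = {}
    for a, b, et in edges:
        undirected.setdefault(et, set()).add(frozenset((a, b)))
    out = set()
    for d in drugs:
        for k in diseases:
            for t in targets:
                if (frozenset((d, k)) in undirected.get("drug_disease", set())
                        and frozenset((d, t)) in undirected.get("drug_target", set())
                        and frozenset((k, t)) in undirected.get("disease_target", set())):
                    out.add((d, k, t))
    return out
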