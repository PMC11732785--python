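from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from webprint import FoodWeb, apply_inclusion_filters, generate_cohort
from webprint.synth import niche_model


def make_web(edges, directed=False, web_id="w", nodes=()):
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return FoodWeb(web_id=web_id, graph=g)


@pytest.fixture
def triangle():
    return make_web([("a", "b"), ("b", "c"), ("a", "c")], web_id="K3")


@pytest.fixture
def four_cycle():
    return make_web([(1, 2), (2, 3), (3, 4), (4, 1)], web_id="C4")


def random_connected_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Largest component of a G(n, p) draw; retried until it has >= 5 nodes."""
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        giant = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        if giant.number_of_nodes() >= 5:
            return giant


@pytest.fixture(scope="session")
def niche_webs():
    """Thirty filtered niche-model webs spanning a range of (S, C)."""
    webs = []
    k = 0
    seed = 0
    while len(webs) < 30:
        S = 25 + 2 * (k % 15)
        C = (0.08, 0.15, 0.22)[k % 3]
        raw = niche_model(S, C, seed=9000 + seed, web_id=f"niche{k:02d}")
        seed += 1
        processed, _ = apply_inclusion_filters(raw)
        if processed is not None:
            webs.append(processed)
            k += 1
    return webs


def filtered_cohort(profiles, master_seed):
    """Generate a cohort, apply inclusion filters, return webs + metadata."""
    cohort = generate_cohort(profiles, master_seed=master_seed)
    by_id = {m.web_id: m for m in cohort.metadata}
    processed, meta = [], []
    for web in cohort.webs:
        p, _ = apply_inclusion_filters(web)
        if p is not None:
            processed.append(p)
            meta.append(by_id[web.web_id])
    return processed, meta
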