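"""Inclusion filters and transformations applied to raw directed webs.

The pipeline mirrors the study-design filters used when curating repository
food webs: count trophic roles on the raw directed web, symmetrize to a
simple undirected graph, keep only the giant component, and require at least
10 nodes with at least 5 consumers and 5 resources.  Failures are reported in
a :class:`FilterDecision`, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .net_io import FoodWeb

#: exclusion reasons, in the order they are tested
REASONS = ("empty", "bipartite_like", "too_few_nodes", "too_few_consumers", "too_few_resources")


@dataclass
class FilterDecision:
    web_id: str
    included: bool
    reasons: list[str] = field(default_factory=list)
    n_nodes_raw: int = 0
    n_nodes_final: int = 0
    n_consumers: int = 0
    n_resources: int = 0
    giant_component_fraction: float = 0.0
    bipartite_warning: bool = False


def count_roles(web: FoodWeb) -> tuple[int, int]:
    """Count consumer and resource nodes on a raw directed web.

    A consumer has at least one incoming edge from a distinct node; a resource
    has at least one outgoing edge to a distinct node.  Self-loops
    (cannibalism) are ignored; a node may count as both.
    """
    if not web.directed:
        raise ValueError("roles require directed web")
    consumers: set[str] = set()
    resources: set[str] = set()
    for u, v in web.graph.edges:
        if u != v:
            resources.add(u)
            consumers.add(v)
    return len(consumers), len(resources)


def to_simple_undirected(web: FoodWeb) -> FoodWeb:
    """Collapse a raw directed web to a simple undirected graph.

    Reciprocal edge pairs merge into one undirected edge, self-loops are
    dropped, and the node set is preserved (isolated nodes are kept at this
    stage -- the giant-component step decides their fate).
    """
    g = nx.Graph()
    g.add_nodes_from(web.graph.nodes)
    if web.directed:
        g.add_edges_from((u, v) for u, v in web.graph.edges if u != v)
    else:
        g.add_edges_from((u, v) for u, v in web.graph.edges if u != v)
    return FoodWeb(web_id=web.web_id, graph=g)


def giant_component(web: FoodWeb) -> FoodWeb:
    """Induced subgraph on the largest connected component.

    Ties between equally large components are broken by the component whose
    lexicographically smallest node label is smallest (a deterministic
    convention; real webs essentially never tie).
    """
    if web.directed:
        raise ValueError("giant_component expects an undirected web")
    if web.n_nodes == 0:
        raise ValueError(f"web {web.web_id!r} is empty")
    comps = [sorted(c) for c in nx.connected_components(web.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    keep = comps[0]
    return FoodWeb(web_id=web.web_id, graph=web.graph.subgraph(keep).copy())


def apply_inclusion_filters(
    web: FoodWeb,
    *,
    bipartite_excluded: bool = False,
    role_stage: str = "raw",
    min_nodes: int = 10,
    min_consumers: int = 5,
    min_resources: int = 5,
) -> tuple[FoodWeb | None, FilterDecision]:
    """Run the full inclusion pipeline on one raw directed web.

    Order: (1) roles on the raw directed web, (2) undirected simplification,
    (3) giant component, (4) size/role thresholds.  ``role_stage="final"``
    recounts roles on the directed web restricted to the surviving node set
    instead (the alternative ordering; the default is the documented one).

    ``bipartite_excluded`` is the metadata-level flag marking a web as
    bipartite by study design; two-colorability of the processed web only
    raises a warning flag, since bipartite-like topology alone is not proof
    of a bipartite sampling design.
    """
    decision = FilterDecision(web_id=web.web_id, included=False, n_nodes_raw=web.n_nodes)
    if web.n_nodes == 0 or web.n_edges == 0:
        decision.reasons.append("empty")
        return None, decision
    if bipartite_excluded:
        decision.reasons.append("bipartite_like")
        return None, decision

    n_consumers, n_resources = count_roles(web)
    undirected = to_simple_undirected(web)
    if undirected.n_edges == 0:
        decision.reasons.append("empty")
        return None, decision
    giant = giant_component(undirected)
    if role_stage == "final":
        sub = FoodWeb(web.web_id, web.graph.subgraph(giant.nodes()).copy())
        n_consumers, n_resources = count_roles(sub)
    elif role_stage != "raw":
        raise ValueError(f"unknown role_stage {role_stage!r}")

    decision.n_consumers = n_consumers
    decision.n_resources = n_resources
    decision.n_nodes_final = giant.n_nodes
    decision.giant_component_fraction = giant.n_nodes / undirected.n_nodes
    decision.bipartite_warning = nx.is_bipartite(giant.graph)

    if giant.n_nodes < min_nodes:
        decision.reasons.append("too_few_nodes")
    if n_consumers < min_consumers:
        decision.reasons.append("too_few_consumers")
    if n_resources < min_resources:
        decision.reasons.append("too_few_resources")

    decision.included = not decision.reasons
    return (giant if decision.included else None), decision
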