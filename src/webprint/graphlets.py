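"""Graphlet degree vectors, GCM-11, and the graphlet correlation distance.

A graphlet is a small connected *induced* subgraph; the six graphlets on two
to four nodes carry 15 automorphism orbits, of which the canonical set
{0, 1, 2, 4, 5, 6, 7, 8, 9, 10, 11} is non-redundant (orbit 3 -- the
triangle -- and orbits 12-14 of the diamond and 4-clique are linearly
dependent on the rest and are excluded).  Canonical orbit positions:

====  =======================  =========================
id    graphlet                 position
====  =======================  =========================
0     edge                     endpoint (= degree)
1     3-path                   end
2     3-path                   middle
4     4-path                   end
5     4-path                   middle
6     3-star                   leaf
7     3-star                   center
8     4-cycle                  any node
9     tailed triangle (paw)    tail tip
10    tailed triangle          triangle node, degree 2
11    tailed triangle          degree-3 hub
====  =======================  =========================

A web's fingerprint is the Spearman correlation matrix between the 11 orbit
count columns (GCM-11); two webs are compared by the Euclidean distance
between the upper triangles of their GCM-11s (GCD-11).

The fast counter uses closed-form combinatorial identities: non-induced
pattern counts have simple matrix expressions, and induced counts follow by
subtracting the contributions of the denser graphlets (paw, diamond,
4-clique), which are counted directly.  An exhaustive subset-enumeration
counter is kept as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .net_io import FoodWeb

#: canonical ids of the 11 non-redundant orbits, in column order
ORBIT_IDS = (0, 1, 2, 4, 5, 6, 7, 8, 9, 10, 11)

#: number of independent entries in the strict upper triangle of a GCM-11
N_UPPER = 55

#: largest possible GCD-11: every upper-triangle entry differing by 2
MAX_GCD11 = float(np.sqrt(N_UPPER * 4.0))


@dataclass
class OrbitCountTable:
    """Per-node counts over the 11 non-redundant orbits (n x 11)."""

    web_id: str
    node_order: list[str]
    counts: np.ndarray  # shape (n, 11), nonnegative integers

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=self.node_order,
            columns=[f"o{i}" for i in ORBIT_IDS],
        )


@dataclass
class GCM11:
    """Symmetric 11x11 Spearman correlation matrix of orbit-count columns."""

    web_id: str
    matrix: np.ndarray

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(11, k=1)
        return self.matrix[iu]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise GCD-11 matrix over an ordered web collection."""

    web_ids: list[str]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.web_ids, columns=self.web_ids)

    def lookup(self, a: str, b: str) -> float:
        i, j = self.web_ids.index(a), self.web_ids.index(b)
        return float(self.values[i, j])


def _validate_processed(web: FoodWeb) -> None:
    if web.directed:
        raise ValueError(f"web {web.web_id!r}: orbit counting needs an undirected web")
    if web.n_nodes < 2:
        raise ValueError(f"web {web.web_id!r}: need at least 2 nodes")
    if any(u == v for u, v in web.graph.edges):
        raise ValueError(f"web {web.web_id!r}: self-loops must be removed first")


def count_orbits(web: FoodWeb) -> OrbitCountTable:
    """Per-node induced-subgraph orbit counts via combinatorial identities.

    All fifteen orbit counts are derived internally (the dense orbits are
    needed for the induced-subgraph corrections); only the 11 canonical
    columns are returned.
    """
    _validate_processed(web)
    nodes = list(web.graph.nodes)
    n = len(nodes)
    A = nx.to_numpy_array(web.graph, nodelist=nodes, dtype=np.int64)
    d = A.sum(axis=1)
    A2 = A @ A  # off-diagonal: common-neighbor counts; diagonal: degree
    tri = (A * A2).sum(axis=1) // 2  # triangles at each node

    def choose2(x):
        return x * (x - 1) // 2

    def choose3(x):
        return x * (x - 1) * (x - 2) // 6

    # --- 3-node orbits -----------------------------------------------------
    s1 = A @ (d - 1)  # sum over neighbors u of (deg(u) - 1)
    o1 = s1 - 2 * tri
    o2 = choose2(d) - tri
    o3 = tri

    # --- non-induced 4-node pattern counts --------------------------------
    nP4end = A @ s1 - d * (d - 1) - 2 * tri
    nP4mid = (d - 1) * s1 - 2 * tri
    nStarleaf = A @ choose2(d - 1)
    nStarcen = choose3(d)
    # 4-cycles through v: pairs u<w in N(v) with a second common neighbor
    sum_cn_pairs = ((A @ A2) * A).sum(axis=1) - A @ d  # sum over u!=w in N(v) of cn(u,w)
    nC4 = sum_cn_pairs / 2 - choose2(d)
    nPawTip = A @ tri - 2 * tri
    nPawDeg2 = (A * A2) @ (d - 2)
    nPawHub = tri * (d - 2)

    # --- dense graphlets counted directly ----------------------------------
    o14 = np.zeros(n, dtype=np.int64)  # 4-cliques at v
    s_edge_cn = np.zeros(n, dtype=np.int64)  # sum over edges within N(v) of cn(a,b)
    for v in range(n):
        nb = np.flatnonzero(A[v])
        if nb.size < 2:
            continue
        B = A[np.ix_(nb, nb)]
        o14[v] = (B * (B @ B)).sum() // 6
        s_edge_cn[v] = (B * A2[np.ix_(nb, nb)]).sum() // 2
    o13 = (A * choose2(A2)).sum(axis=1) - 3 * o14  # diamond hub (degree 3)
    o12 = s_edge_cn - tri - 3 * o14  # diamond shoulder (degree 2)

    # --- induced counts by subtracting denser graphlets --------------------
    o11 = nPawHub - 2 * o13 - 3 * o14
    o10 = nPawDeg2 - 2 * o12 - 2 * o13 - 6 * o14
    o9 = nPawTip - 2 * o12 - 3 * o14
    o8 = nC4 - o12 - o13 - 3 * o14
    o7 = nStarcen - o11 - o13 - o14
    o6 = nStarleaf - o9 - o10 - 2 * o12 - o13 - 3 * o14
    o5 = nP4mid - 2 * o8 - o10 - 2 * o11 - 2 * o12 - 4 * o13 - 6 * o14
    o4 = nP4end - 2 * o8 - 2 * o9 - o10 - 4 * o12 - 2 * o13 - 6 * o14

    counts = np.column_stack([d, o1, o2, o4, o5, o6, o7, o8, o9, o10, o11]).astype(np.int64)
    # post-hoc consistency checks on identities the counts must satisfy
    if counts.min() < 0:
        raise AssertionError(f"web {web.web_id!r}: negative orbit count (internal error)")
    if counts[:, 0].sum() != 2 * web.n_edges:
        raise AssertionError(f"web {web.web_id!r}: degree identity violated (internal error)")
    return OrbitCountTable(web_id=web.web_id, node_order=[str(x) for x in nodes], counts=counts)


# degree signatures of the connected 4-node graphs -> orbit id per in-subset degree
_SIG4 = {
    # (#edges, sorted degree tuple): {degree: orbit id}
    (3, (1, 1, 2, 2)): {1: 4, 2: 5},  # 4-path
    (3, (1, 1, 1, 3)): {1: 6, 3: 7},  # 3-star
    (4, (2, 2, 2, 2)): {2: 8},  # 4-cycle
    (4, (1, 2, 2, 3)): {1: 9, 2: 10, 3: 11},  # tailed triangle
    (5, (2, 2, 3, 3)): {2: 12, 3: 13},  # diamond
    (6, (3, 3, 3, 3)): {3: 14},  # 4-clique
}


def count_orbits_bruteforce(web: FoodWeb, cap: int = 40) -> OrbitCountTable:
    """Oracle counter: exhaustive enumeration of all 2-/3-/4-node subsets.

    Each subset's induced subgraph is classified by edge count and degree
    signature.  Quadratic-to-quartic in n, hence the size cap.
    """
    _validate_processed(web)
    nodes = list(web.graph.nodes)
    n = len(nodes)
    if n > cap:
        raise ValueError(f"web {web.web_id!r}: n={n} exceeds brute-force cap {cap}")
    index = {u: i for i, u in enumerate(nodes)}
    adj = [set() for _ in range(n)]
    for u, v in web.graph.edges:
        adj[index[u]].add(index[v])
        adj[index[v]].add(index[u])

    full = np.zeros((n, 15), dtype=np.int64)
    for a, b in combinations(range(n), 2):
        if b in adj[a]:
            full[a, 0] += 1
            full[b, 0] += 1
    for trip in combinations(range(n), 3):
        degs = [sum(1 for o in trip if o in adj[x]) for x in trip]
        e = sum(degs) // 2
        if e == 3:
            for x in trip:
                full[x, 3] += 1
        elif e == 2 and min(degs) >= 1:
            for x, dg in zip(trip, degs):
                full[x, 1 if dg == 1 else 2] += 1
    for quad in combinations(range(n), 4):
        degs = [sum(1 for o in quad if o in adj[x]) for x in quad]
        if min(degs) == 0:
            continue
        e = sum(degs) // 2
        sig = (e, tuple(sorted(degs)))
        mapping = _SIG4.get(sig)
        if mapping is None:  # 3 edges, degrees (1,1,2,2) w/ disconnected shape etc.
            continue
        for x, dg in zip(quad, degs):
            full[x, mapping[dg]] += 1

    counts = full[:, list(ORBIT_IDS)]
    return OrbitCountTable(web_id=web.web_id, node_order=[str(x) for x in nodes], counts=counts)


def gcm11(counts: OrbitCountTable) -> GCM11:
    """Graphlet correlation matrix: Spearman correlations of orbit columns.

    One pseudo-row of all ones is appended before correlating, so that
    columns constant at zero still carry rank information; any column that is
    constant even after the pseudo-row gets correlation 0 with everything.
    Ties are handled by average ranks.
    """
    X = counts.counts
    if X.shape[0] < 2:
        raise ValueError(f"web {counts.web_id!r}: need at least 2 nodes for a GCM")
    Xp = np.vstack([X, np.ones((1, X.shape[1]), dtype=X.dtype)])
    constant = np.all(Xp == Xp[0, :], axis=0)
    ranks = np.apply_along_axis(rankdata, 0, Xp.astype(float))  # average-rank ties
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.asarray(rho, dtype=float)
    rho[np.isnan(rho)] = 0.0
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    rho = (rho + rho.T) / 2.0
    return GCM11(web_id=counts.web_id, matrix=rho)


def gcd11(a: GCM11, b: GCM11, squared: bool = False) -> float:
    """Graphlet correlation distance: Euclidean norm over the 55
    strictly-upper-triangular GCM entries (``squared=True`` skips the root)."""
    diff = a.upper_triangle() - b.upper_triangle()
    ss = float(np.dot(diff, diff))
    return ss if squared else float(np.sqrt(ss))


def gcm_for_web(web: FoodWeb) -> GCM11:
    """Convenience: orbit counts then GCM-11 for one processed web."""
    return gcm11(count_orbits(web))


def pairwise_distances(webs: list[FoodWeb], squared: bool = False) -> DistanceMatrix:
    """Pairwise GCD-11 over a collection of processed webs (order preserved)."""
    if len(webs) < 2:
        raise ValueError("need at least 2 webs for pairwise distances")
    ids = [w.web_id for w in webs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate web_ids in collection")
    uppers = np.array([gcm_for_web(w).upper_triangle() for w in webs])
    metric = "sqeuclidean" if squared else "euclidean"
    values = squareform(pdist(uppers, metric=metric))
    return DistanceMatrix(web_ids=ids, values=values)
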