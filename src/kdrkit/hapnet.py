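"""Median-joining haplotype networks over a gene region's phased haplotypes.

Observed haplotypes are collapsed to unique nodes carrying a count and a
composition (taxon or diplotype-group tallies), then connected by the
ε-relaxed minimum-spanning network under Hamming distance. Median (Steiner)
vectors — site-wise majorities over connected triplets — are added
iteratively, and finally any median not lying on a shortest path between two
observed haplotypes is pruned. With ε = 0 and all pairwise distances
distinct the observed-node subgraph contains a minimum spanning tree.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from kdrkit.core_io import MISSING, HaplotypeMatrix


@dataclass
class HapNode:
    vector: tuple[int, ...]
    count: int
    composition: dict[str, int] = field(default_factory=dict)
    is_median: bool = False


@dataclass
class HaplotypeNetwork:
    nodes: list[HapNode]
    edges: list[tuple[int, int, int]]  # (node index, node index, Hamming weight)
    epsilon: int = 0
    converged: bool = True

    def graph(self) -> nx.Graph:
        G = nx.Graph()
        for i, node in enumerate(self.nodes):
            G.add_node(
                i,
                vector="".join(map(str, node.vector)),
                count=node.count,
                is_median=node.is_median,
            )
        for u, v, w in self.edges:
            G.add_edge(u, v, weight=w)
        return G


def collapse_haplotypes(
    h: HaplotypeMatrix, labels=None
) -> tuple[np.ndarray, np.ndarray, list[dict[str, int]]]:
    """Merge identical haplotype columns.

    ``labels`` assigns one label per haplotype column (length 2·n_samples),
    e.g. the carrying sample's taxon or diplotype group; compositions tally
    labels per unique haplotype. Returns (unique_haplotypes, counts,
    compositions) with unique rows sorted lexicographically for determinism.
    """
    if (h.haps == MISSING).any():
        raise ValueError("haplotypes contain missing alleles; mask sites first")
    cols = h.haps.T  # one row per haplotype
    if labels is None:
        labels = [""] * cols.shape[0]
    if len(labels) != cols.shape[0]:
        raise ValueError("need one label per haplotype column")
    uniq, inverse = np.unique(cols, axis=0, return_inverse=True)
    counts = np.bincount(inverse, minlength=len(uniq))
    comps: list[dict[str, int]] = [Counter() for _ in range(len(uniq))]
    for col, u in enumerate(inverse):
        comps[u][labels[col]] += 1
    return uniq, counts, [dict(sorted(c.items())) for c in comps]


def _hamming(a: tuple[int, ...], b: tuple[int, ...]) -> int:
    return sum(x != y for x, y in zip(a, b))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def n_components(self) -> int:
        return len({self.find(i) for i in range(len(self.parent))})


def _msn_edges(vectors: list[tuple[int, ...]], epsilon: int) -> list[tuple[int, int, int]]:
    """ε-relaxed minimum spanning network under Hamming distance.

    Edge weight classes are processed in ascending order; within a class an
    edge joins the network iff its endpoints lay in different components
    before the class was opened. Classes keep being admitted until the
    network is connected, then for a further ε weight units. Candidate edges
    inside a class are visited in lexicographic node-key order so ties break
    deterministically.
    """
    n = len(vectors)
    if n <= 1:
        return []
    by_weight: dict[int, list[tuple[int, int]]] = {}
    for i, j in itertools.combinations(range(n), 2):
        by_weight.setdefault(_hamming(vectors[i], vectors[j]), []).append((i, j))
    uf = _UnionFind(n)
    edges: list[tuple[int, int, int]] = []
    connect_weight: int | None = None
    for w in sorted(by_weight):
        if connect_weight is not None and w > connect_weight + epsilon:
            break
        comp_before = {i: uf.find(i) for i in range(n)}
        for i, j in sorted(by_weight[w], key=lambda e: (vectors[e[0]], vectors[e[1]])):
            if comp_before[i] != comp_before[j]:
                edges.append((i, j, w))
                uf.union(i, j)
        if connect_weight is None and uf.n_components() == 1:
            connect_weight = w
    return edges


def _majority_median(
    a: tuple[int, ...], b: tuple[int, ...], c: tuple[int, ...]
) -> tuple[int, ...]:
    """Site-wise majority of a triplet. On binary-coded sites the majority is
    exact (the classical median vector); where all three values differ the
    value of the lexicographically smallest vector is kept, a deterministic
    generalization for multiallelic codings."""
    first = min(a, b, c)
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(first[len(out)])
    return tuple(out)


def median_joining(
    unique_haps: np.ndarray,
    counts=None,
    compositions=None,
    epsilon: int = 0,
    max_rounds: int = 20,
) -> HaplotypeNetwork:
    """Build a median-joining network from unique observed haplotypes.

    Rounds alternate (1) the ε-relaxed minimum-spanning network over the
    current node set, (2) median vectors of every connected triplet (two or
    more edges among the three nodes), adding novel ones as inferred
    (is_median) nodes, until no new medians appear or ``max_rounds`` is hit
    (then ``converged=False``). Medians not on any shortest path between
    observed haplotypes are pruned at the end.
    """
    unique_haps = np.asarray(unique_haps)
    if unique_haps.ndim != 2 or len(unique_haps) < 1:
        raise ValueError("need a 2-D array with >= 1 haplotype")
    observed = [tuple(int(x) for x in row) for row in unique_haps]
    if len(set(observed)) != len(observed):
        raise ValueError("unique_haps contains duplicate rows")
    if counts is None:
        counts = [1] * len(observed)
    if compositions is None:
        compositions = [{} for _ in observed]

    vectors: list[tuple[int, ...]] = list(observed)
    known = set(vectors)
    converged = True
    edges = _msn_edges(vectors, epsilon)
    for _ in range(max_rounds):
        adj: dict[int, set[int]] = {i: set() for i in range(len(vectors))}
        for u, v, _w in edges:
            adj[u].add(v)
            adj[v].add(u)
        new: set[tuple[int, ...]] = set()
        for b in range(len(vectors)):
            for a, c in itertools.combinations(sorted(adj[b]), 2):
                med = _majority_median(vectors[a], vectors[b], vectors[c])
                if med not in known:
                    new.add(med)
        if not new:
            break
        vectors.extend(sorted(new))
        known.update(new)
        edges = _msn_edges(vectors, epsilon)
    else:
        converged = False

    # prune medians not on any observed-observed shortest path
    n_obs = len(observed)
    while True:
        G = nx.Graph()
        G.add_nodes_from(range(len(vectors)))
        for u, v, w in edges:
            G.add_edge(u, v, weight=w)
        dist = dict(nx.all_pairs_dijkstra_path_length(G, weight="weight"))
        drop = set()
        for m in range(n_obs, len(vectors)):
            on_path = any(
                abs(dist[a][m] + dist[m][b] - dist[a][b]) < 1e-9
                for a in range(n_obs)
                for b in range(a + 1, n_obs)
                if m in dist[a] and b in dist[a] and b in dist[m]
            )
            if not on_path:
                drop.add(m)
        if not drop:
            break
        vectors = [v for i, v in enumerate(vectors) if i not in drop]
        edges = _msn_edges(vectors, epsilon)

    nodes = []
    for i, vec in enumerate(vectors):
        if i < n_obs:
            nodes.append(
                HapNode(vec, int(counts[i]), dict(compositions[i]), is_median=False)
            )
        else:
            nodes.append(HapNode(vec, 0, {}, is_median=True))
    return HaplotypeNetwork(nodes, edges, epsilon=epsilon, converged=converged)


def shared_nodes(net: HaplotypeNetwork) -> list[int]:
    """Indices of observed nodes shared between groups (>= 2 labels tallied)."""
    return [
        i
        for i, node in enumerate(net.nodes)
        if not node.is_median and len(node.composition) >= 2
    ]


def _comp_string(node: HapNode) -> str:
    return ";".join(f"{k}:{v}" for k, v in sorted(node.composition.items()))


def export_network(net: HaplotypeNetwork, path: str | Path, format: str = "dot") -> None:
    """Write the network as Graphviz DOT or GraphML.

    Node attributes: ``count`` (drawn as circle size), ``composition``
    (label:count pairs, the fill proportions; empty means uniform fill) and
    ``is_median``. Node ordering is deterministic (input node order, which is
    lexicographic within observed and median blocks).
    """
    path = Path(path)
    if format == "dot":
        lines = ["graph hapnet {", "  node [shape=circle];"]
        for i, node in enumerate(net.nodes):
            label = "".join(map(str, node.vector))
            shape = "point" if node.is_median else "circle"
            lines.append(
                f'  n{i} [label="{label}" count={node.count} shape={shape} '
                f'composition="{_comp_string(node)}"];'
            )
        for u, v, w in sorted(net.edges):
            lines.append(f'  n{u} -- n{v} [label="{w}" weight={w}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "graphml":
        G = net.graph()
        for i, node in enumerate(net.nodes):
            G.nodes[i]["composition"] = _comp_string(node)
        nx.write_graphml(G, str(path))
    else:
        raise ValueError(f"unknown format {format!r}; use 'dot' or 'graphml'")
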