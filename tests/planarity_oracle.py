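"""Brute-force planarity oracle for small graphs (Kuratowski subdivisions).

A graph is planar iff it contains no subdivision of K5 or K3,3. For
graphs with <= ~10 nodes this can be decided by exhaustive search over
branch-vertex sets and internally-disjoint connecting paths, completely
independently of the library's planarity test.
"""

from __future__ import annotations

from itertools import combinations, permutations

import networkx as nx


def is_planar_bruteforce(g: nx.Graph) -> bool:
    if g.number_of_nodes() <= 4 or g.number_of_edges() <= 8:
        return True
    return not (_has_k5_subdivision(g) or _has_k33_subdivision(g))


def _has_k5_subdivision(g: nx.Graph) -> bool:
    nodes = [v for v in g.nodes if g.degree(v) >= 4]
    for branch in combinations(sorted(nodes, key=str), 5):
        spares = [v for v in g.nodes if v not in branch]
        pairs = list(combinations(branch, 2))
        if _connect_pairs(g, pairs, spares):
            return True
    return False


def _has_k33_subdivision(g: nx.Graph) -> bool:
    nodes = sorted((v for v in g.nodes if g.degree(v) >= 3), key=str)
    for side_a in combinations(nodes, 3):
        rest = [v for v in nodes if v not in side_a]
        for side_b in combinations(rest, 3):
            if str(side_a[0]) > str(side_b[0]):
                continue  # unordered bipartition: count each once
            spares = [v for v in g.nodes if v not in side_a and v not in side_b]
            pairs = [(a, b) for a in side_a for b in side_b]
            if _connect_pairs(g, pairs, spares):
                return True
    return False


def _connect_pairs(g: nx.Graph, pairs, spares) -> bool:
    """Can every pair be joined by internally-disjoint paths whose internal
    vertices are distinct spares? Direct edges consume nothing, so they are
    always used when available."""
    chains_needed = [p for p in pairs if not g.has_edge(*p)]
    if not chains_needed:
        return True
    if len(chains_needed) > len(spares):
        return False
    return _assign_chains(g, chains_needed, 0, frozenset(spares))


def _assign_chains(g: nx.Graph, chains, i, free) -> bool:
    if i == len(chains):
        return True
    u, v = chains[i]
    max_len = len(free) - (len(chains) - i - 1)  # leave one spare per later chain
    for length in range(1, max_len + 1):
        for internal in permutations(sorted(free, key=str), length):
            path = (u, *internal, v)
            if all(g.has_edge(path[j], path[j + 1]) for j in range(len(path) - 1)):
                if _assign_chains(g, chains, i + 1, free - set(internal)):
                    return True
    return False


def greedy_planar_filter_oracle(candidates) -> set[tuple[str, str]]:
    """Reference greedy PMFG: re-test planarity by brute force at each step."""
    g = nx.Graph()
    for a, b, _w in candidates[["gene_a", "gene_b", "correlation"]].itertuples(index=False):
        g.add_edge(a, b)
        if not is_planar_bruteforce(g):
            g.remove_edge(a, b)
            if g.degree(a) == 0:
                g.remove_node(a)
            if g.degree(b) == 0:
                g.remove_node(b)
    return {(min(a, b), max(a, b)) for a, b in g.edges}
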