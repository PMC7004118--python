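"""Planar filtered network (PFN) construction.

Two steps: an all-pairs correlation screen retaining pairs significant at
a Benjamini-Hochberg FDR, then greedy planarity-constrained edge
insertion in decreasing |correlation| order. The greedy filter yields
the planar maximally filtered graph (PMFG) of the candidate list: an
edge is kept iff the running graph stays planar after adding it, so the
result never exceeds 3n - 6 edges and always passes a planarity test.

Planarity is decided combinatorially (left-right planarity test via
networkx); the construction is deterministic because candidate order is
fully specified (|r| descending, ties broken lexicographically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ValidationError

logger = logging.getLogger("coexnet")

EDGE_COLUMNS = ["gene_a", "gene_b", "correlation", "p_value", "q_value"]


@dataclass
class PlanarNetwork:
    """Weighted undirected planar graph; edge weights are correlations."""

    graph: nx.Graph
    planarity_certificate: bool = field(default=False)

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "PlanarNetwork":
        ok, _ = nx.check_planarity(graph)
        return cls(graph, ok)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(min(a, b), max(a, b)) for a, b in self.graph.edges}


def correlation_screen(x: ExpressionMatrix, method: str = "pearson",
                       fdr: float = 0.05, top_k: int | None = None) -> pd.DataFrame:
    """All-pairs correlation screen at a given FDR.

    Returns the edge-candidate list: columns gene_a < gene_b, correlation,
    two-sided p, BH q; rows ordered by |correlation| descending with ties
    broken lexicographically on (gene_a, gene_b). ``top_k`` optionally
    restricts candidates to each gene's K strongest partners before the
    FDR screen (off by default).
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    n = x.n_samples
    if n < 3:
        raise ValidationError("correlation screen requires >= 3 samples")
    v = x.values
    if (v.std(axis=1) <= 0).any():
        raise ValidationError("zero-variance genes must be removed before screening")
    if method == "spearman":
        v = stats.rankdata(v, axis=1)
    r = np.corrcoef(v)
    np.clip(r, -1.0, 1.0, out=r)

    iu, ju = np.triu_indices(x.n_genes, k=1)
    rv = r[iu, ju]
    if top_k is not None:
        mask = _top_k_mask(np.abs(r), top_k)
        keep = mask[iu, ju]
        iu, ju, rv = iu[keep], ju[keep], rv[keep]
    # two-sided p from the t transform of r with n-2 df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / np.maximum(1.0 - rv * rv, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rv) >= 1.0] = 0.0
    _, q, _, _ = multipletests(p, method="fdr_bh")

    keep = q < fdr
    genes = np.asarray(x.gene_ids, dtype=object)
    df = pd.DataFrame({
        "gene_a": genes[iu[keep]],
        "gene_b": genes[ju[keep]],
        "correlation": rv[keep],
        "p_value": p[keep],
        "q_value": q[keep],
    })
    # enforce gene_a < gene_b lexicographically
    swap = df["gene_a"] > df["gene_b"]
    df.loc[swap, ["gene_a", "gene_b"]] = df.loc[swap, ["gene_b", "gene_a"]].to_numpy()
    df["_abs"] = df["correlation"].abs()
    df = (df.sort_values(["_abs", "gene_a", "gene_b"],
                         ascending=[False, True, True], kind="stable")
            .drop(columns="_abs").reset_index(drop=True))
    logger.info("correlation screen: %d/%d pairs significant at FDR<%g",
                len(df), len(p), fdr)
    return df


def build_pfn(candidates: pd.DataFrame) -> PlanarNetwork:
    """Greedy planarity-constrained insertion of the ordered candidate list.

    A graph is planar iff every biconnected block is planar, and adding an
    edge (a, b) merges exactly the blocks on the block-cut-tree path
    between a and b, leaving all other blocks untouched. The construction
    therefore maintains the block structure incrementally: candidates
    joining distinct components (or touching a new node) are always safe;
    same-component candidates are rejected in O(1) when the merged block
    would exceed its 3n - 6 planar edge budget, and otherwise tested for
    planarity on the merged block only.
    """
    g = nx.Graph()
    if candidates is None or len(candidates) == 0:
        return PlanarNetwork(g, True)
    comp: dict[str, str] = {}          # union-find over connected components
    comp_size: dict[str, int] = {}
    block_nodes: dict[int, set[str]] = {}
    block_m: dict[int, int] = {}       # edge count per block
    node_blocks: dict[str, set[int]] = {}
    next_block = 0

    def find(a: str) -> str:
        root = a
        while comp[root] != root:
            root = comp[root]
        while comp[a] != root:
            comp[a], a = root, comp[a]
        return root

    def add_node(a: str) -> None:
        if a not in comp:
            comp[a] = a
            comp_size[a] = 1
            node_blocks[a] = set()
            g.add_node(a)

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if comp_size[ra] < comp_size[rb]:
            ra, rb = rb, ra
        comp[rb] = ra
        comp_size[ra] += comp_size.pop(rb)

    def new_block(nodes: set[str], m: int) -> None:
        nonlocal next_block
        bid = next_block
        next_block += 1
        block_nodes[bid] = nodes
        block_m[bid] = m
        for v in nodes:
            node_blocks[v].add(bid)

    def block_path(a: str, b: str) -> list[int]:
        """Blocks on the unique block-cut-tree path from a to b."""
        target = node_blocks[b]
        prev: dict[int, int | None] = {bid: None for bid in node_blocks[a]}
        queue = list(prev)
        while queue:
            nxt: list[int] = []
            for bid in queue:
                if bid in target:
                    path = [bid]
                    while prev[path[-1]] is not None:
                        path.append(prev[path[-1]])
                    return path
                for v in block_nodes[bid]:
                    for nb in node_blocks[v]:
                        if nb not in prev:
                            prev[nb] = bid
                            nxt.append(nb)
            queue = nxt
        raise AssertionError("no block path inside a connected component")

    for a, b, w in candidates[["gene_a", "gene_b", "correlation"]].itertuples(index=False):
        a, b = str(a), str(b)
        add_node(a)
        add_node(b)
        if find(a) != find(b):
            g.add_edge(a, b, weight=float(w))
            union(a, b)
            new_block({a, b}, 1)
            continue
        path = block_path(a, b)
        merged = set().union(*(block_nodes[bid] for bid in path))
        n_m = len(merged)
        m_m = sum(block_m[bid] for bid in path)
        if n_m >= 3 and m_m + 1 > 3 * n_m - 6:
            continue
        g.add_edge(a, b, weight=float(w))
        # materialize the merged block: the LR test is much faster on a
        # plain graph than through a subgraph-view filter
        block_g = nx.Graph()
        block_g.add_nodes_from(merged)
        adj = g._adj
        block_g.add_edges_from(
            (u, v) for u in merged for v in adj[u] if v in merged and u < v)
        ok = True
        if n_m > 60:
            # cheap local rejection first: a nonplanar subgraph certifies
            # nonplanarity, and the Kuratowski subdivision created by the
            # new edge is usually within 2 hops of its endpoints
            local = set(nx.bfs_tree(block_g, a, depth_limit=2))
            local |= set(nx.bfs_tree(block_g, b, depth_limit=2))
            ok, _ = nx.check_planarity(nx.Graph(block_g.subgraph(local)))
        if ok:
            ok, _ = nx.check_planarity(block_g)
        if not ok:
            g.remove_edge(a, b)
            continue
        for bid in path:
            for v in block_nodes.pop(bid):
                node_blocks[v].discard(bid)
            del block_m[bid]
        new_block(merged, m_m + 1)

    ok, _ = nx.check_planarity(g)
    net = PlanarNetwork(g, ok)
    logger.info("PFN: %d nodes, %d edges (planar=%s)", net.n_nodes, net.n_edges, ok)
    return net


def _top_k_mask(abs_r: np.ndarray, k: int) -> np.ndarray:
    """Symmetric mask keeping pairs in either gene's top-k partners."""
    n = abs_r.shape[0]
    a = abs_r.copy()
    np.fill_diagonal(a, -np.inf)
    k = min(k, n - 1)
    thresh = np.partition(a, n - 1 - k, axis=1)[:, n - 1 - k][:, None]
    mask = a >= thresh
    return mask | mask.T
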