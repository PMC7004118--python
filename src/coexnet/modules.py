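"""Multiscale module detection on the planar filtered network.

Modules are found by recursive top-down splitting. Each module's induced
subgraph is partitioned into candidate children by seeded Louvain
community detection on |correlation| edge weights; children below the
minimum module size are first merged into the most strongly connected
sibling. A candidate child is accepted as a module at compactness scale
alpha iff it is either

* significantly compact: its weighted internal density (sum of internal
  edge weights / size) exceeds the density of size-matched random
  connected subgraphs of the parent by at least ``2 / alpha`` null
  standard deviations, or
* quasi-disconnected: its internal edge weight exceeds ``10 / alpha``
  times the weight of its cut to the rest of the parent.

Accepted children become modules and are split recursively; genes of
rejected candidates remain with the parent (leaves therefore partition
the *clustered* subset of each component). Larger alpha relaxes both
conditions, producing smaller and more numerous modules, and a
homogeneous subgraph (whose candidate children look exactly like random
connected subgraphs of itself) is never split. Connected components of
a disconnected (sub)graph become children outright (their cut is empty).

Hubs ("key drivers") are genes whose within-module degree exceeds the
(1 - p_cut) quantile of the degree-preserving rewiring null. Because
degree-preserving rewiring leaves every node's degree unchanged, the
pooled null degree distribution equals the module's own degree multiset
and the quantile is computed exactly rather than by sampling.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix

from .containers import Module, ModuleHierarchy, ValidationError
from .network import PlanarNetwork

logger = logging.getLogger("coexnet")

N_NULL_SUBGRAPHS = 100  # null draws per (parent, child-size) compactness test
Z_BASE = 2.0            # z threshold at alpha = 1
SPARSITY_BASE = 10.0    # internal/cut weight ratio threshold at alpha = 1


def cluster_multiscale(net: PlanarNetwork, alphas: list[float],
                       min_size: int = 10, seed: int = 0) -> ModuleHierarchy:
    """Detect the parent/child module hierarchy at each compactness scale.

    One tree per alpha, rooted at the whole PFN vertex set, merged into a
    single forest. Deterministic given the seed.
    """
    if not alphas:
        raise ValidationError("alphas must be nonempty")
    if min_size < 3:
        raise ValidationError("min_size must be >= 3")
    if net.n_nodes == 0:
        raise ValidationError("empty network")

    modules: list[Module] = []
    counter = 0
    for ai, alpha in enumerate(sorted(alphas)):
        root_id = f"M{counter}"
        counter += 1
        all_genes = frozenset(net.graph.nodes)
        modules.append(Module(root_id, None, float(alpha), all_genes))
        splitter = _Splitter(net.graph, float(alpha), min_size, seed, ai)
        components = sorted(nx.connected_components(net.graph),
                            key=lambda c: (-len(c), min(c)))
        for comp in components:
            if len(comp) < min_size:
                continue  # too small to cluster; left unassigned below the root
            if len(comp) == len(all_genes):
                # connected network: split the root itself
                stack = [(root_id, comp)]
            else:
                mid = f"M{counter}"
                counter += 1
                modules.append(Module(mid, root_id, float(alpha), frozenset(comp)))
                stack = [(mid, comp)]
            while stack:
                parent_id, nodes = stack.pop()
                children = splitter.split(nodes)
                for child in children:
                    cid = f"M{counter}"
                    counter += 1
                    modules.append(Module(cid, parent_id, float(alpha), frozenset(child)))
                    if len(child) >= 2 * min_size:
                        stack.append((cid, child))
    h = ModuleHierarchy(modules)
    logger.info("multiscale clustering: %d modules over %d scales", len(h), len(alphas))
    return h


def nominate_hubs(net: PlanarNetwork, h: ModuleHierarchy, n_perm: int = 100,
                  p_cut: float = 0.05, seed: int = 0) -> ModuleHierarchy:
    """Nominate per-module hub genes against the rewiring degree null.

    ``n_perm``/``seed`` are part of the permutation contract but the
    quantile is exact (see module docstring), so results do not vary
    with them.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if not 0 < p_cut < 1:
        raise ValidationError("p_cut must be in (0, 1)")
    out = []
    for m in h.modules:
        sub = net.graph.subgraph(m.genes)
        degrees = dict(sub.degree())
        if len(degrees) < 3 or sub.number_of_edges() < 2:
            logger.info("module %s too small for hub nomination", m.module_id)
            out.append(Module(m.module_id, m.parent_id, m.alpha, m.genes, frozenset()))
            continue
        vals = np.array(sorted(degrees.values()), dtype=float)
        threshold = np.quantile(vals, 1.0 - p_cut)
        hubs = frozenset(g for g, d in degrees.items() if d > threshold)
        out.append(Module(m.module_id, m.parent_id, m.alpha, m.genes, hubs))
    return ModuleHierarchy(out)


def extract_neighborhood(net: PlanarNetwork, gene: str, k: int) -> set[str]:
    """All genes within shortest-path (hop) distance <= k of ``gene``."""
    if k < 1:
        raise ValidationError("neighborhood depth k must be >= 1")
    if gene not in net.graph:
        raise ValidationError(f"gene {gene!r} not in network")
    lengths = nx.single_source_shortest_path_length(net.graph, gene, cutoff=k)
    return set(lengths)


# ---------------------------------------------------------------------------


class _Splitter:
    """Stateful recursive splitter for one compactness scale."""

    def __init__(self, graph: nx.Graph, alpha: float, min_size: int,
                 seed: int, alpha_index: int) -> None:
        self.graph = graph
        self.alpha = alpha
        self.min_size = min_size
        self.seed = seed
        self.alpha_index = alpha_index
        self._call = 0

    def split(self, nodes) -> list[set[str]]:
        """Return accepted children of ``nodes`` (possibly empty)."""
        nodes = set(nodes)
        if len(nodes) < 2 * self.min_size:
            return []
        sub = self.graph.subgraph(nodes)
        comps = sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c)))
        if len(comps) > 1:
            children = [set(c) for c in comps if len(c) >= self.min_size]
            if children and not (len(children) == 1 and len(children[0]) == len(nodes)):
                return children
            return []
        self._call += 1
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, self.alpha_index, self._call]))
        return _split_connected(sub, self.alpha, self.min_size, rng)


def _split_connected(sub: nx.Graph, alpha: float, min_size: int,
                     rng: np.random.Generator) -> list[set[str]]:
    nodes = sorted(sub.nodes)
    n = len(nodes)
    index = {g: i for i, g in enumerate(nodes)}
    rows, cols, wts = [], [], []
    work = nx.Graph()
    work.add_nodes_from(nodes)
    for a, b, d in sub.edges(data=True):
        w = abs(float(d.get("weight", 1.0)))
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
        wts += [w, w]
        work.add_edge(a, b, weight=w)
    adj = csr_matrix((wts, (rows, cols)), shape=(n, n))

    louvain_seed = int(rng.integers(2 ** 31))
    communities = nx.community.louvain_communities(
        work, weight="weight", seed=louvain_seed)
    if len(communities) < 2:
        return []
    labels = np.empty(n, dtype=int)
    for c, com in enumerate(sorted(communities, key=lambda c: (-len(c), min(c)))):
        for g in com:
            labels[index[g]] = c
    clusters = _agglomerate_inseparable(labels, adj, alpha)
    clusters = _merge_small(clusters, adj, min_size)
    if not clusters or (len(clusters) == 1 and len(clusters[0]) == n):
        return []

    null_cache: dict[int, np.ndarray] = {}

    def null_stats(size: int) -> np.ndarray:
        if size not in null_cache:
            null_cache[size] = _null_density(adj, size, rng)
        return null_cache[size]

    z_req = Z_BASE / alpha
    ratio_req = SPARSITY_BASE / alpha
    total_strength = np.asarray(adj.sum(axis=1)).ravel()
    accepted: list[np.ndarray] = []
    for idx in clusters:
        if len(idx) == n:
            continue
        w_in = float(adj[np.ix_(idx, idx)].sum()) / 2.0
        w_cut = float(total_strength[idx].sum()) - 2.0 * w_in
        stat = w_in / len(idx)
        null = null_stats(len(idx))
        sd = null.std()
        z = (stat - null.mean()) / sd if sd > 1e-9 else 0.0
        ratio = w_in / max(w_cut, 1e-12)
        if z >= z_req or ratio > ratio_req:
            accepted.append(idx)
    out = [set(np.asarray(nodes, dtype=object)[idx]) for idx in accepted]
    out.sort(key=lambda c: (-len(c), min(c)))
    return out


def _agglomerate_inseparable(labels: np.ndarray, adj: csr_matrix,
                             alpha: float) -> list[np.ndarray]:
    """Merge candidate communities that are not separable at scale alpha.

    Two communities are separable when the cut weight between them is
    below (alpha / SPARSITY_BASE) times the smaller internal weight;
    inseparable pairs (strongest cut first) are merged until all
    remaining pairs are separable. This undoes over-fine partitions of
    homogeneous regions while leaving genuinely weak cuts intact.
    """
    clusters = {c: np.flatnonzero(labels == c) for c in np.unique(labels)}
    while len(clusters) > 1:
        w_in = {c: float(adj[np.ix_(idx, idx)].sum()) / 2.0
                for c, idx in clusters.items()}
        best = None
        keys = sorted(clusters)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                cut = float(adj[np.ix_(clusters[a], clusters[b])].sum())
                if cut <= 0:
                    continue
                limit = (alpha / SPARSITY_BASE) * max(min(w_in[a], w_in[b]), 1e-12)
                if cut >= limit:
                    key = (cut, -len(clusters[a]) - len(clusters[b]), a, b)
                    if best is None or key > best[0]:
                        best = (key, a, b)
        if best is None:
            break
        _, a, b = best
        clusters[a] = np.sort(np.concatenate([clusters[a], clusters.pop(b)]))
    return [np.sort(idx) for idx in clusters.values()]


def _merge_small(clusters: list[np.ndarray], adj: csr_matrix,
                 min_size: int) -> list[np.ndarray]:
    """Merge clusters below min_size into the sibling with the strongest
    connecting edge weight (fallback: the largest sibling)."""
    clusters = {c: np.asarray(idx) for c, idx in enumerate(clusters)}
    while len(clusters) > 1:
        small = [c for c, idx in clusters.items() if len(idx) < min_size]
        if not small:
            break
        c = min(small, key=lambda c: (len(clusters[c]), c))
        idx = clusters.pop(c)
        best_sib, best_w = None, -1.0
        for s, sidx in clusters.items():
            w = float(adj[np.ix_(idx, sidx)].sum())
            size_bonus = len(sidx) * 1e-9  # deterministic fallback toward larger sibling
            if w + size_bonus > best_w:
                best_w = w + size_bonus
                best_sib = s
        clusters[best_sib] = np.sort(np.concatenate([clusters[best_sib], idx]))
    out = [np.sort(idx) for idx in clusters.values() if len(idx) >= min_size]
    out.sort(key=lambda idx: (-len(idx), idx[0]))
    return out


def _null_density(adj: csr_matrix, size: int, rng: np.random.Generator,
                  n_draws: int = N_NULL_SUBGRAPHS) -> np.ndarray:
    """Weighted densities of random connected subgraphs grown by seeded BFS."""
    n = adj.shape[0]
    indptr, indices = adj.indptr, adj.indices
    stats = np.empty(n_draws)
    for d in range(n_draws):
        start = int(rng.integers(n))
        chosen = {start}
        frontier = set(indices[indptr[start]:indptr[start + 1]].tolist())
        frontier.discard(start)
        while len(chosen) < size and frontier:
            pick = sorted(frontier)[int(rng.integers(len(frontier)))]
            frontier.discard(pick)
            chosen.add(pick)
            for nb in indices[indptr[pick]:indptr[pick + 1]].tolist():
                if nb not in chosen:
                    frontier.add(nb)
        idx = np.fromiter(chosen, dtype=int)
        w_in = float(adj[np.ix_(idx, idx)].sum()) / 2.0
        stats[d] = w_in / len(idx)
    return stats
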