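"""Weighted pathway-similarity networks from gene-set overlap significance.

For every unordered pair of pathways a one-sided Fisher's exact test
(the upper tail of the hypergeometric distribution) scores the
significance of their gene overlap against the collection's universe.
P-values are Bonferroni-corrected over the number of tested pairs, pairs
with corrected p above the threshold get weight 0 (edge omitted), and
surviving edges are weighted -log10(corrected p), capped to keep
underflowed p-values finite. The result is a sparse weighted graph in
which communities of redundant or related pathways can be detected.

Tail probabilities are computed in log-space (``hypergeom.logsf``) so
the Bonferroni product and the -log10 transform stay accurate far below
double-precision underflow of the p-value itself.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from scipy.stats import hypergeom

from .geneset_io import GeneSetCollection

_LN10 = math.log(10.0)

DEFAULT_ALPHA = 0.01
DEFAULT_WEIGHT_CAP = 300.0


class PathwayGraph:
    """Undirected weighted graph over pathway ids.

    Stores only positive-weight edges; nodes with no surviving edge are
    kept as isolated nodes. ``meta`` records the construction
    parameters (universe size, number of tested pairs, alpha, weight
    cap, whether the threshold applied to raw or corrected p) so that
    querying can replicate the edge rule exactly.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str, float]] = (),
        meta: dict | None = None,
        node_attrs: dict[str, dict] | None = None,
    ):
        self.nodes: list[str] = list(nodes)
        self._index = {n: i for i, n in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValueError("duplicate node ids")
        self._adj: dict[str, dict[str, float]] = {n: {} for n in self.nodes}
        self.meta: dict = dict(meta or {})
        self.node_attrs: dict[str, dict] = dict(node_attrs or {})
        for a, b, w in edges:
            self.add_edge(a, b, w)

    def add_edge(self, a: str, b: str, w: float) -> None:
        if a == b:
            raise ValueError(f"self-edge on {a!r} not allowed")
        if w < 0:
            raise ValueError("negative edge weight")
        if a not in self._adj or b not in self._adj:
            raise KeyError(f"unknown node in edge ({a!r}, {b!r})")
        if w == 0:
            return
        self._adj[a][b] = w
        self._adj[b][a] = w

    # -- queries ---------------------------------------------------------

    def __contains__(self, node: str) -> bool:
        return node in self._adj

    def __len__(self) -> int:
        return len(self.nodes)

    def weight(self, a: str, b: str) -> float:
        return self._adj[a].get(b, 0.0)

    def neighbors(self, node: str) -> dict[str, float]:
        return self._adj[node]

    def degree(self, node: str) -> float:
        """Weighted degree k_i = sum of incident edge weights."""
        return sum(self._adj[node].values())

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate unordered edges once each, in deterministic node order."""
        for a in self.nodes:
            for b, w in self._adj[a].items():
                if self._index[a] < self._index[b]:
                    yield a, b, w

    @property
    def total_weight(self) -> float:
        """m: sum of edge weights, each unordered pair counted once."""
        return sum(w for _, _, w in self.edges())

    @property
    def n_edges(self) -> int:
        return sum(1 for _ in self.edges())

    # -- export / import -------------------------------------------------

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for k, v in self.meta.items():
            g.graph[k] = v
        for n in self.nodes:
            g.add_node(n, **self.node_attrs.get(n, {}))
        for a, b, w in self.edges():
            g.add_edge(a, b, weight=w)
        return g

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))

    @classmethod
    def from_networkx(cls, g) -> "PathwayGraph":
        meta = dict(g.graph)
        node_attrs = {n: dict(d) for n, d in g.nodes(data=True) if d}
        edges = [(a, b, float(d.get("weight", 1.0))) for a, b, d in g.edges(data=True)]
        return cls(list(g.nodes()), edges, meta=meta, node_attrs=node_attrs)

    @classmethod
    def read_graphml(cls, path: str | Path) -> "PathwayGraph":
        import networkx as nx

        return cls.from_networkx(nx.read_graphml(str(path)))

    def write_edge_tsv(self, path: str | Path) -> None:
        """Three-column edge list; weights formatted with full repr."""
        with Path(path).open("w") as fh:
            fh.write("# pathway_a\tpathway_b\tweight\n")
            for a, b, w in self.edges():
                fh.write(f"{a}\t{b}\t{w!r}\n")

    def write_node_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("# pathway\tsource\tn_genes\n")
            for n in self.nodes:
                attrs = self.node_attrs.get(n, {})
                fh.write(f"{n}\t{attrs.get('source', 'unknown')}\t{attrs.get('n_genes', '')}\n")


def overlap_pvalue(set_a: Iterable[str], set_b: Iterable[str], universe_size: int) -> float:
    """One-sided overlap p-value P(X >= |A∩B|), X ~ Hypergeom(N, |A|, |B|).

    This is Fisher's exact test for enrichment of shared genes between
    two sets drawn from a universe of ``universe_size`` genes.
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("gene sets must be non-empty")
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("gene set larger than the universe")
    k = len(a & b)
    # canonical (K, n) order: the tail is symmetric in the two set sizes,
    # and a fixed order makes overlap_pvalue(A, B) == overlap_pvalue(B, A)
    # bit-exactly
    big, small = max(len(a), len(b)), min(len(a), len(b))
    # sf(k-1) = P(X >= k)
    return float(np.clip(hypergeom.sf(k - 1, universe_size, big, small), 0.0, 1.0))


def _pairwise_overlap_logsf(collection: GeneSetCollection) -> tuple[np.ndarray, np.ndarray]:
    """Log upper-tail p-values for all unordered pathway pairs.

    Returns (pair index array of shape (P, 2), log p array of shape (P,)).
    """
    n = len(collection)
    genes = sorted(collection.universe)
    gidx = {g: j for j, g in enumerate(genes)}
    m = np.zeros((n, len(genes)), dtype=np.int32)
    for i, s in enumerate(collection):
        m[i, [gidx[g] for g in s.genes]] = 1
    k = m @ m.T  # pairwise intersection sizes
    sizes = m.sum(axis=1)
    iu = np.triu_indices(n, k=1)
    big = np.maximum(sizes[iu[0]], sizes[iu[1]])
    small = np.minimum(sizes[iu[0]], sizes[iu[1]])
    logp = hypergeom.logsf(k[iu] - 1, collection.universe_size, big, small)
    return np.column_stack(iu), np.minimum(logp, 0.0)


def build_graph(
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    weight_cap: float = DEFAULT_WEIGHT_CAP,
    threshold_on: str = "corrected",
) -> PathwayGraph:
    """Build the pathway-similarity graph from a gene-set collection.

    Parameters
    ----------
    collection
        Gene sets and the background universe for the hypergeometric null.
    alpha
        Significance threshold; pairs above it get weight 0 (edge omitted).
    weight_cap
        Upper bound on edge weights, guarding against -log10(0).
    threshold_on
        ``"corrected"`` (default) thresholds the Bonferroni-corrected
        p-value; ``"raw"`` thresholds the uncorrected one. Weights are
        always computed from the corrected p-value.
    """
    n = len(collection)
    if n < 2:
        raise ValueError("graph construction needs at least 2 pathways")
    if collection.universe_size == 0:
        raise ValueError("empty gene universe")
    if threshold_on not in ("corrected", "raw"):
        raise ValueError(f"threshold_on must be 'raw' or 'corrected', got {threshold_on!r}")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if weight_cap <= 0:
        raise ValueError("weight_cap must be positive")

    pairs, logp = _pairwise_overlap_logsf(collection)
    n_pairs = n * (n - 1) // 2
    log_t = math.log(n_pairs)
    log_alpha = math.log(alpha)
    logp_corr = np.minimum(0.0, logp + log_t)
    keep = (logp_corr if threshold_on == "corrected" else logp) <= log_alpha
    weights = np.minimum(-logp_corr[keep] / _LN10, weight_cap)

    ids = collection.ids
    node_attrs = {s.id: {"source": s.source, "n_genes": len(s.genes)} for s in collection}
    meta = {
        "universe_size": collection.universe_size,
        "n_pairs_tested": n_pairs,
        "alpha": float(alpha),
        "weight_cap": float(weight_cap),
        "threshold_on": threshold_on,
    }
    graph = PathwayGraph(ids, meta=meta, node_attrs=node_attrs)
    for (i, j), w in zip(pairs[keep], weights):
        if w > 0:
            graph.add_edge(ids[i], ids[j], float(w))
    return graph


def edge_weight_from_logp(
    logp: float,
    n_tests: int,
    alpha: float,
    weight_cap: float,
    threshold_on: str = "corrected",
) -> float:
    """Edge weight for a single test, replicating the :func:`build_graph` rule.

    Used by the query stage so temporary query edges are weighted
    exactly as graph edges, with the correction family of the caller.
    """
    logp = min(logp, 0.0)
    logp_corr = min(0.0, logp + math.log(n_tests))
    tested = logp_corr if threshold_on == "corrected" else logp
    if tested > math.log(alpha):
        return 0.0
    return min(-logp_corr / _LN10, weight_cap)
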