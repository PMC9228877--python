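"""Modularity, Louvain community detection, aggregation, and hubness.

Modularity at resolution gamma:

    Q = sum_c [ Sigma_in(c) / (2m)  -  gamma * (Sigma_tot(c) / (2m))^2 ]

where Sigma_in(c) is the intra-community edge weight counted in both
directions, Sigma_tot(c) the summed weighted degrees of the members,
and m the graph's total edge weight. The resolution gamma scales only
the null-model term: gamma < 1 favours fewer, larger communities.

The Louvain algorithm is implemented natively (two phases: greedy
single-node moves, then graph aggregation with self-loops, repeated to
convergence) so that the query stage can reuse the identical ΔQ
arithmetic. Node visit order is drawn from a seeded generator and
reshuffled each pass; ties keep the current community, and among new
communities with equal gain the lowest community id wins, making the
result fully determined by (graph, gamma, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .overlap_graph import PathwayGraph

#: gains below this are treated as zero when deciding whether to move a node
MOVE_TOLERANCE = 1e-12

DEFAULT_RESOLUTION = 0.4


@dataclass
class Partition:
    """A node -> community assignment.

    Community ids are canonical: 0..C-1 with community 0 the largest
    (ties broken by the lexicographically smallest member id).
    ``resolution`` is the gamma the partition was produced at (``None``
    for externally supplied partitions, e.g. planted truth).
    """

    assignment: dict[str, int]
    resolution: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.assignment = canonical_relabel(self.assignment)

    def __len__(self) -> int:
        return len(self.assignment)

    def __getitem__(self, node: str) -> int:
        return self.assignment[node]

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def members(self, community: int) -> list[str]:
        return [n for n, c in self.assignment.items() if c == community]

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for n, c in self.assignment.items():
            out.setdefault(c, []).append(n)
        return out

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"# resolution={self.resolution}\tseed={self.seed}\n")
            fh.write("# pathway\tcommunity\n")
            for n, c in self.assignment.items():
                fh.write(f"{n}\t{c}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Partition":
        resolution: float | None = None
        seed: int | None = None
        assignment: dict[str, int] = {}
        with Path(path).open() as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if line.startswith("#"):
                    for tok in line.lstrip("# ").split("\t"):
                        if tok.startswith("resolution=") and tok != "resolution=None":
                            resolution = float(tok.split("=", 1)[1])
                        elif tok.startswith("seed=") and tok != "seed=None":
                            seed = int(tok.split("=", 1)[1])
                    continue
                if not line.strip():
                    continue
                n, c = line.split("\t")[:2]
                assignment[n] = int(c)
        return cls(assignment, resolution=resolution, seed=seed)


def canonical_relabel(assignment: Mapping[str, int]) -> dict[str, int]:
    """Relabel communities 0..C-1 by decreasing size, ties by smallest member id."""
    groups: dict[int, list[str]] = {}
    for n, c in assignment.items():
        groups.setdefault(c, []).append(n)
    order = sorted(groups, key=lambda c: (-len(groups[c]), min(groups[c])))
    newid = {c: i for i, c in enumerate(order)}
    return {n: newid[c] for n, c in assignment.items()}


@dataclass
class CommunityGraph:
    """Community-level aggregation of a pathway graph.

    Edge values are *average* pairwise weights between member sets
    (absent pathway edges count as 0), so widths are comparable across
    community sizes. Self values use unordered within-community pairs.
    """

    sizes: dict[int, int]
    values: dict[tuple[int, int], float]
    resolution: float | None = None
    seed: int | None = None

    def value(self, a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        return self.values.get(key, 0.0)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"# resolution={self.resolution}\tseed={self.seed}\n")
            fh.write("# community_a\tcommunity_b\tmean_weight\n")
            for (a, b), v in sorted(self.values.items()):
                fh.write(f"{a}\t{b}\t{v!r}\n")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for c, size in self.sizes.items():
            g.add_node(c, n_members=size)
        for (a, b), v in self.values.items():
            if a != b and v > 0:
                g.add_edge(a, b, weight=v)
            elif a == b:
                g.nodes[a]["self_mean_weight"] = v
        return g

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def modularity(
    graph: PathwayGraph,
    partition: Partition | Mapping[str, int],
    resolution: float | None = None,
) -> float:
    """Modularity Q of a partition at the given resolution.

    ``resolution`` defaults to the partition's own; plain mappings
    default to 1.0.
    """
    assignment = partition.assignment if isinstance(partition, Partition) else dict(partition)
    if resolution is None:
        resolution = (
            partition.resolution if isinstance(partition, Partition) else None
        ) or 1.0
    missing = set(graph.nodes) - set(assignment)
    if missing:
        raise ValueError(f"partition does not cover {len(missing)} node(s)")
    m = graph.total_weight
    if m <= 0:
        raise ValueError("modularity undefined on edgeless graph")
    sigma_in: dict[int, float] = {}
    sigma_tot: dict[int, float] = {}
    for node in graph.nodes:
        c = assignment[node]
        sigma_tot[c] = sigma_tot.get(c, 0.0) + graph.degree(node)
        sigma_in.setdefault(c, 0.0)
    for a, b, w in graph.edges():
        if assignment[a] == assignment[b]:
            sigma_in[assignment[a]] += 2.0 * w
    two_m = 2.0 * m
    return sum(
        sigma_in[c] / two_m - resolution * (sigma_tot[c] / two_m) ** 2
        for c in sigma_tot
    )


def delta_q_join(
    k_to_community: float,
    k_node: float,
    sigma_tot_community: float,
    m: float,
    resolution: float,
) -> float:
    """ΔQ for moving an otherwise-isolated single-node community into another.

    The same closed form serves both the Louvain local phase and the
    query stage: ΔQ = k_in/m - gamma * Sigma_tot * k_i / (2 m^2).
    Self-loop terms cancel because the node brings them along.
    """
    return k_to_community / m - resolution * sigma_tot_community * k_node / (2.0 * m * m)


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------

class _Level:
    """Working graph for one Louvain level (self-loops allowed)."""

    __slots__ = ("adj", "loops", "degree", "m")

    def __init__(self, adj: list[dict[int, float]], loops: list[float]):
        self.adj = adj
        self.loops = loops
        # k_i counts self-loops twice, the convention under which
        # sum(degree) == 2m holds with m including loop weights once
        self.degree = [sum(nb.values()) + 2.0 * lo for nb, lo in zip(adj, loops)]
        self.m = sum(self.degree) / 2.0


def _local_pass(level: _Level, comm: list[int], resolution: float, rng) -> bool:
    """Phase 1: greedy single-node moves until a full pass improves nothing."""
    n = len(comm)
    sigma_tot = [0.0] * (max(comm) + 1)
    for i in range(n):
        sigma_tot[comm[i]] += level.degree[i]
    m = level.m
    improved = False
    while True:
        moved = False
        for i in rng.permutation(n):
            i = int(i)
            ci = comm[i]
            ki = level.degree[i]
            # weight from i to each neighbouring community (excluding self-loop)
            links: dict[int, float] = {}
            for j, w in level.adj[i].items():
                links[comm[j]] = links.get(comm[j], 0.0) + w
            sigma_tot[ci] -= ki
            stay_gain = delta_q_join(links.get(ci, 0.0), ki, sigma_tot[ci], m, resolution)
            best_c, best_gain = ci, stay_gain
            for c in sorted(links):
                if c == ci:
                    continue
                g = delta_q_join(links[c], ki, sigma_tot[c], m, resolution)
                if g > best_gain + MOVE_TOLERANCE:
                    best_c, best_gain = c, g
            sigma_tot[best_c] += ki
            if best_c != ci:
                comm[i] = best_c
                moved = improved = True
        if not moved:
            return improved


def _aggregate(level: _Level, comm: list[int]) -> tuple[_Level, list[int]]:
    """Phase 2: collapse communities into super-nodes with self-loops."""
    labels = sorted(set(comm))
    remap = {c: i for i, c in enumerate(labels)}
    nc = len(labels)
    adj: list[dict[int, float]] = [{} for _ in range(nc)]
    loops = [0.0] * nc
    for i, nb in enumerate(level.adj):
        ci = remap[comm[i]]
        loops[ci] += level.loops[i]
        for j, w in nb.items():
            cj = remap[comm[j]]
            if ci == cj:
                loops[ci] += w / 2.0  # each intra edge seen from both ends
            elif ci < cj:
                adj[ci][cj] = adj[ci].get(cj, 0.0) + w
    for a in range(nc):
        for b, w in list(adj[a].items()):
            adj[b][a] = w
    return _Level(adj, loops), [remap[c] for c in comm]


def _louvain_once(graph: PathwayGraph, resolution: float, seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    index = {n: i for i, n in enumerate(graph.nodes)}
    adj: list[dict[int, float]] = [
        {index[b]: w for b, w in graph.neighbors(a).items()} for a in graph.nodes
    ]
    level = _Level(adj, [0.0] * len(graph.nodes))
    node_comm = list(range(len(graph.nodes)))  # community of each original node
    comm = list(range(len(graph.nodes)))
    while True:
        improved = _local_pass(level, comm, resolution, rng)
        if not improved:
            break
        node_comm = [comm[c] for c in node_comm]
        level, _ = _aggregate(level, comm)
        comm = list(range(len(level.adj)))
        node_comm_labels = sorted(set(node_comm))
        remap = {c: i for i, c in enumerate(node_comm_labels)}
        node_comm = [remap[c] for c in node_comm]
    return {n: node_comm[index[n]] for n in graph.nodes}


def louvain(
    graph: PathwayGraph,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 0,
    restarts: int = 1,
) -> Partition:
    """Detect communities by Louvain modularity optimisation.

    With ``restarts > 1`` the algorithm is run at consecutive seeds
    ``seed .. seed+restarts-1`` and the highest-Q partition returned
    (the earliest seed wins ties), exposing initialisation stability.
    Isolated nodes end up in singleton communities.
    """
    if graph.total_weight <= 0:
        raise ValueError("community detection undefined on edgeless graph")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best: tuple[float, int, dict[str, int]] | None = None
    for s in range(seed, seed + restarts):
        assignment = _louvain_once(graph, resolution, s)
        q = modularity(graph, assignment, resolution)
        if best is None or q > best[0] + MOVE_TOLERANCE:
            best = (q, s, assignment)
    assert best is not None
    return Partition(best[2], resolution=resolution, seed=best[1])


# ---------------------------------------------------------------------------
# aggregation & hubness
# ---------------------------------------------------------------------------

def aggregate_communities(graph: PathwayGraph, partition: Partition) -> CommunityGraph:
    """Average pairwise weight between (and within) community member sets."""
    assignment = partition.assignment
    missing = set(graph.nodes) - set(assignment)
    if missing:
        raise ValueError(f"partition does not cover {len(missing)} node(s)")
    sizes: dict[int, int] = {}
    for n in graph.nodes:
        sizes[assignment[n]] = sizes.get(assignment[n], 0) + 1
    totals: dict[tuple[int, int], float] = {}
    for a, b, w in graph.edges():
        key = tuple(sorted((assignment[a], assignment[b])))
        totals[key] = totals.get(key, 0.0) + w
    values: dict[tuple[int, int], float] = {}
    comms = sorted(sizes)
    for i, ca in enumerate(comms):
        for cb in comms[i:]:
            if ca == cb:
                pairs = sizes[ca] * (sizes[ca] - 1) / 2
            else:
                pairs = sizes[ca] * sizes[cb]
            total = totals.get((ca, cb), 0.0)
            values[(ca, cb)] = total / pairs if pairs > 0 else 0.0
    return CommunityGraph(sizes, values, resolution=partition.resolution, seed=partition.seed)


def hubness(graph: PathwayGraph, partition: Partition, node: str) -> float:
    """Weighted degree of ``node`` within its own community's induced subgraph."""
    if node not in graph:
        raise KeyError(f"unknown node {node!r}")
    c = partition[node]
    return sum(
        w for nb, w in graph.neighbors(node).items() if partition[nb] == c
    )


def hubness_all(graph: PathwayGraph, partition: Partition) -> dict[str, float]:
    """Hubness for every node (one pass over the edges)."""
    scores = {n: 0.0 for n in graph.nodes}
    for a, b, w in graph.edges():
        if partition[a] == partition[b]:
            scores[a] += w
            scores[b] += w
    return scores
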