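"""Querying a novel gene set against a learned community network.

The query replicates the graph-construction arithmetic: a one-sided
hypergeometric enrichment p-value is computed between the query set and
every pathway (Bonferroni-corrected over the number of pathways — the
family a user running a plain enrichment analysis would correct over),
and the query is temporarily added as a new node whose edges follow the
graph's own weighting rule. Holding the learned partition fixed and
starting the query as a singleton community, the modularity change ΔQ
of moving it into each existing community ranks the communities; the
modularity is that of the augmented graph (m includes the temporary
node's edges). The stored graph and partition are never modified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from scipy.stats import hypergeom

from .community import Partition, delta_q_join
from .geneset_io import GeneSetCollection
from .overlap_graph import PathwayGraph, edge_weight_from_logp

logger = logging.getLogger(__name__)


@dataclass
class QueryResult:
    """Enrichment and community ranking for one query gene set.

    ``pathway_enrichment`` is sorted by corrected p ascending;
    ``community_ranking`` by ΔQ descending. ``recommended_community``
    is the top community if joining it increases modularity, else
    ``None`` (the query is best left on its own).
    """

    pathway_enrichment: list[tuple[str, float, float]]
    community_ranking: list[tuple[int, float]]
    genes_used: int
    genes_dropped: int

    @property
    def recommended_community(self) -> int | None:
        if self.community_ranking and self.community_ranking[0][1] > 0:
            return self.community_ranking[0][0]
        return None

    def write_enrichment_tsv(self, path: str | Path, top_k: int | None = None) -> None:
        rows = self.pathway_enrichment if top_k is None else self.pathway_enrichment[:top_k]
        with Path(path).open("w") as fh:
            fh.write("# pathway\traw_p\tcorrected_p\n")
            for pid, p, pc in rows:
                fh.write(f"{pid}\t{p!r}\t{pc!r}\n")

    def to_report(self, top_k: int = 20) -> dict:
        return {
            "genes_used": self.genes_used,
            "genes_dropped": self.genes_dropped,
            "recommended_community": self.recommended_community,
            "top_pathways": [
                {"pathway": pid, "raw_p": p, "corrected_p": pc}
                for pid, p, pc in self.pathway_enrichment[:top_k]
            ],
            "community_ranking": [
                {"community": c, "delta_q": dq} for c, dq in self.community_ranking
            ],
        }


def query_gene_set(
    genes: Iterable[str],
    graph: PathwayGraph,
    collection: GeneSetCollection,
    partition: Partition,
) -> QueryResult:
    """Score a novel gene set against every pathway and every community.

    Query genes absent from the collection's universe are dropped (with
    a logged count) rather than widening the universe, which would
    silently change the null of every stored edge.
    """
    if not partition.assignment:
        raise ValueError("empty partition")
    query = {g.upper() for g in genes}
    used = query & collection.universe
    dropped = len(query) - len(used)
    if dropped:
        logger.info("query: %d gene(s) not in the universe were dropped", dropped)
    if not used:
        raise ValueError("no query gene is present in the graph's universe")

    n_pathways = len(graph.nodes)
    universe_n = int(graph.meta.get("universe_size", collection.universe_size))
    alpha = float(graph.meta.get("alpha", 0.01))
    weight_cap = float(graph.meta.get("weight_cap", 300.0))
    threshold_on = str(graph.meta.get("threshold_on", "corrected"))

    # per-pathway enrichment + temporary edges, one pass
    enrichment: list[tuple[str, float, float]] = []
    query_edges: dict[str, float] = {}
    for pid in graph.nodes:
        pset = collection[pid].genes
        k = len(used & pset)
        big, small = max(len(pset), len(used)), min(len(pset), len(used))
        logp = min(float(hypergeom.logsf(k - 1, universe_n, big, small)), 0.0)
        p_raw = min(1.0, float(hypergeom.sf(k - 1, universe_n, big, small)))
        p_corr = min(1.0, p_raw * n_pathways)
        enrichment.append((pid, p_raw, p_corr))
        w = edge_weight_from_logp(logp, n_pathways, alpha, weight_cap, threshold_on)
        if w > 0:
            query_edges[pid] = w
    enrichment.sort(key=lambda row: (row[2], row[1], row[0]))

    k_q = sum(query_edges.values())
    m_aug = graph.total_weight + k_q
    if m_aug <= 0:
        raise ValueError("modularity undefined: graph has no edge weight")
    gamma = partition.resolution if partition.resolution is not None else 1.0

    # Sigma_tot per existing community (query is its own singleton, so
    # existing degrees are unchanged) and query weight into each community
    sigma_tot: dict[int, float] = {c: 0.0 for c in set(partition.assignment.values())}
    for node in graph.nodes:
        sigma_tot[partition[node]] += graph.degree(node)
    k_to: dict[int, float] = {c: 0.0 for c in sigma_tot}
    for pid, w in query_edges.items():
        k_to[partition[pid]] += w

    # in the augmented graph the query's edges also raise the degrees of
    # their existing endpoints, so each community's Sigma_tot grows by the
    # query weight it receives
    ranking = [
        (c, delta_q_join(k_to[c], k_q, sigma_tot[c] + k_to[c], m_aug, gamma))
        for c in sorted(sigma_tot)
    ]
    ranking.sort(key=lambda cd: (-cd[1], cd[0]))
    return QueryResult(
        pathway_enrichment=enrichment,
        community_ranking=ranking,
        genes_used=len(used),
        genes_dropped=dropped,
    )
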