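"""Evaluation utilities: NMI against reference labels, pathway redundancy
profiles, per-community gene over-representation, and founder-agreement
statistics.

NMI here is mutual information normalized by the arithmetic mean of the
two labelling entropies (natural logs), the common default; 1 means the
groupings are identical up to label permutation, 0 that they are
independent. Degenerate conventions: two single-cluster labellings are
identical (1.0); if exactly one labelling has zero entropy there is
nothing to predict and NMI is 0.0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .community import Partition
from .geneset_io import CategoryMap, GeneSetCollection

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalized mutual information
# ---------------------------------------------------------------------------

def nmi(
    labelling_a: Mapping[Hashable, Hashable],
    labelling_b: Mapping[Hashable, Hashable],
) -> float:
    """NMI between two labellings of the same item set, in [0, 1]."""
    if set(labelling_a) != set(labelling_b):
        raise ValueError("labellings cover different item sets")
    items = list(labelling_a)
    n = len(items)
    if n == 0:
        raise ValueError("empty labellings")
    joint: dict[tuple[Hashable, Hashable], int] = {}
    ca: dict[Hashable, int] = {}
    cb: dict[Hashable, int] = {}
    for it in items:
        a, b = labelling_a[it], labelling_b[it]
        joint[(a, b)] = joint.get((a, b), 0) + 1
        ca[a] = ca.get(a, 0) + 1
        cb[b] = cb.get(b, 0) + 1
    h_a = -sum(c / n * math.log(c / n) for c in ca.values())
    h_b = -sum(c / n * math.log(c / n) for c in cb.values())
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * math.log(p_ab / (ca[a] / n * cb[b] / n))
    mi = max(mi, 0.0)
    return min(1.0, mi / ((h_a + h_b) / 2.0))


def evaluate_against_categories(
    partition: Partition | Mapping[str, int],
    categories: CategoryMap,
) -> float:
    """NMI of a partition against curated category labels.

    Restricted to pathways present in both; the number of unlabelled
    (excluded) pathways is logged.
    """
    assignment = partition.assignment if isinstance(partition, Partition) else dict(partition)
    common = set(assignment) & set(categories.assignments)
    if not common:
        raise ValueError("no pathway is present in both the partition and the category map")
    excluded = len(assignment) - len(common)
    if excluded:
        logger.info("evaluation: %d pathway(s) without a category were excluded", excluded)
    return nmi(
        {p: assignment[p] for p in common},
        {p: categories.assignments[p] for p in common},
    )


# ---------------------------------------------------------------------------
# pathway redundancy profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapProfile:
    """Max overlap of one pathway with any eligible partner."""

    pathway: str
    fraction: float
    best_partner: str | None
    has_partner: bool


def max_overlap_fraction(
    collection: GeneSetCollection,
    scope: str = "within-source",
) -> dict[str, OverlapProfile]:
    """Per-pathway maximum overlap fraction |A∩B| / |A| over partners B.

    ``scope`` selects eligible partners: ``"within-source"`` restricts
    to pathways with the same source tag, ``"cross-source"`` to those
    with a different one. The denominator is the focal pathway's own
    size, so a pathway fully contained in a partner scores 1.0.
    Pathways with no eligible partner report 0.0, flagged.
    """
    if scope not in ("within-source", "cross-source"):
        raise ValueError(f"scope must be 'within-source' or 'cross-source', got {scope!r}")
    if len(collection) < 2:
        raise ValueError("redundancy profile needs at least 2 pathways")
    out: dict[str, OverlapProfile] = {}
    for a in collection:
        best, partner = 0.0, None
        for b in collection:
            if b.id == a.id:
                continue
            same = a.source == b.source
            if (scope == "within-source") != same:
                continue
            frac = len(a.genes & b.genes) / len(a.genes)
            if partner is None or frac > best:
                best, partner = frac, b.id
        found = partner is not None
        out[a.id] = OverlapProfile(a.id, best, partner, found)
    return out


def write_redundancy_tsv(
    profiles: Mapping[str, OverlapProfile], scope: str, path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("# pathway\tscope\tbest_partner\tfraction\n")
        for pid, prof in profiles.items():
            fh.write(f"{pid}\t{scope}\t{prof.best_partner or ''}\t{prof.fraction!r}\n")


# ---------------------------------------------------------------------------
# gene over-representation within communities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneCommunityEnrichment:
    """Hypergeometric over-representation of a gene within one community.

    ``x`` of the community's ``n`` pathways contain the gene, out of
    ``big_k`` pathways containing it anywhere among ``big_n`` total.
    """

    gene: str
    community: int
    x: int
    big_k: int
    n: int
    big_n: int
    p: float
    p_adj: float

    @property
    def significant(self) -> bool:
        return bool(self.p_adj <= self._alpha)

    _alpha: float = 0.05


def gene_overrepresentation(
    collection: GeneSetCollection,
    partition: Partition,
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> list[GeneCommunityEnrichment]:
    """Test every (gene, community) pair for over-representation.

    For gene g and community C the p-value is the upper hypergeometric
    tail of drawing x = #{pathways of C containing g} from N total
    pathways of which K contain g, in n = |C| draws. Adjustment across
    all tests is Benjamini-Hochberg by default (``method`` accepts any
    statsmodels ``multipletests`` method, e.g. ``"bonferroni"``).
    """
    assignment = partition.assignment
    missing = [s.id for s in collection if s.id not in assignment]
    if missing:
        raise ValueError(f"partition does not cover {len(missing)} pathway(s)")
    big_n = len(collection)
    comm_sizes: dict[int, int] = {}
    for s in collection:
        c = assignment[s.id]
        comm_sizes[c] = comm_sizes.get(c, 0) + 1
    per_gene_total: dict[str, int] = {}
    per_gene_comm: dict[str, dict[int, int]] = {}
    for s in collection:
        c = assignment[s.id]
        for g in s.genes:
            per_gene_total[g] = per_gene_total.get(g, 0) + 1
            by_comm = per_gene_comm.setdefault(g, {})
            by_comm[c] = by_comm.get(c, 0) + 1

    records: list[tuple[str, int, int, int, int, float]] = []
    for g in sorted(per_gene_total):
        big_k = per_gene_total[g]
        for c in sorted(comm_sizes):
            x = per_gene_comm.get(g, {}).get(c, 0)
            n = comm_sizes[c]
            p = min(1.0, float(hypergeom.sf(x - 1, big_n, big_k, n)))
            records.append((g, c, x, big_k, n, p))
    pvals = [r[5] for r in records]
    _, p_adj, _, _ = multipletests(pvals, method=method)
    out = [
        GeneCommunityEnrichment(
            gene=g, community=c, x=x, big_k=big_k, n=n, big_n=big_n,
            p=p, p_adj=float(pa), _alpha=alpha,
        )
        for (g, c, x, big_k, n, p), pa in zip(records, p_adj)
    ]
    return out


def write_overrepresentation_tsv(
    results: list[GeneCommunityEnrichment], path: str | Path, significant_only: bool = True
) -> None:
    with Path(path).open("w") as fh:
        fh.write("# gene\tcommunity\tx\tK\tn\tN\traw_p\tadjusted_p\n")
        for r in results:
            if significant_only and not r.significant:
                continue
            fh.write(
                f"{r.gene}\t{r.community}\t{r.x}\t{r.big_k}\t{r.n}\t{r.big_n}"
                f"\t{r.p!r}\t{r.p_adj!r}\n"
            )


# ---------------------------------------------------------------------------
# founder / assignment agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupAgreement:
    group: str
    assigned: int
    top_community: int
    founder_counts: dict[int, int]
    rank: int
    agrees: bool


@dataclass
class AgreementReport:
    """Agreement between query-based assignments and founder majorities.

    For each reference group (e.g. a Hallmark pathway) compare the
    community assigned by querying with the community holding the most
    of the group's founder pathways. ``summary`` is the fraction of
    groups where the two coincide (ties count as agreement when the
    assigned community is among the tied maxima).
    """

    per_group: dict[str, GroupAgreement]
    summary: float


def assignment_agreement(
    query_assignments: Mapping[str, int],
    founder_membership: Mapping[str, Mapping[int, int]],
) -> AgreementReport:
    per_group: dict[str, GroupAgreement] = {}
    agree = 0
    for group, assigned in query_assignments.items():
        counts = dict(founder_membership.get(group, {}))
        if not counts:
            logger.warning("group %r has a query assignment but no founders; excluded", group)
            continue
        top_count = max(counts.values())
        argmax = sorted(c for c, k in counts.items() if k == top_count)
        rank = 1 + sum(1 for k in counts.values() if k > counts.get(assigned, 0))
        agrees = assigned in argmax
        agree += agrees
        per_group[group] = GroupAgreement(
            group=group, assigned=assigned, top_community=argmax[0],
            founder_counts=counts, rank=rank, agrees=agrees,
        )
    if not per_group:
        raise ValueError("no group has both a query assignment and founder counts")
    return AgreementReport(per_group=per_group, summary=agree / len(per_group))
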