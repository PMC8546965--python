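"""Pairwise BGC similarity and gene-cluster-family (GCF) assignment.

Two regions are compared through three domain-based components, following
the BiG-SCAPE family of indices:

* **Jaccard** — overlap of the sets of domain *types*;
* **adjacency** — Jaccard over the sets of unordered adjacent domain-type
  pairs along each region's domain order;
* **DSS** (domain sequence similarity) — average protein identity of
  same-type domain copies under greedy best-identity matching, penalized
  by unmatched copies.

``distance = 1 − (w_J·jaccard + w_DSS·dss + w_AI·adjacency)`` with default
weights (0.2, 0.7, 0.1).  Families are the connected components of the
graph with edges at ``distance ≤ cutoff`` (default 0.30): thresholding
alone tends to split families along species lines, and the transitive
closure re-joins them.  Exact duplicate regions are collapsed before
networking and re-expanded into the final member lists.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx

from ._align import fast_identity
from .genome_model import BGCRegion

DEFAULT_WEIGHTS = (0.2, 0.7, 0.1)  # (w_J, w_DSS, w_AI)
DEFAULT_CUTOFF = 0.30


class UndefinedSimilarityError(ValueError):
    """A region without any domain annotation has no defined similarity."""


@dataclass(frozen=True)
class SimilarityEdge:
    region_a: str
    region_b: str
    jaccard: float
    adjacency: float
    dss: float
    distance: float


@dataclass
class GCF:
    """A gene cluster family: one connected component of the network."""

    gcf_id: str
    members: frozenset[str]
    product_class: str
    is_singleton: bool


def _domain_seq(gene, dom) -> str:
    return gene.translation[dom.aa_start : dom.aa_end]


def _region_profile(region: BGCRegion):
    doms = region.all_domains()
    if not doms:
        raise UndefinedSimilarityError(f"region {region.region_id} has no domains")
    types = [d.domain_type for _g, d in doms]
    seqs_by_type: dict[str, list[str]] = {}
    for g, d in doms:
        seqs_by_type.setdefault(d.domain_type, []).append(_domain_seq(g, d))
    adjacent = {frozenset((types[i], types[i + 1])) for i in range(len(types) - 1)
                if types[i] != types[i + 1]}
    return set(types), adjacent, seqs_by_type


def _dss(seqs_a: dict[str, list[str]], seqs_b: dict[str, list[str]]) -> float:
    """Greedy best-identity matching of same-type domain copies."""
    total = 0.0
    n_pairs = 0
    n_unmatched = 0
    for dtype in sorted(set(seqs_a) | set(seqs_b)):
        a = seqs_a.get(dtype, [])
        b = seqs_b.get(dtype, [])
        pairs = sorted(
            ((fast_identity(sa, sb), i, j)
             for i, sa in enumerate(a) for j, sb in enumerate(b)),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        for ident, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            total += ident
            n_pairs += 1
        n_unmatched += (len(a) - len(used_a)) + (len(b) - len(used_b))
    denom = n_pairs + n_unmatched
    return total / denom if denom else 0.0


def _edge_from_profiles(id_a: str, profile_a, id_b: str, profile_b, weights) -> SimilarityEdge:
    types_a, adj_a, seqs_a = profile_a
    types_b, adj_b, seqs_b = profile_b
    jaccard = len(types_a & types_b) / len(types_a | types_b)
    union_adj = adj_a | adj_b
    adjacency = len(adj_a & adj_b) / len(union_adj) if union_adj else 1.0
    dss = _dss(seqs_a, seqs_b)
    w_j, w_dss, w_ai = weights
    distance = 1.0 - (w_j * jaccard + w_dss * dss + w_ai * adjacency)
    return SimilarityEdge(id_a, id_b, jaccard, adjacency, dss, distance)


def bgc_similarity(
    a: BGCRegion, b: BGCRegion, weights: tuple[float, float, float] = DEFAULT_WEIGHTS
) -> SimilarityEdge:
    """Symmetric similarity edge between two regions (see module docstring)."""
    return _edge_from_profiles(
        a.region_id, _region_profile(a), b.region_id, _region_profile(b), weights
    )


def connected_components_from_edges(nodes, edges) -> list[list]:
    """Connected components (sorted members, as lists) of an undirected graph."""
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from(edges)
    return [sorted(c) for c in nx.connected_components(graph)]


def _duplicate_key(region: BGCRegion) -> tuple:
    return (tuple(g.name for g in region.genes), tuple(g.sequence for g in region.genes))


def gcf_families(
    regions: list[BGCRegion],
    cutoff: float = DEFAULT_CUTOFF,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    return_edges: bool = False,
):
    """Assign regions to GCFs via connected components of the thresholded
    similarity network.

    Exact duplicates (identical gene-name arrays and identical sequences)
    are collapsed to one node before the all-pairs comparison and merged
    back afterwards.  Families are ordered by size (descending) then by
    smallest member id; ``gcf_id`` is ``"<rank>_<majority product class>"``.
    """
    if not regions:
        return ([], []) if return_edges else []
    by_id = {r.region_id: r for r in regions}
    if len(by_id) != len(regions):
        raise ValueError("region_ids must be unique")

    # collapse exact duplicates
    rep_of: dict[str, str] = {}
    reps: dict[tuple, str] = {}
    for rid in sorted(by_id):
        key = _duplicate_key(by_id[rid])
        reps.setdefault(key, rid)
        rep_of[rid] = reps[key]
    rep_ids = sorted(set(rep_of.values()))

    profiles = {rid: _region_profile(by_id[rid]) for rid in rep_ids}
    edges: list[SimilarityEdge] = []
    graph_edges = []
    for i, ra in enumerate(rep_ids):
        for rb in rep_ids[i + 1 :]:
            edge = _edge_from_profiles(ra, profiles[ra], rb, profiles[rb], weights)
            edges.append(edge)
            if edge.distance <= cutoff:
                graph_edges.append((ra, rb))

    components = connected_components_from_edges(rep_ids, graph_edges)
    # re-expand duplicates
    expanded = []
    for comp in components:
        members = sorted(rid for rid in by_id if rep_of[rid] in comp)
        expanded.append(members)
    expanded.sort(key=lambda m: (-len(m), m[0]))

    gcfs = []
    for rank, members in enumerate(expanded, start=1):
        # majority class; ties broken alphabetically
        classes = Counter(by_id[m].product_class for m in members)
        best = sorted(classes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        gcfs.append(GCF(
            gcf_id=f"{rank}_{best}",
            members=frozenset(members),
            product_class=best,
            is_singleton=len(members) == 1,
        ))
    if return_edges:
        return gcfs, edges
    return gcfs


def write_edge_table(edges: list[SimilarityEdge], path) -> None:
    with open(path, "w") as fh:
        fh.write("region_a\tregion_b\tjaccard\tadjacency\tdss\tdistance\n")
        for e in sorted(edges, key=lambda e: (e.region_a, e.region_b)):
            fh.write(f"{e.region_a}\t{e.region_b}\t{e.jaccard:.6f}\t"
                     f"{e.adjacency:.6f}\t{e.dss:.6f}\t{e.distance:.6f}\n")


def write_family_table(gcfs: list[GCF], path) -> None:
    with open(path, "w") as fh:
        fh.write("gcf_id\tproduct_class\tn_members\tmembers\n")
        for g in gcfs:
            fh.write(f"{g.gcf_id}\t{g.product_class}\t{len(g.members)}\t"
                     f"{','.join(sorted(g.members))}\n")
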