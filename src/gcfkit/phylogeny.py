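"""Strain phylogeny from conserved single-copy genes (MLSA).

The stages mirror the classical multilocus workflow: group orthologs across
genomes, keep the 30 most conserved universal single-copy families, align
each family (center-star) and trim gappy columns, concatenate, compute
Jukes-Cantor distances, build a neighbor-joining tree, attach bootstrap
supports from column resampling, and reroot on an outgroup.

Neighbor joining is implemented here (Saitou-Nei Q-criterion, deterministic
smallest-index tie-breaks, negative branch lengths clamped to zero with the
deficit moved to the sister branch): on additive distance matrices it
recovers the generating topology exactly, which makes the stage directly
testable.  Rerooting and tree comparison go through dendropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from ._align import center_star, fast_identity
from ._tree import Node, splits
from .genome_model import Gene, GenomeRecord

logger = logging.getLogger(__name__)

JC_SATURATION_P = 0.7499
JC_MAX_DISTANCE = 5.0


@dataclass
class OrthologFamily:
    family_id: str
    members: dict[str, Gene]  # genome accession -> gene
    single_copy: bool
    universal: bool = False
    _extra_copies: dict[str, int] = field(default_factory=dict, repr=False)


@dataclass
class MultipleAlignment:
    sequences: dict[str, str]  # genome accession -> aligned row

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned rows must all have equal length")


@dataclass
class PhyloTree:
    newick: str
    leaves: list[str]
    rooted: bool = False

    def as_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick, schema="newick", taxon_namespace=taxon_namespace,
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )


# ---------------------------------------------------------------------------
# ortholog grouping and family selection


def ortholog_families(
    genomes: list[GenomeRecord], min_identity: float = 0.80
) -> list[OrthologFamily]:
    """Group genes into ortholog families across genomes.

    Named genes group by exact gene-name match.  Unnamed genes join the
    first existing family whose seed member they match at >= ``min_identity``
    nucleotide identity (greedy, input order).  Families present in every
    genome with exactly one copy everywhere are marked universal single-copy.
    """
    accessions = [g.accession for g in genomes]
    fams: dict[str, dict[str, list[Gene]]] = {}
    seeds: dict[str, Gene] = {}
    order: list[str] = []

    def _add(fid: str, acc: str, gene: Gene) -> None:
        fam = fams.setdefault(fid, {})
        fam.setdefault(acc, []).append(gene)
        if fid not in seeds:
            seeds[fid] = gene
            order.append(fid)

    for genome in genomes:
        for gene in genome.genes:
            if gene.name:
                _add(gene.name, genome.accession, gene)
    for genome in genomes:
        for gene in genome.genes:
            if gene.name:
                continue
            placed = False
            for fid in order:
                if fast_identity(gene.sequence, seeds[fid].sequence) >= min_identity:
                    _add(fid, genome.accession, gene)
                    placed = True
                    break
            if not placed:
                _add(f"unnamed_{gene.locus_tag}", genome.accession, gene)

    out = []
    for fid in order:
        fam = fams[fid]
        single = all(len(v) == 1 for v in fam.values())
        universal = single and set(fam) == set(accessions)
        out.append(OrthologFamily(
            family_id=fid,
            members={acc: genes[0] for acc, genes in fam.items()},
            single_copy=single,
            universal=universal,
            _extra_copies={acc: len(v) for acc, v in fam.items() if len(v) > 1},
        ))
    return out


def mean_pairwise_p_distance(family: OrthologFamily) -> float:
    accs = sorted(family.members)
    if len(accs) < 2:
        return 0.0
    total = n = 0
    for i, a in enumerate(accs):
        for b in accs[i + 1 :]:
            total += 1.0 - fast_identity(family.members[a].sequence, family.members[b].sequence)
            n += 1
    return total / n


def select_mlsa_families(families: list[OrthologFamily], k: int = 30) -> list[OrthologFamily]:
    """Pick the ``k`` most conserved universal single-copy families
    (lowest mean pairwise p-distance; ties broken by family id)."""
    if k == 0:
        return []
    candidates = [f for f in families if f.universal]
    if len(candidates) < k:
        raise ValueError(
            f"only {len(candidates)} universal single-copy families available, need {k}")
    scored = sorted(candidates, key=lambda f: (mean_pairwise_p_distance(f), f.family_id))
    return scored[:k]


# ---------------------------------------------------------------------------
# alignment, trimming, distances


def align_and_trim(family: OrthologFamily, gap_fraction_max: float = 0.5) -> MultipleAlignment:
    """Center-star alignment of a family, then removal of columns whose gap
    fraction exceeds ``gap_fraction_max``."""
    if len(family.members) < 2:
        raise ValueError(f"family {family.family_id} has fewer than 2 members")
    seqs = {acc: g.sequence for acc, g in family.members.items()}
    aligned = center_star(seqs)
    rows = sorted(aligned)
    ncol = len(aligned[rows[0]])
    n = len(rows)
    keep = [
        j for j in range(ncol)
        if sum(aligned[r][j] == "-" for r in rows) / n <= gap_fraction_max
    ]
    trimmed = {r: "".join(aligned[r][j] for j in keep) for r in rows}
    return MultipleAlignment(trimmed)


def concatenate(alignments: list[MultipleAlignment]) -> MultipleAlignment:
    if not alignments:
        raise ValueError("no alignments to concatenate")
    accs = set(alignments[0].sequences)
    for a in alignments[1:]:
        if set(a.sequences) != accs:
            raise ValueError("alignments do not share the same genome set")
    return MultipleAlignment(
        {acc: "".join(a.sequences[acc] for a in alignments) for acc in sorted(accs)}
    )


def _encode(alignment: MultipleAlignment) -> tuple[list[str], np.ndarray]:
    accs = sorted(alignment.sequences)
    mat = np.frombuffer(
        "".join(alignment.sequences[a] for a in accs).encode(), dtype=np.uint8
    ).reshape(len(accs), alignment.length)
    return accs, mat


def _jc_from_columns(mat: np.ndarray, accs: list[str]) -> np.ndarray:
    gap = ord("-")
    n = len(accs)
    dist = np.zeros((n, n))
    valid = mat != gap
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {accs[i]} and {accs[j]}")
            p = float((mat[i, both] != mat[j, both]).sum()) / m
            if p >= JC_SATURATION_P:
                d = JC_MAX_DISTANCE
            else:
                d = jukes_cantor_distance(p)
            dist[i, j] = dist[j, i] = d
    return dist


def jukes_cantor_distance(p: float) -> float:
    """d = −(3/4)·ln(1 − (4/3)p); saturates at ``JC_MAX_DISTANCE``."""
    if p >= JC_SATURATION_P:
        return JC_MAX_DISTANCE
    return float(-0.75 * np.log(1.0 - 4.0 * p / 3.0))


def concatenated_distances(alignments: list[MultipleAlignment]) -> tuple[list[str], np.ndarray]:
    """Concatenate alignments and return (accessions, JC distance matrix).

    p-distances use pairwise deletion: only columns where both rows are
    ungapped are compared.
    """
    cat = concatenate(alignments)
    accs, mat = _encode(cat)
    return accs, _jc_from_columns(mat, accs)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(distances: np.ndarray, labels: list[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the smallest index pair; negative
    branch lengths are clamped to zero with the deficit transferred to the
    sister branch.  Returns an unrooted tree (trifurcating root) in newick.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if len(labels) != n:
        raise ValueError("labels must match matrix size")

    nodes: list[Node] = [Node(lbl) for lbl in labels]
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j) index pair
        best = (np.inf, m, m)
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] < best[0] - 1e-12:
                    best = (q[i, j], i, j)
        _, i, j = best
        gi, gj = active[i], active[j]
        d_ij = sub[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2 * (m - 2))
        lj = d_ij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[gi].length = li
        nodes[gj].length = lj
        parent = Node(children=[nodes[gi], nodes[gj]])
        new_row = 0.5 * (D[gi, :] + D[gj, :] - d_ij)
        D = np.vstack([D, new_row])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        g_new = D.shape[0] - 1
        active = [g for g in active if g not in (gi, gj)] + [g_new]

    # final three nodes joined at an unrooted (trifurcating) root
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(length, 0.0)
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(newick=root.to_newick(), leaves=sorted(labels), rooted=False)


# ---------------------------------------------------------------------------
# bootstrap + rerooting


def _parse_to_node(newick: str) -> Node:
    """Parse newick produced by this module back into a Node tree."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True, preserve_underscores=True)

    def _convert(dnode) -> Node:
        node = Node(
            name=(dnode.taxon.label if dnode.taxon else (dnode.label or "")),
            length=dnode.edge.length or 0.0,
        )
        node.children = [_convert(c) for c in dnode.child_nodes()]
        return node

    return _convert(tree.seed_node)


def bootstrap_and_reroot(
    alignments: list[MultipleAlignment],
    n_replicates: int = 1000,
    outgroup: list[str] | None = None,
    seed: int = 42,
) -> PhyloTree:
    """Point-estimate NJ tree with bootstrap supports, rerooted on the
    outgroup's most recent common ancestor edge.

    Supports are the fraction of ``n_replicates`` column-resampled replicate
    trees containing each internal bipartition of the point tree.
    """
    cat = concatenate(alignments)
    accs, mat = _encode(cat)
    if outgroup:
        missing = set(outgroup) - set(accs)
        if missing:
            raise ValueError(f"unknown outgroup accessions: {sorted(missing)}")

    point = nj_tree(_jc_from_columns(mat, accs), accs)
    tree = PhyloTree(newick=point.newick, leaves=sorted(accs), rooted=False)
    if outgroup:
        tree = reroot_on_outgroup(tree, outgroup)
    root = _parse_to_node(tree.newick)

    if n_replicates > 0:
        rng = np.random.default_rng(seed)
        counts: dict[frozenset[str], int] = {}
        ncol = mat.shape[1]
        for _ in range(n_replicates):
            cols = rng.integers(0, ncol, ncol)
            rep_mat = mat[:, cols]
            rep = nj_tree(_jc_from_columns(rep_mat, accs), accs)
            for split in splits(_parse_to_node(rep.newick)):
                counts[split] = counts.get(split, 0) + 1
        # supports are split properties: annotate the (rerooted) point tree
        all_leaves = frozenset(accs)
        anchor = min(all_leaves)
        for node in root.walk():
            if node is root or node.is_leaf:
                continue
            side = frozenset(node.leaves())
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                node.support = counts.get(side, 0) / n_replicates
        tree = PhyloTree(newick=root.to_newick(supports=True),
                         leaves=sorted(accs), rooted=tree.rooted)
    return tree


def reroot_on_outgroup(tree: PhyloTree, outgroup: list[str]) -> PhyloTree:
    """Reroot on the edge above the outgroup's MRCA (idempotent)."""
    dtree = tree.as_dendropy()
    missing = set(outgroup) - {t.label for t in dtree.taxon_namespace}
    if missing:
        raise ValueError(f"unknown outgroup accessions: {sorted(missing)}")
    # already rooted on the outgroup: a root child spans exactly the outgroup
    for child in dtree.seed_node.child_nodes():
        leafset = {l.taxon.label for l in child.leaf_iter()}
        if leafset == set(outgroup):
            return PhyloTree(newick=tree.newick, leaves=tree.leaves, rooted=True)
    if len(outgroup) == 1:
        node = dtree.find_node_with_taxon_label(outgroup[0])
    else:
        node = dtree.mrca(taxon_labels=outgroup)
        if node is dtree.seed_node:
            # tree currently rooted inside the outgroup's span; use the
            # complement clade instead
            others = [t.label for t in dtree.taxon_namespace if t.label not in outgroup]
            node = dtree.mrca(taxon_labels=others)
    length = node.edge.length or 0.0
    dtree.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2,
                         update_bipartitions=False)
    newick = dtree.as_string(schema="newick", suppress_rooting=True,
                             unquoted_underscores=True).strip()
    return PhyloTree(newick=newick, leaves=tree.leaves, rooted=True)


def robinson_foulds(newick_a: str, newick_b: str) -> int:
    """Unrooted RF distance between two newick trees on the same leaf set."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns,
                           suppress_internal_node_taxa=True, preserve_underscores=True)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns,
                           suppress_internal_node_taxa=True, preserve_underscores=True)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(treecompare.symmetric_difference(ta, tb))
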