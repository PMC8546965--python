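"""GCF occurrence matrix over strains, with clustering-based column order.

``presence_absence_matrix`` counts member regions of each family per
genome; ``cluster_and_order`` arranges columns by average-linkage
hierarchical clustering on the Jaccard distance between binarized presence
vectors (dendrogram leaf order) and, when a strain tree is supplied, rows
by the tree's leaf order — the layout used to read clade-specific family
gains and losses off the phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .genome_model import BGCRegion, GenomeRecord
from .phylogeny import PhyloTree
from .similarity_gcf import GCF


@dataclass
class OccurrenceMatrix:
    rows: list[str]  # genome accessions
    columns: list[str]  # gcf ids
    counts: np.ndarray  # shape (len(rows), len(columns)), non-negative ints

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.rows, columns=self.columns)

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "genome"
        df.to_csv(path, sep="\t")

    def to_long_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("genome\tgcf\tcount\n")
            for i, acc in enumerate(self.rows):
                for j, gcf in enumerate(self.columns):
                    fh.write(f"{acc}\t{gcf}\t{int(self.counts[i, j])}\n")


def presence_absence_matrix(
    gcfs: list[GCF],
    genomes: list[GenomeRecord],
    regions: dict[str, BGCRegion],
) -> OccurrenceMatrix:
    """Count occurrences of each family in each genome.

    ``regions`` maps region ids (the families' members) back to region
    objects, which carry the genome attribution.  Genomes without any
    region appear as all-zero rows.
    """
    rows = [g.accession for g in genomes]
    row_index = {acc: i for i, acc in enumerate(rows)}
    columns = [g.gcf_id for g in gcfs]
    counts = np.zeros((len(rows), len(columns)), dtype=int)
    for j, gcf in enumerate(gcfs):
        for rid in sorted(gcf.members):
            if rid not in regions:
                raise ValueError(f"family {gcf.gcf_id} member {rid} has no region object")
            acc = regions[rid].genome_accession
            if acc not in row_index:
                raise ValueError(f"region {rid} references unknown genome {acc}")
            counts[row_index[acc], j] += 1
    return OccurrenceMatrix(rows, columns, counts)


def cluster_and_order(
    matrix: OccurrenceMatrix, tree: PhyloTree | None = None
) -> OccurrenceMatrix:
    """Reorder columns by hierarchical clustering, rows by the strain tree.

    Columns: average-linkage clustering on Jaccard distance between
    binarized presence vectors; output order is the dendrogram leaf order
    (columns pre-sorted by gcf_id so ties resolve deterministically).
    Rows: the tree's newick leaf order when a tree is given.
    """
    col_order = sorted(range(len(matrix.columns)), key=lambda j: matrix.columns[j])
    counts = matrix.counts[:, col_order]
    columns = [matrix.columns[j] for j in col_order]

    if len(columns) > 2:
        presence = (counts > 0).astype(bool).T  # families x genomes
        dists = pdist(presence, metric="jaccard")
        dists = np.nan_to_num(dists, nan=0.0)  # all-zero columns: define d=0
        linkage = hierarchy.linkage(dists, method="average")
        leaf_order = list(hierarchy.leaves_list(linkage))
        counts = counts[:, leaf_order]
        columns = [columns[j] for j in leaf_order]

    rows = list(matrix.rows)
    if tree is not None:
        tree_order = _newick_leaf_order(tree)
        known = [acc for acc in tree_order if acc in rows]
        rest = [acc for acc in rows if acc not in known]
        new_rows = known + rest
        row_idx = [rows.index(acc) for acc in new_rows]
        counts = counts[row_idx, :]
        rows = new_rows
    return OccurrenceMatrix(rows, columns, counts)


def _newick_leaf_order(tree: PhyloTree) -> list[str]:
    dtree = tree.as_dendropy()
    return [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
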