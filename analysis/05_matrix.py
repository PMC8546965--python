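#!/usr/bin/env python
"""Build the GCF presence/absence matrix aligned with the strain tree.

Counts each family's occurrences per strain, clusters columns by Jaccard
distance between presence patterns (average linkage), and orders rows by
the tree's leaf order, so clade-restricted families (and the single
horizontal-transfer gain) read directly off the matrix.
"""

import json
from pathlib import Path

from gcfkit.genome_model import read_genbank
from gcfkit.matrix import cluster_and_order, presence_absence_matrix
from gcfkit.phylogeny import PhyloTree
from gcfkit.similarity_gcf import gcf_families

DATASET = Path("scratch/dataset")
RESULTS = Path("results")


def main() -> None:
    if not DATASET.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    tree_path = RESULTS / "04_tree.nwk"
    if not tree_path.exists():
        raise SystemExit("run analysis/04_mlsa_tree.py first")
    genomes = [read_genbank(p) for p in sorted(DATASET.glob("*.gbk"))]
    regions = {r.region_id: r for g in genomes for r in g.regions}
    gcfs = gcf_families(list(regions.values()))
    tree = PhyloTree(newick=tree_path.read_text().strip(),
                     leaves=sorted(g.accession for g in genomes), rooted=True)

    occ = cluster_and_order(
        presence_absence_matrix(gcfs, genomes, regions), tree)
    occ.to_tsv(RESULTS / "05_matrix.tsv")

    truth = json.loads((DATASET / "truth.json").read_text())
    hgt_leaves = [leaf for leaf, evs in truth["event_realizations"].items()
                  if any(e["kind"] == "hgt_gain" for e in evs)]
    print(f"matrix: {len(occ.rows)} strains x {len(occ.columns)} families, "
          f"{int(occ.counts.sum())} total region occurrences")
    print(f"horizontal-transfer recipients visible as out-of-clade presences: "
          f"{hgt_leaves}")
    print(f"matrix -> {RESULTS / '05_matrix.tsv'}")


if __name__ == "__main__":
    main()
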