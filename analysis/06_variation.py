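#!/usr/bin/env python
"""Within-family variation: completeness groups, iturinic classification,
conserved frameshifts, and the sfp screen.

For the two lipopeptide families with planted events this recovers: the
clade-conserved ppsD / fenE gene deletions as "missing:<gene>" groups, the
single-base ppsE frameshift at position 232 and the 2-base fenD frameshift
at positions 3126-3127 (with their lost domains), the mycosubtilin-type
A-domain signature of the iturinic family, and an all-intact sfp screen.
"""

import json
from pathlib import Path

from gcfkit.genome_model import read_genbank
from gcfkit.pipeline import _match_family_gcf, load_family_reference
from gcfkit.similarity_gcf import gcf_families
from gcfkit.variation import (
    FrameshiftCall,
    classify_iturinic_bgc,
    completeness_groups,
    detect_frameshifts,
    load_signatures,
    sfp_screen,
    write_calls_tsv,
    write_group_tsv,
    write_sfp_tsv,
)

DATASET = Path("scratch/dataset")
RESULTS = Path("results")


def main() -> None:
    if not DATASET.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    genomes = [read_genbank(p) for p in sorted(DATASET.glob("*.gbk"))]
    regions = {r.region_id: r for g in genomes for r in g.regions}
    gcfs = gcf_families(list(regions.values()))
    truth = json.loads((DATASET / "truth.json").read_text())
    RESULTS.mkdir(exist_ok=True)

    groups_all, calls_all = [], []
    for bundle in sorted((DATASET / "refs").glob("*.json")):
        reference = load_family_reference(bundle)
        gcf = _match_family_gcf(reference, gcfs, regions)
        groups = completeness_groups(gcf, reference, regions)
        groups_all.extend(groups)
        print(f"{reference.family_name}: "
              + ", ".join(f"{g.group_label} (n={len(g.members)})" for g in groups))
        for rid in sorted(gcf.members):
            for gene in regions[rid].genes:
                if gene.name in reference.reference_sequences:
                    calls_all.extend(detect_frameshifts(
                        gene, reference.reference_sequences[gene.name],
                        reference.reference_domains.get(gene.name, []),
                        region_id=rid))
    for call in calls_all[:2]:
        print(f"frameshift: {call.gene} {call.kind} at position "
              f"{call.ref_position} (length {call.length}), lost domains: "
              f"{','.join(call.lost_domains)}")
    print(f"{len(calls_all)} frameshift calls in total")

    signatures = load_signatures()
    labels = {}
    for rid, fam in truth["family_membership"].items():
        if fam == "iturin":
            labels[rid] = classify_iturinic_bgc(regions[rid], signatures)
    print(f"iturinic regions classify as: {sorted(set(labels.values()))}")

    sfp_ref = (DATASET / "refs" / "sfp.fasta").read_text().splitlines()[1]
    status = sfp_screen(genomes, sfp_ref)
    n_fs = sum(isinstance(s, FrameshiftCall) for s in status.values())
    print(f"sfp screen: {n_fs} frameshifted of {len(status)} genomes")

    write_group_tsv(groups_all, RESULTS / "06_groups.tsv")
    write_calls_tsv(calls_all, RESULTS / "06_calls.tsv")
    write_sfp_tsv(status, RESULTS / "06_sfp.tsv")
    with open(RESULTS / "06_iturin_classification.tsv", "w") as fh:
        fh.write("region_id\tproduct\n")
        for rid in sorted(labels):
            fh.write(f"{rid}\t{labels[rid]}\n")
    print(f"tables -> {RESULTS}/06_*.tsv")


if __name__ == "__main__":
    main()
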