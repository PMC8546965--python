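"""Within-family variation analyses.

Four screens over the members of a gene cluster family:

* **completeness grouping** — which core biosynthetic genes each member
  region retains (by >=90% identity / >=90% coverage homology to family
  reference sequences), grouping members by their missing-gene profile;
* **iturinic product classification** — the ordered adenylation-domain
  substrate predictions of a region matched against seven-residue product
  signatures (iturin A, bacillomycins, mycosubtilin);
* **frameshift detection** — frame-disrupting indels located on a
  reference gene by global alignment, with the alternative translation and
  the functional domains lost downstream of the shift;
* **sfp screen** — frameshift status of the 4'-phosphopantetheinyl
  transferase gene (whose inactivation abolishes lipopeptide production)
  across all genomes.

Reported frameshift positions are 1-based on the reference gene with
leftmost gap placement.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio.Seq import Seq

from ._align import align_indels, identity_coverage_fast, indel_free_identity
from .genome_model import BGCRegion, DomainAnnotation, Gene, GenomeRecord
from .similarity_gcf import GCF

logger = logging.getLogger(__name__)

HOMOLOGY_MIN_IDENTITY = 0.90
HOMOLOGY_MIN_COVERAGE = 0.90
FRAMESHIFT_ALIGNMENT_IDENTITY_FLOOR = 0.70

#: distinct marker for genomes without any sfp homolog (vs. None == intact)
NO_HOMOLOG = "no_homolog"


class NotHomologousError(ValueError):
    """Gene/reference alignment identity below the homology floor."""


@dataclass
class FamilyReference:
    """Reference gene set for one family (e.g. plipastatin, ppsA..ppsE)."""

    family_name: str
    core_genes: list[str]
    reference_sequences: dict[str, str]
    reference_domains: dict[str, list[DomainAnnotation]]

    def __post_init__(self) -> None:
        missing = [g for g in self.core_genes if g not in self.reference_sequences]
        if missing:
            raise ValueError(f"core genes without reference sequence: {missing}")


@dataclass
class CompletenessGroup:
    group_label: str  # "complete" | "missing:<genes>" | "others"
    family_name: str
    members: list[str]
    missing_genes: frozenset[str]


@dataclass(frozen=True)
class SpecificitySignature:
    product_name: str
    residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.residues) != 7:
            raise ValueError(f"{self.product_name}: signature must have 7 residues")


@dataclass
class FrameshiftCall:
    region_id: str
    gene: str
    kind: str  # "deletion" | "insertion"
    ref_position: int  # 1-based, first affected base, leftmost placement
    length: int
    alt_translation: str
    lost_domains: list[str]


def load_signatures(path: str | Path | None = None) -> list[SpecificitySignature]:
    """Load product signatures from TSV (default: the bundled table)."""
    if path is None:
        source = resources.files("gcfkit.data").joinpath("iturin_signatures.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    sigs = []
    for row in csv.reader(
        (l for l in text.splitlines() if l.strip() and not l.startswith("#")),
        delimiter="\t",
    ):
        sigs.append(SpecificitySignature(row[0], tuple(r.strip() for r in row[1].split(","))))
    names = [s.product_name for s in sigs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate product names in signature table")
    return sigs


# ---------------------------------------------------------------------------
# completeness


def _present_core_genes(
    region: BGCRegion,
    reference: FamilyReference,
    min_identity: float = HOMOLOGY_MIN_IDENTITY,
    min_coverage: float = HOMOLOGY_MIN_COVERAGE,
) -> set[str]:
    present = set()
    for core in reference.core_genes:
        ref = reference.reference_sequences[core]
        for gene in region.genes:
            if abs(len(gene.sequence) - len(ref)) > (1 - min_coverage + 0.1) * len(ref):
                continue
            ident, cov = identity_coverage_fast(gene.sequence, ref)
            if ident >= min_identity and cov >= min_coverage:
                present.add(core)
                break
    return present


def completeness_groups(
    family: GCF,
    reference: FamilyReference,
    regions: dict[str, BGCRegion],
    min_identity: float = HOMOLOGY_MIN_IDENTITY,
    min_coverage: float = HOMOLOGY_MIN_COVERAGE,
) -> list[CompletenessGroup]:
    """Group family members by their missing-core-gene profile.

    No missing genes -> "complete"; 1-3 missing -> "missing:<sorted names>";
    more than 3 missing -> "others".  Groups are ordered by size descending
    (ties by label).
    """
    profiles: dict[frozenset[str], list[str]] = {}
    for rid in sorted(family.members):
        if rid not in regions:
            raise ValueError(f"unknown region id {rid}")
        present = _present_core_genes(regions[rid], reference, min_identity, min_coverage)
        missing = frozenset(reference.core_genes) - present
        profiles.setdefault(missing, []).append(rid)

    groups = []
    others: list[str] = []
    for missing, members in profiles.items():
        if len(missing) > 3:
            others.extend(members)
            continue
        label = "complete" if not missing else "missing:" + ",".join(sorted(missing))
        groups.append(CompletenessGroup(label, reference.family_name, sorted(members), missing))
    if others:
        groups.append(CompletenessGroup(
            "others", reference.family_name, sorted(others), frozenset()))
    groups.sort(key=lambda g: (-len(g.members), g.group_label))
    return groups


# ---------------------------------------------------------------------------
# iturinic classification


def classify_iturinic_bgc(
    region: BGCRegion, signatures: list[SpecificitySignature]
) -> str:
    """Classify an iturinic region by its ordered A-domain substrates.

    Fewer than 7 predictions -> "others" (partial cluster); an exact match
    of all 7 against a signature -> that product; 7 predictions with no
    match -> "unclassified".
    """
    a_domains = [d for _g, d in region.all_domains() if d.domain_type == "AMP-binding"]
    if not a_domains:
        raise ValueError(f"region {region.region_id} is not an NRPS region (no A domains)")
    residues = tuple(d.specificity.strip().lower() for d in a_domains if d.specificity)
    if len(residues) < 7:
        return "others"
    for sig in signatures:
        if residues == tuple(r.lower() for r in sig.residues):
            return sig.product_name
    return "unclassified"


# ---------------------------------------------------------------------------
# frameshift detection


def detect_frameshifts(
    gene: Gene,
    reference: str,
    reference_domains: list[DomainAnnotation] | None = None,
    region_id: str = "",
) -> list[FrameshiftCall]:
    """Find frame-disrupting indels in ``gene`` relative to ``reference``.

    The sequences are aligned globally (affine gaps); each contiguous indel
    run whose length is not a multiple of 3 becomes a call at the 1-based
    reference position of its first gap column (leftmost placement).
    In-frame indels are logged but never reported.  ``alt_translation`` is
    the query's frame-0 translation up to the first stop; ``lost_domains``
    are reference domains not fully contained in the in-frame prefix
    preceding the call.
    """
    reference_domains = reference_domains or []
    # fast path: equal-length, gap-free alignments carry no indels at all
    identity = indel_free_identity(gene.sequence, reference)
    if identity is not None:
        runs = []
    else:
        identity, runs = align_indels(gene.sequence, reference)
    if identity < FRAMESHIFT_ALIGNMENT_IDENTITY_FLOOR:
        raise NotHomologousError(
            f"{gene.name or gene.locus_tag}: alignment identity {identity:.2f} "
            f"below floor {FRAMESHIFT_ALIGNMENT_IDENTITY_FLOOR}")

    alt = str(Seq(gene.sequence[: len(gene.sequence) - len(gene.sequence) % 3]).translate(table=11))
    alt_translation = alt.split("*")[0]

    calls = []
    for run in runs:
        if run.length % 3 == 0:
            logger.info("%s: in-frame %s of %d nt at %d (not a frameshift)",
                        gene.name or gene.locus_tag, run.kind, run.length, run.ref_pos + 1)
            continue
        prefix_aa = run.ref_pos // 3  # complete reference codons before the shift
        lost = [d.domain_type for d in reference_domains if d.aa_end > prefix_aa]
        calls.append(FrameshiftCall(
            region_id=region_id,
            gene=gene.name or gene.locus_tag,
            kind=run.kind,
            ref_position=run.ref_pos + 1,
            length=run.length,
            alt_translation=alt_translation,
            lost_domains=lost,
        ))
    return calls


# ---------------------------------------------------------------------------
# sfp screen


def sfp_screen(
    genomes: list[GenomeRecord],
    sfp_reference: str,
    sfp_domains: list[DomainAnnotation] | None = None,
) -> dict[str, FrameshiftCall | None | str]:
    """Frameshift status of the sfp gene per genome.

    Returns, per accession: a :class:`FrameshiftCall` (first frame-
    disrupting indel), ``None`` for an intact homolog, or :data:`NO_HOMOLOG`
    when the genome carries no gene named sfp and no sequence homolog at
    the >=90%/>=90% rule.
    """
    out: dict[str, FrameshiftCall | None | str] = {}
    for genome in genomes:
        gene = genome.gene_by_name("sfp")
        if gene is None:
            best: tuple[float, Gene | None] = (0.0, None)
            for cand in genome.genes:
                # cheap length prefilter before aligning
                if abs(len(cand.sequence) - len(sfp_reference)) > 0.5 * len(sfp_reference):
                    continue
                ident, cov = identity_coverage_fast(cand.sequence, sfp_reference)
                if ident >= HOMOLOGY_MIN_IDENTITY and cov >= HOMOLOGY_MIN_COVERAGE \
                        and ident > best[0]:
                    best = (ident, cand)
            gene = best[1]
        if gene is None:
            logger.warning("%s: no sfp homolog", genome.accession)
            out[genome.accession] = NO_HOMOLOG
            continue
        calls = detect_frameshifts(gene, sfp_reference, sfp_domains)
        out[genome.accession] = calls[0] if calls else None
    return out


def write_calls_tsv(calls: list[FrameshiftCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tgene\tkind\tref_position\tlength\tlost_domains\n")
        for c in calls:
            fh.write(f"{c.region_id}\t{c.gene}\t{c.kind}\t{c.ref_position}\t"
                     f"{c.length}\t{','.join(c.lost_domains)}\n")


def write_group_tsv(groups: list[CompletenessGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tgroup\tn_members\tmissing_genes\tmembers\n")
        for g in groups:
            fh.write(f"{g.family_name}\t{g.group_label}\t{len(g.members)}\t"
                     f"{','.join(sorted(g.missing_genes))}\t{','.join(g.members)}\n")


def write_sfp_tsv(status: dict[str, FrameshiftCall | None | str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\tstatus\tposition\tlength\n")
        for acc in sorted(status):
            s = status[acc]
            if s is None:
                fh.write(f"{acc}\tintact\t\t\n")
            elif s == NO_HOMOLOG:
                fh.write(f"{acc}\tno_homolog\t\t\n")
            else:
                fh.write(f"{acc}\tframeshift\t{s.ref_position}\t{s.length}\n")
    logger.info("sfp screen written to %s", path)
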