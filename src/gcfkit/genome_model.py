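"""Domain types for annotated genomes and BGC regions, plus GenBank I/O.

The in-memory model mirrors what an antiSMASH-style miner emits: a genome is
a set of contigs carrying CDS features (genes), and optionally pre-delimited
biosynthetic "region" features.  Internally every interval is 0-based
half-open on the contig forward strand; gene sequences are stored on the
coding strand.  GenBank files use the standard 1-based inclusive convention;
:func:`read_genbank` / :func:`write_genbank` convert exactly.

Domain annotations (NRPS/PKS domains with optional adenylation-domain
substrate predictions) ride in a custom ``/domain_annotation`` qualifier of
the form ``type|aa_start|aa_end|specificity`` (amino-acid coordinates,
0-based half-open on the gene's translation).  antiSMASH-style ``aSDomain``
features are also accepted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")

PRODUCT_CLASSES = ("NRPS", "PKS", "NRPS/PKS hybrid", "RiPP", "terpene", "other")


class GenBankParseError(ValueError):
    """Raised when a GenBank record cannot be interpreted; names the feature."""


@dataclass(frozen=True)
class DomainAnnotation:
    """A protein domain on a gene's translation (aa coordinates, half-open)."""

    domain_type: str
    aa_start: int
    aa_end: int
    specificity: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.aa_start < self.aa_end):
            raise ValueError(
                f"invalid domain interval [{self.aa_start},{self.aa_end}) "
                f"for {self.domain_type}"
            )


@dataclass
class Gene:
    """A protein-coding gene; ``sequence`` is the coding strand."""

    locus_tag: str
    name: str
    start: int
    end: int
    strand: int
    sequence: str
    product: str = ""
    domains: list[DomainAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise ValueError(f"{self.locus_tag}: strand must be +1 or -1")
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.locus_tag}: bad interval [{self.start},{self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.locus_tag}: sequence length {len(self.sequence)} != "
                f"span {self.end - self.start}"
            )
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"{self.locus_tag}: invalid bases {sorted(bad)}")
        aa_len = len(self.sequence) // 3
        for d in self.domains:
            if d.aa_end > aa_len:
                raise ValueError(
                    f"{self.locus_tag}: domain {d.domain_type} ends at aa "
                    f"{d.aa_end} beyond translation length {aa_len}"
                )

    @property
    def translation(self) -> str:
        """Full-length translation (table 11), internal stops kept as '*'."""
        n = len(self.sequence) - len(self.sequence) % 3
        return str(Seq(self.sequence[:n]).translate(table=11))


@dataclass
class Contig:
    id: str
    length: int
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.end))
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(
                    f"gene {g.locus_tag} [{g.start},{g.end}) exceeds contig "
                    f"{self.id} length {self.length}"
                )


@dataclass
class BGCRegion:
    """A pre-delimited biosynthetic region: an ordered slice of genes."""

    region_id: str
    genome_accession: str
    contig_id: str
    start: int
    end: int
    product_class: str = "other"
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.product_class not in PRODUCT_CLASSES:
            raise ValueError(f"unknown product class {self.product_class!r}")

    def all_domains(self) -> list[tuple[Gene, DomainAnnotation]]:
        """Domains in genomic order: genes in region order, domains in aa order."""
        out = []
        for g in self.genes:
            for d in sorted(g.domains, key=lambda d: d.aa_start):
                out.append((g, d))
        return out


@dataclass
class GenomeRecord:
    accession: str
    organism: str
    strain: str
    contigs: list[Contig] = field(default_factory=list)
    source_path: str = ""
    regions: list[BGCRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")

    @property
    def genes(self) -> list[Gene]:
        return [g for c in self.contigs for g in c.genes]

    def gene_by_name(self, name: str) -> Gene | None:
        for g in self.genes:
            if g.name == name:
                return g
        return None


# ---------------------------------------------------------------------------
# GenBank I/O


def _clean_sequence(raw: str, context: str) -> str:
    """Uppercase; map IUPAC ambiguity codes other than N to N (logged)."""
    seq = raw.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        n_amb = sum(seq.count(b) for b in bad)
        logger.warning("%s: mapped %d ambiguous bases %s to N", context, n_amb, sorted(bad))
        seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
    return seq


def _parse_domain_qualifiers(quals: dict) -> list[DomainAnnotation]:
    domains = []
    for entry in quals.get("domain_annotation", []):
        parts = entry.split("|")
        if len(parts) not in (3, 4):
            raise GenBankParseError(f"malformed domain_annotation qualifier: {entry!r}")
        dtype, a, b = parts[0], int(parts[1]), int(parts[2])
        spec = parts[3] if len(parts) == 4 else ""
        domains.append(DomainAnnotation(dtype, a, b, spec))
    return domains


def read_genbank(path: str | Path) -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    CDS features become genes (strand-aware coding-strand sequence, 0-based
    half-open coordinates); ``region`` features become :class:`BGCRegion`
    objects containing every CDS whose interval intersects the region span.
    A record with zero CDS features is accepted with a logged warning.
    """
    path = Path(path)
    contigs: list[Contig] = []
    regions: list[BGCRegion] = []
    accession = organism = strain = ""
    n_cds = 0

    for rec in SeqIO.parse(str(path), "genbank"):
        if not accession:
            accession = rec.id or rec.name
            organism = rec.annotations.get("organism", "")
        contig_seq = _clean_sequence(str(rec.seq), rec.id)
        genes: list[Gene] = []
        region_feats = []
        for feat in rec.features:
            if feat.type == "source":
                strain = strain or feat.qualifiers.get("strain", [""])[0]
                organism = feat.qualifiers.get("organism", [organism])[0]
                continue
            if feat.type == "region":
                region_feats.append(feat)
                continue
            if feat.type == "aSDomain":
                continue  # attached to genes in a second pass below
            if feat.type != "CDS":
                continue
            n_cds += 1
            locus = feat.qualifiers.get("locus_tag", [""])[0]
            try:
                start = int(feat.location.start)
                end = int(feat.location.end)
                strand_ = feat.location.strand or 1
                if len(feat.location.parts) > 1:
                    raise GenBankParseError(
                        f"CDS {locus or feat.location}: compound/origin-spanning "
                        "locations are not supported (genomes are handled linearized)"
                    )
                seq = contig_seq[start:end]
                if strand_ == -1:
                    seq = str(Seq(seq).reverse_complement())
                genes.append(
                    Gene(
                        locus_tag=locus,
                        name=feat.qualifiers.get("gene", [""])[0],
                        start=start,
                        end=end,
                        strand=int(strand_),
                        sequence=seq,
                        product=feat.qualifiers.get("product", [""])[0],
                        domains=_parse_domain_qualifiers(feat.qualifiers),
                    )
                )
            except GenBankParseError:
                raise
            except (ValueError, TypeError) as exc:
                raise GenBankParseError(
                    f"malformed CDS feature {locus or feat.location} in {rec.id}: {exc}"
                ) from exc

        # antiSMASH-style aSDomain features -> attach to genes by locus_tag
        by_locus = {g.locus_tag: g for g in genes if g.locus_tag}
        for feat in rec.features:
            if feat.type != "aSDomain":
                continue
            locus = feat.qualifiers.get("locus_tag", [""])[0]
            gene = by_locus.get(locus)
            if gene is None:
                logger.warning("aSDomain without matching CDS locus_tag %r", locus)
                continue
            dtype = feat.qualifiers.get("aSDomain", feat.qualifiers.get("domain", ["?"]))[0]
            a = int(feat.qualifiers.get("protein_start", ["0"])[0])
            b = int(feat.qualifiers.get("protein_end", ["0"])[0])
            spec = feat.qualifiers.get("specificity", [""])[0]
            gene.domains.append(DomainAnnotation(dtype, a, b, spec))

        contig = Contig(id=rec.id or rec.name, length=len(contig_seq), genes=genes)
        contigs.append(contig)

        for i, feat in enumerate(region_feats):
            rstart, rend = int(feat.location.start), int(feat.location.end)
            rid = feat.qualifiers.get("region_id", [f"{accession}_r{len(regions) + 1}"])[0]
            pclass = feat.qualifiers.get("product_class", ["other"])[0]
            member_genes = [g for g in genes if g.start < rend and g.end > rstart]
            regions.append(
                BGCRegion(
                    region_id=rid,
                    genome_accession=accession,
                    contig_id=contig.id,
                    start=rstart,
                    end=rend,
                    product_class=pclass,
                    genes=member_genes,
                )
            )

    if n_cds == 0:
        logger.warning("%s: no CDS features found", path)
    return GenomeRecord(
        accession=accession,
        organism=organism,
        strain=strain,
        contigs=contigs,
        source_path=str(path),
        regions=regions,
    )


def write_genbank(record: GenomeRecord, path: str | Path) -> None:
    """Serialize a :class:`GenomeRecord` as a GenBank flat file.

    Inverse of :func:`read_genbank` on records that satisfy the type
    invariants: ``read_genbank(write_genbank(r)) == r`` field by field.
    """
    seq_records = []
    regions_by_contig: dict[str, list[BGCRegion]] = {}
    for reg in record.regions:
        regions_by_contig.setdefault(reg.contig_id, []).append(reg)

    for contig in record.contigs:
        # rebuild the forward-strand contig sequence from gene slices
        buf = ["N"] * contig.length
        for g in contig.genes:
            fwd = g.sequence if g.strand == 1 else str(Seq(g.sequence).reverse_complement())
            buf[g.start : g.end] = fwd
        rec = SeqRecord(
            Seq("".join(buf)),
            id=contig.id,
            name=contig.id.split(".")[0][:16],
            description=f"{record.organism}".strip(),
        )
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["organism"] = record.organism
        rec.annotations["date"] = "01-JAN-2000"  # fixed: outputs must be byte-reproducible
        src = SeqFeature(FeatureLocation(0, contig.length), type="source")
        src.qualifiers["organism"] = [record.organism]
        if record.strain:
            src.qualifiers["strain"] = [record.strain]
        rec.features.append(src)
        for reg in regions_by_contig.get(contig.id, []):
            rf = SeqFeature(FeatureLocation(reg.start, reg.end), type="region")
            rf.qualifiers["region_id"] = [reg.region_id]
            rf.qualifiers["product_class"] = [reg.product_class]
            rec.features.append(rf)
        for g in contig.genes:
            feat = SeqFeature(FeatureLocation(g.start, g.end, strand=g.strand), type="CDS")
            if g.locus_tag:
                feat.qualifiers["locus_tag"] = [g.locus_tag]
            if g.name:
                feat.qualifiers["gene"] = [g.name]
            if g.product:
                feat.qualifiers["product"] = [g.product]
            feat.qualifiers["codon_start"] = ["1"]
            feat.qualifiers["transl_table"] = ["11"]
            feat.qualifiers["translation"] = [g.translation.rstrip("*")]
            if g.domains:
                feat.qualifiers["domain_annotation"] = [
                    "|".join(
                        [d.domain_type, str(d.aa_start), str(d.aa_end)]
                        + ([d.specificity] if d.specificity else [])
                    )
                    for d in g.domains
                ]
            rec.features.append(feat)
        rec.features.sort(key=lambda f: (int(f.location.start), f.type != "source"))
        seq_records.append(rec)

    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "genbank")


def normalize_strain_fields(record: GenomeRecord) -> GenomeRecord:
    """Append the strain to the organism name when it is missing.

    Many public records omit the strain from the organism field, which
    downstream MLSA/network tools need to tell isolates apart.  Idempotent:
    if the organism already ends with the strain, nothing changes.
    """
    if not record.strain:
        logger.warning("%s: no strain field to transfer", record.accession)
        return record
    if record.organism.endswith(record.strain):
        return record
    return replace(record, organism=f"{record.organism} {record.strain}".strip())


def export_gene_fastas(
    record: GenomeRecord, nt_path: str | Path | None = None, aa_path: str | Path | None = None
) -> None:
    """Write all gene nucleotide and/or protein sequences as FASTA."""

    def _entries(translate: bool) -> Iterable[str]:
        for g in record.genes:
            seq = g.translation.rstrip("*") if translate else g.sequence
            header = f">{record.accession}|{g.locus_tag}|{g.name}"
            yield f"{header}\n{seq}\n"

    if nt_path is not None:
        Path(nt_path).write_text("".join(_entries(False)))
    if aa_path is not None:
        Path(aa_path).write_text("".join(_entries(True)))
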