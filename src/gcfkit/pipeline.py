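"""End-to-end pipeline: normalize -> split -> GCF -> tree -> matrix -> variation.

The pipeline is a thin, deterministic orchestration of the library stages.
Every run writes its artifacts plus a ``manifest.json`` recording SHA-256
hashes of all inputs and outputs; a rerun on identical inputs and config is
byte-identical.  Any stage failure aborts with the stage named, leaving a
``<stage>.partial`` marker next to whatever was already written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .genome_model import BGCRegion, DomainAnnotation, GenomeRecord, normalize_strain_fields, read_genbank
from .matrix import cluster_and_order, presence_absence_matrix
from .phylogeny import align_and_trim, bootstrap_and_reroot, ortholog_families, select_mlsa_families
from .region_tools import SplitRule, split_region
from .similarity_gcf import DEFAULT_CUTOFF, DEFAULT_WEIGHTS, gcf_families, write_edge_table, write_family_table
from .variation import (
    FamilyReference,
    FrameshiftCall,
    completeness_groups,
    detect_frameshifts,
    sfp_screen,
    write_calls_tsv,
    write_group_tsv,
    write_sfp_tsv,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    split_rule_files: list[str] = field(default_factory=list)
    family_reference_files: list[str] = field(default_factory=list)
    sfp_reference_fasta: str | None = None
    gcf_cutoff: float = DEFAULT_CUTOFF
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    mlsa_k: int = 30
    bootstrap_replicates: int = 100
    outgroup: list[str] = field(default_factory=list)
    seed: int = 42

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "weights" in raw:
            raw["weights"] = tuple(raw["weights"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_split_rule(path: str | Path) -> SplitRule:
    """Rule file: JSON with left_fasta/right_fasta (+ optional thresholds)."""
    raw = json.loads(Path(path).read_text())
    base = Path(path).parent

    def _panel(key: str) -> list[str]:
        fasta = base / raw[key]
        return [str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")]

    return SplitRule(
        left_gene_refs=_panel("left_fasta"),
        right_gene_refs=_panel("right_fasta"),
        min_identity=raw.get("min_identity", 0.90),
        min_coverage=raw.get("min_coverage", 0.90),
    )


def load_family_reference(path: str | Path) -> FamilyReference:
    """Bundle file: JSON with family_name, core_genes, fasta, domains_tsv."""
    raw = json.loads(Path(path).read_text())
    base = Path(path).parent
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(base / raw["fasta"]), "fasta")}
    domains: dict[str, list[DomainAnnotation]] = {}
    if raw.get("domains_tsv"):
        for line in (base / raw["domains_tsv"]).read_text().splitlines():
            if not line.strip() or line.startswith("#") or line.startswith("gene\t"):
                continue
            parts = line.split("\t")
            gene, dtype, a, b = parts[0], parts[1], int(parts[2]), int(parts[3])
            spec = parts[4] if len(parts) > 4 else ""
            domains.setdefault(gene, []).append(DomainAnnotation(dtype, a, b, spec))
    return FamilyReference(
        family_name=raw["family_name"],
        core_genes=list(raw["core_genes"]),
        reference_sequences=seqs,
        reference_domains=domains,
    )


def _match_family_gcf(reference: FamilyReference, gcfs, regions):
    """The GCF whose members carry the most core-gene names of a reference."""
    best, best_score = None, -1
    for g in gcfs:
        score = sum(
            1
            for rid in g.members
            for gene in regions[rid].genes
            if gene.name in reference.core_genes
        )
        if score > best_score:
            best, best_score = g, score
    return best if best_score > 0 else None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; return the manifest (also written as manifest.json)."""
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    stage = "configure"
    manifest: dict = {"stages": {}, "inputs": {}, "config": dataclasses.asdict(config)}

    # all referenced files must exist before stage 1 runs
    referenced = [Path(p) for p in config.split_rule_files + config.family_reference_files]
    if config.sfp_reference_fasta:
        referenced.append(Path(config.sfp_reference_fasta))
    missing = [str(p) for p in referenced if not p.exists()]
    if not in_dir.is_dir():
        missing.append(str(in_dir))
    if missing:
        raise PipelineError(stage, f"missing inputs: {missing}")
    out_dir.mkdir(parents=True, exist_ok=True)

    gbk_files = sorted(in_dir.glob("*.gbk")) + sorted(in_dir.glob("*.gb")) + sorted(
        in_dir.glob("*.gbff"))
    if not gbk_files:
        raise PipelineError(stage, f"no GenBank files in {in_dir}")
    for p in gbk_files + referenced:
        manifest["inputs"][p.name] = _sha256(p)

    def _finish_stage(name: str, artifacts: list[Path], t0: float) -> None:
        manifest["stages"][name] = {
            "seconds": round(time.time() - t0, 3),
            "artifacts": {p.name: _sha256(p) for p in artifacts},
        }
        logger.info("stage %s done in %.1fs", name, time.time() - t0)

    def _run(name: str, fn):
        nonlocal stage
        stage = name
        t0 = time.time()
        try:
            artifacts = fn()
        except PipelineError:
            raise
        except Exception as exc:
            (out_dir / f"{name}.partial").write_text(str(exc) + "\n")
            raise PipelineError(name, str(exc)) from exc
        _finish_stage(name, artifacts, t0)

    state: dict = {}

    def stage_read() -> list[Path]:
        genomes = [normalize_strain_fields(read_genbank(p)) for p in gbk_files]
        accs = [g.accession for g in genomes]
        if len(accs) != len(set(accs)):
            raise ValueError("duplicate genome accessions")
        state["genomes"] = genomes
        path = out_dir / "genomes.tsv"
        with open(path, "w") as fh:
            fh.write("accession\torganism\tstrain\tn_genes\tn_regions\n")
            for g in genomes:
                fh.write(f"{g.accession}\t{g.organism}\t{g.strain}\t"
                         f"{len(g.genes)}\t{len(g.regions)}\n")
        return [path]

    def stage_split() -> list[Path]:
        rules = [load_split_rule(p) for p in config.split_rule_files]
        regions: list[BGCRegion] = []
        n_split = 0
        for genome in state["genomes"]:
            for region in genome.regions:
                pieces = [region]
                for rule in rules:
                    pieces = [child for r in pieces for child in split_region(r, rule)]
                if len(pieces) > 1:
                    n_split += 1
                regions.extend(pieces)
        state["regions"] = {r.region_id: r for r in regions}
        path = out_dir / "regions.tsv"
        with open(path, "w") as fh:
            fh.write("region_id\tgenome\tproduct_class\tn_genes\tgenes\n")
            for r in regions:
                fh.write(f"{r.region_id}\t{r.genome_accession}\t{r.product_class}\t"
                         f"{len(r.genes)}\t{','.join(g.name or g.locus_tag for g in r.genes)}\n")
        logger.info("split %d merged regions", n_split)
        return [path]

    def stage_gcf() -> list[Path]:
        regions = list(state["regions"].values())
        gcfs, edges = gcf_families(regions, cutoff=config.gcf_cutoff,
                                   weights=config.weights, return_edges=True)
        state["gcfs"] = gcfs
        e_path, f_path = out_dir / "edges.tsv", out_dir / "gcfs.tsv"
        write_edge_table(edges, e_path)
        write_family_table(gcfs, f_path)
        return [e_path, f_path]

    def stage_tree() -> list[Path]:
        families = ortholog_families(state["genomes"])
        selected = select_mlsa_families(families, config.mlsa_k)
        alignments = [align_and_trim(f) for f in selected]
        tree = bootstrap_and_reroot(
            alignments, n_replicates=config.bootstrap_replicates,
            outgroup=config.outgroup or None, seed=config.seed)
        state["tree"] = tree
        t_path = out_dir / "tree.nwk"
        t_path.write_text(tree.newick + "\n")
        g_path = out_dir / "mlsa_genes.txt"
        g_path.write_text("\n".join(f.family_id for f in selected) + "\n")
        return [t_path, g_path]

    def stage_matrix() -> list[Path]:
        occ = presence_absence_matrix(state["gcfs"], state["genomes"], state["regions"])
        occ = cluster_and_order(occ, state.get("tree"))
        m_path, l_path = out_dir / "matrix.tsv", out_dir / "matrix_long.tsv"
        occ.to_tsv(m_path)
        occ.to_long_tsv(l_path)
        state["matrix"] = occ
        return [m_path, l_path]

    def stage_variation() -> list[Path]:
        artifacts = []
        groups_all, calls_all = [], []
        for ref_file in config.family_reference_files:
            reference = load_family_reference(ref_file)
            gcf = _match_family_gcf(reference, state["gcfs"], state["regions"])
            if gcf is None:
                logger.warning("no GCF matches family reference %s", reference.family_name)
                continue
            groups_all.extend(completeness_groups(gcf, reference, state["regions"]))
            for rid in sorted(gcf.members):
                for gene in state["regions"][rid].genes:
                    if gene.name in reference.reference_sequences:
                        calls_all.extend(detect_frameshifts(
                            gene, reference.reference_sequences[gene.name],
                            reference.reference_domains.get(gene.name, []),
                            region_id=rid))
        g_path, c_path = out_dir / "groups.tsv", out_dir / "calls.tsv"
        write_group_tsv(groups_all, g_path)
        write_calls_tsv(calls_all, c_path)
        artifacts += [g_path, c_path]
        if config.sfp_reference_fasta:
            sfp_ref = next(SeqIO.parse(config.sfp_reference_fasta, "fasta"))
            status = sfp_screen(state["genomes"], str(sfp_ref.seq).upper())
            s_path = out_dir / "sfp_status.tsv"
            write_sfp_tsv(status, s_path)
            artifacts.append(s_path)
        return artifacts

    _run("read", stage_read)
    _run("split", stage_split)
    _run("gcf", stage_gcf)
    _run("tree", stage_tree)
    _run("matrix", stage_matrix)
    _run("variation", stage_variation)

    manifest_path = out_dir / "manifest.json"
    # drop per-stage timings from the hashable part? timings vary; keep them
    # out of the file so reruns are byte-identical
    for st in manifest["stages"].values():
        st.pop("seconds", None)
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
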