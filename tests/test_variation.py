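"""Within-family screens: completeness, product classification, frameshifts."""

from __future__ import annotations

import numpy as np
import pytest

from gcfkit.genome_model import BGCRegion, Contig, DomainAnnotation, Gene, GenomeRecord
from gcfkit.similarity_gcf import GCF
from gcfkit.synthetic_data import (
    FAMILY_BLUEPRINTS,
    PlantedEvent,
    SimConfig,
    random_coding_sequence,
    simulate_dataset,
)
from gcfkit.variation import (
    NO_HOMOLOG,
    FamilyReference,
    FrameshiftCall,
    NotHomologousError,
    classify_iturinic_bgc,
    completeness_groups,
    detect_frameshifts,
    load_signatures,
    sfp_screen,
)


def _seq(length, seed):
    return random_coding_sequence(length, np.random.default_rng(seed)).tobytes().decode()


def _gene(name, seq, domains=None, start=0):
    return Gene(locus_tag=f"L_{name}", name=name, start=start, end=start + len(seq),
                strand=1, sequence=seq, domains=domains or [])


def _region(rid, genes, product_class="NRPS"):
    return BGCRegion(region_id=rid, genome_accession=rid.split("_")[0],
                     contig_id="c", start=0, end=10 ** 6,
                     product_class=product_class, genes=genes)


@pytest.fixture(scope="module")
def pps_reference():
    seqs = {g: _seq(300 * (i + 2), 10 + i) for i, g in
            enumerate(["ppsA", "ppsB", "ppsC", "ppsD", "ppsE"])}
    return FamilyReference(
        family_name="plipastatin",
        core_genes=["ppsA", "ppsB", "ppsC", "ppsD", "ppsE"],
        reference_sequences=seqs,
        reference_domains={g: [DomainAnnotation("Condensation", 10,
                                                len(s) // 3 - 5)]
                           for g, s in seqs.items()})


class TestCompletenessGroups:
    def _family_of(self, member_genes: dict[str, list[str]], reference):
        regions = {}
        for rid, genes in member_genes.items():
            regions[rid] = _region(rid, [
                _gene(g, reference.reference_sequences[g]) for g in genes])
        gcf = GCF("1_NRPS", frozenset(regions), "NRPS", len(regions) == 1)
        return gcf, regions

    def test_full_gene_set_is_complete(self, pps_reference):
        gcf, regions = self._family_of(
            {"A_r1": ["ppsA", "ppsB", "ppsC", "ppsD", "ppsE"]}, pps_reference)
        groups = completeness_groups(gcf, pps_reference, regions)
        assert [g.group_label for g in groups] == ["complete"]
        assert groups[0].missing_genes == frozenset()

    def test_two_missing_genes_label(self, pps_reference):
        gcf, regions = self._family_of(
            {"A_r1": ["ppsA", "ppsB", "ppsC"]}, pps_reference)
        groups = completeness_groups(gcf, pps_reference, regions)
        assert groups[0].group_label == "missing:ppsD,ppsE"
        assert groups[0].missing_genes == frozenset({"ppsD", "ppsE"})

    def test_more_than_three_missing_goes_to_others(self, pps_reference):
        gcf, regions = self._family_of({"A_r1": ["ppsA"]}, pps_reference)
        groups = completeness_groups(gcf, pps_reference, regions)
        assert groups[0].group_label == "others"

    def test_groups_partition_the_family(self, pps_reference):
        gcf, regions = self._family_of(
            {"A_r1": ["ppsA", "ppsB", "ppsC", "ppsD", "ppsE"],
             "B_r1": ["ppsA", "ppsB", "ppsC", "ppsD", "ppsE"],
             "C_r1": ["ppsA", "ppsB", "ppsC"],
             "D_r1": ["ppsA"]}, pps_reference)
        groups = completeness_groups(gcf, pps_reference, regions)
        members = sorted(m for g in groups for m in g.members)
        assert members == sorted(regions)
        assert [len(g.members) for g in groups] == sorted(
            [len(g.members) for g in groups], reverse=True)

    def test_complete_count_non_increasing_with_stricter_identity(
            self, sim, genomes, regions, gcfs, reference_bundles):
        from gcfkit.pipeline import load_family_reference

        reference = load_family_reference(reference_bundles["family_files"][0])
        truth = sim["truth"]
        gcf = next(g for g in gcfs
                   if truth.family_membership[sorted(g.members)[0]] == "plipastatin")
        sizes = []
        for ident in (0.90, 0.97, 0.999):
            groups = completeness_groups(gcf, reference, regions, min_identity=ident)
            complete = next((len(g.members) for g in groups
                             if g.group_label == "complete"), 0)
            sizes.append(complete)
        assert sizes == sorted(sizes, reverse=True)


@pytest.fixture(scope="module")
def signatures():
    return load_signatures()


class TestClassifyIturinic:

    def _iturin_region(self, residues):
        genes = []
        for i, res in enumerate(residues):
            seq = _seq(600, 100 + i)
            genes.append(_gene(f"itu{i}", seq, [
                DomainAnnotation("AMP-binding", 5, 150, res)], start=i * 700))
        return _region("I_r1", genes, product_class="NRPS/PKS hybrid")

    def test_mycosubtilin_signature_matches(self, signatures):
        region = self._iturin_region(
            ["asn", "tyr", "asn", "gln", "pro", "ser", "asn"])
        assert classify_iturinic_bgc(region, signatures) == "mycosubtilin"

    def test_fewer_than_seven_predictions_is_others(self, signatures):
        region = self._iturin_region(["asn", "tyr", "asn", "gln", "pro"])
        assert classify_iturinic_bgc(region, signatures) == "others"

    def test_seven_predictions_without_match_is_unclassified(self, signatures):
        region = self._iturin_region(["trp"] * 7)
        assert classify_iturinic_bgc(region, signatures) == "unclassified"

    def test_no_adenylation_domains_is_an_error(self, signatures):
        region = _region("X_r1", [_gene("x", _seq(300, 1),
                                        [DomainAnnotation("KS", 5, 90)])])
        with pytest.raises(ValueError, match="not an NRPS"):
            classify_iturinic_bgc(region, signatures)

    def test_simulated_iturin_regions_classify_as_mycosubtilin(
            self, sim, regions, signatures):
        truth = sim["truth"]
        for rid, fam in truth.family_membership.items():
            if fam == "iturin":
                assert classify_iturinic_bgc(regions[rid], signatures) == "mycosubtilin"


class TestDetectFrameshifts:
    def _domains_past(self, aa):
        return [DomainAnnotation("Condensation", aa, aa + 200),
                DomainAnnotation("TE", aa + 220, aa + 300)]

    def test_single_base_deletion_at_position_232(self):
        """The canonical conserved single-base deletion: position 232 on a
        3000-nt reference with domains beyond aa 78."""
        ref = _seq(3000, 50)
        query = ref[:231] + ref[232:]
        calls = detect_frameshifts(_gene("ppsE", query), ref, self._domains_past(78))
        assert len(calls) == 1
        c = calls[0]
        assert (c.kind, c.ref_position, c.length) == ("deletion", 232, 1)
        assert c.lost_domains
        assert "*" not in c.alt_translation

    def test_two_base_deletion_at_3126(self):
        ref = _seq(3300, 51)
        # ensure the planted site is not in a homopolymer so the leftmost
        # placement is exactly the planted coordinate
        ref = ref[:3124] + "ATG" + ref[3127:]
        query = ref[:3125] + ref[3127:]
        calls = detect_frameshifts(_gene("fenD", query), ref)
        assert len(calls) == 1
        assert (calls[0].ref_position, calls[0].length) == (3126, 2)

    def test_in_frame_deletion_produces_no_call(self):
        ref = _seq(1500, 52)
        query = ref[:300] + ref[303:]
        assert detect_frameshifts(_gene("g", query), ref) == []

    def test_insertion_is_called_with_kind_insertion(self):
        ref = _seq(900, 53)
        query = ref[:450] + "GA" + ref[450:]
        calls = detect_frameshifts(_gene("g", query), ref)
        assert len(calls) == 1
        assert calls[0].kind == "insertion"
        assert calls[0].length == 2

    def test_non_homologous_sequences_raise(self):
        with pytest.raises(NotHomologousError):
            detect_frameshifts(_gene("g", _seq(600, 54)), _seq(600, 99))

    def test_domains_before_the_shift_are_retained(self):
        ref = _seq(3000, 55)
        domains = [DomainAnnotation("Condensation", 2, 70),
                   DomainAnnotation("AMP-binding", 100, 500)]
        query = ref[:231] + ref[232:]
        calls = detect_frameshifts(_gene("g", query), ref, domains)
        assert calls[0].lost_domains == ["AMP-binding"]  # aa 70 <= 77 prefix

    def test_random_planted_indels_recover_exact_positions(self):
        """Planted non-homopolymer indels of length {1,2,4,5} are recovered
        at exactly the planted 1-based coordinate (leftmost placement)."""
        rng = np.random.default_rng(7)
        n_recovered = 0
        for trial in range(100):
            ref = _seq(1500, 1000 + trial)
            length = int(rng.choice([1, 2, 4, 5]))
            pos = int(rng.integers(10, len(ref) - length - 10))
            # enforce non-homopolymer context at the planted site
            s = pos - 1
            if ref[s - 1] == ref[s + length - 1]:
                continue
            query = ref[:s] + ref[s + length:]
            calls = detect_frameshifts(_gene("g", query), ref)
            assert len(calls) == 1, trial
            assert (calls[0].ref_position, calls[0].length) == (pos, length), trial
            n_recovered += 1
        assert n_recovered >= 60  # most draws are non-homopolymer sites


@pytest.fixture(scope="module")
def sfp_sim(tmp_path_factory):
    config = SimConfig(
        n_strains=8, n_clades=2, n_housekeeping=6, n_bgc_families=1,
        substitution_rate=0.02, seed=5,
        planted_events=[PlantedEvent(
            "frameshift_indel", clade="C2", family="", gene="sfp",
            position=101, indel_length=1)])
    out = tmp_path_factory.mktemp("sfp_sim")
    truth = simulate_dataset(config, out)
    from gcfkit.genome_model import read_genbank
    from gcfkit.synthetic_data import family_reference_sequences

    genomes = [read_genbank(p) for p in sorted(out.glob("*.gbk"))]
    refs = family_reference_sequences(config)
    return genomes, truth, refs["_standalone"]["sfp"]


class TestSfpScreen:
    def test_planted_sfp_frameshift_is_clade_exact(self, sfp_sim):
        genomes, truth, sfp_ref = sfp_sim
        status = sfp_screen(genomes, sfp_ref)
        shifted = {acc for acc, s in status.items() if isinstance(s, FrameshiftCall)}
        assert shifted == set(truth.clade_leaves["C2"])
        for acc in shifted:
            assert status[acc].ref_position == 101
            assert status[acc].length == 1

    def test_intact_genomes_map_to_none(self, sfp_sim):
        genomes, truth, sfp_ref = sfp_sim
        status = sfp_screen(genomes, sfp_ref)
        for acc in truth.clade_leaves["C1"]:
            assert status[acc] is None

    def test_genome_without_sfp_gets_distinct_marker(self, sfp_sim):
        genomes, truth, sfp_ref = sfp_sim
        status = sfp_screen(genomes, sfp_ref)
        assert status[truth.outgroup] == NO_HOMOLOG

    def test_renamed_homolog_is_still_found(self, sfp_sim):
        genomes, truth, sfp_ref = sfp_sim
        target = next(g for g in genomes if g.accession == truth.clade_leaves["C1"][0])
        for gene in target.genes:
            if gene.name == "sfp":
                gene.name = "anonymous"
        status = sfp_screen([target], sfp_ref)
        assert status[target.accession] is None  # found by homology, intact
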