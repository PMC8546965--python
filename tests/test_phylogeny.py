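"""MLSA stages: ortholog grouping, alignment/trimming, JC distances,
neighbor joining against additive oracles, bootstrap and rerooting."""

from __future__ import annotations

import numpy as np
import pytest

from gcfkit._tree import Node, splits
from gcfkit.genome_model import Contig, Gene, GenomeRecord
from gcfkit.phylogeny import (
    JC_MAX_DISTANCE,
    MultipleAlignment,
    OrthologFamily,
    align_and_trim,
    bootstrap_and_reroot,
    concatenate,
    concatenated_distances,
    jukes_cantor_distance,
    mean_pairwise_p_distance,
    nj_tree,
    ortholog_families,
    reroot_on_outgroup,
    robinson_foulds,
    select_mlsa_families,
)


def _genome(acc: str, genes: list[tuple[str, str]]) -> GenomeRecord:
    pos, objs = 0, []
    for i, (name, seq) in enumerate(genes):
        objs.append(Gene(locus_tag=f"{acc}_{i}", name=name, start=pos,
                         end=pos + len(seq), strand=1, sequence=seq))
        pos += len(seq) + 10
    return GenomeRecord(accession=acc, organism="B test", strain=acc,
                        contigs=[Contig(id=acc, length=pos + 10, genes=objs)])


class TestOrthologFamilies:
    def test_named_genes_group_by_exact_name(self):
        gs = [_genome(a, [("rpoB", "ATGAAACCCGGG")]) for a in "ABC"]
        fams = ortholog_families(gs)
        assert len(fams) == 1
        f = fams[0]
        assert f.family_id == "rpoB" and f.single_copy and f.universal
        assert set(f.members) == {"A", "B", "C"}

    def test_duplicated_gene_is_not_single_copy(self):
        g1 = _genome("A", [("rpoB", "ATGAAACCCGGG"), ("rpoB", "ATGAAACCCGGG")])
        g2 = _genome("B", [("rpoB", "ATGAAACCCGGG")])
        fams = ortholog_families([g1, g2])
        assert not fams[0].single_copy and not fams[0].universal

    def test_unnamed_gene_joins_family_by_identity(self):
        seq = "ATGAAACCCGGGTTTAAACCCGGGTTTAAA"
        g1 = _genome("A", [("rpoB", seq)])
        g2 = _genome("B", [("", seq)])
        fams = ortholog_families([g1, g2])
        rpob = next(f for f in fams if f.family_id == "rpoB")
        assert set(rpob.members) == {"A", "B"}

    def test_simulator_housekeeping_families_match_truth(self, sim, genomes):
        fams = ortholog_families(genomes)
        universal = sorted(f.family_id for f in fams if f.universal)
        assert universal == sorted(sim["truth"].mlsa_gene_names)


class TestSelectMlsaFamilies:
    def _family(self, fid, seqs):
        return OrthologFamily(
            family_id=fid,
            members={f"G{i}": Gene(locus_tag=f"G{i}_{fid}", name=fid, start=0,
                                   end=len(s), strand=1, sequence=s)
                     for i, s in enumerate(seqs)},
            single_copy=True, universal=True)

    def test_exactly_k_candidates_all_selected(self):
        fams = [self._family(f"f{i}", ["ATGAAA", "ATGAAA"]) for i in range(5)]
        assert select_mlsa_families(fams, 5) == sorted(fams, key=lambda f: f.family_id)

    def test_divergent_families_are_excluded(self):
        conserved = [self._family(f"c{i}", ["ATGAAACCC" * 4] * 3) for i in range(4)]
        divergent = [self._family(f"d{i}", ["ATGAAACCC" * 4,
                                            "ATGTTTGGG" * 4,
                                            "ATGAAACCC" * 4]) for i in range(2)]
        chosen = select_mlsa_families(conserved + divergent, 4)
        assert sorted(f.family_id for f in chosen) == [f"c{i}" for i in range(4)]

    def test_k_zero_selects_nothing(self):
        assert select_mlsa_families([], 0) == []

    def test_shortfall_raises(self):
        fams = [self._family("f0", ["ATG", "ATG"])]
        with pytest.raises(ValueError, match="1 universal"):
            select_mlsa_families(fams, 30)


class TestAlignAndTrim:
    def test_identical_sequences_align_without_gaps(self):
        fam = TestSelectMlsaFamilies()._family("f", ["ATGAAACCC"] * 4)
        aln = align_and_trim(fam)
        assert set(aln.sequences.values()) == {"ATGAAACCC"}

    def test_rare_insertion_columns_are_trimmed(self):
        base = "ATGAAACCCGGGTTTAAACCCGGGATATAT"
        with_ins = base[:12] + "CGCGCGCGCG" + base[12:]
        seqs = [base] * 9 + [with_ins]
        fam = TestSelectMlsaFamilies()._family("f", seqs)
        aln = align_and_trim(fam, gap_fraction_max=0.5)
        assert aln.length == len(base)

    def test_ungapped_rows_equal_source_sequences(self, genomes):
        fams = ortholog_families(genomes)
        fam = next(f for f in fams if f.universal)
        aln = align_and_trim(fam, gap_fraction_max=1.0)  # trim nothing
        for acc, row in aln.sequences.items():
            assert row.replace("-", "") == fam.members[acc].sequence

    def test_single_member_family_raises(self):
        fam = OrthologFamily("f", {"A": Gene("A_0", "f", 0, 3, 1, "ATG")}, True)
        with pytest.raises(ValueError):
            align_and_trim(fam)


class TestDistances:
    def test_jc_closed_form(self):
        assert jukes_cantor_distance(0.3) == pytest.approx(
            -0.75 * np.log(1 - 0.4), abs=1e-10)
        assert jukes_cantor_distance(0.3) == pytest.approx(0.3831, abs=1e-4)

    def test_identical_rows_have_distance_zero(self):
        aln = MultipleAlignment({"A": "ACGT" * 10, "B": "ACGT" * 10})
        _, d = concatenated_distances([aln])
        assert d[0, 1] == 0.0

    def test_saturation_maps_to_max_distance(self):
        assert jukes_cantor_distance(0.76) == JC_MAX_DISTANCE

    def test_concatenation_length_is_sum_of_parts(self):
        a = MultipleAlignment({"A": "A" * 100, "B": "C" * 100})
        b = MultipleAlignment({"A": "G" * 200, "B": "T" * 200})
        assert concatenate([a, b]).length == 300

    def test_pair_without_comparable_columns_raises(self):
        aln = MultipleAlignment({"A": "AC--", "B": "--GT"})
        with pytest.raises(ValueError, match="A.*B|B.*A"):
            concatenated_distances([aln])


def _tree_distances(newick: str, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path lengths of a newick tree (additivity oracle)."""
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = t.phylogenetic_distance_matrix()
    idx = {x.label: x for x in t.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(idx[labels[i]], idx[labels[j]])
    return d


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 3, 5], [3, 0, 6], [5, 6, 0.0]])
        tree = nj_tree(d, ["A", "B", "C"])
        got = _tree_distances(tree.newick, ["A", "B", "C"])
        assert np.allclose(got, d)

    def test_spec_four_taxon_additive_matrix(self):
        """Additive matrix from ((A:1,B:2):1,(C:3,D:4)): NJ returns the
        AB|CD split with exact branch lengths."""
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0]], dtype=float)
        tree = nj_tree(d, labels)
        assert robinson_foulds(tree.newick, "((A:1,B:2):1,(C:3,D:4):0);") == 0
        assert np.allclose(_tree_distances(tree.newick, labels), d)

    def test_recovers_topology_of_random_additive_matrices(self):
        """50 random trees (n <= 12): NJ on their exact path-length matrices
        returns RF distance 0 and reproduces the matrix (additivity)."""
        rng = np.random.default_rng(99)
        from gcfkit.synthetic_data import _random_topology

        for trial in range(50):
            n = int(rng.integers(4, 13))
            labels = [f"T{i}" for i in range(n)]
            top = _random_topology(labels, rng)
            for node in top.walk():
                if node is not top:
                    node.length = float(rng.uniform(0.05, 1.0))
            top.length = 0.0
            true_newick = top.to_newick()
            d = _tree_distances(true_newick, labels)
            tree = nj_tree(d, labels)
            assert robinson_foulds(tree.newick, true_newick) == 0, trial
            assert np.allclose(_tree_distances(tree.newick, labels), d, atol=1e-9)

    def test_agrees_with_scikit_bio_on_additive_input(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        from gcfkit.synthetic_data import _random_topology

        labels = [f"T{i}" for i in range(8)]
        top = _random_topology(labels, rng)
        for node in top.walk():
            if node is not top:
                node.length = float(rng.uniform(0.1, 1.0))
        top.length = 0.0
        d = _tree_distances(top.to_newick(), labels)
        ours = nj_tree(d, labels)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        assert robinson_foulds(ours.newick, str(theirs)) == 0

    def test_equidistant_matrix_gives_zero_internal_branches(self):
        d = np.ones((5, 5)) - np.eye(5)
        tree = nj_tree(d, list("ABCDE"))
        import dendropy

        t = dendropy.Tree.get(data=tree.newick, schema="newick",
                              preserve_underscores=True)
        internal = [e.length for e in t.preorder_edge_iter()
                    if e.head_node.child_nodes() and e.length is not None]
        assert all(abs(l) < 1e-9 for l in internal)

    def test_asymmetric_matrix_raises(self):
        d = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d, list("ABC"))


@pytest.fixture(scope="module")
def mlsa_alignments(genomes):
    fams = select_mlsa_families(ortholog_families(genomes), 30)
    return [align_and_trim(f) for f in fams]


class TestBootstrapAndReroot:

    def test_zero_replicates_gives_tree_without_supports(self, mlsa_alignments):
        tree = bootstrap_and_reroot(mlsa_alignments, n_replicates=0)
        assert ")1:" not in tree.newick and ")0." not in tree.newick

    def test_supports_lie_in_unit_interval_and_clades_are_strong(
            self, sim, mlsa_alignments):
        truth = sim["truth"]
        tree = bootstrap_and_reroot(mlsa_alignments, n_replicates=100,
                                    outgroup=[truth.outgroup], seed=11)
        assert robinson_foulds(tree.newick, truth.true_tree) == 0
        import dendropy

        t = dendropy.Tree.get(data=tree.newick, schema="newick",
                              suppress_internal_node_taxa=True,
                              preserve_underscores=True)
        supports = [float(n.label) for n in t.preorder_node_iter()
                    if n.label and not n.is_leaf()]
        assert supports and all(0.0 <= s <= 1.0 for s in supports)
        # supports of the true clades specifically
        clade_sets = {frozenset(v) for v in truth.clade_leaves.values()}
        for node in t.preorder_node_iter():
            leafset = frozenset(l.taxon.label for l in node.leaf_iter())
            if leafset in clade_sets and node.label:
                assert float(node.label) >= 0.95

    def test_unknown_outgroup_raises_before_resampling(self, mlsa_alignments):
        with pytest.raises(ValueError, match="NOPE"):
            bootstrap_and_reroot(mlsa_alignments, n_replicates=5, outgroup=["NOPE"])

    def test_rerooting_twice_is_idempotent(self, sim, mlsa_alignments):
        out = [sim["truth"].outgroup]
        tree = bootstrap_and_reroot(mlsa_alignments, n_replicates=0, outgroup=out)
        again = reroot_on_outgroup(tree, out)
        assert again.newick == tree.newick


def test_jc_estimator_recovers_true_branch_length_within_3_sigma():
    """Estimated JC distance over 100 simulated branches is unbiased."""
    from gcfkit.synthetic_data import evolve_sequence, random_coding_sequence

    L = 18000
    true_d = 0.12
    seq = random_coding_sequence(L, np.random.default_rng(0))
    estimates = []
    for seed in range(100):
        out = evolve_sequence(seq, true_d, np.random.default_rng(1000 + seed))
        p = float((out != seq).mean())
        estimates.append(jukes_cantor_distance(p))
    # variance of the JC estimator (delta method)
    p_exp = 0.75 * (1 - np.exp(-4 * true_d / 3))
    var = p_exp * (1 - p_exp) / (L * (1 - 4 * p_exp / 3) ** 2)
    sigma_mean = np.sqrt(var / 100)
    assert abs(np.mean(estimates) - true_d) < 3 * sigma_mean
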