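import numpy as np
import pytest

from laccevo.orthology import (
    assign_og,
    delineate_ogs,
    global_align,
    percent_identity,
    same_species,
    stem_duplications,
)
from laccevo.polyporales import OG_SIZES, _og_of_gene
from laccevo.reconciliation import reconcile
from laccevo.trees import GeneTree, SpeciesTree, parse_newick

from _oracles import nw_score


def gtree(newick, species):
    return GeneTree(parse_newick(newick), species_map=species)


@pytest.fixture(scope="module")
def fixture_recon(gene_tree_mod, species_tree_mod):
    return reconcile(gene_tree_mod, species_tree_mod)


@pytest.fixture(scope="module")
def species_tree_mod():
    from laccevo.polyporales import build_species_tree

    return build_species_tree()


@pytest.fixture(scope="module")
def gene_tree_mod(species_tree_mod):
    from laccevo.polyporales import build_gene_tree

    return build_gene_tree(species_tree_mod)


class TestStemDuplications:
    def test_no_duplications_no_stems(self):
        s = SpeciesTree(parse_newick("(A,B);"), {"AB": {"A", "B"}})
        g = gtree("(a1,b1);", dict(a1="A", b1="B"))
        assert stem_duplications(reconcile(g, s), s, "AB") == []

    def test_single_stem_duplication_found(self):
        s = SpeciesTree(parse_newick("((A,B),C);"), {"AB": {"A", "B"}})
        g = gtree(
            "(((a1,b1),(a2,b2)),c1);",
            dict(a1="A", b1="B", a2="A", b2="B", c1="C"),
        )
        r = reconcile(g, s)
        stems = stem_duplications(r, s, "AB")
        assert len(stems) == 1
        assert stems[0].leaf_labels() == {"a1", "b1", "a2", "b2"}

    def test_fixture_has_six_corepol_stems(self, fixture_recon, species_tree_mod):
        stems = stem_duplications(fixture_recon, species_tree_mod, "CorePol")
        assert len(stems) == 6

    def test_unknown_clade(self, fixture_recon, species_tree_mod):
        with pytest.raises(KeyError, match="unknown clade"):
            stem_duplications(fixture_recon, species_tree_mod, "Nope")


class TestDelineation:
    def test_no_stems_one_group(self):
        s = SpeciesTree(parse_newick("(A,B);"), {"AB": {"A", "B"}})
        g = gtree("(a1,b1);", dict(a1="A", b1="B"))
        r = reconcile(g, s)
        ogs = delineate_ogs(g, r, s, "AB")
        assert len(ogs) == 1
        assert set(ogs[0].members) == {"a1", "b1"}

    def test_fixture_member_counts(
        self, gene_tree_mod, fixture_recon, species_tree_mod
    ):
        ogs = delineate_ogs(gene_tree_mod, fixture_recon, species_tree_mod, "CorePol")
        sizes = {_og_of_gene(og.members[0]): len(og) for og in ogs}
        assert sizes == OG_SIZES

    def test_groups_partition_focal_leaves(
        self, gene_tree_mod, fixture_recon, species_tree_mod
    ):
        ogs = delineate_ogs(gene_tree_mod, fixture_recon, species_tree_mod, "CorePol")
        focal = species_tree_mod.clades["CorePol"]
        focal_genes = {
            l.label for l in gene_tree_mod.leaves() if l.species in focal
        }
        union = set()
        for og in ogs:
            members = set(og.members)
            assert not (union & members)  # pairwise disjoint
            union |= members
        assert union == focal_genes

    def test_pectinate_chain_count(
        self, gene_tree_mod, fixture_recon, species_tree_mod
    ):
        stems = stem_duplications(fixture_recon, species_tree_mod, "CorePol")
        ogs = delineate_ogs(gene_tree_mod, fixture_recon, species_tree_mod, "CorePol")
        assert len(ogs) == len(stems) + 1

    def test_lost_lineages_absent_from_group(
        self, gene_tree_mod, fixture_recon, species_tree_mod
    ):
        ogs = delineate_ogs(gene_tree_mod, fixture_recon, species_tree_mod, "CorePol")
        og_h = next(og for og in ogs if _og_of_gene(og.members[0]) == "H")
        missing = species_tree_mod.clades["CorePol"] - og_h.species
        assert missing == {"T_hirsuta", "T_gibbosa"}


class TestGlobalAlign:
    def test_identical_sequences(self):
        score, ident, cov = global_align("ACGTACGT", "ACGTACGT")
        assert (score, ident, cov) == (8.0, 100.0, 100.0)

    def test_single_mismatch_identity(self):
        assert global_align("ACGT", "ACGA")[1] == 75.0

    def test_score_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), 60))
            b = "".join(rng.choice(list("ACGT"), 50))
            assert global_align(a, b)[0] == global_align(b, a)[0]

    def test_matches_independent_dp(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), 200))
            # related sequence: mutate + indel
            b = list(a)
            for i in rng.choice(200, 30, replace=False):
                b[i] = rng.choice(list("ACGT"))
            del b[50:55]
            b = "".join(b)
            assert global_align(a, b)[0] == nw_score(a, b)

    def test_protein_scoring_uses_blosum62(self):
        score, ident, cov = global_align("MKVLW", "MKVLW")
        # BLOSUM62 diagonal: M5 K5 V4 L4 W11
        assert score == 29.0
        assert ident == 100.0

    def test_alphabet_mix_rejected(self):
        with pytest.raises(ValueError, match="alphabet mix"):
            global_align("ACGT", "MKVLW")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            global_align("", "ACGT")


class TestPercentIdentity:
    def test_identical_its_same_species(self):
        seq = "ACGT" * 50
        assert percent_identity(seq, seq) == 100.0
        assert same_species(seq, seq)

    def test_ten_percent_mutated(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), 700))
        mutated = list(base)
        for i in rng.choice(700, 70, replace=False):
            mutated[i] = rng.choice([c for c in "ACGT" if c != mutated[i]])
        ident = percent_identity(base, "".join(mutated))
        assert ident == pytest.approx(90.0, abs=1.0)
        assert not same_species(base, "".join(mutated))

    def test_length_one_mismatch(self):
        assert percent_identity("A", "C") == 0.0


class TestAssignOg:
    REFS = [
        ("rA1", "ACGTACGTACGTACGTACGT", "A"),
        ("rA2", "ACGTACGTACGTACGTACGA", "A"),
        ("rB1", "TTTTGGGGCCCCAAAATTTT", "B"),
    ]

    def test_identical_query_assigned(self):
        a = assign_og("q", "ACGTACGTACGTACGTACGT", self.REFS)
        assert a.status == "assigned"
        assert a.og == "A"
        assert a.margin > 0

    def test_constructed_tie_is_ambiguous(self):
        refs = [("r1", "ACGTACGT", "A"), ("r2", "ACGTACGT", "B")]
        a = assign_og("q", "ACGTACGT", refs)
        assert a.status == "ambiguous"

    def test_low_identity_unclassified(self):
        a = assign_og("q", "GGGGGGGGGGGGGGGGGGGG", self.REFS)
        assert a.status == "unclassified"

    def test_empty_refs_rejected(self):
        with pytest.raises(ValueError):
            assign_og("q", "ACGT", [])

    def test_deterministic(self):
        a1 = assign_og("q", "ACGTACGTACGTACGTACGT", self.REFS)
        a2 = assign_og("q", "ACGTACGTACGTACGTACGT", self.REFS)
        assert a1 == a2

    def test_simulated_heldout_leaves_reassigned(self, gene_tree_mod):
        from laccevo.simulate import evolve_sequences

        seqs = evolve_sequences(gene_tree_mod.tree, length=300, rate=0.05, seed=9)
        focal_genes = [
            l.label for l in gene_tree_mod.leaves() if "_lac1" not in l.label
        ]
        rng = np.random.default_rng(9)
        held_out = set(rng.choice(focal_genes, 10, replace=False))
        refs = [
            (g, seqs[g], _og_of_gene(g)) for g in focal_genes if g not in held_out
        ]
        correct = 0
        for q in sorted(held_out):
            a = assign_og(q, seqs[q], refs)
            correct += a.status == "assigned" and a.og == _og_of_gene(q)
        assert correct >= 9


class TestGraftingRoute:
    def test_query_grafted_next_to_twin_lands_in_its_group(
        self, gene_tree_mod, species_tree_mod
    ):
        from laccevo.orthology import assign_by_grafting
        from laccevo.simulate import evolve_sequences

        seqs = evolve_sequences(gene_tree_mod.tree, length=200, rate=0.05, seed=2)
        r = reconcile(gene_tree_mod, species_tree_mod)
        ogs = delineate_ogs(gene_tree_mod, r, species_tree_mod, "CorePol")
        target = "T_hirsuta_lacC"
        truth = next(og.name for og in ogs if target in og.members)
        got = assign_by_grafting(
            "query1", seqs[target], gene_tree_mod, seqs, r,
            species_tree_mod, "CorePol",
        )
        # group numbering is positional; the grafted tree keeps the order
        assert got == truth
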