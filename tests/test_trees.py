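import numpy as np
import pytest
from hypothesis import given, strategies as st

from laccevo.trees import (
    GeneTree,
    NewickParseError,
    SpeciesTree,
    Tree,
    annotate_support,
    jc69_distance,
    nj_tree,
    parse_newick,
    write_newick,
)

from conftest import random_tree


class TestParseWrite:
    def test_three_leaf_rooted(self):
        t = parse_newick("((A,B),C);")
        assert len(t.root.children) == 2
        assert t.leaf_labels() == {"A", "B", "C"}

    def test_supports_and_lengths(self):
        t = parse_newick("((A:0.1,B:0.2)90:0.05,C:0.3);")
        (inner,) = t.internal_nodes(include_root=False)
        assert inner.support == 90.0
        assert inner.length == 0.05
        assert t.leaf("A").length == 0.1

    def test_single_leaf(self):
        assert write_newick(parse_newick("A;")) == "A;"

    def test_fractional_supports_scaled_to_percent(self, caplog):
        t = parse_newick("((A,B)0.95,C);")
        (inner,) = t.internal_nodes(include_root=False)
        assert inner.support == 95.0

    def test_nhx_species_tags(self):
        t = parse_newick("((g1[&&NHX:S=A],g2[&&NHX:S=B]),g3[&&NHX:S=C]);")
        assert t.leaf("g1").species == "A"

    @pytest.mark.parametrize(
        "bad",
        ["((A,B);", "((A,B)));", "(A,'B);", "((A,B),C); junk", "(A,B):x;", ""],
    )
    def test_malformed_input_names_offset(self, bad):
        with pytest.raises(NewickParseError, match="position"):
            parse_newick(bad)

    @given(st.integers(0, 10_000))
    def test_round_trip_identity(self, seed):
        labels = [f"L{i}" for i in range((seed % 12) + 2)]
        t = random_tree(seed, labels, lengths=True, supports=True)
        once = parse_newick(write_newick(t))
        twice = parse_newick(write_newick(once))
        assert once == twice

    def test_write_is_order_invariant(self):
        a = parse_newick("((B,A),(D,C));")
        b = parse_newick("((C,D),(A,B));")
        assert write_newick(a) == write_newick(b)

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("((A,A),B);")


class TestQueries:
    def test_mrca_all_leaves_is_root(self):
        t = parse_newick("((A,B),(C,D));")
        assert t.mrca({"A", "B", "C", "D"}) is t.root

    def test_mrca_single_leaf(self):
        t = parse_newick("((A,B),C);")
        assert t.mrca({"A"}).label == "A"

    def test_mrca_across_root(self):
        t = parse_newick("((A,B),(C,D));")
        assert t.mrca({"A", "C"}) is t.root

    def test_mrca_unknown_label(self):
        with pytest.raises(KeyError, match="unknown leaf"):
            parse_newick("((A,B),C);").mrca({"A", "Z"})

    def test_nodal_distance_cases(self):
        t = parse_newick("((A,B),(C,D));")
        assert t.nodal_distance("A", "A") == 0
        assert t.nodal_distance("A", "B") == 2
        assert t.nodal_distance("A", "C") == 4

    @given(st.integers(0, 5_000))
    def test_nodal_distance_is_a_metric(self, seed):
        labels = [f"x{i}" for i in range(6)]
        t = random_tree(seed, labels)
        rng = np.random.default_rng(seed)
        a, b, c = rng.choice(labels, 3, replace=False)
        dab, dba = t.nodal_distance(a, b), t.nodal_distance(b, a)
        assert dab == dba
        assert dab > 0
        assert dab <= t.nodal_distance(a, c) + t.nodal_distance(c, b)


class TestSpeciesAndGeneTrees:
    def test_clade_registry_requires_monophyly(self):
        tree = parse_newick("((A,B),(C,D));")
        SpeciesTree(tree, {"good": {"A", "B"}})
        with pytest.raises(ValueError, match="not monophyletic"):
            SpeciesTree(parse_newick("((A,B),(C,D));"), {"bad": {"A", "C"}})

    def test_gene_tree_requires_species(self):
        with pytest.raises(ValueError, match="without species"):
            GeneTree(parse_newick("((g1,g2),g3);"))

    def test_gene_tree_species_must_exist(self):
        s = SpeciesTree(parse_newick("(A,B);"))
        with pytest.raises(ValueError, match="not in species tree"):
            GeneTree(
                parse_newick("(g1,g2);"),
                species_map={"g1": "A", "g2": "Z"},
                species_tree=s,
            )


class TestSupportAnnotation:
    def test_self_replicates_give_full_support(self):
        t = parse_newick("((A,B),((C,D),E));")
        ann = annotate_support(t, [t.copy() for _ in range(10)])
        sups = [
            n.support
            for n in ann.internal_nodes(include_root=False)
            if n.support is not None
        ]
        assert sups and all(s == 100.0 for s in sups)

    def test_absent_split_gives_zero(self):
        t = parse_newick("((A,B),(C,D));")
        reps = [parse_newick("((A,C),(B,D));")] * 4
        ann = annotate_support(t, reps)
        node = ann.mrca({"A", "B"})
        assert node.support == 0.0

    def test_half_support(self):
        t = parse_newick("((A,B),(C,D));")
        reps = [parse_newick("((A,B),(C,D));"), parse_newick("((A,C),(B,D));")]
        ann = annotate_support(t, reps)
        assert ann.mrca({"A", "B"}).support == 50.0

    def test_leafset_mismatch_lists_difference(self):
        t = parse_newick("((A,B),C);")
        with pytest.raises(ValueError, match="D"):
            annotate_support(t, [parse_newick("((A,B),D);")])

    @given(st.integers(0, 2_000))
    def test_supports_within_range(self, seed):
        labels = [f"s{i}" for i in range(6)]
        t = random_tree(seed, labels)
        reps = [random_tree(seed + k + 1, labels) for k in range(5)]
        ann = annotate_support(t, reps)
        for n in ann.internal_nodes(include_root=False):
            if n.support is not None:
                assert 0.0 <= n.support <= 100.0


class TestNeighborJoining:
    def test_three_taxa(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        t = nj_tree(d, ["A", "B", "C"])
        assert t.leaf_labels() == {"A", "B", "C"}

    def test_additive_four_taxon_recovers_split(self):
        # distances on ((A:1,B:2):1,(C:3,D:1):1)
        d = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        t = nj_tree(d, ["A", "B", "C", "D"])
        split_sides = {side for split in t.bipartitions() for side in split}
        assert frozenset({"A", "B"}) in split_sides or frozenset({"C", "D"}) in split_sides

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[0, 1], [2, 0]], float),  # asymmetric
            np.array([[0, np.nan], [np.nan, 0]], float),
        ],
    )
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            nj_tree(bad, ["A", "B"])

    def test_recovers_topology_from_simulated_sequences(self):
        from laccevo.simulate import evolve_sequences
        from laccevo.trees import jc_distance_matrix

        truth = parse_newick(
            "(((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1):0.1,(E:0.1,F:0.2):0.1);"
        )
        want = truth.bipartitions()
        ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            seqs = evolve_sequences(truth, length=1000, rate=1.0, seed=seed)
            labels, d = jc_distance_matrix(seqs)
            est = nj_tree(d, labels)
            ok += est.bipartitions() == want
        assert ok >= 0.95 * n_seeds

    def test_jc69_distance_formula(self):
        assert jc69_distance("AAAA", "AAAA") == 0.0
        # p = 0.25 -> d = -3/4 ln(1 - 1/3)
        assert jc69_distance("AAAA", "AAAC") == pytest.approx(
            -0.75 * np.log(1 - 1 / 3)
        )


class TestOutgroupRooting:
    def test_reroot_preserves_unrooted_splits(self):
        from laccevo.trees import root_with_outgroup

        t = parse_newick("((A:1,B:1):1,((C:1,D:1):1,E:1):1);")
        rerooted = root_with_outgroup(t, {"C", "D"})
        kids = {frozenset(c.leaf_labels()) for c in rerooted.root.children}
        assert frozenset({"C", "D"}) in kids
        assert rerooted.bipartitions() == t.bipartitions()

    def test_non_split_outgroup_rejected(self):
        from laccevo.trees import root_with_outgroup

        t = parse_newick("((A,B),((C,D),E));")
        with pytest.raises(ValueError, match="split"):
            root_with_outgroup(t, {"A", "C"})

    def test_unknown_outgroup_leaf(self):
        from laccevo.trees import root_with_outgroup

        with pytest.raises(KeyError):
            root_with_outgroup(parse_newick("((A,B),C);"), {"Z"})


class TestCrossChecks:
    def test_nodal_distances_agree_with_dendropy(self):
        import dendropy

        from laccevo.polyporales import build_species_tree

        t = build_species_tree().tree
        dt = dendropy.Tree.get(
            data=write_newick(t), schema="newick", preserve_underscores=True
        )
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in dt.taxon_namespace}
        pairs = [
            ("T_hirsuta", "T_villosa"),
            ("T_hirsuta", "W_cocos"),
            ("B_adusta", "C_unicolor"),
            ("P_sanguineus", "P_puniceus"),
        ]
        for a, b in pairs:
            assert t.nodal_distance(a, b) == pdm.path_edge_count(taxa[a], taxa[b])

    def test_nj_from_fasta_file(self, tmp_path):
        from laccevo.simulate import evolve_sequences
        from laccevo.trees import nj_tree_from_fasta

        truth = parse_newick("((A:0.2,B:0.2):0.2,(C:0.2,D:0.2):0.2);")
        seqs = evolve_sequences(truth, length=2000, rate=1.0, seed=0)
        fasta = tmp_path / "aln.fasta"
        fasta.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        est = nj_tree_from_fasta(fasta)
        assert est.bipartitions() == truth.bipartitions()
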