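import io

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stingless_ssd import load_bundled_table
from stingless_ssd.phylo_io import (
    PhyloTree,
    TraitTableError,
    TreeParseError,
    TreeValidationError,
    check_ultrametric,
    parse_tree,
    prune_to_taxa,
    read_trait_table,
    resolve_polytomies,
    match_taxa,
    normalize_label,
)
from stingless_ssd.synthetic_data import simulate_yule_tree


class TestParse:
    def test_smallest_rooted_tree(self, cherry):
        assert cherry.n_tips == 2
        assert sorted(cherry.tip_labels) == ["A", "B"]
        assert all(d == 1.0 for d in cherry.tip_depths().values())

    def test_three_taxon_depths(self, three_taxon_tree):
        assert three_taxon_tree.n_tips == 3
        assert all(d == 2.0 for d in three_taxon_tree.tip_depths().values())

    def test_round_trip_identity(self, three_taxon_tree):
        text = three_taxon_tree.to_newick()
        again = parse_tree(text)
        assert again.to_newick() == text
        assert again.tip_depths() == three_taxon_tree.tip_depths()

    def test_quoted_and_underscored_labels_normalized(self):
        tree = parse_tree("('Melipona beecheii':1,Melipona_favosa:1);")
        assert sorted(tree.tip_labels) == ["Melipona beecheii", "Melipona favosa"]

    def test_nexus_translate_table(self):
        nexus = (
            "#NEXUS\nBEGIN TREES;\n"
            "TRANSLATE 1 A, 2 B, 3 C;\n"
            "TREE one = ((1:1,2:1):1,3:2);\nEND;\n"
        )
        tree = parse_tree(nexus, dialect="nexus")
        assert sorted(tree.tip_labels) == ["A", "B", "C"]
        assert all(d == 2.0 for d in tree.tip_depths().values())

    def test_malformed_newick_raises_parse_error(self):
        with pytest.raises(TreeParseError):
            parse_tree("((A:1,B:1:1,C:2);")

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises((TreeParseError, TreeValidationError)):
            parse_tree("(A:1,A:1);")

    def test_branch_lengths_full_precision(self):
        tree = parse_tree("(A:0.123456789012345,B:1.5e-3);")
        lengths = sorted(tree.edge_length[1:])
        assert lengths == pytest.approx([1.5e-3, 0.123456789012345], abs=0)


class TestUltrametric:
    def test_ultrametric_tree_flag_true(self, three_taxon_tree):
        flag, dev = check_ultrametric(three_taxon_tree, rel_tol=1e-6)
        assert flag and dev == 0.0

    def test_uneven_depths_deviation(self):
        # depths 1 and 2, mean 1.5 -> max deviation 0.5/1.5
        flag, dev = check_ultrametric(parse_tree("(A:1,B:2);"))
        assert not flag
        assert dev == pytest.approx(1 / 3)

    def test_simulated_tree_is_ultrametric(self):
        tree = simulate_yule_tree(40, 1.0, seed=7)
        flag, dev = check_ultrametric(tree, rel_tol=1e-12)
        assert flag and dev <= 1e-12

    def test_zero_depth_tree_errors(self):
        with pytest.raises(TreeValidationError):
            check_ultrametric(parse_tree("(A:0,B:0);"))

    def test_invariant_under_tip_reordering(self):
        a = parse_tree("((A:1,B:1):1,C:2);")
        b = parse_tree("(C:2,(B:1,A:1):1);")
        assert check_ultrametric(a) == check_ultrametric(b)


class TestPrune:
    def test_path_length_conservation(self, three_taxon_tree):
        pruned = prune_to_taxa(three_taxon_tree, {"A", "C"})
        assert pruned.to_newick() == "(A:2,C:2);"

    def test_prune_to_all_tips_is_identity(self, three_taxon_tree):
        pruned = prune_to_taxa(three_taxon_tree, set(three_taxon_tree.tip_labels))
        assert pruned.to_newick() == three_taxon_tree.to_newick()

    def test_unknown_taxon_error_lists_names(self, three_taxon_tree):
        with pytest.raises(TreeValidationError, match="Zzz"):
            prune_to_taxa(three_taxon_tree, {"A", "Zzz"})

    @given(seed=st.integers(0, 2**31 - 1), data=st.data())
    def test_pairwise_distances_preserved_on_random_trees(self, seed, data):
        tree = simulate_yule_tree(10, 1.0, seed=seed)
        labels = tree.tip_labels
        keep = data.draw(
            st.sets(st.sampled_from(labels), min_size=2, max_size=len(labels))
        )
        pruned = prune_to_taxa(tree, keep)
        # tip-to-tip path lengths are invariant under pruning (the root-side
        # stalk above the retained clade is dropped, so depths need not be)
        from _oracles import _pairwise_distances

        def tip_dists(t):
            d = _pairwise_distances(t)
            idx = {t.labels[i]: i for i in t.tip_indices}
            return d, idx

        d_full, i_full = tip_dists(tree)
        d_sub, i_sub = tip_dists(pruned)
        for a in keep:
            for b in keep:
                assert d_sub[i_sub[a], i_sub[b]] == pytest.approx(
                    d_full[i_full[a], i_full[b]], abs=1e-12
                )


class TestResolvePolytomies:
    def test_resolution_is_binary_with_zero_branches(self):
        tree = parse_tree("(A:1,B:1,C:1,D:1);")
        assert not tree.is_binary
        fixed = resolve_polytomies(tree, seed=3)
        assert fixed.is_binary
        assert fixed.n_tips == 4
        for t, d in fixed.tip_depths().items():
            assert d == pytest.approx(1.0, abs=1e-15)


class TestTraitTable:
    def test_bundled_fixture_shape(self, caste_table):
        assert len(caste_table) == 44
        assert int(caste_table["worker_mm"].isna().sum()) == 3  # T. extranea + 2 Euglossini
        assert np.isnan(caste_table.loc["Trichotrigona extranea", "worker_mm"])
        assert caste_table["queen_mm"].notna().all() and caste_table["male_mm"].notna().all()

    def test_all_castes_equal_row(self):
        df = read_trait_table(io.StringIO("species,worker_mm,male_mm,queen_mm\nX,1.0,1.0,1.0\n"))
        assert df.loc["X"].tolist() == [1.0, 1.0, 1.0]

    def test_negative_size_rejected(self):
        with pytest.raises(TraitTableError, match="queen_mm"):
            read_trait_table(io.StringIO("species,worker_mm,male_mm,queen_mm\nX,1.0,1.0,-1\n"))

    def test_duplicate_species_rejected(self):
        buf = "species,worker_mm,male_mm,queen_mm\nX,1,1,1\nX,2,2,2\n"
        with pytest.raises(TraitTableError, match="duplicate"):
            read_trait_table(io.StringIO(buf))

    def test_row_missing_both_reproductives_rejected(self):
        buf = "species,worker_mm,male_mm,queen_mm\nX,1,NA,\n"
        with pytest.raises(TraitTableError, match="male and queen"):
            read_trait_table(io.StringIO(buf))


class TestMatching:
    def test_label_normalization(self):
        assert normalize_label("  Melipona_beecheii ") == normalize_label("melipona  beecheii")

    def test_match_drops_unmatched_and_rekeys(self, caste_table):
        tree = parse_tree("((Melipona_beecheii:1,MELIPONA_FAVOSA:1):1,Not_a_bee:2);")
        pruned, aligned = match_taxa(tree, caste_table)
        assert pruned.n_tips == 2
        assert set(aligned.index) == {"Melipona beecheii", "MELIPONA FAVOSA"}

    def test_melipona_exclusion_leaves_32_taxa(self, caste_table):
        non_melipona = caste_table[caste_table["genus"] != "Melipona"]
        assert len(non_melipona) == 32
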