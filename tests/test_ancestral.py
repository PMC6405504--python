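import shutil
import subprocess
import textwrap

import matplotlib

matplotlib.use("Agg")
import numpy as np
import pytest

from stingless_ssd.ancestral import interpolate_branch, ml_ancestral_states, paint_tree
from stingless_ssd.dimorphism import ssdi_table
from stingless_ssd.phylo_io import parse_tree, write_tree
from stingless_ssd.synthetic_data import simulate_bm, simulate_yule_tree

from conftest import spawn_seeds
from _oracles import gls_ancestral_state


class TestWorkedExamples:
    def test_cherry_root_is_equal_branch_average(self, cherry):
        anc = ml_ancestral_states(cherry, {"A": 0.0, "B": 2.0})
        assert anc.state(cherry.root) == pytest.approx(1.0)

    def test_three_taxon_root_matches_gls_closed_form(self, three_taxon_tree):
        anc = ml_ancestral_states(three_taxon_tree, {"A": 1.0, "B": 3.0, "C": 0.0})
        assert anc.state(three_taxon_tree.root) == pytest.approx(8 / 7)

    def test_constant_tips_reconstruct_constant(self, three_taxon_tree):
        anc = ml_ancestral_states(three_taxon_tree, {"A": 2.5, "B": 2.5, "C": 2.5})
        assert anc.states == pytest.approx(np.full(three_taxon_tree.n_nodes, 2.5))

    def test_single_tip_rejected(self):
        tree = simulate_yule_tree(2, 1.0, seed=0)
        with pytest.raises(ValueError):
            ml_ancestral_states(tree, {tree.tip_labels[0]: 1.0})


class TestOracleEquivalence:
    def test_all_node_estimates_equal_gls_projection(self):
        # re-rooted contrasts recursion vs brute-force GLS on random trees
        for s in spawn_seeds(4242, 20):
            tree = simulate_yule_tree(15, 1.0, seed=s)
            x = simulate_bm(tree, sigma2=1.0, root_state=3.0, seed=s + 1)
            anc = ml_ancestral_states(tree, x)
            for node in range(tree.n_nodes):
                if tree.is_tip(node):
                    continue
                oracle = gls_ancestral_state(tree, dict(x), node)
                assert anc.state(node) == pytest.approx(oracle, abs=1e-8)

    def test_reconstruction_is_linear_in_data(self):
        tree = simulate_yule_tree(12, 1.0, seed=5)
        x = simulate_bm(tree, sigma2=1.0, seed=6)
        base = ml_ancestral_states(tree, x)
        scaled = ml_ancestral_states(tree, 3.0 * x + 2.0)
        assert scaled.states == pytest.approx(3.0 * base.states + 2.0)

    def test_root_state_within_tip_range(self):
        for s in spawn_seeds(77, 10):
            tree = simulate_yule_tree(10, 1.0, seed=s)
            x = simulate_bm(tree, sigma2=2.0, seed=s + 2)
            anc = ml_ancestral_states(tree, x)
            assert x.min() - 1e-12 <= anc.state(tree.root) <= x.max() + 1e-12

    def test_root_estimate_unbiased_under_bm(self):
        # mean error over replicates within 2 Monte-Carlo SEs of zero
        errors = []
        for s in spawn_seeds(31337, 500):
            tree = simulate_yule_tree(12, 1.0, seed=s)
            x = simulate_bm(tree, sigma2=1.0, root_state=1.5, seed=s + 9)
            errors.append(ml_ancestral_states(tree, x).state(tree.root) - 1.5)
        se = np.std(errors, ddof=1) / np.sqrt(len(errors))
        assert abs(np.mean(errors)) < 2 * se + 1e-12

    def test_sigma2_recorded_but_scale_free(self):
        tree = simulate_yule_tree(10, 1.0, seed=3)
        x = simulate_bm(tree, sigma2=1.0, seed=4)
        a = ml_ancestral_states(tree, x)
        b = ml_ancestral_states(tree, x * 10.0)
        assert b.sigma2 == pytest.approx(100.0 * a.sigma2)
        assert b.states == pytest.approx(10.0 * a.states)


class TestInterpolation:
    def test_midpoint_and_endpoints(self, cherry):
        anc = ml_ancestral_states(cherry, {"A": 0.0, "B": 2.0})
        tip_a = next(i for i in cherry.tip_indices if cherry.labels[i] == "A")
        length = cherry.edge_length[tip_a]
        assert interpolate_branch(anc, tip_a, 0.0) == pytest.approx(anc.state(cherry.root))
        assert interpolate_branch(anc, tip_a, length) == pytest.approx(0.0)
        assert interpolate_branch(anc, tip_a, length / 2) == pytest.approx(
            (anc.state(cherry.root) + 0.0) / 2
        )

    def test_out_of_range_rejected(self, cherry):
        anc = ml_ancestral_states(cherry, {"A": 0.0, "B": 2.0})
        tip_a = cherry.tip_indices[0]
        with pytest.raises(ValueError):
            interpolate_branch(anc, tip_a, 1.5 * cherry.edge_length[tip_a])


class TestPaintedTree:
    def test_two_tip_gradient_figure(self, cherry):
        anc = ml_ancestral_states(cherry, {"A": -1.0, "B": 1.0}, trait="SSDi")
        fig = paint_tree(anc)
        assert fig is not None
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_constant_states_warn_single_colour(self, three_taxon_tree):
        anc = ml_ancestral_states(three_taxon_tree, {"A": 1.0, "B": 1.0, "C": 1.0})
        with pytest.warns(UserWarning, match="single colour"):
            fig = paint_tree(anc)
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_melipona_like_clade_reconstructs_negative(self, caste_table):
        # all-Melipona subtree: every tip SSDi < 0, so every internal state
        # (a weighted average) must be < 0 too
        melipona = caste_table[caste_table["genus"] == "Melipona"]
        ssdi = ssdi_table(melipona)["ssdi"]
        tree = simulate_yule_tree(len(melipona), 1.0, seed=99)
        renamed = {old: new for old, new in zip(tree.tip_labels, ssdi.index)}
        tree.labels = [renamed.get(l, l) if l else l for l in tree.labels]
        anc = ml_ancestral_states(tree, ssdi)
        internal = [anc.state(i) for i in range(tree.n_nodes) if not tree.is_tip(i)]
        assert all(s < 0 for s in internal)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
class TestAgainstPhytools:
    """phytools::fastAnc is the reference for ML states under BM."""

    def test_node_states_match_fastanc(self, tmp_path):
        tree = simulate_yule_tree(10, 1.0, seed=21)
        x = simulate_bm(tree, sigma2=1.0, root_state=1.0, seed=22)
        write_tree(tree, tmp_path / "tree.nwk")
        x.rename("value").rename_axis("species").to_frame().to_csv(tmp_path / "x.csv")
        script = textwrap.dedent(
            """
            suppressMessages(library(phytools))
            args <- commandArgs(trailingOnly = TRUE)
            tr <- read.tree(args[1])
            d <- read.csv(args[2])
            x <- setNames(d$value, d$species)
            a <- fastAnc(tr, x[tr$tip.label])
            cat(sprintf("%.12f", sort(as.numeric(a))), sep = "\\n")
            """
        )
        (tmp_path / "anc.R").write_text(script)
        out = subprocess.run(
            ["Rscript", "--vanilla", str(tmp_path / "anc.R"), str(tmp_path / "tree.nwk"), str(tmp_path / "x.csv")],
            capture_output=True, text=True, check=True,
        )
        ref = np.array([float(v) for v in out.stdout.split()])
        ours = np.sort([
            s for i, s in enumerate(ml_ancestral_states(tree, x).states) if not tree.is_tip(i)
        ])
        assert ours == pytest.approx(ref, abs=1e-6)
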