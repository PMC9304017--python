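"""Posterior summaries: distances, frequencies, diagnostics, MAP, rescaling."""

import math

import dendropy
import numpy as np
import pytest

from genphy.mcmc import run_prior_only
from genphy.priors import PriorConfig
from genphy.summarize import (
    average_sd_split_frequencies,
    branch_score_distance,
    convergence_diagnostics,
    effective_sample_size,
    map_summary,
    merged_divergence_probabilities,
    potential_scale_reduction,
    rescale_to_calibration,
    split_node_shared_frequencies,
)
from genphy.tree import enumerate_neighbor_merges, merge_height_classes, parse_tree

from conftest import random_trees


class TestBranchScoreDistance:
    def test_identity_and_single_branch_difference(self):
        a = parse_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        assert branch_score_distance(a, a) == 0.0
        b = parse_tree("((A:0.1,B:0.1):0.15,C:0.25);")
        # only the root height moved by 0.05: affects the inner branch
        # and both root-child branches
        expected = math.sqrt(0.05 ** 2 + 0.05 ** 2)
        assert branch_score_distance(a, b) == pytest.approx(expected)

    def test_three_tip_topology_difference(self):
        a = parse_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        b = parse_tree("((A:0.1,C:0.1):0.1,B:0.2);")
        # AB branch (0.1) present only in a; AC branch only in b; tips A
        # equal, B and C tip branches differ by 0.1 each
        expected = math.sqrt(0.1 ** 2 * 4)
        assert branch_score_distance(a, b) == pytest.approx(expected)

    def test_tip_mismatch(self):
        a = parse_tree("(A:0.1,B:0.1);")
        c = parse_tree("(A:0.1,C:0.1);")
        with pytest.raises(ValueError):
            branch_score_distance(a, c)

    def test_metric_properties_and_dendropy_agreement(self):
        trees = random_trees(5, 6, seed=37, model="MIB")
        taxa = dendropy.TaxonNamespace()
        dtrees = [
            dendropy.Tree.get(
                data=t.newick(include_classes=False), schema="newick",
                taxon_namespace=taxa, rooting="force-rooted",
            )
            for t in trees
        ]
        for dt in dtrees:
            dt.encode_bipartitions()
        for i in range(len(trees)):
            for j in range(len(trees)):
                d = branch_score_distance(trees[i], trees[j])
                assert d == pytest.approx(branch_score_distance(trees[j], trees[i]))
                ref = dendropy.calculate.treecompare.euclidean_distance(
                    dtrees[i], dtrees[j]
                )
                assert d == pytest.approx(ref, abs=1e-9)
        for i, j, k in [(0, 1, 2), (1, 3, 4), (2, 4, 5)]:
            assert branch_score_distance(trees[i], trees[k]) <= (
                branch_score_distance(trees[i], trees[j])
                + branch_score_distance(trees[j], trees[k])
                + 1e-12
            )


class TestFrequencies:
    def test_identical_samples_have_unit_frequencies(self):
        tree = parse_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        tables = split_node_shared_frequencies([tree] * 7)
        assert all(v == 1.0 for v in tables.splits.values())
        assert all(v == 1.0 for v in tables.nodes.values())
        assert tables.n_samples == 7

    def test_multifurcation_distinct_from_resolution(self):
        star = parse_tree("(A:0.2,B:0.2,C:0.2);")
        resolved = parse_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        tables = split_node_shared_frequencies([star, resolved])
        root_records = [
            rec for rec in tables.nodes if rec[0] == frozenset("ABC")
        ]
        assert len(root_records) == 2  # trifurcating and bifurcating roots

    def test_half_trace_linearity(self):
        trees = random_trees(5, 8, seed=41)
        full = split_node_shared_frequencies(trees)
        a = split_node_shared_frequencies(trees[:4])
        b = split_node_shared_frequencies(trees[4:])
        for clade, freq in full.splits.items():
            assert freq == pytest.approx(
                (a.splits.get(clade, 0) + b.splits.get(clade, 0)) / 2
            )


class TestMergedDivergenceProbabilities:
    def test_reference_only_trace_gives_zero(self):
        tree = parse_tree("(((A:0.05,B:0.05):0.05,C:0.1):0.1,D:0.2);")
        probs = merged_divergence_probabilities(tree, [tree] * 5)
        assert all(rec["probability"] == 0.0 for rec in probs.values())

    def test_merged_trace_gives_one(self):
        tree = parse_tree("(((A:0.05,B:0.05):0.05,C:0.1):0.1,D:0.2);")
        (pair, merged), *_ = enumerate_neighbor_merges(tree)
        probs = merged_divergence_probabilities(tree, [merged] * 4)
        assert probs[pair]["probability"] == 1.0
        others = [p for p in probs if p != pair]
        assert all(probs[p]["probability"] == 0.0 for p in others)

    def test_mixed_trace_counts(self):
        tree = parse_tree("(((A:0.05,B:0.05):0.05,C:0.1):0.1,D:0.2);")
        (pair, merged), *_ = enumerate_neighbor_merges(tree)
        trace = [merged] * 3 + [tree] * 7
        probs = merged_divergence_probabilities(tree, trace)
        assert probs[pair]["probability"] == pytest.approx(0.3)
        assert probs[pair]["time_gap"] == pytest.approx(0.05)


class TestDiagnostics:
    def test_identical_chains(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=400)
        assert potential_scale_reduction([x, x.copy(), x.copy()]) == (
            pytest.approx(1.0, abs=0.01)
        )
        trees = random_trees(4, 30, seed=43)
        assert average_sd_split_frequencies([trees, list(trees)]) == 0.0

    def test_low_frequency_splits_excluded(self):
        # a split at 5% in every chain is below the 10% threshold
        common = parse_tree("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        rare = parse_tree("((A:0.1,C:0.1):0.1,(B:0.1,D:0.1):0.1);")
        chain = [common] * 19 + [rare]
        asdsf_all = average_sd_split_frequencies([chain, chain], 0.10)
        assert asdsf_all == 0.0  # rare splits at 5% excluded, rest identical

    def test_white_noise_ess_near_length(self):
        rng = np.random.default_rng(7)
        L = 4000
        ess = effective_sample_size(rng.normal(size=L))
        assert ess == pytest.approx(L, rel=0.15)

    def test_ar1_ess_deflation(self):
        # AR(1) with coefficient phi has autocorrelation time (1+phi)/(1-phi)
        rng = np.random.default_rng(11)
        phi = 0.7
        L = 60_000
        x = np.empty(L)
        x[0] = rng.normal()
        eps = rng.normal(size=L)
        for i in range(1, L):
            x[i] = phi * x[i - 1] + eps[i]
        expected = L * (1 - phi) / (1 + phi)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.15)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            potential_scale_reduction([np.arange(10.0)])

    def test_diverged_chains_flagged(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 500)
        b = rng.normal(5.0, 1.0, 500)
        assert potential_scale_reduction([a, b]) > 2.0


class TestMapSummary:
    def test_single_tree_trace(self):
        tree = parse_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        report = map_summary([tree] * 6)
        assert report.map_probability == 1.0
        assert report.map_tree.model_key() == tree.model_key()
        assert report.means["root_height"] == pytest.approx(0.2)
        assert sum(report.n_divergences_probs.values()) == pytest.approx(1.0)

    def test_histogram_and_interval(self, prior_config):
        trace = run_prior_only(prior_config, 4, generations=4000,
                               sample_freq=10, seed=5)
        report = map_summary(trace.samples, burn_in=100)
        assert sum(report.n_divergences_probs.values()) == pytest.approx(1.0)
        lo, hi = report.n_divergences_interval
        assert 1 <= lo <= hi <= 3
        assert "ne_mu" in report.means

    def test_map_heights_are_conditional_means(self):
        a = parse_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        b = parse_tree("((A:0.14,B:0.14):0.1,C:0.24);")
        other = parse_tree("((A:0.1,C:0.1):0.1,B:0.2);")
        report = map_summary([a, b, a, b, other])
        assert report.map_tree.root_height == pytest.approx(0.22)


class TestCalibrationRescaling:
    def test_identity_when_target_equals_mean(self):
        trees = random_trees(4, 6, seed=47)
        mean_root = np.mean([t.root_height for t in trees])
        out = rescale_to_calibration(trees, mean_root)
        for a, b in zip(out, trees):
            assert a == b

    def test_rescaled_mean_matches_target_exactly(self):
        trees = random_trees(4, 6, seed=49)
        out = rescale_to_calibration(trees, 23.07)
        assert np.mean([t.root_height for t in out]) == pytest.approx(23.07)
        # one global factor: tree lengths scale identically, topologies fixed
        factor = 23.07 / np.mean([t.root_height for t in trees])
        for a, b in zip(out, trees):
            assert a.model_key() == b.model_key()
            assert a.tree_length() == pytest.approx(factor * b.tree_length())
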