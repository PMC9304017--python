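"""Coalescent likelihood: closed forms, normalization, oracle agreement."""

import itertools
import math

import numpy as np
import pytest
import scipy.linalg

from genphy.likelihood import (
    BiallelicMatrix,
    LikelihoodEvaluator,
    ModelParams,
    PartialTable,
    branch_generator,
    branch_pullback,
    character_probability,
    combine_partials,
    constant_probability,
    data_log_likelihood,
    leaf_partials,
    root_probability,
)
from genphy.tree import parse_tree, polytomies_to_zero_branches

from conftest import random_trees


def _het_closed_form(ne_mu):
    """P(two copies from one population differ), u=v=mu=1: derived by
    integrating the two-state flip probability over the exponential
    pairwise coalescence time."""
    return 4.0 * ne_mu / (1.0 + 8.0 * ne_mu)


def _all_patterns(species, n=2):
    for reds in itertools.product(range(n + 1), repeat=len(species)):
        yield {s: (n, r) for s, r in zip(species, reds)}


class TestPartials:
    def test_leaf_delta(self):
        table = leaf_partials(2, 1)
        assert table.get(2, 1) == 1.0
        assert table.values.sum() == 1.0
        assert leaf_partials(0, 0).is_neutral
        with pytest.raises(ValueError):
            leaf_partials(2, 3)

    def test_zero_duration_identity(self):
        table = leaf_partials(2, 1)
        out = branch_pullback(table, 0.0, 0.001)
        assert np.array_equal(out.values, table.values)

    def test_single_lineage_flip_closed_form(self):
        # u=v=mu=1: off-diagonal transition probability (1 - e^{-2t})/2
        Q = branch_generator(1, 0.001, 1.0, 1.0, 1.0)
        for t in (0.01, 0.3, 2.0):
            E = scipy.linalg.expm(Q * t)
            assert E[0, 1] == pytest.approx((1 - math.exp(-2 * t)) / 2, rel=1e-12)

    def test_no_coalescence_probability(self):
        # k=2, no mutation: P(still 2 lineages at t) = exp(-t/(2 ne_mu))
        ne = 0.01
        Q = branch_generator(2, ne, 1.0, 1.0, 0.0)
        table = leaf_partials(2, 2)
        for t in (0.005, 0.02):
            out = branch_pullback(table, t, ne, mu=0.0)
            assert out.get(2, 2) == pytest.approx(math.exp(-t / (2 * ne)), rel=1e-9)

    def test_eig_matches_expm(self):
        rng = np.random.default_rng(4)
        for K in (2, 4, 7):
            ne = float(rng.uniform(3e-4, 5e-3))
            Q = branch_generator(K, ne, 1.0, 1.0, 1.0)
            v = rng.random(Q.shape[0])
            t = float(rng.uniform(0.001, 0.1))
            table = branch_pullback(PartialTable(K, v), t, ne)
            direct = scipy.linalg.expm(Q * t) @ v
            assert np.allclose(table.values, np.maximum(direct, 0), atol=1e-10)

    def test_combine_neutral_and_forced(self):
        f = leaf_partials(2, 1)
        assert np.array_equal(
            combine_partials([f, leaf_partials(0, 0)]).values, f.values
        )
        # one red and one green copy: the hypergeometric weight for the
        # only contributing allocation is 1/C(2,1), and the halved entry
        # is exactly what pattern normalization requires downstream
        two = combine_partials([leaf_partials(1, 1), leaf_partials(1, 0)])
        assert two.get(2, 1) == pytest.approx(0.5)

    def test_combine_order_and_association_invariance(self):
        rng = np.random.default_rng(8)
        tables = [PartialTable(k, rng.random(k * (k + 3) // 2)) for k in (2, 3, 2)]
        a = combine_partials(tables)
        b = combine_partials(tables[::-1])
        c = combine_partials([tables[1], combine_partials([tables[2], tables[0]])])
        assert np.allclose(a.values, b.values, atol=1e-12)
        assert np.allclose(a.values, c.values, atol=1e-12)

    def test_root_stationary_law(self):
        assert root_probability(leaf_partials(1, 1), 0.001) == pytest.approx(0.5)
        assert root_probability(leaf_partials(1, 1), 0.001, u=3.0, v=1.0) == (
            pytest.approx(0.25)
        )  # pi green = 3/4, red observed


class TestCharacterProbability:
    def test_single_population_heterozygosity(self):
        tree = parse_tree("(A:0.05,B:0.05);")
        for ne in (0.0005, 0.001, 0.01):
            p = character_probability(tree, ModelParams(ne_mu=ne), {"A": (2, 1)})
            assert p == pytest.approx(_het_closed_form(ne), rel=1e-9)

    def test_patterns_sum_to_one(self):
        params = ModelParams(ne_mu=0.002)
        for tree in random_trees(4, 4, seed=23):
            total = sum(
                character_probability(tree, params, pat)
                for pat in _all_patterns(tree.tip_labels)
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_sum_to_one_asymmetric_rates(self):
        params = ModelParams(ne_mu=0.003, u=2.0, v=0.5)
        tree = parse_tree("((A:0.02,B:0.02):0.03,C:0.05);")
        total = sum(
            character_probability(tree, params, pat)
            for pat in _all_patterns(tree.tip_labels)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_multifurcation_equals_zero_branch_expansion(self):
        params = ModelParams(ne_mu=0.001)
        for newick in [
            "(A:0.2,B:0.2,C:0.2);",
            "((A:0.05,B:0.05,C:0.05):0.1,(D:0.1,E:0.1):0.05);",
        ]:
            tree = parse_tree(newick)
            binary = polytomies_to_zero_branches(tree)
            for pat in _all_patterns(tree.tip_labels):
                pa = character_probability(tree, params, pat)
                pb = character_probability(binary, params, pat)
                assert abs(pa - pb) < 1e-10

    def test_degenerate_recent_root(self):
        # root height and ne -> 0: all copies share one state
        tree = parse_tree("(A:1e-8,B:1e-8);")
        params = ModelParams(ne_mu=1e-8)
        p_same = character_probability(
            tree, params, {"A": (2, 0), "B": (2, 0)}
        ) + character_probability(tree, params, {"A": (2, 2), "B": (2, 2)})
        assert p_same == pytest.approx(1.0, abs=1e-5)

    def test_unknown_species_rejected(self):
        tree = parse_tree("(A:0.05,B:0.05);")
        with pytest.raises(ValueError, match="unknown species"):
            character_probability(tree, ModelParams(), {"Z": (2, 1)})


class TestConstantProbability:
    def test_complement_of_heterozygosity(self):
        tree = parse_tree("(A:0.05,B:0.05);")
        ne = 0.001
        p = constant_probability(tree, ModelParams(ne_mu=ne), {"A": 2})
        assert p == pytest.approx(1.0 - _het_closed_form(ne), rel=1e-9)

    def test_decreases_with_root_height(self):
        ne = 0.001
        values = []
        for h in (0.01, 0.05, 0.1, 0.3):
            tree = parse_tree(f"(A:{h},B:{h});")
            values.append(
                constant_probability(
                    tree, ModelParams(ne_mu=ne), {"A": 2, "B": 2}
                )
            )
        assert all(a > b for a, b in zip(values, values[1:]))


class TestDataLogLikelihood:
    def test_empty_matrix_raises_no_term(self):
        tree = parse_tree("(A:0.05,B:0.05);")
        data = BiallelicMatrix(
            ("A", "B"), np.zeros((0, 2), dtype=int), np.zeros((0, 2), dtype=int)
        )
        assert data_log_likelihood(tree, ModelParams(), data) == 0.0

    def test_pattern_collapsing_matches_direct_sum(self):
        tree = parse_tree("((A:0.02,B:0.02):0.02,C:0.04);")
        params = ModelParams(ne_mu=0.002)
        rng = np.random.default_rng(3)
        r = rng.integers(0, 3, size=(60, 3))
        n = np.full((60, 3), 2)
        data = BiallelicMatrix(("A", "B", "C"), n, r)
        lnl = data_log_likelihood(tree, params, data)
        direct = sum(
            math.log(
                character_probability(
                    tree, params, {s: (2, int(r[i, j])) for j, s in enumerate("ABC")}
                )
            )
            for i in range(60)
        )
        assert lnl == pytest.approx(direct, rel=1e-10)

    def test_variable_only_correction_value(self):
        tree = parse_tree("(A:0.05,B:0.05);")
        params = ModelParams(ne_mu=0.001)
        n = np.full((3, 2), 2)
        r = np.array([[1, 0], [2, 0], [1, 2]])
        data = BiallelicMatrix(("A", "B"), n, r, variable_only=True)
        lnl = data_log_likelihood(tree, params, data)
        p_const = constant_probability(tree, params, {"A": 2, "B": 2})
        direct = sum(
            math.log(
                character_probability(
                    tree, params, {"A": (2, int(ra)), "B": (2, int(rb))}
                )
                / (1.0 - p_const)
            )
            for ra, rb in r
        )
        assert lnl == pytest.approx(direct, rel=1e-10)

    def test_true_tree_beats_perturbed_tree(self):
        from genphy.simulate import SimStudyConfig, simulate_matrix
        from genphy.priors import PriorConfig

        rng = np.random.default_rng(17)
        tree = parse_tree("((A:0.02,B:0.02):0.08,C:0.1);")
        params = ModelParams(ne_mu=0.001)
        wins = 0
        for _ in range(5):
            data = simulate_matrix(
                tree, params, SimStudyConfig(n_species=3, m=1000), rng
            )
            perturbed = parse_tree("((A:0.06,B:0.06):0.04,C:0.1);")
            wins += data_log_likelihood(tree, params, data) > data_log_likelihood(
                perturbed, params, data
            )
        assert wins >= 3


class TestVariableOnlyBiasCorrection:
    def test_corrected_mle_unbiased_uncorrected_biased(self):
        """Filtering to variable characters inflates divergence unless the
        likelihood conditions on variability: grid-search MLE root heights
        on 2-tip data, with and without the correction."""
        from genphy.simulate import SimStudyConfig, simulate_matrix
        from genphy.priors import PriorConfig

        rng = np.random.default_rng(29)
        true_h = 0.02
        tree = parse_tree(f"(A:{true_h},B:{true_h});")
        params = ModelParams(ne_mu=0.001)
        grid = np.linspace(0.005, 0.08, 40)
        mle_corr, mle_raw = [], []
        for _ in range(6):
            full = simulate_matrix(
                tree, params, SimStudyConfig(n_species=2, m=4000), rng
            )
            var = full.drop_constant()
            raw = BiallelicMatrix(var.species, var.n, var.r, variable_only=False)
            for target, matrix in ((mle_corr, var), (mle_raw, raw)):
                lnls = []
                for h in grid:
                    cand = parse_tree(f"(A:{h},B:{h});")
                    lnls.append(data_log_likelihood(cand, params, matrix))
                target.append(grid[int(np.argmax(lnls))])
        bias_corr = np.mean(mle_corr) - true_h
        bias_raw = np.mean(mle_raw) - true_h
        assert abs(bias_corr) < 0.006
        assert bias_raw > 0.015  # strong upward bias without the correction


class TestMonteCarloOracle:
    def test_three_tip_pattern_probabilities(self):
        """Analytic probabilities vs forward gene-tree simulation."""
        from genphy.simulate import evolve_character, sample_gene_tree

        rng = np.random.default_rng(41)
        tree = parse_tree("((A:0.03,B:0.03):0.05,C:0.08);")
        ne = 0.004
        params = ModelParams(ne_mu=ne)
        n_sim = 30000
        counts = {}
        for _ in range(n_sim):
            gt = sample_gene_tree(tree, ne, 2, rng)
            pat = evolve_character(gt, rng=rng)
            key = tuple(pat[s][1] for s in ("A", "B", "C"))
            counts[key] = counts.get(key, 0) + 1
        n_checked = n_outside = 0
        for key, count in counts.items():
            p = character_probability(
                tree, params, {s: (2, key[i]) for i, s in enumerate("ABC")}
            )
            se = math.sqrt(p * (1 - p) / n_sim)
            n_checked += 1
            if abs(count / n_sim - p) > 3 * se:
                n_outside += 1
        assert n_checked >= 15
        # with ~27 patterns, even one 3-sigma excursion is unusual
        assert n_outside <= 1
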