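"""Tree data model: parsing, height classes, merge/split, enumeration."""

import itertools

import numpy as np
import pytest

from genphy.tree import (
    GeneralizedTree,
    RootClassError,
    SplitAllocation,
    TreeError,
    count_tree_models,
    enumerate_neighbor_merges,
    enumerate_tree_models,
    height_bounds,
    merge_height_classes,
    parse_tree,
    polytomies_to_zero_branches,
    split_height_class,
)

from conftest import random_trees


class TestParsing:
    @pytest.mark.parametrize(
        "newick,n_tips,n_internal,n_classes,heights",
        [
            ("((A:0.1,B:0.1):0.1,C:0.2);", 3, 2, 2, {0.1, 0.2}),
            (
                "((A:0.1,B:0.1)[&hc=1]:0.1,(C:0.1,D:0.1)[&hc=1]:0.1)[&hc=2];",
                4, 3, 2, {0.1, 0.2},
            ),
            ("(A:0.2,B:0.2,C:0.2);", 3, 1, 1, {0.2}),
        ],
    )
    def test_examples(self, newick, n_tips, n_internal, n_classes, heights):
        tree = parse_tree(newick)
        assert tree.n_tips == n_tips
        assert len(tree.internal_nodes()) == n_internal
        assert tree.n_classes == n_classes
        assert set(np.round(list(tree.class_heights.values()), 12)) == heights

    def test_non_ultrametric_rejected(self):
        with pytest.raises(TreeError, match="ultrametric"):
            parse_tree("((A:0.1,B:0.15):0.1,C:0.2);")

    def test_shared_class_height_mismatch_names_node(self):
        bad = "((A:0.1,B:0.1)[&hc=1]:0.1,(C:0.15,D:0.15)[&hc=1]:0.05)[&hc=2];"
        with pytest.raises(TreeError, match="height class"):
            parse_tree(bad)

    def test_missing_branch_lengths(self):
        with pytest.raises(TreeError):
            parse_tree("((A,B),C);")

    def test_round_trip_random_trees(self):
        for tree in random_trees(6, 8, seed=3):
            again = parse_tree(tree.newick())
            assert again == tree
            assert parse_tree(again.newick()) == tree

    def test_round_trip_preserves_sharing(self):
        tree = parse_tree(
            "((A:0.1,B:0.1)[&hc=1]:0.1,(C:0.1,D:0.1)[&hc=1]:0.1)[&hc=2];"
        )
        again = parse_tree(tree.newick())
        assert again.n_classes == 2
        assert again.model_key() == tree.model_key()


class TestHeightBounds:
    def test_cherry_class_bounded_by_root(self):
        tree = parse_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        cid = next(c for c in tree.class_heights if tree.class_heights[c] < 0.15)
        lower, upper = height_bounds(tree, cid)
        assert (lower, upper) == (0.0, 0.2)

    def test_shared_cherry_class(self):
        tree = parse_tree(
            "((A:0.1,B:0.1)[&hc=1]:0.1,(C:0.1,D:0.1)[&hc=1]:0.1)[&hc=2];"
        )
        cid = next(c for c in tree.class_heights if tree.class_heights[c] < 0.15)
        assert tuple(height_bounds(tree, cid)) == (0.0, 0.2)

    def test_middle_class_bounded_both_sides(self):
        tree = parse_tree("(((A:0.05,B:0.05):0.05,C:0.1):0.1,D:0.2);")
        mid = next(
            c for c, h in tree.class_heights.items() if abs(h - 0.1) < 1e-12
        )
        lower, upper = height_bounds(tree, mid)
        assert (lower, upper) == pytest.approx((0.05, 0.2))

    def test_root_class_signaled_distinctly(self):
        tree = parse_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        with pytest.raises(RootClassError):
            height_bounds(tree, tree.root_class())

    def test_interior_moves_preserve_validity(self):
        for tree in random_trees(6, 5, seed=11):
            for cid in tree.class_heights:
                if cid == tree.root_class():
                    continue
                lower, upper = height_bounds(tree, cid)
                for frac in (0.25, 0.75):
                    moved = tree.copy()
                    moved.class_heights[cid] = lower + frac * (upper - lower)
                    moved.validate()


class TestMergeSplit:
    def test_merge_cherries_creates_shared_class(self):
        tree = parse_tree("((A:0.09,B:0.09):0.11,(C:0.1,D:0.1):0.1);")
        order = tree.classes_by_height()
        merged = merge_height_classes(tree, order[0], order[1])
        assert merged.n_classes == 2
        cherry_class = [
            c for c in merged.class_heights if c != merged.root_class()
        ]
        assert len(cherry_class) == 1
        members = merged.class_members()[cherry_class[0]]
        assert len(members) == 2
        assert merged.class_heights[cherry_class[0]] == pytest.approx(0.1)

    def test_parent_child_merge_creates_multifurcation(self):
        tree = parse_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        order = tree.classes_by_height()
        merged = merge_height_classes(tree, order[0], order[1])
        assert merged.n_classes == 1
        assert len(merged.root.children) == 3
        assert merged.root_height == pytest.approx(0.2)

    def test_non_neighbors_rejected(self):
        tree = parse_tree("(((A:0.05,B:0.05):0.05,C:0.1):0.1,D:0.2);")
        order = tree.classes_by_height()
        with pytest.raises(TreeError, match="neighbor"):
            merge_height_classes(tree, order[0], order[2])

    def test_split_detaches_polytomy_children(self):
        tree = parse_tree("(A:0.2,B:0.2,C:0.2);")
        root_clade = tree.root.clade()
        alloc = SplitAllocation(
            resolves={root_clade: [[frozenset("A"), frozenset("B")]]}
        )
        out = split_height_class(tree, tree.root_class(), alloc, 0.12)
        assert out.n_classes == 2
        assert out.model_key() == parse_tree("((A:0.12,B:0.12):0.08,C:0.2);").model_key()

    def test_split_then_merge_is_identity(self):
        for tree in random_trees(6, 10, seed=13):
            merges = enumerate_neighbor_merges(tree)
            for (young, old), merged in merges:
                # re-split the merged class back to the original state;
                # siblings deleted together become multiple detached
                # subsets of their common parent
                deleted = [
                    n for n in tree.class_members()[young]
                    if n.parent.class_id == old
                ]
                moves = [
                    n.clade() for n in tree.class_members()[young]
                    if n.parent.class_id != old
                ]
                resolves: dict = {}
                for n in deleted:
                    resolves.setdefault(n.parent.clade(), []).append(
                        frozenset(c.clade() for c in n.children)
                    )
                alloc = SplitAllocation(moves=moves, resolves=resolves)
                back = split_height_class(
                    merged, old, alloc, tree.class_heights[young]
                )
                assert back == tree

    def test_split_errors(self):
        tree = parse_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        cid = tree.classes_by_height()[0]
        node = tree.class_members()[cid][0].clade()
        with pytest.raises(TreeError, match="empty"):
            split_height_class(tree, cid, SplitAllocation(), 0.05)
        with pytest.raises(TreeError, match="old class"):
            split_height_class(tree, cid, SplitAllocation(moves=[node]), 0.05)
        with pytest.raises(TreeError):
            split_height_class(tree, cid, SplitAllocation(moves=[node]), 0.5)


class TestNeighborMerges:
    def test_star_tree_has_no_merges(self):
        assert enumerate_neighbor_merges(parse_tree("(A:0.2,B:0.2,C:0.2);")) == []

    def test_caterpillar_three_heights(self):
        tree = parse_tree("(((A:0.05,B:0.05):0.05,C:0.1):0.1,D:0.2);")
        merges = enumerate_neighbor_merges(tree)
        assert len(merges) == 2
        for _, merged in merges:
            merged.validate()
            assert merged.n_classes == 2

    def test_count_equals_adjacent_pairs(self):
        for tree in random_trees(7, 6, seed=17):
            merges = enumerate_neighbor_merges(tree)
            assert len(merges) == tree.n_classes - 1
            for _, merged in merges:
                merged.validate()


class TestZeroBranchExpansion:
    def test_binary_tree_unchanged(self):
        tree = parse_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        out = polytomies_to_zero_branches(tree)
        assert out.model_key() == tree.model_key()

    @pytest.mark.parametrize("n_children", [3, 5])
    def test_polytomy_resolved(self, n_children):
        tips = ",".join(f"t{i}:0.2" for i in range(n_children))
        tree = parse_tree(f"({tips});")
        out = polytomies_to_zero_branches(tree)
        assert all(len(n.children) == 2 for n in out.internal_nodes())
        assert len(out.internal_nodes()) == n_children - 1
        assert out.tree_length() == pytest.approx(tree.tree_length())
        zero = sum(
            1 for n in out.internal_nodes() if n.parent is not None
            and out.branch_length(n) == 0.0
        )
        assert zero == n_children - 2


# -- independent enumeration oracle -----------------------------------------


def _oracle_models(labels):
    """Independently coded enumerator: build trees by recursive tip-set
    partitioning, enumerate height-class partitions by brute force over
    all set partitions, and keep those admitting a strictly decreasing
    height assignment (checked by topological sort over the precedence
    relation instead of cycle detection)."""

    def trees(tips):
        tips = tuple(sorted(tips))
        if len(tips) == 1:
            yield tips[0]
            return
        # partitions of the tip set into >= 2 blocks
        first, rest = tips[0], tips[1:]
        for assignment in itertools.product(range(len(tips)), repeat=len(rest)):
            blocks = {}
            blocks.setdefault(0, []).append(first)
            for tip, b in zip(rest, assignment):
                blocks.setdefault(b, []).append(tip)
            if len(blocks) < 2:
                continue
            norm = tuple(sorted(tuple(sorted(b)) for b in blocks.values()))
            if norm != tuple(sorted(norm)):
                continue
            yield from (
                ("node", combo)
                for combo in itertools.product(*[list(trees(b)) for b in norm])
            )

    def clades(structure):
        if isinstance(structure, str):
            return frozenset([structure]), []
        tipset = frozenset()
        nodes = []
        children = []
        for sub in structure[1]:
            c, sub_nodes = clades(sub)
            tipset |= c
            children.append(c)
            nodes.extend(sub_nodes)
        nodes.append((tipset, frozenset(children)))
        return tipset, nodes

    seen = set()
    for structure in trees(labels):
        _, nodes = clades(structure)
        key = frozenset(nodes)
        if key in seen:
            continue
        seen.add(key)
        idx = list(range(len(nodes)))
        above = {
            i: {j for j in idx if j != i and nodes[i][0] < nodes[j][0]}
            for i in idx
        }
        for partition in _all_set_partitions(idx):
            block_of = {}
            for bi, block in enumerate(partition):
                for i in block:
                    block_of[i] = bi
            ok = all(
                block_of[i] != block_of[j] for i in idx for j in above[i]
            )
            if not ok:
                continue
            # greedy topological ordering of blocks by the ancestor relation
            order_edges = {
                (block_of[j], block_of[i])
                for i in idx for j in above[i]
                if block_of[i] != block_of[j]
            }
            n_blocks = len(partition)
            remaining = set(range(n_blocks))
            ok = True
            while remaining:
                sinks = [
                    b for b in remaining
                    if not any((b, other) in order_edges for other in remaining)
                ]
                if not sinks:
                    ok = False
                    break
                remaining -= set(sinks)
            if ok:
                part_key = frozenset(
                    frozenset(nodes[i] for i in block) for block in partition
                )
                yield (key, part_key)


def _all_set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _all_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


class TestModelCounting:
    def test_small_counts(self):
        assert count_tree_models(2) == 1
        assert count_tree_models(3) == 4

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_matches_independent_oracle(self, n):
        labels = tuple(f"t{i}" for i in range(n))
        oracle = set(_oracle_models(labels))
        mine = set(enumerate_tree_models(labels))
        assert len(mine) == count_tree_models(n)
        assert len(oracle) == len(mine)

    def test_bounds(self):
        with pytest.raises(TreeError):
            count_tree_models(9)

    def test_operations_emit_valid_trees(self):
        for tree in random_trees(6, 6, seed=19):
            tree.validate()
            for _, merged in enumerate_neighbor_merges(tree):
                merged.validate()
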