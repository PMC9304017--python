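"""Generalized trees: shared divergences, multifurcations, merges.

Builds a five-species tree in which two cherries share one divergence
time, then explores the discrete neighborhood reachable by merging
adjacent divergence times.
"""

from genphy import (
    count_tree_models,
    enumerate_neighbor_merges,
    height_bounds,
    parse_tree,
)

# [&hc=k] comments assign internal nodes to shared height classes
newick = "(((A:0.02,B:0.02)[&hc=1]:0.08,(C:0.02,D:0.02)[&hc=1]:0.08)[&hc=2]:0.1,E:0.2)[&hc=3];"
tree = parse_tree(newick)

print(f"tips: {tree.n_tips}, internal nodes: {len(tree.internal_nodes())}, "
      f"divergence times: {tree.n_classes}")
# 3 divergence times for 4 internal nodes: the two cherries diverged in
# one shared event at 0.02 expected substitutions per site
for cid in tree.classes_by_height():
    members = tree.class_members()[cid]
    print(f"  time {tree.class_heights[cid]:.3f}: "
          f"{len(members)} node(s) {[sorted(m.clade()) for m in members]}")

lower, upper = height_bounds(tree, tree.classes_by_height()[1])
print(f"the middle divergence may slide anywhere in ({lower}, {upper})")

print("\nmerging adjacent divergence times (each merge is one candidate "
      "shared-divergence scenario):")
for (young, old), merged in enumerate_neighbor_merges(tree):
    print(f"  {tree.class_heights[young]:.3f}+{tree.class_heights[old]:.3f} -> "
          f"{merged.n_classes} times, newick {merged.newick(precision=3)}")

n = count_tree_models(5)
print(f"\ndiscrete model space for 5 tips: {n} (topology, sharing) classes")
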