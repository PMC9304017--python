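"""Rooted trees with shared and multifurcating divergences.

A *generalized tree* is a rooted, potentially multifurcating topology over N
tips in which every internal node is assigned to one of ``1 <= n_classes <=
N - 1`` divergence-time classes.  All nodes in a class share one height
(time before present, in expected substitutions per site), so two or more
nodes mapped to the same class model a single, shared divergence event, and
a node with three or more children models a multifurcation.  The height of
every node is strictly less than its parent's height, tips sit at height 0,
and branch lengths are derived quantities (parent height minus child
height); class heights are the single source of truth.

Serialization uses an annotated newick dialect in which a node comment
``[&hc=<int>]`` gives the (1-based) height-class index of an internal node;
nodes carrying the same index share a divergence time.  Internal nodes
without a comment get their own class.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "TreeError",
    "RootClassError",
    "HeightInterval",
    "Node",
    "GeneralizedTree",
    "SplitAllocation",
    "parse_tree",
    "write_tree",
    "height_bounds",
    "merge_height_classes",
    "split_height_class",
    "enumerate_neighbor_merges",
    "polytomies_to_zero_branches",
    "count_tree_models",
    "enumerate_tree_models",
]

HEIGHT_TOL = 1e-9


class TreeError(ValueError):
    """Raised for structurally invalid trees or malformed newick input."""


class RootClassError(TreeError):
    """Raised when a bounded height interval is requested for the root class.

    The root's height has no upper bound inside the tree (its prior
    provides the only constraint), so it is signaled distinctly.
    """


class HeightInterval:
    """Open interval ``(lower, upper)`` of legal heights for a class."""

    __slots__ = ("lower", "upper")

    def __init__(self, lower: float, upper: float):
        if not (0.0 <= lower < upper):
            raise TreeError(f"invalid height interval ({lower}, {upper})")
        self.lower = float(lower)
        self.upper = float(upper)

    def __contains__(self, h: float) -> bool:
        return self.lower < h < self.upper

    def __iter__(self):
        return iter((self.lower, self.upper))

    def __repr__(self):
        return f"HeightInterval({self.lower!r}, {self.upper!r})"


class Node:
    """One node of a :class:`GeneralizedTree`.

    Tips carry a ``label`` and sit at height 0; internal nodes carry a
    ``class_id`` into the tree's ``class_heights`` map.
    """

    __slots__ = ("children", "parent", "label", "class_id", "_tree")

    def __init__(self, label: str | None = None, class_id: int | None = None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.label = label
        self.class_id = class_id
        self._tree: GeneralizedTree | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def height(self) -> float:
        if self.is_tip:
            return 0.0
        return self._tree.class_heights[self.class_id]

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def clade(self) -> frozenset:
        """Frozen set of tip labels descending from (or at) this node."""
        if self.is_tip:
            return frozenset((self.label,))
        return frozenset(lab for c in self.children for lab in c.clade())

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def __repr__(self):
        if self.is_tip:
            return f"<Tip {self.label}>"
        return f"<Node hc={self.class_id} children={len(self.children)}>"


class GeneralizedTree:
    """A rooted tree with height-class (shared divergence) structure.

    Parameters
    ----------
    root
        Root node of a fully linked node structure.
    class_heights
        Mapping from class id to height.  Every internal node's
        ``class_id`` must be a key of this mapping.
    allow_zero_branches
        Permit ``child height == parent height`` (used only for the
        zero-branch bifurcating expansion of multifurcations).
    """

    def __init__(
        self,
        root: Node,
        class_heights: dict[int, float],
        allow_zero_branches: bool = False,
        validate: bool = True,
        tip_labels: tuple | None = None,
    ):
        self.root = root
        self.class_heights = dict(class_heights)
        self.allow_zero_branches = allow_zero_branches
        # trees are immutable once constructed (operations build new
        # instances), so the preorder node list is computed once
        nodes: list[Node] = []
        stack = [root]
        while stack:
            node = stack.pop()
            node._tree = self
            nodes.append(node)
            stack.extend(reversed(node.children))
        self._nodes = nodes
        if tip_labels is None:
            tip_labels = tuple(sorted(n.label for n in nodes if not n.children))
        self.tip_labels = tip_labels
        if validate:
            self.validate()

    # -- basic structure ------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_classes(self) -> int:
        return len(self.class_heights)

    @property
    def root_height(self) -> float:
        return self.root.height

    def preorder(self) -> Iterator[Node]:
        return iter(self._nodes)

    def postorder(self) -> Iterator[Node]:
        return reversed(self._nodes)

    def internal_nodes(self) -> list[Node]:
        return [n for n in self._nodes if n.children]

    def tips(self) -> list[Node]:
        return [n for n in self._nodes if not n.children]

    def class_members(self) -> dict[int, list[Node]]:
        members: dict[int, list[Node]] = {cid: [] for cid in self.class_heights}
        for node in self.internal_nodes():
            members[node.class_id].append(node)
        return members

    def classes_by_height(self) -> list[int]:
        """Class ids sorted youngest to oldest (ties broken by id)."""
        return sorted(self.class_heights, key=lambda c: (self.class_heights[c], c))

    def root_class(self) -> int:
        return self.root.class_id

    def branch_length(self, node: Node) -> float:
        if node.parent is None:
            return 0.0
        return node.parent.height - node.height

    def tree_length(self) -> float:
        return sum(self.branch_length(n) for n in self.preorder() if n.parent is not None)

    # -- identity keys ---------------------------------------------------

    def node_records(self) -> frozenset:
        """Node identities: (clade, frozenset of child clades).

        The child-clade set distinguishes a multifurcating node from any
        bifurcating resolution of it over the same tip set.
        """
        recs = []
        for node in self.internal_nodes():
            recs.append((node.clade(), frozenset(c.clade() for c in node.children)))
        return frozenset(recs)

    def topology_key(self) -> frozenset:
        return self.node_records()

    def model_key(self) -> tuple:
        """Canonical key for (topology, height-sharing pattern).

        Two trees have equal keys iff they have the same multifurcating
        topology and the same partition of nodes into height classes,
        regardless of the numerical heights.
        """
        members = self.class_members()
        partition = frozenset(
            frozenset((n.clade(), frozenset(c.clade() for c in n.children)) for n in nodes)
            for nodes in members.values()
        )
        return (self.node_records(), partition)

    def split_key(self) -> frozenset:
        """Set of nontrivial splits (clades below internal branches)."""
        return frozenset(
            n.clade() for n in self.internal_nodes() if n.parent is not None
        )

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        n_tips = self.n_tips
        if n_tips < 2:
            raise TreeError("a tree needs at least two tips")
        internals = self.internal_nodes()
        n_internal = len(internals)
        if not (1 <= self.n_classes <= n_internal <= n_tips - 1):
            raise TreeError(
                f"need 1 <= n_classes ({self.n_classes}) <= n_internal "
                f"({n_internal}) <= N-1 ({n_tips - 1})"
            )
        seen_tips = [t.label for t in self.tips()]
        if len(seen_tips) != len(set(seen_tips)):
            raise TreeError("duplicate tip labels")
        members = self.class_members()
        for cid, nodes in members.items():
            if not nodes:
                raise TreeError(f"height class {cid} has no node assigned to it")
        if self.root.parent is not None:
            raise TreeError("root has a parent")
        for node in internals:
            if len(node.children) < 2:
                raise TreeError(f"internal node {set(node.clade())} has < 2 children")
            if node.class_id not in self.class_heights:
                raise TreeError(
                    f"node {set(node.clade())} maps to unknown class {node.class_id}"
                )
            h = node.height
            if h <= 0.0 and not (self.allow_zero_branches and h == 0.0):
                raise TreeError(f"internal node {set(node.clade())} at height {h} <= 0")
            for child in node.children:
                if child.parent is not node:
                    raise TreeError("broken parent link")
                if self.allow_zero_branches:
                    ok = child.height <= h
                else:
                    ok = child.height < h
                if not ok:
                    raise TreeError(
                        f"node {set(child.clade())} height {child.height} not below "
                        f"its parent's height {h}"
                    )
        # no node shares a class with an ancestor (strict heights already
        # imply it, but check structurally for the zero-branch case too)
        for node in internals:
            anc = node.parent
            while anc is not None:
                if anc.class_id == node.class_id and not self.allow_zero_branches:
                    raise TreeError("node shares a height class with an ancestor")
                anc = anc.parent

    # -- copying ---------------------------------------------------------

    def copy(self) -> "GeneralizedTree":
        def rebuild(node: Node) -> Node:
            new = Node(label=node.label, class_id=node.class_id)
            for child in node.children:
                clone = rebuild(child)
                clone.parent = new
                new.children.append(clone)
            return new

        return GeneralizedTree(
            rebuild(self.root),
            dict(self.class_heights),
            allow_zero_branches=self.allow_zero_branches,
            validate=False,
            tip_labels=self.tip_labels,
        )

    # -- serialization ---------------------------------------------------

    def newick(self, include_classes: bool = True, precision: int = 17) -> str:
        """Annotated newick string; classes appear as ``[&hc=<rank>]``.

        Class indices are 1-based ranks in height order (youngest first),
        so the dialect round-trips through any comment-preserving parser.
        """
        rank = {cid: i + 1 for i, cid in enumerate(self.classes_by_height())}
        fmt = f"%.{precision}g"

        def render(node: Node) -> str:
            if node.is_tip:
                s = node.label
            else:
                s = "(" + ",".join(render(c) for c in node.children) + ")"
                if include_classes:
                    s += f"[&hc={rank[node.class_id]}]"
            if node.parent is not None:
                s += ":" + (fmt % self.branch_length(node))
            return s

        return render(self.root) + ";"

    def __repr__(self):
        return f"<GeneralizedTree N={self.n_tips} n_classes={self.n_classes}>"

    def __eq__(self, other):
        if not isinstance(other, GeneralizedTree):
            return NotImplemented
        if self.model_key() != other.model_key():
            return False
        mine = {frozenset(m.clade() for m in nodes): self.class_heights[c]
                for c, nodes in self.class_members().items()}
        theirs = {frozenset(m.clade() for m in nodes): other.class_heights[c]
                  for c, nodes in other.class_members().items()}
        return all(math.isclose(mine[k], theirs[k], rel_tol=0, abs_tol=HEIGHT_TOL)
                   for k in mine)

    __hash__ = None


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------


def _extract_hc(comments: Sequence[str]) -> int | None:
    for comment in comments:
        body = comment.strip().lstrip("&")
        for field in body.split(","):
            if "=" in field:
                key, _, value = field.partition("=")
                if key.strip() == "hc":
                    try:
                        return int(value)
                    except ValueError as exc:
                        raise TreeError(f"malformed height-class comment {comment!r}") from exc
    return None


def parse_tree(text: str) -> GeneralizedTree:
    """Parse an annotated newick string into a :class:`GeneralizedTree`.

    Branch lengths must describe an ultrametric tree (all tips equidistant
    from the root, to within ``1e-9``).  A node comment ``[&hc=<int>]``
    assigns the node to a shared height class; internal nodes without a
    comment each get their own class.  Nodes assigned to one class must sit
    at equal heights.
    """
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        rooting="force-rooted",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
        extract_comment_metadata=False,
    )
    # depths from root
    depth = {dtree.seed_node: 0.0}
    for edge in dtree.preorder_edge_iter():
        if edge.head_node is dtree.seed_node:
            continue
        length = edge.length
        if length is None:
            raise TreeError("newick input lacks branch lengths")
        depth[edge.head_node] = depth[edge.tail_node] + float(length)
    leaf_depths = [depth[leaf] for leaf in dtree.leaf_node_iter()]
    max_depth = max(leaf_depths)
    for leaf, d in zip(dtree.leaf_node_iter(), leaf_depths):
        if abs(d - max_depth) > HEIGHT_TOL:
            raise TreeError(
                f"non-ultrametric input: tip {leaf.taxon.label!r} at depth {d}, "
                f"expected {max_depth}"
            )

    class_heights: dict[int, float] = {}
    next_auto = [0]

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            return Node(label=dnode.taxon.label)
        height = max_depth - depth[dnode]
        hc = _extract_hc(dnode.comments)
        if hc is not None:
            cid = ("hc", hc)
        else:
            next_auto[0] += 1
            cid = ("auto", next_auto[0])
        node = Node(class_id=cid)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        if cid in class_heights:
            if abs(class_heights[cid] - height) > HEIGHT_TOL:
                raise TreeError(
                    f"node {sorted(l.taxon.label for l in dnode.leaf_iter())} in "
                    f"height class {cid[1]} sits at height {height}, but the class "
                    f"height is {class_heights[cid]}"
                )
        else:
            class_heights[cid] = height
        return node

    root = convert(dtree.seed_node)
    # renumber class ids to plain ints, youngest first
    order = sorted(class_heights, key=lambda c: class_heights[c])
    remap = {cid: i for i, cid in enumerate(order)}
    for node in root.preorder():
        if not node.is_tip:
            node.class_id = remap[node.class_id]
    heights = {remap[c]: h for c, h in class_heights.items()}
    try:
        return GeneralizedTree(root, heights)
    except TreeError as exc:
        raise TreeError(f"invalid tree in newick input: {exc}") from exc


def write_tree(tree: GeneralizedTree, **kwargs) -> str:
    return tree.newick(**kwargs)


# ---------------------------------------------------------------------------
# height classes: bounds, merge, split
# ---------------------------------------------------------------------------


def height_bounds(tree: GeneralizedTree, class_id: int) -> HeightInterval:
    """Open interval of heights the class can move to without breaking
    any invariant: (oldest child height, youngest parent height) over the
    nodes mapped to the class."""
    if class_id not in tree.class_heights:
        raise TreeError(f"unknown height class {class_id}")
    if class_id == tree.root_class():
        raise RootClassError("the root class has no parent-bounded interval")
    members = tree.class_members()[class_id]
    lower = max(child.height for node in members for child in node.children)
    upper = min(node.parent.height for node in members)
    return HeightInterval(lower, upper)


def neighbor_class_pairs(tree: GeneralizedTree) -> list[tuple[int, int]]:
    """(young, old) class-id pairs adjacent in the sorted height order."""
    order = tree.classes_by_height()
    return [(order[i], order[i + 1]) for i in range(len(order) - 1)]


def merge_height_classes(
    tree: GeneralizedTree, class_young: int, class_old: int,
    validate: bool = True,
) -> GeneralizedTree:
    """Merge two neighboring height classes into one shared divergence.

    All nodes of the younger class are raised to the older class's height.
    A raised node whose parent belongs to the older class would end up at
    its parent's height; it is deleted and its children are reattached to
    the parent, creating (or widening) a multifurcation.  The result has
    one height class fewer.
    """
    pairs = neighbor_class_pairs(tree)
    if (class_young, class_old) not in pairs:
        raise TreeError(
            f"classes {class_young} and {class_old} are not neighboring "
            f"(young, old) classes"
        )
    new = tree.copy()
    members = new.class_members()[class_young]
    for node in members:
        if node.parent is not None and node.parent.class_id == class_old:
            parent = node.parent
            parent.remove_child(node)
            for child in list(node.children):
                node.remove_child(child)
                parent.add_child(child)
        else:
            node.class_id = class_old
    del new.class_heights[class_young]
    out = GeneralizedTree(new.root, new.class_heights, validate=False,
                          tip_labels=tree.tip_labels)
    if validate:
        out.validate()
    return out


class SplitAllocation:
    """How to split one height class into two.

    ``moves`` lists the clades of member nodes that move to the new,
    younger class.  ``resolves`` maps the clade of a multifurcating
    member to one or more *disjoint* subsets (each of size >= 2, jointly
    proper) of its child clades; every subset is detached onto its own
    new node at the new height while the member itself stays.  Multiple
    subsets make the split the exact inverse of a merge that removed
    several sibling nodes at once.  Members not mentioned stay at the
    old height.
    """

    def __init__(
        self,
        moves: Iterable[frozenset] = (),
        resolves: dict[frozenset, Iterable[Iterable[frozenset]]] | None = None,
    ):
        self.moves = frozenset(frozenset(m) for m in moves)
        # subsets are kept in a canonical sorted order so that detachment
        # (and hence child order, serialization and downstream proposal
        # enumeration) is identical across processes regardless of hash
        # randomization
        self.resolves = {
            frozenset(k): tuple(
                sorted(
                    (frozenset(frozenset(c) for c in subset) for subset in v),
                    key=lambda s: sorted(sorted(c) for c in s),
                )
            )
            for k, v in (resolves or {}).items()
        }

    def __repr__(self):
        return f"SplitAllocation(moves={self.moves}, resolves={self.resolves})"


def split_height_class(
    tree: GeneralizedTree,
    class_id: int,
    allocation: SplitAllocation,
    new_height: float,
    validate: bool = True,
) -> GeneralizedTree:
    """Split a height class: inverse of :func:`merge_height_classes`.

    Nodes designated by the allocation move (or spawn, for polytomy
    resolutions) to a new class at ``new_height``, which must be younger
    than the class height and older than every child of an affected node.
    Both resulting classes must be nonempty, which requires at least one
    mover-or-resolution and at least one stayer-or-resolution.

    Merging the two resulting classes restores the input tree whenever
    ``new_height`` keeps them height-order neighbors.
    """
    if class_id not in tree.class_heights:
        raise TreeError(f"unknown height class {class_id}")
    old_height = tree.class_heights[class_id]
    if not (0.0 < new_height < old_height):
        raise TreeError(f"new height {new_height} not in (0, {old_height})")
    new = tree.copy()
    members = {node.clade(): node for node in new.class_members()[class_id]}
    unknown = (set(allocation.moves) | set(allocation.resolves)) - set(members)
    if unknown:
        raise TreeError(f"allocation names non-member nodes: {unknown}")
    if allocation.moves & set(allocation.resolves):
        raise TreeError("a node cannot both move and resolve")
    n_stay = len(members) - len(allocation.moves)
    if not (allocation.moves or allocation.resolves):
        raise TreeError("empty allocation: new class would be empty")
    if n_stay == 0 and not allocation.resolves:
        raise TreeError("total allocation: old class would be empty")

    new_cid = max(new.class_heights) + 1
    lower = 0.0
    for clade in allocation.moves:
        node = members[clade]
        lower = max(lower, max(c.height for c in node.children))
        node.class_id = new_cid
    for clade, subsets in allocation.resolves.items():
        node = members[clade]
        by_clade = {c.clade(): c for c in node.children}
        seen: set = set()
        total_detached = 0
        for child_clades in subsets:
            if len(child_clades) < 2:
                raise TreeError("each detached subset needs >= 2 children")
            if child_clades & seen:
                raise TreeError("detached subsets must be disjoint")
            seen |= child_clades
            unknown_children = child_clades - set(by_clade)
            if unknown_children:
                raise TreeError(
                    f"resolution names unknown children of {set(clade)}"
                )
            total_detached += len(child_clades)
        # after detaching, the node's children are the untouched ones plus
        # one fresh node per subset; it must remain a proper internal node
        if len(node.children) - total_detached + len(subsets) < 2:
            raise TreeError("resolutions must leave the node >= 2 children")
        for child_clades in subsets:
            # deterministic attachment order regardless of hash seed
            picked = [by_clade[c] for c in sorted(child_clades, key=sorted)]
            lower = max(lower, max(c.height for c in picked))
            fresh = Node(class_id=new_cid)
            for child in picked:
                node.remove_child(child)
                fresh.add_child(child)
            node.add_child(fresh)
    if new_height <= lower:
        raise TreeError(
            f"new height {new_height} not above affected children (> {lower})"
        )
    new.class_heights[new_cid] = new_height
    out = GeneralizedTree(new.root, new.class_heights, validate=False,
                          tip_labels=tree.tip_labels)
    if validate:
        out.validate()
    return out


def enumerate_neighbor_merges(
    tree: GeneralizedTree,
) -> list[tuple[tuple[int, int], GeneralizedTree]]:
    """All single merges of height-order-adjacent class pairs.

    Each merge creates a shared divergence or a multifurcation.  A tree
    with one class yields an empty list.
    """
    out = []
    for young, old in neighbor_class_pairs(tree):
        out.append(((young, old), merge_height_classes(tree, young, old)))
    return out


def polytomies_to_zero_branches(tree: GeneralizedTree) -> GeneralizedTree:
    """Strictly bifurcating version of the tree, resolving each
    multifurcation into nested bifurcations joined by zero-length
    branches.  Used only as a likelihood cross-check; total branch length
    and tip set are preserved."""
    new = tree.copy()
    next_cid = max(new.class_heights) + 1
    changed = False
    for node in list(new.preorder()):
        while len(node.children) > 2:
            changed = True
            first, second = node.children[0], node.children[1]
            node.remove_child(first)
            node.remove_child(second)
            inner = Node(class_id=next_cid)
            new.class_heights[next_cid] = new.class_heights[node.class_id]
            next_cid += 1
            inner.add_child(first)
            inner.add_child(second)
            node.children.insert(0, inner)
            inner.parent = node
    if not changed:
        return tree.copy()
    return GeneralizedTree(
        new.root, new.class_heights, allow_zero_branches=True, validate=False
    )


# ---------------------------------------------------------------------------
# enumeration of the discrete model space
# ---------------------------------------------------------------------------


def _set_partitions(items: list) -> Iterator[list[list]]:
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def _topologies(tips: tuple) -> Iterator[Node]:
    """All rooted multifurcating labeled topologies over the tips."""
    if len(tips) == 1:
        yield Node(label=tips[0])
        return
    for part in _set_partitions(list(tips)):
        if len(part) < 2:
            continue
        blocks = [tuple(sorted(b)) for b in part]
        for combo in itertools.product(*[list(_topologies(b)) for b in blocks]):
            root = Node(class_id=-1)
            for sub in combo:
                root.add_child(_copy_subtree(sub))
            yield root


def _copy_subtree(node: Node) -> Node:
    new = Node(label=node.label, class_id=node.class_id)
    for c in node.children:
        new.add_child(_copy_subtree(c))
    return new


def _valid_partitions(internals: list[Node]) -> Iterator[list[list[Node]]]:
    """Partitions of the internal nodes into height classes such that no
    class holds an ancestor-descendant pair and the induced class
    precedence digraph (A above B if some node of A is an ancestor of some
    node of B) is acyclic, i.e. a consistent total height order exists."""
    ancestors: dict[int, set[int]] = {}
    index = {id(n): i for i, n in enumerate(internals)}
    for node in internals:
        anc = set()
        p = node.parent
        while p is not None:
            anc.add(index[id(p)])
            p = p.parent
        ancestors[index[id(node)]] = anc

    for part in _set_partitions(list(range(len(internals)))):
        ok = True
        for block in part:
            bset = set(block)
            for i in block:
                if ancestors[i] & bset:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        # acyclicity of class precedence
        block_of = {}
        for bi, block in enumerate(part):
            for i in block:
                block_of[i] = bi
        edges: dict[int, set[int]] = {bi: set() for bi in range(len(part))}
        for i in range(len(internals)):
            for a in ancestors[i]:
                if block_of[a] != block_of[i]:
                    edges[block_of[a]].add(block_of[i])
        if _is_acyclic(edges):
            yield [[internals[i] for i in block] for block in part]


def _is_acyclic(edges: dict[int, set[int]]) -> bool:
    state: dict[int, int] = {}

    def visit(v: int) -> bool:
        state[v] = 1
        for w in edges[v]:
            s = state.get(w, 0)
            if s == 1:
                return False
            if s == 0 and not visit(w):
                return False
        state[v] = 2
        return True

    return all(visit(v) for v in edges if state.get(v, 0) == 0)


def enumerate_tree_models(tip_labels: Sequence[str]) -> Iterator[tuple]:
    """Yield the canonical model key of every generalized tree model
    (topology plus height-sharing pattern) over the given tips.

    Keys match :meth:`GeneralizedTree.model_key`, so sampled trees can be
    classified against this enumeration.
    """
    tips = tuple(sorted(tip_labels))
    for topo_root in _topologies(tips):
        internals = [n for n in topo_root.preorder() if not n.is_tip]
        recs = frozenset(
            (n.clade(), frozenset(c.clade() for c in n.children)) for n in internals
        )
        for part in _valid_partitions(internals):
            partition = frozenset(
                frozenset(
                    (n.clade(), frozenset(c.clade() for c in n.children))
                    for n in block
                )
                for block in part
            )
            yield (recs, partition)


def count_tree_models(n_tips: int) -> int:
    """Number of generalized tree models on ``n_tips`` labeled tips.

    A model is a rooted multifurcating topology together with a valid
    partition of its internal nodes into height classes (heights
    unlabeled).  Exhaustive enumeration; practical for ``n_tips <= 8``.
    """
    if not (1 <= n_tips <= 8):
        raise TreeError("exhaustive enumeration is limited to 1 <= N <= 8")
    if n_tips == 1:
        return 1
    labels = [f"t{i}" for i in range(n_tips)]
    return sum(1 for _ in enumerate_tree_models(labels))
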