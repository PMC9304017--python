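"""Prior distributions over generalized trees and nuisance parameters.

The tree prior is uniform over the discrete space of generalized tree
models (rooted multifurcating topology plus the partition of internal
nodes into height classes), with the root height following a parametric
distribution (gamma or exponential) and every non-root class height
beta-distributed between the present and the height of the youngest
parent of any node mapped to the class:

    h_k = U_k * X,   X ~ Beta(alpha_tau, 1),
    U_k = min{ height(parent(v)) : v in class k }.

With ``alpha_tau = 1`` (the default used throughout), non-root heights
are uniform on ``(0, U_k)``.  The second beta parameter is fixed at one;
only the alpha parameter is exposed, and at the default the two readings
coincide with a uniform density.

A single mutation-scaled diploid effective population size ``ne_mu``
(shared across branches) gets a gamma prior parameterized by shape and
mean.  The mutation rate ``mu`` and the stationary frequency ``pi`` of
the green state are fixed constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from genphy.tree import GeneralizedTree, Node, TreeError

__all__ = [
    "GammaDist",
    "ExponentialDist",
    "PriorConfig",
    "log_tree_prior",
    "log_ne_prior",
    "sample_heights",
    "random_bifurcating_tree",
    "sample_tree_from_prior",
    "sample_trees_min_gap",
]


@dataclass(frozen=True)
class GammaDist:
    """Gamma distribution parameterized by shape and mean (scale = mean/shape)."""

    shape: float
    mean: float

    def __post_init__(self):
        if self.shape <= 0 or self.mean <= 0:
            raise ValueError("gamma shape and mean must be positive")

    @property
    def scale(self) -> float:
        return self.mean / self.shape

    def log_pdf(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        a, s = self.shape, self.scale
        return (a - 1.0) * math.log(x) - x / s - math.lgamma(a) - a * math.log(s)

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.shape, self.scale))


@dataclass(frozen=True)
class ExponentialDist:
    """Exponential distribution parameterized by its mean."""

    mean: float

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("exponential mean must be positive")

    def log_pdf(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        return -x / self.mean - math.log(self.mean)

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.exponential(self.mean))


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the joint prior.

    root_age : distribution of the root height (expected substitutions/site)
    alpha_tau : alpha parameter of the nested beta distributions on
        non-root heights (1 => uniform)
    ne : gamma prior on the shared mutation-scaled diploid effective
        population size ``ne_mu``
    pi : stationary frequency of the green character state (fixed)
    mu : overall mutation rate (1 => time in expected substitutions/site)
    """

    root_age: GammaDist | ExponentialDist = field(
        default_factory=lambda: GammaDist(shape=10.0, mean=0.2)
    )
    alpha_tau: float = 1.0
    ne: GammaDist = field(default_factory=lambda: GammaDist(shape=20.0, mean=0.001))
    pi: float = 0.5
    mu: float = 1.0

    def __post_init__(self):
        if self.alpha_tau <= 0:
            raise ValueError("alpha_tau must be positive")
        if not (0.0 <= self.pi <= 1.0):
            raise ValueError("pi must be in [0, 1]")


def _class_parent_bounds(tree: GeneralizedTree) -> dict[int, float]:
    """U_k: height of the youngest parent over nodes mapped to each
    non-root class."""
    bounds: dict[int, float] = {}
    root_class = tree.root_class()
    for cid, members in tree.class_members().items():
        if cid == root_class:
            continue
        bounds[cid] = min(node.parent.height for node in members)
    return bounds


def log_tree_prior(tree: GeneralizedTree, config: PriorConfig) -> float:
    """Log prior density of the tree's heights given its model.

    The uniform-topology term is a constant and omitted (it cancels in
    MCMC; :func:`genphy.tree.count_tree_models` exists for tests).
    Returns ``-inf`` for heights outside the nested support instead of
    raising, so proposals into invalid states are simply rejected.
    """
    lp = config.root_age.log_pdf(tree.root_height)
    a = config.alpha_tau
    for cid, upper in _class_parent_bounds(tree).items():
        h = tree.class_heights[cid]
        if not (0.0 < h < upper):
            return -math.inf
        lp += math.log(a) + (a - 1.0) * (math.log(h) - math.log(upper)) - math.log(upper)
    return lp


def log_ne_prior(ne_mu: float, config: PriorConfig) -> float:
    """Log gamma prior density of the shared mutation-scaled population
    size; ``-inf`` for nonpositive values."""
    return config.ne.log_pdf(ne_mu)


# ---------------------------------------------------------------------------
# direct sampling
# ---------------------------------------------------------------------------


def sample_heights(
    tree: GeneralizedTree, config: PriorConfig, rng: np.random.Generator
) -> None:
    """Redraw all class heights in place from the prior, given the
    tree's (topology, partition) model.

    Classes are processed root-downward (each class only after every
    class containing a parent of one of its nodes), so each draw is
    ``U_k * Beta(alpha_tau, 1)``.
    """
    members = tree.class_members()
    root_class = tree.root_class()
    tree.class_heights[root_class] = config.root_age.sample(rng)
    # classes whose every member's parent-class is already assigned
    parent_classes: dict[int, set[int]] = {}
    for cid, nodes in members.items():
        if cid == root_class:
            continue
        parent_classes[cid] = {node.parent.class_id for node in nodes}
    assigned = {root_class}
    pending = set(parent_classes)
    while pending:
        ready = [c for c in pending if parent_classes[c] <= assigned]
        if not ready:
            raise TreeError("cyclic height-class precedence")
        for cid in sorted(ready):
            upper = min(
                tree.class_heights[node.parent.class_id] for node in members[cid]
            )
            x = float(rng.random()) ** (1.0 / config.alpha_tau)
            tree.class_heights[cid] = upper * x
            assigned.add(cid)
            pending.discard(cid)


def random_bifurcating_tree(
    labels: Sequence[str], config: PriorConfig, rng: np.random.Generator
) -> GeneralizedTree:
    """Randomly assemble a strictly bifurcating tree with independent
    divergences (each node its own height class) and prior-drawn heights."""
    labels = list(labels)
    if len(labels) < 2:
        raise TreeError("need at least two tips")
    nodes = [Node(label=lab) for lab in labels]
    next_cid = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(class_id=next_cid)
        next_cid += 1
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    heights = {cid: 1.0 + cid for cid in range(next_cid)}  # placeholder, ordered
    tree = GeneralizedTree(nodes[0], heights, validate=False)
    sample_heights(tree, config, rng)
    tree.validate()
    return tree


def uniform_bifurcating_topology(
    labels: Sequence[str], rng: np.random.Generator
) -> Node:
    """Exactly uniform rooted binary labeled topology by sequential leaf
    insertion: the (k+1)-th tip attaches to any of the 2k - 1 positions
    (every branch, or above the root) with equal probability, giving each
    of the (2n - 3)!! topologies the same weight."""
    labels = list(labels)
    if len(labels) < 2:
        raise TreeError("need at least two tips")
    root = Node(class_id=0)
    root.add_child(Node(label=labels[0]))
    root.add_child(Node(label=labels[1]))
    next_cid = 1

    def nonroot_nodes(node):
        out = []
        stack = list(node.children)
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    for lab in labels[2:]:
        tip = Node(label=lab)
        nodes = nonroot_nodes(root)
        slot = int(rng.integers(len(nodes) + 1))
        fresh = Node(class_id=next_cid)
        next_cid += 1
        if slot == len(nodes):  # insert above the old root
            fresh.add_child(root)
            fresh.add_child(tip)
            root = fresh
        else:
            target = nodes[slot]
            parent = target.parent
            parent.remove_child(target)
            fresh.add_child(target)
            fresh.add_child(tip)
            parent.add_child(fresh)
    return root


def sample_tree_from_prior(
    labels: Sequence[str],
    config: PriorConfig,
    rng: np.random.Generator,
    model: str = "MG",
    mix_generations: int = 1000,
) -> GeneralizedTree:
    """Draw a generalized tree from the prior.

    For the generalized model this follows the assemble-then-mix recipe:
    (1) randomly assemble a strictly bifurcating tree with no shared
    divergences; (2) run ``mix_generations`` generations of
    topology-changing MCMC moves targeting the prior (N moves per
    generation); (3) redraw the root age and the other divergence times
    from their distributions given the final model.

    Under ``model="MIB"`` (independent bifurcating divergences) the
    uniform topology distribution is sampled exactly by sequential leaf
    insertion instead of mixing; the two routes agree in distribution
    and the test suite checks both against exhaustive enumeration.
    """
    if model == "MIB":
        root = uniform_bifurcating_topology(sorted(labels), rng)
        heights = {n.class_id: 1.0 + i
                   for i, n in enumerate(nd for nd in root.preorder()
                                         if not nd.is_tip)}
        tree = GeneralizedTree(root, heights, validate=False)
        sample_heights(tree, config, rng)
        tree.validate()
        return tree

    from genphy.mcmc import mix_topology_under_prior  # lazy: avoid cycle

    tree = random_bifurcating_tree(labels, config, rng)
    if len(labels) > 2:
        tree = mix_topology_under_prior(
            tree, config, rng, generations=mix_generations, model=model
        )
    sample_heights(tree, config, rng)
    tree.validate()
    return tree


def min_height_gap(tree: GeneralizedTree) -> float:
    """Smallest gap between consecutive divergence times.  A tree with a
    single divergence time has no gap (returns +inf)."""
    hs = sorted(tree.class_heights.values())
    if len(hs) < 2:
        return math.inf
    return min(b - a for a, b in zip(hs, hs[1:]))


def sample_trees_min_gap(
    labels: Sequence[str],
    config: PriorConfig,
    rng: np.random.Generator,
    min_gap: float = 0.001,
    n_accept: int = 100,
    model: str = "MG",
    mix_generations: int = 1000,
) -> tuple[list[GeneralizedTree], int]:
    """Rejection-sample prior trees whose divergence times are all at
    least ``min_gap`` apart.

    Nested-uniform height draws frequently put two divergence times so
    close together that no finite dataset could distinguish them; the
    rejection rule discards such trees before simulation.  Returns the
    accepted trees and the number of rejected draws.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be nonnegative")
    accepted: list[GeneralizedTree] = []
    n_rejected = 0
    while len(accepted) < n_accept:
        tree = sample_tree_from_prior(
            labels, config, rng, model=model, mix_generations=mix_generations
        )
        if min_height_gap(tree) >= min_gap:
            accepted.append(tree)
        else:
            n_rejected += 1
    return accepted, n_rejected
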