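"""Metropolis-Hastings and reversible-jump sampling of the joint
posterior over generalized trees and parameters.

The state is a generalized tree (topology, height-class partition, class
heights) plus the shared mutation-scaled population size ``ne_mu``.  Per
generation, ``N`` (the number of tips) moves are drawn in proportion to
schedule weights:

* ``height_slide`` -- reflected uniform window on one non-root class
  height inside its legal interval;
* ``height_multiplier`` / ``root_scale`` / ``tree_scale`` /
  ``ne_multiplier`` -- standard multiplier proposals (Jacobian ``m`` per
  scaled coordinate);
* ``nni`` -- rooted nearest-neighbor interchange constrained by heights
  (a swapped-in child must be younger than its new parent), leaving all
  heights and the class partition unchanged;
* ``rj`` -- a fair coin between merging a uniformly chosen pair of
  height-order-neighboring classes and the reverse split move, which
  draws a uniform valid allocation (movers and polytomy resolutions) and
  a new height uniform on the interval that keeps the two classes
  neighbors.  The Hastings ratio counts forward and backward choices
  exactly; the dimension-matching Jacobian is one because the new height
  is drawn directly.

Disabling the ``rj`` move (and starting from a bifurcating tree with
independent divergences) confines the chain to the conventional
independent-bifurcating model; everything else is unchanged.

Correctness of all acceptance ratios is validated by prior-recovery:
chains run with the likelihood fixed at one must reproduce direct prior
simulation, checked in the test suite against exhaustive enumeration of
the model space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from genphy.likelihood import BiallelicMatrix, LikelihoodEvaluator
from genphy.priors import (
    PriorConfig,
    log_ne_prior,
    log_tree_prior,
    random_bifurcating_tree,
)
from genphy.tree import (
    GeneralizedTree,
    Node,
    SplitAllocation,
    TreeError,
    height_bounds,
    merge_height_classes,
    neighbor_class_pairs,
    split_height_class,
)

__all__ = [
    "ChainState",
    "MoveSchedule",
    "Trace",
    "TraceSample",
    "apply_move",
    "run_chain",
    "run_prior_only",
    "mix_topology_under_prior",
]

DEFAULT_WEIGHTS = {
    "height_slide": 3.0,
    "height_multiplier": 2.0,
    "root_scale": 2.0,
    "tree_scale": 1.0,
    "ne_multiplier": 2.0,
    "nni": 3.0,
    "rj": 3.0,
}


@dataclass
class MoveSchedule:
    """Move weights and the reversible-jump switch.

    ``rj_enabled=False`` zeroes the rj weight, restricting the chain to
    trees with independent, bifurcating divergences (given a conforming
    start).  ``moves_per_generation`` defaults to the number of tips.
    """

    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    rj_enabled: bool = True
    moves_per_generation: int | None = None

    def kinds_and_probs(self) -> tuple[list[str], np.ndarray]:
        weights = dict(self.weights)
        if not self.rj_enabled:
            weights["rj"] = 0.0
        kinds = [k for k, w in weights.items() if w > 0]
        if not kinds:
            raise ValueError("schedule needs at least one positive move weight")
        if any(w < 0 for w in weights.values()):
            raise ValueError("move weights must be nonnegative")
        probs = np.array([weights[k] for k in kinds])
        return kinds, probs / probs.sum()


@dataclass
class ChainState:
    tree: GeneralizedTree
    ne_mu: float
    log_prior: float
    log_lik: float


@dataclass
class TraceSample:
    generation: int
    tree: GeneralizedTree
    ne_mu: float
    log_lik: float
    log_prior: float


@dataclass
class Trace:
    """Sampled states of one chain, plus enough metadata to replicate it."""

    samples: list[TraceSample]
    seed: int
    chain_id: int = 0
    generations: int = 0
    sample_freq: int = 1
    n_accepted: int = 0
    n_proposed: int = 0

    def scalars(self, burn_in: int = 0) -> dict[str, np.ndarray]:
        kept = self.samples[burn_in:]
        return {
            "root_height": np.array([s.tree.root_height for s in kept]),
            "tree_length": np.array([s.tree.tree_length() for s in kept]),
            "ne_mu": np.array([s.ne_mu for s in kept]),
            "n_heights": np.array([s.tree.n_classes for s in kept], dtype=float),
            "log_lik": np.array([s.log_lik for s in kept]),
            "log_prior": np.array([s.log_prior for s in kept]),
        }

    def trees(self, burn_in: int = 0) -> list[GeneralizedTree]:
        return [s.tree for s in self.samples[burn_in:]]


# ---------------------------------------------------------------------------
# proposals: each returns (tree', ne', log_hastings_plus_jacobian) or None
# ---------------------------------------------------------------------------


def _nonroot_classes(tree: GeneralizedTree) -> list[int]:
    rc = tree.root_class()
    return [c for c in tree.class_heights if c != rc]


# height-only proposals return ("heights", {class: new height}, lhj) and
# are applied in place with rollback (no tree copy); structural proposals
# return a fresh tree


def _propose_height_slide(tree, ne, rng, class_id: int | None = None):
    classes = _nonroot_classes(tree)
    if not classes:
        return None
    cid = classes[rng.integers(len(classes))] if class_id is None else class_id
    lower, upper = height_bounds(tree, cid)
    width = upper - lower
    h = tree.class_heights[cid] + (rng.random() - 0.5) * width
    if h < lower:
        h = 2.0 * lower - h
    elif h > upper:
        h = 2.0 * upper - h
    if not (lower < h < upper):
        return None
    return "heights", {cid: h}, 0.0


def _propose_height_multiplier(tree, ne, rng, lam: float = 0.8):
    classes = _nonroot_classes(tree)
    if not classes:
        return None
    cid = classes[rng.integers(len(classes))]
    m = math.exp(lam * (rng.random() - 0.5))
    lower, upper = height_bounds(tree, cid)
    h = tree.class_heights[cid] * m
    if not (lower < h < upper):
        return None
    return "heights", {cid: h}, math.log(m)


def _propose_root_scale(tree, ne, rng, lam: float = 0.3):
    cid = tree.root_class()
    m = math.exp(lam * (rng.random() - 0.5))
    h = tree.class_heights[cid] * m
    max_child = max(c.height for c in tree.root.children)
    if h <= max_child:
        return None
    return "heights", {cid: h}, math.log(m)


def _propose_tree_scale(tree, ne, rng, lam: float = 0.3):
    m = math.exp(lam * (rng.random() - 0.5))
    changes = {cid: h * m for cid, h in tree.class_heights.items()}
    return "heights", changes, tree.n_classes * math.log(m)


def _propose_ne_multiplier(tree, ne, rng, lam: float = 1.0):
    m = math.exp(lam * (rng.random() - 0.5))
    return tree, ne * m, math.log(m)


def _nni_triples(tree: GeneralizedTree):
    triples = []
    for c in tree.internal_nodes():
        if c.parent is None:
            continue
        for y in c.parent.children:
            if y is c or y.height >= c.height:
                continue
            for x in c.children:
                triples.append((c, x, y))
    return triples


def _class_bounds_unchecked(tree: GeneralizedTree, cid: int) -> tuple[float, float]:
    members = tree.class_members()[cid]
    lower = max(child.height for node in members for child in node.children)
    upper = min(node.parent.height for node in members)
    return lower, upper


def _propose_nni(tree, ne, rng):
    """Rooted NNI with a height redraw, applied in place.

    Swap a child x of a non-root internal node c with a (younger) sibling
    y of c, then redraw the height of c's class uniformly on the interval
    that keeps the swap reversible: above both the new children and the
    outgoing child x (so the reverse swap stays legal), below the
    youngest parent of the class.  Forward and reverse triple counts and
    interval lengths enter the Hastings ratio.  Returns an undo closure
    for rejection.
    """
    triples = _nni_triples(tree)
    if not triples:
        return None
    n_fwd = len(triples)
    c, x, y = triples[rng.integers(n_fwd)]
    p = c.parent
    cid = c.class_id
    h_old = tree.class_heights[cid]
    # reverse redraw interval uses the pre-swap class bounds, floored by y
    lower_orig, upper = _class_bounds_unchecked(tree, cid)
    lower_rev = max(lower_orig, y.height)
    width_rev = upper - lower_rev
    c.remove_child(x)
    p.add_child(x)
    p.remove_child(y)
    c.add_child(y)

    def undo():
        p.remove_child(x)
        c.remove_child(y)
        c.add_child(x)
        p.add_child(y)
        tree.class_heights[cid] = h_old

    lower_new, _ = _class_bounds_unchecked(tree, cid)
    lo_f = max(lower_new, x.height)
    if not (lo_f < upper) or width_rev <= 0:
        undo()
        return None
    h_new = lo_f + rng.random() * (upper - lo_f)
    tree.class_heights[cid] = h_new
    n_rev = len(_nni_triples(tree))
    if n_rev == 0:
        undo()
        return None
    lhj = (
        math.log(n_fwd) - math.log(n_rev)
        + math.log(upper - lo_f) - math.log(width_rev)
    )
    return "undo", undo, lhj


_PATTERN_CACHE: dict[int, list[list[tuple[int, ...]]]] = {}


def _detachment_patterns(d: int) -> list[list[tuple[int, ...]]]:
    """Ways to detach disjoint child groups from a node of out-degree d:
    set partitions of the children with >= 2 blocks (the node keeps one
    child per block) and at least one block of size >= 2 (something is
    actually detached).  Each listed pattern holds only the detached
    (size >= 2) blocks, in a deterministic order."""
    pats = _PATTERN_CACHE.get(d)
    if pats is None:
        from genphy.tree import _set_partitions

        pats = []
        for part in _set_partitions(list(range(d))):
            if len(part) >= 2 and any(len(b) >= 2 for b in part):
                pats.append(sorted(tuple(sorted(b)) for b in part if len(b) >= 2))
        pats.sort()
        _PATTERN_CACHE[d] = pats
    return pats


def _allocation_options(node: Node) -> int:
    """stay + move + number of detachment patterns for a polytomy."""
    return 2 + len(_detachment_patterns(len(node.children)))


def _n_allocations(members: Sequence[Node]) -> int:
    total = 1
    for node in members:
        total *= _allocation_options(node)
    return total - 2  # exclude all-stay and all-move-without-resolution


def _merge_reverse_terms(tree: GeneralizedTree, young: int, old: int,
                         merged: GeneralizedTree) -> float | None:
    """log of the reverse-split proposal's (1/A)(1/width) factor."""
    members_young = tree.class_members()[young]
    child_max = max(c.height for n in members_young for c in n.children)
    h_old = tree.class_heights[old]
    below = [h for h in merged.class_heights.values() if h < h_old]
    lower = max([child_max] + below)
    width = h_old - lower
    if width <= 0:
        return None
    merged_members = merged.class_members()[old]
    n_alloc = _n_allocations(merged_members)
    if n_alloc <= 0:
        return None
    return -math.log(n_alloc) - math.log(width)


def _propose_rj_merge(tree, ne, rng):
    pairs = neighbor_class_pairs(tree)
    if not pairs:
        return None
    young, old = pairs[rng.integers(len(pairs))]
    merged = merge_height_classes(tree, young, old, validate=False)
    rev = _merge_reverse_terms(tree, young, old, merged)
    if rev is None:
        return None
    # q_fwd = 1/len(pairs); q_rev = (1/n')(1/A)(1/width) with n' = len(pairs)
    return merged, ne, rev


def _propose_rj_split(tree, ne, rng):
    cids = sorted(tree.class_heights)
    cid = cids[rng.integers(len(cids))]
    members = sorted(tree.class_members()[cid], key=lambda n: min(n.clade()))
    n_alloc = _n_allocations(members)
    if n_alloc <= 0:
        return None
    options = [_allocation_options(n) for n in members]
    while True:
        choices = [int(rng.integers(o)) for o in options]
        if all(c == 0 for c in choices):
            continue
        if all(c == 1 for c in choices):
            continue
        break
    moves, resolves = [], {}
    child_max = 0.0
    for node, choice in zip(members, choices):
        if choice == 0:
            continue
        if choice == 1:
            moves.append(node.clade())
            child_max = max(child_max, max(c.height for c in node.children))
        else:
            pattern = _detachment_patterns(len(node.children))[choice - 2]
            subsets = []
            for block in pattern:
                picked = [node.children[i] for i in block]
                subsets.append(frozenset(c.clade() for c in picked))
                child_max = max(child_max, max(c.height for c in picked))
            resolves[node.clade()] = subsets
    h_c = tree.class_heights[cid]
    below = [h for h in tree.class_heights.values() if h < h_c]
    lower = max([child_max] + below)
    width = h_c - lower
    if width <= 0:
        return None
    h_new = lower + rng.random() * width
    allocation = SplitAllocation(moves=moves, resolves=resolves)
    try:
        new = split_height_class(tree, cid, allocation, h_new, validate=False)
    except TreeError:
        return None
    # q_fwd = (1/n)(1/A)(1/width); q_rev = 1/len(pairs') with len(pairs') = n
    return new, ne, math.log(n_alloc) + math.log(width)


def _propose_rj(tree, ne, rng):
    if rng.random() < 0.5:
        return _propose_rj_merge(tree, ne, rng)
    return _propose_rj_split(tree, ne, rng)


_PROPOSALS: dict[str, Callable] = {
    "height_slide": _propose_height_slide,
    "height_multiplier": _propose_height_multiplier,
    "root_scale": _propose_root_scale,
    "tree_scale": _propose_tree_scale,
    "ne_multiplier": _propose_ne_multiplier,
    "nni": _propose_nni,
    "topology_nni_constrained": _propose_nni,
    "rj": _propose_rj,
    "rj_merge": _propose_rj_merge,
    "rj_split": _propose_rj_split,
}


def apply_move(
    state: ChainState,
    move_kind: str,
    rng: np.random.Generator,
    config: PriorConfig,
    loglik_fn: Callable[[GeneralizedTree, float], float] | None = None,
) -> tuple[ChainState, dict]:
    """Propose and Metropolis-Hastings-accept/reject one move.

    Returns the (possibly unchanged) state and a dict of log acceptance
    terms.  ``loglik_fn=None`` fixes the likelihood at one (prior-only
    sampling).  Calling ``rj_merge``/``rj_split`` directly assumes the
    two directions are scheduled with equal probability, as they are by
    the paired ``rj`` move.
    """
    try:
        proposal_fn = _PROPOSALS[move_kind]
    except KeyError:
        raise ValueError(f"unknown move kind {move_kind!r}") from None
    proposal = proposal_fn(state.tree, state.ne_mu, rng)
    info = {"kind": move_kind, "accepted": False}
    if proposal is None:
        return state, info
    first, payload, lhj = proposal
    rollback = None
    if first == "heights":
        tree2, ne2 = state.tree, state.ne_mu
        old = {cid: tree2.class_heights[cid] for cid in payload}
        tree2.class_heights.update(payload)
        rollback = lambda: tree2.class_heights.update(old)
    elif first == "undo":
        tree2, ne2 = state.tree, state.ne_mu
        rollback = payload
    else:
        tree2, ne2 = first, payload
    lp2 = log_tree_prior(tree2, config) + log_ne_prior(ne2, config)
    if lp2 == -math.inf:
        if rollback is not None:
            rollback()
        return state, info
    ll2 = 0.0 if loglik_fn is None else loglik_fn(tree2, ne2)
    log_alpha = (lp2 - state.log_prior) + (ll2 - state.log_lik) + lhj
    info.update(
        log_prior_ratio=lp2 - state.log_prior,
        log_lik_ratio=ll2 - state.log_lik,
        log_hastings=lhj,
        log_alpha=log_alpha,
    )
    if log_alpha >= 0.0 or rng.random() < math.exp(log_alpha):
        info["accepted"] = True
        return ChainState(tree2, ne2, lp2, ll2), info
    if rollback is not None:
        rollback()
    return state, info


# ---------------------------------------------------------------------------
# chain drivers
# ---------------------------------------------------------------------------


def _initial_tree(
    start,
    labels: Sequence[str],
    config: PriorConfig,
    rng: np.random.Generator,
    model: str,
) -> GeneralizedTree:
    if isinstance(start, GeneralizedTree):
        return start.copy()
    if start == "comb":
        if model == "MIB" and len(labels) > 2:
            raise ValueError("the comb start is outside the M_IB space")
        root = Node(class_id=0)
        for lab in sorted(labels):
            root.add_child(Node(label=lab))
        tree = GeneralizedTree(root, {0: config.root_age.sample(rng)})
        return tree
    if start == "random_bifurcating":
        return random_bifurcating_tree(labels, config, rng)
    raise ValueError(f"unknown start {start!r}")


def run_chain(
    data: BiallelicMatrix | None,
    prior_config: PriorConfig,
    generations: int,
    sample_freq: int = 10,
    seed: int = 1,
    schedule: MoveSchedule | None = None,
    start="random_bifurcating",
    model: str = "MG",
    labels: Sequence[str] | None = None,
    chain_id: int = 0,
    audit: bool = False,
    warmup_generations: int = 0,
) -> Trace:
    """Run one MCMC chain and return its trace.

    ``model="MIB"`` disables the reversible-jump move so the chain stays
    in the space of bifurcating trees with independent divergences.
    ``data=None`` samples the prior (likelihood fixed at one).  The run
    is deterministic given ``seed``.

    ``warmup_generations`` prepends an unrecorded warmup phase that only
    shapes the starting state of the recorded run: topology moves get
    double weight and the likelihood is tempered up a short ladder
    (power 0.5 -> 1), which lets a chain started from a random topology
    cross between competing tree models cheaply before sampling begins.
    Nothing from the warmup enters the trace.
    """
    if schedule is None:
        schedule = MoveSchedule()
    if model == "MIB":
        schedule = MoveSchedule(
            dict(schedule.weights), rj_enabled=False,
            moves_per_generation=schedule.moves_per_generation,
        )
    elif model != "MG":
        raise ValueError("model must be 'MG' or 'MIB'")
    if data is not None:
        labels = data.species
    if labels is None:
        raise ValueError("labels are required when no data is given")
    rng = np.random.default_rng(seed)
    tree = _initial_tree(start, labels, prior_config, rng, model)
    if set(tree.tip_labels) != set(labels):
        raise ValueError("starting tree tips do not match the data")
    ne = prior_config.ne.sample(rng)

    loglik_fn = None
    if data is not None:
        pi = prior_config.pi
        if not (0.0 < pi < 1.0):
            raise ValueError("data analysis needs 0 < pi < 1")
        # keep the stationary substitution rate equal to mu: 2uv/(u+v) = 1
        u, v = 1.0 / (2.0 * (1.0 - pi)), 1.0 / (2.0 * pi)
        evaluator = LikelihoodEvaluator(data, u=u, v=v, mu=prior_config.mu)
        loglik_fn = evaluator.loglik

    lp = log_tree_prior(tree, prior_config) + log_ne_prior(ne, prior_config)
    ll = 0.0 if loglik_fn is None else loglik_fn(tree, ne)
    state = ChainState(tree, ne, lp, ll)

    kinds, probs = schedule.kinds_and_probs()
    per_gen = schedule.moves_per_generation or len(labels)

    if warmup_generations > 0 and loglik_fn is not None:
        warm_weights = dict(schedule.weights)
        warm_weights["nni"] = 2.0 * warm_weights.get("nni", 3.0)
        warm_weights["rj"] = 2.0 * warm_weights.get("rj", 3.0)
        warm_schedule = MoveSchedule(warm_weights, rj_enabled=schedule.rj_enabled)
        wkinds, wprobs = warm_schedule.kinds_and_probs()
        betas = (0.5, 0.625, 0.75, 0.875, 1.0)
        per_step = max(1, warmup_generations // len(betas))
        raw_ll = state.log_lik
        for beta in betas:
            tempered = (lambda b: lambda t, n: b * loglik_fn(t, n))(beta)
            state = ChainState(state.tree, state.ne_mu, state.log_prior,
                               beta * raw_ll)
            for _ in range(per_step):
                picks = rng.choice(len(wkinds), size=per_gen, p=wprobs)
                for pick in picks:
                    state, _ = apply_move(
                        state, wkinds[pick], rng, prior_config, tempered
                    )
            raw_ll = state.log_lik / beta
        state = ChainState(state.tree, state.ne_mu, state.log_prior, raw_ll)
    samples: list[TraceSample] = []
    n_acc = n_prop = 0
    for gen in range(1, generations + 1):
        picks = rng.choice(len(kinds), size=per_gen, p=probs)
        for pick in picks:
            kind = kinds[pick]
            state, info = apply_move(state, kind, rng, prior_config, loglik_fn)
            n_prop += 1
            if info["accepted"]:
                n_acc += 1
                if kind in ("rj", "rj_merge", "rj_split"):
                    # chase an accepted jump with a height update to help
                    # the new dimension mix
                    state, info2 = apply_move(
                        state, "height_slide", rng, prior_config, loglik_fn
                    )
                    n_prop += 1
                    n_acc += info2["accepted"]
            if audit:
                lp_chk = log_tree_prior(state.tree, prior_config) + log_ne_prior(
                    state.ne_mu, prior_config
                )
                ll_chk = 0.0 if loglik_fn is None else loglik_fn(state.tree, state.ne_mu)
                assert abs(lp_chk - state.log_prior) < 1e-8
                assert abs(ll_chk - state.log_lik) < 1e-8
        if gen % sample_freq == 0:
            samples.append(
                TraceSample(gen, state.tree.copy(), state.ne_mu,
                            state.log_lik, state.log_prior)
            )
    return Trace(samples, seed=seed, chain_id=chain_id, generations=generations,
                 sample_freq=sample_freq, n_accepted=n_acc, n_proposed=n_prop)


def run_prior_only(
    prior_config: PriorConfig,
    n_tips: int | Sequence[str],
    generations: int,
    sample_freq: int = 10,
    seed: int = 1,
    schedule: MoveSchedule | None = None,
    model: str = "MG",
    start="random_bifurcating",
) -> Trace:
    """Sample the prior by MCMC (likelihood fixed at one).

    The long-run distribution over (topology class, number of divergence
    times, heights) must match direct prior simulation; that agreement
    is the decisive audit of every Hastings ratio.
    """
    if isinstance(n_tips, int):
        labels = [f"sp{i + 1}" for i in range(n_tips)]
    else:
        labels = list(n_tips)
    return run_chain(
        None, prior_config, generations, sample_freq=sample_freq, seed=seed,
        schedule=schedule, start=start, model=model, labels=labels,
    )


_MIX_WEIGHTS = {"nni": 3.0, "rj": 3.0, "height_slide": 2.0}


def mix_topology_under_prior(
    tree: GeneralizedTree,
    config: PriorConfig,
    rng: np.random.Generator,
    generations: int = 1000,
    model: str = "MG",
) -> GeneralizedTree:
    """Topology-mixing stage of prior simulation: run topology-changing
    moves (plus height slides, which keep the nested-height support
    explorable) under the prior for ``generations`` generations of N
    moves each, starting from the given tree."""
    weights = dict(_MIX_WEIGHTS)
    if model == "MIB":
        weights["rj"] = 0.0
    schedule = MoveSchedule(weights, rj_enabled=(model == "MG"))
    kinds, probs = schedule.kinds_and_probs()
    per_gen = tree.n_tips
    lp = log_tree_prior(tree, config) + log_ne_prior(config.ne.mean, config)
    state = ChainState(tree.copy(), config.ne.mean, lp, 0.0)
    for _ in range(generations):
        picks = rng.choice(len(kinds), size=per_gen, p=probs)
        for pick in picks:
            state, _ = apply_move(state, kinds[pick], rng, config, None)
    # in-place topology moves leave the cached node order stale; return a
    # freshly built copy so traversal order matches the topology
    return state.tree.copy()
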