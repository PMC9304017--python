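"""Posterior summaries and convergence diagnostics for sampled trees.

Terminology for summarizing generalized trees:

* a *split* is a branch, identified by the set of tips descending from
  it;
* a *node* is a split together with the set of splits immediately
  descending from it -- this distinguishes a multifurcating node from
  any bifurcating resolution over the same tips;
* a *shared divergence* is a set of two or more nodes mapped to one
  height class.  Event identity ignores the numeric heights.

Chain diagnostics follow the standard MCMC toolkit: the average SD of
split frequencies across chains (ASDSF, with a minimum split-frequency
threshold), the potential scale reduction factor (PSRF, square-root
form of the Brooks-Gelman statistic), and autocorrelation-based
effective sample sizes (Geyer's initial positive sequence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from genphy.tree import GeneralizedTree, enumerate_neighbor_merges

__all__ = [
    "SummaryReport",
    "branch_score_distance",
    "split_node_shared_frequencies",
    "FrequencyTables",
    "merged_divergence_probabilities",
    "convergence_diagnostics",
    "Diagnostics",
    "effective_sample_size",
    "potential_scale_reduction",
    "average_sd_split_frequencies",
    "map_summary",
    "rescale_to_calibration",
]


# ---------------------------------------------------------------------------
# tree distance
# ---------------------------------------------------------------------------


def _clade_map(tree: GeneralizedTree) -> dict[int, frozenset]:
    """Clade (tip set) of every node by id(), children resolved first."""
    clades: dict[int, frozenset] = {}
    stack: list[tuple] = [(tree.root, False)]
    while stack:
        node, ready = stack.pop()
        if node.is_tip:
            clades[id(node)] = frozenset((node.label,))
        elif ready:
            clades[id(node)] = frozenset().union(
                *(clades[id(c)] for c in node.children)
            )
        else:
            stack.append((node, True))
            stack.extend((c, False) for c in node.children)
    return clades


def _branch_lengths_by_clade(tree: GeneralizedTree) -> dict[frozenset, float]:
    clades = _clade_map(tree)
    out: dict[frozenset, float] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        out[clades[id(node)]] = tree.branch_length(node)
    return out


def branch_score_distance(tree_a: GeneralizedTree, tree_b: GeneralizedTree) -> float:
    """Square root of the sum of squared branch-length differences over
    the union of the two trees' branches (a branch absent from one tree
    contributes its full length).  Zero iff the trees agree in topology
    and branch lengths."""
    if set(tree_a.tip_labels) != set(tree_b.tip_labels):
        raise ValueError("trees must share one tip set")
    la = _branch_lengths_by_clade(tree_a)
    lb = _branch_lengths_by_clade(tree_b)
    total = 0.0
    for clade in set(la) | set(lb):
        diff = la.get(clade, 0.0) - lb.get(clade, 0.0)
        total += diff * diff
    return math.sqrt(total)


# ---------------------------------------------------------------------------
# frequencies of splits, nodes, shared divergences
# ---------------------------------------------------------------------------


def _node_record(node, clades: dict[int, frozenset] | None = None) -> tuple:
    if clades is None:
        return (node.clade(), frozenset(c.clade() for c in node.children))
    return (
        clades[id(node)],
        frozenset(clades[id(c)] for c in node.children),
    )


def _shared_events(
    tree: GeneralizedTree, clades: dict[int, frozenset] | None = None
) -> set[frozenset]:
    events = set()
    for nodes in tree.class_members().values():
        if len(nodes) >= 2:
            events.add(frozenset(_node_record(n, clades) for n in nodes))
    return events


@dataclass
class FrequencyTables:
    splits: dict[frozenset, float]
    nodes: dict[tuple, float]
    shared_divergences: dict[frozenset, float]
    topologies: dict[tuple, float]
    n_samples: int


def split_node_shared_frequencies(
    samples: Sequence[GeneralizedTree],
) -> FrequencyTables:
    """Sample frequencies of splits, nodes, shared-divergence events and
    full tree models across a posterior sample of trees."""
    if not samples:
        raise ValueError("need at least one sampled tree")
    splits: dict[frozenset, int] = {}
    nodes: dict[tuple, int] = {}
    shared: dict[frozenset, int] = {}
    topologies: dict[tuple, int] = {}
    for tree in samples:
        clades = _clade_map(tree)
        records = {}
        for node in tree.internal_nodes():
            rec = _node_record(node, clades)
            records[id(node)] = rec
            nodes[rec] = nodes.get(rec, 0) + 1
            if node.parent is not None:
                splits[rec[0]] = splits.get(rec[0], 0) + 1
        shared_here = set()
        partition = []
        for members in tree.class_members().values():
            block = frozenset(records[id(n)] for n in members)
            partition.append(block)
            if len(members) >= 2:
                shared_here.add(block)
        for ev in shared_here:
            shared[ev] = shared.get(ev, 0) + 1
        mk = (frozenset(records.values()), frozenset(partition))
        topologies[mk] = topologies.get(mk, 0) + 1
    n = len(samples)
    as_freq = lambda d: {k: v / n for k, v in d.items()}
    return FrequencyTables(
        as_freq(splits), as_freq(nodes), as_freq(shared), as_freq(topologies), n
    )


def merged_divergence_probabilities(
    reference_tree: GeneralizedTree,
    samples: Sequence[GeneralizedTree],
) -> dict[tuple[int, int], dict]:
    """Posterior probability of each single neighbor-merge of the
    reference tree's divergence times.

    Every merge of height-order-adjacent classes of the reference
    creates a shared divergence or a multifurcation; a posterior sample
    contains that scenario when the merged class's node records all
    appear mapped to one height class (a single multifurcating record
    counts when the sample contains that node).  Returns, per merged
    class pair, the scenario probability and the reference time gap.
    """
    if not samples:
        raise ValueError("need at least one sampled tree")
    ref_tips = set(reference_tree.tip_labels)
    for s in samples[:1]:
        if set(s.tip_labels) != ref_tips:
            raise ValueError("sample tip set does not match the reference")
    scenarios = {}
    for (young, old), merged in enumerate_neighbor_merges(reference_tree):
        members = merged.class_members()[old]
        records = frozenset(_node_record(n) for n in members)
        gap = (
            reference_tree.class_heights[old] - reference_tree.class_heights[young]
        )
        scenarios[(young, old)] = {"records": records, "time_gap": gap, "count": 0}
    for tree in samples:
        clades = _clade_map(tree)
        class_records = [
            frozenset(_node_record(n, clades) for n in nodes)
            for nodes in tree.class_members().values()
        ]
        for info in scenarios.values():
            if any(info["records"] <= cr for cr in class_records):
                info["count"] += 1
    n = len(samples)
    return {
        pair: {
            "probability": info["count"] / n,
            "time_gap": info["time_gap"],
            "records": info["records"],
        }
        for pair, info in scenarios.items()
    }


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of one scalar chain via Geyer's initial positive sequence."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return float(n)
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        return float(n)
    # autocovariances via FFT
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # sum of adjacent pairs must stay positive (and we truncate there)
    tau = 1.0
    for lag in range(1, n - 1, 2):
        pair = rho[lag] + rho[lag + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(n / tau)


def potential_scale_reduction(chains: Sequence[np.ndarray]) -> float:
    """PSRF across chains: the square-root form of the Brooks-Gelman
    scale-reduction statistic."""
    if len(chains) < 2:
        raise ValueError("PSRF needs at least two chains")
    n = min(len(c) for c in chains)
    arr = np.array([np.asarray(c[:n], dtype=float) for c in chains])
    m = arr.shape[0]
    means = arr.mean(axis=1)
    W = float(arr.var(axis=1, ddof=1).mean())
    B_over_n = float(means.var(ddof=1))
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B_over_n
    r2 = (m + 1) / m * var_plus / W - (n - 1) / (m * n)
    return math.sqrt(max(r2, 0.0))


def average_sd_split_frequencies(
    chains: Sequence[Sequence[GeneralizedTree]],
    min_frequency: float = 0.10,
) -> float:
    """ASDSF across chains' tree samples: mean over splits reaching the
    minimum frequency in at least one chain of the across-chain standard
    deviation of the split's frequency."""
    if len(chains) < 2:
        raise ValueError("ASDSF needs at least two chains")
    freqs: list[dict[frozenset, float]] = []
    for trees in chains:
        counts: dict[frozenset, int] = {}
        for tree in trees:
            for clade in tree.split_key():
                counts[clade] = counts.get(clade, 0) + 1
        freqs.append({k: v / len(trees) for k, v in counts.items()})
    splits = {
        s
        for f in freqs
        for s, fr in f.items()
        if fr >= min_frequency
    }
    if not splits:
        return 0.0
    sds = [
        float(np.std([f.get(s, 0.0) for f in freqs], ddof=1)) for s in sorted(
            splits, key=lambda c: sorted(c)
        )
    ]
    return float(np.mean(sds))


@dataclass
class Diagnostics:
    asdsf: float
    psrf: dict[str, float]
    ess: dict[str, float]


def convergence_diagnostics(
    chains,
    burn_in: int = 0,
    scalars: Sequence[str] = ("root_height", "tree_length", "ne_mu"),
    min_split_frequency: float = 0.10,
) -> Diagnostics:
    """ASDSF, PSRF and ESS across two or more chain traces.

    ``chains`` are :class:`genphy.mcmc.Trace` objects; ``burn_in`` is the
    number of leading samples dropped from each.  ESS is summed over
    chains (each chain's autocorrelation time estimated separately).
    """
    if len(chains) < 2:
        raise ValueError("multi-chain diagnostics need >= 2 chains")
    tree_chains = [t.trees(burn_in) for t in chains]
    scalar_chains = [t.scalars(burn_in) for t in chains]
    asdsf = average_sd_split_frequencies(tree_chains, min_split_frequency)
    psrf = {
        name: potential_scale_reduction([sc[name] for sc in scalar_chains])
        for name in scalars
    }
    ess = {
        name: float(sum(effective_sample_size(sc[name]) for sc in scalar_chains))
        for name in scalars
    }
    return Diagnostics(asdsf=asdsf, psrf=psrf, ess=ess)


# ---------------------------------------------------------------------------
# MAP summary and calibration rescaling
# ---------------------------------------------------------------------------


def _equal_tailed_interval(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    lo = (1.0 - level) / 2.0
    return float(np.quantile(x, lo)), float(np.quantile(x, 1.0 - lo))


@dataclass
class SummaryReport:
    """Posterior summary of a sample of generalized trees."""

    n_samples: int
    means: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    n_divergences_probs: dict[int, float]
    n_divergences_interval: tuple[int, int]
    map_tree: GeneralizedTree
    map_probability: float
    frequencies: FrequencyTables
    map_height_summaries: dict[tuple, dict[str, float]] = field(default_factory=dict)


def map_summary(
    samples: Sequence,
    burn_in: int = 0,
    credible_level: float = 0.95,
) -> SummaryReport:
    """Summarize posterior samples: MAP tree model (most frequent;
    ties broken by lexicographically smallest newick), posterior means
    and equal-tailed credible intervals of root height, tree length,
    ``ne_mu`` and the number of divergence times, plus frequency tables.

    ``samples`` may be trees or :class:`genphy.mcmc.TraceSample`s (the
    latter contribute ``ne_mu``).
    """
    samples = list(samples)[burn_in:]
    if not samples:
        raise ValueError("no samples after burn-in")
    trees = [s.tree if hasattr(s, "tree") else s for s in samples]
    nes = [s.ne_mu for s in samples if hasattr(s, "ne_mu")]

    freqs = split_node_shared_frequencies(trees)
    best_freq = max(freqs.topologies.values())
    best_keys = [k for k, v in freqs.topologies.items() if v == best_freq]
    candidates: dict[tuple, GeneralizedTree] = {}
    for tree in trees:
        mk = tree.model_key()
        if mk in best_keys and mk not in candidates:
            candidates[mk] = tree
    map_key, map_tree = min(
        candidates.items(), key=lambda kv: kv[1].newick(include_classes=False)
    )

    # heights annotated on the MAP model, conditional on that model
    matching = [t for t in trees if t.model_key() == map_key]
    height_summ: dict[tuple, dict[str, float]] = {}
    for cid, members in map_tree.class_members().items():
        key = frozenset(_node_record(n) for n in members)
        values = []
        for t in matching:
            for cid2, members2 in t.class_members().items():
                if frozenset(_node_record(n) for n in members2) == key:
                    values.append(t.class_heights[cid2])
                    break
        arr = np.array(values)
        lo, hi = _equal_tailed_interval(arr, credible_level)
        height_summ[key] = {"mean": float(arr.mean()), "lower": lo, "upper": hi}
    mean_heights = {
        cid: height_summ[frozenset(_node_record(n) for n in members)]["mean"]
        for cid, members in map_tree.class_members().items()
    }
    map_annotated = map_tree.copy()
    map_annotated.class_heights.update(mean_heights)

    scalars = {
        "root_height": np.array([t.root_height for t in trees]),
        "tree_length": np.array([t.tree_length() for t in trees]),
        "n_divergences": np.array([t.n_classes for t in trees], dtype=float),
    }
    if nes:
        scalars["ne_mu"] = np.array(nes)
    means = {k: float(v.mean()) for k, v in scalars.items()}
    intervals = {k: _equal_tailed_interval(v, credible_level) for k, v in scalars.items()}

    ndiv = scalars["n_divergences"].astype(int)
    probs = {int(k): int(c) / len(ndiv) for k, c in zip(*np.unique(ndiv, return_counts=True))}
    lo, hi = _equal_tailed_interval(ndiv.astype(float), credible_level)
    return SummaryReport(
        n_samples=len(trees),
        means=means,
        intervals=intervals,
        n_divergences_probs=probs,
        n_divergences_interval=(int(math.floor(lo)), int(math.ceil(hi))),
        map_tree=map_annotated,
        map_probability=best_freq,
        frequencies=freqs,
        map_height_summaries=height_summ,
    )


def rescale_to_calibration(
    samples: Sequence[GeneralizedTree], target_mean_root_age: float
) -> list[GeneralizedTree]:
    """Rescale every sampled tree by one global factor so the posterior
    mean root age equals the target (secondary-calibration rescaling,
    e.g. from expected substitutions per site to millions of years).
    Topologies and relative node depths are untouched."""
    if target_mean_root_age <= 0:
        raise ValueError("target mean root age must be positive")
    samples = list(samples)
    mean_root = float(np.mean([t.root_height for t in samples]))
    if mean_root <= 0:
        raise ValueError("posterior mean root height is zero")
    factor = target_mean_root_age / mean_root
    out = []
    for tree in samples:
        new = tree.copy()
        for cid in new.class_heights:
            new.class_heights[cid] *= factor
        out.append(new)
    return out
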