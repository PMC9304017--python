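"""Simulation of gene trees and biallelic characters on generalized trees.

Gene trees branch according to a multispecies coalescent within the
species tree: within every species-tree branch, each pair of gene
lineages coalesces at rate ``1/(2 ne_mu)`` per unit of
expected-substitutions time; at a multifurcating node the lineages of
all children enter the ancestral population simultaneously; above the
root, coalescence continues until one lineage remains.  Characters then
evolve along each gene tree under the two-state CTMC (root state drawn
from stationarity), and are summarized as per-species allele counts.

Characters are unlinked by default (an independent gene tree per
character); linked mode reuses one gene tree for all sites of a locus.
Constant characters are retained unless a filter is applied afterwards,
matching study designs that compare analyses with and without constant
(or with only per-locus subsampled) characters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from genphy.likelihood import BiallelicMatrix, ModelParams
from genphy.priors import PriorConfig
from genphy.tree import GeneralizedTree, Node

__all__ = [
    "GeneTreeNode",
    "GeneTree",
    "SimStudyConfig",
    "InferenceSettings",
    "ReplicateResult",
    "StudyReport",
    "sample_gene_tree",
    "evolve_character",
    "simulate_matrix",
    "one_variable_per_locus",
    "pairwise_heterozygosity_mc",
    "run_simulation_study",
]


class GeneTreeNode:
    """One coalescent node: tips carry a species label, internals a pair
    (or, above multifurcations, any number >= 2 is still pairwise --
    coalescences are always binary) of children."""

    __slots__ = ("time", "children", "species", "state")

    def __init__(self, time: float, children=(), species: str | None = None):
        self.time = time
        self.children = list(children)
        self.species = species
        self.state: int | None = None  # 0 = green, 1 = red


@dataclass
class GeneTree:
    """A character's genealogy; branch lengths in expected substitutions
    per site, tips at time 0 assigned to species."""

    root: GeneTreeNode

    def tips(self) -> list[GeneTreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.children:
                stack.extend(node.children)
            else:
                out.append(node)
        return out

    def tmrca(self) -> float:
        return self.root.time


def _coalesce_pool(
    pool: list[GeneTreeNode],
    t_start: float,
    t_end: float,
    ne_mu: float,
    rng: np.random.Generator,
) -> tuple[list[GeneTreeNode], float]:
    """Coalesce lineages between t_start and t_end (may be inf)."""
    t = t_start
    rate_per_pair = 1.0 / (2.0 * ne_mu)
    while len(pool) > 1:
        k = len(pool)
        total = rate_per_pair * k * (k - 1) / 2.0
        t_next = t + rng.exponential(1.0 / total)
        if t_next >= t_end:
            return pool, t_end
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        parent = GeneTreeNode(t_next, children=(pool[i], pool[j]))
        pool = [x for idx, x in enumerate(pool) if idx not in (i, j)] + [parent]
        t = t_next
    return pool, t_end


def sample_gene_tree(
    species_tree: GeneralizedTree,
    ne_mu: float,
    samples_per_species: int | Mapping[str, int] = 2,
    rng: np.random.Generator | None = None,
) -> GeneTree:
    """Draw one gene tree from the multispecies coalescent."""
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(samples_per_species, int):
        samples = {lab: samples_per_species for lab in species_tree.tip_labels}
    else:
        samples = dict(samples_per_species)

    def rec(node: Node) -> list[GeneTreeNode]:
        if node.is_tip:
            return [GeneTreeNode(0.0, species=node.label)
                    for _ in range(samples.get(node.label, 0))]
        pool: list[GeneTreeNode] = []
        for child in node.children:
            sub = rec(child)
            sub, _ = _coalesce_pool(sub, child.height, node.height, ne_mu, rng)
            pool.extend(sub)
        return pool

    pool = rec(species_tree.root)
    pool, _ = _coalesce_pool(pool, species_tree.root_height, math.inf, ne_mu, rng)
    return GeneTree(pool[0])


def evolve_character(
    gene_tree: GeneTree,
    u: float = 1.0,
    v: float = 1.0,
    mu: float = 1.0,
    rng: np.random.Generator | None = None,
) -> dict[str, tuple[int, int]]:
    """Evolve one biallelic character along a gene tree.

    The root state is drawn from the stationary law (green with
    probability ``pi = u/(u+v)``); states flip along branches at rates
    ``u mu`` (red->green) and ``v mu`` (green->red).  Returns per-species
    ``(copies sampled, red copies)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    pi_green = u / (u + v)
    total = (u + v) * mu
    counts: dict[str, list[int]] = {}
    root = gene_tree.root
    root.state = 0 if rng.random() < pi_green else 1
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.children:
            n_r = counts.setdefault(node.species, [0, 0])
            n_r[0] += 1
            n_r[1] += node.state
            continue
        for child in node.children:
            d = node.time - child.time
            if total > 0 and d > 0:
                p_event = 1.0 - math.exp(-total * d)
                if node.state == 0:  # green -> red with prob (v/(u+v)) * p
                    flip = rng.random() < (v / (u + v)) * p_event
                    child.state = 1 if flip else 0
                else:
                    flip = rng.random() < (u / (u + v)) * p_event
                    child.state = 0 if flip else 1
            else:
                child.state = node.state
            stack.append(child)
    return {sp: (n, r) for sp, (n, r) in counts.items()}


@dataclass
class SimStudyConfig:
    """Conditions for one simulation study.

    Defaults mirror the headline study design: datasets of 50,000
    unlinked biallelic characters from one diploid individual (two
    copies) per species on nine-species trees, with the shared ``ne_mu``
    drawn per replicate from gamma(shape 20, mean 0.001) and that same
    distribution reused as the analysis prior.
    """

    n_species: int = 9
    m: int = 50_000
    samples_per_species: int = 2
    tree_source: str = "MG"          # "MG" | "MIB" | "fixed"
    fixed_tree: GeneralizedTree | None = None
    linkage: tuple[int, int] | None = None   # (loci, sites per locus)
    filter: str = "all"              # "all" | "variable" | "one_per_locus"
    min_height_gap: float = 0.001
    prior: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self):
        if self.m <= 0:
            raise ValueError("m must be positive")
        if self.linkage is not None:
            loci, sites = self.linkage
            if loci * sites != self.m:
                raise ValueError("loci * sites must equal m")
        if self.tree_source == "fixed" and self.fixed_tree is None:
            raise ValueError("fixed tree source needs a tree")


def simulate_matrix(
    species_tree: GeneralizedTree,
    params: ModelParams,
    config: SimStudyConfig,
    rng: np.random.Generator,
) -> BiallelicMatrix:
    """Simulate a biallelic character matrix on a species tree.

    Unlinked mode draws one gene tree per character; linked mode draws
    one gene tree per locus and evolves all of the locus's sites along
    it.  All characters (constant included) are retained; apply
    :meth:`BiallelicMatrix.drop_constant` or
    :func:`one_variable_per_locus` afterwards for the filtered designs.
    """
    species = tuple(sorted(species_tree.tip_labels))
    if config.linkage is None:
        plan = [(i, 1) for i in range(config.m)]
    else:
        loci, sites = config.linkage
        plan = [(i, sites) for i in range(loci)]
    n_rows = np.zeros((config.m, len(species)), dtype=np.int64)
    r_rows = np.zeros((config.m, len(species)), dtype=np.int64)
    locus_map = np.zeros(config.m, dtype=np.int64)
    col = {s: i for i, s in enumerate(species)}
    row = 0
    for locus, sites in plan:
        gtree = sample_gene_tree(
            species_tree, params.ne_mu, config.samples_per_species, rng
        )
        for _ in range(sites):
            counts = evolve_character(gtree, params.u, params.v, params.mu, rng)
            for sp, (n, r) in counts.items():
                n_rows[row, col[sp]] = n
                r_rows[row, col[sp]] = r
            locus_map[row] = locus
            row += 1
    return BiallelicMatrix(species, n_rows, r_rows, locus_map=locus_map)


def one_variable_per_locus(
    matrix: BiallelicMatrix, rng: np.random.Generator
) -> BiallelicMatrix:
    """Keep at most one variable character per locus (chosen uniformly
    among the locus's variable characters); the result is flagged
    ``variable_only`` so the likelihood correction applies."""
    if matrix.locus_map is None:
        raise ValueError("matrix has no locus assignment")
    variable = matrix.variable_mask()
    keep: list[int] = []
    for locus in np.unique(matrix.locus_map):
        rows = np.flatnonzero((matrix.locus_map == locus) & variable)
        if rows.size:
            keep.append(int(rows[rng.integers(rows.size)]))
    keep = sorted(keep)
    return BiallelicMatrix(
        matrix.species,
        matrix.n[keep],
        matrix.r[keep],
        variable_only=True,
    )


def pairwise_heterozygosity_mc(
    ne_mu: float,
    m: int,
    rng: np.random.Generator,
    u: float = 1.0,
    v: float = 1.0,
    mu: float = 1.0,
) -> float:
    """Monte-Carlo fraction of characters at which the two gene copies of
    one diploid individual differ, in a single population.

    Vectorized special case of the general machinery: the pairwise
    coalescence time is Exp with mean ``2 ne_mu``; looking across the
    genealogy, the two copies are separated by twice that time, over
    which a stationary two-state chain changes state with probability
    ``2 pi (1 - pi) (1 - exp(-(u + v) mu t))``.  Agrees with
    :func:`sample_gene_tree` + :func:`evolve_character` (tested) at a
    fraction of the cost; the expectation has the closed form
    ``4 ne_mu / (1 + 8 ne_mu)`` in the symmetric unit-rate case.
    """
    times = rng.exponential(2.0 * ne_mu, size=m)
    pi_green = u / (u + v)
    p_diff = 2.0 * pi_green * (1.0 - pi_green) * (
        1.0 - np.exp(-(u + v) * mu * 2.0 * times)
    )
    return float((rng.random(m) < p_diff).mean())


# ---------------------------------------------------------------------------
# simulation-study driver
# ---------------------------------------------------------------------------


@dataclass
class InferenceSettings:
    """How each simulated dataset is analyzed.

    ``models`` lists the tree models to fit ("MG" and/or "MIB").
    ``favorable_mib`` reruns the M_IB analyses under friendlier
    conditions: chains twice as long, sampled half as frequently, and
    started from the true tree.
    """

    models: tuple[str, ...] = ("MG",)
    chains: int = 4
    generations: int = 15_000
    sample_freq: int = 10
    burn_in_fraction: float = 1.0 / 3.0
    warmup_generations: int = 0
    favorable_mib: bool = False


@dataclass
class ReplicateResult:
    true_tree: GeneralizedTree
    ne_mu: float
    results: dict[str, dict]


@dataclass
class StudyReport:
    study: SimStudyConfig
    inference: InferenceSettings
    n_replicates: int
    seed: int
    replicates: list[ReplicateResult]

    def merged_pairs(self, model: str = "MG") -> list[dict]:
        """All merged-neighbor records pooled over replicates."""
        out = []
        for rep in self.replicates:
            for pair, rec in rep.results[model]["merged_probs"].items():
                out.append(dict(rec, pair=pair))
        return out


def _chain_seed(seed: int, replicate: int, model_idx: int, chain: int) -> int:
    return (1_000_003 * seed + 7919 * replicate + 613 * model_idx + chain) % (2**31)


def run_simulation_study(
    study: SimStudyConfig,
    inference: InferenceSettings,
    n_replicates: int,
    seed: int = 1,
) -> StudyReport:
    """Simulate replicate datasets and analyze each one.

    Per replicate: draw a species tree (fixed, or from the generalized /
    independent-bifurcating prior with the minimum height-gap rejection
    rule), draw ``ne_mu`` from its gamma prior (the same distribution
    used as the analysis prior), simulate characters, run the requested
    chains for each model, and summarize merged-neighbor posterior
    probabilities against the true tree, per-sample branch-score
    distances, true-node support and convergence diagnostics.
    """
    from genphy.mcmc import run_chain
    from genphy.priors import sample_trees_min_gap
    from genphy.summarize import (
        branch_score_distance,
        convergence_diagnostics,
        merged_divergence_probabilities,
        split_node_shared_frequencies,
    )

    rng = np.random.default_rng(seed)
    labels = [f"sp{i + 1}" for i in range(study.n_species)]
    replicates: list[ReplicateResult] = []
    for rep in range(n_replicates):
        if study.tree_source == "fixed":
            true_tree = study.fixed_tree.copy()
        else:
            trees, _ = sample_trees_min_gap(
                labels, study.prior, rng, min_gap=study.min_height_gap,
                n_accept=1, model=study.tree_source,
            )
            true_tree = trees[0]
        ne_mu = study.prior.ne.sample(rng)
        params = ModelParams(ne_mu=ne_mu)
        data = simulate_matrix(true_tree, params, study, rng)
        if study.filter == "variable":
            data = data.drop_constant()
        elif study.filter == "one_per_locus":
            data = one_variable_per_locus(data, rng)

        results: dict[str, dict] = {}
        for mi, model in enumerate(inference.models):
            gens, freq = inference.generations, inference.sample_freq
            start = "random_bifurcating"
            if model == "MIB" and inference.favorable_mib:
                gens, freq = 2 * gens, 2 * freq
                start = true_tree
            traces = [
                run_chain(
                    data, study.prior, generations=gens, sample_freq=freq,
                    seed=_chain_seed(seed, rep, mi, c), model=model,
                    start=start, chain_id=c,
                    warmup_generations=inference.warmup_generations,
                )
                for c in range(inference.chains)
            ]
            burn = int(inference.burn_in_fraction * len(traces[0].samples))
            pooled = [t for tr in traces for t in tr.trees(burn)]
            merged = merged_divergence_probabilities(true_tree, pooled)
            freqs = split_node_shared_frequencies(pooled)
            true_nodes = {
                rec: freqs.nodes.get(rec, 0.0)
                for rec in (
                    ( n.clade(), frozenset(c.clade() for c in n.children) )
                    for n in true_tree.internal_nodes()
                )
            }
            from genphy.summarize import _shared_events
            true_shared = {
                ev: freqs.shared_divergences.get(ev, 0.0)
                for ev in _shared_events(true_tree)
            }
            dists = np.array(
                [branch_score_distance(t, true_tree) for t in pooled]
            )
            diag = (
                convergence_diagnostics(traces, burn_in=burn)
                if inference.chains >= 2
                else None
            )
            results[model] = {
                "merged_probs": merged,
                "true_node_probs": true_nodes,
                "true_shared_probs": true_shared,
                "distance_mean": float(dists.mean()),
                "distance_interval": (
                    float(np.quantile(dists, 0.025)),
                    float(np.quantile(dists, 0.975)),
                ),
                "diagnostics": diag,
                "n_posterior_samples": len(pooled),
            }
        replicates.append(ReplicateResult(true_tree, ne_mu, results))
    return StudyReport(study, inference, n_replicates, seed, replicates)
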