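"""Coalescent likelihood of biallelic characters on a generalized tree.

The probability of each character's per-species allele counts is computed
directly from the species tree by integrating analytically over all gene
trees (multispecies coalescent, one shared mutation-scaled diploid
population size ``ne_mu`` on every branch) and all mutational histories
(two-state CTMC with relative rates ``u`` red->green and ``v``
green->red, overall rate ``mu``, stationary green frequency
``pi = u/(u + v)``).

Partial likelihoods at a point in the tree are tables ``F(k, r)`` over
the number ``k`` of ancestral gene lineages of the sample below and the
number ``r`` of them in the red state.  Three operations assemble the
likelihood in one post-order pass:

* a leaf contributes ``F(n, r) = 1`` at its observed counts;
* a branch of duration ``t`` maps ``F -> exp(Q t) F`` where ``Q``
  couples pairwise coalescence (rate ``1/(2 ne_mu)`` per pair, same-color
  pairs feeding ``k - 1``; color-discordant coalescences annihilate) with
  per-lineage color flips;
* children of a node (two or more -- a multifurcation is handled by
  folding children in arbitrary order) are merged with hypergeometric
  allocation weights, the probability that a uniformly chosen subset of
  the parent's exchangeable lineages carries a given share of the red
  copies.

At the root the branch process is continued to absorption at a single
lineage, whose color is weighted by the stationary law (green with
probability ``pi``).  With this convention the result is the probability
of the observed unordered allele-count pattern, so pattern probabilities
sum to one.

When only variable characters are analyzed, each character's probability
is divided by one minus the probability of a constant character (for
that character's sample sizes), correcting the ascertainment bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from genphy.tree import GeneralizedTree, Node

__all__ = [
    "ModelParams",
    "BiallelicMatrix",
    "PartialTable",
    "leaf_partials",
    "branch_pullback",
    "combine_partials",
    "root_probability",
    "character_probability",
    "constant_probability",
    "data_log_likelihood",
    "LikelihoodEvaluator",
]


@dataclass(frozen=True)
class ModelParams:
    """Mutation and population parameters of the character model.

    ``u`` and ``v`` are the relative rates of mutating red->green and
    green->red; ``pi = u/(u+v)`` is the stationary green frequency, so
    ``u = v`` gives the symmetric two-state (JC69-equivalent) model.
    ``ne_mu`` is the mutation-scaled diploid effective population size
    shared by all branches; the pairwise coalescence rate is
    ``1/(2 ne_mu)`` per unit of expected-substitutions time.
    """

    ne_mu: float = 0.001
    u: float = 1.0
    v: float = 1.0
    mu: float = 1.0

    def __post_init__(self):
        if self.u <= 0 or self.v <= 0:
            raise ValueError("u and v must be positive")
        if self.ne_mu <= 0:
            raise ValueError("ne_mu must be positive")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")

    @property
    def pi(self) -> float:
        return self.u / (self.u + self.v)


# ---------------------------------------------------------------------------
# (k, r) state indexing
# ---------------------------------------------------------------------------


def table_dim(K: int) -> int:
    return K * (K + 3) // 2


def state_index(k: int, r: int) -> int:
    return (k - 1) * (k + 2) // 2 + r


def _states(K: int) -> list[tuple[int, int]]:
    return [(k, r) for k in range(1, K + 1) for r in range(k + 1)]


class PartialTable:
    """Partial likelihoods F(k, r), 1 <= k <= K, 0 <= r <= k, flattened.

    ``K == 0`` marks the neutral element (a species with no sampled
    copies), which combines as an identity.
    """

    __slots__ = ("K", "values")

    def __init__(self, K: int, values: np.ndarray | None = None):
        self.K = int(K)
        if values is None:
            values = np.zeros(table_dim(self.K))
        values = np.asarray(values, dtype=float)
        if values.shape != (table_dim(self.K),):
            raise ValueError("values shape does not match K")
        self.values = values

    def get(self, k: int, r: int) -> float:
        return float(self.values[state_index(k, r)])

    def set(self, k: int, r: int, value: float) -> None:
        self.values[state_index(k, r)] = value

    @property
    def is_neutral(self) -> bool:
        return self.K == 0

    def __repr__(self):
        return f"<PartialTable K={self.K}>"


def leaf_partials(n: int, r: int) -> PartialTable:
    """Leaf initialization: unit mass at the observed counts ``(n, r)``.

    ``n == 0`` yields the neutral table for a species with missing data.
    """
    if not (0 <= r <= n):
        raise ValueError(f"need 0 <= r <= n, got n={n}, r={r}")
    table = PartialTable(n)
    if n > 0:
        table.set(n, r, 1.0)
    return table


# ---------------------------------------------------------------------------
# branch generator and propagation
# ---------------------------------------------------------------------------


_GENERATOR_PARTS: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _generator_parts(K: int, u: float, v: float, mu: float):
    """Split Q = M + C / (4 ne_mu): the mutation part M is fixed given
    (u, v, mu) and the coalescent part C has unit coefficient, so a new
    population size only needs a scalar multiply-add."""
    key = (K, u, v, mu)
    parts = _GENERATOR_PARTS.get(key)
    if parts is not None:
        return parts
    dim = table_dim(K)
    M = np.zeros((dim, dim))
    C = np.zeros((dim, dim))
    for k in range(1, K + 1):
        for r in range(k + 1):
            i = state_index(k, r)
            M[i, i] = -(r * u * mu + (k - r) * v * mu)
            C[i, i] = -(k * (k - 1))
            # backward-Kolmogorov mutation terms use the forward-in-time
            # flip rates: a green lineage turns red at v*mu, a red one
            # green at u*mu
            if r + 1 <= k:
                M[i, state_index(k, r + 1)] += (k - r) * v * mu
            if r - 1 >= 0:
                M[i, state_index(k, r - 1)] += r * u * mu
            if k + 1 <= K:
                C[i, state_index(k + 1, r + 1)] += r * (k + 1)
                C[i, state_index(k + 1, r)] += (k - r) * (k + 1)
    if len(_GENERATOR_PARTS) > 256:
        _GENERATOR_PARTS.clear()
    _GENERATOR_PARTS[key] = (M, C)
    return M, C


def branch_generator(K: int, ne_mu: float, u: float, v: float, mu: float) -> np.ndarray:
    """Dense generator Q of the within-branch process on (k, r) tables.

    Rows/columns follow :func:`state_index`.  Partial tables evolve up a
    branch as ``dF/dt = Q F``: probability flows from ``k + 1`` tables
    into ``k`` via same-color pair coalescence, color-discordant
    coalescences drain mass (they are inconsistent with the color
    bookkeeping), and color flips redistribute ``r`` at per-lineage
    rates ``u mu`` and ``v mu``.
    """
    M, C = _generator_parts(K, u, v, mu)
    return M + C * (1.0 / (4.0 * ne_mu))


class _Propagator:
    """Cached spectral solution of one branch generator.

    Falls back to scaling-and-squaring ``expm`` when the eigenbasis is
    ill-conditioned (reconstruction error above 1e-9).
    """

    def __init__(self, K: int, ne_mu: float, u: float, v: float, mu: float, pi: float):
        self.K = K
        self.Q = branch_generator(K, ne_mu, u, v, mu)
        self._pi = pi
        self._use_eig: bool | None = None  # decided on first apply
        self._absorb_cache: np.ndarray | None = None

    def _decompose(self) -> None:
        self._use_eig = False
        try:
            w, V = scipy.linalg.eig(self.Q)
            if np.abs(w.imag).max() <= 1e-9 * np.abs(w.real).max():
                w, V = w.real, V.real
            scale = max(1.0, np.abs(self.Q).max())
            if np.abs(self.Q @ V - V * w).max() <= 1e-9 * scale:
                self._w, self._V = w, V
                self._Vinv = scipy.linalg.inv(V)
                self._use_eig = True
        except np.linalg.LinAlgError:
            pass

    @property
    def _absorb(self) -> np.ndarray:
        if self._absorb_cache is None:
            self._absorb_cache = self._absorption_vector(self._pi)
        return self._absorb_cache

    def apply(self, values: np.ndarray, duration: float) -> np.ndarray:
        """exp(Q * duration) @ values; values may be (dim,) or (dim, m)."""
        if duration < 0:
            raise ValueError("branch duration must be nonnegative")
        if duration == 0.0:
            return values
        if self._use_eig is None:
            self._decompose()
        if self._use_eig:
            ew = np.exp(self._w * duration)  # deep underflow flushes to 0
            if values.ndim == 1:
                out = self._V @ (ew * (self._Vinv @ values))
            else:
                out = self._V @ (ew[:, None] * (self._Vinv @ values))
            if np.iscomplexobj(out):
                out = out.real
        else:
            E = scipy.linalg.expm(self.Q * duration)
            out = E @ values
        return np.maximum(out, 0.0)

    def _absorption_vector(self, pi: float) -> np.ndarray:
        """Vector a with p = a . F for the infinite root branch.

        Continues the branch process to absorption at k = 1 and weights
        the single ancestral lineage by the stationary color law (green
        with probability pi).
        """
        dim = table_dim(self.K)
        w = np.zeros(dim)
        w[state_index(1, 0)] = pi
        w[state_index(1, 1)] = 1.0 - pi
        if self.K == 1:
            return w
        trans = [state_index(k, r) for k in range(2, self.K + 1) for r in range(k + 1)]
        absorb = [state_index(1, 0), state_index(1, 1)]
        T = self.Q[np.ix_(trans, trans)]
        S = self.Q[np.ix_(absorb, trans)]
        # value(x) = E[w at absorption | start x] solves T' val = -S' w_abs
        val = scipy.linalg.solve(-T.T, S.T @ w[absorb])
        a = np.array(w)
        a[trans] = val
        return a

    def absorb(self, values: np.ndarray) -> np.ndarray:
        return self._absorb @ values


class PropagatorCache:
    """Propagators keyed by (K, ne_mu); a small LRU keeps the current and
    recently proposed population sizes alive across MCMC moves."""

    def __init__(self, u: float, v: float, mu: float, pi: float | None = None, maxsize: int = 64):
        self.u, self.v, self.mu = u, v, mu
        self.pi = u / (u + v) if pi is None else pi
        self.maxsize = maxsize
        self._cache: dict[tuple[int, float], _Propagator] = {}

    def get(self, K: int, ne_mu: float) -> _Propagator:
        key = (K, ne_mu)
        prop = self._cache.get(key)
        if prop is None:
            prop = _Propagator(K, ne_mu, self.u, self.v, self.mu, self.pi)
            if len(self._cache) >= self.maxsize:
                drop = next(iter(self._cache))
                del self._cache[drop]
            self._cache[key] = prop
        return prop


def branch_pullback(
    table: PartialTable,
    duration: float,
    ne_mu: float,
    u: float = 1.0,
    v: float = 1.0,
    mu: float = 1.0,
) -> PartialTable:
    """Evolve a partial table up a branch of the given duration."""
    if table.is_neutral:
        return table
    prop = _Propagator(table.K, ne_mu, u, v, mu, pi=u / (u + v))
    return PartialTable(table.K, prop.apply(table.values, duration))


# ---------------------------------------------------------------------------
# combining descendant branches
# ---------------------------------------------------------------------------

_COMBINE_PLANS: dict[tuple[int, int], tuple] = {}


def _combine_plan(K1: int, K2: int):
    """Index/weight arrays for merging partials of two descendant
    branches with K1 and K2 sampled copies below."""
    plan = _COMBINE_PLANS.get((K1, K2))
    if plan is not None:
        return plan
    idx1, idx2, idxz, wts = [], [], [], []
    for k1 in range(1, K1 + 1):
        for r1 in range(k1 + 1):
            for k2 in range(1, K2 + 1):
                for r2 in range(k2 + 1):
                    k, r = k1 + k2, r1 + r2
                    w = (
                        math.comb(r, r1)
                        * math.comb(k - r, k1 - r1)
                        / math.comb(k, k1)
                    )
                    idx1.append(state_index(k1, r1))
                    idx2.append(state_index(k2, r2))
                    idxz.append(state_index(k, r))
                    wts.append(w)
    # dense weight matrix mapping the flattened outer product of the two
    # child tables to the parent table: one BLAS product per combine
    d1, d2 = table_dim(K1), table_dim(K2)
    W = np.zeros((table_dim(K1 + K2), d1 * d2))
    for i1, i2, iz, w in zip(idx1, idx2, idxz, wts):
        W[iz, i1 * d2 + i2] = w
    plan = (W, d1, d2)
    _COMBINE_PLANS[(K1, K2)] = plan
    return plan


def _combine_pair_values(v1: np.ndarray, K1: int, v2: np.ndarray, K2: int) -> np.ndarray:
    W, d1, d2 = _combine_plan(K1, K2)
    if v1.ndim == 1:
        return W @ np.outer(v1, v2).ravel()
    m = v1.shape[1]
    kr = (v1[:, None, :] * v2[None, :, :]).reshape(d1 * d2, m)
    return W @ kr


def combine_partials(children: Sequence[PartialTable]) -> PartialTable:
    """Merge the partial tables at the top of two or more descendant
    branches, folding left to right.

    The hypergeometric allocation weights make the result independent of
    child order and association; a single child (or any neutral table) is
    passed through unchanged, which is what makes a multifurcation's
    likelihood identical to a series of zero-length bifurcations.
    """
    tables = [t for t in children if not t.is_neutral]
    if not tables:
        return PartialTable(0, np.zeros(0))
    acc = tables[0]
    for nxt in tables[1:]:
        values = _combine_pair_values(acc.values, acc.K, nxt.values, nxt.K)
        acc = PartialTable(acc.K + nxt.K, values)
    return acc


def root_probability(
    table: PartialTable,
    root_ne_mu: float,
    u: float = 1.0,
    v: float = 1.0,
    mu: float = 1.0,
    pi: float | None = None,
) -> float:
    """Terminate the recursion above the root: continue the coalescent
    to a single lineage and weight its color by the stationary law."""
    if table.is_neutral:
        return 1.0
    if pi is None:
        pi = u / (u + v)
    prop = _Propagator(table.K, root_ne_mu, u, v, mu, pi)
    return float(prop.absorb(table.values))


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


class BiallelicMatrix:
    """Per-character, per-species allele counts.

    ``n[i, s]`` is the number of gene copies sampled from species ``s``
    for character ``i`` (0 encodes missing data) and ``r[i, s]`` how many
    of them are the red allele.  ``variable_only`` flags a matrix from
    which constant characters were excluded, switching on the
    ascertainment-bias correction in the likelihood.  ``locus_map``
    optionally assigns each character to a locus (for linked-character
    simulations and per-locus subsampling).
    """

    def __init__(
        self,
        species: Sequence[str],
        n: np.ndarray,
        r: np.ndarray,
        variable_only: bool = False,
        locus_map: np.ndarray | None = None,
    ):
        self.species = tuple(species)
        self.n = np.asarray(n, dtype=np.int64)
        self.r = np.asarray(r, dtype=np.int64)
        if self.n.ndim != 2 or self.n.shape != self.r.shape:
            raise ValueError("n and r must be matching 2-D arrays")
        if self.n.shape[1] != len(self.species):
            raise ValueError("column count must equal the number of species")
        if np.any(self.r < 0) or np.any(self.r > self.n):
            raise ValueError("need 0 <= r <= n")
        if np.any(self.n.sum(axis=1) == 0):
            raise ValueError("every character needs data for >= 1 species")
        self.variable_only = bool(variable_only)
        if locus_map is not None:
            locus_map = np.asarray(locus_map, dtype=np.int64)
            if locus_map.shape != (self.n.shape[0],):
                raise ValueError("locus_map must have one entry per character")
        self.locus_map = locus_map
        if variable_only and np.any(~self.variable_mask()):
            raise ValueError("variable_only matrix contains constant characters")

    @property
    def m(self) -> int:
        """Number of characters."""
        return self.n.shape[0]

    def variable_mask(self) -> np.ndarray:
        """True where a character shows both alleles among sampled copies."""
        return (self.r.sum(axis=1) > 0) & (self.r.sum(axis=1) < self.n.sum(axis=1))

    def drop_constant(self) -> "BiallelicMatrix":
        mask = self.variable_mask()
        return BiallelicMatrix(
            self.species,
            self.n[mask],
            self.r[mask],
            variable_only=True,
            locus_map=None if self.locus_map is None else self.locus_map[mask],
        )

    def proportion_missing(self) -> float:
        full = np.max(self.n, axis=0, keepdims=True)
        with np.errstate(invalid="ignore"):
            return float(1.0 - self.n.sum() / (full.sum() * self.m))


# ---------------------------------------------------------------------------
# full-data evaluation
# ---------------------------------------------------------------------------


@dataclass
class _PatternGroup:
    profile: tuple[int, ...]        # copies sampled per species
    patterns: np.ndarray            # (g, S) red counts
    weights: np.ndarray             # (g,)
    const_rows: tuple[int, int]     # rows holding the all-green / all-red patterns


class LikelihoodEvaluator:
    """Reusable evaluator: collapses the data to weighted site patterns
    once, then computes the log-likelihood for any (tree, ne_mu).

    Patterns sharing a sample-size profile are evaluated together, so a
    branch's matrix exponential is applied to all of them in one product.
    Under the symmetric model (u == v) a pattern and its color complement
    are equiprobable and are folded together.
    """

    def __init__(
        self,
        data: BiallelicMatrix,
        u: float = 1.0,
        v: float = 1.0,
        mu: float = 1.0,
        fold: bool | None = None,
    ):
        self.species = data.species
        self.u, self.v, self.mu = u, v, mu
        self.variable_only = data.variable_only
        if fold is None:
            fold = u == v
        self.fold = fold and u == v
        self.cache = PropagatorCache(u, v, mu)
        self.groups: list[_PatternGroup] = []

        profiles = [tuple(row) for row in data.n]
        by_profile: dict[tuple[int, ...], dict[tuple[int, ...], float]] = {}
        for prof, rrow in zip(profiles, data.r):
            pat = tuple(rrow)
            if self.fold:
                comp = tuple(np.asarray(prof) - np.asarray(pat))
                pat = min(pat, comp)
            by_profile.setdefault(prof, {})
            by_profile[prof][pat] = by_profile[prof].get(pat, 0.0) + 1.0
        for prof, counter in sorted(by_profile.items()):
            all_green = tuple(0 for _ in prof)
            all_red = tuple(prof)
            if self.fold:
                all_red = all_green
            counter.setdefault(all_green, 0.0)
            counter.setdefault(all_red, 0.0)
            pats = sorted(counter)
            weights = np.array([counter[p] for p in pats])
            patterns = np.array(pats, dtype=np.int64)
            const_rows = (pats.index(all_green), pats.index(all_red))
            self.groups.append(_PatternGroup(prof, patterns, weights, const_rows))

    # -- core recursion --------------------------------------------------

    def _leaf_matrix(self, n_copies: int, reds: np.ndarray) -> np.ndarray:
        P = np.zeros((table_dim(n_copies), len(reds)))
        P[[state_index(n_copies, int(r)) for r in reds], np.arange(len(reds))] = 1.0
        return P

    def _leaf_matrices(self, group: _PatternGroup) -> dict[str, tuple[np.ndarray, int]]:
        cached = getattr(group, "_leaves", None)
        if cached is None:
            cached = {}
            for col, sp in enumerate(self.species):
                nc = group.profile[col]
                if nc > 0:
                    cached[sp] = (self._leaf_matrix(nc, group.patterns[:, col]), nc)
            group._leaves = cached
        return cached

    def _group_probs(self, tree: GeneralizedTree, ne_mu: float, group: _PatternGroup) -> np.ndarray:
        leaves = self._leaf_matrices(group)
        memo = getattr(group, "_memo", None)
        if memo is None:
            memo = group._memo = {}
        if len(memo) > 256:
            memo.clear()

        def signature(node: Node) -> tuple:
            """Everything the node-bottom partials depend on: subtree
            shape, tip identities, all heights below, the node's own
            height (via child branch durations) and ne_mu."""
            if node.is_tip:
                return (node.label,)
            return (
                node.height,
                tuple((signature(c), c.height) for c in node.children),
            )

        def rec(node: Node, sig: tuple) -> tuple[np.ndarray | None, int]:
            key = (ne_mu, sig)
            hit = memo.get(key)
            if hit is not None:
                return hit
            parts: list[tuple[int, np.ndarray]] = []
            h = node.height
            for child, (csig, _) in zip(node.children, sig[1]):
                if child.is_tip:
                    if child.label not in leaves:
                        continue
                    P, Kc = leaves[child.label]
                else:
                    P, Kc = rec(child, csig)
                    if Kc == 0:
                        continue
                duration = h - child.height
                if duration > 0:
                    P = self.cache.get(Kc, ne_mu).apply(P, duration)
                parts.append((Kc, P))
            if not parts:
                out: tuple = (None, 0)
            else:
                K, P = parts[0]
                for Kc, Pc in parts[1:]:
                    P = _combine_pair_values(P, K, Pc, Kc)
                    K += Kc
                out = (P, K)
            memo[key] = out
            return out

        P, K = rec(tree.root, signature(tree.root))
        if K == 0:
            return np.ones(group.patterns.shape[0])
        return self.cache.get(K, ne_mu)._absorb @ P

    def pattern_probabilities(
        self, tree: GeneralizedTree, ne_mu: float
    ) -> list[tuple[_PatternGroup, np.ndarray]]:
        return [(g, self._group_probs(tree, ne_mu, g)) for g in self.groups]

    def loglik(self, tree: GeneralizedTree, ne_mu: float) -> float:
        total = 0.0
        for group, probs in self.pattern_probabilities(tree, ne_mu):
            probs = np.maximum(probs, 1e-300)
            logp = np.log(probs)
            if self.variable_only:
                ig, ir = group.const_rows
                p_const = probs[ig] + probs[ir] if ig != ir else 2.0 * probs[ig]
                p_const = min(p_const, 1.0 - 1e-300)
                logp = logp - math.log1p(-p_const)
            total += float(group.weights @ logp)
        return total


# ---------------------------------------------------------------------------
# single-character convenience API
# ---------------------------------------------------------------------------


def character_probability(
    tree: GeneralizedTree,
    params: ModelParams,
    pattern: Mapping[str, tuple[int, int]],
) -> float:
    """Probability of one character's allele counts ``{species: (n, r)}``.

    Species omitted from the pattern (or with ``n == 0``) are treated as
    missing.  Post-order composition of leaf tables, branch pull-backs,
    hypergeometric combines and the root absorption.
    """
    unknown = set(pattern) - set(tree.tip_labels)
    if unknown:
        raise ValueError(f"pattern names unknown species: {sorted(unknown)}")
    cache = PropagatorCache(params.u, params.v, params.mu, params.pi)

    def rec(node: Node) -> PartialTable:
        parts = []
        for child in node.children:
            if child.is_tip:
                n, r = pattern.get(child.label, (0, 0))
                table = leaf_partials(n, r)
            else:
                table = rec(child)
            if table.is_neutral:
                continue
            duration = node.height - child.height
            if duration > 0:
                prop = cache.get(table.K, params.ne_mu)
                table = PartialTable(table.K, prop.apply(table.values, duration))
            parts.append(table)
        return combine_partials(parts)

    table = rec(tree.root)
    if table.is_neutral:
        return 1.0
    return float(cache.get(table.K, params.ne_mu).absorb(table.values))


def constant_probability(
    tree: GeneralizedTree,
    params: ModelParams,
    sample_sizes: Mapping[str, int],
) -> float:
    """Probability that a character is constant (all red or all green)
    given the per-species numbers of sampled copies."""
    all_green = {s: (n, 0) for s, n in sample_sizes.items()}
    all_red = {s: (n, n) for s, n in sample_sizes.items()}
    return character_probability(tree, params, all_green) + character_probability(
        tree, params, all_red
    )


def data_log_likelihood(
    tree: GeneralizedTree, params: ModelParams, data: BiallelicMatrix
) -> float:
    """Log-likelihood of a character matrix: the sum of per-pattern log
    probabilities times pattern weights, with the variable-only
    ascertainment correction applied when the matrix is flagged."""
    if data.m == 0:
        return 0.0
    ev = LikelihoodEvaluator(data, u=params.u, v=params.v, mu=params.mu)
    return ev.loglik(tree, params.ne_mu)
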