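"""Stochastic character mapping: full trait histories on a tree.

A *mapped history* is one complete realization of binary-trait evolution on
a fixed rooted tree: a state at every node plus, for every branch, an
ordered list of (state, duration) segments from the parent end to the child
end.  Histories are drawn either

* conditional on observed tip states (``sample_history``): node states are
  sampled jointly from the exact conditional distribution (root-to-tip pass
  over Felsenstein partials), then each branch path is drawn conditional on
  its endpoint states by *uniformization* — the chain is embedded in a
  Poisson process with dominating rate ``Lambda = 1.05 * max(q01, q10)`` and
  the number of (possibly virtual) jumps is drawn from its exact
  endpoint-conditioned distribution, with the series truncated at cumulative
  Poisson mass 1 - 1e-10; or

* unconditionally from the model (``simulate_history_prior``): the root
  state is drawn from the root policy and paths are simulated forward
  (Gillespie) down every branch.

For Bayes-factor work only the number of 0 -> 1 events per history matters,
so batch counters (:func:`posterior_origin_counts`,
:func:`prior_origin_counts`) sample node states for many histories at once
and count within-branch gains through the same uniformization bridge,
vectorized across histories, without materializing segment lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from . import mk
from .mk import MkModel, _flat, _pmat_scalars, _states_for, _tip_partials
from .phylo_io import Phylogeny, TraitMatrix

__all__ = [
    "MappedHistory",
    "MappingSummary",
    "sample_history",
    "sample_histories",
    "simulate_history_prior",
    "simulate_histories_prior",
    "count_origins",
    "summarize_maps",
    "posterior_origin_counts",
    "prior_origin_counts",
]

TRUNCATION_MASS = 1e-10
MAX_REJECTION_ATTEMPTS = 10**6


class PathSamplingError(RuntimeError):
    """Endpoint-conditioned path sampling failed (degenerate endpoints after
    the uniformization series was truncated and rejection fallback exhausted
    its attempt budget)."""


@dataclass
class MappedHistory:
    """One realization of character evolution on a tree.

    ``node_states[i]`` is the state at postorder node ``i``;
    ``segments[i]`` lists (state, duration) pairs along the branch above
    node ``i`` ordered from the parent end (empty for the root).
    """

    tree: Phylogeny
    node_states: np.ndarray
    segments: list = field(repr=False)

    def validate(self, atol: float = 1e-9) -> None:
        """Check the history invariants; raises AssertionError on violation."""
        flat = _flat(self.tree)
        for i in range(len(flat.nodes) - 1):
            segs = self.segments[i]
            assert segs, f"branch above node {i} has no segments"
            total = sum(d for _, d in segs)
            assert abs(total - flat.brlen[i]) <= atol, "durations != branch length"
            assert segs[0][0] == self.node_states[flat.parent[i]]
            assert segs[-1][0] == self.node_states[i]
            for (a, _), (b, _) in zip(segs, segs[1:]):
                assert a != b, "adjacent segments with equal state"

    def dwell_times(self) -> np.ndarray:
        """(n_branches, 2) dwell time per state on each non-root branch."""
        flat = _flat(self.tree)
        out = np.zeros((len(flat.nodes) - 1, 2))
        for i in range(len(flat.nodes) - 1):
            for s, d in self.segments[i]:
                out[i, s] += d
        return out


def count_origins(history: MappedHistory, count_root: bool = True) -> int:
    """Number of 0 -> 1 gain events in a history.

    A root reconstructed in state 1 counts as one origin by default (so
    "the trait evolved once" stays well defined); pass ``count_root=False``
    to tally only within-branch gains.
    """
    n = 0
    for segs in history.segments:
        for (a, _), (b, _) in zip(segs, segs[1:]):
            if a == 0 and b == 1:
                n += 1
    flat = _flat(history.tree)
    if count_root and history.node_states[flat.root] == 1:
        n += 1
    return n


# ---------------------------------------------------------------------------
# Uniformization engine
# ---------------------------------------------------------------------------


class _MapEngine:
    """Per (tree, model) tables for endpoint-conditioned path sampling."""

    def __init__(self, tree: Phylogeny, model: MkModel):
        q01, q10 = model.q01, model.q10
        if max(q01, q10) <= 0:
            raise ValueError("sampling requires at least one positive rate")
        self.tree = tree
        self.model = model
        self.flat = _flat(tree)
        self.n_branches = len(self.flat.nodes) - 1
        # P(t) per non-root branch as scalar tuples
        self.P = [
            _pmat_scalars(q01, q10, self.flat.brlen[i])
            for i in range(self.n_branches)
        ]
        self.Lam = 1.05 * max(q01, q10)
        self.R = np.array(
            [
                [1.0 - q01 / self.Lam, q01 / self.Lam],
                [q10 / self.Lam, 1.0 - q10 / self.Lam],
            ]
        )
        self._rpow = [np.eye(2), self.R.copy()]
        self._jump_cache: dict = {}

    def rpow(self, n: int) -> np.ndarray:
        while len(self._rpow) <= n:
            self._rpow.append(self._rpow[-1] @ self.R)
        return self._rpow[n]

    def _rpow_table(self, nmax: int) -> np.ndarray:
        """(nmax+1, 2, 2) stacked matrix powers of R."""
        self.rpow(nmax)
        return np.stack(self._rpow[: nmax + 1])

    def jump_dist(self, branch: int, a: int, b: int):
        """CDF over the number of uniformized jumps on *branch* given
        endpoint states (a, b); None if those endpoints are impossible."""
        key = (branch, a, b)
        if key not in self._jump_cache:
            lt = self.Lam * self.flat.brlen[branch]
            if lt == 0.0:
                cdf = np.array([1.0]) if a == b else None
            else:
                # truncate where the Poisson tail mass drops below 1e-10
                nmax = int(
                    max(
                        4,
                        lt + 12.0 * math.sqrt(lt) + 12.0,
                    )
                )
                ns = np.arange(nmax + 1)
                logpois = -lt + ns * math.log(lt) - special.gammaln(ns + 1)
                pois = np.exp(logpois)
                rab = self._rpow_table(nmax)[:, a, b]
                w = pois * rab
                total = w.sum()
                if total <= 0.0:
                    cdf = None
                else:
                    cdf = np.cumsum(w) / total
                    cdf[-1] = 1.0
            self._jump_cache[key] = cdf
        return self._jump_cache[key]

    def sample_chain(self, a: int, b: int, n: int, rng) -> list[int]:
        """States after each of n uniformized jumps, conditioned to end at b."""
        states = []
        x = a
        for k in range(n):
            m = n - k - 1  # jumps remaining after this one
            rm = self.rpow(m)
            rm1 = self.rpow(m + 1)
            den = rm1[x, b]
            if den <= 0.0:
                raise PathSamplingError("degenerate uniformization chain step")
            p1 = self.R[x, 1] * rm[1, b] / den
            x = 1 if rng.random() < p1 else 0
            states.append(x)
        return states

    def sample_branch_path(self, branch: int, a: int, b: int, rng):
        """(state, duration) segments along *branch* given endpoints."""
        t = self.flat.brlen[branch]
        cdf = self.jump_dist(branch, a, b)
        if cdf is None:
            return self._rejection_path(branch, a, b, rng)
        n = int(np.searchsorted(cdf, rng.random()))
        if n == 0:
            return [(a, t)]
        times = np.sort(rng.random(n)) * t
        chain = self.sample_chain(a, b, n, rng)
        return _merge_segments(a, chain, times, t)

    def _rejection_path(self, branch: int, a: int, b: int, rng):
        """Forward-simulation fallback when the truncated series is unusable."""
        t = self.flat.brlen[branch]
        q = (self.model.q01, self.model.q10)
        for _ in range(MAX_REJECTION_ATTEMPTS):
            segs = _forward_path(a, t, q, rng)
            if segs[-1][0] == b:
                return segs
        raise PathSamplingError(
            f"rejection fallback exceeded {MAX_REJECTION_ATTEMPTS} attempts on a "
            "branch; consider different uniformization settings or rates"
        )


def _merge_segments(a: int, chain: list[int], times: np.ndarray, t: float):
    """Collapse virtual (self) jumps into (state, duration) segments."""
    segs = []
    cur_state = a
    cur_start = 0.0
    for x, tm in zip(chain, times):
        if x != cur_state:
            segs.append((cur_state, tm - cur_start))
            cur_state = x
            cur_start = tm
    segs.append((cur_state, t - cur_start))
    return segs


def _forward_path(a: int, t: float, q: tuple[float, float], rng):
    """Gillespie simulation of the chain on one branch from state a."""
    segs = []
    x = a
    pos = 0.0
    while True:
        rate = q[0] if x == 0 else q[1]
        if rate <= 0.0:
            segs.append((x, t - pos))
            return segs
        wait = rng.exponential(1.0 / rate)
        if pos + wait >= t:
            segs.append((x, t - pos))
            return segs
        segs.append((x, wait))
        pos += wait
        x = 1 - x


# ---------------------------------------------------------------------------
# Node-state sampling (single and batch)
# ---------------------------------------------------------------------------


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _conditional_node_tables(engine: _MapEngine, trait, character):
    """Per-node Bernoulli tables for joint conditional node-state sampling.

    Returns (root_p1, p1_given_parent) where ``p1_given_parent[i, a]`` is
    P(state_i = 1 | parent state a, tip data below i).
    """
    flat = engine.flat
    states = _states_for(engine.tree, trait, character)
    tp = _tip_partials(flat, states)
    L0, L1, logscale = mk._prune(flat, tp, engine.model.q01, engine.model.q10)
    if not math.isfinite(logscale):
        raise ValueError("tip data have zero likelihood under this model")
    pi0, pi1 = engine.model.pi()
    r = flat.root
    z = pi0 * L0[r] + pi1 * L1[r]
    root_p1 = pi1 * L1[r] / z

    p1 = np.zeros((engine.n_branches, 2))
    for i in range(engine.n_branches):
        p00, p01, p10, p11 = engine.P[i]
        w00, w01 = p00 * L0[i], p01 * L1[i]
        w10, w11 = p10 * L0[i], p11 * L1[i]
        p1[i, 0] = w01 / (w00 + w01) if (w00 + w01) > 0 else 0.0
        p1[i, 1] = w11 / (w10 + w11) if (w10 + w11) > 0 else 0.0
    return root_p1, p1


def _sample_node_states_batch(engine, root_p1, p1_tables, n, rng) -> np.ndarray:
    """Joint conditional node states for n histories; (n, n_nodes) int8."""
    flat = engine.flat
    nn = len(flat.nodes)
    out = np.zeros((n, nn), dtype=np.int8)
    r = flat.root
    out[:, r] = rng.random(n) < root_p1
    for i in range(nn - 2, -1, -1):  # preorder = reverse postorder, skip root
        pa = out[:, flat.parent[i]]
        p = p1_tables[i, pa]
        out[:, i] = rng.random(n) < p
    return out


def _prior_node_states_batch(engine, n, rng) -> np.ndarray:
    flat = engine.flat
    nn = len(flat.nodes)
    pi0, pi1 = engine.model.pi()
    out = np.zeros((n, nn), dtype=np.int8)
    out[:, flat.root] = rng.random(n) < pi1
    for i in range(nn - 2, -1, -1):
        p00, p01, p10, p11 = engine.P[i]
        pa = out[:, flat.parent[i]]
        p = np.where(pa == 1, p11, p01)
        out[:, i] = rng.random(n) < p
    return out


def _bridge_gain_counts(engine: _MapEngine, node_states: np.ndarray, rng) -> np.ndarray:
    """Number of within-branch 0->1 jumps per history, via the uniformization
    bridge, vectorized across histories branch by branch."""
    flat = engine.flat
    n_hist = node_states.shape[0]
    counts = np.zeros(n_hist, dtype=np.int64)
    for i in range(engine.n_branches):
        a_all = node_states[:, flat.parent[i]]
        b_all = node_states[:, i]
        for a in (0, 1):
            for b in (0, 1):
                idx = np.nonzero((a_all == a) & (b_all == b))[0]
                if idx.size == 0:
                    continue
                cdf = engine.jump_dist(i, a, b)
                if cdf is None:
                    raise PathSamplingError(
                        "impossible endpoint pair in bridge counting"
                    )
                ns = np.searchsorted(cdf, rng.random(idx.size))
                live = ns > 0
                if not live.any():
                    continue
                idx = idx[live]
                nact = ns[live]
                nmax = int(nact.max())
                rtab = engine._rpow_table(nmax + 1)  # (nmax+2, 2, 2)
                A = rtab[:, :, b]  # A[m, s] = R^m[s, b]
                x = np.full(idx.size, a, dtype=np.int8)
                for k in range(nmax):
                    act = k < nact
                    if not act.any():
                        break
                    m = nact[act] - k - 1
                    xa = x[act]
                    den = A[m + 1, xa]
                    num = engine.R[xa, 1] * A[m, 1]
                    with np.errstate(invalid="ignore", divide="ignore"):
                        pr = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
                    new = (rng.random(xa.size) < pr).astype(np.int8)
                    gains = (xa == 0) & (new == 1)
                    np.add.at(counts, idx[act], gains.astype(np.int64))
                    x[act] = new
    return counts


# ---------------------------------------------------------------------------
# Public sampling API
# ---------------------------------------------------------------------------


def sample_history(
    tree: Phylogeny,
    trait: TraitMatrix,
    model: MkModel,
    seed=None,
    character: str | None = None,
) -> MappedHistory:
    """Draw one full history conditional on the observed tip states."""
    return sample_histories(tree, trait, model, 1, seed, character)[0]


def sample_histories(
    tree: Phylogeny,
    trait: TraitMatrix,
    model: MkModel,
    n_maps: int,
    seed=None,
    character: str | None = None,
) -> list[MappedHistory]:
    """Draw ``n_maps`` conditional histories; reproducible given seed."""
    rng = _as_rng(seed)
    engine = _MapEngine(tree, model)
    root_p1, p1 = _conditional_node_tables(engine, trait, character)
    states = _sample_node_states_batch(engine, root_p1, p1, n_maps, rng)
    return [_paths_for(engine, states[k], rng) for k in range(n_maps)]


def _paths_for(engine: _MapEngine, node_states: np.ndarray, rng) -> MappedHistory:
    flat = engine.flat
    segments = []
    for i in range(engine.n_branches):
        a = int(node_states[flat.parent[i]])
        b = int(node_states[i])
        segments.append(engine.sample_branch_path(i, a, b, rng))
    segments.append([])  # root has no subtending branch
    return MappedHistory(tree=engine.tree, node_states=node_states.copy(),
                         segments=segments)


def simulate_history_prior(tree: Phylogeny, model: MkModel, seed=None) -> MappedHistory:
    """Forward-simulate one unconditional history (the 'prior' side)."""
    rng = _as_rng(seed)
    flat = _flat(tree)
    pi0, pi1 = model.pi()
    nn = len(flat.nodes)
    node_states = np.zeros(nn, dtype=np.int8)
    segments: list = [None] * nn
    segments[flat.root] = []
    node_states[flat.root] = 1 if rng.random() < pi1 else 0
    q = (model.q01, model.q10)
    for i in range(nn - 2, -1, -1):
        a = int(node_states[flat.parent[i]])
        segs = _forward_path(a, flat.brlen[i], q, rng)
        segments[i] = segs
        node_states[i] = segs[-1][0]
    return MappedHistory(tree=tree, node_states=node_states, segments=segments)


def simulate_histories_prior(tree, model, n_sim: int, seed=None) -> list[MappedHistory]:
    rng = _as_rng(seed)
    return [simulate_history_prior(tree, model, rng) for _ in range(n_sim)]


def posterior_origin_counts(
    tree: Phylogeny,
    trait: TraitMatrix,
    model: MkModel,
    n_maps: int,
    seed=None,
    character: str | None = None,
    count_root: bool = True,
) -> np.ndarray:
    """Origin (0->1 event) counts of ``n_maps`` conditional histories.

    Distributionally identical to ``count_origins`` over
    ``sample_histories`` but vectorized: node states are sampled jointly and
    within-branch gains are counted through the uniformization bridge
    without building segment lists.
    """
    rng = _as_rng(seed)
    engine = _MapEngine(tree, model)
    root_p1, p1 = _conditional_node_tables(engine, trait, character)
    states = _sample_node_states_batch(engine, root_p1, p1, n_maps, rng)
    counts = _bridge_gain_counts(engine, states, rng)
    if count_root:
        counts += states[:, engine.flat.root] == 1
    return counts


def prior_origin_counts(
    tree: Phylogeny,
    model: MkModel,
    n_sim: int,
    seed=None,
    count_root: bool = True,
) -> np.ndarray:
    """Origin counts of ``n_sim`` unconditional (prior) histories.

    Endpoint states are simulated forward through P(t); within-branch gains
    given the endpoints follow the same bridge law as forward simulation, so
    the counts are exact draws from the prior origin-count distribution.
    """
    rng = _as_rng(seed)
    engine = _MapEngine(tree, model)
    states = _prior_node_states_batch(engine, n_sim, rng)
    counts = _bridge_gain_counts(engine, states, rng)
    if count_root:
        counts += states[:, engine.flat.root] == 1
    return counts


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class MappingSummary:
    """Monte-Carlo summary of a set of histories on one tree.

    ``node_pp1``/``node_pp_se`` are postorder-aligned empirical frequencies
    of state 1 with binomial standard errors; ``origin_distribution`` is the
    empirical distribution of origin counts; ``branch_dwell`` is the
    (n_branches, 2) mean dwell time per state (rows sum to branch lengths).
    """

    tree: Phylogeny
    n_maps: int
    node_pp1: np.ndarray
    node_pp_se: np.ndarray
    origin_distribution: dict
    origin_mean: float
    branch_dwell: np.ndarray
    state_dwell: np.ndarray  # (2,) mean total dwell per state


def summarize_maps(histories: list[MappedHistory], count_root: bool = True) -> MappingSummary:
    """Summarize >= 1 histories drawn on the same tree."""
    if not histories:
        raise ValueError("summarize_maps requires at least one history")
    tree = histories[0].tree
    labels = tree.tip_labels
    for h in histories[1:]:
        if h.tree is not tree and h.tree.tip_labels != labels:
            raise ValueError("histories were drawn on different trees")
    n = len(histories)
    states = np.stack([h.node_states for h in histories])
    p = states.mean(axis=0)
    se = np.sqrt(p * (1 - p) / n)
    counts = np.array([count_origins(h, count_root=count_root) for h in histories])
    vals, freq = np.unique(counts, return_counts=True)
    dist = {int(v): f / n for v, f in zip(vals, freq)}
    dwell = np.mean([h.dwell_times() for h in histories], axis=0)
    return MappingSummary(
        tree=tree,
        n_maps=n,
        node_pp1=p,
        node_pp_se=se,
        origin_distribution=dist,
        origin_mean=float(counts.mean()),
        branch_dwell=dwell,
        state_dwell=dwell.sum(axis=0),
    )
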