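"""Two-state Mk model of a binary trait on a fixed rooted tree.

The model is a continuous-time Markov chain on {0, 1} with a gain rate
``q01`` (0 -> 1 per unit branch length) and a loss rate ``q10`` (1 -> 0).
With ``s = q01 + q10`` the transition probabilities have the closed form

    P01(t) = (q01 / s) * (1 - exp(-s t)),
    P10(t) = (q10 / s) * (1 - exp(-s t)),

diagonals by complement, and P(0) = I (also the s = 0 limit).  Tip data may
be missing, in which case a tip contributes the all-ones partial likelihood.
The tree likelihood is computed by Felsenstein pruning; ancestral marginal
posteriors by a standard up-down (outside) pass; rates are estimated by
log-parameterized quasi-Newton optimization with multistarts, either with
equal rates (ER, q01 = q10) or all rates different (ARD).

Root-state distributions: ``flat`` (1/2, 1/2; the default, matching common
stochastic-mapping practice), ``stationary`` (q10/s, q01/s), or
``fixed`` with user-supplied probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .phylo_io import Node, Phylogeny, TraitMatrix

__all__ = [
    "MkModel",
    "MkFit",
    "AsrResult",
    "RateModelComparison",
    "transition_probabilities",
    "tree_log_likelihood",
    "fit_mk",
    "compare_rate_models",
    "ancestral_marginals",
]

RATE_BOUNDS = (1e-9, 1e3)


class OptimizerError(RuntimeError):
    """Rate optimization failed; carries the best fit seen so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class MkModel:
    """A two-state Mk model: rates plus a root-distribution policy."""

    q01: float
    q10: float
    root_policy: str = "flat"
    root_pi: tuple | None = None

    def __post_init__(self):
        for r in (self.q01, self.q10):
            if not math.isfinite(r) or r < 0:
                raise ValueError(f"rates must be finite and >= 0, got {r}")
        if self.root_policy not in ("flat", "stationary", "fixed"):
            raise ValueError(f"unknown root policy: {self.root_policy!r}")
        if self.root_policy == "fixed":
            if self.root_pi is None:
                raise ValueError("fixed root policy requires root_pi")
            p0, p1 = self.root_pi
            if p0 < 0 or p1 < 0 or abs(p0 + p1 - 1.0) > 1e-9:
                raise ValueError("root_pi must be non-negative and sum to 1")

    def pi(self) -> tuple[float, float]:
        """Root-state distribution implied by the policy."""
        if self.root_policy == "flat":
            return (0.5, 0.5)
        if self.root_policy == "fixed":
            return (float(self.root_pi[0]), float(self.root_pi[1]))
        s = self.q01 + self.q10
        if s <= 0:
            return (0.5, 0.5)  # degenerate chain: any distribution is stationary
        return (self.q10 / s, self.q01 / s)


def _pmat_scalars(q01: float, q10: float, t: float):
    """(p00, p01, p10, p11) for elapsed time t; closed form."""
    s = q01 + q10
    if s <= 0.0 or t == 0.0:
        return 1.0, 0.0, 0.0, 1.0
    f = -math.expm1(-s * t)  # 1 - exp(-s t), accurate for small s*t
    p01 = q01 / s * f
    p10 = q10 / s * f
    return 1.0 - p01, p01, p10, 1.0 - p10


def transition_probabilities(model: MkModel, t: float) -> np.ndarray:
    """2x2 row-stochastic transition matrix P(t)."""
    if not math.isfinite(t) or t < 0:
        raise ValueError(f"branch length must be finite and >= 0, got {t}")
    p00, p01, p10, p11 = _pmat_scalars(model.q01, model.q10, t)
    return np.array([[p00, p01], [p10, p11]])


# ---------------------------------------------------------------------------
# Flattened tree + pruning likelihood
# ---------------------------------------------------------------------------


class _Flat:
    """Postorder-indexed view of a Phylogeny for fast likelihood loops."""

    def __init__(self, tree: Phylogeny):
        self.tree = tree
        self.nodes: list[Node] = tree.postorder()
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        self.parent = [
            self.index[id(n.parent)] if n.parent is not None else -1
            for n in self.nodes
        ]
        self.brlen = [
            float(n.length) if n.length is not None else 0.0 for n in self.nodes
        ]
        self.is_leaf = [n.is_leaf for n in self.nodes]
        self.tip_index = {n.label: self.index[id(n)] for n in self.nodes if n.is_leaf}
        self.root = len(self.nodes) - 1


def _flat(tree: Phylogeny) -> _Flat:
    cached = getattr(tree, "_phylorigins_flat", None)
    if cached is None:
        cached = _Flat(tree)
        tree._phylorigins_flat = cached
    return cached


def _states_for(tree: Phylogeny, trait: TraitMatrix, character: str | None) -> dict:
    """Map every tip label to 0/1/None; error on tips absent from the data."""
    col = trait.column(character)
    missing = [t for t in tree.tip_labels if t not in col]
    if missing:
        raise ValueError(
            f"tips absent from trait data and not flagged missing: {missing[:5]}"
        )
    return {t: col[t] for t in tree.tip_labels}


def _tip_partials(flat: _Flat, states: dict) -> list[tuple[float, float]]:
    out = [None] * len(flat.nodes)
    for label, i in flat.tip_index.items():
        s = states[label]
        if s is None:
            out[i] = (1.0, 1.0)
        elif s == 0:
            out[i] = (1.0, 0.0)
        else:
            out[i] = (0.0, 1.0)
    return out


def _prune(flat: _Flat, tip_partials, q01, q10):
    """Scaled postorder partials; returns (L0, L1, logscale)."""
    n = len(flat.nodes)
    L0 = [0.0] * n
    L1 = [0.0] * n
    logscale = 0.0
    brlen = flat.brlen
    children = flat.children
    for i in range(n):
        tp = tip_partials[i]
        if tp is not None:
            L0[i], L1[i] = tp
            continue
        l0 = l1 = 1.0
        for c in children[i]:
            p00, p01, p10, p11 = _pmat_scalars(q01, q10, brlen[c])
            l0 *= p00 * L0[c] + p01 * L1[c]
            l1 *= p10 * L0[c] + p11 * L1[c]
        scale = l0 if l0 > l1 else l1
        if scale <= 0.0:
            return None, None, -math.inf
        L0[i] = l0 / scale
        L1[i] = l1 / scale
        logscale += math.log(scale)
    return L0, L1, logscale


def tree_log_likelihood(
    tree: Phylogeny,
    trait: TraitMatrix,
    model: MkModel,
    character: str | None = None,
) -> float:
    """Log likelihood of a single binary character by Felsenstein pruning.

    Missing tips contribute the (1, 1) partial; with *all* tips missing the
    log-likelihood is exactly 0 (total uncertainty).
    """
    flat = _flat(tree)
    states = _states_for(tree, trait, character)
    tp = _tip_partials(flat, states)
    L0, L1, logscale = _prune(flat, tp, model.q01, model.q10)
    if not math.isfinite(logscale):
        return -math.inf
    pi0, pi1 = model.pi()
    r = flat.root
    lik = pi0 * L0[r] + pi1 * L1[r]
    if lik <= 0.0:
        return -math.inf
    return math.log(lik) + logscale


# ---------------------------------------------------------------------------
# Rate estimation
# ---------------------------------------------------------------------------


@dataclass
class MkFit:
    """A fitted Mk model with its fit diagnostics."""

    model: MkModel
    log_likelihood: float
    aic: float
    n_params: int
    variant: str
    converged: bool


@dataclass
class RateModelComparison:
    """ER vs ARD comparison: likelihood-ratio test (1 df) and AIC."""

    er: MkFit
    ard: MkFit
    lrt_statistic: float
    lrt_p_value: float
    preferred_lrt: str
    preferred_aic: str


def fit_mk(
    tree: Phylogeny,
    trait: TraitMatrix,
    variant: str = "equal_rates",
    root_policy: str = "flat",
    root_pi: tuple | None = None,
    character: str | None = None,
    bounds: tuple[float, float] = RATE_BOUNDS,
    n_starts: int = 5,
) -> MkFit:
    """Maximum-likelihood rates for one character.

    ``equal_rates`` constrains q01 = q10 (1 parameter); ``all_rates_different``
    frees both (2 parameters).  Optimization is quasi-Newton (L-BFGS-B) on
    log rates from ``n_starts`` log-spaced seeds; the best finishing point
    wins.  AIC = 2k - 2 lnL.
    """
    if variant not in ("equal_rates", "all_rates_different"):
        raise ValueError(f"unknown variant: {variant!r}")
    flat = _flat(tree)
    states = _states_for(tree, trait, character)
    tp = _tip_partials(flat, states)
    lo, hi = math.log(bounds[0]), math.log(bounds[1])

    def make_model(x) -> MkModel:
        if variant == "equal_rates":
            q = math.exp(x[0])
            return MkModel(q, q, root_policy=root_policy, root_pi=root_pi)
        return MkModel(
            math.exp(x[0]), math.exp(x[1]), root_policy=root_policy, root_pi=root_pi
        )

    def neg(x) -> float:
        m = make_model(x)
        L0, L1, logscale = _prune(flat, tp, m.q01, m.q10)
        if not math.isfinite(logscale):
            return 1e300
        pi0, pi1 = m.pi()
        lik = pi0 * L0[flat.root] + pi1 * L1[flat.root]
        if lik <= 0.0:
            return 1e300
        return -(math.log(lik) + logscale)

    ndim = 1 if variant == "equal_rates" else 2
    seeds = np.log(np.geomspace(1e-3, 10.0, n_starts))
    best = None
    any_success = False
    for s in seeds:
        x0 = np.full(ndim, s)
        res = optimize.minimize(
            neg,
            x0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * ndim,
            options={"ftol": 1e-10, "gtol": 1e-8},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    model = make_model(best.x)
    lnl = -best.fun
    fit = MkFit(
        model=model,
        log_likelihood=lnl,
        aic=2 * ndim - 2 * lnl,
        n_params=ndim,
        variant=variant,
        converged=any_success,
    )
    if not any_success:
        raise OptimizerError("rate optimization failed from every start", best=fit)
    return fit


def compare_rate_models(
    tree: Phylogeny,
    trait: TraitMatrix,
    character: str | None = None,
    root_policy: str = "flat",
    alpha: float = 0.05,
    **kwargs,
) -> RateModelComparison:
    """Fit ER and ARD and compare by LRT (chi-square, 1 df) and AIC.

    The pipeline default follows the LRT; AIC is reported alongside because
    the two can disagree near the significance boundary.
    """
    er = fit_mk(tree, trait, "equal_rates", root_policy=root_policy,
                character=character, **kwargs)
    ard = fit_mk(tree, trait, "all_rates_different", root_policy=root_policy,
                 character=character, **kwargs)
    # models are nested: guard against optimizer jitter putting ARD below ER
    lrt = max(0.0, 2.0 * (ard.log_likelihood - er.log_likelihood))
    p = float(stats.chi2.sf(lrt, df=1))
    return RateModelComparison(
        er=er,
        ard=ard,
        lrt_statistic=lrt,
        lrt_p_value=p,
        preferred_lrt="all_rates_different" if p < alpha else "equal_rates",
        preferred_aic="all_rates_different" if ard.aic < er.aic else "equal_rates",
    )


# ---------------------------------------------------------------------------
# Marginal ancestral-state reconstruction
# ---------------------------------------------------------------------------


@dataclass
class AsrResult:
    """Per-node marginal posterior of state 1, postorder-aligned with
    ``nodes``; ``pp1[i] + pp0[i] = 1`` at every node."""

    tree: Phylogeny
    nodes: list = field(repr=False)
    pp1: list = field(repr=False)
    log_likelihood: float

    def pp(self, node: Node) -> float:
        """Posterior probability of state 1 at *node*."""
        flat = _flat(self.tree)
        return self.pp1[flat.index[id(node)]]

    def pp_for_clade(self, taxa) -> float:
        """PP of state 1 at the MRCA of *taxa* (named-clade reporting)."""
        from .phylo_io import mrca

        return self.pp(mrca(self.tree, taxa))


def ancestral_marginals(
    tree: Phylogeny,
    trait: TraitMatrix,
    model: MkModel,
    character: str | None = None,
) -> AsrResult:
    """Exact marginal posterior of state 1 at every node (up-down pass).

    Tips with observed states get PP 1 for the observed state; missing tips
    get genuine marginals.  At the root the marginal is the normalized
    product of the root distribution and the root partials.
    """
    flat = _flat(tree)
    states = _states_for(tree, trait, character)
    tp = _tip_partials(flat, states)
    q01, q10 = model.q01, model.q10
    L0, L1, logscale = _prune(flat, tp, q01, q10)
    if not math.isfinite(logscale):
        raise ValueError("data have zero likelihood under this model")
    pi0, pi1 = model.pi()
    r = flat.root
    lik = pi0 * L0[r] + pi1 * L1[r]
    lnl = math.log(lik) + logscale

    n = len(flat.nodes)
    # messages from child c to its parent: M_c[i] = (P(t_c) @ L_c)[i]
    M0 = [0.0] * n
    M1 = [0.0] * n
    for c in range(n - 1):  # root excluded
        p00, p01, p10, p11 = _pmat_scalars(q01, q10, flat.brlen[c])
        M0[c] = p00 * L0[c] + p01 * L1[c]
        M1[c] = p10 * L0[c] + p11 * L1[c]

    # outside pass: G[v] = P(rest of data | state at v), normalized per node
    G0 = [0.0] * n
    G1 = [0.0] * n
    G0[r], G1[r] = pi0, pi1
    for v in range(n - 1, -1, -1):
        kids = flat.children[v]
        for c in kids:
            s0, s1 = G0[v], G1[v]
            for d in kids:
                if d != c:
                    s0 *= M0[d]
                    s1 *= M1[d]
            p00, p01, p10, p11 = _pmat_scalars(q01, q10, flat.brlen[c])
            g0 = s0 * p00 + s1 * p10
            g1 = s0 * p01 + s1 * p11
            z = g0 + g1
            if z > 0:
                g0, g1 = g0 / z, g1 / z
            G0[c], G1[c] = g0, g1

    pp1 = [0.0] * n
    for v in range(n):
        w0 = G0[v] * L0[v]
        w1 = G1[v] * L1[v]
        z = w0 + w1
        pp1[v] = w1 / z if z > 0 else 0.5
    return AsrResult(tree=tree, nodes=flat.nodes, pp1=pp1, log_likelihood=lnl)
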