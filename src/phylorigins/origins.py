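"""Bayes-factor tests of single vs. multiple trait origins.

The test compares the hypothesis H0 that a trait arose exactly once on the
tree with the alternative HA that it arose two or more times.  Both sides
are estimated by Monte Carlo: the *prior* probability of each hypothesis
from unconditional forward simulations of the fitted (or supplied) Mk
process, the *posterior* probability from stochastic maps conditioned on
the observed tip states.  Then

    BF = [post P(H0) / post P(HA)] / [prior P(H0) / prior P(HA)],

reported together with log10(BF), 2 ln(BF) and the model posterior
probability ppH0 = BF / (1 + BF) (equal prior model odds).  Histories in
which the trait never arises are excluded before forming the odds — both
hypotheses presuppose the trait evolved — and the excluded fraction is
reported.  A rate-sensitivity grid re-runs the test at exaggerated
gain:loss settings (e.g. 10:1 and 1:10) around the empirical rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import mk, simmap
from .phylo_io import Phylogeny, TraitMatrix

__all__ = [
    "OriginOdds",
    "OriginsResult",
    "origin_odds",
    "bf_to_model_pp",
    "bayes_factor_single_origin",
    "sensitivity_grid",
    "origins_table",
]


class OriginOdds(NamedTuple):
    """Conditional single/multiple-origin probabilities from histories."""

    p_single: float
    p_multiple: float
    n_used: int
    excluded_fraction: float


def _to_counts(histories) -> np.ndarray:
    if isinstance(histories, np.ndarray):
        return histories.astype(np.int64)
    if histories and isinstance(histories[0], simmap.MappedHistory):
        return np.array([simmap.count_origins(h) for h in histories])
    return np.asarray(list(histories), dtype=np.int64)


def origin_odds(histories) -> OriginOdds:
    """P(exactly one origin), P(two or more) among histories with >= 1 origin.

    Accepts a list of :class:`~phylorigins.simmap.MappedHistory` or an array
    of origin counts.  Zero-origin histories are excluded (conditioning on
    the trait having evolved) and their fraction reported.  At least ~100
    histories are recommended for stable odds.  Raises if the trait never
    arises in any history.
    """
    counts = _to_counts(histories)
    if counts.size == 0:
        raise ValueError("origin_odds requires at least one history")
    arose = counts >= 1
    n_used = int(arose.sum())
    if n_used == 0:
        raise ValueError("trait never arises under these settings")
    single = int((counts == 1).sum())
    return OriginOdds(
        p_single=single / n_used,
        p_multiple=(n_used - single) / n_used,
        n_used=n_used,
        excluded_fraction=1.0 - n_used / counts.size,
    )


def bf_to_model_pp(bf: float) -> tuple[float, float]:
    """Model posterior probabilities (ppH0, ppHA) under equal prior odds.

    ppH0 = BF / (1 + BF); monotone increasing in BF; the pair sums to 1.
    """
    if not (bf >= 0):
        raise ValueError(f"Bayes factor must be >= 0, got {bf}")
    if math.isinf(bf):
        return (1.0, 0.0)
    return (bf / (1.0 + bf), 1.0 / (1.0 + bf))


@dataclass
class OriginsResult:
    """One row of the origins analysis (one trait at one rate setting)."""

    trait: str
    gain: float
    loss: float
    rate_label: str
    n_prior: int
    n_maps: int
    prior_p_single: float
    prior_p_multiple: float
    prior_excluded_fraction: float
    post_p_single: float
    post_p_multiple: float
    post_excluded_fraction: float
    bf: float
    log10_bf: float
    twice_ln_bf: float
    pp_h0: float
    pp_ha: float
    se_prior_p_single: float
    se_post_p_single: float
    se_log_bf: float
    se_bf: float
    is_bound: bool = False
    bound: str | None = None


def _binomial_se(p: float, n: int) -> float:
    return math.sqrt(p * (1.0 - p) / n) if n > 0 else float("nan")


def _odds_with_bound(odds: OriginOdds):
    """Half-count correction for degenerate (0 or 1) conditional odds.

    No smoothing is applied in the regular case; a degenerate side is
    replaced by a half count so the BF can be reported as a *bound*, flagged
    rather than silently infinite.
    """
    single = odds.p_single * odds.n_used
    multiple = odds.p_multiple * odds.n_used
    degenerate = single == 0 or multiple == 0
    s = max(single, 0.5)
    m = max(multiple, 0.5)
    return s / (s + m), degenerate


def bayes_factor_single_origin(
    tree: Phylogeny,
    trait: TraitMatrix,
    rates: tuple[float, float],
    n_sim: int = 1000,
    n_maps: int = 1000,
    seed=None,
    character: str | None = None,
    root_policy: str = "flat",
    count_root: bool = True,
    rate_label: str | None = None,
) -> OriginsResult:
    """Run the full single- vs multiple-origins Bayes-factor test.

    *rates* are the fixed (gain, loss) values used for both the prior
    simulations and the posterior maps.  Degenerate odds produce a flagged
    bound (``is_bound``/``bound``) instead of a silent 0 or infinity.
    """
    gain, loss = rates
    if gain <= 0 or loss <= 0:
        raise ValueError("rates must be > 0 for the origins test")
    rng = simmap._as_rng(seed)
    model = mk.MkModel(gain, loss, root_policy=root_policy)
    prior_counts = simmap.prior_origin_counts(
        tree, model, n_sim, rng, count_root=count_root
    )
    post_counts = simmap.posterior_origin_counts(
        tree, trait, model, n_maps, rng, character=character, count_root=count_root
    )
    prior = origin_odds(prior_counts)
    post = origin_odds(post_counts)

    p_prior, deg_prior = _odds_with_bound(prior)
    p_post, deg_post = _odds_with_bound(post)
    prior_odds = p_prior / (1.0 - p_prior)
    post_odds = p_post / (1.0 - p_post)
    bf = post_odds / prior_odds
    is_bound = deg_prior or deg_post
    bound = None
    if is_bound:
        # direction of the bound: a missing HA (or H0) count can only push
        # the true BF further in the direction already reported
        up = (post.p_multiple == 0) or (prior.p_single == 0)
        bound = f"{'>' if up else '<'} {bf:.6g}"

    se_prior = _binomial_se(prior.p_single, prior.n_used)
    se_post = _binomial_se(post.p_single, post.n_used)

    def _inv_var(p, n):  # delta-method variance of ln odds
        return 1.0 / (n * p * (1.0 - p)) if 0 < p < 1 and n > 0 else float("nan")

    var_ln = _inv_var(post.p_single, post.n_used) + _inv_var(
        prior.p_single, prior.n_used
    )
    se_ln = math.sqrt(var_ln) if var_ln == var_ln else float("nan")
    pp_h0, pp_ha = bf_to_model_pp(bf)
    return OriginsResult(
        trait=character or (trait.characters[0] if len(trait.characters) == 1 else "trait"),
        gain=gain,
        loss=loss,
        rate_label=rate_label or f"{gain:g}:{loss:g}",
        n_prior=n_sim,
        n_maps=n_maps,
        prior_p_single=prior.p_single,
        prior_p_multiple=prior.p_multiple,
        prior_excluded_fraction=prior.excluded_fraction,
        post_p_single=post.p_single,
        post_p_multiple=post.p_multiple,
        post_excluded_fraction=post.excluded_fraction,
        bf=bf,
        log10_bf=math.log10(bf),
        twice_ln_bf=2.0 * math.log(bf),
        pp_h0=pp_h0,
        pp_ha=pp_ha,
        se_prior_p_single=se_prior,
        se_post_p_single=se_post,
        se_log_bf=se_ln,
        se_bf=bf * se_ln if se_ln == se_ln else float("nan"),
        is_bound=is_bound,
        bound=bound,
    )


def sensitivity_grid(
    tree: Phylogeny,
    trait: TraitMatrix,
    empirical_rates: tuple[float, float] | None = None,
    ratios: Sequence[tuple[float, float]] = ((10.0, 1.0), (1.0, 10.0)),
    scale: float = 1.0,
    n_sim: int = 1000,
    n_maps: int = 1000,
    seed=None,
    character: str | None = None,
    root_policy: str = "flat",
    count_root: bool = True,
) -> list[OriginsResult]:
    """Origins test at the empirical rates plus each exaggerated ratio.

    With ``empirical_rates=None`` an equal-rates Mk fit supplies them (the
    fitted gain = loss value labels the first row, mirroring rate-grid
    reports such as "0.47:0.47").  Each ratio (a, b) runs at rates
    (a * scale, b * scale).
    """
    rng = simmap._as_rng(seed)
    if empirical_rates is None:
        fit = mk.fit_mk(tree, trait, "equal_rates", root_policy=root_policy,
                        character=character)
        empirical_rates = (fit.model.q01, fit.model.q10)
    g, l = empirical_rates
    settings = [((g, l), f"{g:.2f}:{l:.2f} (empirical)")]
    for a, b in ratios:
        settings.append(((a * scale, b * scale), f"{a:g}:{b:g}"))
    return [
        bayes_factor_single_origin(
            tree,
            trait,
            rates,
            n_sim=n_sim,
            n_maps=n_maps,
            seed=rng,
            character=character,
            root_policy=root_policy,
            count_root=count_root,
            rate_label=label,
        )
        for rates, label in settings
    ]


def origins_table(results: list[OriginsResult]) -> pd.DataFrame:
    """Render results as a table with one row per (trait, rate setting)."""
    return pd.DataFrame(
        [
            {
                "trait": r.trait,
                "rates": r.rate_label,
                "gain": r.gain,
                "loss": r.loss,
                "BF": r.bf,
                "log10BF": r.log10_bf,
                "twice_lnBF": r.twice_ln_bf,
                "ppH0": r.pp_h0,
                "ppHA": r.pp_ha,
                "se_BF": r.se_bf,
                "bound": r.bound or "",
            }
            for r in results
        ]
    )
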