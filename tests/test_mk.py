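"""Mk model: transition probabilities, pruning likelihood, fits, marginals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylorigins import (
    MkModel,
    TraitMatrix,
    ancestral_marginals,
    compare_rate_models,
    fit_mk,
    parse_newick,
    transition_probabilities,
    tree_log_likelihood,
)

from _oracles import enum_likelihood, enum_marginals, pmat_expm
from conftest import mk_trait, yule


def random_states(tree, rng, p_missing=0.15):
    out = {}
    for label in tree.tip_labels:
        u = rng.random()
        out[label] = None if u < p_missing else int(u > 0.5 + p_missing / 2)
    if all(v is None for v in out.values()):
        out[tree.tip_labels[0]] = 1
    return out


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        P = transition_probabilities(MkModel(3.2, 0.7), 0.0)
        assert np.allclose(P, np.eye(2))

    def test_symmetric_long_time_limit(self):
        P = transition_probabilities(MkModel(1.0, 1.0), 100.0)
        assert np.allclose(P, 0.5, atol=1e-12)

    def test_closed_form_value(self):
        P = transition_probabilities(MkModel(0.47, 0.47), 1.0)
        assert P[0, 1] == pytest.approx(0.5 * (1 - math.exp(-0.94)), abs=1e-12)

    @pytest.mark.parametrize("q01,q10,t", [
        (0.47, 0.47, 1.0), (2.0, 0.1, 0.3), (0.0, 1.5, 2.0), (5.0, 3.0, 0.05),
    ])
    def test_matches_matrix_exponential(self, q01, q10, t):
        P = transition_probabilities(MkModel(q01, q10), t)
        assert np.allclose(P, pmat_expm(q01, q10, t), atol=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(
        q01=st.floats(0.0, 50.0),
        q10=st.floats(0.0, 50.0),
        t1=st.floats(0.0, 10.0),
        t2=st.floats(0.0, 10.0),
    )
    def test_rows_stochastic_and_semigroup(self, q01, q10, t1, t2):
        m = MkModel(q01, q10)
        P1 = transition_probabilities(m, t1)
        assert (P1 >= 0).all() and (P1 <= 1).all()
        assert np.allclose(P1.sum(axis=1), 1.0, atol=1e-12)
        lhs = P1 @ transition_probabilities(m, t2)
        assert np.allclose(lhs, transition_probabilities(m, t1 + t2), atol=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probabilities(MkModel(1, 1), -0.1)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            MkModel(-0.1, 1.0)
        with pytest.raises(ValueError):
            MkModel(float("nan"), 1.0)


class TestTreeLogLikelihood:
    def test_two_tip_hand_expansion(self):
        t = parse_newick("(A:1,B:1);")
        traits = TraitMatrix.from_dict({"A": 0, "B": 0})
        m = MkModel(0.5, 0.5)
        P = transition_probabilities(m, 1.0)
        hand = 0.5 * (P[0, 0] ** 2 + P[1, 0] ** 2)
        assert tree_log_likelihood(t, traits, m) == pytest.approx(math.log(hand))

    def test_all_missing_gives_zero(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        traits = TraitMatrix.from_dict({"A": None, "B": None, "C": None})
        assert tree_log_likelihood(t, traits, MkModel(0.8, 0.3)) == pytest.approx(0.0)

    def test_absent_tip_errors(self):
        t = parse_newick("(A:1,B:1);")
        traits = TraitMatrix.from_dict({"A": 0})
        with pytest.raises(ValueError, match="absent"):
            tree_log_likelihood(t, traits, MkModel(1, 1))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_on_six_tip_trees(self, seed):
        rng = np.random.default_rng(seed)
        t = yule(seed, 6)
        states = random_states(t, rng)
        q01, q10 = rng.uniform(0.05, 3.0, size=2)
        traits = TraitMatrix.from_dict(states)
        got = tree_log_likelihood(t, traits, MkModel(q01, q10))
        want = math.log(enum_likelihood(t, states, q01, q10))
        assert got == pytest.approx(want, rel=1e-10)

    def test_invariant_to_child_order(self):
        a = parse_newick("((A:1,B:2):0.5,C:3);")
        b = parse_newick("(C:3,(B:2,A:1):0.5);")
        traits = TraitMatrix.from_dict({"A": 0, "B": 1, "C": 1})
        m = MkModel(0.7, 0.2)
        assert tree_log_likelihood(a, traits, m) == pytest.approx(
            tree_log_likelihood(b, traits, m), rel=1e-14
        )

    def test_invariant_to_degree_two_suppression(self):
        unary = parse_newick("((A:1):1,B:2);")  # degree-2 node above A
        flat = parse_newick("(A:2,B:2);")
        traits = TraitMatrix.from_dict({"A": 0, "B": 1})
        m = MkModel(0.9, 0.4)
        assert tree_log_likelihood(unary, traits, m) == pytest.approx(
            tree_log_likelihood(flat, traits, m), rel=1e-14
        )


class TestFitMk:
    def test_constant_trait_hits_lower_bound(self):
        t = yule(3, 30)
        traits = TraitMatrix.from_dict({l: 0 for l in t.tip_labels})
        fit = fit_mk(t, traits, "equal_rates")
        assert fit.model.q01 <= 1e-6
        assert fit.log_likelihood == pytest.approx(math.log(0.5), abs=1e-4)

    def test_ard_never_below_er(self):
        for seed in (1, 4, 9):
            tree, traits, _ = mk_trait(seed, 40, gain=0.6, loss=0.2)
            er = fit_mk(tree, traits, "equal_rates")
            ard = fit_mk(tree, traits, "all_rates_different")
            assert ard.log_likelihood >= er.log_likelihood - 1e-8

    def test_comparison_report_consistency(self):
        tree, traits, _ = mk_trait(2, 60)
        rep = compare_rate_models(tree, traits)
        assert rep.lrt_statistic == pytest.approx(
            2 * (rep.ard.log_likelihood - rep.er.log_likelihood), abs=1e-9
        )
        assert 0 <= rep.lrt_p_value <= 1
        assert rep.er.aic == pytest.approx(2 - 2 * rep.er.log_likelihood)
        assert rep.ard.aic == pytest.approx(4 - 2 * rep.ard.log_likelihood)

    def test_er_consistency_bias_shrinks_with_tips(self):
        """ER estimates on ER-simulated data improve from 100 to 500 tips."""
        errs = {}
        for n in (100, 500):
            rel = []
            for seed in range(6):
                tree, traits, _ = mk_trait(1000 + seed, n, gain=0.47, loss=0.47)
                fit = fit_mk(tree, traits, "equal_rates")
                rel.append(abs(fit.model.q01 - 0.47) / 0.47)
            errs[n] = np.median(rel)
        assert errs[500] < errs[100]


class TestAncestralMarginals:
    def test_observed_tip_pp_is_one(self):
        t = parse_newick("(A:1,B:1);")
        traits = TraitMatrix.from_dict({"A": 1, "B": 0})
        res = ancestral_marginals(t, traits, MkModel(0.5, 0.5))
        assert res.pp(t.tip("A")) == pytest.approx(1.0)
        assert res.pp(t.tip("B")) == pytest.approx(0.0)

    def test_two_tip_symmetric_root(self):
        t = parse_newick("(A:1,B:1);")
        traits = TraitMatrix.from_dict({"A": 0, "B": 1})
        res = ancestral_marginals(t, traits, MkModel(0.5, 0.5))
        assert res.pp(t.root) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_on_six_tip_trees(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = yule(100 + seed, 6)
        states = random_states(t, rng)
        q01, q10 = rng.uniform(0.05, 3.0, size=2)
        traits = TraitMatrix.from_dict(states)
        res = ancestral_marginals(t, traits, MkModel(q01, q10))
        want = enum_marginals(t, states, q01, q10)
        assert np.allclose(res.pp1, want, atol=1e-10)

    def test_root_marginal_equals_normalized_root_partials(self):
        """Under the flat policy the root PP must equal L1/(L0+L1)."""
        tree, traits, _ = mk_trait(5, 12)
        m = MkModel(0.8, 0.3)
        res = ancestral_marginals(tree, traits, m)
        # independent route: likelihood with root pinned via fixed policies
        l1 = math.exp(
            tree_log_likelihood(tree, traits, MkModel(0.8, 0.3, "fixed", (0.0, 1.0)))
        )
        l0 = math.exp(
            tree_log_likelihood(tree, traits, MkModel(0.8, 0.3, "fixed", (1.0, 0.0)))
        )
        assert res.pp(tree.root) == pytest.approx(l1 / (l0 + l1), rel=1e-10)

    def test_pp_sums_to_one(self):
        tree, traits, _ = mk_trait(8, 25)
        res = ancestral_marginals(tree, traits, MkModel(0.6, 0.9))
        assert all(0.0 <= p <= 1.0 for p in res.pp1)


class TestRootPolicies:
    def test_stationary_pi(self):
        assert MkModel(1.0, 3.0, "stationary").pi() == pytest.approx((0.75, 0.25))

    def test_fixed_pi_validated(self):
        with pytest.raises(ValueError):
            MkModel(1, 1, "fixed", (0.7, 0.7))
        with pytest.raises(ValueError):
            MkModel(1, 1, "fixed")
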