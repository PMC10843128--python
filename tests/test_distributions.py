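"""Distribution algebra: construction invariants, projections, priors,
surprisal, entropy, KL divergence and support policies."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infodecomp.distributions import (
    InvalidDistributionError,
    JointDistribution,
    SupportError,
    apply_support_policy,
    condition,
    cross_entropy,
    kl_divergence,
    local_surprisal,
    marginalize,
    product_of_marginals,
    read_json,
    read_tsv,
    shannon_entropy,
    uniform_prior,
    write_json,
    write_tsv,
)
from infodecomp.fixtures import random_distribution


class TestConstruction:
    def test_zero_probability_states_dropped(self):
        P = JointDistribution(["A", "B"], None, {("0", "0"): 0.5, ("1", "1"): 0.5, ("0", "1"): 0.0})
        assert set(P.support()) == {("0", "0"), ("1", "1")}

    @pytest.mark.parametrize(
        "pmf",
        [
            {("0",): -0.2, ("1",): 1.2},  # negative mass
            {("0",): 0.4, ("1",): 0.4},  # does not sum to 1
            {("0", "0"): 1.0},  # wrong arity
            {},  # empty support
        ],
    )
    def test_invalid_tables_rejected(self, pmf):
        with pytest.raises(InvalidDistributionError):
            JointDistribution(["A"], None, pmf)

    def test_symbol_outside_declared_alphabet_rejected(self):
        with pytest.raises(InvalidDistributionError):
            JointDistribution(["A"], [("0", "1")], {("2",): 1.0})

    def test_ingest_renormalization_is_opt_in(self):
        pmf = {("0",): 0.5 + 2e-7, ("1",): 0.5}
        with pytest.raises(InvalidDistributionError):
            JointDistribution(["A"], None, pmf)
        P = JointDistribution(["A"], None, pmf, normalize=True)
        assert math.isclose(sum(P.pmf.values()), 1.0, abs_tol=1e-15)


class TestMarginalize(object):
    def test_xor_single_variable_is_fair_coin(self, xor):
        m = marginalize(xor, [0])
        assert m.prob(("0",)) == pytest.approx(0.5, abs=1e-12)
        assert m.prob(("1",)) == pytest.approx(0.5, abs=1e-12)

    def test_all_variables_is_identity(self, xor):
        assert marginalize(xor, [0, 1, 2]).allclose(xor)

    def test_uniform_stays_uniform(self, uniform3):
        m = marginalize(uniform3, [0, 1])
        assert all(p == pytest.approx(0.25, abs=1e-12) for p in m.pmf.values())

    def test_invalid_subsets_rejected(self, xor):
        for bad in ([], [0, 0], [5]):
            with pytest.raises(ValueError):
                marginalize(xor, bad)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_chain_rule(self, seed):
        """Marginalizing in two steps equals marginalizing once: for B within
        A, marg(marg(P, A), B-positions) == marg(P, B)."""
        P = random_distribution(3, 2, seed=seed)
        mA = marginalize(P, [0, 2])
        assert marginalize(mA, [1]).allclose(marginalize(P, [2]), atol=1e-12)
        assert marginalize(mA, [0, 1]).allclose(mA, atol=1e-12)


class TestCondition:
    def test_xor_given_target_zero(self, xor):
        c = condition(xor, 2, "0")
        assert c.variables == ("X1", "X2")
        assert c.prob(("0", "0")) == pytest.approx(0.5, abs=1e-12)
        assert c.prob(("1", "1")) == pytest.approx(0.5, abs=1e-12)
        assert len(c.pmf) == 2

    def test_independent_variables_unchanged(self, uniform3):
        c = condition(uniform3, 0, "1")
        assert all(p == pytest.approx(0.25, abs=1e-12) for p in c.pmf.values())
        assert len(c.pmf) == 4

    def test_law_of_total_probability(self):
        P = random_distribution(3, 2, seed=7)
        rest = marginalize(P, [0, 1])
        mixed = {}
        for (t,), pt in P.marginal_probs((2,)).items():
            c = condition(P, 2, t)
            for s, p in c.pmf.items():
                mixed[s] = mixed.get(s, 0.0) + pt * p
        assert all(abs(mixed[s] - rest.prob(s)) < 1e-12 for s in mixed)

    def test_zero_probability_value_rejected(self, xor):
        with pytest.raises(SupportError):
            condition(xor, 2, "2")


class TestPriors:
    def test_product_of_marginals_of_xor_is_uniform(self, xor):
        Q = product_of_marginals(xor)
        assert len(Q.pmf) == 8
        assert all(p == pytest.approx(0.125, abs=1e-12) for p in Q.pmf.values())

    def test_product_distribution_is_fixed_point(self, uniform3):
        assert product_of_marginals(uniform3).allclose(uniform3)

    def test_giant_bit_marginal_product_is_uniform(self, giant3):
        Q = product_of_marginals(giant3)
        assert all(p == pytest.approx(0.125, abs=1e-12) for p in Q.pmf.values())

    def test_uniform_prior_spans_declared_alphabets(self, xor):
        U = uniform_prior(xor)
        assert len(U.pmf) == 8
        assert kl_divergence(xor, U) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_prior_fixed_point(self, uniform3):
        assert uniform_prior(uniform3).allclose(uniform3)


class TestSurprisalEntropy:
    def test_uniform_full_state_surprisal(self, uniform3):
        assert local_surprisal(uniform3, ("0", "1", "0")) == pytest.approx(3.0, abs=1e-12)

    def test_xor_projections(self, xor):
        assert local_surprisal(xor, ("0", "0", "0"), [0]) == pytest.approx(1.0, abs=1e-12)
        assert local_surprisal(xor, ("0", "0", "0")) == pytest.approx(2.0, abs=1e-12)

    def test_zero_probability_state_names_offender(self, xor):
        with pytest.raises(SupportError, match="X1"):
            local_surprisal(xor, ("0", "0", "1"))

    def test_entropy_values(self, xor, uniform3):
        assert shannon_entropy(xor) == pytest.approx(2.0, abs=1e-12)
        assert shannon_entropy(uniform3) == pytest.approx(3.0, abs=1e-12)
        point = JointDistribution(["A", "B"], [("0", "1")] * 2, {("0", "1"): 1.0})
        assert shannon_entropy(point) == pytest.approx(0.0, abs=1e-12)

    def test_entropy_is_expected_surprisal(self):
        P = random_distribution(2, 3, seed=11)
        e = sum(p * local_surprisal(P, s) for s, p in P.pmf.items())
        assert shannon_entropy(P) == pytest.approx(e, abs=1e-12)


class TestKL:
    def test_identity_is_zero(self, xor):
        assert kl_divergence(xor, xor) == pytest.approx(0.0, abs=1e-12)

    def test_xor_against_its_marginal_product(self, xor):
        assert kl_divergence(xor, product_of_marginals(xor)) == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_direct_sum_equals_expected_surprisal_difference(self, seed):
        """The sum form of D(P||Q) equals E_P[hQ(x) - hP(x)]."""
        P = random_distribution(3, 2, seed=seed)
        Q = random_distribution(3, 2, seed=seed + 77_777)
        direct = kl_divergence(P, Q)
        local = sum(
            p * (local_surprisal(Q, s) - local_surprisal(P, s)) for s, p in P.pmf.items()
        )
        assert direct == pytest.approx(local, abs=1e-9)
        assert direct >= -1e-9
        assert cross_entropy(P, Q) == pytest.approx(direct + shannon_entropy(P), abs=1e-9)

    def test_independence_prior_never_less_random(self):
        for seed in range(5):
            P = random_distribution(3, 2, seed=seed)
            assert shannon_entropy(product_of_marginals(P)) >= shannon_entropy(P) - 1e-9


class TestSupportPolicy:
    @staticmethod
    def _mismatched_pair():
        P = JointDistribution(
            ["A", "B"], [("0", "1")] * 2,
            {("0", "0"): 0.5, ("1", "1"): 0.4, ("0", "1"): 0.1},
        )
        Q = JointDistribution(["A", "B"], [("0", "1")] * 2, {("0", "0"): 0.5, ("1", "1"): 0.5})
        return P, Q

    def test_strict_passes_nested_support(self, xor):
        U = uniform_prior(xor)
        P2, Q2 = apply_support_policy(xor, U, "strict")
        assert P2 is xor and Q2 is U

    def test_strict_raises_on_violation(self):
        P, Q = self._mismatched_pair()
        with pytest.raises(SupportError):
            apply_support_policy(P, Q, "strict")

    def test_restrict_drops_and_renormalizes(self):
        P, Q = self._mismatched_pair()
        P2, _ = apply_support_policy(P, Q, "restrict")
        assert P2.prob(("0", "1")) == 0.0
        assert P2.prob(("0", "0")) == pytest.approx(0.5 / 0.9, abs=1e-12)
        assert P2.prob(("1", "1")) == pytest.approx(0.4 / 0.9, abs=1e-12)

    def test_pseudocount_covers_full_alphabet_product(self):
        P, Q = self._mismatched_pair()
        _, Q2 = apply_support_policy(P, Q, "pseudocount", eps=1e-6)
        assert len(Q2.pmf) == 4
        assert math.isfinite(kl_divergence(P, Q2))

    def test_pseudocount_requires_positive_eps(self):
        P, Q = self._mismatched_pair()
        with pytest.raises(ValueError):
            apply_support_policy(P, Q, "pseudocount", eps=0.0)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["tsv", "csv", "json"])
    def test_write_read_identity(self, tmp_path, xor, fmt):
        path = tmp_path / f"xor.{fmt}"
        if fmt == "json":
            write_json(xor, path)
            back = read_json(path)
        else:
            write_tsv(xor, path)
            back = read_tsv(path)
        assert back.variables == xor.variables
        assert back.allclose(xor, atol=1e-12)
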