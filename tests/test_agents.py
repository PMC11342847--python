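"""Learning-model update rules, belief updating and the CVaR readout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvarlearn import agents
from cvarlearn.agents import (
    BeliefGrid,
    CVaRParams,
    PEIRSParams,
    RW1Params,
    RW2Params,
    RWState,
    bayes_update,
    cvar_readout,
    event_density_params,
    peirs_decision_values,
    peirs_step,
    positive_learning_bias,
    rw1_step,
    rw2_step,
    softmax_prob,
    value_at_risk,
)

outcomes = st.floats(min_value=0.01, max_value=0.99)


class TestSoftmax:
    def test_equal_values_are_even(self):
        for beta in (0.0, 1.0, 50.0):
            assert softmax_prob(0.5, 0.5, beta) == pytest.approx(0.5)

    def test_unit_logit(self):
        assert softmax_prob(0.6, 0.5, 10.0) == pytest.approx(1 / (1 + np.exp(-1)))

    def test_zero_beta_is_random(self):
        assert softmax_prob(0.9, 0.1, 0.0) == 0.5
        assert softmax_prob(-2.0, 7.0, 0.0) == 0.5

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            softmax_prob(np.nan, 0.5, 1.0)


class TestRescorlaWagner:
    def test_rw1_update(self):
        state = RWState.initial("rw1")
        new = rw1_step(state, 0, 0.99, RW1Params(alpha=0.2, beta=1.0))
        assert new.v[0] == pytest.approx(0.598)
        assert new.v[1] == 0.5  # other deck untouched

    def test_rw1_fixed_points(self):
        state = RWState.initial("rw1")
        assert rw1_step(state, 0, 0.7, RW1Params(0.0, 1.0)).v[0] == 0.5
        assert rw1_step(state, 1, 0.5, RW1Params(0.3, 1.0)).v[1] == 0.5

    def test_rw2_asymmetric_branches(self):
        p = RW2Params(alpha_pos=0.3, alpha_neg=0.1, beta=1.0)
        state = RWState.initial("rw2")
        assert rw2_step(state, 0, 0.4, p).v[0] == pytest.approx(0.49)
        assert rw2_step(state, 0, 0.6, p).v[0] == pytest.approx(0.53)

    def test_rw2_tie_uses_positive_rate(self):
        # delta exactly 0: the positive branch is taken, value unchanged
        p = RW2Params(alpha_pos=0.9, alpha_neg=0.1, beta=1.0)
        assert rw2_step(RWState.initial("rw2"), 0, 0.5, p).v[0] == 0.5

    @given(alpha=st.floats(0.01, 0.99), stream=st.lists(outcomes, min_size=1, max_size=40))
    @settings(deadline=None, max_examples=40)
    def test_rw2_symmetric_equals_rw1_bitwise(self, alpha, stream):
        s1 = RWState.initial("rw1")
        s2 = RWState.initial("rw2")
        p1 = RW1Params(alpha=alpha, beta=1.0)
        p2 = RW2Params(alpha_pos=alpha, alpha_neg=alpha, beta=1.0)
        for r in stream:
            s1 = rw1_step(s1, 0, r, p1)
            s2 = rw2_step(s2, 0, r, p2)
        assert s1.v[0] == s2.v[0]  # bit-for-bit

    @pytest.mark.parametrize("ap,an,expected", [
        (0.3, 0.1, 0.75), (0.2, 0.2, 0.5), (0.4, 0.1, 0.8),
    ])
    def test_positive_learning_bias(self, ap, an, expected):
        assert positive_learning_bias(ap, an) == pytest.approx(expected)

    def test_positive_learning_bias_rejects_zero_sum(self):
        with pytest.raises(ValueError):
            positive_learning_bias(0.0, 0.0)


class TestPEIRS:
    def test_spread_update(self):
        p = PEIRSParams(alpha_q=0.0, alpha_s=0.5, omega=0.0, s0=0.1, beta=1.0)
        state = RWState.initial("peirs", p)
        new = peirs_step(state, 0, 0.2, p)  # delta = -0.3, |delta| = 0.3
        assert new.s[0] == pytest.approx(0.2)

    def test_spread_fixed_points(self):
        p = PEIRSParams(0.0, 0.0, 0.0, 0.1, 1.0)
        assert peirs_step(RWState.initial("peirs", p), 0, 0.9, p).s[0] == 0.1
        p2 = PEIRSParams(0.0, 0.7, 0.0, 0.3, 1.0)
        # |delta| = S: spread unchanged
        assert peirs_step(RWState.initial("peirs", p2), 0, 0.8, p2).s[0] == pytest.approx(0.3)

    def test_decision_values_omega_zero(self):
        p = PEIRSParams(0.1, 0.1, 0.0, 0.4, 1.0)
        state = RWState(v=np.array([0.7, 0.6]), s=np.array([0.4, 0.4]))
        assert peirs_decision_values(state, p) == pytest.approx((0.7, 0.6))

    def test_decision_values_saturating_omega(self):
        p = PEIRSParams(0.1, 0.1, 500.0, 0.4, 1.0)
        state = RWState(v=np.array([0.7, 0.7]), s=np.array([0.2, 0.1]))
        va, vb = peirs_decision_values(state, p)
        assert va == pytest.approx(0.9, abs=1e-6)
        assert vb == pytest.approx(0.8, abs=1e-6)

    def test_decision_values_neutral_pair(self):
        p = PEIRSParams(0.1, 0.1, 7.0, 0.4, 1.0)
        state = RWState(v=np.array([0.5, 0.5]), s=np.array([0.3, 0.1]))
        assert peirs_decision_values(state, p) == pytest.approx((0.5, 0.5))


class TestEvidenceDensity:
    def test_symmetric_case(self):
        a, b = event_density_params(0.5, 0.009)
        assert a == pytest.approx(-0.5 * (0.25 - 0.5 + 0.009) / 0.009, abs=1e-10)
        assert a == b

    def test_mirror_symmetry(self):
        a1, b1 = event_density_params(0.7, 0.009)
        a2, b2 = event_density_params(0.3, 0.009)
        assert a1 == pytest.approx(b2, abs=1e-12)
        assert b1 == pytest.approx(a2, abs=1e-12)

    def test_inverts_beta_moment_map(self, rng):
        # mean and variance identities to 1e-10 on 1000 random feasible pairs
        for _ in range(1000):
            r = rng.uniform(0.02, 0.98)
            v = rng.uniform(1e-4, 0.9) * r * (1 - r)
            a, b = event_density_params(r, v)
            assert a > 0 and b > 0
            mean = a / (a + b)
            var = a * b / ((a + b) ** 2 * (a + b + 1))
            assert mean == pytest.approx(r, abs=1e-10)
            assert var == pytest.approx(v, abs=1e-10)

    def test_infeasible_variance_names_outcome(self):
        with pytest.raises(ValueError, match="0.99"):
            event_density_params(0.99, 0.02)


class TestBayesUpdate:
    def test_single_observation_mode_near_outcome(self):
        b = bayes_update(BeliefGrid.flat(), 0.5)
        assert b.grid[np.argmax(b.density)] == pytest.approx(0.5, abs=0.003)
        b2 = bayes_update(BeliefGrid.flat(), 0.745)
        assert b2.grid[np.argmax(b2.density)] == pytest.approx(0.745, abs=0.05)

    def test_repeated_identical_outcomes_concentrate_mean(self):
        b = BeliefGrid.flat()
        for _ in range(30):
            b = bayes_update(b, 0.5)
        assert b.mean() == pytest.approx(0.5, abs=0.01)

    @given(stream=st.lists(outcomes, min_size=1, max_size=30))
    @settings(deadline=None, max_examples=30)
    def test_normalization_preserved(self, stream):
        b = BeliefGrid.flat(n=97)
        for r in stream:
            b = bayes_update(b, r)
            assert abs(b.density.sum() - 1.0) <= 1e-9

    def test_rejects_unnormalized_belief(self):
        b = BeliefGrid.flat()
        b.density = b.density * 2
        with pytest.raises(ValueError):
            bayes_update(b, 0.5)

    def test_belief_mean_tracks_outcome_mean(self, rng):
        # the estimate of the value distribution is an unbiased running
        # average of outcomes (plus the washing-out 0.5 prior)
        stream = rng.uniform(0.2, 0.9, size=25)
        b = BeliefGrid.flat()
        for r in stream:
            b = bayes_update(b, r)
        expected = (0.5 + stream.sum()) / (1 + len(stream))
        assert b.mean() == pytest.approx(expected, abs=0.005)


def _cvar_oracle(grid, density, eta):
    """Exhaustive conditional expectation over the discrete grid."""
    cdf = np.cumsum(density)
    cdf /= cdf[-1]
    q = 1 + eta if eta <= 0 else eta
    idx = next(i for i in range(len(grid)) if cdf[i] >= q - 1e-12)
    pts = range(0, idx + 1) if eta <= 0 else range(idx, len(grid))
    num = sum(grid[i] * density[i] for i in pts)
    den = sum(density[i] for i in pts)
    return num / den


class TestCVaRReadout:
    def test_eta_zero_is_belief_mean(self, rng):
        b = BeliefGrid.flat()
        for r in rng.uniform(0.1, 0.9, size=7):
            b = bayes_update(b, r)
        assert cvar_readout(b, 0.0) == pytest.approx(b.mean(), abs=1e-12)

    def test_uniform_tails(self):
        # uniform belief on (0, 1): E[Z | Z <= 0.05] = 0.025 etc.
        n = 1000
        grid = np.linspace(0.5 / n, 1 - 0.5 / n, n)
        b = BeliefGrid(grid=grid, density=np.full(n, 1.0 / n))
        assert cvar_readout(b, -0.95) == pytest.approx(0.025, abs=0.002)
        assert cvar_readout(b, 0.95) == pytest.approx(0.975, abs=0.002)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            b = BeliefGrid.flat(n=211)
            for r in rng.uniform(0.05, 0.95, size=rng.integers(0, 12)):
                b = bayes_update(b, r)
            for eta in np.linspace(-0.99, 0.99, 67):
                expected = _cvar_oracle(b.grid, b.density, float(eta))
                assert cvar_readout(b, float(eta)) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_eta_and_bracketed(self, rng):
        for _ in range(5):
            b = BeliefGrid.flat(n=151)
            for r in rng.uniform(0.05, 0.95, size=rng.integers(1, 15)):
                b = bayes_update(b, r)
            etas = np.linspace(-0.99, 0.99, 41)
            vals = [cvar_readout(b, float(e)) for e in etas]
            assert all(v2 >= v1 - 1e-12 for v1, v2 in zip(vals, vals[1:]))
            mean = b.mean()
            for e, v in zip(etas, vals):
                assert b.grid[0] - 1e-12 <= v <= b.grid[-1] + 1e-12
                if e < 0:
                    assert v <= mean + 1e-12
                elif e > 0:
                    assert v >= mean - 1e-12

    def test_var_quantile_on_uniform(self):
        b = BeliefGrid.flat(n=9601)
        var = value_at_risk(b, -0.95)
        mass = b.density[b.grid <= var + 1e-12].sum()
        assert mass == pytest.approx(0.05, abs=1.0 / 9601)

    def test_eta_bounds_enforced(self):
        with pytest.raises(ValueError):
            cvar_readout(BeliefGrid.flat(), 1.0)
        with pytest.raises(ValueError):
            cvar_readout(BeliefGrid.flat(), -1.0)
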