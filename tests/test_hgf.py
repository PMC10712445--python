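"""Perceptual model: update equations, reductions, invariants, routing."""

import copy

import numpy as np
import pytest

from conftest import random_hgf_draws
from efficacy_hgf.hgf import (BeliefState, HGFParams, filter_inputs,
                              filter_session, hgf_update, sigmoid)


def _params_from_draw(d, kappa=None, n_levels=None):
    return HGFParams(
        omega2=d["omega2"], omega3=d["omega3"],
        kappa=d["kappa"] if kappa is None else kappa,
        mu2_0=d["mu2"], sigma2_0=d["sigma2"],
        mu3_0=d["mu3"], sigma3_0=d["sigma3"],
        n_levels=d["n_levels"] if n_levels is None else n_levels,
    )


def test_sigmoid_values():
    assert sigmoid(0.0) == 0.5
    assert sigmoid(2.0) == pytest.approx(0.8807970779778823, abs=1e-12)
    for x in np.linspace(-20, 20, 41):
        assert sigmoid(x) == pytest.approx(1.0 - sigmoid(-x), abs=1e-12)
        assert 0.0 < sigmoid(x) < 1.0


def test_update_hand_example():
    """Unit prior, no diffusion, reward observed: posterior lands at
    (mu2, sigma2) = (0.4, 0.8)."""
    params = HGFParams(omega2=-700.0, kappa=0.0, mu2_0=0.0, sigma2_0=1.0)
    state, diag = hgf_update(params.initial_state(), 1, params)
    assert diag.mu_hat1 == pytest.approx(0.5, abs=1e-12)
    assert diag.delta1 == pytest.approx(0.5, abs=1e-12)
    assert diag.sigma_hat2 == pytest.approx(1.0, abs=1e-12)
    assert state.sigma2 == pytest.approx(0.8, abs=1e-12)
    assert state.mu2 == pytest.approx(0.4, abs=1e-12)


def test_update_symmetry_at_indifference():
    params = HGFParams(omega2=-2.0, n_levels=2, mu2_0=0.0, sigma2_0=1.0)
    s1, _ = hgf_update(params.initial_state(), 1, params)
    s0, _ = hgf_update(params.initial_state(), 0, params)
    assert s1.mu2 == pytest.approx(-s0.mu2, abs=1e-12)
    assert s1.sigma2 == pytest.approx(s0.sigma2, abs=1e-12)


def test_scalar_oracle_matches_production_kernel():
    """The naive scalar update chain and the array kernel agree to 1e-12,
    including on which trial (if any) the precision failure occurs."""
    from efficacy_hgf.hgf import NonPositivePrecisionError
    rng = np.random.default_rng(123)
    for d in random_hgf_draws(1000, seed=99):
        params = _params_from_draw(d)
        n = int(rng.integers(1, 6))
        u_seq = rng.integers(2, size=n)
        state = params.initial_state()
        try:
            traj = filter_inputs(u_seq, params)
        except NonPositivePrecisionError:
            with pytest.raises(NonPositivePrecisionError):
                for u in u_seq:
                    state, _ = hgf_update(state, int(u), params)
            continue
        for k, u in enumerate(u_seq):
            state, diag = hgf_update(state, int(u), params)
            assert diag.mu_hat1 == pytest.approx(traj.mu_hat1[k], abs=1e-12)
            assert diag.sigma_hat2 == pytest.approx(traj.sigma_hat2[k], abs=1e-12)
            assert state.mu2 == pytest.approx(traj.mu2[k], abs=1e-12)
            assert state.sigma2 == pytest.approx(traj.sigma2[k], abs=1e-12)
            assert state.mu3 == pytest.approx(traj.mu3[k], abs=1e-12)
            assert state.sigma3 == pytest.approx(traj.sigma3[k], abs=1e-12)


def test_kappa_zero_collapses_three_to_two_levels():
    rng = np.random.default_rng(7)
    for rep in range(100):
        u = rng.integers(2, size=27)
        omega2 = rng.uniform(-8, -1)
        t3 = filter_inputs(u, HGFParams(omega2=omega2, kappa=0.0, n_levels=3))
        t2 = filter_inputs(u, HGFParams(omega2=omega2, n_levels=2))
        np.testing.assert_allclose(t3.mu2, t2.mu2, atol=1e-10)
        np.testing.assert_allclose(t3.sigma2, t2.sigma2, atol=1e-10)
        np.testing.assert_allclose(t3.sigma_hat2, t2.sigma_hat2, atol=1e-10)


def test_positivity_and_precision_floor():
    from efficacy_hgf.hgf import NonPositivePrecisionError
    rng = np.random.default_rng(17)
    for d in random_hgf_draws(200, seed=5):
        params = _params_from_draw(d)
        try:
            traj = filter_inputs(rng.integers(2, size=30), params)
        except NonPositivePrecisionError:
            continue  # positivity is asserted on valid runs only
        assert np.all(traj.sigma2 > 0)
        assert np.all(traj.sigma_hat2 > 0)
        assert np.all(traj.sigma3 > 0)
        pi_hat1 = 1.0 / (traj.mu_hat1 * (1.0 - traj.mu_hat1))
        assert np.all(pi_hat1 >= 4.0 - 1e-12)
        # predictive variance exceeds the carried-over posterior variance
        prev_sigma2 = np.concatenate([[params.sigma2_0], traj.sigma2[:-1]])
        assert np.all(traj.sigma_hat2 > prev_sigma2)
    # equality of the precision floor only at indifference
    t = filter_inputs([1], HGFParams(mu2_0=0.0))
    assert 1.0 / (t.mu_hat1[0] * (1 - t.mu_hat1[0])) == pytest.approx(4.0)


def test_no_lookahead():
    rng = np.random.default_rng(31)
    u = rng.integers(2, size=40)
    params = HGFParams(omega2=-3.0)
    full = filter_inputs(u, params)
    for k in (1, 10, 25):
        prefix = filter_inputs(u[:k], params)
        np.testing.assert_array_equal(prefix.mu2, full.mu2[:k])
        np.testing.assert_array_equal(prefix.sigma_hat2, full.sigma_hat2[:k])


def test_consistent_input_monotone_learning():
    traj = filter_inputs(np.ones(27, dtype=int), HGFParams(omega2=-4.0))
    assert np.all(np.diff(traj.mu2) > 0)
    # uncertainty contracts while outcomes remain informative (it drifts
    # back up late, once mu_hat1 saturates and trials carry no information)
    assert np.all(np.diff(traj.sigma_hat2[:9]) < 0)
    assert traj.sigma_hat2.min() < 0.7 * traj.sigma_hat2[0]


def test_frozen_beliefs_fixed_point():
    params = HGFParams(omega2=-700.0, kappa=0.0, sigma2_0=1e-12, mu2_0=0.7)
    traj = filter_inputs(np.ones(20, dtype=int), params)
    np.testing.assert_allclose(traj.mu2, 0.7, atol=1e-9)


def test_condition_routing_independence(played_session, us3_agent):
    """Shuffling noChoice outcomes leaves the Choice hierarchy untouched."""
    _, agent, _ = us3_agent
    base = filter_session(played_session, agent["Choice"], agent["noChoice"])
    shuffled = copy.deepcopy(played_session)
    rng = np.random.default_rng(0)
    nc = [t for t in shuffled.trials if t.condition == "noChoice"]
    rewards = [t.rewarded_stimulus for t in nc]
    rng.shuffle(rewards)
    for t, r in zip(nc, rewards):
        t.rewarded_stimulus = r
        t.reward = int(t.selected == r)
    after = filter_session(shuffled, agent["Choice"], agent["noChoice"])
    np.testing.assert_array_equal(base.mu_self, after.mu_self)
    np.testing.assert_array_equal(base.sigma_self, after.sigma_self)


def test_filter_session_shapes_and_replay(played_session, us3_agent):
    _, agent, _ = us3_agent
    pb1 = filter_session(played_session, agent["Choice"], agent["noChoice"])
    pb2 = filter_session(played_session, agent["Choice"], agent["noChoice"])
    assert len(pb1.choice) == 27 and len(pb1.nochoice) == 27
    np.testing.assert_array_equal(pb1.mu_self, pb2.mu_self)
    np.testing.assert_array_equal(pb1.sigma_other, pb2.sigma_other)


@pytest.mark.parametrize("kwargs", [
    dict(sigma2_0=0.0), dict(sigma3_0=-1.0), dict(kappa=-0.1),
    dict(n_levels=4),
])
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        HGFParams(**kwargs)
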