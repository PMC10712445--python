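"""Response models: links, limits, and likelihood scoring."""

import numpy as np
import pytest

from efficacy_hgf.hgf import filter_session
from efficacy_hgf.models import get_model
from efficacy_hgf.responses import (RWParams, rw_filter, rw_update,
                                    session_log_likelihood, softmax_prob,
                                    unit_square_prob)
from efficacy_hgf.task import TaskConfig, generate_schedule, simulate_session


class TestSoftmax:
    def test_symmetric_indifference(self):
        for beta in (0.1, 1.0, 10.0):
            assert softmax_prob(0.5, beta) == pytest.approx(0.5, abs=1e-15)

    def test_pure_noise_limit(self):
        for mu in (0.1, 0.5, 0.9):
            assert softmax_prob(mu, 1e-12) == pytest.approx(0.5, abs=1e-9)

    def test_verbatim_printed_form(self):
        assert softmax_prob(0.5, 2.0, form="verbatim") == pytest.approx(
            1.0 / (1.0 + np.exp(-1.0)), abs=1e-12)

    def test_forms_differ_and_complement(self):
        mus = np.linspace(0.05, 0.95, 19)
        sym = softmax_prob(mus, 1.7)
        verb = softmax_prob(mus, 1.7, form="verbatim")
        np.testing.assert_allclose(sym + softmax_prob(1 - mus, 1.7), 1.0,
                                   atol=1e-12)
        assert not np.allclose(verb + softmax_prob(1 - mus, 1.7,
                                                   form="verbatim"), 1.0)
        assert np.all(np.diff(sym) > 0) and np.all(np.diff(verb) > 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            softmax_prob(0.5, 0.0)
        with pytest.raises(ValueError):
            softmax_prob(0.5, -1.0)


class TestUnitSquare:
    def test_identity_at_unit_slope(self):
        for mu in (0.2, 0.5, 0.8):
            assert unit_square_prob(mu, np.exp(-1.0)) == pytest.approx(
                mu, abs=1e-12)

    def test_worked_value(self):
        assert unit_square_prob(0.8, np.exp(-2.0)) == pytest.approx(
            0.64 / 0.68, abs=1e-12)

    def test_indifference_for_any_slope(self):
        for sh2 in (1e-6, np.exp(-1.0), 0.5, 5.0):
            assert unit_square_prob(0.5, sh2) == pytest.approx(0.5, abs=1e-12)

    def test_monotone_in_belief_and_certainty(self):
        mus = np.linspace(0.05, 0.95, 30)
        p = unit_square_prob(mus, 0.2)
        assert np.all(np.diff(p) > 0)
        # for a fixed off-centre belief, more certainty is more deterministic
        sh2 = np.array([0.5, 0.2, 0.05, 0.01])
        p_up = unit_square_prob(0.7, sh2)
        assert np.all(np.diff(p_up) > 0)
        p_dn = unit_square_prob(0.3, sh2)
        assert np.all(np.diff(p_dn) < 0)

    def test_floor_absorbs_large_variance(self):
        # sigma_hat2 >= 1 would invert the link; the floor keeps it proper
        assert unit_square_prob(0.9, 3.0) > 0.5
        assert unit_square_prob(0.9, 3.0) == unit_square_prob(0.9, 1.0)

    def test_complement(self):
        mus = np.linspace(0.05, 0.95, 19)
        np.testing.assert_allclose(
            unit_square_prob(mus, 0.1) + unit_square_prob(1 - mus, 0.1),
            1.0, atol=1e-12)


class TestRescorlaWagner:
    def test_single_step(self):
        assert rw_update(0.5, 1, 0.1) == pytest.approx(0.55)

    def test_limits(self):
        assert rw_update(0.3, 1, 1.0) == 1.0
        assert rw_update(0.3, 1, 0.0) == 0.3

    def test_filter_stays_in_unit_interval(self):
        rng = np.random.default_rng(2)
        v = rw_filter(rng.integers(2, size=200), RWParams(alpha=0.4))
        assert np.all((v > 0) & (v < 1))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            RWParams(alpha=0.0)
        with pytest.raises(ValueError):
            RWParams(beta=-1.0)


class TestSessionLikelihood:
    def test_chance_model_log_likelihood(self, played_session, us3_agent):
        from efficacy_hgf.responses import ResponseParams
        model = get_model("3L_sm")
        _, agent, _ = us3_agent
        beliefs = filter_session(played_session, agent["Choice"],
                                 agent["noChoice"])
        resp = ResponseParams(beta_choice=1e-12, beta_nochoice=1e-12)
        ll, rows = session_log_likelihood(played_session, beliefs, resp, model)
        assert ll == pytest.approx(27 * np.log(0.5), abs=1e-6)
        assert len(rows) == 27

    def test_scores_choice_trials_only(self, played_session, us3_model,
                                       us3_agent):
        import copy
        _, agent, resp = us3_agent
        beliefs = filter_session(played_session, agent["Choice"],
                                 agent["noChoice"])
        ll, _ = session_log_likelihood(played_session, beliefs, resp,
                                       us3_model)
        flipped = copy.deepcopy(played_session)
        for t in flipped.trials:
            if t.condition == "noChoice":
                t.selected = "blue" if t.selected == "yellow" else "yellow"
                t.reward = int(t.selected == t.rewarded_stimulus)
        ll_flip, _ = session_log_likelihood(flipped, beliefs, resp, us3_model)
        assert ll == ll_flip
        ll_all, rows_all = session_log_likelihood(
            played_session, beliefs, resp, us3_model, score_nochoice=True)
        assert len(rows_all) == 54 and ll_all != ll

    def test_generating_model_beats_mismatched(self, default_task, us3_model,
                                               us3_agent):
        """Across seeds, sessions score higher under their generating model
        than under the Rescorla-Wagner control."""
        _, agent, resp = us3_agent
        rw_model = get_model("RW_sm")
        rw = RWParams(alpha=0.5, beta=1.0)
        diffs = []
        for seed in range(50):
            sched = generate_schedule(default_task, seed=seed)
            sess = simulate_session(sched, agent, resp, us3_model,
                                    seed=1000 + seed)
            beliefs = filter_session(sess, agent["Choice"], agent["noChoice"])
            ll_gen, _ = session_log_likelihood(sess, beliefs, resp, us3_model)
            u_by_cond = {
                cond: [t.input_u for t in sess.trials if t.condition == cond]
                for cond in ("Choice", "noChoice")}
            v = {c: rw_filter(u, rw) for c, u in u_by_cond.items()}
            ll_rw, _ = session_log_likelihood(sess, v, rw, rw_model)
            diffs.append(ll_gen - ll_rw)
        assert np.mean(diffs) > 0
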