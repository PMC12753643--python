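"""Learning-model dynamics: per-trial operations, invariants, kernel parity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arbrl.models import (
    LatentState,
    choice_logit_terms,
    choice_prob,
    effective_omega,
    init_state,
    overall_values,
    relative_reliability,
    session_negloglik,
    update_omega,
    update_values,
)
from arbrl.params import ModelParams
from arbrl.task import SIDE_NAME, STIM_NAME, make_block_spec, simulate_session

unit = st.floats(0.0, 1.0, allow_nan=False)


class TestInitState:
    def test_dynamic_rho_starts_at_omega0(self):
        p = ModelParams(omega0=0.3, alpha_omega=0.1, zeta_omega=0.05, rho=0.6)
        s = init_state("dynamic_omega_rho", p)
        assert s.omega == 0.3
        assert (s.v_stimA, s.v_stimB, s.v_left, s.v_right) == (0.5,) * 4

    def test_default_init_gives_zero_reliability(self):
        p = ModelParams(omega0=0.3, alpha_omega=0.1, zeta_omega=0.05)
        s = init_state("dynamic_omega_vcho", p)
        assert relative_reliability(s, "L", "A", 1) == 0.0

    def test_v_init_configurable(self):
        p = ModelParams(omega=0.5)
        s = init_state("static_omega", p, v_init=0.0)
        assert s.v_stimA == 0.0 and s.v_right == 0.0


class TestOverallValues:
    def test_hand_arithmetic_static_combination(self):
        # ws=0.75: OV_left = .75*.6+.25*.3, OV_right = .75*.2+.25*.5
        s = LatentState(0.6, 0.2, 0.3, 0.5, 0.75)
        p = ModelParams(omega=0.75)
        ovl, ovr = overall_values(s, "L", p, "static_omega")
        assert ovl == pytest.approx(0.525)
        assert ovr == pytest.approx(0.275)

    def test_pure_stimulus_weighting_ignores_action_values(self):
        s = LatentState(0.7, 0.1, 0.9, 0.9, 1.0)
        p = ModelParams(omega=1.0)
        ovl, _ = overall_values(s, "L", p, "static_omega")
        assert ovl == pytest.approx(0.7)

    def test_rho_half_scales_static_overall_values(self):
        s = LatentState(0.6, 0.2, 0.3, 0.5, 0.75)
        ov_static = overall_values(s, "R", ModelParams(omega=0.75), "static_omega")
        p = ModelParams(omega0=0.75, alpha_omega=0.1, zeta_omega=0.05, rho=0.5)
        ov_rho = overall_values(s, "R", p, "dynamic_omega_rho")
        np.testing.assert_allclose(np.array(ov_rho), 0.5 * np.array(ov_static))


class TestChoiceProb:
    def test_symmetric_values_give_half(self):
        assert choice_prob(0.4, 0.4, 12.0, 0.0) == pytest.approx(0.5)

    def test_logistic_evaluation(self):
        assert choice_prob(0.0, 0.1, 20.0, 0.0) == pytest.approx(
            1 / (1 + np.exp(-2)), abs=1e-12
        )

    def test_logit_decomposition_matches_softmax(self, rng):
        # per-system sensitivity terms must reassemble the direct logit
        for model_id in ("static_omega", "dynamic_omega_rho"):
            for _ in range(200):
                s = LatentState(*rng.random(4), rng.random())
                p = ModelParams(
                    beta1=rng.uniform(0, 20), beta0=rng.uniform(-2, 2),
                    omega=s.omega, omega0=s.omega, alpha_omega=0.1,
                    zeta_omega=0.05, rho=rng.random(),
                )
                side = SIDE_NAME[rng.integers(2)]
                ovl, ovr = overall_values(s, side, p, model_id)
                direct_logit = p.beta1 * (ovr - ovl) + p.beta0
                terms = choice_logit_terms(s, side, p, model_id)
                assert terms["logit"] == pytest.approx(direct_logit, abs=1e-12)


class TestUpdateValues:
    def test_chosen_value_moves_toward_reward(self):
        s = LatentState(0.5, 0.5, 0.5, 0.5, 0.5)
        p = ModelParams(alpha_pos=0.5, alpha_neg=0.2, zeta=0.0)
        out = update_values(s, "L", "A", "L", 1, p)
        assert out.v_stimA == pytest.approx(0.75)
        assert out.v_left == pytest.approx(0.75)

    def test_unchosen_value_decays(self):
        s = LatentState(0.5, 0.8, 0.5, 0.8, 0.5)
        p = ModelParams(alpha_pos=0.5, alpha_neg=0.2, zeta=0.3)
        out = update_values(s, "L", "A", "L", 1, p)
        assert out.v_stimB == pytest.approx(0.56)
        assert out.v_right == pytest.approx(0.56)

    def test_zero_decay_keeps_unchosen_constant(self):
        s = LatentState(0.5, 0.8, 0.5, 0.8, 0.5)
        p = ModelParams(alpha_pos=0.5, alpha_neg=0.2, zeta=0.0)
        out = update_values(s, "L", "A", "L", 0, p)
        assert out.v_stimB == 0.8 and out.v_right == 0.8

    @given(v=unit, a_pos=unit, a_neg=unit, z=unit, r=st.integers(0, 1))
    @settings(max_examples=200, derandomize=True)
    def test_values_stay_in_unit_interval(self, v, a_pos, a_neg, z, r):
        s = LatentState(v, 1 - v, v / 2, 1 - v / 2, 0.5)
        p = ModelParams(alpha_pos=a_pos, alpha_neg=a_neg, zeta=z)
        out = update_values(s, "R", "B", "L", r, p)
        for val in (out.v_stimA, out.v_stimB, out.v_left, out.v_right):
            assert 0.0 <= val <= 1.0


class TestRelativeReliability:
    def test_chosen_value_difference_and_rpe_identity(self):
        s = LatentState(0.7, 0.1, 0.4, 0.9, 0.5)
        drel = relative_reliability(s, "L", "A", 1, "v_cho")
        assert drel == pytest.approx(0.3)
        rpe_action = 1 - 0.4
        rpe_stim = 1 - 0.7
        assert drel == pytest.approx(rpe_action - rpe_stim)

    def test_symmetric_state_gives_zero_for_every_kind(self):
        s = LatentState(0.4, 0.4, 0.4, 0.4, 0.5)
        for kind in ("v_cho", "abs_rpe", "abs_dv", "sum_v"):
            assert relative_reliability(s, "L", "A", 1, kind) == 0.0

    def test_vcho_bounded_on_random_states(self, rng):
        for _ in range(10_000):
            s = LatentState(*rng.random(4), 0.5)
            d = relative_reliability(
                s, SIDE_NAME[rng.integers(2)], STIM_NAME[rng.integers(2)],
                int(rng.integers(2)), "v_cho",
            )
            assert -1.0 <= d <= 1.0


class TestUpdateOmega:
    def test_hand_arithmetic(self):
        p = ModelParams(omega0=0.3, alpha_omega=0.2, zeta_omega=0.05)
        assert update_omega(0.5, 0.2, p) == pytest.approx(0.51)

    def test_fixed_point_at_omega0_with_zero_reliability(self):
        p = ModelParams(omega0=0.3, alpha_omega=0.2, zeta_omega=0.05)
        assert update_omega(0.3, 0.0, p) == 0.3

    @given(w=unit, d=st.floats(-1, 1, allow_nan=False), a=unit, z=unit, w0=unit)
    @settings(max_examples=500, derandomize=True)
    def test_omega_stays_in_unit_interval(self, w, d, a, z, w0):
        p = ModelParams(omega0=w0, alpha_omega=a, zeta_omega=z)
        assert 0.0 <= update_omega(w, d, p) <= 1.0


class TestEffectiveOmega:
    def test_rho_half_reduces_to_omega(self):
        w = np.linspace(0, 1, 11)
        np.testing.assert_allclose(effective_omega(w, 0.5), w)

    def test_omega_half_gives_rho(self):
        assert effective_omega(0.5, 0.61) == pytest.approx(0.61)

    def test_saturated_omega_dominates(self):
        assert effective_omega(1.0, 0.2) == 1.0
        assert effective_omega(0.0, 0.8) == 0.0

    def test_degenerate_corner_continuous_along_rho_half(self):
        assert effective_omega(0.0, 1.0) == 0.0
        assert effective_omega(1.0, 0.0) == 1.0

    @given(w=st.floats(0.01, 0.99), r=st.floats(0.01, 0.99))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_both_arguments(self, w, r):
        eps = 1e-3
        base = effective_omega(w, r)
        assert effective_omega(min(w + eps, 1.0), r) >= base
        assert effective_omega(w, min(r + eps, 1.0)) >= base


class TestSessionNegloglik:
    def test_chance_model_likelihood(self, small_session):
        sess, _ = small_session
        p = ModelParams(beta1=0.0, beta0=0.0, zeta=0.0)
        nll, _ = session_negloglik("stim_only", p, sess)
        assert nll == pytest.approx(sess.n_blocks * 80 * np.log(2))

    def test_deterministic_output(self, small_session, control_params):
        sess, _ = small_session
        a = session_negloglik("dynamic_omega_rho", control_params, sess)
        b = session_negloglik("dynamic_omega_rho", control_params, sess)
        assert a[0] == b[0]

    def test_generating_params_beat_perturbed_on_average(self, control_params):
        rng = np.random.default_rng(3)
        wins = 0
        n = 40
        for i in range(n):
            blocks = [make_block_spec("what_where", rng) for _ in range(5)]
            sess, _ = simulate_session(
                "dynamic_omega_rho", control_params, blocks, rng
            )
            nll_true, _ = session_negloglik(
                "dynamic_omega_rho", control_params, sess, return_trajectories=False
            )
            perturbed = ModelParams(
                alpha_pos=0.2, alpha_neg=0.8, zeta=0.1, beta1=2.0, beta0=0.5,
                omega0=0.8, alpha_omega=0.05, zeta_omega=0.2, rho=0.5,
            )
            nll_pert, _ = session_negloglik(
                "dynamic_omega_rho", perturbed, sess, return_trajectories=False
            )
            wins += nll_true < nll_pert
        assert wins / n > 0.9


class TestKernelMatchesScalarReference:
    """The jitted engine must reproduce a trial loop composed from the
    public scalar operations, state and likelihood alike."""

    @pytest.mark.parametrize(
        "model_id",
        ["stim_only", "action_only", "static_omega", "dynamic_omega_vcho",
         "dynamic_omega_absrpe", "dynamic_omega_absdv", "dynamic_omega_sumv",
         "dynamic_omega_rho"],
    )
    def test_trajectories_match(self, model_id):
        rng = np.random.default_rng(21)
        params = ModelParams(
            alpha_pos=0.6, alpha_neg=0.3, zeta=0.25, beta1=6.0, beta0=0.3,
            omega=0.6, omega0=0.4, alpha_omega=0.3, zeta_omega=0.08, rho=0.65,
        )
        if model_id.startswith("dynamic_omega_") and model_id != "dynamic_omega_rho":
            params.reliability_kind = model_id.split("_")[-1]
        blocks = [make_block_spec("what_where", rng) for _ in range(4)]
        sess, trajs = simulate_session(model_id, params, blocks, rng)
        nll, ev_trajs = session_negloglik(model_id, params, sess)

        total_ref = 0.0
        for (spec, trials), traj in zip(sess.blocks, ev_trajs):
            state = init_state(model_id, params)
            for t, trec in enumerate(trials):
                ovl, ovr = overall_values(state, trec.stimA_side, params, model_id)
                pr = choice_prob(ovl, ovr, params.beta1, params.beta0)
                assert traj.p_right[t] == pytest.approx(pr, abs=1e-12)
                assert traj.ov_left[t] == pytest.approx(ovl, abs=1e-12)
                p_obs = pr if trec.choice_side == "R" else 1 - pr
                total_ref -= np.log(np.clip(p_obs, 1e-10, 1 - 1e-10))
                kind = (
                    "v_cho" if model_id == "dynamic_omega_rho"
                    else {"vcho": "v_cho", "absrpe": "abs_rpe",
                          "absdv": "abs_dv", "sumv": "sum_v"}.get(
                        model_id.split("_")[-1], "v_cho")
                )
                drel = relative_reliability(
                    state, trec.choice_side, trec.choice_stim, trec.reward, kind
                )
                assert traj.drel[t] == pytest.approx(drel, abs=1e-12)
                state = update_values(
                    state, trec.choice_side, trec.choice_stim,
                    trec.stimA_side, trec.reward, params,
                )
                if model_id.startswith("dynamic"):
                    state.omega = update_omega(state.omega, drel, params)
        assert nll == pytest.approx(total_ref, abs=1e-9)
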