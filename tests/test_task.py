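"""Task environments: block draws, reward contingencies, simulation purity."""

import numpy as np
import pytest

from arbrl.params import ModelParams
from arbrl.task import (
    BlockSpec,
    CohortSpec,
    TrialRecord,
    generate_cohort,
    make_block_spec,
    sample_reward,
    simulate_raw,
    simulate_session,
)


class TestMakeBlockSpec:
    def test_what_only_forces_what_blocks(self, rng):
        assert all(
            make_block_spec("what_only", rng).block_type == "what" for _ in range(50)
        )

    def test_reversal_uniform_over_30_to_50(self, rng):
        draws = np.array(
            [make_block_spec("what_where", rng).reversal_trial for _ in range(10_000)]
        )
        assert draws.min() >= 30 and draws.max() <= 50
        expected = 10_000 / 21
        sd = np.sqrt(10_000 * (1 / 21) * (20 / 21))
        counts = np.bincount(draws - 30, minlength=21)
        assert np.all(np.abs(counts - expected) < 3 * sd)

    def test_block_type_and_schedule_frequencies(self, rng):
        specs = [make_block_spec("what_where", rng) for _ in range(10_000)]
        frac_what = np.mean([s.block_type == "what" for s in specs])
        assert abs(frac_what - 0.5) < 3 * np.sqrt(0.25 / 10_000)
        for p in (0.8, 0.7, 0.6):
            frac = np.mean([s.p_better == p for s in specs])
            assert abs(frac - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 10_000)

    def test_invalid_task_rejected(self, rng):
        with pytest.raises(ValueError):
            make_block_spec("which", rng)


class TestBlockSpecInvariants:
    def test_what_only_where_block_rejected(self):
        with pytest.raises(ValueError):
            BlockSpec("what_only", "where", 0.8, 40, "L")

    def test_better_id_must_match_dimension(self):
        with pytest.raises(ValueError):
            BlockSpec("what_where", "what", 0.8, 40, "L")
        with pytest.raises(ValueError):
            BlockSpec("what_where", "where", 0.8, 40, "A")


class TestSampleReward:
    def test_deterministic_limit(self, rng):
        spec = BlockSpec("what_only", "what", 1.0, 40, "A")
        assert all(
            sample_reward(spec, t, "L", "A", rng) == 1 for t in range(1, 40)
        )

    @pytest.mark.parametrize(
        "block_type,better,choice_side,choice_stim,trial,expected_p",
        [
            ("what", "A", "L", "A", 10, 0.8),  # better stimulus pre-reversal
            ("what", "A", "L", "A", 40, 0.2),  # flip applies at the reversal trial
            ("where", "L", "L", "B", 40, 0.2),  # previously better side at reversal
            ("where", "L", "R", "A", 39, 0.2),  # worse side pre-reversal
        ],
    )
    def test_reward_rates_match_schedule(
        self, block_type, better, choice_side, choice_stim, trial, expected_p
    ):
        rng = np.random.default_rng(3)
        task = "what_only" if block_type == "what" else "what_where"
        spec = BlockSpec(task, block_type, 0.8, 40, better)
        draws = [
            sample_reward(spec, trial, choice_side, choice_stim, rng)
            for _ in range(10_000)
        ]
        sd = np.sqrt(expected_p * (1 - expected_p) / 10_000)
        assert abs(np.mean(draws) - expected_p) < 3 * sd

    def test_trial_out_of_range(self, rng):
        spec = BlockSpec("what_only", "what", 0.8, 40, "A")
        with pytest.raises(ValueError):
            sample_reward(spec, 81, "L", "A", rng)


class TestTrialRecord:
    def test_inconsistent_choice_stim_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            TrialRecord(1, stimA_side="L", choice_side="L", choice_stim="B", reward=0)

    def test_reward_must_be_binary(self):
        with pytest.raises(ValueError):
            TrialRecord(1, stimA_side="L", choice_side="L", choice_stim="A", reward=2)


class TestSimulateSession:
    def test_flat_softmax_chooses_sides_evenly(self):
        rng = np.random.default_rng(0)
        p = ModelParams(beta1=0.0, beta0=0.0, zeta=0.0)
        specs = [BlockSpec("what_only", "what", 0.8, 40, "A") for _ in range(125)]
        raw = simulate_raw("stim_only", p, specs, rng, record=False)
        frac_right = raw["choice_side"].mean()
        assert abs(frac_right - 0.5) < 3 * np.sqrt(0.25 / raw["choice_side"].size)

    def test_strong_stimulus_learner_acquires_preference(self):
        # late-acquisition performance of a committed stimulus-based learner
        rng = np.random.default_rng(1)
        p = ModelParams(
            alpha_pos=0.5, alpha_neg=0.5, zeta=0.3, beta1=20.0, beta0=0.0, omega=1.0
        )
        specs = [BlockSpec("what_only", "what", 0.8, 40, "A") for _ in range(2000)]
        raw = simulate_raw("static_omega", p, specs, rng, record=False)
        late_acq = raw["choice_stim"][:, 25:39] == 0  # stimulus A before reversal
        assert late_acq.mean() > 0.7

    def test_bit_identical_on_same_seed(self, control_params):
        blocks = [
            make_block_spec("what_where", np.random.default_rng(4)) for _ in range(5)
        ]
        s1, t1 = simulate_session(
            "dynamic_omega_rho", control_params, blocks, np.random.default_rng(9)
        )
        s2, t2 = simulate_session(
            "dynamic_omega_rho", control_params, blocks, np.random.default_rng(9)
        )
        assert s1 == s2
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.p_right, b.p_right)

    def test_side_assignment_independent_of_reward(self, control_params):
        rng = np.random.default_rng(2)
        specs = [BlockSpec("what_only", "what", 0.8, 40, "A") for _ in range(500)]
        raw = simulate_raw("dynamic_omega_rho", control_params, specs, rng)
        # conditional on choosing stimulus A, side layout should not predict reward
        chose_a = raw["choice_stim"] == 0
        stim_side = raw["stimA_side"][chose_a]
        rew = raw["reward"][chose_a]
        r = np.corrcoef(stim_side, rew)[0, 1]
        assert abs(r) < 3 / np.sqrt(chose_a.sum())

    def test_balanced_sides_option_exactly_counterbalances(self, control_params):
        rng = np.random.default_rng(5)
        specs = [BlockSpec("what_only", "what", 0.8, 40, "A") for _ in range(20)]
        raw = simulate_raw(
            "dynamic_omega_rho", control_params, specs, rng, balanced_sides=True
        )
        assert np.all(raw["stimA_side"].sum(axis=1) == 40)


class TestGenerateCohort:
    def test_empty_cohort(self, rng):
        data, truth = generate_cohort(CohortSpec(n_subjects=0), rng)
        assert data == {} and truth.empty

    def test_lesion_group_means_ordered(self):
        rng = np.random.default_rng(8)
        kw = dict(n_subjects=20, n_sessions=1, blocks_per_session=2)
        _, t_ctrl = generate_cohort(CohortSpec(group="control", **kw), rng)
        _, t_amyg = generate_cohort(CohortSpec(group="amygdala", **kw), rng)
        _, t_vs = generate_cohort(CohortSpec(group="vs", **kw), rng)
        assert t_amyg["omega0"].mean() < t_ctrl["omega0"].mean()
        assert t_vs["rho"].mean() < t_ctrl["rho"].mean()

    def test_one_rho_per_subject(self):
        rng = np.random.default_rng(8)
        data, truth = generate_cohort(
            CohortSpec(n_subjects=3, n_sessions=4, blocks_per_session=2), rng
        )
        assert (truth.groupby("subject")["rho"].nunique() == 1).all()
        assert set(data) == set(truth["subject"])
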