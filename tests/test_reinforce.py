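"""Reward model, episode mechanics and the REINFORCE update."""

import numpy as np
import pytest

from molevolve import (
    MoleculeRecord,
    PolicyConfig,
    PolicyNetwork,
    TrainerConfig,
    compute_reward,
    curriculum_train,
    policy_gradient_update,
    run_episode,
)
from molevolve.policy import masked_action_probs
from molevolve.properties import fingerprint_array
from molevolve.reinforce import (
    Adam,
    Episode,
    EpisodeStep,
    LOG_COLUMNS,
    policy_rollout,
)
from molevolve.transforms import STOP_ACTION

CH4 = MoleculeRecord.from_smiles("C")


@pytest.fixture()
def net():
    return PolicyNetwork(PolicyConfig(n_core_fragments=7, top_p=1.0),
                         rng_seed=2)


class TestReward:
    def test_breakdown_satisfies_invariants(self, records100):
        for src, gen in zip(records100[:10], records100[10:20]):
            br = compute_reward(src, gen)
            assert br.sa_norm == pytest.approx(1.0 - (br.sa_raw - 1.0) / 9.0)
            assert br.reward == pytest.approx(
                0.5 * br.sa_norm + 0.5 * br.qed)
            assert not br.penalty_applied

    def test_identity_penalty(self, records100):
        rec = records100[0]
        same = compute_reward(rec, rec)
        assert same.penalty_applied
        assert same.reward == pytest.approx(
            0.5 * same.sa_norm + 0.5 * same.qed - 0.05)

    def test_reward_bounded(self, records100):
        for src in records100[:30]:
            br = compute_reward(src, src)
            assert -0.05 <= br.reward <= 1.0


class TestEpisodes:
    def test_m1_is_exactly_one_transform_no_stop(self, net):
        for seed in range(5):
            ep = run_episode(net, CH4, 1, seed)
            assert len(ep.steps) == 1
            assert ep.steps[0].action != STOP_ACTION
            assert ep.n_transform_steps == 1

    def test_step_limit_and_stop_semantics(self, net):
        for seed in range(5):
            ep = run_episode(net, CH4, 3, seed)
            assert 1 <= len(ep.steps) <= 3
            # STOP, if present, is terminal and never first
            stops = [i for i, s in enumerate(ep.steps)
                     if s.action == STOP_ACTION]
            assert all(i == len(ep.steps) - 1 for i in stops)
            assert ep.steps[0].action != STOP_ACTION

    def test_deterministic_under_seed(self, net):
        a = run_episode(net, CH4, 2, 99)
        b = run_episode(net, CH4, 2, 99)
        assert a.final.smiles == b.final.smiles
        assert [s.action for s in a.steps] == [s.action for s in b.steps]

    def test_invalid_m_rejected(self, net):
        with pytest.raises(ValueError):
            run_episode(net, CH4, 0, 1)


class TestPolicyGradientUpdate:
    def test_baseline_ema_arithmetic(self, net):
        cfg = TrainerConfig(max_steps=1)
        fp = fingerprint_array(CH4)
        episodes = [Episode(CH4, (EpisodeStep(fp, 3, None, None, True, 0.0),),
                            CH4, 1.0) for _ in range(15)]
        new_b = policy_gradient_update(net, episodes, 0.0, cfg, Adam())
        assert new_b == pytest.approx(0.1)  # 0.9*0 + 0.1*mean(R)=1

    def test_mixed_sources_rejected(self, net):
        cfg = TrainerConfig(max_steps=1)
        other = MoleculeRecord.from_smiles("CC")
        eps = [Episode(CH4, (), CH4, 0.5), Episode(other, (), other, 0.5)]
        with pytest.raises(ValueError):
            policy_gradient_update(net, eps, 0.0, cfg, Adam())

    def test_equal_rewards_leave_only_entropy_pressure(self, net):
        """With zero advantage and beta=0 the update is a no-op."""
        cfg = TrainerConfig(max_steps=1, entropy_coeff=0.0)
        fp = fingerprint_array(CH4)
        episodes = [Episode(CH4, (EpisodeStep(fp, 3, None, None, True, 0.0),),
                            CH4, 0.7) for _ in range(5)]
        before = net.forward(CH4).action_probs.copy()
        policy_gradient_update(net, episodes, 0.7, cfg, Adam())
        after = net.forward(CH4).action_probs
        assert np.allclose(before, after)

    def test_rewarded_action_probability_rises(self):
        """Reward on one action concentrates the policy on it (toy MDP)."""
        cfg = TrainerConfig(max_steps=1, entropy_coeff=0.0,
                            learning_rate=1e-2)
        target = 5
        fp = fingerprint_array(CH4)
        gains = []
        for seed in range(3):
            net = PolicyNetwork(PolicyConfig(n_core_fragments=7, top_p=1.0),
                                rng_seed=seed)
            opt = Adam(lr=cfg.learning_rate)
            rng = np.random.default_rng(seed)
            b = 0.0
            start = net.forward(CH4).action_probs[target]
            for _ in range(25):
                episodes = []
                for _ in range(15):
                    (za, _, _), _ = net.logits(fp)
                    probs = masked_action_probs(za, 1.0, mask_stop=True)
                    a = int(rng.choice(len(probs), p=probs))
                    episodes.append(Episode(
                        CH4, (EpisodeStep(fp, a, None, None, True, 0.0),),
                        CH4, 1.0 if a == target else 0.0))
                b = policy_gradient_update(net, episodes, b, cfg, opt)
            gains.append(net.forward(CH4).action_probs[target] - start)
        assert all(g > 0 for g in gains)


class TestCurriculum:
    def test_log_contract_and_methane_seed(self, library, tmp_path):
        cfg = TrainerConfig(max_steps=1, epochs=3, epoch_sample_size=20,
                            rng_seed=4)
        policy, rows = curriculum_train(cfg, library=library,
                                        out_dir=str(tmp_path))
        assert len(rows) == 3
        assert all(set(r) == set(LOG_COLUMNS) for r in rows)
        log = (tmp_path / "training_log.csv").read_text().strip().splitlines()
        assert len(log) == 4  # header + one row per epoch
        assert (tmp_path / "epoch0000.npz").exists()
        # epoch-0 similarity is measured against methane itself
        assert 0.0 <= rows[0]["avg_sim"] <= 1.0
        assert rows[0]["avg_traj_len"] == pytest.approx(1.0)
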