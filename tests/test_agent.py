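"""The conservative distributional dosing agent."""

import numpy as np
import pytest

from glycorl.agent import PolicyArtifact, QuantileValue, train
from glycorl.nn import no_grad
from glycorl.pipeline import TransitionDataset
from glycorl.agent import _sampling_probabilities

from conftest import make_bandit_dataset, tiny_agent_config


def _expected_q(artifact, state, dose, n_taus=16) -> float:
    with no_grad():
        q = artifact.critic.expected_q(np.atleast_2d(state), np.array([dose]), n_taus)
    return float(q.data.ravel()[0])


@pytest.fixture(scope="module")
def degenerate_bandit_artifact():
    # single action, constant reward 0.2: the return distribution is a point
    # mass, so the quantile function should be flat. A small conservatism
    # weight is used because the CQL term deliberately biases in-data Q
    # upward, which is not the property probed here.
    ds = make_bandit_dataset({2: 0.2}, n=400)
    return train(ds, tiny_agent_config(gradient_steps=800, cql_alpha=0.1))


class TestBanditOptimality:
    def test_recovers_enumerable_optimal_dose(self):
        ds = make_bandit_dataset({0: -1.0, 1: -1.0, 2: 0.2, 3: -1.0, 4: -1.0, 5: -1.0})
        art = train(ds, tiny_agent_config(gradient_steps=1000))
        assert art.recommend(np.full(3, 0.5)) == 2

    def test_degenerate_return_distribution_quantiles(self, degenerate_bandit_artifact):
        qv = degenerate_bandit_artifact.critic_quantiles(
            np.full(3, 0.5), 2.0, [0.1, 0.3, 0.5, 0.7, 0.9]
        )
        for q in qv:
            assert q.value == pytest.approx(0.2, abs=0.05)

    def test_two_outcome_bandit_quantile_ordering(self):
        # rewards -1 / 0.2 equally likely at the same dose: the learned
        # return distribution must spread, with tau=0.25 below tau=0.75
        rng = np.random.default_rng(1)
        n = 600
        rewards = rng.choice([-1.0, 0.2], size=n)
        states = np.full((n, 3), 0.5)
        ds = TransitionDataset(
            states=states, actions=np.full(n, 2.0), rewards=rewards,
            next_states=states, dones=np.ones(n, bool), patient_ids=np.arange(n),
            hours=np.zeros(n, int), episode_ids=np.arange(n),
            episode_returns=rewards.copy(), feature_names=["a", "b", "c"],
        )
        art = train(ds, tiny_agent_config(gradient_steps=800, cql_alpha=0.1))
        lo = art.critic_quantiles(np.full(3, 0.5), 2.0, [0.25])[0].value
        hi = art.critic_quantiles(np.full(3, 0.5), 2.0, [0.75])[0].value
        assert lo < hi


class TestConservatism:
    def test_ood_dose_pushed_below_in_data_and_ablation(self):
        # dataset covers doses {0,1,2} only; dose 8 is out of distribution
        ds = make_bandit_dataset({0: 0.0, 1: 0.1, 2: 0.2}, n=600)
        conservative = train(ds, tiny_agent_config(gradient_steps=600, cql_alpha=5.0))
        ablation = train(ds, tiny_agent_config(gradient_steps=600, cql_alpha=0.0))
        s = np.full(3, 0.5)
        q8_cons = _expected_q(conservative, s, 8.0)
        q8_abl = _expected_q(ablation, s, 8.0)
        best_in_data = max(_expected_q(conservative, s, d) for d in (0.0, 1.0, 2.0))
        assert q8_cons <= best_in_data
        assert q8_cons <= q8_abl


class TestDeterminismAndInterface:
    def test_identical_seed_gives_identical_recommendations(self, prep):
        cfg = tiny_agent_config(gradient_steps=120)
        a = train(prep["train"], cfg)
        b = train(prep["train"], cfg)
        probe = prep["test"].states[:50]
        np.testing.assert_array_equal(a.recommend(probe), b.recommend(probe))

    def test_save_load_roundtrip(self, trained_artifact, prep, tmp_path):
        trained_artifact.save(tmp_path / "art")
        loaded = PolicyArtifact.load(tmp_path / "art")
        probe = prep["test"].states[:50]
        np.testing.assert_array_equal(
            trained_artifact.recommend(probe), loaded.recommend(probe)
        )
        assert loaded.feature_names == trained_artifact.feature_names

    def test_recommend_clip_and_round_half_up(self, trained_artifact):
        art = trained_artifact
        orig = art.actor.mean_action
        try:
            art.actor.mean_action = lambda s: np.array([11.3])
            assert art.recommend(np.zeros(len(art.feature_names))) == 10
            art.actor.mean_action = lambda s: np.array([2.5])
            assert art.recommend(np.zeros(len(art.feature_names))) == 3
            art.actor.mean_action = lambda s: np.array([2.49])
            assert art.recommend(np.zeros(len(art.feature_names))) == 2
        finally:
            art.actor.mean_action = orig

    def test_recommend_always_integer_in_range(self, trained_artifact, prep):
        doses = trained_artifact.recommend(prep["test"].states[:200])
        assert doses.dtype.kind == "i"
        assert np.all((doses >= 0) & (doses <= 10))

    def test_dimension_mismatch_rejected(self, trained_artifact):
        with pytest.raises(ValueError, match="features"):
            trained_artifact.recommend(np.zeros(3))

    def test_quantile_domain_checks(self, trained_artifact):
        s = np.zeros(len(trained_artifact.feature_names))
        with pytest.raises(ValueError):
            trained_artifact.critic_quantiles(s, 2.0, [0.0, 0.5])
        with pytest.raises(ValueError):
            QuantileValue(tau=1.2, value=0.0)

    def test_quantile_average_monte_carlo_consistency(self, degenerate_bandit_artifact):
        art = degenerate_bandit_artifact
        s = np.full(len(art.feature_names), 0.5)
        rng = np.random.default_rng(0)
        q64 = np.mean([q.value for q in art.critic_quantiles(s, 2.0, rng.random(64))])
        q256 = np.mean([q.value for q in art.critic_quantiles(s, 2.0, rng.random(256))])
        assert abs(q64 - q256) < 0.05


class TestDiscountAndSampling:
    def test_constant_reward_chain_value_matches_geometric_series(self):
        # long chain of identical states, reward 0.2 each step: the start
        # value should approach 0.2 / (1 - 0.67) = 0.606
        n_eps, H = 30, 30
        states = np.full((n_eps * H, 2), 0.5)
        dones = np.zeros(n_eps * H, bool)
        dones[H - 1 :: H] = True
        ds = TransitionDataset(
            states=states, actions=np.zeros(n_eps * H), rewards=np.full(n_eps * H, 0.2),
            next_states=states, dones=dones,
            patient_ids=np.repeat(np.arange(n_eps), H),
            hours=np.tile(np.arange(H), n_eps),
            episode_ids=np.repeat(np.arange(n_eps), H),
            episode_returns=np.full(n_eps, 0.2 / 0.33),
            feature_names=["a", "b"],
        )
        art = train(
            ds, tiny_agent_config(gradient_steps=1500, cql_alpha=0.1, target_sync_rate=0.02)
        )
        v = _expected_q(art, np.full(2, 0.5), 0.0)
        assert v == pytest.approx(0.2 / (1 - 0.67), abs=0.1)

    def test_return_weighted_sampling_limits(self):
        ds = make_bandit_dataset({0: -1.0, 2: 0.2}, n=200, seed=3)
        # temperature -> infinity: uniform over transitions
        p_uniform = _sampling_probabilities(ds, temperature=1e9)
        rng = np.random.default_rng(0)
        draws = rng.choice(len(ds), size=100_000, p=p_uniform)
        freq = np.bincount(draws, minlength=len(ds)) / 100_000
        assert np.all(np.abs(freq - 1.0 / len(ds)) < 0.02)
        # small temperature: the top-return episodes dominate
        p_sharp = _sampling_probabilities(ds, temperature=0.05)
        top = ds.episode_returns == ds.episode_returns.max()
        assert p_sharp[top].sum() > 0.99
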