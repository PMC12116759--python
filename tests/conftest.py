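"""Shared fixtures: a small simulated cohort, preprocessed datasets, and a
compact trained artifact reused by tests that need a policy but do not test
training quality itself."""

import numpy as np
import pytest

from glycorl.agent import AgentConfig, train
from glycorl.pipeline import TransitionDataset, preprocess_cohort
from glycorl.simulator import SimConfig, simulate_cohort


def tiny_agent_config(**overrides) -> AgentConfig:
    base = dict(
        hidden_layers=(32, 32),
        batch_size=64,
        gradient_steps=400,
        actor_lr=1e-3,
        critic_lr=1e-3,
        cql_alpha=1.0,
        n_ood_action_samples=6,
        n_actor_action_samples=2,
        n_quantile_samples=8,
        n_target_quantile_samples=8,
        n_expectation_taus=4,
        quantile_embed_dim=32,
        return_sampling_temperature=2.0,
        seed=0,
    )
    base.update(overrides)
    return AgentConfig(**base)


def make_bandit_dataset(
    reward_by_dose: dict[int, float],
    n: int = 600,
    n_features: int = 3,
    seed: int = 0,
) -> TransitionDataset:
    """Single-state contextual bandit: every episode is one 'done' transition."""
    rng = np.random.default_rng(seed)
    doses = rng.choice(sorted(reward_by_dose), size=n).astype(float)
    rewards = np.array([reward_by_dose[int(d)] for d in doses])
    states = np.full((n, n_features), 0.5)
    return TransitionDataset(
        states=states,
        actions=doses,
        rewards=rewards,
        next_states=states,
        dones=np.ones(n, bool),
        patient_ids=np.arange(n),
        hours=np.zeros(n, int),
        episode_ids=np.arange(n),
        episode_returns=rewards.copy(),
        feature_names=[f"f{i}" for i in range(n_features)],
    )


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimConfig(n_patients=120, seed=42))


@pytest.fixture(scope="session")
def prep(small_cohort):
    traj, patients = small_cohort
    return preprocess_cohort(traj, patients, seed=0)


@pytest.fixture(scope="session")
def trained_artifact(prep):
    return train(prep["train"], tiny_agent_config(gradient_steps=500))
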