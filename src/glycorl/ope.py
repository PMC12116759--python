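"""Off-policy evaluation and model selection.

Fitted-Q evaluation (FQE) estimates the value of a learned dosing policy
from logged transitions by regressing an evaluation critic onto iterated
Bellman targets r + gamma * Q(s', pi(s')). The behavior (clinician) value is
the empirical discounted return of the logged episodes — on-policy data
makes the empirical estimator unbiased, so no fitted model is needed there.

Uncertainty is quantified with percentile bootstrap confidence intervals
over per-episode values (10,000 resamples by default), and the multi-model
training protocol selects the seed whose FQE value has the highest lower
95% confidence bound — a pessimistic selection rule suited to offline RL's
high seed-to-seed variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .agent import AgentConfig, PolicyArtifact, train as train_agent
from .nn import MLP, Tensor, concat, hard_update, no_grad, Adam
from .pipeline import TransitionDataset, select_patients, subsample_patients
from .simulator import MAX_DOSE

__all__ = [
    "OPEResult",
    "FQEConfig",
    "fqe_evaluate",
    "behavior_returns",
    "bootstrap_ci",
    "select_best",
    "multiseed_protocol",
]


@dataclass
class OPEResult:
    """Estimated mean policy value with a percentile-bootstrap 95% CI."""

    mean_value: float
    ci_low: float
    ci_high: float
    n_episodes: int
    n_bootstrap: int
    method: str  # "fqe" | "empirical"
    per_episode_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean_value <= self.ci_high:
            raise ValueError("bootstrap CI must bracket the mean value")


@dataclass
class FQEConfig:
    """Evaluation-critic hyperparameters (non-distributional MLP)."""

    gamma: float = 0.67
    hidden_layers: tuple[int, ...] = (256, 256)
    lr: float = 3e-4
    batch_size: int = 256
    gradient_steps: int = 5000
    target_update_interval: int = 100
    n_bootstrap: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must be in (0, 1)")
        if self.lr <= 0 or self.gradient_steps < 1:
            raise ValueError("invalid FQE optimization settings")


def bootstrap_ci(
    values: np.ndarray,
    n_resamples: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile CI of the mean under resampling with replacement."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("bootstrap_ci needs at least one value")
    rng = np.random.default_rng(seed)
    n = values.size
    idx = rng.integers(0, n, size=(n_resamples, n))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _episode_order(dataset: TransitionDataset) -> list[np.ndarray]:
    """Indices of each episode's transitions in temporal order."""
    order = []
    for ep in np.unique(dataset.episode_ids):
        rows = np.flatnonzero(dataset.episode_ids == ep)
        rows = rows[np.argsort(dataset.hours[rows], kind="stable")]
        order.append(rows)
    return order


def behavior_returns(
    dataset: TransitionDataset,
    gamma: float = 0.67,
    n_bootstrap: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, OPEResult]:
    """Empirical discounted return of each logged episode, with CI.

    This is the clinician (behavior-policy) value: return_e = sum_t
    gamma^t * r_t over the episode's transitions in temporal order.
    """
    returns = []
    for rows in _episode_order(dataset):
        r = dataset.rewards[rows]
        returns.append(float(np.sum(r * gamma ** np.arange(len(r)))))
    returns = np.asarray(returns)
    lo, hi = bootstrap_ci(returns, n_resamples=n_bootstrap, seed=seed)
    mean = float(returns.mean())
    result = OPEResult(
        mean_value=mean,
        ci_low=min(lo, mean),
        ci_high=max(hi, mean),
        n_episodes=len(returns),
        n_bootstrap=n_bootstrap,
        method="empirical",
        per_episode_values=returns,
    )
    return returns, result


def _policy_doses(policy, states: np.ndarray) -> np.ndarray:
    """Evaluate a policy (artifact or callable) on a state matrix."""
    if isinstance(policy, PolicyArtifact):
        doses = np.asarray(policy.recommend(states), dtype=float)
    else:
        doses = np.asarray(policy(states), dtype=float)
    if doses.shape != (len(states),):
        raise ValueError("policy must return one dose per state")
    if not np.all((doses >= 0) & (doses <= MAX_DOSE)):
        raise ValueError(f"policy emitted doses outside [0, {MAX_DOSE}]")
    return doses


# value scale is bounded: per-step reward in [-1.1, 0.2], so |V| <= 1.1/(1-gamma)
_DIVERGENCE_FACTOR = 10.0


def fqe_evaluate(
    dataset: TransitionDataset,
    policy,
    config: FQEConfig | None = None,
) -> OPEResult:
    """Fitted-Q evaluation of a deterministic dosing policy on logged data.

    Fits Q_pi by iterating Bellman regression with a periodically synced
    target network; the per-episode value is Q(s_0, pi(s_0)) at the episode's
    first state, and the mean over episodes is bootstrapped for a 95% CI.
    ``policy`` is a PolicyArtifact or a callable mapping a (B, d) state
    matrix to doses in [0, 10].
    """
    config = config or FQEConfig()
    rng = np.random.default_rng(config.seed)
    d = dataset.states.shape[1]
    net = MLP(d + 1, list(config.hidden_layers), 1, rng)
    target_net = MLP(d + 1, list(config.hidden_layers), 1, np.random.default_rng(config.seed + 1))
    hard_update(target_net.parameters, net.parameters)
    opt = Adam(net.parameters, config.lr)

    pi_next = _policy_doses(policy, dataset.next_states)
    n = len(dataset)
    not_done = 1.0 - dataset.dones.astype(float)
    v_cap = _DIVERGENCE_FACTOR * 1.1 / (1.0 - config.gamma)

    def q_values(network, states, doses) -> np.ndarray:
        with no_grad():
            x = concat([Tensor(states), Tensor(doses.reshape(-1, 1) / MAX_DOSE)], axis=1)
            return network(x).data.ravel()

    for step in range(config.gradient_steps):
        idx = rng.integers(0, n, size=min(config.batch_size, n))
        target_q = q_values(target_net, dataset.next_states[idx], pi_next[idx])
        y = dataset.rewards[idx] + config.gamma * not_done[idx] * target_q
        x = concat(
            [Tensor(dataset.states[idx]), Tensor(dataset.actions[idx].reshape(-1, 1) / MAX_DOSE)],
            axis=1,
        )
        pred = net(x)
        loss = ((pred - Tensor(y.reshape(-1, 1))) ** 2).mean()
        if not np.isfinite(loss.data) or np.max(np.abs(pred.data)) > v_cap:
            raise RuntimeError(
                f"FQE diverged at step {step}: loss={loss.data!r}, "
                f"max|Q|={np.max(np.abs(pred.data)):.2f} (cap {v_cap:.2f})"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        if (step + 1) % config.target_update_interval == 0:
            hard_update(target_net.parameters, net.parameters)

    starts = dataset.episode_start_indices
    s0 = dataset.states[starts]
    pi0 = _policy_doses(policy, s0)
    values = q_values(net, s0, pi0)
    lo, hi = bootstrap_ci(values, n_resamples=config.n_bootstrap, seed=config.seed)
    mean = float(values.mean())
    return OPEResult(
        mean_value=mean,
        ci_low=min(lo, mean),
        ci_high=max(hi, mean),
        n_episodes=len(values),
        n_bootstrap=config.n_bootstrap,
        method="fqe",
        per_episode_values=values,
    )


def select_best(results: list[OPEResult]) -> int:
    """Index of the result with the highest lower 95% bound (ties: lowest index)."""
    if not results:
        raise ValueError("select_best needs at least one result")
    lows = np.asarray([r.ci_low for r in results])
    return int(np.argmax(lows))


def multiseed_protocol(
    train_data: TransitionDataset,
    test_data: TransitionDataset,
    n_models: int,
    agent_config: AgentConfig,
    fqe_config: FQEConfig | None = None,
    base_seed: int = 0,
    subsample_frac: float = 0.80,
) -> dict:
    """Train many seeds on 80% patient subsamples; keep the max-lower-bound one.

    Each model i trains on an independent ``subsample_frac`` draw of training
    patients with seed ``base_seed + i``, is FQE-evaluated on the held-out
    test set, and the winner is the model whose FQE 95% CI has the highest
    lower bound. Returns the winning artifact, all artifacts' OPE results,
    and the winner index.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    fqe_config = fqe_config or FQEConfig()
    results: list[OPEResult] = []
    artifacts: list[PolicyArtifact] = []
    for i in range(n_models):
        seed_i = base_seed + i
        ids = subsample_patients(train_data.patient_ids, frac=subsample_frac, seed=seed_i)
        subset = select_patients(train_data, ids)
        cfg_i = replace(agent_config, seed=seed_i)
        artifact = train_agent(subset, cfg_i)
        res = fqe_evaluate(test_data, artifact, replace(fqe_config, seed=seed_i))
        artifacts.append(artifact)
        results.append(res)
    winner = select_best(results)
    return {
        "selected": artifacts[winner],
        "selected_index": winner,
        "results": results,
        "artifacts": artifacts,
    }
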