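"""Continuous-action conservative Q-learning with an implicit-quantile critic.

The learner combines three ingredients tailored to offline dosing data:

* **Distributional critic (IQN).** Instead of a scalar Q(s, a), the critic
  maps (state, action, quantile fraction tau) to the tau-quantile of the
  return distribution. Quantile fractions are embedded with a cosine basis
  and merged multiplicatively with a state-action trunk; training minimizes
  the quantile-regression Huber loss against distributional Bellman targets.

* **Conservatism (CQL).** A regularizer pushes down Q-values of actions the
  dataset does not support: the penalty is the log-sum-exp of expected Q
  over sampled candidate doses (uniform on [0, 10] plus actor samples)
  minus the expected Q at the dataset action. This keeps the learned policy
  grounded in doses clinicians actually gave.

* **Return-weighted batch sampling.** Transitions are drawn with probability
  proportional to a softmax of their episode's discounted return, so that
  high-return trajectories shape the policy more than low-return ones and
  the conservatism term is not dominated by poor behavior.

The actor is a squashed Gaussian rescaled to the dose range [0, 10]: it
samples stochastically during training (entropy-regularized) and recommends
its deterministic mean, rounded to a whole number of units, at deployment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import MLP, Adam, Linear, Tensor, concat, hard_update, no_grad, soft_update, where
from .pipeline import TransitionDataset
from .simulator import MAX_DOSE

__all__ = [
    "AgentConfig",
    "PolicyArtifact",
    "QuantileValue",
    "train",
    "recommend",
    "critic_quantiles",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class AgentConfig:
    """Hyperparameters of the dosing agent.

    ``gamma``, ``batch_size``, the learning rates, ``hidden_layers`` and
    ``dropout_p`` follow the published training setup (gamma = 0.67 gives a
    ~3 h effective horizon matching how fast glucose moves). The CQL weight,
    quantile-sample counts, cosine embedding dimension, Huber kappa, target
    sync rate and entropy handling are implementation choices from the CQL /
    IQN literature, all exposed here.
    """

    gamma: float = 0.67
    batch_size: int = 256
    actor_lr: float = 1e-4
    critic_lr: float = 3e-4
    hidden_layers: tuple[int, ...] = (512, 512, 512)
    dropout_p: float = 0.1
    cql_alpha: float = 5.0
    n_quantile_samples: int = 8
    n_target_quantile_samples: int = 8
    n_expectation_taus: int = 4
    quantile_embed_dim: int = 64
    huber_kappa: float = 1.0
    n_ood_action_samples: int = 10
    n_actor_action_samples: int = 4
    target_sync_rate: float = 0.005
    gradient_steps: int = 10_000
    seed: int = 0
    return_sampling_temperature: float = 1.0
    actor_entropy_coeff: float = 0.01
    greedy_distill_coeff: float = 1.0
    log_std_bounds: tuple[float, float] = (-5.0, 2.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.actor_lr <= 0 or self.critic_lr <= 0:
            raise ValueError("learning rates must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.cql_alpha < 0:
            raise ValueError("cql_alpha must be non-negative")
        if self.return_sampling_temperature <= 0:
            raise ValueError("return_sampling_temperature must be positive")


@dataclass(frozen=True)
class QuantileValue:
    """Estimated return at quantile fraction tau for one (state, action)."""

    tau: float
    value: float

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie in (0, 1)")


# --------------------------------------------------------------------------
# Networks
# --------------------------------------------------------------------------


class IQNCritic:
    """Implicit quantile critic Z_tau(s, a).

    A state-action trunk produces an embedding psi(s, a); the quantile
    fraction is embedded with a cosine basis phi_j(tau) =
    relu(sum_i cos(pi * i * tau) w_ij + b_j); the elementwise product
    psi * phi feeds a small head emitting the tau-quantile value.
    """

    def __init__(self, state_dim: int, cfg: AgentConfig, rng: np.random.Generator):
        h = cfg.hidden_layers[-1]
        self.trunk = MLP(
            state_dim + 1,
            list(cfg.hidden_layers[:-1]),
            h,
            rng,
            dropout_p=cfg.dropout_p,
            final_activation=True,
        )
        self.tau_embed = Linear(cfg.quantile_embed_dim, h, rng)
        self.head_hidden = Linear(h, h, rng)
        self.head_out = Linear(h, 1, rng)
        self.embed_dim = cfg.quantile_embed_dim

    @property
    def parameters(self):
        return (
            self.trunk.parameters
            + self.tau_embed.parameters
            + self.head_hidden.parameters
            + self.head_out.parameters
        )

    def quantile_values(self, states, actions, taus: np.ndarray, train: bool = False) -> Tensor:
        """Quantile values for each row and each tau: returns a (B, N) tensor.

        ``actions`` may be a Tensor (gradient flows into the action input,
        as needed by the actor update) or a plain array.
        """
        B, N = taus.shape
        s = states if isinstance(states, Tensor) else Tensor(np.asarray(states, float))
        if isinstance(actions, Tensor):
            a = actions.reshape((B, 1))
        else:
            a = Tensor(np.asarray(actions, float).reshape(B, 1))
        x = concat([s, a * (1.0 / MAX_DOSE)], axis=1)
        psi = self.trunk(x, train=train)  # (B, h)
        i_idx = np.arange(self.embed_dim)
        cos_feat = np.cos(np.pi * i_idx[None, None, :] * taus[:, :, None])
        phi = (Tensor(cos_feat.reshape(B * N, self.embed_dim)) @ self.tau_embed.W
               + self.tau_embed.b).relu()
        z = psi.repeat_rows(N) * phi
        q = self.head_out(self.head_hidden(z).relu())
        return q.reshape((B, N))

    def expected_q(self, states, actions, n_taus: int, train: bool = False) -> Tensor:
        """Expected Q as the mean over an equally-spaced quantile midpoint grid."""
        B = states.shape[0] if not isinstance(states, Tensor) else states.shape[0]
        taus = np.tile((np.arange(n_taus) + 0.5) / n_taus, (B, 1))
        return self.quantile_values(states, actions, taus, train=train).mean(
            axis=1, keepdims=True
        )


class SquashedGaussianActor:
    """Stochastic policy: tanh-squashed Gaussian rescaled to doses in [0, 10]."""

    def __init__(self, state_dim: int, cfg: AgentConfig, rng: np.random.Generator):
        self.net = MLP(state_dim, list(cfg.hidden_layers), 2, rng, dropout_p=cfg.dropout_p)
        self.lo, self.hi = cfg.log_std_bounds

    @property
    def parameters(self):
        return self.net.parameters

    def _stats(self, s: Tensor, train: bool = False) -> tuple[Tensor, Tensor]:
        out = self.net(s, train=train)
        mu = out[:, 0:1]
        log_std = self.lo + 0.5 * (self.hi - self.lo) * (out[:, 1:2].tanh() + 1.0)
        return mu, log_std

    def sample(self, s, eps: np.ndarray, train: bool = False) -> tuple[Tensor, Tensor]:
        """Reparameterized action sample and its log-density.

        ``eps`` is standard-normal noise of shape (B, 1). The log-density
        includes the tanh-squash change of variables.
        """
        s = s if isinstance(s, Tensor) else Tensor(np.asarray(s, float))
        mu, log_std = self._stats(s, train=train)
        u = mu + log_std.exp() * Tensor(eps)
        t = u.tanh()
        action = (t + 1.0) * (MAX_DOSE / 2.0)
        log_prob = (
            -log_std
            - 0.5 * Tensor(eps**2)
            - 0.5 * LOG_2PI
            - ((1.0 - t**2) * (MAX_DOSE / 2.0) + 1e-6).log()
        )
        return action, log_prob

    def mean_action(self, s) -> np.ndarray:
        """Deterministic (mean) dose, continuous in [0, 10]."""
        with no_grad():
            s = s if isinstance(s, Tensor) else Tensor(np.asarray(s, float))
            mu, _ = self._stats(s, train=False)
            return ((np.tanh(mu.data) + 1.0) * (MAX_DOSE / 2.0)).ravel()


# --------------------------------------------------------------------------
# Artifact
# --------------------------------------------------------------------------


@dataclass
class PolicyArtifact:
    """A trained policy: networks, config, normalization context, log."""

    actor: SquashedGaussianActor
    critic: IQNCritic
    config: AgentConfig
    feature_names: list[str]
    norm_stats: dict[str, tuple[float, float]]
    training_log: dict = field(default_factory=dict)

    def recommend(self, state: np.ndarray) -> np.ndarray | int:
        """Integer dose recommendation in {0, ..., 10}.

        The actor's mean action is clipped to [0, 10] and rounded half-up.
        Accepts a single feature vector or a (B, d) matrix.
        """
        state = np.asarray(state, dtype=float)
        single = state.ndim == 1
        s = np.atleast_2d(state)
        if s.shape[1] != len(self.feature_names):
            raise ValueError(
                f"state has {s.shape[1]} features; artifact expects {len(self.feature_names)}"
            )
        a = np.clip(self.actor.mean_action(s), 0.0, MAX_DOSE)
        dose = np.floor(a + 0.5).astype(int)  # round half-up
        return int(dose[0]) if single else dose

    def continuous_action(self, state: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(np.asarray(state, dtype=float))
        return np.clip(self.actor.mean_action(s), 0.0, MAX_DOSE)

    def critic_quantiles(self, state, action, taus) -> list[QuantileValue]:
        """Return-distribution quantile estimates for one (state, action)."""
        taus = np.asarray(taus, dtype=float).ravel()
        if np.any((taus <= 0) | (taus >= 1)):
            raise ValueError("all taus must lie in the open interval (0, 1)")
        s = np.atleast_2d(np.asarray(state, dtype=float))
        with no_grad():
            q = self.critic.quantile_values(
                np.repeat(s, len(taus), axis=0),
                np.full(len(taus), float(action)),
                taus.reshape(-1, 1),
            )
        return [QuantileValue(float(t), float(v)) for t, v in zip(taus, q.data.ravel())]

    # -------------------------------------------------------------- storage
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, p in enumerate(self.actor.parameters):
            arrays[f"actor_{i}"] = p.data
        for i, p in enumerate(self.critic.parameters):
            arrays[f"critic_{i}"] = p.data
        np.savez(d / "parameters.npz", **arrays)
        cfg = asdict(self.config)
        cfg["hidden_layers"] = list(cfg["hidden_layers"])
        cfg["log_std_bounds"] = list(cfg["log_std_bounds"])
        (d / "config.json").write_text(json.dumps(cfg, indent=1))
        side = {
            "feature_names": self.feature_names,
            "norm_stats": {k: list(v) for k, v in self.norm_stats.items()},
            "training_log": self.training_log,
        }
        (d / "artifact.json").write_text(json.dumps(side, indent=1))

    @classmethod
    def load(cls, directory) -> "PolicyArtifact":
        d = Path(directory)
        cfg_raw = json.loads((d / "config.json").read_text())
        cfg_raw["hidden_layers"] = tuple(cfg_raw["hidden_layers"])
        cfg_raw["log_std_bounds"] = tuple(cfg_raw["log_std_bounds"])
        config = AgentConfig(**cfg_raw)
        side = json.loads((d / "artifact.json").read_text())
        state_dim = len(side["feature_names"])
        rng = np.random.default_rng(0)
        actor = SquashedGaussianActor(state_dim, config, rng)
        critic = IQNCritic(state_dim, config, rng)
        arrays = np.load(d / "parameters.npz")
        for i, p in enumerate(actor.parameters):
            p.data = arrays[f"actor_{i}"]
        for i, p in enumerate(critic.parameters):
            p.data = arrays[f"critic_{i}"]
        return cls(
            actor=actor,
            critic=critic,
            config=config,
            feature_names=side["feature_names"],
            norm_stats={k: tuple(v) for k, v in side["norm_stats"].items()},
            training_log=side["training_log"],
        )


# --------------------------------------------------------------------------
# Loss pieces
# --------------------------------------------------------------------------


def _huber(delta: Tensor, kappa: float) -> Tensor:
    small = np.abs(delta.data) <= kappa
    return where(small, 0.5 * delta**2, kappa * (delta.abs() - 0.5 * kappa))


def _quantile_huber_loss(online: Tensor, target: np.ndarray, taus: np.ndarray, kappa: float) -> Tensor:
    """Quantile-regression Huber loss.

    online: (B, N) tensor of quantile estimates at fractions ``taus``;
    target: (B, N') constant Bellman target samples. Pairwise TD errors are
    weighted by |tau - 1{error < 0}|; summed over online quantiles, averaged
    over target samples and batch.
    """
    B, N = online.shape
    Np = target.shape[1]
    delta = Tensor(target.reshape(B, 1, Np)) - online.reshape((B, N, 1))
    weight = np.abs(taus[:, :, None] - (delta.data < 0.0))
    loss = Tensor(weight) * _huber(delta, kappa) * (1.0 / kappa)
    return loss.mean(axis=2).sum(axis=1).mean()


def _sampling_probabilities(dataset: TransitionDataset, temperature: float) -> np.ndarray:
    returns = dataset.episode_returns
    if len(returns) == 0 or not np.all(np.isfinite(returns)):
        warnings.warn("episode returns missing or non-finite; falling back to uniform sampling")
        return np.full(len(dataset), 1.0 / len(dataset))
    z = returns / temperature
    z = z - z.max()
    ep_weight = np.exp(z)
    w = ep_weight[dataset.episode_ids]
    return w / w.sum()


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------


def train(dataset: TransitionDataset, config: AgentConfig) -> PolicyArtifact:
    """Train the conservative distributional agent on logged transitions.

    All randomness (initialization, batch sampling, quantile fractions,
    candidate OOD actions, actor noise, dropout) derives from
    ``config.seed``; identical seed and dataset give identical artifacts.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(config.seed)
    d = dataset.states.shape[1]

    actor = SquashedGaussianActor(d, config, rng)
    critic = IQNCritic(d, config, rng)
    target_critic = IQNCritic(d, config, np.random.default_rng(config.seed + 1))
    hard_update(target_critic.parameters, critic.parameters)

    opt_critic = Adam(critic.parameters, config.critic_lr)
    opt_actor = Adam(actor.parameters, config.actor_lr)
    probs = _sampling_probabilities(dataset, config.return_sampling_temperature)

    n = len(dataset)
    log: dict[str, list] = {"step": [], "critic_loss": [], "cql_term": [], "actor_loss": []}
    n_rand = config.n_ood_action_samples
    n_pol = config.n_actor_action_samples
    m = config.n_expectation_taus

    for step in range(config.gradient_steps):
        idx = rng.choice(n, size=config.batch_size, p=probs)
        s = dataset.states[idx]
        a = dataset.actions[idx]
        r = dataset.rewards[idx]
        s1 = dataset.next_states[idx]
        not_done = 1.0 - dataset.dones[idx].astype(float)
        B = len(idx)

        # ---- distributional Bellman target (no gradient)
        taus = rng.random((B, config.n_quantile_samples))
        taus_t = rng.random((B, config.n_target_quantile_samples))
        with no_grad():
            eps1 = rng.standard_normal((B, 1))
            a1, _ = actor.sample(s1, eps1)
            zt = target_critic.quantile_values(s1, a1.data.ravel(), taus_t)
        target = r[:, None] + config.gamma * not_done[:, None] * zt.data

        # ---- critic loss: quantile regression + conservatism
        online = critic.quantile_values(s, a, taus, train=True)
        qr_loss = _quantile_huber_loss(online, target, taus, config.huber_kappa)

        with no_grad():
            eps_pol = rng.standard_normal((B, n_pol))
            pol_actions = np.column_stack(
                [actor.sample(s, eps_pol[:, j : j + 1])[0].data.ravel() for j in range(n_pol)]
            )
        rand_actions = rng.uniform(0.0, MAX_DOSE, size=(B, n_rand))
        candidates = np.column_stack([a, rand_actions, pol_actions])  # (B, C); col 0 = data
        C = candidates.shape[1]
        q_all = critic.expected_q(
            np.repeat(s, C, axis=0), candidates.reshape(-1), m, train=True
        ).reshape((B, C))
        lse = q_all.logsumexp(axis=1) - float(np.log(C))
        q_data = q_all[:, 0]
        cql_term = (lse - q_data).mean()

        critic_loss = qr_loss + config.cql_alpha * cql_term
        if not np.isfinite(critic_loss.data):
            raise RuntimeError(
                f"critic loss diverged at step {step}: qr={qr_loss.data!r}, "
                f"cql={cql_term.data!r}"
            )
        opt_critic.zero_grad()
        opt_actor.zero_grad()
        critic_loss.backward()
        opt_critic.step()

        # ---- actor: maximize expected Q with entropy regularization.
        # The conservative critic is multimodal in the dose, so pure gradient
        # ascent stalls in local optima; a distillation term pulls the actor
        # toward the critic's best whole-unit dose at each batch state.
        eps_a = rng.standard_normal((B, 1))
        a_pi, logp = actor.sample(s, eps_a, train=True)
        q_pi = critic.expected_q(s, a_pi, m)
        actor_loss = (config.actor_entropy_coeff * logp - q_pi).mean()
        if config.greedy_distill_coeff > 0:
            grid = np.arange(0.0, MAX_DOSE + 1.0)
            with no_grad():
                q_grid = critic.expected_q(
                    np.repeat(s, len(grid), axis=0), np.tile(grid, B), m
                ).reshape((B, len(grid)))
            a_greedy = grid[np.argmax(q_grid.data, axis=1)].reshape(-1, 1)
            distill = (((a_pi.reshape((B, 1)) - Tensor(a_greedy)) * (1.0 / MAX_DOSE)) ** 2).mean()
            actor_loss = actor_loss + config.greedy_distill_coeff * distill
        if not np.isfinite(actor_loss.data):
            raise RuntimeError(f"actor loss diverged at step {step}")
        opt_critic.zero_grad()
        opt_actor.zero_grad()
        actor_loss.backward()
        opt_actor.step()

        soft_update(target_critic.parameters, critic.parameters, config.target_sync_rate)

        if step % 100 == 0 or step == config.gradient_steps - 1:
            log["step"].append(step)
            log["critic_loss"].append(float(critic_loss.data))
            log["cql_term"].append(float(cql_term.data))
            log["actor_loss"].append(float(actor_loss.data))

    return PolicyArtifact(
        actor=actor,
        critic=critic,
        config=config,
        feature_names=list(dataset.feature_names),
        norm_stats=dict(dataset.norm_stats),
        training_log=log,
    )


def recommend(artifact: PolicyArtifact, state: np.ndarray):
    """Module-level alias for :meth:`PolicyArtifact.recommend`."""
    return artifact.recommend(state)


def critic_quantiles(artifact: PolicyArtifact, state, action, taus) -> list[QuantileValue]:
    """Module-level alias for :meth:`PolicyArtifact.critic_quantiles`."""
    return artifact.critic_quantiles(state, action, taus)
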