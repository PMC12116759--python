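"""Descriptive statistics comparing a learned dosing policy with clinicians.

Given hourly model recommendations and the doses actually administered, this
module computes the standard policy-audit statistics for glycemic control:

* time in range (TIR): fraction of hourly glucose values inside the closed
  70-180 mg/dL band (hypoglycemia is defined as <70 and hyperglycemia as
  >180, so both boundary values count as in range);
* per-patient cumulative dose difference Delta = sum_t (model - observed),
  positive when the model recommends more insulin than was given;
* TIR and mean glucose binned by Delta, and mean doses binned by glucose
  range — the two headline comparison views;
* exact agreement rate, top/bottom-decile disagreement profiles, MAE against
  a reference dosing scheme with a paired-comparison t test, and seeded
  permutation feature importance for the policy's recommendations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .agent import PolicyArtifact
from .ope import bootstrap_ci
from .pipeline import TransitionDataset

__all__ = [
    "TIR_LOW",
    "TIR_HIGH",
    "PolicyComparison",
    "time_in_range",
    "cumulative_difference",
    "build_comparisons",
    "tir_by_difference",
    "dose_by_glucose",
    "agreement_rate",
    "disagreement_deciles",
    "mae_vs_reference",
    "permutation_importance",
    "ArtifactSimPolicy",
]

TIR_LOW = 70.0
TIR_HIGH = 180.0

#: default per-patient cumulative-difference bin edges (units over 24 h);
#: outer bins open-ended
DEFAULT_DELTA_EDGES = (-10.0, -3.0, 3.0, 10.0)

#: default glucose bin edges (mg/dL) for the dose-by-glucose profile
DEFAULT_GLUCOSE_EDGES = (70.0, 100.0, 140.0, 180.0, 200.0, 250.0)


def time_in_range(glucose) -> float:
    """Fraction of glucose values within [70, 180] mg/dL (closed interval)."""
    g = np.asarray(glucose, dtype=float)
    if g.size == 0:
        raise ValueError("time_in_range needs a non-empty series")
    return float(np.mean((g >= TIR_LOW) & (g <= TIR_HIGH)))


def cumulative_difference(model_doses, observed_doses) -> float:
    """Sum over hours of (model dose - observed dose)."""
    m = np.asarray(model_doses, dtype=float)
    o = np.asarray(observed_doses, dtype=float)
    if m.shape != o.shape:
        raise ValueError("dose sequences must have equal length")
    return float(np.sum(m - o))


@dataclass
class PolicyComparison:
    """Hourly model-vs-observed comparison for one patient episode."""

    patient_id: object
    model_doses: np.ndarray
    observed_doses: np.ndarray
    glucose: np.ndarray
    delta: float = field(init=False)
    tir: float = field(init=False)
    mean_glucose: float = field(init=False)

    def __post_init__(self) -> None:
        self.model_doses = np.asarray(self.model_doses, float)
        self.observed_doses = np.asarray(self.observed_doses, float)
        self.glucose = np.asarray(self.glucose, float)
        self.delta = cumulative_difference(self.model_doses, self.observed_doses)
        self.tir = time_in_range(self.glucose)
        self.mean_glucose = float(self.glucose.mean())


def build_comparisons(
    dataset: TransitionDataset, artifact: PolicyArtifact
) -> list[PolicyComparison]:
    """One PolicyComparison per episode of a test TransitionDataset.

    The glucose series used for TIR covers every hour of the episode
    (states plus the final next-state observation).
    """
    if dataset.raw_glucose is None:
        raise ValueError("dataset lacks raw glucose; rebuild with raw_glucose")
    model = np.asarray(artifact.recommend(dataset.states), dtype=float)
    out = []
    for ep in np.unique(dataset.episode_ids):
        rows = np.flatnonzero(dataset.episode_ids == ep)
        rows = rows[np.argsort(dataset.hours[rows], kind="stable")]
        glucose = np.append(dataset.raw_glucose[rows], dataset.next_glucose[rows[-1]])
        out.append(
            PolicyComparison(
                patient_id=dataset.patient_ids[rows[0]],
                model_doses=model[rows],
                observed_doses=dataset.actions[rows],
                glucose=glucose,
            )
        )
    return out


def _bin_labels(edges: tuple[float, ...]) -> list[str]:
    labels = [f"<{edges[0]:g}"]
    labels += [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    labels += [f">={edges[-1]:g}"]
    return labels


def tir_by_difference(
    comparisons: list[PolicyComparison],
    edges: tuple[float, ...] = DEFAULT_DELTA_EDGES,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean TIR and mean glucose of patients binned by cumulative difference.

    Empty bins are omitted (reported as absent, not as zero).
    """
    if not comparisons:
        raise ValueError("no comparisons given")
    deltas = np.array([c.delta for c in comparisons])
    tirs = np.array([c.tir for c in comparisons])
    mg = np.array([c.mean_glucose for c in comparisons])
    idx = np.digitize(deltas, edges)
    labels = _bin_labels(edges)
    rows = []
    for b in range(len(edges) + 1):
        mask = idx == b
        if not mask.any():
            continue
        lo, hi = bootstrap_ci(tirs[mask], n_resamples=n_bootstrap, seed=seed + b)
        rows.append(
            {
                "bin": labels[b],
                "mean_tir": tirs[mask].mean(),
                "tir_ci_low": min(lo, tirs[mask].mean()),
                "tir_ci_high": max(hi, tirs[mask].mean()),
                "mean_glucose": mg[mask].mean(),
                "n": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def dose_by_glucose(
    model_doses,
    observed_doses,
    glucose,
    edges: tuple[float, ...] = DEFAULT_GLUCOSE_EDGES,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean model and observed dose within each glucose range."""
    m = np.asarray(model_doses, float)
    o = np.asarray(observed_doses, float)
    g = np.asarray(glucose, float)
    idx = np.digitize(g, edges)
    labels = _bin_labels(edges)
    rows = []
    for b in range(len(edges) + 1):
        mask = idx == b
        if not mask.any():
            continue
        mlo, mhi = bootstrap_ci(m[mask], n_resamples=n_bootstrap, seed=seed + 2 * b)
        olo, ohi = bootstrap_ci(o[mask], n_resamples=n_bootstrap, seed=seed + 2 * b + 1)
        mm, om = m[mask].mean(), o[mask].mean()
        rows.append(
            {
                "glucose_bin": labels[b],
                "mean_model_dose": mm,
                "model_ci_low": min(mlo, mm),
                "model_ci_high": max(mhi, mm),
                "mean_observed_dose": om,
                "observed_ci_low": min(olo, om),
                "observed_ci_high": max(ohi, om),
                "n": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def agreement_rate(model_doses, observed_doses) -> float:
    """Fraction of hours where the (integer) model dose equals the observed dose."""
    m = np.asarray(model_doses, float)
    o = np.asarray(observed_doses, float)
    if m.shape != o.shape:
        raise ValueError("dose sequences must have equal length")
    if m.size == 0:
        raise ValueError("no timesteps to compare")
    return float(np.mean(m == o))


def disagreement_deciles(
    model_doses, observed_doses, glucose, features: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Profiles of the top and bottom deciles of |model - observed|.

    Returns a two-row frame (bottom_decile, top_decile) with mean glucose,
    mean model and observed dose, mean absolute difference and, when a
    feature table aligned with the timesteps is given, the mean of every
    feature within each decile.
    """
    m = np.asarray(model_doses, float)
    o = np.asarray(observed_doses, float)
    g = np.asarray(glucose, float)
    n = m.size
    if n < 10:
        raise ValueError("need at least 10 timesteps for deciles")
    absdiff = np.abs(m - o)
    order = np.argsort(absdiff, kind="stable")
    k = n // 10
    bottom, top = order[:k], order[-k:]
    rows = {}
    for name, sel in (("bottom_decile", bottom), ("top_decile", top)):
        row = {
            "mean_abs_difference": absdiff[sel].mean(),
            "mean_glucose": g[sel].mean(),
            "mean_model_dose": m[sel].mean(),
            "mean_observed_dose": o[sel].mean(),
            "n": len(sel),
        }
        if features is not None:
            for c in features.columns:
                row[f"mean_{c}"] = float(features[c].to_numpy()[sel].mean())
        rows[name] = row
    return pd.DataFrame(rows).T


def mae_vs_reference(candidate_doses, reference_doses) -> tuple[float, float]:
    """Mean absolute error between two aligned dose sequences, with a t test.

    Returns ``(mae, p_value)`` where the p value comes from a one-sample t
    test of the signed hourly errors against zero — the paired-comparison
    reading of a two-sample t test on aligned sequences.
    """
    c = np.asarray(candidate_doses, float)
    r = np.asarray(reference_doses, float)
    if c.shape != r.shape:
        raise ValueError("dose sequences must have equal length")
    err = np.abs(c - r)
    mae = float(err.mean())
    if np.allclose(c, r):
        return mae, 1.0
    t = sps.ttest_1samp(c - r, 0.0)
    return mae, float(t.pvalue)


def compare_maes(errors_a, errors_b) -> float:
    """Two-sample t test p value between two absolute-error vectors."""
    t = sps.ttest_ind(np.asarray(errors_a, float), np.asarray(errors_b, float))
    return float(t.pvalue)


def permutation_importance(
    artifact: PolicyArtifact,
    states: np.ndarray | TransitionDataset,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature importance as dose sensitivity to column permutation.

    For each feature, the column is shuffled across states and the mean
    absolute change in the recommended (continuous) dose is recorded;
    averaging over ``n_repeats`` seeded permutations. Features are returned
    ranked by score. This is a model-agnostic approximation to coalitional
    (SHAP-style) attribution that only requires forward passes.
    """
    if isinstance(states, TransitionDataset):
        states = states.states
    states = np.asarray(states, float)
    rng = np.random.default_rng(seed)
    base = artifact.continuous_action(states)
    scores = []
    for j, name in enumerate(artifact.feature_names):
        deltas = []
        for _ in range(n_repeats):
            perm = states.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            deltas.append(np.abs(artifact.continuous_action(perm) - base).mean())
        scores.append({"feature": name, "importance": float(np.mean(deltas))})
    df = pd.DataFrame(scores).sort_values("importance", ascending=False).reset_index(drop=True)
    return df


# --------------------------------------------------------------------------
# Simulator adapter: run a trained artifact inside the virtual ICU
# --------------------------------------------------------------------------


class ArtifactSimPolicy:
    """Adapts a PolicyArtifact to the simulator's observation protocol.

    Reconstructs the artifact's state vector from the simulator observation:
    current glucose, four lags backfilled with the earliest measurement,
    hourly deltas, the glucose-change/insulin ratio, covariates, and the
    hour index — then normalizes with the artifact's training statistics.
    Features the simulator does not expose at decision time (a handful of
    hourly labs) are represented by their training-set midpoint; the learned
    policies lean on glucose history and statics, so this is a benign
    approximation used only for Monte-Carlo rollouts.
    """

    def __init__(self, artifact: PolicyArtifact, integer_doses: bool = True):
        self.artifact = artifact
        self.integer = integer_doses
        self.names = artifact.feature_names
        self.stats = artifact.norm_stats

    def _norm(self, name: str, value: float) -> float:
        lo, hi = self.stats[name]
        return float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))

    def __call__(self, obs: dict) -> float:
        hist = obs["glucose_history"]
        g = hist[-1]
        first = hist[0]
        lags = [hist[-1 - k] if len(hist) > k else first for k in range(1, 5)]
        seq = [g] + lags  # lag0 .. lag4
        deltas = [seq[k] - seq[k + 1] for k in range(4)]
        prev_insulin = obs.get("prev_insulin", 0.0)
        ratio = deltas[0] / max(prev_insulin, 0.1)
        raw = {
            "glucose": g,
            "glucose_lag1": lags[0],
            "glucose_lag2": lags[1],
            "glucose_lag3": lags[2],
            "glucose_lag4": lags[3],
            "glucose_delta1": deltas[0],
            "glucose_delta2": deltas[1],
            "glucose_delta3": deltas[2],
            "glucose_delta4": deltas[3],
            "glucose_insulin_ratio": ratio,
            "hour_idx": obs.get("hour", 0),
        }
        vec = np.empty(len(self.names))
        for i, name in enumerate(self.names):
            if name in raw:
                vec[i] = self._norm(name, raw[name])
            elif name in obs:
                vec[i] = self._norm(name, float(obs[name]))
            else:
                vec[i] = 0.5  # unobserved hourly lab: training-set midpoint
        if self.integer:
            return float(self.artifact.recommend(vec))
        return float(self.artifact.continuous_action(vec)[0])
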