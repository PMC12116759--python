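"""From raw trajectory tables to normalized transition datasets.

The stages mirror standard EHR-to-MDP preprocessing for offline RL on ICU
time series:

1. :func:`apply_exclusions` — remove flagged patients (death in the first
   24 h, ambiguous medication records, no glucose within three hours,
   exposure to other short-acting insulins), with a per-criterion tally.
2. :func:`align_and_bin` — bin raw timestamps into 1-hour steps (doses
   summed, vitals/labs averaged), re-index time from the first glucose
   measurement, and keep only the first 24 h of data.
3. :func:`handle_missingness` — drop features with more than 30% missing
   entries (measured on the training split), forward-fill within patient,
   then k-NN imputation (k=5) for what remains, with training rows as the
   donor pool.
4. :func:`engineer_glucose_features` — four hourly glucose lags, lagged
   hourly deltas, and the glucose-change/insulin-dose response ratio with
   the dose floored at 0.1 U.
5. :func:`normalize` — min-max scale every state feature to [0, 1] using
   training-split statistics, clipping out-of-range test values.
6. :func:`build_transitions` — consecutive-hour (s, a, r, s', done) tuples
   with actions clipped to [0, 10] and the reward computed from the glucose
   observed at the next hour.
7. :func:`split_patients` / :func:`subsample_patients` — patient-level
   85/15 train/test split and 80% training subsamples for the multi-seed
   training protocol.

All statistics that could leak information (missingness rates, imputation
donors, normalization ranges) are computed on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .rewards import RewardParams, DEFAULT_REWARD_PARAMS, shaped_reward
from .simulator import (
    AGGREGATION,
    DYNAMIC_FEATURES,
    EXCLUSION_FLAGS,
    MAX_DOSE,
    STATIC_FEATURES,
)

__all__ = [
    "apply_exclusions",
    "align_and_bin",
    "MissingnessHandler",
    "handle_missingness",
    "engineer_glucose_features",
    "delta_insulin_ratio",
    "Normalizer",
    "normalize",
    "build_transitions",
    "split_patients",
    "subsample_patients",
    "TransitionDataset",
    "preprocess_cohort",
]

GLUCOSE_LAGS = 4
MIN_INSULIN_FOR_RATIO = 0.1


# --------------------------------------------------------------------------
# 1. Exclusion filters
# --------------------------------------------------------------------------


def apply_exclusions(
    trajectories: pd.DataFrame, patients: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Drop flagged patients; tally removals per criterion in declared order.

    A patient carrying several flags is counted once, under the first
    matching criterion in :data:`~glycorl.simulator.EXCLUSION_FLAGS` order.
    """
    missing = [f for f in EXCLUSION_FLAGS if f not in patients.columns]
    if missing:
        raise KeyError(f"patient table lacks exclusion flag columns: {missing}")
    tally: dict[str, int] = {}
    remaining = patients
    for flag in EXCLUSION_FLAGS:
        hit = remaining[flag].astype(bool)
        tally[flag] = int(hit.sum())
        remaining = remaining[~hit]
    keep_ids = remaining["patient_id"]
    traj = trajectories[trajectories["patient_id"].isin(keep_ids)].reset_index(drop=True)
    return traj, remaining.reset_index(drop=True), tally


# --------------------------------------------------------------------------
# 2. Hourly alignment
# --------------------------------------------------------------------------


def align_and_bin(
    trajectories: pd.DataFrame,
    aggregation: dict[str, str] | None = None,
    window_hours: int = 24,
) -> pd.DataFrame:
    """Bin raw rows into hourly steps and re-anchor time at first glucose.

    Raw rows carry a ``hour`` column (float hours since ICU admission; may be
    sub-hourly). Within each integer hour, features are aggregated per the
    schema (insulin summed, vitals/labs averaged). Only the first
    ``window_hours`` hours since admission are kept, and the emitted
    ``hour`` index starts at 0 at the hour of the first glucose measurement.
    Patients with no glucose at all are dropped with a warning.
    """
    agg = dict(AGGREGATION if aggregation is None else aggregation)
    df = trajectories.copy()
    df["hour"] = np.floor(df["hour"].astype(float)).astype(int)
    df = df[df["hour"] < window_hours]
    value_cols = [c for c in df.columns if c not in ("patient_id", "hour")]
    agg_map = {c: agg.get(c, "mean") for c in value_cols}
    hourly = df.groupby(["patient_id", "hour"], as_index=False).agg(agg_map)

    out = []
    for pid, grp in hourly.groupby("patient_id", sort=True):
        grp = grp.sort_values("hour")
        has_glucose = grp["glucose"].notna()
        if not has_glucose.any():
            import warnings

            warnings.warn(f"patient {pid!r} has no glucose measurements; dropped")
            continue
        first = int(grp.loc[has_glucose, "hour"].iloc[0])
        grp = grp[grp["hour"] >= first].copy()
        grp["hour"] = grp["hour"] - first
        out.append(grp)
    if not out:
        return hourly.iloc[0:0]
    return pd.concat(out, ignore_index=True)


# --------------------------------------------------------------------------
# 3. Missingness: drop rule, forward fill, k-NN
# --------------------------------------------------------------------------


class MissingnessHandler:
    """Training-split-governed missingness policy.

    ``fit`` measures per-feature missingness on the training table and fixes
    the dropped-feature list (strictly greater than ``threshold``); it also
    retains the forward-filled training rows as the k-NN donor pool.
    ``transform`` forward-fills within patient and imputes residual gaps
    (leading NaNs that forward fill cannot reach) by k-nearest neighbours
    over features scaled to the training min-max range, so that no feature
    dominates the Euclidean distance.
    """

    def __init__(self, threshold: float = 0.30, k: int = 5, feature_cols: list[str] | None = None):
        if not 0.0 <= threshold < 1.0:
            raise ValueError("threshold must be in [0, 1)")
        self.threshold = threshold
        self.k = k
        self.feature_cols = feature_cols
        self.dropped_: list[str] = []
        self._imputer: KNNImputer | None = None
        self._scale: tuple[np.ndarray, np.ndarray] | None = None
        self._kept: list[str] = []

    @staticmethod
    def _ffill(table: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        table = table.copy()
        table[cols] = table.groupby("patient_id", sort=False)[cols].ffill()
        return table

    def fit(self, train: pd.DataFrame) -> "MissingnessHandler":
        cols = self.feature_cols
        if cols is None:
            cols = [c for c in train.columns if c not in ("patient_id", "hour")]
        rates = train[cols].isna().mean()
        self.dropped_ = [c for c in cols if rates[c] > self.threshold]
        self._kept = [c for c in cols if c not in self.dropped_]
        filled = self._ffill(train, self._kept)
        donors = filled[self._kept].to_numpy(dtype=float)
        lo = np.nanmin(donors, axis=0)
        hi = np.nanmax(donors, axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        self._scale = (lo, span)
        self._imputer = KNNImputer(n_neighbors=self.k)
        self._imputer.fit((donors - lo) / span)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self._imputer is None:
            raise RuntimeError("fit before transform")
        table = table.drop(columns=[c for c in self.dropped_ if c in table.columns])
        table = self._ffill(table, self._kept)
        block = table[self._kept].to_numpy(dtype=float)
        if np.isnan(block).any():
            lo, span = self._scale
            imputed = self._imputer.transform((block - lo) / span) * span + lo
            table = table.copy()
            table[self._kept] = imputed
        assert not table[self._kept].isna().any().any(), "imputation left missing values"
        return table


def handle_missingness(
    train: pd.DataFrame,
    *others: pd.DataFrame,
    threshold: float = 0.30,
    k: int = 5,
) -> tuple[list[pd.DataFrame], list[str]]:
    """Functional wrapper: fit on ``train``, transform train and others."""
    handler = MissingnessHandler(threshold=threshold, k=k).fit(train)
    tables = [handler.transform(t) for t in (train, *others)]
    return tables, handler.dropped_


# --------------------------------------------------------------------------
# 4. Glucose feature engineering
# --------------------------------------------------------------------------


def delta_insulin_ratio(delta_glucose, insulin) -> np.ndarray:
    """Glucose change per unit of insulin, dose floored at 0.1 U."""
    d = np.asarray(delta_glucose, dtype=float)
    a = np.asarray(insulin, dtype=float)
    return d / np.maximum(a, MIN_INSULIN_FOR_RATIO)


def engineer_glucose_features(table: pd.DataFrame) -> pd.DataFrame:
    """Add glucose history features per patient.

    * ``glucose_lag{1..4}``: prior hourly glucose values; lags reaching
      before the first observation are backfilled with the earliest observed
      glucose (zero would be physiologically absurd and would distort
      normalization).
    * ``glucose_delta{1..4}``: hourly changes within the same 4-hour window
      (``delta_k = lag_{k-1} - lag_k``, with the current value as lag 0).
    * ``glucose_insulin_ratio``: last hour's glucose change per unit of the
      insulin dose that preceded it (floor 0.1 U) — a crude observable
      signature of the patient's insulin sensitivity.
    """
    out = []
    for _, grp in table.groupby("patient_id", sort=False):
        grp = grp.sort_values("hour").copy()
        g = grp["glucose"].astype(float)
        first = g.iloc[0]
        for k in range(1, GLUCOSE_LAGS + 1):
            grp[f"glucose_lag{k}"] = g.shift(k).fillna(first)
        prev = g
        for k in range(1, GLUCOSE_LAGS + 1):
            lagged = grp[f"glucose_lag{k}"]
            grp[f"glucose_delta{k}"] = prev - lagged
            prev = lagged
        prev_insulin = grp["insulin"].astype(float).shift(1).fillna(0.0)
        grp["glucose_insulin_ratio"] = delta_insulin_ratio(
            grp["glucose_delta1"], prev_insulin
        )
        out.append(grp)
    return pd.concat(out, ignore_index=True)


ENGINEERED_FEATURES = (
    [f"glucose_lag{k}" for k in range(1, GLUCOSE_LAGS + 1)]
    + [f"glucose_delta{k}" for k in range(1, GLUCOSE_LAGS + 1)]
    + ["glucose_insulin_ratio"]
)


# --------------------------------------------------------------------------
# 5. Normalization
# --------------------------------------------------------------------------


class Normalizer:
    """Per-feature min-max scaling to [0, 1] with training-split statistics.

    Features that are constant on the training split are dropped (their
    min equals their max, so they carry no information). Transformed values
    outside the training range are clipped to [0, 1].
    """

    def __init__(self, feature_cols: list[str]):
        self.feature_cols = list(feature_cols)
        self.stats_: dict[str, tuple[float, float]] = {}
        self.dropped_constant_: list[str] = []

    def fit(self, train: pd.DataFrame) -> "Normalizer":
        self.stats_ = {}
        self.dropped_constant_ = []
        for c in self.feature_cols:
            lo = float(train[c].min())
            hi = float(train[c].max())
            if hi > lo:
                self.stats_[c] = (lo, hi)
            else:
                self.dropped_constant_.append(c)
        return self

    @property
    def kept_features(self) -> list[str]:
        return [c for c in self.feature_cols if c in self.stats_]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        unknown = [c for c in self.stats_ if c not in table.columns]
        if unknown:
            raise KeyError(f"table lacks features required by normalizer: {unknown}")
        table = table.drop(columns=[c for c in self.dropped_constant_ if c in table.columns])
        table = table.copy()
        for c, (lo, hi) in self.stats_.items():
            table[c] = ((table[c] - lo) / (hi - lo)).clip(0.0, 1.0)
        return table


def normalize(
    table: pd.DataFrame,
    feature_cols: list[str],
    stats: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Min-max scale ``feature_cols``; fit stats on ``table`` when not given."""
    norm = Normalizer(feature_cols)
    if stats is None:
        norm.fit(table)
    else:
        norm.stats_ = dict(stats)
        norm.dropped_constant_ = [c for c in feature_cols if c not in stats]
    return norm.transform(table), dict(norm.stats_)


# --------------------------------------------------------------------------
# 6. Transition construction
# --------------------------------------------------------------------------


@dataclass
class TransitionDataset:
    """Flat arrays of (s, a, r, s', done) transitions grouped into episodes."""

    states: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    next_states: np.ndarray
    dones: np.ndarray
    patient_ids: np.ndarray
    hours: np.ndarray
    episode_ids: np.ndarray
    episode_returns: np.ndarray
    feature_names: list[str]
    norm_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    raw_glucose: np.ndarray | None = None  # glucose (mg/dL) at s_t, for analyses
    next_glucose: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.states)
        for name in ("actions", "rewards", "next_states", "dones", "episode_ids"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_episodes(self) -> int:
        return len(self.episode_returns)

    @property
    def episode_start_indices(self) -> np.ndarray:
        _, first = np.unique(self.episode_ids, return_index=True)
        return np.sort(first)

    def save(self, directory) -> None:
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "hour": self.hours,
                "episode_id": self.episode_ids,
                "action": self.actions,
                "reward": self.rewards,
                "done": self.dones,
            }
        )
        for i, name in enumerate(self.feature_names):
            df[f"s::{name}"] = self.states[:, i]
            df[f"s1::{name}"] = self.next_states[:, i]
        if self.raw_glucose is not None:
            df["glucose_mgdl"] = self.raw_glucose
            df["next_glucose_mgdl"] = self.next_glucose
        df.to_parquet(d / "transitions.parquet", index=False)
        sidecar = {
            "feature_names": self.feature_names,
            "norm_stats": {k: list(v) for k, v in self.norm_stats.items()},
            "episode_returns": self.episode_returns.tolist(),
        }
        (d / "metadata.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, directory) -> "TransitionDataset":
        import json
        from pathlib import Path

        d = Path(directory)
        df = pd.read_parquet(d / "transitions.parquet")
        meta = json.loads((d / "metadata.json").read_text())
        names = meta["feature_names"]
        return cls(
            states=df[[f"s::{n}" for n in names]].to_numpy(float),
            actions=df["action"].to_numpy(float),
            rewards=df["reward"].to_numpy(float),
            next_states=df[[f"s1::{n}" for n in names]].to_numpy(float),
            dones=df["done"].to_numpy(bool),
            patient_ids=df["patient_id"].to_numpy(),
            hours=df["hour"].to_numpy(int),
            episode_ids=df["episode_id"].to_numpy(int),
            episode_returns=np.asarray(meta["episode_returns"], float),
            feature_names=list(names),
            norm_stats={k: tuple(v) for k, v in meta["norm_stats"].items()},
            raw_glucose=df["glucose_mgdl"].to_numpy(float) if "glucose_mgdl" in df else None,
            next_glucose=df["next_glucose_mgdl"].to_numpy(float) if "next_glucose_mgdl" in df else None,
        )


def build_transitions(
    table: pd.DataFrame,
    feature_names: list[str],
    reward_params: RewardParams = DEFAULT_REWARD_PARAMS,
    gamma: float = 0.67,
    norm_stats: dict[str, tuple[float, float]] | None = None,
    raw_glucose_col: str = "glucose_raw",
) -> TransitionDataset:
    """Assemble (s, a, r, s', done) tuples from a normalized hourly table.

    For each consecutive hour pair within a patient: the state is the feature
    vector at hour t, the action the insulin dose at t clipped to [0, 10],
    and the reward the shaped reward of the glucose observed at t+1 under
    that action — the action's consequence, which is the causal reading of
    "reward for taking action a at state s_t". The final pair of an episode
    is flagged done; single-hour patients are skipped with a warning.

    Episode returns (discount ``gamma``) are stored for return-weighted batch
    sampling during training.
    """
    states, actions, rewards, next_states = [], [], [], []
    dones, pids, hrs, epids, raw_g, nxt_g = [], [], [], [], [], []
    ep_returns = []
    ep = 0
    for pid, grp in table.groupby("patient_id", sort=True):
        grp = grp.sort_values("hour")
        if len(grp) < 2:
            import warnings

            warnings.warn(f"patient {pid!r} has a single hour of data; skipped")
            continue
        feats = grp[feature_names].to_numpy(dtype=float)
        dose = grp["insulin"].to_numpy(dtype=float).clip(0.0, MAX_DOSE)
        glucose = grp[raw_glucose_col].to_numpy(dtype=float)
        hours = grp["hour"].to_numpy()
        n = len(grp) - 1
        r = shaped_reward(glucose[1:], dose[:-1], reward_params)
        states.append(feats[:-1])
        next_states.append(feats[1:])
        actions.append(dose[:-1])
        rewards.append(r)
        done = np.zeros(n, dtype=bool)
        done[-1] = True
        dones.append(done)
        pids.append(np.repeat(pid, n))
        hrs.append(hours[:-1])
        epids.append(np.repeat(ep, n))
        raw_g.append(glucose[:-1])
        nxt_g.append(glucose[1:])
        ep_returns.append(float(np.sum(r * gamma ** np.arange(n))))
        ep += 1
    if not states:
        raise ValueError("no usable episodes in table")
    return TransitionDataset(
        states=np.concatenate(states),
        actions=np.concatenate(actions),
        rewards=np.concatenate(rewards),
        next_states=np.concatenate(next_states),
        dones=np.concatenate(dones),
        patient_ids=np.concatenate(pids),
        hours=np.concatenate(hrs),
        episode_ids=np.concatenate(epids),
        episode_returns=np.asarray(ep_returns),
        feature_names=list(feature_names),
        norm_stats=norm_stats or {},
        raw_glucose=np.concatenate(raw_g),
        next_glucose=np.concatenate(nxt_g),
    )


# --------------------------------------------------------------------------
# 7. Splitting
# --------------------------------------------------------------------------


def split_patients(
    patient_ids: np.ndarray | pd.Series,
    train_frac: float = 0.85,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Patient-level train/test split, deterministic under seed."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    ids = np.unique(np.asarray(patient_ids))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    n_train = int(round(train_frac * len(ids)))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def subsample_patients(
    patient_ids: np.ndarray | pd.Series, frac: float = 0.80, seed: int = 0
) -> np.ndarray:
    """Draw floor(frac * n) patients without replacement, seeded."""
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    ids = np.unique(np.asarray(patient_ids))
    rng = np.random.default_rng(seed)
    n = int(np.floor(frac * len(ids)))
    return np.sort(rng.choice(ids, size=n, replace=False))


def select_patients(dataset: TransitionDataset, patient_ids: np.ndarray) -> TransitionDataset:
    """Restrict a TransitionDataset to a subset of patients (re-indexing episodes)."""
    mask = np.isin(dataset.patient_ids, patient_ids)
    epids = dataset.episode_ids[mask]
    kept_eps, new_epids = np.unique(epids, return_inverse=True)
    return TransitionDataset(
        states=dataset.states[mask],
        actions=dataset.actions[mask],
        rewards=dataset.rewards[mask],
        next_states=dataset.next_states[mask],
        dones=dataset.dones[mask],
        patient_ids=dataset.patient_ids[mask],
        hours=dataset.hours[mask],
        episode_ids=new_epids,
        episode_returns=dataset.episode_returns[kept_eps],
        feature_names=dataset.feature_names,
        norm_stats=dataset.norm_stats,
        raw_glucose=None if dataset.raw_glucose is None else dataset.raw_glucose[mask],
        next_glucose=None if dataset.next_glucose is None else dataset.next_glucose[mask],
    )


# --------------------------------------------------------------------------
# End-to-end convenience
# --------------------------------------------------------------------------


def preprocess_cohort(
    trajectories: pd.DataFrame,
    patients: pd.DataFrame,
    reward_params: RewardParams = DEFAULT_REWARD_PARAMS,
    gamma: float = 0.67,
    train_frac: float = 0.85,
    missing_threshold: float = 0.30,
    knn_k: int = 5,
    seed: int = 0,
) -> dict:
    """Run the full pipeline: exclusions through train/test TransitionDatasets.

    Returns a dict with ``train``/``test`` TransitionDatasets, the exclusion
    ``tally``, the fitted ``normalizer`` and ``missingness`` handler, the
    state ``feature_names`` and the patient id split.
    """
    traj, pts, tally = apply_exclusions(trajectories, patients)
    hourly = align_and_bin(traj)

    # broadcast static covariates into the hourly table
    statics = pts[["patient_id"] + STATIC_FEATURES]
    hourly = hourly.merge(statics, on="patient_id", how="left")

    train_ids, test_ids = split_patients(pts["patient_id"], train_frac=train_frac, seed=seed)
    is_train = hourly["patient_id"].isin(train_ids)
    dynamic_cols = [c for c in DYNAMIC_FEATURES if c in hourly.columns]
    handler = MissingnessHandler(
        threshold=missing_threshold, k=knn_k, feature_cols=dynamic_cols
    ).fit(hourly[is_train])
    train_tab = handler.transform(hourly[is_train])
    test_tab = handler.transform(hourly[~is_train])

    train_tab = engineer_glucose_features(train_tab)
    test_tab = engineer_glucose_features(test_tab)
    for tab in (train_tab, test_tab):
        tab["glucose_raw"] = tab["glucose"]
        tab["insulin"] = tab["insulin"].fillna(0.0)
        tab["hour_idx"] = tab["hour"]  # normalized copy; raw hour kept for ordering

    feature_cols = (
        ["glucose"]
        + ENGINEERED_FEATURES
        + [c for c in dynamic_cols if c not in handler.dropped_]
        + STATIC_FEATURES
        + ["hour_idx"]
    )
    norm = Normalizer(feature_cols).fit(train_tab)
    train_tab = norm.transform(train_tab)
    test_tab = norm.transform(test_tab)
    feature_names = norm.kept_features

    train_ds = build_transitions(
        train_tab, feature_names, reward_params, gamma, norm_stats=dict(norm.stats_)
    )
    test_ds = build_transitions(
        test_tab, feature_names, reward_params, gamma, norm_stats=dict(norm.stats_)
    )
    return {
        "train": train_ds,
        "test": test_ds,
        "tally": tally,
        "normalizer": norm,
        "missingness": handler,
        "feature_names": feature_names,
        "train_ids": train_ids,
        "test_ids": test_ids,
    }
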