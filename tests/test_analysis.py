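"""Policy-audit statistics: TIR, dose differences, agreement, importance."""

import numpy as np
import pandas as pd
import pytest

from glycorl.analysis import (
    PolicyComparison,
    agreement_rate,
    build_comparisons,
    cumulative_difference,
    disagreement_deciles,
    dose_by_glucose,
    mae_vs_reference,
    permutation_importance,
    time_in_range,
    tir_by_difference,
)


class TestTimeInRange:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([100, 150, 170], 1.0),
            ([65, 100, 200, 150], 0.5),
            ([70, 180], 1.0),  # closed interval: boundaries are in range
            ([69.9, 180.1], 0.0),
        ],
    )
    def test_examples(self, series, expected):
        assert time_in_range(series) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            time_in_range([])

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(50, 250, 100)
        assert time_in_range(g) == time_in_range(rng.permutation(g))


class TestCumulativeDifference:
    @pytest.mark.parametrize(
        "model, observed, expected",
        [([1, 1, 1], [1, 1, 1], 0.0), ([2, 3, 1], [1, 1, 1], 3.0), ([0, 0], [2, 3], -5.0)],
    )
    def test_examples(self, model, observed, expected):
        assert cumulative_difference(model, observed) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cumulative_difference([1], [1, 2])

    def test_exact_sum_no_reassociation(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0, 10, 24)
        o = rng.uniform(0, 10, 24)
        assert abs(cumulative_difference(m, o) - (np.sum(m) - np.sum(o))) < 1e-9


class TestTirByDifference:
    def _cmp(self, pid, model, observed, glucose):
        return PolicyComparison(pid, np.array(model, float), np.array(observed, float),
                                np.array(glucose, float))

    def test_all_zero_delta_single_bin(self):
        comps = [self._cmp(i, [1, 1], [1, 1], [150, 150]) for i in range(5)]
        table = tir_by_difference(comps, n_bootstrap=100)
        assert len(table) == 1 and table.n.iloc[0] == 5

    def test_hand_built_two_bins(self):
        comps = [
            self._cmp(0, [1, 1], [1, 1], [150, 160]),       # delta 0, TIR 1.0
            self._cmp(1, [5, 5], [2, 3], [250, 150]),        # delta +5, TIR 0.5
        ]
        table = tir_by_difference(comps, edges=(-3.0, 3.0), n_bootstrap=100)
        by_bin = dict(zip(table.bin, table.mean_tir))
        assert by_bin["[-3,3)"] == 1.0
        assert by_bin[">=3"] == 0.5

    def test_empty_bins_absent(self):
        comps = [self._cmp(0, [0], [0], [150])]
        table = tir_by_difference(comps, edges=(-10.0, 10.0), n_bootstrap=100)
        assert len(table) == 1


class TestDoseByGlucose:
    def test_constant_dose_everywhere(self):
        g = np.array([60, 90, 120, 160, 190, 220, 300], float)
        d = np.full_like(g, 2.0)
        table = dose_by_glucose(d, d, g, n_bootstrap=100)
        assert (table.mean_model_dose == 2.0).all()
        assert (table.mean_observed_dose == 2.0).all()
        assert len(table) == 7  # every default bin occupied once

    def test_hand_built_means(self):
        g = np.array([80, 85, 150, 150, 260, 260], float)
        model = np.array([0, 1, 2, 4, 8, 10], float)
        obs = np.array([1, 1, 3, 3, 6, 6], float)
        table = dose_by_glucose(model, obs, g, n_bootstrap=100).set_index("glucose_bin")
        assert table.loc["[70,100)", "mean_model_dose"] == 0.5
        assert table.loc["[140,180)", "mean_model_dose"] == 3.0
        assert table.loc[">=250", "mean_model_dose"] == 9.0
        assert table.loc[">=250", "mean_observed_dose"] == 6.0

    def test_self_comparison_identical_columns(self):
        rng = np.random.default_rng(2)
        g = rng.uniform(50, 300, 200)
        d = np.round(rng.uniform(0, 10, 200))
        table = dose_by_glucose(d, d, g, n_bootstrap=100)
        np.testing.assert_array_equal(table.mean_model_dose, table.mean_observed_dose)


class TestAgreement:
    def test_identical(self):
        assert agreement_rate([1, 2, 3], [1, 2, 3]) == 1.0

    def test_half(self):
        assert agreement_rate([1, 2, 3, 4], [1, 2, 0, 0]) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            agreement_rate([], [])

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(3)
        m = rng.integers(0, 10, 50)
        o = rng.integers(0, 10, 50)
        perm = rng.permutation(50)
        assert agreement_rate(m, o) == agreement_rate(m[perm], o[perm])


class TestDisagreementDeciles:
    def test_hand_built_membership(self):
        # 20 timesteps with |difference| = 0..19: bottom decile = {0,1},
        # top decile = {18,19}
        obs = np.zeros(20)
        model = np.arange(20.0)
        g = np.linspace(100, 290, 20)
        out = disagreement_deciles(model, obs, g)
        assert out.loc["bottom_decile", "mean_abs_difference"] == 0.5
        assert out.loc["top_decile", "mean_abs_difference"] == 18.5
        assert out.loc["top_decile", "mean_glucose"] == pytest.approx(g[-2:].mean())

    def test_constant_disagreement_symmetric(self):
        out = disagreement_deciles(np.full(30, 4.0), np.full(30, 1.0), np.full(30, 150.0))
        assert (
            out.loc["bottom_decile", "mean_abs_difference"]
            == out.loc["top_decile", "mean_abs_difference"]
            == 3.0
        )

    def test_feature_table_summaries(self):
        feats = pd.DataFrame({"sofa": np.arange(20.0)})
        out = disagreement_deciles(np.arange(20.0), np.zeros(20), np.full(20, 150.0), feats)
        assert out.loc["top_decile", "mean_sofa"] == 18.5

    def test_too_few_timesteps_rejected(self):
        with pytest.raises(ValueError):
            disagreement_deciles(np.ones(5), np.zeros(5), np.full(5, 150.0))

    def test_ordering_invariant(self):
        rng = np.random.default_rng(4)
        m, o = rng.uniform(0, 10, 40), rng.uniform(0, 10, 40)
        out = disagreement_deciles(m, o, np.full(40, 150.0))
        assert (
            out.loc["top_decile", "mean_abs_difference"]
            >= out.loc["bottom_decile", "mean_abs_difference"]
        )


class TestMAE:
    def test_identical_zero(self):
        mae, p = mae_vs_reference([1, 2, 3], [1, 2, 3])
        assert mae == 0.0 and p == 1.0

    def test_hand_computed(self):
        mae, _ = mae_vs_reference([2, 4], [1, 1])
        assert mae == 2.0

    def test_symmetry(self):
        a, b = [2.0, 4.0, 1.0], [1.0, 1.0, 5.0]
        assert mae_vs_reference(a, b)[0] == mae_vs_reference(b, a)[0]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae_vs_reference([1], [1, 2])


class _FakeArtifact:
    """Deterministic stand-in policy for importance tests."""

    def __init__(self, feature_names, fn):
        self.feature_names = feature_names
        self._fn = fn

    def continuous_action(self, states):
        return self._fn(np.atleast_2d(states))


class TestPermutationImportance:
    def test_constant_policy_scores_zero(self):
        art = _FakeArtifact(["a", "b"], lambda s: np.full(len(s), 3.0))
        rng = np.random.default_rng(0)
        out = permutation_importance(art, rng.random((50, 2)), seed=0)
        assert (out.importance == 0.0).all()

    def test_glucose_only_policy_ranks_glucose_first(self):
        names = ["glucose", "x1", "x2"]
        art = _FakeArtifact(names, lambda s: 10.0 * s[:, 0])
        rng = np.random.default_rng(1)
        out = permutation_importance(art, rng.random((100, 3)), seed=1)
        assert out.feature.iloc[0] == "glucose"
        assert out.importance.iloc[0] > out.importance.iloc[1:].max()

    def test_seeded_determinism(self, trained_artifact, prep):
        a = permutation_importance(trained_artifact, prep["test"].states[:100], seed=7)
        b = permutation_importance(trained_artifact, prep["test"].states[:100], seed=7)
        pd.testing.assert_frame_equal(a, b)


def test_build_comparisons_covers_every_episode(prep, trained_artifact):
    comps = build_comparisons(prep["test"], trained_artifact)
    assert len(comps) == prep["test"].n_episodes
    for c in comps[:5]:
        # glucose series has one more point than the dose series (final state)
        assert len(c.glucose) == len(c.model_doses) + 1
        assert 0.0 <= c.tir <= 1.0
        assert c.delta == pytest.approx(np.sum(c.model_doses - c.observed_doses))
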