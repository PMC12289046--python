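import numpy as np
import pandas as pd
import pytest
from scipy.special import stdtr

import varmatch as vm
from varmatch.analysis import (
    aggregate_importance,
    default_feature_groups,
    feature_ablation,
    paired_compare,
    permutation_importance,
    validate_feature_groups,
)
from varmatch.ensemble import downsample_negatives, make_trial_splits, tune_and_train
from varmatch.errors import ConfigurationError, ValidationError

TINY_GRID = [{"n_estimators": 60, "max_depth": 8}]


class TestPairedCompare:
    def test_identical_vectors_flagged_degenerate(self):
        rep = paired_compare([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert rep.mean_diff == 0.0
        assert rep.degenerate_variance
        assert np.isnan(rep.p_value)

    def test_constant_shift_zero_width_ci(self):
        a = np.array([0.5, 0.6, 0.7])
        rep = paired_compare(a + 0.1, a)
        assert rep.mean_diff == pytest.approx(0.1)
        assert rep.ci_low == rep.ci_high == pytest.approx(0.1)
        assert rep.degenerate_variance

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.8, 0.05, size=20)
        b = rng.normal(0.75, 0.05, size=20)
        rep = paired_compare(a, b)
        d = a - b
        n = len(d)
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        p = 2 * (1 - stdtr(n - 1, abs(t_stat)))
        assert rep.p_value == pytest.approx(p, abs=1e-12)
        assert rep.df == 19
        assert rep.ci_low < rep.mean_diff < rep.ci_high

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValidationError):
            paired_compare([0.1, 0.2], [0.1])


@pytest.fixture(scope="module")
def tiny_model(tiny_corpus, tiny_matrix):
    src, tgt, truth = tiny_corpus
    _, matrix = tiny_matrix
    matched = [s for s in src.variable_names if s in truth.targets_of]
    sp = make_trial_splits(matched, 1, 0.8, 0)[0]
    ts = downsample_negatives(sp, truth, tgt, k=10, seed=sp.seed,
                              features=matrix)
    model = tune_and_train(ts, TINY_GRID, "hr30", folds=3, seed=1)
    test = matrix[matrix["source_name"].isin(sp.test_sources)]
    return model, test, truth


class TestPermutationImportance:
    def test_constant_column_zero_decline(self, tiny_model):
        model, test, truth = tiny_model
        test = test.copy()
        test["Derive_info_null_src"] = 1.0  # constant across test pairs
        imp = permutation_importance(model, test, truth, n_repeats=2, seed=3)
        assert imp.loc["Derive_info_null_src"].abs().max() == 0.0

    def test_bit_reproducible(self, tiny_model):
        model, test, truth = tiny_model
        a = permutation_importance(model, test, truth, n_repeats=1, seed=9)
        b = permutation_importance(model, test, truth, n_repeats=1, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_feature_rejected(self, tiny_model):
        model, test, truth = tiny_model
        with pytest.raises(ValidationError):
            permutation_importance(model, test.drop(columns=["Fuzzy_on_label"]),
                                   truth, n_repeats=1, seed=0)


class TestAggregateImportance:
    def test_single_trial_identity(self):
        frame = pd.DataFrame({"hr10": [0.3, 0.1, 0.2]},
                             index=pd.Index(list("abc"), name="feature"))
        agg = aggregate_importance([frame])
        pd.testing.assert_frame_equal(agg["mean_importance"], frame)
        assert list(agg["mean_rank"]["hr10"]) == [1.0, 3.0, 2.0]

    def test_mean_and_average_rank(self):
        idx = pd.Index(["f", "g"], name="feature")
        t1 = pd.DataFrame({"mrr": [0.03, 0.06]}, index=idx)
        t2 = pd.DataFrame({"mrr": [0.05, 0.01]}, index=idx)
        agg = aggregate_importance([t1, t2])
        assert agg["mean_importance"].loc["f", "mrr"] == pytest.approx(0.04)
        # f ranked 2 then 1 -> average 1.5
        assert agg["mean_rank"].loc["f", "mrr"] == pytest.approx(1.5)

    def test_tied_declines_get_averaged_ranks(self):
        idx = pd.Index(["f", "g"], name="feature")
        agg = aggregate_importance(
            [pd.DataFrame({"mrr": [0.02, 0.02]}, index=idx)]
        )
        assert list(agg["mean_rank"]["mrr"]) == [1.5, 1.5]


class TestFeatureGroups:
    def test_default_partition_sizes(self):
        groups = default_feature_groups(vm.feature_names())
        assert len(groups["embedding"]) == 12
        assert len(groups["fuzzy"]) == 3
        assert len(groups["other"]) == 6

    def test_validator_rejects_non_partition(self):
        names = vm.feature_names()
        with pytest.raises(ConfigurationError):
            validate_feature_groups({"a": names[:5]}, names)
        with pytest.raises(ConfigurationError):
            validate_feature_groups({"a": names, "b": []}, names)
        with pytest.raises(ConfigurationError):
            validate_feature_groups({"a": names, "b": names[:1]}, names)


@pytest.fixture(scope="module")
def ablation_setup(tiny_corpus, tiny_matrix):
    src, tgt, truth = tiny_corpus
    _, matrix = tiny_matrix
    matrix = matrix.copy()
    rng = np.random.default_rng(17)
    # inject a pure-noise feature so one group is signal-free
    matrix.insert(2, "Noise_feature", rng.random(len(matrix)))
    config = vm.ExperimentConfig(
        n_trials=3, k_negatives=10, folds=3, master_seed=5,
        grid=vm.ExperimentConfig.pack_grid(TINY_GRID), baselines=False,
        control=False,
    )
    return src, tgt, truth, matrix, config


class TestFeatureAblation:
    def test_noise_group_decline_ci_contains_zero(self, ablation_setup):
        src, tgt, truth, matrix, config = ablation_setup
        cols = [c for c in matrix.columns
                if c not in ("source_name", "target_name", "label")]
        groups = {
            "noise": ["Noise_feature"],
            "signal": [c for c in cols if c != "Noise_feature"],
        }
        report = feature_ablation(src, tgt, truth, config, groups,
                                  full_matrix=matrix, metrics=("hr10", "mrr"))
        noise = report.comparisons["noise"]["hr10"]
        assert noise.ci_low <= 0.0 <= noise.ci_high or noise.mean_diff == 0.0
        # removing every informative feature leaves only noise: the model
        # collapses and the decline is large and positive
        signal = report.comparisons["signal"]["hr10"]
        assert signal.mean_diff > 0.3

    def test_group_removing_everything_rejected(self, ablation_setup):
        src, tgt, truth, matrix, config = ablation_setup
        cols = [c for c in matrix.columns
                if c not in ("source_name", "target_name", "label")]
        with pytest.raises(ConfigurationError):
            feature_ablation(src, tgt, truth, config, {"all": cols},
                             full_matrix=matrix, metrics=("hr10",))
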