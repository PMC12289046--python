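import numpy as np
import pandas as pd
import pytest

import varmatch as vm
from varmatch.dictionary import MatchTable, StudyDictionary, VariableRecord
from varmatch.ensemble import (
    TrialSplit,
    downsample_negatives,
    make_trial_splits,
    predict_and_rank,
    run_experiment,
    tune_and_train,
)
from varmatch.errors import ValidationError

from oracle_utils import reference_scale_standin

TINY_GRID = [{"n_estimators": 60, "max_depth": 8}]


class TestTrialSplits:
    def test_reference_scale_ratio(self):
        sources = [f"S{i}" for i in range(347)]
        sp = make_trial_splits(sources, 1, 0.8, 0)[0]
        assert len(sp.train_sources) == 277
        assert len(sp.test_sources) == 70

    def test_deterministic_and_partition(self):
        sources = [f"s{i}" for i in range(10)]
        a = make_trial_splits(sources, 3, 0.8, 42)
        b = make_trial_splits(sources, 3, 0.8, 42)
        assert a == b
        for sp in a:
            assert len(sp.train_sources) == 8 and len(sp.test_sources) == 2
            assert not set(sp.train_sources) & set(sp.test_sources)
            assert set(sp.train_sources) | set(sp.test_sources) == set(sources)
        # different trials differ
        assert len({sp.test_sources for sp in a}) > 1

    def test_too_few_sources(self):
        with pytest.raises(ValidationError):
            make_trial_splits(["a", "b"], 1)


def _mini_setup():
    tgt = StudyDictionary("T", [
        VariableRecord("T", "S", "d", f"t{i}", f"label {i}") for i in range(10)
    ])
    src = StudyDictionary("S", [
        VariableRecord("S", "S", "d", "a", "label a"),
    ])
    truth = MatchTable.from_pairs([("a", "t0")], src, tgt)
    split = TrialSplit(0, 1, ("a",), ())
    return tgt, truth, split


class TestDownsampleNegatives:
    def test_small_case_excludes_truth(self):
        tgt, truth, split = _mini_setup()
        ts = downsample_negatives(split, truth, tgt, k=5, seed=0)
        assert ts.n_positives == 1 and ts.n_negatives == 5
        negs = ts.table[ts.table["label"] == 0]
        assert len(negs) == 5
        assert "t0" not in set(negs["target_name"])
        assert negs["target_name"].is_unique

    def test_k_zero_positives_only(self):
        tgt, truth, split = _mini_setup()
        ts = downsample_negatives(split, truth, tgt, k=0, seed=0)
        assert len(ts.table) == 1
        assert ts.n_negatives == 0

    def test_pool_cap_warns(self):
        tgt, truth, split = _mini_setup()
        with pytest.warns(UserWarning, match="pool"):
            ts = downsample_negatives(split, truth, tgt, k=50, seed=0)
        assert ts.n_negatives == 9  # everything except the truth target
        assert ts.capped_sources == ["a"]

    def test_multi_match_source_samples_per_positive(self):
        tgt = StudyDictionary("T", [
            VariableRecord("T", "S", "d", f"t{i}", f"label {i}")
            for i in range(500)
        ])
        src = StudyDictionary("S", [VariableRecord("S", "S", "d", "a", "la")])
        truth = MatchTable.from_pairs([("a", "t0"), ("a", "t1")], src, tgt)
        ts = downsample_negatives(TrialSplit(0, 1, ("a",), ()), truth, tgt,
                                  k=100, seed=0)
        assert ts.n_positives == 2
        assert ts.n_negatives == 200  # m * k, deduplicated within the source
        negs = ts.table[ts.table["label"] == 0]["target_name"]
        assert negs.is_unique
        assert not {"t0", "t1"} & set(negs)


class TestTuneAndTrain:
    def test_single_grid_point(self, tiny_corpus, tiny_matrix):
        src, tgt, truth = tiny_corpus
        _, matrix = tiny_matrix
        matched = [s for s in src.variable_names if s in truth.targets_of]
        sp = make_trial_splits(matched, 1, 0.8, 0)[0]
        ts = downsample_negatives(sp, truth, tgt, k=10, seed=sp.seed,
                                  features=matrix)
        model = tune_and_train(ts, TINY_GRID, "hr30", folds=3, seed=1)
        assert len(model.cv_table) == 1
        assert model.params == TINY_GRID[0]

    def test_argmax_consistency_and_tie_break(self, tiny_corpus, tiny_matrix):
        src, tgt, truth = tiny_corpus
        _, matrix = tiny_matrix
        matched = [s for s in src.variable_names if s in truth.targets_of]
        sp = make_trial_splits(matched, 1, 0.8, 0)[0]
        ts = downsample_negatives(sp, truth, tgt, k=10, seed=sp.seed,
                                  features=matrix)
        grid = [{"n_estimators": 60, "max_depth": 8},
                {"n_estimators": 80, "max_depth": 8}]
        model = tune_and_train(ts, grid, "mrr", folds=3, seed=1)
        metrics = model.cv_table["mean_cv_metric"].to_numpy()
        chosen = grid[int(np.argmax(metrics))]
        assert model.params == chosen  # argmax, first on ties


class TestPredictAndRank:
    def test_identical_rows_full_tie(self, tiny_corpus, tiny_matrix):
        src, tgt, truth = tiny_corpus
        _, matrix = tiny_matrix
        matched = [s for s in src.variable_names if s in truth.targets_of]
        sp = make_trial_splits(matched, 1, 0.8, 0)[0]
        ts = downsample_negatives(sp, truth, tgt, k=10, seed=sp.seed,
                                  features=matrix)
        model = tune_and_train(ts, TINY_GRID, "hr30", folds=3, seed=1)
        test = matrix[matrix["source_name"] == matched[0]].copy()
        for c in model.feature_columns:
            test[c] = test[c].iloc[0]
        ranked = predict_and_rank(model, test)
        rl = ranked[matched[0]]
        n = len(rl)
        assert np.allclose(rl.ranks, (n + 1) / 2)

    def test_schema_mismatch_lists_columns(self, tiny_corpus, tiny_matrix):
        src, tgt, truth = tiny_corpus
        _, matrix = tiny_matrix
        matched = [s for s in src.variable_names if s in truth.targets_of]
        sp = make_trial_splits(matched, 1, 0.8, 0)[0]
        ts = downsample_negatives(sp, truth, tgt, k=10, seed=sp.seed,
                                  features=matrix)
        model = tune_and_train(ts, TINY_GRID, "hr30", folds=3, seed=1)
        bad = matrix.drop(columns=["Fuzzy_on_label"])
        with pytest.raises(ValidationError, match="Fuzzy_on_label"):
            predict_and_rank(model, bad)


@pytest.fixture(scope="module")
def tiny_result(tiny_corpus, tiny_matrix):
    src, tgt, truth = tiny_corpus
    _, matrix = tiny_matrix
    config = vm.ExperimentConfig(
        n_trials=2, k_negatives=10, folds=3, master_seed=5,
        grid=vm.ExperimentConfig.pack_grid(TINY_GRID),
    )
    return run_experiment(src, tgt, truth, config, full_matrix=matrix)


class TestRunExperiment:
    def test_two_trials_with_baselines(self, tiny_result):
        assert len(tiny_result.trials) == 2
        for tr in tiny_result.trials:
            assert "ensemble" in tr.eval
            sim = [m for m in tr.eval if "_on_" in m]
            assert len(sim) == 15
            assert tr.n_pos_test >= 1
            # full test matrix: every test source paired with all 40 targets
            n_test_sources = len({p for p in
                                  tr.probabilities["source_name"]})
            assert tr.n_pos_test + tr.n_neg_test == n_test_sources * 40

    def test_deterministic_rerun(self, tiny_corpus, tiny_matrix, tiny_result):
        src, tgt, truth = tiny_corpus
        _, matrix = tiny_matrix
        config = vm.ExperimentConfig(
            n_trials=2, k_negatives=10, folds=3, master_seed=5,
            grid=vm.ExperimentConfig.pack_grid(TINY_GRID),
        )
        again = run_experiment(src, tgt, truth, config, full_matrix=matrix)
        assert again.report_json() == tiny_result.report_json()

    def test_empty_truth_rejected(self, tiny_corpus):
        src, tgt, _ = tiny_corpus
        with pytest.raises(ValidationError, match="no matched sources"):
            run_experiment(src, tgt, MatchTable([]), vm.ExperimentConfig())


class TestReferenceScaleCounts:
    """Training/test-set construction arithmetic at reference scale."""

    def test_counts_from_standin(self):
        src, tgt, truth = reference_scale_standin()
        assert len(src) == 347 and len(tgt) == 1322
        assert len(truth) == 438
        assert truth.n_sources == 347
        assert truth.n_multi_match == 68
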