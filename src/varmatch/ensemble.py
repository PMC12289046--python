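"""Random-Forest ensemble protocol for variable matching.

One *trial* is: split the matched source variables 4:1 into train/test (the
split is by source variable, never by pair, so no pair of a test source can
leak into training); down-sample negatives in the training set (200 unmatched
targets per positive instance, drawn per source excluding all of that
source's true targets); tune hyperparameters by grouped 5-fold grid-search
cross-validation selecting on a ranking metric (HR-30 or MRR); refit on the
full training set; score every (test source x all targets) pair with the
positive-class probability and rank.  The test set keeps all negatives.

The experiment loop repeats this over independently seeded trials and also
evaluates every similarity feature as a single-channel baseline ranker, plus
a random-truth control whose expected HR-n is the analytic baseline
n / n_targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .dictionary import MatchTable, StudyDictionary
from .errors import ConfigurationError, ValidationError
from .features import DEFAULT_METHODS, PairFeaturizer
from .metrics import (
    DEFAULT_CUTOFFS,
    EvalResult,
    RankedList,
    evaluate,
    rank_by_column,
)

#: the full hyperparameter sweep: 3 x 3 x 2 x 2 x 2 = 72 grid points
FULL_GRID: list[dict] = [
    {
        "n_estimators": n,
        "max_depth": d,
        "criterion": c,
        "min_samples_split": s,
        "max_features": f,
    }
    for n in (100, 300, 500)
    for d in (None, 10, 20)
    for c in ("gini", "entropy")
    for s in (2, 10)
    for f in ("sqrt", 0.5)
]

#: default grid for routine experiments (use FULL_GRID for an exhaustive
#: sweep).  Forest size drives the granularity of the vote-based match
#: probabilities: ranking a few hundred candidates needs at least ~300 trees,
#: otherwise equal-probability tie blocks swallow the top of the list.
#: A depth cap keeps leaves impure, so match probabilities stay graded in
#: the weak-signal tail instead of collapsing into an all-zero tie block.
SMALL_GRID: list[dict] = [
    {"n_estimators": 300, "max_depth": 10},
    {"n_estimators": 500, "max_depth": 10},
]


@dataclass(frozen=True)
class TrialSplit:
    trial_id: int
    seed: int
    train_sources: tuple[str, ...]
    test_sources: tuple[str, ...]


@dataclass
class TrainingSet:
    """Down-sampled labeled training pairs, optionally with features."""

    table: pd.DataFrame
    feature_columns: list[str] | None
    n_positives: int
    n_negatives: int
    capped_sources: list[str] = field(default_factory=list)


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    params: dict
    selection_metric: str
    cv_table: pd.DataFrame
    feature_columns: list[str]


@dataclass
class TrialResult:
    trial_id: int
    seed: int
    best_params: dict
    n_pos_train: int
    n_neg_train: int
    n_pos_test: int
    n_neg_test: int
    eval: dict[str, EvalResult]
    probabilities: pd.DataFrame


def _derive_seed(master_seed: int, *stream: int) -> int:
    ss = np.random.SeedSequence([master_seed, *stream])
    return int(ss.generate_state(1)[0] % (2**31))


def make_trial_splits(
    sources: Sequence[str],
    n_trials: int = 50,
    train_fraction: float = 0.8,
    master_seed: int = 0,
) -> list[TrialSplit]:
    """Independent per-trial random splits of the matched sources.

    Training side takes floor(train_fraction * N) sources (277/70 at N=347
    and a 4:1 ratio); each trial's RNG is derived deterministically from the
    master seed and the trial id.
    """
    sources = list(sources)
    n = len(sources)
    if n < 5:
        raise ValidationError(f"need at least 5 sources to split, got {n}")
    n_train = int(train_fraction * n)
    if n_train == 0 or n_train == n:
        raise ValidationError(
            f"train fraction {train_fraction} infeasible for {n} sources"
        )
    splits = []
    for t in range(n_trials):
        rng = np.random.default_rng([master_seed, t])
        perm = rng.permutation(n)
        train = tuple(sorted(sources[i] for i in perm[:n_train]))
        test = tuple(sorted(sources[i] for i in perm[n_train:]))
        splits.append(
            TrialSplit(trial_id=t, seed=_derive_seed(master_seed, t),
                       train_sources=train, test_sources=test)
        )
    return splits


def downsample_negatives(
    split: TrialSplit,
    truth: MatchTable,
    target_dict: StudyDictionary,
    k: int = 200,
    seed: int = 0,
    features: pd.DataFrame | None = None,
) -> TrainingSet:
    """Build the down-sampled training set for one trial.

    A source with m positive instances contributes m*k distinct negative
    pairs, drawn uniformly without replacement from the targets not matched
    to that source (capped at the pool size with a warning).  With 351
    positives and k=200 this yields exactly 70,200 negatives.
    """
    rng = np.random.default_rng([seed, 1])
    tgt_names = np.asarray(target_dict.variable_names)
    rows: list[tuple[str, str, int]] = []
    capped: list[str] = []
    n_pos = n_neg = 0
    for src in split.train_sources:
        truth_targets = truth.targets_of.get(src, set())
        positives = [t for t in truth_targets if t in target_dict]
        for t in sorted(positives):
            rows.append((src, t, 1))
        n_pos += len(positives)
        pool = tgt_names[~np.isin(tgt_names, sorted(truth_targets))]
        need = len(positives) * k
        if need > len(pool):
            warnings.warn(
                f"negative pool for {src!r} smaller than {need}; taking all "
                f"{len(pool)}",
                stacklevel=2,
            )
            capped.append(src)
            need = len(pool)
        chosen = rng.choice(pool, size=need, replace=False) if need else []
        for t in chosen:
            rows.append((src, str(t), 0))
        n_neg += need
    table = pd.DataFrame(rows, columns=["source_name", "target_name", "label"])
    feature_columns = None
    if features is not None:
        feature_columns = [
            c for c in features.columns
            if c not in ("source_name", "target_name", "label")
        ]
        indexed = features.set_index(["source_name", "target_name"])
        table = pd.concat(
            [
                table.reset_index(drop=True),
                indexed.loc[
                    list(zip(table["source_name"], table["target_name"])),
                    feature_columns,
                ].reset_index(drop=True),
            ],
            axis=1,
        )
    return TrainingSet(table=table, feature_columns=feature_columns,
                       n_positives=n_pos, n_negatives=n_neg,
                       capped_sources=capped)


def _parse_metric(name: str) -> tuple[str, int | None]:
    key = name.lower().replace("-", "").replace("_", "")
    if key == "mrr":
        return "mrr", None
    if key.startswith("hr"):
        return "hr", int(key[2:])
    raise ConfigurationError(f"unknown selection metric {name!r}")


def _metric_value(table: pd.DataFrame, prob: np.ndarray, metric: str,
                  cutoff: int | None) -> float:
    """Ranking metric over a labeled pair table scored by `prob`."""
    scored = table[["source_name", "target_name", "label"]].copy()
    scored["prob"] = prob
    truth = MatchTable(
        scored.loc[scored["label"] == 1, ["source_name", "target_name"]]
        .itertuples(index=False, name=None)
    )
    ranked = rank_by_column(scored, "prob")
    ranked = {s: r for s, r in ranked.items() if s in truth.targets_of}
    ev = evaluate(ranked, truth, cutoffs=(cutoff,) if cutoff else (30,))
    return ev.mrr if metric == "mrr" else ev.hr[cutoff]


def _grouped_folds(sources: list[str], table: pd.DataFrame, folds: int,
                   seed: int) -> list[np.ndarray]:
    """Assign whole sources to folds; every fold must hold >=1 positive."""
    for attempt in range(10):
        rng = np.random.default_rng([seed, 2, attempt])
        perm = rng.permutation(len(sources))
        assignment = [
            [sources[i] for i in chunk]
            for chunk in np.array_split(perm, folds)
        ]
        masks = [
            table["source_name"].isin(group).to_numpy()
            for group in assignment
        ]
        if all((table.loc[m, "label"] == 1).any() for m in masks):
            return masks
    raise ValidationError(
        "could not build cross-validation folds with positives in each fold"
    )


def tune_and_train(
    train: TrainingSet,
    grid: Sequence[dict] = tuple(SMALL_GRID),
    selection_metric: str = "hr30",
    folds: int = 5,
    seed: int = 0,
) -> TrainedModel:
    """Grouped grid-search CV on the training set, then refit the best point.

    Folds group all pairs of a source together so within-fold rankings (over
    each source's down-sampled candidate set) are well defined.  The grid
    point with the highest mean validation metric wins; ties go to the first
    point in grid order.
    """
    grid = list(grid)
    if not grid:
        raise ConfigurationError("hyperparameter grid is empty")
    if train.feature_columns is None:
        raise ValidationError("training set has no feature columns attached")
    metric, cutoff = _parse_metric(selection_metric)
    table = train.table
    X = table[train.feature_columns].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    sources = list(dict.fromkeys(table["source_name"]))
    masks = _grouped_folds(sources, table, folds, seed)
    rs = _derive_seed(seed, 3)

    cv_rows = []
    for params in grid:
        fold_scores = []
        for mask in masks:
            forest = RandomForestClassifier(random_state=rs, n_jobs=1, **params)
            forest.fit(X[~mask], y[~mask])
            prob = forest.predict_proba(X[mask])[:, 1]
            fold_scores.append(
                _metric_value(table.loc[mask], prob, metric, cutoff)
            )
        cv_rows.append({**params, "mean_cv_metric": float(np.mean(fold_scores))})
    cv_table = pd.DataFrame(cv_rows)
    best_idx = int(np.argmax(cv_table["mean_cv_metric"].to_numpy()))
    best = grid[best_idx]

    forest = RandomForestClassifier(random_state=rs, n_jobs=1, **best)
    forest.fit(X, y)
    return TrainedModel(forest=forest, params=dict(best),
                        selection_metric=selection_metric,
                        cv_table=cv_table,
                        feature_columns=list(train.feature_columns))


def predict_and_rank(
    model: TrainedModel, test_table: pd.DataFrame
) -> dict[str, RankedList]:
    """Positive-class probability per pair, then per-source ranking."""
    missing = [c for c in model.feature_columns if c not in test_table.columns]
    if missing:
        raise ValidationError(f"test table missing feature column(s) {missing}")
    X = test_table[model.feature_columns].to_numpy(dtype=float)
    scored = test_table[["source_name", "target_name"]].copy()
    scored["prob"] = model.forest.predict_proba(X)[:, 1]
    return rank_by_column(scored, "prob")


@dataclass
class ExperimentConfig:
    """Configuration of the multi-trial matching experiment."""

    methods: tuple[str, ...] = DEFAULT_METHODS
    n_trials: int = 50
    train_fraction: float = 0.8
    k_negatives: int = 200
    folds: int = 5
    grid: tuple = tuple(
        tuple(sorted(g.items())) for g in SMALL_GRID
    )
    selection_metric: str = "hr30"
    cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS
    master_seed: int = 0
    baselines: bool = True
    control: bool = True

    def grid_dicts(self) -> list[dict]:
        return [dict(g) for g in self.grid]

    @staticmethod
    def pack_grid(grid: Sequence[dict]) -> tuple:
        return tuple(tuple(sorted(g.items())) for g in grid)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    trials: list[TrialResult]
    feature_columns: list[str]

    def metric_frame(self) -> pd.DataFrame:
        """Long frame: one row per (trial, model, metric)."""
        rows = []
        for tr in self.trials:
            for model_name, ev in tr.eval.items():
                for key, val in ev.as_dict().items():
                    rows.append(
                        {"trial_id": tr.trial_id, "model": model_name,
                         "metric": key, "value": val}
                    )
        return pd.DataFrame(rows)

    def mean_metrics(self) -> pd.DataFrame:
        """Per-model mean of each metric across trials (models x metrics)."""
        frame = self.metric_frame()
        return frame.pivot_table(index="model", columns="metric",
                                 values="value", aggfunc="mean")

    def trial_series(self, model: str, metric: str) -> np.ndarray:
        frame = self.metric_frame()
        sel = frame[(frame["model"] == model) & (frame["metric"] == metric)]
        return sel.sort_values("trial_id")["value"].to_numpy()

    def report_json(self) -> str:
        """Canonical JSON report (used for bit-reproducibility checks)."""
        import json

        payload = {
            "n_trials": len(self.trials),
            "feature_columns": self.feature_columns,
            "trials": [
                {
                    "trial_id": tr.trial_id,
                    "seed": tr.seed,
                    "best_params": {k: str(v) for k, v in tr.best_params.items()},
                    "counts": [tr.n_pos_train, tr.n_neg_train,
                               tr.n_pos_test, tr.n_neg_test],
                    "eval": {
                        m: {k: repr(v) for k, v in ev.as_dict().items()}
                        for m, ev in sorted(tr.eval.items())
                    },
                    "probabilities": [
                        repr(p) for p in tr.probabilities["prob"]
                    ],
                }
                for tr in self.trials
            ],
        }
        return json.dumps(payload, sort_keys=True)


def run_experiment(
    source_dict: StudyDictionary,
    target_dict: StudyDictionary,
    truth: MatchTable,
    config: ExperimentConfig | None = None,
    *,
    featurizer: PairFeaturizer | None = None,
    full_matrix: pd.DataFrame | None = None,
    drop_features: Sequence[str] = (),
) -> ExperimentResult:
    """Run the full multi-trial training/evaluation loop.

    The feature matrix over (matched source x every target) is computed once
    and shared across trials; ``drop_features`` removes columns before
    training (used by feature ablation).  Per trial the result holds the
    ensemble's metrics, every single-channel baseline's metrics and a
    random-truth control.
    """
    config = config or ExperimentConfig()
    matched = [s for s in source_dict.variable_names if s in truth.targets_of]
    if not matched:
        raise ValidationError("no matched sources in the ground truth")

    if full_matrix is None:
        if featurizer is None:
            featurizer = PairFeaturizer(source_dict, target_dict, config.methods)
        full_matrix = featurizer.matrix(matched, truth)
    all_features = [
        c for c in full_matrix.columns
        if c not in ("source_name", "target_name", "label")
    ]
    feature_columns = [c for c in all_features if c not in set(drop_features)]
    if not feature_columns:
        raise ConfigurationError("dropping these features leaves none")

    splits = make_trial_splits(matched, config.n_trials,
                               config.train_fraction, config.master_seed)
    grid = config.grid_dicts()
    trials = []
    for split in splits:
        assert not set(split.train_sources) & set(split.test_sources)
        train_set = downsample_negatives(
            split, truth, target_dict, k=config.k_negatives,
            seed=split.seed, features=full_matrix,
        )
        train_set.feature_columns = feature_columns
        model = tune_and_train(train_set, grid, config.selection_metric,
                               config.folds, seed=split.seed)
        test_mask = full_matrix["source_name"].isin(split.test_sources)
        test_table = full_matrix.loc[test_mask]
        ranked = predict_and_rank(model, test_table)
        evals: dict[str, EvalResult] = {
            "ensemble": evaluate(ranked, truth, config.cutoffs)
        }
        if config.baselines:
            for col in feature_columns:
                if "_on_" not in col:
                    continue
                evals[col] = evaluate(
                    rank_by_column(test_table, col), truth, config.cutoffs
                )
        if config.control:
            # label-permuted control: retrain the chosen forest on shuffled
            # training labels, so its ranking is independent of the truth and
            # HR-n has the analytic baseline n / n_targets
            rng = np.random.default_rng([config.master_seed, split.trial_id, 7])
            y_perm = rng.permutation(
                train_set.table["label"].to_numpy(dtype=int)
            )
            X_train = train_set.table[feature_columns].to_numpy(dtype=float)
            null_forest = RandomForestClassifier(
                random_state=_derive_seed(split.seed, 4), n_jobs=1,
                **model.params,
            )
            null_forest.fit(X_train, y_perm)
            null_model = TrainedModel(
                forest=null_forest, params=model.params,
                selection_metric=model.selection_metric,
                cv_table=model.cv_table, feature_columns=feature_columns,
            )
            evals["label_permuted_control"] = evaluate(
                predict_and_rank(null_model, test_table), truth, config.cutoffs
            )
            # random-ranking control: candidates ranked by iid uniform scores
            # and judged against one designated true target per source, so
            # E[HR-n] is exactly n / n_targets
            scored = test_table[["source_name", "target_name"]].copy()
            scored["prob"] = rng.random(len(scored))
            designated = MatchTable(
                (src, min(truth.targets_of[src])) for src in split.test_sources
            )
            evals["random_ranking_control"] = evaluate(
                rank_by_column(scored, "prob"), designated, config.cutoffs
            )
        probs = pd.DataFrame(
            [
                (r.source_name, t, p)
                for r in ranked.values()
                for t, p in zip(r.entries, r.scores)
            ],
            columns=["source_name", "target_name", "prob"],
        )
        n_pos_test = int(test_table["label"].sum())
        trials.append(
            TrialResult(
                trial_id=split.trial_id,
                seed=split.seed,
                best_params=model.params,
                n_pos_train=train_set.n_positives,
                n_neg_train=train_set.n_negatives,
                n_pos_test=n_pos_test,
                n_neg_test=int(len(test_table) - n_pos_test),
                eval=evals,
                probabilities=probs,
            )
        )
    return ExperimentResult(config=config, trials=trials,
                            feature_columns=feature_columns)
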