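"""Across-trial statistics: paired model comparison, permutation feature
importance, and feature-group ablation.

Model comparison uses two-sided paired t-tests over aligned per-trial metric
values with a t-based 95% confidence interval on the mean difference.
Permutation importance shuffles one feature column across the whole held-out
pair matrix, re-scores and re-ranks, and reports the decline of each ranking
metric relative to the unpermuted baseline (negative declines are possible
and meaningful).  Ablation reruns the full experiment with a feature group
removed, under identical splits and seeds, and compares trial-by-trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .dictionary import MatchTable, StudyDictionary
from .ensemble import (
    ExperimentConfig,
    ExperimentResult,
    TrainedModel,
    run_experiment,
)
from .errors import ConfigurationError, ValidationError
from .metrics import evaluate, rank_by_column

IMPORTANCE_METRICS = ("hr5", "hr10", "mrr")


@dataclass
class ComparisonReport:
    """Paired across-trial comparison of two models on one metric."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    n_trials: int
    degenerate_variance: bool

    @property
    def df(self) -> int:
        return self.n_trials - 1


def paired_compare(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> ComparisonReport:
    """Two-sided paired t-test of per-trial metric values (A minus B).

    When the paired differences have zero variance the t statistic is
    undefined; the report then carries p = NaN with ``degenerate_variance``
    set, and a zero-width confidence interval at the mean difference.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(
            f"score vectors must align by trial: {a.shape} vs {b.shape}"
        )
    if a.size < 2:
        raise ValidationError("need at least 2 trials for a paired test")
    diff = a - b
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    n = diff.size
    if sd_diff == 0.0:
        return ComparisonReport(
            mean_a=float(a.mean()), mean_b=float(b.mean()),
            sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
            mean_diff=mean_diff, ci_low=mean_diff, ci_high=mean_diff,
            p_value=float("nan"), n_trials=n, degenerate_variance=True,
        )
    t_res = stats.ttest_rel(a, b)
    half = stats.t.ppf(0.975, n - 1) * sd_diff / np.sqrt(n)
    return ComparisonReport(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        mean_diff=mean_diff,
        ci_low=mean_diff - float(half), ci_high=mean_diff + float(half),
        p_value=float(t_res.pvalue), n_trials=n, degenerate_variance=False,
    )


def permutation_importance(
    model: TrainedModel,
    test_table: pd.DataFrame,
    truth: MatchTable,
    metrics: Sequence[str] = IMPORTANCE_METRICS,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature performance declines on one trial's held-out pairs.

    For each feature column the values are shuffled globally across all test
    pairs (``n_repeats`` times), pairs are re-scored and re-ranked, and the
    decline is baseline minus the mean permuted metric.  Returns a frame
    indexed by feature with one column per metric.
    """
    unknown = [c for c in model.feature_columns if c not in test_table.columns]
    if unknown:
        raise ValidationError(f"test table missing feature column(s) {unknown}")

    def metric_values(table: pd.DataFrame) -> dict[str, float]:
        X = table[model.feature_columns].to_numpy(dtype=float)
        scored = table[["source_name", "target_name"]].copy()
        scored["prob"] = model.forest.predict_proba(X)[:, 1]
        cutoffs = sorted(
            {int(m[2:]) for m in metrics if m.startswith("hr")}
        ) or [30]
        ev = evaluate(rank_by_column(scored, "prob"), truth, cutoffs)
        vals = {f"hr{n}": v for n, v in ev.hr.items()}
        vals["mrr"] = ev.mrr
        return {m: vals[m] for m in metrics}

    baseline = metric_values(test_table)
    rows = {}
    for f_idx, feat in enumerate(model.feature_columns):
        declines = {m: [] for m in metrics}
        for rep in range(n_repeats):
            rng = np.random.default_rng([seed, f_idx, rep])
            permuted = test_table.copy()
            permuted[feat] = rng.permutation(permuted[feat].to_numpy())
            vals = metric_values(permuted)
            for m in metrics:
                declines[m].append(baseline[m] - vals[m])
        rows[feat] = {m: float(np.mean(declines[m])) for m in metrics}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "feature"
    return frame[list(metrics)]


def aggregate_importance(
    per_trial: Sequence[pd.DataFrame],
) -> dict[str, pd.DataFrame]:
    """Aggregate per-trial permutation-importance declines two ways.

    ``mean_importance``: mean decline per feature over trials.
    ``mean_rank``: features ranked within each trial (1 = largest decline,
    ties averaged), then ranks averaged over trials.
    """
    if not per_trial:
        raise ValidationError("need at least one trial of importance scores")
    metrics = list(per_trial[0].columns)
    stacked = pd.concat(per_trial, keys=range(len(per_trial)), names=["trial"])
    mean_importance = stacked.groupby(level="feature").mean().loc[
        per_trial[0].index, metrics
    ]
    rank_frames = []
    for frame in per_trial:
        ranks = pd.DataFrame(
            {m: rankdata(-frame[m].to_numpy(), method="average")
             for m in metrics},
            index=frame.index,
        )
        rank_frames.append(ranks)
    mean_rank = (
        pd.concat(rank_frames, keys=range(len(rank_frames)), names=["trial"])
        .groupby(level="feature")
        .mean()
        .loc[per_trial[0].index, metrics]
    )
    return {"mean_importance": mean_importance, "mean_rank": mean_rank}


def default_feature_groups(feature_columns: Sequence[str]) -> dict[str, list[str]]:
    """The three canonical groups: embedding-derived (12), fuzzy-derived (3)
    and other/metadata (6)."""
    groups = {
        "embedding": [
            c for c in feature_columns
            if "_on_" in c and not c.startswith("Fuzzy")
        ],
        "fuzzy": [c for c in feature_columns if c.startswith("Fuzzy_on_")],
        "other": [c for c in feature_columns if "_on_" not in c],
    }
    validate_feature_groups(groups, feature_columns)
    return groups


def validate_feature_groups(
    groups: Mapping[str, Sequence[str]], feature_columns: Sequence[str]
) -> None:
    """Groups must partition the feature set; no empties, no overlap."""
    seen: list[str] = []
    for name, cols in groups.items():
        if not cols:
            raise ConfigurationError(f"feature group {name!r} is empty")
        seen.extend(cols)
    if sorted(seen) != sorted(feature_columns):
        raise ConfigurationError(
            "feature groups must partition the feature set exactly"
        )


@dataclass
class AblationReport:
    """Per-group, per-metric paired comparison of full vs ablated models."""

    groups: dict[str, list[str]]
    comparisons: dict[str, dict[str, ComparisonReport]]  # group -> metric
    full_means: dict[str, float]

    def frame(self) -> pd.DataFrame:
        rows = []
        for group, by_metric in self.comparisons.items():
            for metric, rep in by_metric.items():
                rows.append(
                    {
                        "group": group,
                        "metric": metric,
                        "full_mean": rep.mean_a,
                        "decline": rep.mean_diff,
                        "ci_low": rep.ci_low,
                        "ci_high": rep.ci_high,
                        "p_value": rep.p_value,
                    }
                )
        return pd.DataFrame(rows)


def feature_ablation(
    source_dict: StudyDictionary,
    target_dict: StudyDictionary,
    truth: MatchTable,
    config: ExperimentConfig | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
    *,
    full_result: ExperimentResult | None = None,
    full_matrix: pd.DataFrame | None = None,
    metrics: Sequence[str] = ("hr5", "hr10", "hr20", "hr30", "mrr"),
) -> AblationReport:
    """Rerun the experiment with each feature group removed and compare.

    Splits, negative draws and forest seeds are identical to the full model's
    (they derive from the master seed only), so comparisons are paired trial
    by trial.
    """
    config = config or ExperimentConfig()
    if full_result is None:
        full_result = run_experiment(source_dict, target_dict, truth, config,
                                     full_matrix=full_matrix)
    feature_columns = full_result.feature_columns
    groups = dict(groups) if groups else default_feature_groups(feature_columns)
    validate_feature_groups(groups, feature_columns)

    comparisons: dict[str, dict[str, ComparisonReport]] = {}
    for name, cols in groups.items():
        if sorted(cols) == sorted(feature_columns):
            raise ConfigurationError(
                f"group {name!r} would remove every feature"
            )
        ablated = run_experiment(
            source_dict, target_dict, truth, config,
            full_matrix=full_matrix, drop_features=cols,
        )
        comparisons[name] = {
            m: paired_compare(
                full_result.trial_series("ensemble", m),
                ablated.trial_series("ensemble", m),
            )
            for m in metrics
        }
    full_means = {
        m: float(np.mean(full_result.trial_series("ensemble", m)))
        for m in metrics
    }
    return AblationReport(groups=groups, comparisons=comparisons,
                          full_means=full_means)
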