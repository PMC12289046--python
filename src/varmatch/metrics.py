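"""Per-source candidate ranking with median-resolved ties, HR-n and MRR.

For each source variable, every target-study variable is a candidate and is
ranked by descending score.  Candidates with exactly equal scores form a tie
block and all receive the median of the list positions the block occupies
(e.g., a three-way tie at positions 4-6 is ranked 5 for all three) — the
average-rank convention.  HR-n counts a source as a hit when the smallest
median-resolved rank among its true targets is <= n; MRR averages the
reciprocal of that smallest rank (which may be fractional under ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .dictionary import MatchTable
from .errors import ValidationError

DEFAULT_CUTOFFS = (5, 10, 15, 20, 30)


@dataclass
class RankedList:
    """Candidates of one source ordered by descending score, with
    median-resolved fractional ranks."""

    source_name: str
    entries: list[str]
    scores: np.ndarray
    ranks: np.ndarray

    def rank_of(self, target: str) -> float:
        return float(self.ranks[self.entries.index(target)])

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class EvalResult:
    """HR at each cutoff plus MRR over a set of evaluated sources."""

    hr: dict[int, float]
    mrr: float
    per_source_first_hit_rank: dict[str, float]
    v_all: int

    def v_hit(self, n: int) -> int:
        return sum(1 for r in self.per_source_first_hit_rank.values() if r <= n)

    def as_dict(self) -> dict[str, float]:
        out = {f"hr{n}": v for n, v in self.hr.items()}
        out["mrr"] = self.mrr
        return out


def rank_candidates(scores: Mapping[str, float]) -> RankedList:
    """Rank a source's candidates by descending score with median ties.

    The rank vector is a permutation-with-ties of positions 1..N: a tie block
    occupying positions p..p+k-1 receives rank (2p + k - 1) / 2 for every
    member, so ranks always sum to N(N+1)/2.
    """
    if not scores:
        raise ValidationError("cannot rank an empty candidate set")
    names = list(scores)
    vals = np.asarray([scores[n] for n in names], dtype=float)
    bad = [n for n, v in zip(names, vals) if math.isnan(v)]
    if bad:
        raise ValidationError(f"NaN score for candidate(s) {bad}")
    ranks = rankdata(-vals, method="average")
    order = np.argsort(-vals, kind="stable")
    return RankedList(
        source_name="",
        entries=[names[i] for i in order],
        scores=vals[order],
        ranks=ranks[order],
    )


def _first_hit_rank(ranked: RankedList, truth_targets: set[str]) -> float:
    present = [t for t in truth_targets if t in set(ranked.entries)]
    if not present:
        raise ValidationError(
            f"no truth target of {ranked.source_name!r} in the candidate set"
        )
    return min(ranked.rank_of(t) for t in present)


def _check_truth(results: Mapping[str, RankedList], truth: MatchTable) -> None:
    missing = [s for s in results if s not in truth.targets_of]
    if missing:
        raise ValidationError(
            f"source(s) without ground-truth targets: {missing}"
        )


def hit_ratio(
    results: Mapping[str, RankedList], truth: MatchTable, n: int
) -> float:
    """Fraction of sources whose best true target has rank <= n (strict)."""
    _check_truth(results, truth)
    hits = sum(
        1
        for src, ranked in results.items()
        if _first_hit_rank(ranked, truth.targets_of[src]) <= n
    )
    return hits / len(results)


def mean_reciprocal_rank(
    results: Mapping[str, RankedList], truth: MatchTable
) -> float:
    """Mean over sources of 1 / (smallest rank among true targets)."""
    _check_truth(results, truth)
    return float(
        np.mean(
            [
                1.0 / _first_hit_rank(ranked, truth.targets_of[src])
                for src, ranked in results.items()
            ]
        )
    )


def evaluate(
    results: Mapping[str, RankedList],
    truth: MatchTable,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
) -> EvalResult:
    """HR at every cutoff plus MRR, sharing one pass over the rankings."""
    _check_truth(results, truth)
    first_hit = {
        src: _first_hit_rank(ranked, truth.targets_of[src])
        for src, ranked in results.items()
    }
    v_all = len(first_hit)
    hr = {
        n: sum(1 for r in first_hit.values() if r <= n) / v_all
        for n in cutoffs
    }
    mrr = float(np.mean([1.0 / r for r in first_hit.values()]))
    return EvalResult(hr=hr, mrr=mrr, per_source_first_hit_rank=first_hit,
                      v_all=v_all)


def rank_by_column(
    table, score_column: str, *, cutoffs: Sequence[int] = DEFAULT_CUTOFFS
) -> dict[str, RankedList]:
    """Build per-source ranked lists from a pair table using one column as
    the ranking score (the single-channel baseline rankers)."""
    out: dict[str, RankedList] = {}
    for src, group in table.groupby("source_name", sort=False):
        ranked = rank_candidates(
            dict(zip(group["target_name"], group[score_column]))
        )
        ranked.source_name = src
        out[src] = ranked
    return out
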