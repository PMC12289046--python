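"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package: ranking uses an
explicit sort-and-assign-median-positions loop, and string similarity uses a
plain insert/delete grid dynamic program (the package computes the same
quantity through a longest-common-subsequence recurrence).
"""

from __future__ import annotations

from itertools import groupby


def median_rank_oracle(scores: dict[str, float]) -> dict[str, float]:
    """Sort candidates by descending score, then give every member of a tie
    block the median of the positions the block occupies."""
    items = sorted(scores.items(), key=lambda kv: -kv[1])
    ranks: dict[str, float] = {}
    pos = 1
    for _, group in groupby(items, key=lambda kv: kv[1]):
        block = list(group)
        k = len(block)
        positions = list(range(pos, pos + k))
        median = (positions[(k - 1) // 2] + positions[k // 2]) / 2
        for name, _ in block:
            ranks[name] = median
        pos += k
    return ranks


def indel_distance_oracle(a: str, b: str) -> int:
    """Edit distance with insertions and deletions only (no substitution)."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            best = min(prev[j] + 1, cur[j - 1] + 1)
            if a[i - 1] == b[j - 1]:
                best = min(best, prev[j - 1])
            cur[j] = best
        prev = cur
    return prev[m]


def token_set_ratio_oracle(a: str, b: str) -> float:
    """Token-set-ratio recomputed through the insert/delete grid DP."""
    set_a = sorted(set(a.split()))
    set_b = sorted(set(b.split()))
    if not set_a or not set_b:
        return 0.0  # empty-side convention
    inter = sorted(set(set_a) & set(set_b))
    diff_a = sorted(set(set_a) - set(inter))
    diff_b = sorted(set(set_b) - set(inter))
    s0 = " ".join(inter)
    s1 = " ".join(inter + diff_a)
    s2 = " ".join(inter + diff_b)

    def sim(x: str, y: str) -> float:
        total = len(x) + len(y)
        if total == 0:
            return 1.0
        return 1.0 - indel_distance_oracle(x, y) / total

    return 100.0 * max(sim(s0, s1), sim(s0, s2), sim(s1, s2))


def reference_scale_standin():
    """Dictionaries and ground truth at reference scale: 347 source
    variables, 1322 target variables, 438 truth pairs over 347 unique
    sources of which exactly 68 have multiple true targets.

    Synthetic stand-in (the real dictionaries are access-restricted): names
    and labels are generic; only the combinatorial structure matters.
    """
    from varmatch.dictionary import MatchTable, StudyDictionary, VariableRecord

    def record(study, name, label):
        return VariableRecord(study_id=study, sheet_name="S1",
                              sheet_description="Stand-in sheet",
                              variable_name=name, variable_label=label)

    n_src, n_tgt = 347, 1322
    src = StudyDictionary("EU-like", [
        record("EU-like", f"S{i:03d}", f"source variable {i}")
        for i in range(n_src)
    ])
    tgt = StudyDictionary("JP-like", [
        record("JP-like", f"T{i:04d}", f"target variable {i}")
        for i in range(n_tgt)
    ])
    # 91 extra pairs spread over 68 multi-match sources: 68 get one extra
    # target, 23 of those get a second extra -> 347 + 68 + 23 = 438 pairs
    pairs = [(f"S{i:03d}", f"T{i:04d}") for i in range(n_src)]
    for j in range(68):
        pairs.append((f"S{j:03d}", f"T{400 + j:04d}"))
    for j in range(23):
        pairs.append((f"S{j:03d}", f"T{500 + j:04d}"))
    truth = MatchTable.from_pairs(pairs, src, tgt)
    return src, tgt, truth
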