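"""Text channels used by every similarity method.

Each variable contributes three text channels:

* ``label_text`` — the variable label;
* ``sheet_text`` — the description of the data sheet containing it;
* ``label_key_text`` — the label concatenated with the derivation rule, or
  with keywords extracted from it when the rule is long (> 20 words).

Keyword extraction scores candidate n-grams by cosine similarity of their
embedding to the embedding of the full rule and keeps the best ones greedily,
up to a word budget — the mechanism popularized by embedding-based keyphrase
extractors.  Long rules are thereby condensed into a phrase of comparable
length to a label, keeping the concatenated channel balanced.

Fuzzy matching works on a separately normalized form of the text (lowercase,
punctuation and stop words removed, Porter-stemmed); the embedding channels
always receive the raw text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._porter import porter_stem
from ._stopwords import STOP_WORDS
from .dictionary import VariableRecord

#: rules longer than this many words are condensed to keywords
KEYWORD_WORD_THRESHOLD = 20
#: maximum number of words returned by keyword extraction
DEFAULT_MAX_KEYWORDS = 15

_PUNCT_RE = re.compile(r"[^a-z0-9\s]+")


@dataclass(frozen=True)
class TextBundle:
    """The three text channels plus the metadata counts for one variable."""

    label_text: str
    sheet_text: str
    label_key_text: str
    label_word_count: int
    rule_word_count: int
    rule_absent: bool


def extract_keywords(
    rule: str,
    embedder,
    max_keywords: int = DEFAULT_MAX_KEYWORDS,
    *,
    word_threshold: int = KEYWORD_WORD_THRESHOLD,
    ngram_range: tuple[int, int] = (1, 2),
) -> str:
    """Condense a long derivation rule into at most ``max_keywords`` words.

    Rules of ``word_threshold`` or fewer words are returned verbatim.  For
    longer rules, candidate n-grams (``ngram_range``, order of first
    occurrence) are embedded and ranked by cosine similarity to the full-rule
    embedding; phrases are selected greedily in descending score, words that
    were already selected are dropped, and selection stops once the word
    budget is filled.  Output words appear in selection order and always occur
    in the input rule.
    """
    words = rule.split()
    if len(words) <= word_threshold:
        return rule

    lo, hi = ngram_range
    candidates: list[str] = []
    seen_cand: set[str] = set()
    for n in range(lo, hi + 1):
        for i in range(len(words) - n + 1):
            phrase = " ".join(words[i : i + n])
            key = phrase.lower()
            if key not in seen_cand:
                seen_cand.add(key)
                candidates.append(phrase)

    vectors = embedder.embed([rule] + candidates)
    ref = np.asarray(vectors[0].values, dtype=float)
    ref_norm = np.linalg.norm(ref)
    scores = []
    for vec in vectors[1:]:
        v = np.asarray(vec.values, dtype=float)
        denom = ref_norm * np.linalg.norm(v)
        scores.append(float(ref @ v / denom) if denom > 0 else 0.0)

    order = sorted(range(len(candidates)), key=lambda i: (-scores[i], i))
    selected: list[str] = []
    seen_words: set[str] = set()
    for i in order:
        new = [w for w in candidates[i].split() if w.lower() not in seen_words]
        if not new or len(selected) + len(new) > max_keywords:
            continue
        selected.extend(new)
        seen_words.update(w.lower() for w in new)
        if len(selected) == max_keywords:
            break
    return " ".join(selected)


def build_text_bundle(
    record: VariableRecord,
    embedder,
    *,
    max_keywords: int = DEFAULT_MAX_KEYWORDS,
) -> TextBundle:
    """Assemble the three text channels for one variable record."""
    label = record.variable_label
    rule = record.derivation_rule
    if rule:
        label_key = label + " " + extract_keywords(rule, embedder, max_keywords)
    else:
        label_key = label
    return TextBundle(
        label_text=label,
        sheet_text=record.sheet_description,
        label_key_text=label_key,
        label_word_count=len(label.split()),
        rule_word_count=len(rule.split()),
        rule_absent=rule == "",
    )


def _normalize_once(text: str) -> str:
    lowered = _PUNCT_RE.sub(" ", text.lower())
    tokens = [porter_stem(t) for t in lowered.split() if t not in STOP_WORDS]
    return " ".join(tokens)


@lru_cache(maxsize=65536)
def normalize_for_fuzzy(text: str) -> str:
    """Normalize text for fuzzy matching: lowercase, strip punctuation,
    drop English stop words, Porter-stem, re-join with single spaces.

    The pass is applied to a fixed point (Porter stemming alone is not
    idempotent, e.g. "employment" -> "employ" -> "emploi", and a stem can
    land on a stop word), so normalization as a whole is idempotent: both
    comparison sides always see fully reduced tokens.  All-stop-word input
    yields the empty string (fuzzy score 0 downstream).
    """
    prev, cur = None, text
    while cur != prev:
        prev, cur = cur, _normalize_once(cur)
    return cur
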