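"""Assemble the 21 machine-learning features for source-target variable pairs.

Each pair carries 15 similarity features (5 methods x 3 text channels) and 6
metadata features (label length, derivation-rule length and rule absence for
each side), plus a binary label: 1 when the pair is in the ground-truth match
table.  Feature order is fixed and named; booleans are encoded 0/1; tree
ensembles consume the features unscaled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dictionary import MatchTable, StudyDictionary
from .errors import ValidationError
from .similarity import (
    CHANNELS,
    FUZZY_METHOD,
    ChannelScores,
    SimilarityScorer,
    get_backend,
    token_set_ratio,
)
from .textprep import TextBundle, build_text_bundle, normalize_for_fuzzy

#: method ids used when no explicit configuration is given: four embedding
#: backends plus fuzzy matching, mirroring the five-method design
DEFAULT_METHODS = (
    "offline-hash",
    "offline-hash-b",
    "offline-hash-c",
    "offline-hash-d",
    FUZZY_METHOD,
)

#: feature-name prefix per method id (pretrained ids keep their field names)
METHOD_PREFIX = {
    "e5-large-v2": "E5",
    "all-mpnet-base-v2": "MPNet",
    "all-MiniLM-L12-v2": "MiniLM",
    "BioLORD-2023": "BioLORD",
    FUZZY_METHOD: "Fuzzy",
    "offline-hash": "HashA",
    "offline-hash-b": "HashB",
    "offline-hash-c": "HashC",
    "offline-hash-d": "HashD",
}

META_FEATURES = (
    "Label_len_src",
    "Label_len_tgt",
    "Derive_info_len_src",
    "Derive_info_len_tgt",
    "Derive_info_null_src",
    "Derive_info_null_tgt",
)


def method_prefix(method_id: str) -> str:
    return METHOD_PREFIX.get(method_id, method_id.replace("-", "_"))


def similarity_feature_names(methods: Sequence[str] = DEFAULT_METHODS) -> list[str]:
    return [
        f"{method_prefix(m)}_on_{ch}" for m in methods for ch in CHANNELS
    ]


def feature_names(methods: Sequence[str] = DEFAULT_METHODS) -> list[str]:
    """Canonical ordered names of all 21 features."""
    return similarity_feature_names(methods) + list(META_FEATURES)


@dataclass(frozen=True)
class PairFeatureVector:
    """Named feature values for one source-target pair."""

    source_name: str
    target_name: str
    features: dict[str, float]
    label: int
    labeled: bool  # False in prediction mode (no ground truth supplied)

    @property
    def n_similarity(self) -> int:
        return sum(1 for n in self.features if "_on_" in n)

    @property
    def n_metadata(self) -> int:
        return sum(1 for n in self.features if "_on_" not in n)


def build_features(
    src_bundle: TextBundle,
    tgt_bundle: TextBundle,
    scores: Sequence[ChannelScores],
    truth: MatchTable | None = None,
    *,
    source_name: str,
    target_name: str,
    methods: Sequence[str] = DEFAULT_METHODS,
) -> PairFeatureVector:
    """Assemble one pair's feature vector from precomputed channel scores."""
    by_method = {s.method_id: s for s in scores}
    missing = [m for m in methods if m not in by_method]
    if missing:
        raise ValidationError(f"missing similarity scores for method(s) {missing}")
    feats: dict[str, float] = {}
    for m in methods:
        channel_vals = by_method[m].as_dict()
        for ch in CHANNELS:
            feats[f"{method_prefix(m)}_on_{ch}"] = float(channel_vals[ch])
    feats["Label_len_src"] = float(src_bundle.label_word_count)
    feats["Label_len_tgt"] = float(tgt_bundle.label_word_count)
    feats["Derive_info_len_src"] = float(src_bundle.rule_word_count)
    feats["Derive_info_len_tgt"] = float(tgt_bundle.rule_word_count)
    feats["Derive_info_null_src"] = float(src_bundle.rule_absent)
    feats["Derive_info_null_tgt"] = float(tgt_bundle.rule_absent)
    label = int((source_name, target_name) in truth) if truth is not None else 0
    return PairFeatureVector(
        source_name=source_name,
        target_name=target_name,
        features=feats,
        label=label,
        labeled=truth is not None,
    )


def enumerate_pairs(
    source_dict: StudyDictionary,
    target_dict: StudyDictionary,
    sources: Sequence[str] | None = None,
    truth: MatchTable | None = None,
) -> pd.DataFrame:
    """All (source, target) pairs for the listed sources, with labels but no
    features: one row per target-dictionary variable per source."""
    if sources is None:
        sources = source_dict.variable_names
    unknown = [s for s in sources if s not in source_dict]
    if unknown:
        raise ValidationError(f"unknown source variable(s) {unknown}")
    tgt_names = target_dict.variable_names
    n_tgt = len(tgt_names)
    frame = pd.DataFrame(
        {
            "source_name": np.repeat(list(sources), n_tgt),
            "target_name": np.tile(tgt_names, len(sources)),
        }
    )
    if truth is not None:
        frame["label"] = [
            int((s, t) in truth)
            for s, t in zip(frame["source_name"], frame["target_name"])
        ]
    else:
        frame["label"] = 0
    return frame


class PairFeaturizer:
    """Compute the full feature matrix for a dictionary pair efficiently.

    Text bundles are built once per variable; embedding channels are scored
    as matrix products over unique channel texts; fuzzy channels go through a
    memoized token-set-ratio.  Keyword extraction uses the first embedding
    method's backend unless ``keyword_backend`` overrides it.
    """

    def __init__(
        self,
        source_dict: StudyDictionary,
        target_dict: StudyDictionary,
        methods: Sequence[str] = DEFAULT_METHODS,
        *,
        keyword_backend: str | None = None,
    ):
        self.source_dict = source_dict
        self.target_dict = target_dict
        self.methods = list(methods)
        emb_methods = [m for m in self.methods if m != FUZZY_METHOD]
        kw_id = keyword_backend or (emb_methods[0] if emb_methods else "offline-hash")
        self._kw_embedder = get_backend(kw_id)
        self.scorer = SimilarityScorer(self.methods)

        self.src_bundles = {
            r.variable_name: build_text_bundle(r, self._kw_embedder)
            for r in source_dict
        }
        self.tgt_bundles = {
            r.variable_name: build_text_bundle(r, self._kw_embedder)
            for r in target_dict
        }
        self._channel_cache: dict[str, np.ndarray] = {}

    # -- vectorized channel scoring -------------------------------------

    def _texts(self, bundles: dict[str, TextBundle], channel: str) -> list[str]:
        attr = {"label": "label_text", "sheet": "sheet_text",
                "label_key": "label_key_text"}[channel]
        return [getattr(b, attr) for b in bundles.values()]

    def _embedding_score_matrix(self, method: str, channel: str) -> np.ndarray:
        key = f"{method}:{channel}"
        if key not in self._channel_cache:
            backend = self.scorer.backends[method]
            src = np.stack([v.values for v in
                            backend.embed(self._texts(self.src_bundles, channel))])
            tgt = np.stack([v.values for v in
                            backend.embed(self._texts(self.tgt_bundles, channel))])
            sn = np.linalg.norm(src, axis=1, keepdims=True)
            tn = np.linalg.norm(tgt, axis=1, keepdims=True)
            np.divide(src, sn, out=src, where=sn > 0)
            np.divide(tgt, tn, out=tgt, where=tn > 0)
            self._channel_cache[key] = src @ tgt.T
        return self._channel_cache[key]

    def _fuzzy_score_matrix(self, channel: str) -> np.ndarray:
        key = f"{FUZZY_METHOD}:{channel}"
        if key not in self._channel_cache:
            src_norm = [normalize_for_fuzzy(t)
                        for t in self._texts(self.src_bundles, channel)]
            tgt_norm = [normalize_for_fuzzy(t)
                        for t in self._texts(self.tgt_bundles, channel)]
            mat = np.empty((len(src_norm), len(tgt_norm)))
            for i, a in enumerate(src_norm):
                for j, b in enumerate(tgt_norm):
                    mat[i, j] = token_set_ratio(a, b)
            self._channel_cache[key] = mat
        return self._channel_cache[key]

    def score_matrix(self, method: str, channel: str) -> np.ndarray:
        """(n_source, n_target) similarity matrix for one method/channel."""
        if method == FUZZY_METHOD:
            return self._fuzzy_score_matrix(channel)
        return self._embedding_score_matrix(method, channel)

    # -- public matrix construction -------------------------------------

    def matrix(
        self,
        sources: Sequence[str] | None = None,
        truth: MatchTable | None = None,
    ) -> pd.DataFrame:
        """Feature table: one row per (listed source) x (every target)."""
        frame = enumerate_pairs(self.source_dict, self.target_dict, sources, truth)
        src_pos = {n: i for i, n in enumerate(self.src_bundles)}
        tgt_pos = {n: i for i, n in enumerate(self.tgt_bundles)}
        rows = frame["source_name"].map(src_pos).to_numpy()
        cols = frame["target_name"].map(tgt_pos).to_numpy()
        for m in self.methods:
            for ch in CHANNELS:
                frame[f"{method_prefix(m)}_on_{ch}"] = (
                    self.score_matrix(m, ch)[rows, cols]
                )
        src_meta = {
            n: (b.label_word_count, b.rule_word_count, float(b.rule_absent))
            for n, b in self.src_bundles.items()
        }
        tgt_meta = {
            n: (b.label_word_count, b.rule_word_count, float(b.rule_absent))
            for n, b in self.tgt_bundles.items()
        }
        sm = np.array([src_meta[s] for s in frame["source_name"]],
                      dtype=float).reshape(len(frame), 3)
        tm = np.array([tgt_meta[t] for t in frame["target_name"]],
                      dtype=float).reshape(len(frame), 3)
        frame["Label_len_src"] = sm[:, 0]
        frame["Label_len_tgt"] = tm[:, 0]
        frame["Derive_info_len_src"] = sm[:, 1]
        frame["Derive_info_len_tgt"] = tm[:, 1]
        frame["Derive_info_null_src"] = sm[:, 2]
        frame["Derive_info_null_tgt"] = tm[:, 2]
        names = feature_names(self.methods)
        return frame[["source_name", "target_name", *names, "label"]]

    @property
    def feature_columns(self) -> list[str]:
        return feature_names(self.methods)


def build_pair_matrix(
    source_dict: StudyDictionary,
    target_dict: StudyDictionary,
    sources: Sequence[str] | None = None,
    truth: MatchTable | None = None,
    methods: Sequence[str] = DEFAULT_METHODS,
) -> pd.DataFrame:
    """Convenience wrapper: featurize all pairs for the listed sources."""
    return PairFeaturizer(source_dict, target_dict, methods).matrix(sources, truth)
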