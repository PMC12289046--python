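"""Similarity scorers: pluggable sentence-embedding backends scored by cosine
similarity, plus token-set-ratio fuzzy matching.

Embedding backends are looked up in a registry by id.  The pretrained
sentence-transformer models (E5, MPNet, MiniLM, BioLORD-2023) are registered
lazily and require the optional ``embeddings`` extra; the ``offline-hash``
family is a seeded character-n-gram hashing embedder (fixed dimension,
L2-normalized) that runs with no model download and is fully deterministic
across platforms, so the complete pipeline is testable offline.  Four
registered hash variants differ in n-gram sizes and hashing salt, giving the
ensemble genuinely diverse lexical views.

``token_set_ratio`` reproduces the classic fuzzy-matching scorer: tokenize,
deduplicate, sort, then take the maximum normalized indel similarity over the
intersection/difference string constructions.  The indel distance is computed
as ``len(a) + len(b) - 2*LCS(a, b)`` with a vectorized longest-common-
subsequence row recurrence.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError
from .textprep import TextBundle, normalize_for_fuzzy

FUZZY_METHOD = "fuzzy"
CHANNELS = ("label", "sheet", "label_key")


@dataclass(frozen=True)
class EmbeddingVector:
    values: np.ndarray
    backend_id: str

    @property
    def dim(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class ChannelScores:
    """The three per-channel similarity scores of one method for one pair."""

    method_id: str
    on_label: float
    on_sheet: float
    on_label_key: float

    def as_dict(self) -> dict[str, float]:
        return {
            "label": self.on_label,
            "sheet": self.on_sheet,
            "label_key": self.on_label_key,
        }


class HashingEmbedder:
    """Seeded character-n-gram hashing embedder.

    Each text is mapped to a fixed-dimension vector by hashing its character
    n-grams (and word unigrams) into signed buckets, then L2-normalizing.
    Deterministic across platforms (hashing via blake2b, never Python's
    randomized ``hash``).  Empty text maps to the zero vector with a warning.
    """

    def __init__(self, backend_id: str = "offline-hash", *, dim: int = 256,
                 ngram_sizes: Sequence[int] = (3,), use_words: bool = True,
                 salt: int = 0):
        self.backend_id = backend_id
        self.dim = dim
        self.ngram_sizes = tuple(ngram_sizes)
        self.use_words = use_words
        self._salt = str(salt).encode()
        self.n_calls = 0  # number of embed() invocations, for cache tests

    def _features(self, text: str) -> list[str]:
        text = text.lower()
        feats: list[str] = []
        padded = f" {text} "
        for n in self.ngram_sizes:
            feats.extend(padded[i : i + n] for i in range(len(padded) - n + 1))
        if self.use_words:
            feats.extend(f"w:{w}" for w in text.split())
        return feats

    def embed(self, texts: Sequence[str]) -> list[EmbeddingVector]:
        self.n_calls += 1
        out = []
        for text in texts:
            vec = np.zeros(self.dim)
            if text.strip() == "":
                warnings.warn(
                    f"{self.backend_id}: empty text embedded as zero vector",
                    stacklevel=2,
                )
            else:
                for feat in self._features(text):
                    digest = hashlib.blake2b(
                        feat.encode("utf-8", "replace"), salt=self._salt[:16],
                        digest_size=8,
                    ).digest()
                    idx = int.from_bytes(digest[:4], "little") % self.dim
                    sign = 1.0 if digest[4] & 1 else -1.0
                    vec[idx] += sign
                norm = np.linalg.norm(vec)
                if norm > 0:
                    vec /= norm
            out.append(EmbeddingVector(values=vec, backend_id=self.backend_id))
        return out


class SentenceTransformerBackend:
    """Adapter around a pretrained sentence-transformers model.

    Only constructed on first use; raises :class:`ConfigurationError` when the
    optional dependency is missing.  For E5-family models both sides are
    embedded with the ``"query: "`` prefix (symmetric semantic-textual-
    similarity usage).
    """

    def __init__(self, backend_id: str, model_name: str, *, prefix: str = ""):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ConfigurationError(
                f"backend {backend_id!r} needs the optional "
                f"'embeddings' extra (sentence-transformers)"
            ) from exc
        self.backend_id = backend_id
        self._prefix = prefix
        self._model = SentenceTransformer(model_name)
        self.n_calls = 0

    def embed(self, texts: Sequence[str]) -> list[EmbeddingVector]:  # pragma: no cover
        self.n_calls += 1
        arr = self._model.encode([self._prefix + t for t in texts])
        return [EmbeddingVector(values=np.asarray(v, dtype=float),
                                backend_id=self.backend_id) for v in arr]


class CachedEmbedder:
    """Wrap a backend so each distinct string is embedded exactly once."""

    def __init__(self, backend):
        self.backend = backend
        self.backend_id = backend.backend_id
        self._cache: dict[str, EmbeddingVector] = {}

    def embed(self, texts: Sequence[str]) -> list[EmbeddingVector]:
        todo = [t for t in dict.fromkeys(texts) if t not in self._cache]
        if todo:
            for text, vec in zip(todo, self.backend.embed(todo)):
                self._cache[text] = vec
        return [self._cache[t] for t in texts]


_REGISTRY: dict[str, Callable[[], object]] = {}


def register_backend(backend_id: str, factory: Callable[[], object]) -> None:
    _REGISTRY[backend_id] = factory


def registered_backends() -> list[str]:
    return sorted(_REGISTRY)


def get_backend(backend_id: str, *, cached: bool = True):
    """Instantiate a registered backend (wrapped in an embedding cache)."""
    try:
        factory = _REGISTRY[backend_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown embedding backend {backend_id!r}; "
            f"registered: {registered_backends()}"
        ) from None
    backend = factory()
    return CachedEmbedder(backend) if cached else backend


register_backend("offline-hash", lambda: HashingEmbedder(
    "offline-hash", dim=256, ngram_sizes=(3,), use_words=True, salt=11))
register_backend("offline-hash-b", lambda: HashingEmbedder(
    "offline-hash-b", dim=384, ngram_sizes=(2, 3), use_words=True, salt=23))
register_backend("offline-hash-c", lambda: HashingEmbedder(
    "offline-hash-c", dim=256, ngram_sizes=(4,), use_words=True, salt=37))
register_backend("offline-hash-d", lambda: HashingEmbedder(
    "offline-hash-d", dim=192, ngram_sizes=(3, 5), use_words=False, salt=53))
register_backend("e5-large-v2", lambda: SentenceTransformerBackend(
    "e5-large-v2", "intfloat/e5-large-v2", prefix="query: "))
register_backend("all-mpnet-base-v2", lambda: SentenceTransformerBackend(
    "all-mpnet-base-v2", "sentence-transformers/all-mpnet-base-v2"))
register_backend("all-MiniLM-L12-v2", lambda: SentenceTransformerBackend(
    "all-MiniLM-L12-v2", "sentence-transformers/all-MiniLM-L12-v2"))
register_backend("BioLORD-2023", lambda: SentenceTransformerBackend(
    "BioLORD-2023", "FremyCompany/BioLORD-2023"))


def cosine(a: EmbeddingVector, b: EmbeddingVector) -> float:
    """Cosine similarity; 0 when either vector has zero norm."""
    if a.backend_id != b.backend_id or a.dim != b.dim:
        raise ValueError(
            f"incompatible embeddings: {a.backend_id}/{a.dim} "
            f"vs {b.backend_id}/{b.dim}"
        )
    na, nb = np.linalg.norm(a.values), np.linalg.norm(b.values)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a.values @ b.values / (na * nb))


def _lcs_length(a: str, b: str) -> int:
    """Longest common subsequence length (vectorized row recurrence)."""
    if not a or not b:
        return 0
    bx = np.frombuffer(b.encode("utf-32-le"), dtype=np.uint32)
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    for ch in a:
        code = ord(ch)
        cand = np.maximum(prev[1:], prev[:-1] + (bx == code))
        np.maximum.accumulate(cand, out=cand)
        prev[1:] = cand
    return int(prev[-1])


def indel_similarity(a: str, b: str) -> float:
    """Normalized indel similarity: 1 - indel_distance / (len(a)+len(b))."""
    total = len(a) + len(b)
    if total == 0:
        return 1.0
    distance = total - 2 * _lcs_length(a, b)
    return 1.0 - distance / total


@lru_cache(maxsize=262144)
def token_set_ratio(a: str, b: str) -> float:
    """Token-set-ratio fuzzy score on the 0-100 scale.

    Inputs are expected to be pre-normalized (see
    :func:`varmatch.textprep.normalize_for_fuzzy`).  Tokens are deduplicated
    and sorted; with I the sorted intersection and D1/D2 the sorted
    differences, the score is the maximum normalized indel similarity over
    the string pairs (I, I+D1), (I, I+D2), (I+D1, I+D2), scaled by 100.
    """
    set_a = sorted(set(a.split()))
    set_b = sorted(set(b.split()))
    if not set_a or not set_b:
        return 0.0
    inter = sorted(set(set_a) & set(set_b))
    diff_a = sorted(set(set_a) - set(inter))
    diff_b = sorted(set(set_b) - set(inter))
    s0 = " ".join(inter)
    s1 = " ".join(inter + diff_a)
    s2 = " ".join(inter + diff_b)
    best = max(
        indel_similarity(s0, s1),
        indel_similarity(s0, s2),
        indel_similarity(s1, s2),
    )
    return 100.0 * best


def embed(texts: Sequence[str], backend_id: str) -> list[EmbeddingVector]:
    """Embed a batch of texts with a registered backend (cached)."""
    return get_backend(backend_id).embed(texts)


@dataclass
class SimilarityScorer:
    """Bundle of embedding backends + fuzzy matching for pair scoring."""

    method_ids: Sequence[str]
    backends: dict[str, CachedEmbedder] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mid in self.method_ids:
            if mid != FUZZY_METHOD and mid not in self.backends:
                self.backends[mid] = get_backend(mid)

    def _channel_texts(self, bundle: TextBundle) -> tuple[str, str, str]:
        return bundle.label_text, bundle.sheet_text, bundle.label_key_text

    def score_pair(self, src: TextBundle, tgt: TextBundle) -> list[ChannelScores]:
        """One :class:`ChannelScores` per requested method, in method order."""
        out = []
        src_texts = self._channel_texts(src)
        tgt_texts = self._channel_texts(tgt)
        for mid in self.method_ids:
            if mid == FUZZY_METHOD:
                vals = [
                    token_set_ratio(normalize_for_fuzzy(s), normalize_for_fuzzy(t))
                    for s, t in zip(src_texts, tgt_texts)
                ]
            else:
                backend = self.backends[mid]
                src_vecs = backend.embed(list(src_texts))
                tgt_vecs = backend.embed(list(tgt_texts))
                vals = [cosine(s, t) for s, t in zip(src_vecs, tgt_vecs)]
            out.append(ChannelScores(mid, *vals))
        return out


def score_pair(
    src: TextBundle, tgt: TextBundle, methods: Sequence[str]
) -> list[ChannelScores]:
    """Score one pair of text bundles with the requested methods."""
    return SimilarityScorer(list(methods)).score_pair(src, tgt)
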