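import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import varmatch as vm
from varmatch.errors import ConfigurationError
from varmatch.similarity import (
    EmbeddingVector,
    HashingEmbedder,
    CachedEmbedder,
    cosine,
    token_set_ratio,
)
from varmatch.textprep import build_text_bundle
from varmatch.dictionary import VariableRecord

from oracle_utils import token_set_ratio_oracle

TOKENS = st.lists(
    st.text(alphabet="abcdefgh", min_size=1, max_size=6), min_size=0,
    max_size=8,
).map(" ".join)


def vec(values, backend="offline-hash"):
    return EmbeddingVector(values=np.asarray(values, dtype=float),
                           backend_id=backend)


class TestCosine:
    def test_identity_orthogonal_closed_form(self):
        v = vec([2.0, 1.0, 0.5])
        assert cosine(v, v) == pytest.approx(1.0)
        assert cosine(vec([1, 0]), vec([0, 1])) == pytest.approx(0.0)
        assert cosine(vec([1, 1]), vec([1, 0])) == pytest.approx(
            1 / np.sqrt(2), abs=1e-6)

    def test_zero_norm_and_mismatch(self):
        assert cosine(vec([0, 0]), vec([1, 1])) == 0.0
        with pytest.raises(ValueError):
            cosine(vec([1, 0]), vec([1, 0, 0]))
        with pytest.raises(ValueError):
            cosine(vec([1, 0]), vec([1, 0], backend="other"))


class TestEmbeddingBackends:
    def test_cache_embeds_each_string_once(self):
        raw = HashingEmbedder("t", dim=32)
        cached = CachedEmbedder(raw)
        out = cached.embed(["sex", "sex"])
        assert raw.n_calls == 1
        np.testing.assert_array_equal(out[0].values, out[1].values)
        cached.embed(["sex"])
        assert raw.n_calls == 1  # served from cache

    def test_deterministic_across_instances(self):
        a = vm.get_backend("offline-hash").embed(["abc"])[0]
        b = vm.get_backend("offline-hash").embed(["abc"])[0]
        np.testing.assert_array_equal(a.values, b.values)
        assert np.all(np.isfinite(a.values))
        assert np.linalg.norm(a.values) == pytest.approx(1.0)

    def test_empty_text_zero_vector_with_warning(self):
        with pytest.warns(UserWarning, match="empty text"):
            out = vm.embed([""], "offline-hash")
        assert not out[0].values.any()

    def test_unknown_backend_lists_registered(self):
        with pytest.raises(ConfigurationError, match="offline-hash"):
            vm.get_backend("no-such-model")

    def test_variants_differ(self):
        a = vm.get_backend("offline-hash").embed(["body mass index"])[0]
        b = vm.get_backend("offline-hash-b").embed(["body mass index"])[0]
        assert a.dim != b.dim or not np.array_equal(a.values, b.values)


class TestTokenSetRatio:
    def test_identity_and_empty(self):
        assert token_set_ratio("bodi mass index", "bodi mass index") == 100.0
        assert token_set_ratio("bodi mass index", "") == 0.0
        assert token_set_ratio("", "") == 0.0

    def test_subset_scores_100(self):
        assert token_set_ratio("vital sign bmi baselin", "bmi baselin") == 100.0

    @given(a=TOKENS, b=TOKENS)
    @settings(max_examples=150, deadline=None)
    def test_symmetry_and_oracle(self, a, b):
        left = token_set_ratio(a, b)
        assert left == token_set_ratio(b, a)
        assert left == pytest.approx(token_set_ratio_oracle(a, b), abs=1e-9)

    def test_against_oracle_on_corpus_labels(self, standard_corpus):
        src, tgt, _ = standard_corpus
        rng = np.random.default_rng(5)
        src_norms = [vm.normalize_for_fuzzy(r.variable_label) for r in src]
        tgt_norms = [vm.normalize_for_fuzzy(r.variable_label) for r in tgt]
        for _ in range(60):
            a = src_norms[rng.integers(len(src_norms))]
            b = tgt_norms[rng.integers(len(tgt_norms))]
            assert token_set_ratio(a, b) == pytest.approx(
                token_set_ratio_oracle(a, b), abs=1e-9)


class TestScorePair:
    @pytest.fixture()
    def bundles(self, hash_embedder):
        r1 = VariableRecord("EU", "S", "Vitals", "BMI",
                            "Body mass index at baseline")
        r2 = VariableRecord("JP", "S", "Vital signs", "BMIB",
                            "Body mass index (BMI) baseline")
        return (build_text_bundle(r1, hash_embedder),
                build_text_bundle(r2, hash_embedder))

    def test_identical_bundles_score_one(self, bundles):
        b, _ = bundles
        scores = vm.score_pair(b, b, ["offline-hash"])
        assert scores[0].on_label == pytest.approx(1.0)
        assert scores[0].on_sheet == pytest.approx(1.0)
        assert scores[0].on_label_key == pytest.approx(1.0)

    def test_five_methods_fifteen_numbers(self, bundles):
        a, b = bundles
        scores = vm.score_pair(a, b, vm.DEFAULT_METHODS)
        assert len(scores) == 5
        values = [v for s in scores
                  for v in (s.on_label, s.on_sheet, s.on_label_key)]
        assert len(values) == 15
        for s in scores:
            lo, hi = (0, 100) if s.method_id == "fuzzy" else (-1, 1)
            for v in (s.on_label, s.on_sheet, s.on_label_key):
                assert lo <= v <= hi

    def test_symmetry(self, bundles):
        a, b = bundles
        fwd = vm.score_pair(a, b, vm.DEFAULT_METHODS)
        rev = vm.score_pair(b, a, vm.DEFAULT_METHODS)
        for f, r in zip(fwd, rev):
            assert f.on_label == pytest.approx(r.on_label)
            assert f.on_label_key == pytest.approx(r.on_label_key)


def test_featurizer_matches_per_pair_scoring(tiny_corpus, tiny_matrix):
    """The vectorized matrix path and score_pair agree pair by pair."""
    src, tgt, truth = tiny_corpus
    featurizer, matrix = tiny_matrix
    rng = np.random.default_rng(2)
    rows = matrix.sample(5, random_state=7)
    for _, row in rows.iterrows():
        sb = featurizer.src_bundles[row["source_name"]]
        tb = featurizer.tgt_bundles[row["target_name"]]
        scores = featurizer.scorer.score_pair(sb, tb)
        for s in scores:
            prefix = vm.features.method_prefix(s.method_id)
            assert row[f"{prefix}_on_label"] == pytest.approx(s.on_label)
            assert row[f"{prefix}_on_sheet"] == pytest.approx(s.on_sheet)
            assert row[f"{prefix}_on_label_key"] == pytest.approx(
                s.on_label_key)
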