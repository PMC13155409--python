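"""Contextual embedding regimes: layer-0 invariance, truncation, donors."""

import numpy as np
import pytest

from cocktail_ctx.embedding_context import (
    ContextSpec,
    SyntheticEmbeddingModel,
    extract_word_embeddings,
    make_unrelated_context,
    untrained_control_adapter,
)


@pytest.fixture(scope="module")
def model():
    return SyntheticEmbeddingModel.create(vocab_size=200, dim=16, seed=2)


@pytest.fixture(scope="module")
def transcript(model):
    rng = np.random.default_rng(9)
    return [f"w{t:04d}" for t in rng.integers(0, model.vocab_size, size=20)]


@pytest.fixture(scope="module")
def donor(model):
    rng = np.random.default_rng(10)
    return tuple(f"w{t:04d}" for t in rng.integers(0, model.vocab_size, size=40))


class _SplitTokenAdapter:
    """Wraps the synthetic model, splitting designated words into two tokens
    whose second (final) token carries the word identity — exercises the
    final-token selection rule for multi-token words."""

    def __init__(self, base: SyntheticEmbeddingModel, split_words: set[str]):
        self.base = base
        self.split_words = split_words
        self.n_layers = base.n_layers
        self.dim = base.dim
        self.model_id = "split-" + base.model_id

    def tokenize(self, words):
        tokens, spans = [], []
        for w in words:
            if w in self.split_words:
                spans.append([len(tokens), len(tokens) + 1])
                tokens.extend(["w0000", w])  # filler piece, then final token
            else:
                spans.append([len(tokens)])
                tokens.append(w)
        return tokens, spans

    def forward(self, tokens, visible_window=None):
        return self.base.forward(tokens, visible_window=visible_window)


class TestSyntheticModel:
    def test_layer0_is_lexicon_lookup(self, model, transcript):
        out = model.forward(transcript)
        expected = model._token_vectors(transcript)
        np.testing.assert_array_equal(out[0], expected)

    def test_pure_previous_token_mixing(self):
        # alpha=1, window 1, gamma=1: each layer-1 vector is the predecessor's
        model = SyntheticEmbeddingModel.create(
            vocab_size=50, dim=8, seed=3,
            alphas=(0.0, 1.0), windows=(1, 1), gamma=1.0,
        )
        words = ["w0001", "w0002", "w0003", "w0004"]
        out = model.forward(words)
        lex = model._token_vectors(words)
        np.testing.assert_allclose(out[1][1:], lex[:-1], atol=1e-12)

    def test_unknown_token_named_in_error(self, model):
        with pytest.raises(KeyError, match="w9999"):
            model.forward(["w0001", "w9999"])
        with pytest.raises(KeyError, match="hello"):
            model.forward(["hello"])

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="context-free"):
            SyntheticEmbeddingModel.create(
                vocab_size=10, dim=4, alphas=(0.5, 0.5), windows=(1, 2)
            )
        with pytest.raises(ValueError, match="nondecreasing"):
            SyntheticEmbeddingModel.create(
                vocab_size=10, dim=4, alphas=(0.0, 0.1, 0.2), windows=(1, 8, 4)
            )


class TestExtractWordEmbeddings:
    def test_layer0_invariant_across_context_modes(self, model, transcript, donor):
        related = extract_word_embeddings(transcript, model)
        unrelated = extract_word_embeddings(
            transcript, model, ContextSpec(mode="unrelated", donor=donor)
        )
        truncated = extract_word_embeddings(
            transcript, model, ContextSpec(mode="truncated", m_tokens=3)
        )
        np.testing.assert_array_equal(related.layer(0), unrelated.layer(0))
        np.testing.assert_array_equal(related.layer(0), truncated.layer(0))

    def test_window_saturation_matches_full_context(self, model, transcript):
        full = extract_word_embeddings(transcript, model)
        sat = extract_word_embeddings(
            transcript, model,
            ContextSpec(mode="truncated", m_tokens=len(transcript) + 130),
        )
        np.testing.assert_allclose(full.data, sat.data, atol=1e-12)

    def test_unrelated_differs_at_contextual_layers(self, model, transcript, donor):
        related = extract_word_embeddings(transcript, model)
        unrelated = extract_word_embeddings(
            transcript, model, ContextSpec(mode="unrelated", donor=donor)
        )
        top = model.n_layers
        diffs = np.linalg.norm(
            related.layer(top) - unrelated.layer(top), axis=1
        )
        assert np.all(diffs[1:] > 1e-8)  # every non-initial word differs
        assert diffs[0] == 0.0  # trial-initial word has no context to replace

    def test_truncation_distance_monotone_in_window(self, model, transcript):
        # monotone from M=2 up: the M=1 endpoint has an *empty* (zero)
        # context term, which under the normalized-average mixing rule can
        # lie closer to the full-context average than any single
        # predecessor's vector does
        full = extract_word_embeddings(transcript, model)
        top = model.n_layers
        dists = []
        for m in (2, 4, 8, 12, 16, 20, 25):
            trunc = extract_word_embeddings(
                transcript, model, ContextSpec(mode="truncated", m_tokens=m)
            )
            dists.append(
                np.linalg.norm(full.layer(top) - trunc.layer(top), axis=1).mean()
            )
        assert all(b <= a + 1e-12 for a, b in zip(dists, dists[1:]))
        assert dists[-1] < 1e-12

    def test_determinism(self, model, transcript):
        a = extract_word_embeddings(transcript, model)
        b = extract_word_embeddings(transcript, model)
        np.testing.assert_array_equal(a.data, b.data)

    def test_final_token_represents_multitoken_word(self, model, transcript):
        split = _SplitTokenAdapter(model, {transcript[5]})
        plain = extract_word_embeddings(transcript, model)
        multi = extract_word_embeddings(transcript, split)
        # layer 0 of the split word equals the lexicon vector of its final
        # token, which carries the word identity
        np.testing.assert_array_equal(multi.layer(0)[5], plain.layer(0)[5])
        assert multi.data.shape == plain.data.shape


class TestMakeUnrelatedContext:
    def test_first_word_stands_alone(self, transcript, donor, model):
        seq = make_unrelated_context(transcript, donor, 0)
        assert seq == [transcript[0]]
        unrelated = extract_word_embeddings(
            transcript, model, ContextSpec(mode="unrelated", donor=donor)
        )
        related = extract_word_embeddings(transcript, model)
        np.testing.assert_allclose(
            unrelated.data[0], related.data[0], atol=1e-12
        )

    def test_construction_rule(self, transcript, donor):
        seq = make_unrelated_context(transcript, donor, 3)
        assert len(seq) == 4
        assert seq[:3] == list(donor[:3])
        assert seq[-1] == transcript[3]

    def test_lengths_enumerate(self, transcript, donor):
        lengths = [
            len(make_unrelated_context(transcript, donor, k))
            for k in range(len(transcript))
        ]
        assert lengths == list(range(1, len(transcript) + 1))

    def test_short_donor_rejected(self, transcript):
        with pytest.raises(ValueError, match="donor"):
            make_unrelated_context(transcript, ("w0001",), 5)


class TestUntrainedControl:
    def test_same_seed_identical(self, model):
        a = untrained_control_adapter(model, seed=4)
        b = untrained_control_adapter(model, seed=4)
        np.testing.assert_array_equal(a.lexicon, b.lexicon)
        assert a.alphas == b.alphas
        assert a.windows == b.windows

    def test_interface_and_layer0_contract(self, model, transcript):
        control = untrained_control_adapter(model, seed=4)
        assert control.n_layers == model.n_layers
        assert control.dim == model.dim
        related = extract_word_embeddings(transcript, control)
        trunc = extract_word_embeddings(
            transcript, control, ContextSpec(mode="truncated", m_tokens=2)
        )
        np.testing.assert_array_equal(related.layer(0), trunc.layer(0))

    def test_lexicon_independent_of_reference(self, model):
        control = untrained_control_adapter(model, seed=4)
        corr = np.corrcoef(
            model.lexicon.ravel(), control.lexicon.ravel()
        )[0, 1]
        assert abs(corr) < 0.05


class TestPersistence:
    def test_hdf5_round_trip(self, model, transcript, tmp_path):
        from cocktail_ctx.embedding_context import (
            embedding_tensor_from_hdf5,
            embedding_tensor_to_hdf5,
        )

        tensor = extract_word_embeddings(
            transcript, model, ContextSpec(mode="truncated", m_tokens=5)
        )
        path = tmp_path / "emb.h5"
        embedding_tensor_to_hdf5(tensor, path)
        back = embedding_tensor_from_hdf5(path)
        np.testing.assert_array_equal(back.data, tensor.data)
        assert back.context.mode == "truncated"
        assert back.context.m_tokens == 5
        assert back.model_id == tensor.model_id
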