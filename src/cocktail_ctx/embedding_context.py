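"""Layer-wise contextual word embeddings under controlled context regimes.

The analysis treats a language model as a black box satisfying a small
adapter contract: a tokenizer mapping words to tokens, and a deterministic
``forward`` producing per-layer, per-token vectors where layer 0 is the
context-free token embedding.  Word representations are read off the final
token of each word.

Three context regimes are supported:

``related``
    the word's true preceding transcript (the default);
``truncated``
    an attention window of ``M`` tokens — the current token plus its ``M-1``
    predecessors — emulating attention-mask truncation;
``unrelated``
    the word's preceding context replaced by an equal-length prefix of a
    donor transcript, preserving context *length* while destroying its
    semantic relation to the word.

The bundled :class:`SyntheticEmbeddingModel` realizes the contract with an
explicit, analytically tractable mixing rule: at layer ``l`` a word's vector
is ``(1 - alpha_l) * V[w_t] + alpha_l * c_t`` where ``c_t`` is a
geometrically decayed average of the preceding ``K_l`` token vectors.  With
``alpha_0 = 0`` and windows ``K_l`` nondecreasing in depth, deeper layers
integrate progressively longer context, the structural property the analysis
probes for in neural data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import h5py
import numpy as np

__all__ = [
    "ModelAdapter",
    "ContextSpec",
    "EmbeddingTensor",
    "SyntheticEmbeddingModel",
    "extract_word_embeddings",
    "make_unrelated_context",
    "untrained_control_adapter",
    "embedding_tensor_to_hdf5",
    "embedding_tensor_from_hdf5",
]


@runtime_checkable
class ModelAdapter(Protocol):
    """Contract every embedding backend must satisfy.

    ``forward`` must be deterministic and its layer-0 output for a token must
    not depend on any other token.
    """

    n_layers: int  # contextual layers; total layer count is n_layers + 1
    dim: int
    model_id: str

    def tokenize(
        self, words: Sequence[str]
    ) -> tuple[list[str], list[list[int]]]:
        """Return (token sequence, per-word token-index spans)."""
        ...

    def forward(
        self, tokens: Sequence[str], visible_window: int | None = None
    ) -> np.ndarray:
        """Return (n_layers + 1) x n_tokens x dim vectors; layer 0 first.

        ``visible_window=M`` restricts each token's context to itself plus
        its ``M - 1`` predecessors; ``None`` means full causal context.
        """
        ...


@dataclass(frozen=True)
class ContextSpec:
    """Which context regime to embed words under."""

    mode: str = "related"  # related | unrelated | truncated
    m_tokens: int | None = None  # window size for truncated mode
    donor: tuple[str, ...] | None = None  # donor transcript for unrelated mode

    def __post_init__(self) -> None:
        if self.mode not in ("related", "unrelated", "truncated"):
            raise ValueError(f"unknown context mode {self.mode!r}")
        if self.mode == "truncated":
            if self.m_tokens is None or self.m_tokens < 1:
                raise ValueError("truncated mode requires m_tokens >= 1")
        if self.mode == "unrelated" and not self.donor:
            raise ValueError("unrelated mode requires a nonempty donor transcript")

    def label(self) -> str:
        if self.mode == "truncated":
            return f"truncated-{self.m_tokens}"
        return self.mode


@dataclass(frozen=True)
class EmbeddingTensor:
    """Words x dim x (layers + 1) contextual representations."""

    data: np.ndarray
    context: ContextSpec
    model_id: str
    word_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if d.ndim != 3:
            raise ValueError("embedding tensor must be words x dim x layers")
        if not np.all(np.isfinite(d)):
            raise ValueError("embedding tensor must be finite")

    @property
    def n_words(self) -> int:
        return self.data.shape[0]

    @property
    def dim(self) -> int:
        return self.data.shape[1]

    @property
    def n_layers(self) -> int:
        """Number of contextual layers (total layers minus layer 0)."""
        return self.data.shape[2] - 1

    def layer(self, index: int) -> np.ndarray:
        """Words x dim matrix at one layer (0 = context-free embeddings)."""
        return self.data[:, :, index]


_DEFAULT_WINDOWS = (1, 1, 2, 4, 8, 16, 32, 64, 128)
_DEFAULT_ALPHAS = (0.0, 0.1, 0.2, 0.3, 0.35, 0.4, 0.45, 0.5, 0.5)


@dataclass(frozen=True)
class SyntheticEmbeddingModel:
    """Analytically tractable contextual embedding model.

    ``lexicon`` holds one unit-scale vector per vocabulary word.  Layer ``l``
    mixes the current token's lexical vector with a decayed average of its
    visible predecessors::

        e_l(t) = (1 - alpha_l) V[w_t]
                 + alpha_l * sum_{j=1..min(K_l, t)} gamma^(j-1) V[w_{t-j}]
                           / sum_{j=1..min(K_l, t)} gamma^(j-1)

    Layer 0 has ``alpha_0 = 0`` (context-free); windows ``K_l`` are
    nondecreasing in ``l``.  The tokenizer maps one word to one token.
    """

    lexicon: np.ndarray
    alphas: tuple[float, ...] = _DEFAULT_ALPHAS
    windows: tuple[int, ...] = _DEFAULT_WINDOWS
    gamma: float = 0.95
    model_id: str = "synthetic"

    def __post_init__(self) -> None:
        lex = np.asarray(self.lexicon, dtype=float)
        object.__setattr__(self, "lexicon", lex)
        if lex.ndim != 2:
            raise ValueError("lexicon must be vocab x dim")
        if len(self.alphas) != len(self.windows):
            raise ValueError("alphas and windows must have equal length")
        if self.alphas[0] != 0.0:
            raise ValueError("layer 0 must be context-free (alpha_0 = 0)")
        if any(not 0.0 <= a <= 1.0 for a in self.alphas):
            raise ValueError("alphas must lie in [0, 1]")
        if any(k2 < k1 for k1, k2 in zip(self.windows[1:], self.windows[2:])):
            raise ValueError("windows must be nondecreasing across layers")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")

    @property
    def n_layers(self) -> int:
        return len(self.alphas) - 1

    @property
    def dim(self) -> int:
        return self.lexicon.shape[1]

    @property
    def vocab_size(self) -> int:
        return self.lexicon.shape[0]

    @classmethod
    def create(
        cls,
        vocab_size: int = 2000,
        dim: int = 64,
        seed: int = 0,
        **kwargs,
    ) -> "SyntheticEmbeddingModel":
        """Random unit-scale lexicon (rows ~ N(0, I/dim), norm ~ 1)."""
        rng = np.random.default_rng(seed)
        lex = rng.standard_normal((vocab_size, dim)) / np.sqrt(dim)
        return cls(lexicon=lex, **kwargs)

    # -- adapter contract ---------------------------------------------------

    def tokenize(
        self, words: Sequence[str]
    ) -> tuple[list[str], list[list[int]]]:
        return list(words), [[i] for i in range(len(words))]

    def _token_vectors(self, tokens: Sequence[str]) -> np.ndarray:
        idx = []
        for tok in tokens:
            if tok.startswith("w") and tok[1:].isdigit():
                i = int(tok[1:])
                if i >= self.vocab_size:
                    raise KeyError(f"token {tok!r} outside the model vocabulary")
            else:
                raise KeyError(f"cannot embed unknown token {tok!r}")
            idx.append(i)
        return self.lexicon[idx]

    def forward(
        self, tokens: Sequence[str], visible_window: int | None = None
    ) -> np.ndarray:
        vecs = self._token_vectors(tokens)  # T x D
        t_len = vecs.shape[0]
        out = np.empty((self.n_layers + 1, t_len, self.dim))
        max_k = max(self.windows[1:], default=1)
        if visible_window is not None:
            max_k = min(max_k, visible_window - 1)
        # decayed partial sums over predecessors, shared across layers
        weights = self.gamma ** np.arange(max(max_k, 1))
        for layer, (alpha, k) in enumerate(zip(self.alphas, self.windows)):
            if alpha == 0.0:
                out[layer] = vecs
                continue
            k_eff = k if visible_window is None else min(k, visible_window - 1)
            ctx = np.zeros_like(vecs)
            for t in range(t_len):
                m = min(k_eff, t)
                if m > 0:
                    w = weights[:m]
                    ctx[t] = (w[:, None] * vecs[t - 1 :: -1][:m]).sum(0) / w.sum()
            out[layer] = (1.0 - alpha) * vecs + alpha * ctx
        return out


def make_unrelated_context(
    transcript: Sequence[str], donor: Sequence[str], word_index: int
) -> list[str]:
    """Replace word ``k``'s preceding context with a donor-transcript prefix.

    Returns ``donor[0:k]`` followed by ``transcript[k]`` — a sequence of
    length ``k + 1`` whose final word is the word of interest with an
    equal-length but semantically unrelated context.
    """
    k = word_index
    if k < 0 or k >= len(transcript):
        raise IndexError(f"word_index {k} outside transcript of {len(transcript)}")
    if len(donor) < k:
        raise ValueError(
            f"donor transcript ({len(donor)} words) shorter than required prefix {k}"
        )
    return list(donor[:k]) + [transcript[k]]


def extract_word_embeddings(
    transcript: Sequence[str],
    adapter: ModelAdapter,
    context: ContextSpec | None = None,
) -> EmbeddingTensor:
    """Per-word, per-layer representations under the requested context regime.

    The final token of each word represents it.  ``related`` runs one causal
    forward pass over the full transcript; ``truncated`` restricts each
    token's visible window to ``m_tokens``; ``unrelated`` re-embeds every word
    at the end of a donor-prefix sequence of matching length.
    """
    if context is None:
        context = ContextSpec()
    words = list(transcript)
    if not words:
        raise ValueError("transcript is empty")

    if context.mode == "unrelated":
        donor = list(context.donor)  # type: ignore[arg-type]
        rows = []
        for k in range(len(words)):
            seq = make_unrelated_context(words, donor, k)
            tokens, spans = adapter.tokenize(seq)
            layers = adapter.forward(tokens)
            rows.append(layers[:, spans[-1][-1], :])  # layers x dim
        data = np.stack(rows).transpose(0, 2, 1)  # words x dim x layers
        return EmbeddingTensor(data=data, context=context, model_id=adapter.model_id)

    tokens, spans = adapter.tokenize(words)
    window = context.m_tokens if context.mode == "truncated" else None
    layers = adapter.forward(tokens, visible_window=window)
    last = [span[-1] for span in spans]
    data = layers[:, last, :].transpose(1, 2, 0)  # words x dim x layers
    return EmbeddingTensor(data=data, context=context, model_id=adapter.model_id)


def untrained_control_adapter(
    reference: SyntheticEmbeddingModel | None = None,
    seed: int = 0,
    vocab_size: int | None = None,
    dim: int | None = None,
) -> SyntheticEmbeddingModel:
    """Architecture-matched control with freshly random parameters.

    Mirrors re-initialising a trained network with random weights: the layer
    structure (depth, dimension, nondecreasing windows) is preserved, but the
    lexicon and mixing coefficients are drawn anew, independent of any
    lexicon used to generate data.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if reference is not None:
        vocab_size = reference.vocab_size
        dim = reference.dim
        n_layers = reference.n_layers
    else:
        vocab_size = vocab_size or 2000
        dim = dim or 64
        n_layers = len(_DEFAULT_ALPHAS) - 1
    lex = rng.standard_normal((vocab_size, dim)) / np.sqrt(dim)
    alphas = (0.0,) + tuple(np.sort(rng.uniform(0.05, 0.95, size=n_layers)))
    windows = (1,) + tuple(
        int(k) for k in np.sort(rng.integers(1, 129, size=n_layers))
    )
    return SyntheticEmbeddingModel(
        lexicon=lex,
        alphas=alphas,
        windows=windows,
        gamma=float(rng.uniform(0.5, 0.99)),
        model_id=f"untrained-control-{seed}",
    )


def embedding_tensor_to_hdf5(tensor: EmbeddingTensor, path) -> None:
    import json

    with h5py.File(path, "w") as f:
        ds = f.create_dataset("embeddings", data=tensor.data)
        ds.attrs["model_id"] = tensor.model_id
        ds.attrs["context"] = json.dumps(
            {
                "mode": tensor.context.mode,
                "m_tokens": tensor.context.m_tokens,
                "donor_len": len(tensor.context.donor or ()),
            }
        )


def embedding_tensor_from_hdf5(path) -> EmbeddingTensor:
    import json

    with h5py.File(path, "r") as f:
        ds = f["embeddings"]
        meta = json.loads(ds.attrs["context"])
        donor = ("<donor>",) * meta["donor_len"] if meta["donor_len"] else None
        ctx = ContextSpec(
            mode=meta["mode"], m_tokens=meta["m_tokens"], donor=donor
        )
        return EmbeddingTensor(
            data=ds[()], context=ctx, model_id=str(ds.attrs["model_id"])
        )
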