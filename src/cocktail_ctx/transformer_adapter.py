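"""Optional adapter exposing a Hugging Face causal LM as a ModelAdapter.

Requires the ``llm`` extra (transformers + torch); nothing in the core
pipeline or the test suite imports this module.  Per-layer decoder hidden
states are read out at the final token of each word; context truncation is
implemented by restricting the attention mask to the last ``M`` positions
relative to each token (sliding causal window).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


class TransformerAdapter:
    """Wrap a pretrained decoder-only LM behind the embedding contract."""

    def __init__(self, model_name: str, device: str = "cpu"):
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "TransformerAdapter requires the 'llm' extra "
                "(pip install cocktail-ctx[llm])"
            ) from exc
        self._tok = AutoTokenizer.from_pretrained(model_name)
        self._model = AutoModel.from_pretrained(
            model_name, output_hidden_states=True
        ).to(device)
        self._model.eval()
        self.device = device
        self.model_id = model_name
        self.dim = int(self._model.config.hidden_size)
        self.n_layers = int(self._model.config.num_hidden_layers)

    def tokenize(self, words: Sequence[str]):
        tokens: list[str] = []
        spans: list[list[int]] = []
        for i, word in enumerate(words):
            text = word if i == 0 else " " + word
            ids = self._tok.tokenize(text)
            spans.append(list(range(len(tokens), len(tokens) + len(ids))))
            tokens.extend(ids)
        return tokens, spans

    def forward(self, tokens: Sequence[str], visible_window: int | None = None):
        import torch

        ids = torch.tensor(
            [self._tok.convert_tokens_to_ids(list(tokens))], device=self.device
        )
        n = ids.shape[1]
        if visible_window is None:
            mask = None
        else:
            # sliding causal window: token t attends to [t - M + 1, t]
            idx = torch.arange(n)
            keep = (idx[None, :] <= idx[:, None]) & (
                idx[None, :] > idx[:, None] - visible_window
            )
            mask = torch.where(keep, 0.0, float("-inf"))[None, None].to(self.device)
        with torch.no_grad():
            out = self._model(input_ids=ids, attention_mask=mask)
        hidden = torch.stack(out.hidden_states, dim=0)[:, 0]  # layers x T x D
        return np.asarray(hidden.cpu().numpy(), dtype=float)
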