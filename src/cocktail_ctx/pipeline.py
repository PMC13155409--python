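"""End-to-end synthetic parameter-recovery studies.

Ties the modules together: generate a cocktail-party experiment, simulate
ground-truth neural envelopes, embed both speech streams under the context
regimes of interest, fit leave-one-trial-out ridge encoding models, and run
the paired electrode statistics.  The headline study checks that the
analysis chain recovers the properties built into the generator:

* attended brain scores exceed unattended ones (gain asymmetry);
* contextual layers beat the context-free layer 0 for the attended stream;
* related context beats unrelated context for the attended stream;
* the unattended context-length curve saturates at the generator's short
  true context window while the attended curve keeps improving to full
  context (timescale asymmetry);
* the aligned embedding model beats an architecture-matched untrained
  control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cocktail_ctx.acoustic_features import lagged_envelope_matrix
from cocktail_ctx.embedding_context import (
    ContextSpec,
    EmbeddingTensor,
    SyntheticEmbeddingModel,
    extract_word_embeddings,
    untrained_control_adapter,
)
from cocktail_ctx.encoding_model import (
    BrainScoreTable,
    FilterOptions,
    LagConfig,
    RidgeConfig,
    extract_lagged_word_responses,
    fit_loto_brain_scores,
)
from cocktail_ctx.stats_compare import (
    PairedComparison,
    compare_scores,
    context_length_curve,
    layer_curve,
)
from cocktail_ctx.synthetic_data import (
    ExperimentConfig,
    ExperimentDataset,
    GroundTruth,
    generate_experiment,
    score_repeat_detection,
    simulate_button_presses,
    simulate_neural_recording,
    synthetic_word_envelope,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "RecoveryResult", "run_recovery_study",
           "run_envelope_comparison", "make_donor_transcript"]


@dataclass(frozen=True)
class StudyConfig:
    """Scale and ground-truth parameters of one synthetic study.

    Defaults are the standard desk-scale conditions: 25 trials, 100
    electrodes, 64-dimensional embeddings, attended/unattended readout gains
    1.0/0.4 and true context windows 50/10 tokens.
    """

    n_trials: int = 25
    n_electrodes: int = 100
    dim: int = 64
    vocab_size: int = 2000
    seed: int = 0
    layers: tuple[int, ...] = tuple(range(9))
    selected_layer: int = 8
    context_lengths: tuple = (1, 5, 10, 15, 50, "full")
    g_att: float = 1.0
    g_unatt: float = 0.4
    k_att: int = 50
    k_unatt: int = 10
    ridge: RidgeConfig = field(default_factory=RidgeConfig)
    lag: LagConfig = field(default_factory=LagConfig)
    filters: FilterOptions = field(default_factory=FilterOptions)


@dataclass
class RecoveryResult:
    """All scores, comparisons and curves of one recovery study."""

    table: BrainScoreTable
    comparisons: dict[str, PairedComparison]
    layer_curves: dict[str, pd.DataFrame]
    context_curves: dict[str, tuple[pd.DataFrame, list[PairedComparison]]]
    behavior: dict[str, dict[str, float]]
    config: StudyConfig

    def summary(self) -> str:
        lines = ["Parameter-recovery study", "=" * 24]
        for role, stats in self.behavior.items():
            lines.append(
                f"1-back detection ({role}): {stats['rate']:.0%} "
                f"({stats['detected']:.0f}/{stats['total']:.0f})"
            )
        lines.append("")
        for comp in self.comparisons.values():
            lines.append(str(comp))
        lines.append("")
        for cond, (df, comps) in self.context_curves.items():
            lines.append(f"context-length curve ({cond}):")
            lines.append(df.to_string(index=False))
            for c in comps:
                lines.append("  " + str(c))
        return "\n".join(lines)


def make_donor_transcript(
    vocab_size: int, length: int, seed: int
) -> tuple[str, ...]:
    """Random word sequence from the model vocabulary, used as the
    semantically unrelated context donor."""
    rng = np.random.default_rng(seed)
    return tuple(f"w{t:04d}" for t in rng.integers(0, vocab_size, size=length))


def _word_mask(words, kept_indices, filters: FilterOptions) -> np.ndarray:
    """Row selector into kept_indices after the repeated-word filter."""
    keep = np.ones(len(kept_indices), dtype=bool)
    if filters.exclude_repeated_words:
        is_rep = np.array([words[i].is_repeat for i in kept_indices])
        keep &= ~is_rep
    return keep


def _fit_condition(
    tensors: list[EmbeddingTensor],
    layer: int,
    responses,
    kept,
    masks,
    ridge: RidgeConfig,
    meta: dict,
) -> BrainScoreTable:
    feats = [
        t.layer(layer)[k][m] for t, k, m in zip(tensors, kept, masks)
    ]
    resp = [r.data[m] for r, m in zip(responses, masks)]
    fit = fit_loto_brain_scores(feats, resp, ridge_cfg=ridge, metadata=meta)
    return fit.to_table()


def run_recovery_study(cfg: StudyConfig | None = None) -> RecoveryResult:
    """Run the full synthetic study and its statistical read-outs."""
    if cfg is None:
        cfg = StudyConfig()
    exp_cfg = ExperimentConfig(
        n_trials=cfg.n_trials, vocab_size=cfg.vocab_size, rng_seed=cfg.seed
    )
    dataset = generate_experiment(exp_cfg)
    adapter = SyntheticEmbeddingModel.create(
        vocab_size=cfg.vocab_size, dim=cfg.dim, seed=cfg.seed + 101
    )
    truth = GroundTruth.default(
        n_electrodes=cfg.n_electrodes, dim=cfg.dim, seed=cfg.seed + 202,
        g_att=cfg.g_att, g_unatt=cfg.g_unatt,
        true_context_len_att=cfg.k_att, true_context_len_unatt=cfg.k_unatt,
    )
    logger.info("simulating %d trials x %d electrodes", cfg.n_trials, cfg.n_electrodes)
    recordings = simulate_neural_recording(dataset, truth, adapter, mode="envelope")

    presses = simulate_button_presses(dataset, seed=cfg.seed + 303)
    behavior = score_repeat_detection(dataset, presses)

    trial_keep = np.ones(cfg.n_trials, dtype=bool)
    if cfg.filters.exclude_trials_with_unattended_detections:
        for i, trial in enumerate(dataset.trials):
            sub = ExperimentDataset(config=exp_cfg, trials=(trial,))
            one = score_repeat_detection(
                sub,
                type(presses)(press_times_s=(presses.press_times_s[i],)),
            )
            if one["unattended"]["detected"] > 0:
                trial_keep[i] = False
        logger.info("trial filter keeps %d/%d trials", int(trial_keep.sum()), cfg.n_trials)

    donor = make_donor_transcript(cfg.vocab_size, 400, cfg.seed + 404)
    tables: list[BrainScoreTable] = []

    per_cond: dict[str, dict] = {}
    for cond in ("attended", "unattended"):
        words_by_trial = [
            w for w, k in zip(dataset.stream_words(cond), trial_keep) if k
        ]
        recs = [r for r, k in zip(recordings, trial_keep) if k]
        responses, kept, masks = [], [], []
        for words, rec in zip(words_by_trial, recs):
            resp = extract_lagged_word_responses(
                rec.data, [w.onset_s for w in words], cfg.lag
            )
            responses.append(resp)
            kept.append(resp.word_indices)
            masks.append(_word_mask(words, resp.word_indices, cfg.filters))
        texts = [[w.text for w in words] for words in words_by_trial]
        per_cond[cond] = dict(
            texts=texts, responses=responses, kept=kept, masks=masks
        )

        related = [extract_word_embeddings(t, adapter) for t in texts]
        per_cond[cond]["related"] = related
        for layer in cfg.layers:
            tables.append(
                _fit_condition(
                    related, layer, responses, kept, masks, cfg.ridge,
                    dict(layer=layer, condition=cond, context_mode="related",
                         context_len="full", feature_set="embedding",
                         adapter="aligned"),
                )
            )

        unrelated = [
            extract_word_embeddings(
                t, adapter, ContextSpec(mode="unrelated", donor=donor)
            )
            for t in texts
        ]
        tables.append(
            _fit_condition(
                unrelated, cfg.selected_layer, responses, kept, masks, cfg.ridge,
                dict(layer=cfg.selected_layer, condition=cond,
                     context_mode="unrelated", context_len="full",
                     feature_set="embedding", adapter="aligned"),
            )
        )

        for m in cfg.context_lengths:
            if m == "full":
                continue  # the related full-context fit covers this point
            truncated = [
                extract_word_embeddings(
                    t, adapter, ContextSpec(mode="truncated", m_tokens=int(m))
                )
                for t in texts
            ]
            tables.append(
                _fit_condition(
                    truncated, cfg.selected_layer, responses, kept, masks,
                    cfg.ridge,
                    dict(layer=cfg.selected_layer, condition=cond,
                         context_mode="truncated", context_len=int(m),
                         feature_set="embedding", adapter="aligned"),
                )
            )

    control = untrained_control_adapter(adapter, seed=cfg.seed + 505)
    ctrl_tensors = [
        extract_word_embeddings(t, control) for t in per_cond["attended"]["texts"]
    ]
    tables.append(
        _fit_condition(
            ctrl_tensors, cfg.selected_layer,
            per_cond["attended"]["responses"], per_cond["attended"]["kept"],
            per_cond["attended"]["masks"], cfg.ridge,
            dict(layer=cfg.selected_layer, condition="attended",
                 context_mode="related", context_len="full",
                 feature_set="embedding", adapter="untrained"),
        )
    )

    table = BrainScoreTable.concat(tables)

    aligned_full = dict(
        context_mode="related", context_len="full",
        feature_set="embedding", adapter="aligned",
    )
    comparisons = {
        "attended_vs_unattended": compare_scores(
            table, "condition", "attended", "unattended", fixed=aligned_full,
            name="attended vs unattended (layer-averaged)",
        ),
        "contextual_vs_layer0_attended": compare_scores(
            table, "layer", cfg.selected_layer, 0,
            fixed={**aligned_full, "condition": "attended"},
            name=f"layer {cfg.selected_layer} vs layer 0 (attended)",
        ),
        "related_vs_unrelated_attended": compare_scores(
            table, "context_mode", "related", "unrelated",
            fixed=dict(condition="attended", layer=cfg.selected_layer,
                       context_len="full", feature_set="embedding",
                       adapter="aligned"),
            name="related vs unrelated context (attended)",
        ),
        "aligned_vs_untrained_attended": compare_scores(
            table, "adapter", "aligned", "untrained",
            fixed=dict(condition="attended", layer=cfg.selected_layer,
                       context_mode="related", context_len="full",
                       feature_set="embedding"),
            name="aligned vs untrained adapter (attended)",
        ),
    }

    layer_curves = {}
    context_curves = {}
    for cond in ("attended", "unattended"):
        curve, _ = layer_curve(
            table, cfg.layers, fixed={**aligned_full, "condition": cond}
        )
        layer_curves[cond] = curve
        ctx_fixed = dict(
            condition=cond, layer=cfg.selected_layer,
            context_mode=("related", "truncated"), feature_set="embedding",
            adapter="aligned",
        )
        context_curves[cond] = context_length_curve(
            table, cfg.context_lengths, fixed=ctx_fixed,
            adjacent_comparisons=True,
        )

    comparisons["attended_full_vs_m15"] = compare_scores(
        table, "context_len", "full", 15,
        fixed=dict(condition="attended", layer=cfg.selected_layer,
                   context_mode=("related", "truncated"),
                   feature_set="embedding", adapter="aligned"),
        name="full vs 15-token context (attended)",
    )

    return RecoveryResult(
        table=table,
        comparisons=comparisons,
        layer_curves=layer_curves,
        context_curves=context_curves,
        behavior=behavior,
        config=cfg,
    )


def run_envelope_comparison(
    n_trials: int = 6,
    n_electrodes: int = 12,
    dim: int = 32,
    seed: int = 0,
    acoustic_gain_sd: float = 0.6,
    layer: int = 8,
    ridge: RidgeConfig | None = None,
) -> tuple[BrainScoreTable, PairedComparison]:
    """Acoustic-control study: envelope-only vs envelope+embedding features.

    Per word the envelope feature is the seven-window lagged 1000-Hz
    envelope (1750 values); the fused feature concatenates the selected
    embedding layer (width D + 1750).  With nonzero embedding readouts the
    fused model must outperform the envelope-only model.
    """
    ridge = ridge or RidgeConfig()
    exp_cfg = ExperimentConfig(n_trials=n_trials, rng_seed=seed)
    dataset = generate_experiment(exp_cfg)
    adapter = SyntheticEmbeddingModel.create(
        vocab_size=exp_cfg.vocab_size, dim=dim, seed=seed + 101
    )
    truth = GroundTruth.default(
        n_electrodes=n_electrodes, dim=dim, seed=seed + 202,
        acoustic_gain_sd=acoustic_gain_sd,
    )
    recordings = simulate_neural_recording(dataset, truth, adapter, mode="envelope")

    env_rng = np.random.default_rng(seed + 303)
    feats_env, feats_fused, resp = [], [], []
    for trial, rec in zip(dataset.trials, recordings):
        words = trial.attended_words
        onsets = [w.onset_s for w in words]
        env1k = synthetic_word_envelope(
            [w for conv in trial.conversations for w in conv],
            trial.duration_s, fs_hz=1000.0, rng=env_rng,
        )
        envmat = lagged_envelope_matrix(env1k, np.asarray(onsets))
        r = extract_lagged_word_responses(rec.data, onsets)
        common = np.intersect1d(envmat.word_indices, r.word_indices)
        env_rows = envmat.data[np.isin(envmat.word_indices, common)]
        resp_rows = r.data[np.isin(r.word_indices, common)]
        tensor = extract_word_embeddings([w.text for w in words], adapter)
        emb_rows = tensor.layer(layer)[common]
        feats_env.append(env_rows)
        feats_fused.append(np.concatenate([emb_rows, env_rows], axis=1))
        resp.append(resp_rows)

    t_env = fit_loto_brain_scores(
        feats_env, resp, ridge_cfg=ridge,
        metadata=dict(condition="attended", layer=layer, feature_set="envelope"),
    ).to_table()
    t_fused = fit_loto_brain_scores(
        feats_fused, resp, ridge_cfg=ridge,
        metadata=dict(condition="attended", layer=layer,
                      feature_set="embedding+envelope"),
    ).to_table()
    table = BrainScoreTable.concat([t_env, t_fused])
    comp = compare_scores(
        table, "feature_set", "embedding+envelope", "envelope",
        fixed=dict(condition="attended", layer=layer),
        name="embedding+envelope vs envelope-only (attended)",
    )
    return table, comp
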