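"""Experiment generator: structure, determinism, repeat logic, behaviour."""

import numpy as np
import pytest

from cocktail_ctx.embedding_context import SyntheticEmbeddingModel
from cocktail_ctx.synthetic_data import (
    ButtonPressLog,
    ExperimentConfig,
    ExperimentDataset,
    GroundTruth,
    dataset_from_tsv,
    dataset_to_tsv,
    generate_experiment,
    score_repeat_detection,
    simulate_button_presses,
    simulate_neural_recording,
)


def _repeat_gaps(dataset):
    gaps = []
    for trial in dataset.trials:
        for conv in trial.conversations:
            onsets = [w.onset_s for w in conv if w.is_repeat]
            gaps.extend(np.diff(onsets))
    return np.array(gaps)


class TestGenerateExperiment:
    def test_default_trial_count(self, default_dataset):
        assert len(default_dataset) == 25

    def test_infeasible_packing_raises(self):
        cfg = ExperimentConfig(
            n_trials=1, trial_duration_mean_s=5.0, trial_duration_sd_s=0.01,
            words_per_trial_mean=400.0, words_per_trial_sd=1.0,
        )
        with pytest.raises(ValueError, match="do not fit"):
            generate_experiment(cfg)

    def test_determinism_byte_identical(self, tmp_path):
        cfg = ExperimentConfig(n_trials=4, rng_seed=42)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        dataset_to_tsv(generate_experiment(cfg), p1)
        dataset_to_tsv(generate_experiment(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_words_sorted_nonoverlapping_within_bounds(self, default_dataset):
        for trial in default_dataset.trials:
            for conv in trial.conversations:
                onsets = np.array([w.onset_s for w in conv])
                offsets = np.array([w.offset_s for w in conv])
                assert np.all(np.diff(onsets) > 0)
                assert np.all(offsets[:-1] <= onsets[1:] + 1e-9)
                assert onsets[0] >= 0
                assert offsets[-1] <= trial.duration_s

    def test_switch_counts(self, default_dataset):
        for trial in default_dataset.trials:
            att = trial.attended_words
            un = trial.unattended_words
            n_att = sum(
                att[i].talker_id != att[i + 1].talker_id for i in range(len(att) - 1)
            )
            n_un = sum(
                un[i].talker_id != un[i + 1].talker_id for i in range(len(un) - 1)
            )
            assert n_att == 1
            assert n_un == 2

    def test_repeats_duplicate_previous_token(self, default_dataset):
        seen = 0
        for trial in default_dataset.trials:
            for conv in trial.conversations:
                for i, w in enumerate(conv):
                    if w.is_repeat:
                        assert i > 0
                        assert w.token_id == conv[i - 1].token_id
                        seen += 1
        assert seen > 50

    def test_repeats_never_overlap_across_streams(self, default_dataset):
        for trial in default_dataset.trials:
            r1 = [(w.onset_s, w.offset_s) for w in trial.conversations[0] if w.is_repeat]
            r2 = [(w.onset_s, w.offset_s) for w in trial.conversations[1] if w.is_repeat]
            for a0, a1 in r1:
                for b0, b1 in r2:
                    assert a1 <= b0 or b1 <= a0

    def test_repeat_gap_mean_near_configured(self):
        gaps = []
        for seed in range(3):
            ds = generate_experiment(ExperimentConfig(rng_seed=seed))
            gaps.append(_repeat_gaps(ds))
        gaps = np.concatenate(gaps)
        assert gaps.size >= 500
        se = gaps.std(ddof=1) / np.sqrt(gaps.size)
        assert abs(gaps.mean() - 7.0) < 3 * se + 0.05

    def test_too_dense_repeats_rejected(self):
        cfg = ExperimentConfig(n_trials=1, repeat_interval_mean_s=0.5)
        with pytest.raises(ValueError, match="repeat"):
            generate_experiment(cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ExperimentConfig(n_trials=0)
        with pytest.raises(ValueError):
            ExperimentConfig(attended_switch_fracs=(0.7, 0.3))
        with pytest.raises(ValueError):
            ExperimentConfig(vocab_size=1)

    def test_tsv_round_trip_preserves_words(self, small_dataset, tmp_path):
        path = tmp_path / "transcript.tsv"
        dataset_to_tsv(small_dataset, path)
        back = dataset_from_tsv(path)
        for t_in, t_out in zip(small_dataset.trials, back.trials):
            for c_in, c_out in zip(t_in.conversations, t_out.conversations):
                assert len(c_in) == len(c_out)
                for w_in, w_out in zip(c_in, c_out):
                    assert w_in.text == w_out.text
                    assert w_in.onset_s == pytest.approx(w_out.onset_s)
                    assert w_in.is_repeat == w_out.is_repeat


class TestSimulateNeuralRecording:
    def test_noiseless_forward_model_is_kernel_sum(self, small_dataset):
        dim = 32
        adapter = SyntheticEmbeddingModel.create(vocab_size=2000, dim=dim, seed=5)
        truth = GroundTruth.default(
            n_electrodes=4, dim=dim, seed=9, noise_sd=0.0, acoustic_gain_sd=0.0,
            g_unatt=0.0,
        )
        recs = simulate_neural_recording(small_dataset, truth, adapter)
        trial = small_dataset.trials[0]
        rec = recs[0]
        words = trial.attended_words
        tokens, spans = adapter.tokenize([w.text for w in words])
        layers = adapter.forward(
            tokens, visible_window=truth.true_context_len_att
        )
        emb = layers[-1][[s[-1] for s in spans]]
        expected = np.zeros_like(rec.data)
        for w, x in zip(words, emb):
            amp = truth.g_att * (truth.readout_weights @ x)
            i0 = int(round(w.onset_s * 100))
            k = truth.lag_kernel
            seg = slice(i0, min(i0 + k.size, expected.shape[1]))
            expected[:, seg] += np.outer(amp, k[: seg.stop - seg.start])
        np.testing.assert_allclose(rec.data, expected, atol=1e-10)

    def test_forward_model_linearity_in_weights(self, small_dataset, adapter):
        base = GroundTruth.default(
            n_electrodes=3, dim=32, seed=9, noise_sd=0.0, acoustic_gain_sd=0.0
        )
        doubled = GroundTruth(
            readout_weights=2.0 * base.readout_weights,
            acoustic_gain=base.acoustic_gain,
            noise_sd=0.0,
            rng_seed=base.rng_seed,
        )
        r1 = simulate_neural_recording(small_dataset, base, adapter)
        r2 = simulate_neural_recording(small_dataset, doubled, adapter)
        for a, b in zip(r1, r2):
            np.testing.assert_allclose(2.0 * a.data, b.data, atol=1e-10)

    def test_dim_mismatch_raises(self, small_dataset):
        adapter = SyntheticEmbeddingModel.create(vocab_size=2000, dim=16, seed=5)
        truth = GroundTruth.default(n_electrodes=3, dim=32, seed=9)
        with pytest.raises(ValueError, match="dim"):
            simulate_neural_recording(small_dataset, truth, adapter)

    def test_determinism(self, small_dataset, adapter):
        truth = GroundTruth.default(n_electrodes=3, dim=32, seed=9)
        r1 = simulate_neural_recording(small_dataset, truth, adapter)
        r2 = simulate_neural_recording(small_dataset, truth, adapter)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.data, b.data)


class TestBehaviour:
    def test_perfect_detection_presses_fixed_delay(self, small_dataset):
        log = simulate_button_presses(
            small_dataset, p_hit=1.0, p_false=0.0,
            reaction_s_mean=1.0, reaction_s_sd=0.0, seed=1,
        )
        for trial, presses in zip(small_dataset.trials, log.press_times_s):
            expected = sorted(
                w.onset_s + 1.0
                for w in trial.attended_words
                if w.is_repeat and w.onset_s + 1.0 <= trial.duration_s
            )
            assert list(presses) == pytest.approx(expected)

    def test_no_presses_when_probabilities_zero(self, small_dataset):
        log = simulate_button_presses(small_dataset, p_hit=0.0, p_false=0.0)
        assert all(len(p) == 0 for p in log.press_times_s)

    def test_hit_rate_matches_binomial(self):
        cfg = ExperimentConfig(n_trials=25, rng_seed=3)
        ds = generate_experiment(cfg)
        n_rep = sum(
            1 for t in ds.trials for w in t.attended_words if w.is_repeat
        )
        log = simulate_button_presses(
            ds, p_hit=0.7, p_false=0.0, reaction_s_mean=0.5,
            reaction_s_sd=0.0, seed=8,
        )
        n_press = sum(len(p) for p in log.press_times_s)
        se = np.sqrt(0.7 * 0.3 * n_rep)
        assert abs(n_press - 0.7 * n_rep) < 4 * se + 2

    def test_invalid_probability_raises(self, small_dataset):
        with pytest.raises(ValueError):
            simulate_button_presses(small_dataset, p_hit=1.4)

    def test_detection_window_boundary(self, small_dataset):
        trial = small_dataset.trials[0]
        repeats = [w for w in trial.attended_words if w.is_repeat]
        assert repeats
        inside = repeats[0].onset_s + 1.9
        outside = (repeats[1].onset_s + 2.1) if len(repeats) > 1 else None
        presses = [inside] + ([outside] if outside is not None else [])
        log = ButtonPressLog(
            press_times_s=tuple(
                tuple(sorted(presses)) if i == 0 else ()
                for i in range(len(small_dataset.trials))
            )
        )
        scores = score_repeat_detection(small_dataset, log)
        assert scores["attended"]["detected"] == 1

    def test_detection_rate_counting(self, small_dataset):
        log = simulate_button_presses(
            small_dataset, p_hit=1.0, p_false=0.0,
            reaction_s_mean=0.5, reaction_s_sd=0.0, seed=1,
        )
        scores = score_repeat_detection(small_dataset, log)
        assert scores["attended"]["rate"] == pytest.approx(1.0)
        assert scores["unattended"]["detected"] == 0

    def test_empty_inputs_zero_rate(self):
        ds = ExperimentDataset(config=ExperimentConfig(), trials=())
        scores = score_repeat_detection(ds, ButtonPressLog(press_times_s=()))
        assert scores["attended"]["rate"] == 0.0
        assert scores["attended"]["total"] == 0.0
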