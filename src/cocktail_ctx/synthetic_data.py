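"""Synthetic cocktail-party experiments with ground-truth neural readouts.

The generator emulates a dual-conversation auditory-attention paradigm: each
trial carries two simultaneous, independent conversations of word-annotated
speech.  The cued (attended) conversation contains a single talker switch at
~50% of the trial; the uncued one contains two switches at ~25% and ~75%.
Both streams embed occasional 1-back word repeats (a word re-uttered
immediately after itself) used for behavioural attention verification; repeat
events in the two streams never overlap in time.

Neural recordings are simulated as a linear readout of context-dependent word
representations: electrode ``e`` responds to each word with amplitude
``g_cond * (w_e . x_word)``, where ``x_word`` is the word's contextual
embedding computed over the stream's true context window (longer for the
attended stream), convolved with a 0-500 ms response kernel, plus a shared
acoustic-envelope component and Gaussian noise.  A ``raw`` mode wraps the same
envelope in a 70-150 Hz amplitude-modulated carrier with pink noise and 60-Hz
line contamination so the preprocessing chain can be validated end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "ExperimentConfig",
    "Word",
    "TrialSpec",
    "ExperimentDataset",
    "GroundTruth",
    "ButtonPressLog",
    "SimulatedRecording",
    "generate_experiment",
    "simulate_neural_recording",
    "simulate_button_presses",
    "score_repeat_detection",
    "synthetic_word_envelope",
    "dataset_to_tsv",
    "dataset_from_tsv",
    "recordings_to_hdf5",
    "recordings_from_hdf5",
]

#: word-duration log-normal: median 250 ms (the median word length used for the
#: fixed acoustic windows downstream), log-sd chosen for a natural spread
_WORD_DUR_MEDIAN_S = 0.250
_WORD_DUR_LOG_SD = 0.35
#: margin kept free at both ends of each conversation, seconds
_EDGE_MARGIN_S = 0.25
#: minimum spacing imposed between repeat events across the two streams
_REPEAT_GUARD_S = 0.25


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of the simulated experiment.

    Defaults reproduce the published paradigm: 25 trials of mean duration
    44.2 s (SD 2.0), 138 words per trial on average (SD 6.86, summed over the
    two conversations), repeat onsets ~7.0 s apart (SD 1.0) within a stream,
    one attended talker switch at 50% and two unattended switches at 25%/75%.
    """

    n_trials: int = 25
    trial_duration_mean_s: float = 44.2
    trial_duration_sd_s: float = 2.0
    words_per_trial_mean: float = 138.0
    words_per_trial_sd: float = 6.86
    repeat_interval_mean_s: float = 7.0
    repeat_interval_sd_s: float = 1.0
    attended_switch_fracs: tuple[float, ...] = (0.5,)
    unattended_switch_fracs: tuple[float, ...] = (0.25, 0.75)
    vocab_size: int = 2000
    n_talkers: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.trial_duration_mean_s <= 0 or self.trial_duration_sd_s < 0:
            raise ValueError("trial durations must be positive")
        if self.vocab_size < 2:
            raise ValueError("vocab_size must be >= 2")
        for fracs in (self.attended_switch_fracs, self.unattended_switch_fracs):
            arr = np.asarray(fracs, dtype=float)
            if arr.size and (
                np.any(arr <= 0) or np.any(arr >= 1) or np.any(np.diff(arr) <= 0)
            ):
                raise ValueError(
                    "switch fractions must be strictly increasing within (0, 1)"
                )
        if self.n_talkers < 2:
            raise ValueError("need at least two talkers")


@dataclass(frozen=True)
class Word:
    """One word event inside a conversation."""

    token_id: int
    text: str
    onset_s: float
    duration_s: float
    conversation_id: int
    talker_id: int
    is_repeat: bool = False

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class TrialSpec:
    """A trial: two word-annotated conversations plus attendance metadata."""

    trial_id: int
    duration_s: float
    conversations: tuple[tuple[Word, ...], tuple[Word, ...]]
    attended_conversation_id: int
    noise_condition: str

    def words(self, conversation_id: int) -> tuple[Word, ...]:
        if conversation_id not in (1, 2):
            raise ValueError("conversation_id must be 1 or 2")
        return self.conversations[conversation_id - 1]

    @property
    def attended_words(self) -> tuple[Word, ...]:
        return self.words(self.attended_conversation_id)

    @property
    def unattended_words(self) -> tuple[Word, ...]:
        return self.words(3 - self.attended_conversation_id)


@dataclass(frozen=True)
class ExperimentDataset:
    """All trials of one simulated experiment, with the generating config."""

    config: ExperimentConfig
    trials: tuple[TrialSpec, ...]

    def __len__(self) -> int:
        return len(self.trials)

    def stream_words(self, condition: Literal["attended", "unattended"]):
        """Per-trial word tuples for one attention condition."""
        attr = "attended_words" if condition == "attended" else "unattended_words"
        return [getattr(t, attr) for t in self.trials]


@dataclass(frozen=True)
class GroundTruth:
    """Forward-model parameters of the simulated neural readout.

    ``readout_weights`` (electrodes x embedding-dim) projects each word's
    contextual embedding onto electrode amplitudes; attended words are scaled
    by ``g_att``, unattended by ``g_unatt``.  ``true_context_len_att/unatt``
    are the context-window sizes (in tokens, current token included) at which
    the generating embeddings are computed — the attended stream integrates a
    longer context than the unattended one by default.  ``lag_kernel`` is the
    per-word response profile over 0-500 ms at 100 Hz.
    """

    readout_weights: np.ndarray
    g_att: float = 1.0
    g_unatt: float = 0.4
    true_context_len_att: int = 50
    true_context_len_unatt: int = 10
    lag_kernel: np.ndarray = field(
        default_factory=lambda: default_lag_kernel()
    )
    acoustic_gain: np.ndarray | None = None
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.readout_weights, dtype=float)
        object.__setattr__(self, "readout_weights", w)
        if w.ndim != 2:
            raise ValueError("readout_weights must be electrodes x dim")
        if not (self.g_att >= self.g_unatt >= 0):
            raise ValueError("expected g_att >= g_unatt >= 0")
        if not (self.true_context_len_att >= self.true_context_len_unatt >= 1):
            raise ValueError("expected K_att >= K_unatt >= 1")
        k = np.asarray(self.lag_kernel, dtype=float)
        object.__setattr__(self, "lag_kernel", k)
        if k.ndim != 1 or k.size > 51:
            raise ValueError("lag_kernel must be 1-D and supported on [0, 0.5] s")
        if self.acoustic_gain is None:
            object.__setattr__(self, "acoustic_gain", np.zeros(w.shape[0]))
        else:
            g = np.asarray(self.acoustic_gain, dtype=float)
            if g.shape != (w.shape[0],):
                raise ValueError("acoustic_gain must be one value per electrode")
            object.__setattr__(self, "acoustic_gain", g)

    @property
    def n_electrodes(self) -> int:
        return self.readout_weights.shape[0]

    @property
    def dim(self) -> int:
        return self.readout_weights.shape[1]

    @classmethod
    def default(
        cls,
        n_electrodes: int = 100,
        dim: int = 64,
        seed: int = 0,
        acoustic_gain_sd: float = 0.3,
        **kwargs,
    ) -> "GroundTruth":
        rng = np.random.default_rng(seed)
        w = rng.standard_normal((n_electrodes, dim))
        gain = acoustic_gain_sd * rng.standard_normal(n_electrodes)
        return cls(readout_weights=w, acoustic_gain=gain, rng_seed=seed, **kwargs)


def default_lag_kernel(fs_hz: float = 100.0) -> np.ndarray:
    """Hann-shaped word-response profile over 0-400 ms, peak amplitude 1."""
    n = int(round(0.4 * fs_hz)) + 1
    return np.hanning(n + 2)[1:-1]


@dataclass(frozen=True)
class ButtonPressLog:
    """Button-press times per trial, seconds from trial start, sorted."""

    press_times_s: tuple[tuple[float, ...], ...]

    def for_trial(self, index: int) -> tuple[float, ...]:
        return self.press_times_s[index]


@dataclass(frozen=True)
class SimulatedRecording:
    """One trial's simulated electrode signals.

    ``data`` is electrodes x samples at ``fs_hz``.  For raw mode,
    ``modulator`` holds the generating high-gamma envelope (electrodes x
    samples at 100 Hz) that amplitude-modulated the carrier, used as the
    oracle when validating the preprocessing chain.
    """

    trial_id: int
    data: np.ndarray
    fs_hz: float
    mode: str
    modulator: np.ndarray | None = None


# ---------------------------------------------------------------------------
# experiment generation
# ---------------------------------------------------------------------------

_NOISE_CONDITIONS = ("babble-9", "babble-12", "pedestrian-9", "pedestrian-12")


def _tile_conversation(
    rng: np.random.Generator,
    n_words: int,
    duration_s: float,
    start_s: float,
    conversation_id: int,
    talkers: Sequence[int],
    switch_fracs: Sequence[float],
    vocab_size: int,
) -> list[Word]:
    """Place ``n_words`` non-overlapping words between start_s and the trial end.

    Word durations are log-normal (median 250 ms); inter-word gaps are drawn
    exponential and linearly rescaled so the requested count packs exactly
    into the available span.  Raises if the words alone cannot fit.
    """
    durs = _WORD_DUR_MEDIAN_S * np.exp(
        _WORD_DUR_LOG_SD * rng.standard_normal(n_words)
    )
    available = duration_s - start_s - _EDGE_MARGIN_S
    total_speech = float(np.sum(durs))
    if total_speech >= available:
        raise ValueError(
            f"{n_words} words (total speech {total_speech:.1f} s) do not fit in "
            f"{available:.1f} s of conversation time"
        )
    gaps = rng.exponential(1.0, size=n_words)
    gaps[0] *= 0.25  # shorter lead-in before the first word
    gaps *= (available - total_speech) / float(np.sum(gaps))
    onsets = start_s + np.cumsum(gaps) + np.concatenate(([0.0], np.cumsum(durs[:-1])))

    switch_times = [f * duration_s for f in switch_fracs]
    tokens = rng.integers(0, vocab_size, size=n_words)
    words = []
    for i in range(n_words):
        seg = int(np.searchsorted(switch_times, onsets[i], side="right"))
        talker = talkers[seg % 2]  # two talkers alternate across segments
        tok = int(tokens[i])
        words.append(
            Word(
                token_id=tok,
                text=f"w{tok:04d}",
                onset_s=float(onsets[i]),
                duration_s=float(durs[i]),
                conversation_id=conversation_id,
                talker_id=int(talker),
                is_repeat=False,
            )
        )
    return words


def _insert_repeats(
    rng: np.random.Generator,
    words: list[Word],
    blocked: list[tuple[float, float]],
    mean_s: float,
    sd_s: float,
) -> list[Word]:
    """Turn selected words into 1-back repeats with ~N(mean, sd) onset gaps.

    A repeat duplicates the token of the immediately preceding word in the
    same conversation.  Candidate words overlapping a blocked interval (a
    repeat already placed in the other conversation, with a guard margin) are
    skipped; candidates are chosen nearest the target onset so the realised
    gap distribution stays centred on the configured mean.
    """
    if len(words) < 3:
        return words
    onsets = np.array([w.onset_s for w in words])
    mean_spacing = float(np.mean(np.diff(onsets)))
    if mean_s < 3.0 * mean_spacing:
        raise ValueError(
            "repeat_interval_mean_s implies more repeat events than words fit"
        )
    out = list(words)
    prev_onset = float(onsets[0])
    while True:
        target = prev_onset + rng.normal(mean_s, sd_s)
        if target > onsets[-1]:
            break
        order = np.argsort(np.abs(onsets - target))
        placed = False
        for idx in order:
            i = int(idx)
            if i == 0 or out[i].is_repeat or out[i - 1].is_repeat:
                continue
            if out[i].onset_s <= prev_onset + 2.0:
                continue
            lo = out[i].onset_s - _REPEAT_GUARD_S
            hi = out[i].offset_s + _REPEAT_GUARD_S
            if any(b0 < hi and b1 > lo for b0, b1 in blocked):
                continue
            prev = out[i - 1]
            out[i] = replace(
                out[i], token_id=prev.token_id, text=prev.text, is_repeat=True
            )
            blocked.append((out[i].onset_s, out[i].offset_s))
            prev_onset = out[i].onset_s
            placed = True
            break
        if not placed:
            prev_onset = target  # no eligible word near the target; move on
    return out


def generate_experiment(config: ExperimentConfig | None = None) -> ExperimentDataset:
    """Generate a full multi-trial cocktail-party experiment.

    Fully reproducible from ``config.rng_seed``.  Per trial the word count is
    drawn around ``words_per_trial_mean`` (split between the two
    conversations), the duration around ``trial_duration_mean_s``; the
    attended conversation begins first and carries one talker switch, the
    unattended conversation two.
    """
    if config is None:
        config = ExperimentConfig()
    rng = np.random.default_rng(config.rng_seed)
    trials = []
    for trial_id in range(config.n_trials):
        duration = float(
            max(
                rng.normal(config.trial_duration_mean_s, config.trial_duration_sd_s),
                0.25 * config.trial_duration_mean_s,
            )
        )
        n_total = int(
            max(
                round(rng.normal(config.words_per_trial_mean, config.words_per_trial_sd)),
                4,
            )
        )
        n_att = n_total // 2 + int(rng.integers(0, 2)) * (n_total % 2)
        n_unatt = n_total - n_att

        attended_id = int(rng.integers(1, 3))
        talker_pool = rng.choice(config.n_talkers, size=4, replace=False)
        start_att = float(rng.uniform(0.25, 0.75))
        start_unatt = start_att + float(rng.uniform(0.5, 1.5))

        att_words = _tile_conversation(
            rng, n_att, duration, start_att, attended_id,
            talker_pool[:2], config.attended_switch_fracs, config.vocab_size,
        )
        unatt_words = _tile_conversation(
            rng, n_unatt, duration, start_unatt, 3 - attended_id,
            talker_pool[2:], config.unattended_switch_fracs, config.vocab_size,
        )

        blocked: list[tuple[float, float]] = []
        att_words = _insert_repeats(
            rng, att_words, blocked,
            config.repeat_interval_mean_s, config.repeat_interval_sd_s,
        )
        unatt_words = _insert_repeats(
            rng, unatt_words, blocked,
            config.repeat_interval_mean_s, config.repeat_interval_sd_s,
        )

        convs = (
            tuple(att_words if attended_id == 1 else unatt_words),
            tuple(unatt_words if attended_id == 1 else att_words),
        )
        trials.append(
            TrialSpec(
                trial_id=trial_id,
                duration_s=duration,
                conversations=convs,
                attended_conversation_id=attended_id,
                noise_condition=_NOISE_CONDITIONS[trial_id % 4],
            )
        )
    return ExperimentDataset(config=config, trials=tuple(trials))


# ---------------------------------------------------------------------------
# acoustic word envelope (simulation-side)
# ---------------------------------------------------------------------------

def synthetic_word_envelope(
    words: Iterable[Word],
    duration_s: float,
    fs_hz: float = 100.0,
    rng: np.random.Generator | None = None,
    amplitude_jitter: float = 0.25,
    smooth_ms: float = 20.0,
) -> np.ndarray:
    """Word-shaped speech envelope: smoothed rectangular pulse per word.

    Stands in for the auditory-spectrogram envelope when no audio waveform
    exists (the generator works at the text/timing level).  Pulse amplitudes
    are jittered around 1 to mimic natural intensity variation.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = int(round(duration_s * fs_hz))
    env = np.zeros(n)
    for w in words:
        a = max(1.0 + amplitude_jitter * rng.standard_normal(), 0.1)
        i0 = int(round(w.onset_s * fs_hz))
        i1 = min(int(round(w.offset_s * fs_hz)), n)
        env[i0:i1] = np.maximum(env[i0:i1], a)
    m = max(int(round(smooth_ms * 1e-3 * fs_hz)), 1)
    win = np.hanning(2 * m + 1)
    win /= win.sum()
    return np.convolve(env, win, mode="same")


# ---------------------------------------------------------------------------
# neural simulation
# ---------------------------------------------------------------------------

def _stream_embeddings(embed_model, words: Sequence[Word], window: int) -> np.ndarray:
    """Top-layer embeddings of a word stream at a fixed context window."""
    tokens, word_to_token = embed_model.tokenize([w.text for w in words])
    layers = embed_model.forward(tokens, visible_window=window)
    last_tok = [span[-1] for span in word_to_token]
    return layers[-1][last_tok]  # words x dim


def _envelope_signal(
    trial: TrialSpec,
    truth: GroundTruth,
    embed_model,
    rng: np.random.Generator,
    fs_hz: float = 100.0,
    with_noise: bool = True,
) -> np.ndarray:
    n = int(round(trial.duration_s * fs_hz))
    sig = np.zeros((truth.n_electrodes, n))
    kernel = truth.lag_kernel
    for cond, gain, window in (
        ("attended", truth.g_att, truth.true_context_len_att),
        ("unattended", truth.g_unatt, truth.true_context_len_unatt),
    ):
        words = trial.attended_words if cond == "attended" else trial.unattended_words
        if not words:
            continue
        emb = _stream_embeddings(embed_model, words, window)
        if emb.shape[1] != truth.dim:
            raise ValueError(
                f"embedding dim {emb.shape[1]} does not match readout dim {truth.dim}"
            )
        amps = gain * (emb @ truth.readout_weights.T)  # words x electrodes
        for w, a in zip(words, amps):
            i0 = int(round(w.onset_s * fs_hz))
            seg = slice(i0, min(i0 + kernel.size, n))
            sig[:, seg] += np.outer(a, kernel[: seg.stop - seg.start])
    env = synthetic_word_envelope(
        [w for conv in trial.conversations for w in conv],
        trial.duration_s, fs_hz, rng,
    )
    sig += np.outer(truth.acoustic_gain, env)
    if with_noise and truth.noise_sd > 0:
        sig += truth.noise_sd * rng.standard_normal(sig.shape)
    return sig


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-power noise, unit variance, per channel."""
    n = shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (
        rng.standard_normal((shape[0], freqs.size))
        + 1j * rng.standard_normal((shape[0], freqs.size))
    ) * scale
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_neural_recording(
    dataset: ExperimentDataset,
    truth: GroundTruth,
    embed_model,
    mode: Literal["envelope", "raw"] = "envelope",
    raw_fs_hz: float = 1000.0,
    pink_noise_sd: float = 0.4,
    line_amplitude: float = 2.0,
) -> list[SimulatedRecording]:
    """Simulate every trial's electrode signals under the forward model.

    ``envelope`` mode returns the 100-Hz high-gamma amplitude directly (the
    linear word readout plus acoustic component and Gaussian noise).  ``raw``
    mode returns a 1000-Hz broadband signal whose 70-150 Hz band is
    amplitude-modulated by that same envelope, plus pink noise and a 60-Hz
    line tone, for validating the preprocessing chain; the per-electrode
    modulator is attached as the recovery oracle.
    """
    if mode not in ("envelope", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(truth.rng_seed)
    out = []
    for trial in dataset.trials:
        env = _envelope_signal(trial, truth, embed_model, rng)
        if mode == "envelope":
            out.append(SimulatedRecording(trial.trial_id, env, 100.0, mode))
            continue
        # positive, band-limited modulator: the amplitude of band-passed
        # noise can only be tracked at the sub-band envelope bandwidth, so
        # the generating envelope is low-passed (5 Hz) before modulating,
        # then shifted well above zero
        sos_lp = sps.butter(4, 3.0, btype="lowpass", fs=100.0, output="sos")
        smooth = sps.sosfiltfilt(sos_lp, env, axis=1)
        sd = smooth.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        mod = np.maximum(
            smooth - smooth.mean(axis=1, keepdims=True) + 2.0 * sd, 0.05 * sd
        )
        up = int(round(raw_fs_hz / 100.0))
        n_raw = mod.shape[1] * up
        mod_raw = np.maximum(sps.resample_poly(mod, up, 1, axis=1)[:, :n_raw], 0.0)
        carrier = rng.standard_normal((truth.n_electrodes, n_raw))
        sos = sps.butter(4, [70, 150], btype="bandpass", fs=raw_fs_hz, output="sos")
        carrier = sps.sosfiltfilt(sos, carrier, axis=1)
        carrier /= carrier.std(axis=1, keepdims=True)
        t = np.arange(n_raw) / raw_fs_hz
        raw = (
            mod_raw * carrier
            + pink_noise_sd * float(np.mean(mod)) * _pink_noise(rng, (truth.n_electrodes, n_raw))
            + line_amplitude * float(np.mean(mod)) * np.sin(2 * np.pi * 60.0 * t)
        )
        out.append(SimulatedRecording(trial.trial_id, raw, raw_fs_hz, mode, modulator=mod))
    return out


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def simulate_button_presses(
    dataset: ExperimentDataset,
    p_hit: float = 0.7,
    p_false: float = 0.05,
    reaction_s_mean: float = 0.9,
    reaction_s_sd: float = 0.25,
    seed: int = 0,
) -> ButtonPressLog:
    """Simulate 1-back detection presses.

    Each attended-stream repeat elicits a press with probability ``p_hit`` at
    onset plus a (truncated-at-zero) Gaussian reaction delay; unattended
    repeats elicit presses with probability ``p_false`` — the paper-style
    signature of occasional attention drift to the uncued stream.
    """
    for name, p in (("p_hit", p_hit), ("p_false", p_false)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    logs = []
    for trial in dataset.trials:
        presses = []
        for words, p in (
            (trial.attended_words, p_hit),
            (trial.unattended_words, p_false),
        ):
            for w in words:
                if w.is_repeat and rng.random() < p:
                    delay = max(rng.normal(reaction_s_mean, reaction_s_sd), 0.0)
                    t = w.onset_s + delay
                    if t <= trial.duration_s:
                        presses.append(t)
        logs.append(tuple(sorted(presses)))
    return ButtonPressLog(press_times_s=tuple(logs))


def score_repeat_detection(
    dataset: ExperimentDataset,
    presses: ButtonPressLog,
    window_s: float = 2.0,
) -> dict[str, dict[str, float]]:
    """Score 1-back detection: a repeat counts as detected iff a press falls
    within ``window_s`` of its onset; each press is credited to at most one
    repeat (shortest press-to-onset delay first, so a press is attributed to
    its most plausible cause when windows of the two streams overlap)."""
    counts = {"attended": [0, 0], "unattended": [0, 0]}
    for trial, trial_presses in zip(dataset.trials, presses.press_times_s):
        events = []
        for role, words in (
            ("attended", trial.attended_words),
            ("unattended", trial.unattended_words),
        ):
            for w in words:
                if w.is_repeat:
                    counts[role][1] += 1
                    events.append((w.onset_s, role, len(events)))
        pairs = [
            (t - onset, ev_idx, j)
            for onset, _, ev_idx in events
            for j, t in enumerate(trial_presses)
            if 0.0 <= t - onset <= window_s
        ]
        used_ev: set[int] = set()
        used_press: set[int] = set()
        for delay, ev_idx, j in sorted(pairs):
            if ev_idx in used_ev or j in used_press:
                continue
            used_ev.add(ev_idx)
            used_press.add(j)
            counts[events[ev_idx][1]][0] += 1
    out = {}
    for role, (det, tot) in counts.items():
        out[role] = {
            "detected": float(det),
            "total": float(tot),
            "rate": det / tot if tot else 0.0,
        }
    return out


# ---------------------------------------------------------------------------
# I/O: transcript TSV, recordings HDF5, press-log JSON
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "trial_id", "conversation_id", "talker_id", "token",
    "onset_s", "duration_s", "is_repeat",
]


def dataset_to_tsv(dataset: ExperimentDataset, path: str | Path) -> None:
    """Write the word-level transcript table (UTF-8, tab-separated)."""
    rows = []
    for trial in dataset.trials:
        for conv in trial.conversations:
            for w in conv:
                rows.append(
                    (trial.trial_id, w.conversation_id, w.talker_id, w.text,
                     w.onset_s, w.duration_s, int(w.is_repeat))
                )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def dataset_from_tsv(
    path: str | Path,
    trial_durations_s: Mapping[int, float] | None = None,
    attended_ids: Mapping[int, int] | None = None,
) -> ExperimentDataset:
    """Rebuild a word-level dataset from a transcript TSV.

    Durations and attendance labels are not part of the transcript table; when
    not supplied, each trial's duration is taken as the last word offset plus
    an edge margin and conversation 1 is assumed attended.
    """
    df = pd.read_csv(path, sep="\t")
    trials = []
    for trial_id, tdf in df.groupby("trial_id"):
        convs: list[tuple[Word, ...]] = []
        for cid in (1, 2):
            cdf = tdf[tdf.conversation_id == cid].sort_values("onset_s")
            words = tuple(
                Word(
                    token_id=int(r.token[1:]) if str(r.token).startswith("w")
                    and str(r.token)[1:].isdigit() else hash(r.token) % (2**31),
                    text=str(r.token),
                    onset_s=float(r.onset_s),
                    duration_s=float(r.duration_s),
                    conversation_id=cid,
                    talker_id=int(r.talker_id),
                    is_repeat=bool(r.is_repeat),
                )
                for r in cdf.itertuples()
            )
            convs.append(words)
        dur = (
            trial_durations_s[int(trial_id)]
            if trial_durations_s is not None
            else max(w.offset_s for c in convs for w in c) + _EDGE_MARGIN_S
        )
        att = attended_ids[int(trial_id)] if attended_ids is not None else 1
        trials.append(
            TrialSpec(
                trial_id=int(trial_id),
                duration_s=float(dur),
                conversations=(convs[0], convs[1]),
                attended_conversation_id=int(att),
                noise_condition=_NOISE_CONDITIONS[int(trial_id) % 4],
            )
        )
    cfg = ExperimentConfig(n_trials=max(len(trials), 1))
    return ExperimentDataset(config=cfg, trials=tuple(trials))


def recordings_to_hdf5(
    recordings: Sequence[SimulatedRecording],
    path: str | Path,
    labels: Sequence[str] | None = None,
) -> None:
    """Persist recordings as /trials/<id>/data with fs_hz and mode attrs."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("trials")
        for rec in recordings:
            g = grp.create_group(str(rec.trial_id))
            g.create_dataset("data", data=rec.data)
            g.attrs["fs_hz"] = rec.fs_hz
            g.attrs["mode"] = rec.mode
            if rec.modulator is not None:
                g.create_dataset("modulator", data=rec.modulator)
        if labels is None and recordings:
            labels = [f"E{i:03d}" for i in range(recordings[0].data.shape[0])]
        if labels is not None:
            f.create_dataset(
                "electrode_labels",
                data=np.array(labels, dtype=h5py.string_dtype()),
            )


def recordings_from_hdf5(path: str | Path) -> list[SimulatedRecording]:
    out = []
    with h5py.File(path, "r") as f:
        for tid in sorted(f["trials"], key=int):
            g = f["trials"][tid]
            out.append(
                SimulatedRecording(
                    trial_id=int(tid),
                    data=g["data"][()],
                    fs_hz=float(g.attrs["fs_hz"]),
                    mode=str(g.attrs["mode"]),
                    modulator=g["modulator"][()] if "modulator" in g else None,
                )
            )
    return out


def presses_to_json(presses: ButtonPressLog, path: str | Path) -> None:
    payload = {str(i): list(p) for i, p in enumerate(presses.press_times_s)}
    Path(path).write_text(json.dumps(payload, indent=1))


def presses_from_json(path: str | Path) -> ButtonPressLog:
    payload = json.loads(Path(path).read_text())
    keys = sorted(payload, key=int)
    return ButtonPressLog(tuple(tuple(payload[k]) for k in keys))
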