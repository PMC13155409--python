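"""Auditory-spectrogram speech envelope and per-word lagged-envelope features.

The spectrogram follows the classic cochlear-model stages: a bank of 128
logarithmically spaced constant-Q filters (~180 Hz - 7 kHz), hair-cell
transduction (half-wave rectification and a low-pass membrane filter),
cube-root intensity compression, a lateral inhibitory network along the
spectral axis (first spectral difference, half-wave rectified), and short
temporal integration to 1000-Hz frames.  Averaging the spectrogram across
frequency gives a one-dimensional speech envelope.

For each word, the control feature is a lagged-envelope matrix: seven 250-ms
windows (the median word length) cut from the envelope starting at the word
onset with a 50-ms stride, concatenated into one 1750-sample row.  The
1000-Hz frame rate makes each window exactly 250 samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

logger = logging.getLogger(__name__)

__all__ = [
    "AuditorySpectrogram",
    "WordEnvelopeMatrix",
    "auditory_spectrogram",
    "spectrogram_to_envelope",
    "lagged_envelope_matrix",
    "read_wav_mono",
]

_N_CHANNELS = 128
_F_LO_HZ = 180.0
_F_HI_HZ = 7000.0
_FRAME_RATE_HZ = 1000.0
_HAIRCELL_LP_HZ = 2000.0
_INTEGRATION_MS = 8.0


@dataclass(frozen=True)
class AuditorySpectrogram:
    """128-channel nonnegative time-frequency representation."""

    data: np.ndarray  # channels x frames
    frame_rate_hz: float
    center_freqs_hz: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        f = np.asarray(self.center_freqs_hz, dtype=float)
        object.__setattr__(self, "center_freqs_hz", f)
        if d.shape[0] != f.size:
            raise ValueError("one centre frequency per channel required")
        if np.any(np.diff(f) <= 0):
            raise ValueError("centre frequencies must be increasing")


@dataclass(frozen=True)
class WordEnvelopeMatrix:
    """Per-word lagged envelope windows, words x (n_lags * T_env)."""

    data: np.ndarray
    word_indices: np.ndarray  # indices into the input word list that were kept
    env_fs_hz: float = 1000.0
    window_ms: float = 250.0
    stride_ms: float = 50.0
    n_lags: int = 7

    @property
    def n_words(self) -> int:
        return self.data.shape[0]

    @property
    def samples_per_window(self) -> int:
        return int(round(self.window_ms * 1e-3 * self.env_fs_hz))


def _cochlear_centers() -> np.ndarray:
    """128 log-spaced centres (constant ratio between neighbours)."""
    return np.geomspace(_F_LO_HZ, _F_HI_HZ, _N_CHANNELS)


def read_wav_mono(path: str | Path) -> tuple[np.ndarray, float]:
    """Load a PCM WAV file as float mono in [-1, 1]."""
    fs, data = wavfile.read(path)
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.max(np.abs(data)) > 0:
        data = data / np.max(np.abs(data))
    return data, float(fs)


def auditory_spectrogram(
    audio: np.ndarray,
    fs: float,
    q_factor: float = 8.0,
    return_stages: bool = False,
) -> AuditorySpectrogram | tuple[AuditorySpectrogram, dict[str, np.ndarray]]:
    """Cochlear-model auditory spectrogram at 1000-Hz frames.

    Stages, in order: constant-Q band-pass filterbank (frequency-domain
    Gaussian magnitude windows of bandwidth ``f_c / q_factor``), half-wave
    rectification plus hair-cell low-pass, cube-root compression, lateral
    inhibition (rectified first difference across channels), and short-window
    temporal integration down to 1000-Hz frames.

    With ``return_stages`` the pre-inhibition (compressed) representation is
    returned alongside, which scales as ``amplitude**(1/3)``.
    """
    audio = np.asarray(audio, dtype=float).ravel()
    if fs < 8000:
        raise ValueError("audio sampling rate must be at least 8 kHz")
    centers = _cochlear_centers()
    n = audio.size
    if n == 0:
        empty = np.zeros((_N_CHANNELS, 0))
        spec = AuditorySpectrogram(empty, _FRAME_RATE_HZ, centers)
        return (spec, {"compressed": empty}) if return_stages else spec

    spectrum = np.fft.rfft(audio)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # hair-cell membrane low-pass (first-order) applied in the same pass
    lp = 1.0 / np.sqrt(1.0 + (freqs / _HAIRCELL_LP_HZ) ** 2)

    band = np.empty((_N_CHANNELS, n))
    for k, fc in enumerate(centers):
        sigma = fc / q_factor
        win = np.exp(-0.5 * ((freqs - fc) / sigma) ** 2)
        band[k] = np.fft.irfft(spectrum * win, n=n)
    # hair cell: half-wave rectify, then low-pass the rectified signal
    rect = np.maximum(band, 0.0)
    rect_spec = np.fft.rfft(rect, axis=-1)
    rect = np.fft.irfft(rect_spec * lp, n=n, axis=-1)
    rect = np.maximum(rect, 0.0)
    compressed = np.cbrt(rect)
    # lateral inhibitory network: rectified first difference along frequency
    lin = np.maximum(np.diff(compressed, axis=0, prepend=compressed[:1]), 0.0)
    # temporal integration and frame decimation
    width = max(int(round(_INTEGRATION_MS * 1e-3 * fs)), 1)
    kernel = np.ones(width) / width
    integrated = sps.fftconvolve(lin, kernel[None, :], mode="same", axes=-1)
    n_frames = int(round(n / fs * _FRAME_RATE_HZ))
    idx = np.minimum((np.arange(n_frames) / _FRAME_RATE_HZ * fs).astype(int), n - 1)
    frames = np.maximum(integrated[:, idx], 0.0)
    spec = AuditorySpectrogram(frames, _FRAME_RATE_HZ, centers)
    if return_stages:
        return spec, {"compressed": compressed, "filterbank": band}
    return spec


def spectrogram_to_envelope(spec: AuditorySpectrogram) -> np.ndarray:
    """Frequency-average the spectrogram into a 1-D speech envelope."""
    return spec.data.mean(axis=0)


def lagged_envelope_matrix(
    envelope: np.ndarray,
    word_onsets_s: np.ndarray,
    env_fs_hz: float = 1000.0,
    window_ms: float = 250.0,
    stride_ms: float = 50.0,
    n_lags: int = 7,
) -> WordEnvelopeMatrix:
    """Cut the per-word lagged envelope windows.

    For each onset, ``n_lags`` windows of ``window_ms`` starting at
    onset + {0, stride, ..., (n_lags-1)*stride} are concatenated into one row.
    Words whose last window would run past the envelope are dropped with a
    warning; windows are cut from the continuous envelope and may overlap
    neighbouring words.
    """
    envelope = np.asarray(envelope, dtype=float).ravel()
    onsets = np.asarray(word_onsets_s, dtype=float).ravel()
    t = int(round(window_ms * 1e-3 * env_fs_hz))
    stride = int(round(stride_ms * 1e-3 * env_fs_hz))
    span = (n_lags - 1) * stride + t
    rows, kept, dropped = [], [], []
    for i, onset in enumerate(onsets):
        i0 = int(round(onset * env_fs_hz))
        if i0 < 0 or i0 + span > envelope.size:
            dropped.append(i)
            continue
        row = np.concatenate(
            [envelope[i0 + k * stride : i0 + k * stride + t] for k in range(n_lags)]
        )
        rows.append(row)
        kept.append(i)
    if dropped:
        logger.warning(
            "dropped %d word(s) whose lag windows exceed the envelope: %s",
            len(dropped), dropped,
        )
    data = np.array(rows) if rows else np.zeros((0, n_lags * t))
    return WordEnvelopeMatrix(
        data=data,
        word_indices=np.array(kept, dtype=int),
        env_fs_hz=env_fs_hz,
        window_ms=window_ms,
        stride_ms=stride_ms,
        n_lags=n_lags,
    )
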