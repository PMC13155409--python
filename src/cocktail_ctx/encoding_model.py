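"""Ridge encoding models from word features to lagged neural responses.

For every word, the neural target is the high-gamma envelope averaged in
seven 200-ms windows starting at word onset with a 50-ms stride (a 500-ms
span).  Per electrode, a multi-output ridge regression maps word features
(embeddings, lagged envelopes, or their concatenation) to the seven lag
targets jointly, under leave-one-trial-out (LOTO) cross-validation:
the regularization strength is chosen per electrode by an inner LOTO sweep
over the training trials, the model is refit on all training trials, and the
held-out trial is scored by the Pearson correlation between predicted and
actual responses across its words ("brain score"), averaged over lags, then
over trials.

The fitter works from per-trial sufficient statistics (Gram and
cross-product matrices), so the nested cross-validation costs one
eigendecomposition and a few matrix products per fold regardless of the
total word count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cocktail_ctx.acoustic_features import WordEnvelopeMatrix
from cocktail_ctx.embedding_context import EmbeddingTensor
from cocktail_ctx.neural_preprocess import HighGammaEnvelope

logger = logging.getLogger(__name__)

__all__ = [
    "LagConfig",
    "RidgeConfig",
    "FilterOptions",
    "WordResponseMatrix",
    "BrainScoreTable",
    "FitResult",
    "extract_lagged_word_responses",
    "ridge_closed_form",
    "fit_loto_brain_scores",
    "combine_features",
]


@dataclass(frozen=True)
class LagConfig:
    """Lagged word-response windows: seven 200-ms frames, 50-ms stride,
    spanning 500 ms post word onset."""

    window_ms: float = 200.0
    n_lags: int = 7
    stride_ms: float = 50.0

    @property
    def span_ms(self) -> float:
        return (self.n_lags - 1) * self.stride_ms + self.window_ms


@dataclass(frozen=True)
class RidgeConfig:
    """Regularization sweep and conditioning choices for the LOTO fit."""

    lambda_grid: tuple[float, ...] = tuple(np.logspace(-2, 4, 13))
    standardize: bool = True
    score_mode: str = "lag_mean"  # lag_mean | concat

    def __post_init__(self) -> None:
        grid = tuple(float(v) for v in self.lambda_grid)
        object.__setattr__(self, "lambda_grid", grid)
        if any(v <= 0 for v in grid) or any(
            b <= a for a, b in zip(grid, grid[1:])
        ):
            raise ValueError("lambda_grid must be positive and increasing")
        if self.score_mode not in ("lag_mean", "concat"):
            raise ValueError("score_mode must be 'lag_mean' or 'concat'")


@dataclass(frozen=True)
class FilterOptions:
    """Optional robustness filters applied identically to features and
    responses: drop 1-back repeat words, and drop trials in which the subject
    (or simulated subject) responded to unattended-stream repeats."""

    exclude_repeated_words: bool = False
    exclude_trials_with_unattended_detections: bool = False


@dataclass(frozen=True)
class WordResponseMatrix:
    """Per-word lagged neural targets: words x electrodes x n_lags."""

    data: np.ndarray
    word_indices: np.ndarray
    lag_config: LagConfig = field(default_factory=LagConfig)

    @property
    def n_words(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]


def extract_lagged_word_responses(
    hg: HighGammaEnvelope | np.ndarray,
    word_onsets_s: Sequence[float],
    lag_cfg: LagConfig | None = None,
    fs_hz: float = 100.0,
) -> WordResponseMatrix:
    """Average the 100-Hz high-gamma envelope in each word's lag windows.

    Entry (w, e, k) is the mean of electrode ``e`` over
    [onset_w + k*stride, onset_w + k*stride + window); at 100 Hz each 200-ms
    window averages 20 samples.  Words whose 500-ms span runs past the
    envelope are dropped with a warning.  ``hg`` may be a
    :class:`HighGammaEnvelope` or a plain electrodes x samples array at
    ``fs_hz`` (simulated envelope-mode signals fluctuate around a baseline
    and may be signed).
    """
    if lag_cfg is None:
        lag_cfg = LagConfig()
    onsets = np.asarray(list(word_onsets_s), dtype=float)
    if onsets.size == 0:
        raise ValueError("empty word list")
    if isinstance(hg, HighGammaEnvelope):
        signal, fs = hg.data, hg.fs_hz
    else:
        signal, fs = np.atleast_2d(np.asarray(hg, dtype=float)), fs_hz
    win = int(round(lag_cfg.window_ms * 1e-3 * fs))
    stride = int(round(lag_cfg.stride_ms * 1e-3 * fs))
    span = (lag_cfg.n_lags - 1) * stride + win
    n = signal.shape[1]
    rows, kept, dropped = [], [], []
    for i, onset in enumerate(onsets):
        i0 = int(round(onset * fs))
        if i0 < 0 or i0 + span > n:
            dropped.append(i)
            continue
        lags = np.stack(
            [
                signal[:, i0 + k * stride : i0 + k * stride + win].mean(axis=1)
                for k in range(lag_cfg.n_lags)
            ],
            axis=1,
        )  # electrodes x n_lags
        rows.append(lags)
        kept.append(i)
    if dropped:
        logger.warning(
            "dropped %d word(s) whose 500-ms span exceeds the envelope", len(dropped)
        )
    data = (
        np.stack(rows)
        if rows
        else np.zeros((0, signal.shape[0], lag_cfg.n_lags))
    )
    return WordResponseMatrix(
        data=data, word_indices=np.array(kept, dtype=int), lag_config=lag_cfg
    )


def ridge_closed_form(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge weights ``(X'X + lam I)^-1 X'Y``.

    The bare solver: no centering or scaling is applied here — the
    cross-validated fitter owns standardization (and the intercept, via
    centering) so that train-fold statistics never touch test rows.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("degenerate design matrix")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    if lam <= 0:
        raise ValueError("lam must be positive")
    p = X.shape[1]
    return np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ Y)


def combine_features(
    embeddings: EmbeddingTensor | np.ndarray,
    envmat: WordEnvelopeMatrix,
    layer: int | None = None,
) -> np.ndarray:
    """Concatenate embedding and lagged-envelope features row-wise.

    Width is ``D + n_lags * T_env``.  Word alignment is verified: counts must
    match, and when both sides carry word indices they must agree.
    """
    if isinstance(embeddings, EmbeddingTensor):
        if layer is None:
            raise ValueError("specify the embedding layer to fuse")
        emb = embeddings.layer(layer)
        emb_idx = embeddings.word_indices
    else:
        emb = np.atleast_2d(np.asarray(embeddings, dtype=float))
        emb_idx = None
    if emb.shape[0] != envmat.data.shape[0]:
        raise ValueError(
            f"word count mismatch: {emb.shape[0]} embeddings vs "
            f"{envmat.data.shape[0]} envelope rows"
        )
    if emb_idx is not None:
        bad = np.nonzero(np.asarray(emb_idx) != envmat.word_indices)[0]
        if bad.size:
            raise ValueError(f"word alignment mismatch at rows {bad.tolist()}")
    return np.concatenate([emb, envmat.data], axis=1)


# ---------------------------------------------------------------------------
# LOTO fitting from per-trial sufficient statistics
# ---------------------------------------------------------------------------


class _TrialStats:
    """Per-trial sufficient statistics for centered, standardized ridge."""

    def __init__(self, X: np.ndarray, Y: np.ndarray):
        self.X = X
        self.Y = Y
        self.n = X.shape[0]
        self.sx = X.sum(axis=0)
        self.sy = Y.sum(axis=0)
        self.G = X.T @ X
        self.C = X.T @ Y


class _FoldSolver:
    """Ridge solutions on a training set defined by excluded trials."""

    def __init__(self, stats: list[_TrialStats], exclude: frozenset[int],
                 standardize: bool):
        self.exclude = exclude
        idx = [i for i in range(len(stats)) if i not in exclude]
        self.train_trials = idx
        n = sum(stats[i].n for i in idx)
        sx = sum(stats[i].sx for i in idx)
        sy = sum(stats[i].sy for i in idx)
        G = sum(stats[i].G for i in idx)
        C = sum(stats[i].C for i in idx)
        self.mx = sx / n
        self.my = sy / n
        Gc = G - n * np.outer(self.mx, self.mx)
        Cc = C - n * np.outer(self.mx, self.my)
        if standardize:
            var = np.diag(Gc) / n
            sd = np.sqrt(np.maximum(var, 0.0))
            sd[sd <= 1e-12] = 1.0
        else:
            sd = np.ones(Gc.shape[0])
        self.sd = sd
        A = Gc / np.outer(sd, sd)
        self.B = Cc / sd[:, None]
        # small symmetric eigendecomposition; all lambda solves are diagonal
        vals, V = np.linalg.eigh((A + A.T) / 2.0)
        self.evals = np.maximum(vals, 0.0)
        self.V = V
        self.B_rot = V.T @ self.B

    def weights(self, lam: float) -> np.ndarray:
        return self.V @ (self.B_rot / (self.evals + lam)[:, None])

    def predict(self, X: np.ndarray, lam: float) -> np.ndarray:
        Xs = (X - self.mx) / self.sd
        return Xs @ self.weights(lam) + self.my


class _DualFoldSolver:
    """Dual-form (kernel) ridge for wide designs (features > training words).

    Mathematically identical to the primal closed form via
    ``(X'X + lam I)^-1 X'Y = X'(XX' + lam I)^-1 Y``; the n x n
    eigendecomposition makes the lambda sweep cheap when p >> n.
    """

    def __init__(self, Xs: list[np.ndarray], Ys: list[np.ndarray],
                 exclude: frozenset[int], standardize: bool):
        self.exclude = exclude
        idx = [i for i in range(len(Xs)) if i not in exclude]
        self.train_trials = idx
        X = np.concatenate([Xs[i] for i in idx], axis=0)
        Y = np.concatenate([Ys[i] for i in idx], axis=0)
        self.mx = X.mean(axis=0)
        self.my = Y.mean(axis=0)
        if standardize:
            sd = X.std(axis=0)
            sd[sd <= 1e-12] = 1.0
        else:
            sd = np.ones(X.shape[1])
        self.sd = sd
        self.Xs_tr = (X - self.mx) / sd
        K = self.Xs_tr @ self.Xs_tr.T
        vals, U = np.linalg.eigh((K + K.T) / 2.0)
        self.evals = np.maximum(vals, 0.0)
        self.U = U
        self.Y_rot = U.T @ (Y - self.my)

    def predict(self, X: np.ndarray, lam: float) -> np.ndarray:
        Xs = (X - self.mx) / self.sd
        M = (Xs @ self.Xs_tr.T) @ self.U  # n_test x n_train, rotated
        return M @ (self.Y_rot / (self.evals + lam)[:, None]) + self.my


def _pearson_columns(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r across rows; zero-variance columns score 0."""
    p = pred - pred.mean(axis=0)
    a = actual - actual.mean(axis=0)
    sp = np.sqrt((p * p).sum(axis=0))
    sa = np.sqrt((a * a).sum(axis=0))
    denom = sp * sa
    ok = denom > 1e-30
    r = np.zeros(pred.shape[1])
    r[ok] = (p * a).sum(axis=0)[ok] / denom[ok]
    if not np.all(ok):
        logger.warning("%d zero-variance column(s) scored 0", int((~ok).sum()))
    return np.clip(r, -1.0, 1.0)


def _fold_scores(
    pred: np.ndarray, actual: np.ndarray, n_elec: int, n_lags: int, mode: str
) -> np.ndarray:
    """Per-electrode score of one held-out trial."""
    if mode == "concat":
        r = _pearson_columns(
            pred.reshape(pred.shape[0], n_elec, n_lags).transpose(1, 0, 2).reshape(n_elec, -1).T,
            actual.reshape(actual.shape[0], n_elec, n_lags).transpose(1, 0, 2).reshape(n_elec, -1).T,
        )
        return r
    r = _pearson_columns(pred, actual)
    return r.reshape(n_elec, n_lags).mean(axis=1)


@dataclass
class FitResult:
    """Brain scores of one feature set: per-trial and trial-averaged."""

    per_trial_scores: np.ndarray  # trials x electrodes, NaN where skipped
    chosen_lambda: np.ndarray  # trials x electrodes
    trial_ids: list[int]
    fold_train_trials: dict[int, list[int]]
    metadata: dict

    @property
    def electrode_scores(self) -> np.ndarray:
        """Mean over trials of the per-trial held-out scores."""
        return np.nanmean(self.per_trial_scores, axis=0)

    def to_table(self, **extra) -> "BrainScoreTable":
        meta = {**self.metadata, **extra}
        rows = []
        n_trials, n_elec = self.per_trial_scores.shape
        for t in range(n_trials):
            for e in range(n_elec):
                s = self.per_trial_scores[t, e]
                if np.isnan(s):
                    continue
                rows.append({"electrode": e, "trial": self.trial_ids[t],
                             "score": float(s), **meta})
        return BrainScoreTable(pd.DataFrame(rows))


def fit_loto_brain_scores(
    features: Sequence[np.ndarray],
    responses: Sequence[WordResponseMatrix | np.ndarray],
    ridge_cfg: RidgeConfig | None = None,
    min_words: int = 3,
    metadata: dict | None = None,
) -> FitResult:
    """Nested leave-one-trial-out ridge brain scores.

    ``features`` is one (words x p) matrix per trial; ``responses`` one
    (words x electrodes x n_lags) array (or :class:`WordResponseMatrix`) per
    trial, row-aligned with the features.  For each outer fold, the
    regularization strength is selected per electrode by inner LOTO on the
    training trials (maximizing the mean held-out score), the model is refit
    on all training trials and the held-out trial is scored.  Held-out trials
    with fewer than ``min_words`` words are skipped with a log entry.
    """
    if ridge_cfg is None:
        ridge_cfg = RidgeConfig()
    n_trials = len(features)
    if n_trials < 3:
        raise ValueError("leave-one-trial-out needs at least 3 trials")
    if len(responses) != n_trials:
        raise ValueError("features and responses trial counts differ")

    Xs, Ys = [], []
    n_elec = n_lags = None
    for X, R in zip(features, responses):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        arr = R.data if isinstance(R, WordResponseMatrix) else np.asarray(R, dtype=float)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.shape[0] != X.shape[0]:
            raise ValueError("feature/response word counts differ within a trial")
        if n_elec is None:
            n_elec, n_lags = arr.shape[1], arr.shape[2]
        elif (n_elec, n_lags) != arr.shape[1:]:
            raise ValueError("inconsistent electrode/lag shape across trials")
        Xs.append(X)
        Ys.append(arr.reshape(arr.shape[0], -1))

    p = Xs[0].shape[1]
    total_words = sum(x.shape[0] for x in Xs)
    use_dual = p > total_words  # wide designs: n x n dual form is cheaper
    stats = None if use_dual else [_TrialStats(X, Y) for X, Y in zip(Xs, Ys)]

    def make_solver(exclude: frozenset[int]):
        if use_dual:
            return _DualFoldSolver(Xs, Ys, exclude, ridge_cfg.standardize)
        return _FoldSolver(stats, exclude, ridge_cfg.standardize)

    grid = np.asarray(ridge_cfg.lambda_grid)
    per_trial = np.full((n_trials, n_elec), np.nan)
    chosen = np.full((n_trials, n_elec), np.nan)
    fold_train: dict[int, list[int]] = {}

    for o in range(n_trials):
        if Xs[o].shape[0] < min_words:
            logger.warning("fold %d skipped: held-out trial has %d < %d words",
                           o, Xs[o].shape[0], min_words)
            continue
        inner_sum = np.zeros((grid.size, n_elec))
        inner_cnt = 0
        for j in range(n_trials):
            if j == o or Xs[j].shape[0] < min_words:
                continue
            solver = make_solver(frozenset({o, j}))
            for li, lam in enumerate(grid):
                pred = solver.predict(Xs[j], lam)
                inner_sum[li] += _fold_scores(
                    pred, Ys[j], n_elec, n_lags, ridge_cfg.score_mode
                )
            inner_cnt += 1
        if inner_cnt == 0:
            logger.warning("fold %d skipped: no valid inner folds", o)
            continue
        best = np.argmax(inner_sum, axis=0)  # per electrode
        outer = make_solver(frozenset({o}))
        fold_train[o] = outer.train_trials
        scores_o = np.empty(n_elec)
        for li in np.unique(best):
            lam = float(grid[li])
            pred = outer.predict(Xs[o], lam)
            s = _fold_scores(pred, Ys[o], n_elec, n_lags, ridge_cfg.score_mode)
            mask = best == li
            scores_o[mask] = s[mask]
            chosen[o, mask] = lam
        per_trial[o] = scores_o

    return FitResult(
        per_trial_scores=per_trial,
        chosen_lambda=chosen,
        trial_ids=list(range(n_trials)),
        fold_train_trials=fold_train,
        metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# score table
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "electrode", "trial", "layer", "condition", "context_mode",
    "context_len", "feature_set", "score",
]


class BrainScoreTable:
    """Tidy per-(electrode, trial) brain scores with condition metadata.

    Columns: electrode, trial, layer, condition, context_mode, context_len,
    feature_set, score.  Missing metadata columns are filled with defaults so
    tables from different runs concatenate cleanly.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        defaults = {
            "layer": -1, "condition": "n/a", "context_mode": "related",
            "context_len": "full", "feature_set": "embedding",
            "adapter": "aligned",
        }
        for col, val in defaults.items():
            if col not in df.columns:
                df[col] = val
        if "score" not in df.columns or "electrode" not in df.columns:
            raise ValueError("score table needs 'electrode' and 'score' columns")
        if "trial" not in df.columns:
            df["trial"] = -1
        if len(df) and not df["score"].between(-1.0, 1.0).all():
            raise ValueError("scores must lie in [-1, 1]")
        self.df = df[_TABLE_COLUMNS + [c for c in df.columns if c not in _TABLE_COLUMNS]]

    def __len__(self) -> int:
        return len(self.df)

    @staticmethod
    def concat(tables: Iterable["BrainScoreTable"]) -> "BrainScoreTable":
        return BrainScoreTable(pd.concat([t.df for t in tables], ignore_index=True))

    def select(self, **criteria) -> "BrainScoreTable":
        """Filter rows; a tuple/list/set criterion matches any of its values."""
        df = self.df
        for col, val in criteria.items():
            if isinstance(val, (tuple, list, set, frozenset)):
                df = df[df[col].isin(list(val))]
            else:
                df = df[df[col] == val]
        return BrainScoreTable(df.reset_index(drop=True))

    def electrode_means(self, **criteria) -> pd.Series:
        """Trial-averaged score per electrode for one condition selection."""
        sub = self.select(**criteria).df
        return sub.groupby("electrode")["score"].mean()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "BrainScoreTable":
        return BrainScoreTable(pd.read_csv(path))
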