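"""Paired electrode statistics: Wilcoxon signed-rank comparisons and curves.

The electrode is the statistical unit: per-trial brain scores are averaged
across trials first, then the two arms of a contrast are paired per
electrode and tested with a two-sided Wilcoxon signed-rank test under a
Bonferroni-corrected threshold (default alpha = 0.05/6).  Reported effect
size is the median of the paired differences.

The signed-rank test is implemented tie-aware: zero differences are dropped,
absolute differences are mid-ranked, and W is the positive-rank sum.  For
n <= 25 the two-sided p-value is exact — the null distribution of W over all
2^n sign patterns is built by dynamic programming on the (doubled, hence
integer) rank values, which handles tied mid-ranks exactly.  For larger n a
normal approximation with tie correction and continuity correction is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from cocktail_ctx.encoding_model import BrainScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "PairedComparison",
    "wilcoxon_signed_rank",
    "compare_scores",
    "layer_curve",
    "context_length_curve",
]

_EXACT_N_MAX = 25


@dataclass(frozen=True)
class PairedComparison:
    """Outcome of one paired two-sided signed-rank comparison."""

    name: str
    n: int
    W: float
    p: float
    median_diff: float
    alpha: float
    significant: bool

    def __str__(self) -> str:
        star = "*" if self.significant else ""
        return (
            f"{self.name}: n={self.n}, W={self.W:g}, p={self.p:.3g}{star}, "
            f"median diff={self.median_diff:+.4f} (alpha={self.alpha:.3g})"
        )


def _exact_two_sided_p(ranks: np.ndarray, w: float) -> float:
    """Exact p over all 2^n sign patterns via DP on doubled (integer) ranks."""
    r2 = np.round(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2.0 * w))
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(
    a: Sequence[float],
    b: Sequence[float] | None = None,
    force_asymptotic: bool = False,
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples (or differences).

    Returns ``(W, p)`` with W the positive-rank sum.  Zero differences are
    dropped and tied absolute differences mid-ranked.  Exact enumeration for
    n <= 25, normal approximation with tie and continuity corrections beyond
    (or when forced).
    """
    a = np.asarray(a, dtype=float)
    if b is not None:
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        d = a - b
    else:
        d = a
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("degenerate pairing: all differences are zero")
    ranks = spstats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= _EXACT_N_MAX and not force_asymptotic:
        return w, _exact_two_sided_p(ranks, w)
    mean = n * (n + 1) / 4.0
    var = float((ranks**2).sum()) / 4.0  # tie-corrected via actual mid-ranks
    if var == 0:
        raise ValueError("degenerate pairing: zero rank variance")
    diff = w - mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * spstats.norm.sf(abs(z))))


def compare_scores(
    table: BrainScoreTable,
    contrast: str,
    arm_a,
    arm_b,
    fixed: dict | None = None,
    name: str | None = None,
    alpha: float = 0.05,
    n_comparisons: int = 6,
) -> PairedComparison:
    """Paired electrode comparison between two arms of one metadata column.

    Scores are trial-averaged per electrode within each arm (and any
    ``fixed`` selection), paired by electrode, and tested two-sided with a
    Bonferroni-corrected threshold ``alpha / n_comparisons``.  The reported
    effect is the median of per-electrode (arm_a - arm_b) differences.
    """
    fixed = fixed or {}
    means_a = table.electrode_means(**{**fixed, contrast: arm_a})
    means_b = table.electrode_means(**{**fixed, contrast: arm_b})
    if set(means_a.index) != set(means_b.index):
        only_a = sorted(set(means_a.index) - set(means_b.index))
        only_b = sorted(set(means_b.index) - set(means_a.index))
        raise ValueError(
            f"electrode sets differ between arms: only in {arm_a}: {only_a}; "
            f"only in {arm_b}: {only_b}"
        )
    idx = sorted(means_a.index)
    d = means_a.loc[idx].to_numpy() - means_b.loc[idx].to_numpy()
    w, p = wilcoxon_signed_rank(d)
    corrected = alpha / n_comparisons
    return PairedComparison(
        name=name or f"{contrast}: {arm_a} vs {arm_b}",
        n=len(idx),
        W=w,
        p=p,
        median_diff=float(np.median(d)),
        alpha=corrected,
        significant=bool(p < corrected),
    )


def _grid_curve(
    table: BrainScoreTable,
    column: str,
    grid: Sequence,
    fixed: dict | None,
    adjacent: bool,
    alpha: float,
    n_comparisons: int,
) -> tuple[pd.DataFrame, list[PairedComparison]]:
    fixed = fixed or {}
    rows = []
    for g in grid:
        means = table.electrode_means(**{**fixed, column: g})
        if means.empty:
            raise ValueError(f"no scores for {column}={g!r} under {fixed}")
        n = len(means)
        if n < 2:
            logger.warning("%s=%r has a single electrode; SEM undefined", column, g)
            sem = np.nan
        else:
            sem = float(means.std(ddof=1) / np.sqrt(n))
        rows.append({column: g, "mean": float(means.mean()), "sem": sem, "n": n})
    comparisons = []
    if adjacent:
        for g1, g2 in zip(grid, grid[1:]):
            comparisons.append(
                compare_scores(
                    table, column, g2, g1, fixed=fixed,
                    name=f"{column}: {g2} vs {g1}",
                    alpha=alpha, n_comparisons=n_comparisons,
                )
            )
    return pd.DataFrame(rows), comparisons


def layer_curve(
    table: BrainScoreTable,
    layers: Sequence[int],
    fixed: dict | None = None,
    adjacent_comparisons: bool = False,
    alpha: float = 0.05,
    n_comparisons: int = 6,
) -> tuple[pd.DataFrame, list[PairedComparison]]:
    """Mean and SEM (across trial-averaged electrodes) of scores per layer."""
    return _grid_curve(
        table, "layer", list(layers), fixed, adjacent_comparisons, alpha, n_comparisons
    )


def plot_curves(
    curves: dict[str, pd.DataFrame],
    x_column: str,
    out_path,
    ylabel: str = "brain score (r)",
    title: str | None = None,
) -> None:
    """Plot per-condition mean±SEM curves (requires matplotlib)."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("plot_curves requires matplotlib") from exc
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for name, df in curves.items():
        x = np.arange(len(df))
        ax.errorbar(x, df["mean"], yerr=df["sem"], label=name, capsize=2)
        ax.set_xticks(x)
        ax.set_xticklabels([str(v) for v in df[x_column]])
    ax.set_xlabel(x_column.replace("_", " "))
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def context_length_curve(
    table: BrainScoreTable,
    lengths: Sequence = (1, 5, 10, 15, 50, "full"),
    fixed: dict | None = None,
    adjacent_comparisons: bool = False,
    alpha: float = 0.05,
    n_comparisons: int = 6,
) -> tuple[pd.DataFrame, list[PairedComparison]]:
    """Mean and SEM of scores as a function of context length."""
    return _grid_curve(
        table, "context_len", list(lengths), fixed, adjacent_comparisons,
        alpha, n_comparisons,
    )
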