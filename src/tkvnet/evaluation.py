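"""Segmentation accuracy and volume-agreement statistics.

Overlap metrics (Dice, Jaccard) are computed from voxel-wise confusion
counts pooled over all slices of one subject, then averaged across
subjects — never pooled across subjects.  Volume agreement follows the
standard clinical reporting layout: per-subject absolute difference and
percent difference (relative to the reference), summarized by mean and
sample standard deviation (n−1 denominator), plus a Bland–Altman analysis
with bias and 95% limits of agreement (bias ± 1.96·SD of the signed
percent differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel tallies of a predicted vs reference mask (TN not needed)."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn)


def confusion(pred: Sequence[np.ndarray] | np.ndarray,
              truth: Sequence[np.ndarray] | np.ndarray) -> ConfusionCounts:
    """Pool voxel-wise TP/FP/FN over all slices of one subject."""
    if isinstance(pred, np.ndarray):
        pred, truth = [pred], [truth]  # type: ignore[list-item]
    if len(pred) != len(truth):
        raise ValueError("pred and truth stacks must have equal length")
    tp = fp = fn = 0
    for p, t in zip(pred, truth):
        p = np.asarray(p).astype(bool)
        t = np.asarray(t).astype(bool)
        if p.shape != t.shape:
            raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
        tp += int(np.count_nonzero(p & t))
        fp += int(np.count_nonzero(p & ~t))
        fn += int(np.count_nonzero(~p & t))
    return ConfusionCounts(tp, fp, fn)


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP/(2TP+FP+FN); empty vs empty -> 1."""
    den = 2 * c.tp + c.fp + c.fn
    if den == 0:
        return 1.0
    return 2 * c.tp / den


def jaccard(c: ConfusionCounts) -> float:
    """Jaccard coefficient TP/(TP+FP+FN); empty vs empty -> 1.

    Satisfies the identity J = D/(2−D) with :func:`dsc`.
    """
    den = c.tp + c.fp + c.fn
    if den == 0:
        return 1.0
    return c.tp / den


# ---------------------------------------------------------------------------
# Agreement tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementRow:
    subject_id: str
    ground_truth_ml: float
    predicted_ml: float

    @property
    def diff_ml(self) -> float:
        return abs(self.predicted_ml - self.ground_truth_ml)

    @property
    def diff_pct(self) -> float:
        return 100.0 * self.diff_ml / self.ground_truth_ml


@dataclass(frozen=True)
class AgreementSummary:
    """Mean and sample SD (n−1) of each agreement-table column."""

    n: int
    mean_truth: float
    sd_truth: float
    mean_pred: float
    sd_pred: float
    mean_diff: float
    sd_diff: float
    mean_diff_pct: float
    sd_diff_pct: float


def agreement_table(pairs: Sequence[tuple[float, float]],
                    subject_ids: Sequence[str] | None = None,
                    ) -> tuple[list[AgreementRow], AgreementSummary]:
    """Per-subject (reference, predicted) volume agreement plus summary.

    Each row reports the absolute difference in mL and as a percentage of
    the reference; the summary gives means and sample SDs of all columns.
    """
    if not pairs:
        raise ValueError("need at least one (truth, pred) pair")
    if subject_ids is None:
        subject_ids = [f"subject_{i + 1}" for i in range(len(pairs))]
    rows = []
    for sid, (truth, pred) in zip(subject_ids, pairs):
        if truth <= 0:
            raise ValueError(f"{sid}: reference volume must be positive")
        rows.append(AgreementRow(sid, float(truth), float(pred)))

    def _ms(vals: list[float]) -> tuple[float, float]:
        arr = np.asarray(vals)
        sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
        return float(arr.mean()), sd

    mt, st = _ms([r.ground_truth_ml for r in rows])
    mp, sp = _ms([r.predicted_ml for r in rows])
    md, sd_ = _ms([r.diff_ml for r in rows])
    mpc, spc = _ms([r.diff_pct for r in rows])
    summary = AgreementSummary(len(rows), mt, st, mp, sp, md, sd_, mpc, spc)
    return rows, summary


def agreement_frame(rows: Sequence[AgreementRow]) -> pd.DataFrame:
    """Agreement rows as a DataFrame in the standard reporting layout."""
    return pd.DataFrame({
        "subject_id": [r.subject_id for r in rows],
        "ground_truth_ml": [r.ground_truth_ml for r in rows],
        "predicted_ml": [r.predicted_ml for r in rows],
        "diff_ml": [r.diff_ml for r in rows],
        "diff_pct": [r.diff_pct for r in rows],
    })


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltman:
    """Bias and 95% limits of agreement of signed percent differences."""

    differences_pct: tuple[float, ...]
    bias: float
    loa_lower: float
    loa_upper: float
    sign_convention: str  # "pred_minus_truth" or "truth_minus_pred"
    denominator: str  # "pairwise_mean", "truth" or "pred"


def bland_altman(pairs: Sequence[tuple[float, float]],
                 sign_convention: str = "pred_minus_truth",
                 denominator: str = "pairwise_mean") -> BlandAltman:
    """Bland–Altman analysis of (reference, predicted) volume pairs.

    The signed percent difference of each pair is
    ``100 * (pred - truth) / D`` (or its negation under the
    ``truth_minus_pred`` convention) with denominator ``D`` chosen among
    the pairwise mean, the reference, or the prediction.  Bias is the mean
    difference; the limits of agreement are bias ± 1.96 × sample SD.
    """
    if len(pairs) < 2:
        raise ValueError("Bland–Altman needs at least two pairs")
    if sign_convention not in ("pred_minus_truth", "truth_minus_pred"):
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    diffs = []
    for truth, pred in pairs:
        if denominator == "pairwise_mean":
            den = (truth + pred) / 2.0
        elif denominator == "truth":
            den = truth
        elif denominator == "pred":
            den = pred
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
        if den == 0:
            raise ValueError("zero denominator in percent difference")
        d = 100.0 * (pred - truth) / den
        diffs.append(d if sign_convention == "pred_minus_truth" else -d)
    arr = np.asarray(diffs)
    bias = float(arr.mean())
    sd = float(np.std(arr, ddof=1))
    return BlandAltman(tuple(diffs), bias, bias - 1.96 * sd, bias + 1.96 * sd,
                       sign_convention, denominator)


def bland_altman_all_conventions(pairs: Sequence[tuple[float, float]],
                                 sign_convention: str = "pred_minus_truth",
                                 ) -> dict[str, BlandAltman]:
    """The analysis under every denominator convention, keyed by name."""
    return {den: bland_altman(pairs, sign_convention, den)
            for den in ("pairwise_mean", "truth", "pred")}


def bland_altman_plot(ba: BlandAltman, pairs: Sequence[tuple[float, float]],
                      path: str) -> None:
    """Write the classic mean-vs-difference plot with bias and LoA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = [(t + p) / 2.0 for t, p in pairs]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, ba.differences_pct, color="tab:blue")
    for y, style, label in ((ba.bias, "-", f"bias {ba.bias:.2f}%"),
                            (ba.loa_upper, "--", f"+1.96 SD {ba.loa_upper:.2f}%"),
                            (ba.loa_lower, "--", f"-1.96 SD {ba.loa_lower:.2f}%")):
        ax.axhline(y, linestyle=style, color="tab:red")
        ax.annotate(label, (max(means), y), fontsize=8,
                    ha="right", va="bottom")
    ax.set_xlabel("Mean of reference and predicted TKV (mL)")
    ax.set_ylabel("Difference (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def compare_groups(sample_a: Sequence[float], sample_b: Sequence[float],
                   normality_alpha: float = 0.05,
                   force: str | None = None) -> float:
    """Two-sided two-sample comparison p-value.

    Uses Student's t-test when both samples pass a Shapiro–Wilk normality
    check at ``normality_alpha``, otherwise the Mann–Whitney U test;
    ``force`` in {"t", "mannwhitney"} overrides the check.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 1.0  # identical constant groups: no evidence of difference
    if force == "t":
        use_t = True
    elif force == "mannwhitney":
        use_t = False
    elif force is None:
        try:
            use_t = (stats.shapiro(a).pvalue > normality_alpha
                     and stats.shapiro(b).pvalue > normality_alpha)
        except ValueError:
            use_t = False
    else:
        raise ValueError(f"unknown force option {force!r}")
    if use_t:
        return float(stats.ttest_ind(a, b).pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
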