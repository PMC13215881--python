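"""Rank-frequency baseline, per-cell accuracy, and scaling-law fitting.

The baseline predicts, for each masked rank position, the gene most commonly
observed at that rank in a *reference* tokenized corpus (the pretraining
split — never the evaluation set itself, enforced by a provenance-hash
check).  It is content-blind: predictions depend only on the rank index, so
it isolates what the encoder learns from cell context beyond marginal rank
statistics.

Scaling behaviour is summarized by fitting ``loss(N) = a * N**(-alpha) + c``
to (parameter count or FLOPs, held-out loss) points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from ._nn import IGNORE_LABEL
from .tokenize import TokenizedDataset

__all__ = [
    "BaselineRankTable",
    "ScalingFitResult",
    "build_rank_baseline",
    "baseline_predict",
    "percent_correct_per_cell",
    "fit_power_law",
]


@dataclass
class BaselineRankTable:
    """rank position (0-based over gene tokens) -> modal gene token."""

    table: np.ndarray  # modal gene token per rank
    fallback: int  # globally most frequent gene token
    reference_hash: str = ""

    def __getitem__(self, rank: int) -> int:
        if 0 <= rank < len(self.table):
            return int(self.table[rank])
        return self.fallback


def build_rank_baseline(reference: TokenizedDataset) -> BaselineRankTable:
    """Modal gene per rank over the reference corpus; ties to the smaller token id.

    Ranks index gene positions only (CLS and EOS are excluded), so rank 0 is
    the highest-scoring gene of each cell.
    """
    if len(reference) == 0:
        raise ValueError("empty reference corpus")
    max_rank = max(len(t) - 2 for t in reference.tokens)
    vocab_max = max(int(t.max()) for t in reference.tokens) + 1
    counts = np.zeros((max_rank, vocab_max), dtype=np.int64)
    global_counts = np.zeros(vocab_max, dtype=np.int64)
    for t in reference.tokens:
        genes = t[1:-1]
        counts[np.arange(len(genes)), genes] += 1
        np.add.at(global_counts, genes, 1)
    # argmax returns the first (smallest token id) among ties
    table = counts.argmax(axis=1)
    fallback = int(global_counts.argmax())
    return BaselineRankTable(
        table=table, fallback=fallback, reference_hash=reference.provenance_hash()
    )


def baseline_predict(
    masked_ids: np.ndarray,
    lengths: np.ndarray,
    labels: np.ndarray,
    table: BaselineRankTable,
) -> np.ndarray:
    """Rank-lookup predictions at labeled (masked) positions.

    Returns an array shaped like ``masked_ids`` with the table's gene at each
    labeled position and IGNORE_LABEL elsewhere.  Position ``p`` of a cell's
    sequence corresponds to rank ``p - 1`` (position 0 is CLS).
    """
    preds = np.full_like(masked_ids, IGNORE_LABEL)
    rows, cols = np.nonzero(labels != IGNORE_LABEL)
    for r, c in zip(rows, cols):
        preds[r, c] = table[c - 1]
    return preds


def percent_correct_per_cell(predictions: np.ndarray, labels: np.ndarray):
    """100 * (exact-token matches / masked positions), per cell.

    Cells with zero masked positions are excluded from the returned list and
    counted.  Returns (per-cell percentages, n_excluded).
    """
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have identical shapes")
    sel = labels != IGNORE_LABEL
    out = []
    excluded = 0
    for i in range(labels.shape[0]):
        n = int(sel[i].sum())
        if n == 0:
            excluded += 1
            continue
        correct = int((predictions[i][sel[i]] == labels[i][sel[i]]).sum())
        out.append(100.0 * correct / n)
    return out, excluded


@dataclass
class ScalingFitResult:
    """Fit of ``loss(N) = a * N**(-alpha) + c`` plus a log-log reference fit."""

    a: float
    alpha: float
    c: float
    residuals: np.ndarray
    loglog_alpha: float  # slope fit with c fixed to 0
    loglog_a: float
    non_monotone: bool = False

    def predict(self, n: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(n, dtype=float) ** (-self.alpha) + self.c

    def summary(self) -> str:
        lines = [
            "Power-law scaling fit: loss(N) = a * N^(-alpha) + c",
            f"  a      = {self.a:.6g}",
            f"  alpha  = {self.alpha:.6g}",
            f"  c      = {self.c:.6g}",
            f"  log-log reference (c=0): alpha = {self.loglog_alpha:.6g}, a = {self.loglog_a:.6g}",
            f"  RMS residual = {float(np.sqrt(np.mean(self.residuals**2))):.3g}",
        ]
        if self.non_monotone:
            lines.append("  warning: loss series is not monotone decreasing")
        return "\n".join(lines)


def fit_power_law(points) -> ScalingFitResult:
    """Nonlinear least squares on (N, loss) points.

    Initialization: alpha from the log-log slope, c at 0.9x the smallest
    loss, a to match the first point.  A non-monotone loss series is fitted
    anyway but flagged.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (N, loss) points")
    n, y = pts[:, 0], pts[:, 1]
    if np.any(n <= 0):
        raise ValueError("abscissae must be positive")
    non_monotone = bool(np.any(np.diff(y[np.argsort(n)]) > 0))

    # log-log fit with c = 0 (requires positive losses; shift defensively)
    ypos = np.maximum(y, 1e-12)
    slope, intercept = np.polyfit(np.log(n), np.log(ypos), 1)
    loglog_alpha = max(0.0, -slope)
    loglog_a = float(np.exp(intercept))

    c0 = 0.9 * float(y.min())
    alpha0 = max(loglog_alpha, 1e-3)
    a0 = max((y[0] - c0), 1e-9) * n[0] ** alpha0

    def model(n_, a, alpha, c):
        return a * n_ ** (-alpha) + c

    try:
        popt, _ = scipy.optimize.curve_fit(
            model,
            n,
            y,
            p0=[a0, alpha0, max(c0, 0.0)],
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20_000,
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        a, alpha, c = (float(v) for v in popt)
    except RuntimeError:
        a, alpha, c = float(a0), float(alpha0), float(max(c0, 0.0))
    residuals = y - model(n, a, alpha, c)
    return ScalingFitResult(
        a=a,
        alpha=alpha,
        c=c,
        residuals=residuals,
        loglog_alpha=float(loglog_alpha),
        loglog_a=loglog_a,
        non_monotone=non_monotone,
    )


def assert_disjoint_reference(table: BaselineRankTable, eval_dataset: TokenizedDataset) -> None:
    """Guard: the baseline's reference corpus must not be the evaluation set."""
    if table.reference_hash and table.reference_hash == eval_dataset.provenance_hash():
        raise ValueError("baseline reference corpus equals the evaluation dataset")
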