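"""Per-chip probe-level statistics: detection calls, signal summaries,
and between-chip scale normalization.

Detection of a transcript on one chip tests whether the discrimination
scores R_p = (PM_p - MM_p)/(PM_p + MM_p) of its probe pairs sit above a
small threshold tau, via the exact one-sided Wilcoxon signed-rank test.
Because R_p is a ratio of intensities it is invariant to uniform chip
scaling, so detection runs on un-normalized intensities; fold changes
are computed downstream on scale-normalized signals.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import DetectionParams, ProbePairMatrix
from .wilcoxon import batch_signed_rank_p, signed_rank_p_exact

__all__ = [
    "discrimination_scores",
    "detection_call",
    "detect_chip",
    "signal_summary",
    "signal_chip",
    "scale_normalize",
]

CALL_PRESENT = "Present"
CALL_MARGINAL = "Marginal"
CALL_ABSENT = "Absent"

# One-step biweight tuning: 5 MADs reject, small additive guard against
# zero spread.
_BIWEIGHT_C = 5.0
_BIWEIGHT_EPS = 1e-4


def discrimination_scores(pm, mm) -> np.ndarray:
    """(PM - MM) / (PM + MM) per probe pair, each in (-1, 1)."""
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if pm.shape != mm.shape:
        raise ValueError("PM and MM must be paired (equal shape)")
    if not (np.all(pm > 0) and np.all(mm > 0)):
        raise ValueError("intensities must be strictly positive")
    return (pm - mm) / (pm + mm)


def _call_from_p(p: np.ndarray, params: DetectionParams) -> np.ndarray:
    call = np.full(p.shape, CALL_ABSENT, dtype=object)
    call[p <= params.alpha2] = CALL_MARGINAL
    call[p <= params.alpha1] = CALL_PRESENT
    return call


def detection_call(pm, mm, params: DetectionParams = DetectionParams()):
    """Detection p-value and Present/Marginal/Absent call for one gene.

    Returns ``(p_detect, call)`` where p_detect is the exact one-sided
    signed-rank p of the discrimination scores against tau.
    """
    scores = discrimination_scores(pm, mm)
    p = signed_rank_p_exact(scores, center=params.tau, alternative="greater")
    call = _call_from_p(np.array([p]), params)[0]
    return p, call


def detect_chip(matrix: ProbePairMatrix,
                params: DetectionParams = DetectionParams()) -> pd.DataFrame:
    """Detection calls for every gene on one chip.

    Returns a DataFrame with columns gene_id, p_detect, call, sorted by
    gene_id.
    """
    genes_out: list[np.ndarray] = []
    p_out: list[np.ndarray] = []
    for genes, pm, mm in matrix.groups():
        scores = discrimination_scores(pm, mm)
        p = batch_signed_rank_p(scores - params.tau, alternative="greater")
        genes_out.append(genes)
        p_out.append(p)
    gene_ids = np.concatenate(genes_out)
    p = np.concatenate(p_out)
    out = pd.DataFrame({
        "gene_id": gene_ids.astype(str),
        "p_detect": p,
        "call": _call_from_p(p, params),
    })
    return out.sort_values("gene_id", kind="stable").reset_index(drop=True)


def _biweight_rows(x: np.ndarray) -> np.ndarray:
    """One-step Tukey biweight location per row of ``x``."""
    med = np.median(x, axis=-1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=-1, keepdims=True)
    u = (x - med) / (_BIWEIGHT_C * mad + _BIWEIGHT_EPS)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    est = (w * x).sum(axis=-1) / w.sum(axis=-1)
    # Zero spread: the biweight degenerates, fall back to the median.
    flat = (mad[..., 0] == 0.0)
    est = np.where(flat, med[..., 0], est)
    return est


def signal_summary(pm, mm, floor: float = 1.0) -> float:
    """Robust log2 signal for one gene on one chip.

    One-step Tukey biweight location of log2(max(PM_p - MM_p, floor));
    returns the median when the MAD is zero.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if pm.shape != mm.shape or pm.ndim != 1 or pm.size == 0:
        raise ValueError("PM and MM must be paired non-empty vectors")
    x = np.log2(np.maximum(pm - mm, floor))
    return float(_biweight_rows(x[np.newaxis, :])[0])


def signal_chip(matrix: ProbePairMatrix, floor: float = 1.0) -> pd.Series:
    """log2 signal for every gene on one chip (index gene_id, sorted)."""
    if floor <= 0:
        raise ValueError("floor must be > 0")
    genes_out: list[np.ndarray] = []
    sig_out: list[np.ndarray] = []
    for genes, pm, mm in matrix.groups():
        x = np.log2(np.maximum(pm - mm, floor))
        genes_out.append(genes)
        sig_out.append(_biweight_rows(x))
    s = pd.Series(
        np.concatenate(sig_out),
        index=pd.Index(np.concatenate(genes_out).astype(str), name="gene_id"),
        name="log2_signal",
    )
    return s.sort_index(kind="stable")


def scale_normalize(signals: pd.DataFrame | Sequence[pd.Series],
                    target: float = 500.0,
                    trim: float = 0.02) -> tuple[pd.DataFrame, pd.Series]:
    """Global scaling: bring every chip's trimmed mean intensity to ``target``.

    ``signals`` holds per-gene log2 signals, one column (or Series) per
    chip.  Each chip is multiplied on the linear scale by
    target / trimmed_mean(linear signals), i.e. log2 signals are shifted
    by log2 of that factor.  Returns (normalized signals, scale factors).
    """
    if not target > 0:
        raise ValueError("target must be > 0")
    if not (0.0 <= trim < 0.5):
        raise ValueError("trim must be in [0, 0.5)")
    if not isinstance(signals, pd.DataFrame):
        signals = pd.concat(list(signals), axis=1)
    if signals.shape[1] < 1:
        raise ValueError("need at least one chip")
    if not np.isfinite(signals.to_numpy()).all():
        raise ValueError("signals must be finite")
    linear = np.power(2.0, signals.to_numpy(dtype=float))
    means = np.array([
        stats.trim_mean(linear[:, j], proportiontocut=trim)
        for j in range(linear.shape[1])
    ])
    if np.any(means <= 0):
        raise ValueError("chip with nonpositive trimmed mean cannot be scaled")
    factors = target / means
    normalized = signals + np.log2(factors)[np.newaxis, :]
    return normalized, pd.Series(factors, index=signals.columns, name="scale_factor")
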