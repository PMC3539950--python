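"""Differential expression: pooled all-pairs and paired designs.

Pooled (cross-sectional rat) design: every treatment pool is compared
against every control pool (3x3 = 9, 3x2 = 6, or 2x2 = 4 cells).  Per
cell and gene, the fold change is the ratio of normalized signals and
the comparison p-value is a two-sided exact signed-rank test on the
per-probe-pair log2 background-floored PM - MM differences.  The
average p across cells is ranked against Benjamini-Hochberg step-up
thresholds; a gene is differentially expressed only if it additionally
clears the conjunctive >= 1.5-fold filter in *every* cell (same
direction) and is called Present on every chip of at least one side.

Paired (human) design: per-subject fold changes on normalized signals
plus a two-sided paired t-test on per-subject log2 signals; a gene is
differentially expressed when it is expressed, clears the fold
threshold in every subject, and the paired t p-value is below alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detection import CALL_PRESENT
from .types import Chip, DEParamsPooled, ProbePairMatrix
from .wilcoxon import batch_signed_rank_p

__all__ = [
    "AnalyzedChip",
    "PoolComparisonGrid",
    "compare_chips",
    "all_pairs_comparisons",
    "conjunctive_fold_filter",
    "fdr_step_up",
    "pooled_de",
    "paired_de",
    "classify_catalog",
]


@dataclass(frozen=True)
class AnalyzedChip:
    """A chip together with its per-gene normalized log2 signals."""

    chip: Chip
    signal: pd.Series            # log2, scale-normalized, index gene_id
    scale_factor: float = 1.0

    @property
    def chip_id(self) -> str:
        return self.chip.chip_id

    @property
    def condition(self) -> str:
        return self.chip.condition


@dataclass(frozen=True)
class PoolComparisonGrid:
    """All-pairs treatment-vs-control comparison results.

    ``folds`` and ``pvals`` are gene x cell DataFrames; cell labels are
    "treatment_id:control_id".
    """

    folds: pd.DataFrame
    pvals: pd.DataFrame
    cells: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if self.folds.shape != self.pvals.shape:
            raise ValueError("folds and pvals must align")
        if self.folds.shape[1] != len(self.cells):
            raise ValueError("cell labels and columns disagree")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _probe_log_values(matrix: ProbePairMatrix, scale: float, floor: float):
    """Per-group log2(max(scale * (PM - MM), floor)) arrays."""
    out = []
    for genes, pm, mm in matrix.groups():
        out.append((genes, np.log2(np.maximum(scale * (pm - mm), floor))))
    return out


def compare_chips(treatment: AnalyzedChip, control: AnalyzedChip,
                  floor: float = 1.0) -> pd.DataFrame:
    """Per-gene (fold, p) for one treatment chip vs one control chip.

    fold = 2**(signal_T - signal_C) on the normalized signals; p is the
    two-sided exact signed-rank p of the per-probe-pair differences of
    log2 background-floored PM - MM (chip scale factors applied so the
    probe-level comparison sees the same normalization as the fold).
    """
    tm, cm = treatment.chip.matrix, control.chip.matrix
    if not tm.same_design(cm):
        raise ValueError("chips come from different designs")
    t_vals = _probe_log_values(tm, treatment.scale_factor, floor)
    c_vals = _probe_log_values(cm, control.scale_factor, floor)
    genes_out, p_out = [], []
    for (genes_t, xt), (genes_c, xc) in zip(t_vals, c_vals):
        p = batch_signed_rank_p(xt - xc, alternative="two-sided")
        genes_out.append(genes_t)
        p_out.append(p)
    gene_ids = pd.Index(np.concatenate(genes_out).astype(str), name="gene_id")
    p = pd.Series(np.concatenate(p_out), index=gene_ids).sort_index(kind="stable")
    sig_t = treatment.signal.reindex(p.index)
    sig_c = control.signal.reindex(p.index)
    if sig_t.isna().any() or sig_c.isna().any():
        raise ValueError("signals do not cover every gene on the chips")
    fold = np.power(2.0, sig_t - sig_c)
    return pd.DataFrame({"fold": fold, "p": p})


def all_pairs_comparisons(treatment_pools: Sequence[AnalyzedChip],
                          control_pools: Sequence[AnalyzedChip],
                          floor: float = 1.0) -> PoolComparisonGrid:
    """Compare every treatment pool against every control pool."""
    if len(treatment_pools) == 0 or len(control_pools) == 0:
        raise ValueError("need at least one pool on each side")
    folds, pvals, cells = {}, {}, []
    for t in treatment_pools:
        for c in control_pools:
            label = f"{t.chip_id}:{c.chip_id}"
            res = compare_chips(t, c, floor=floor)
            folds[label] = res["fold"]
            pvals[label] = res["p"]
            cells.append((t.chip_id, c.chip_id))
    return PoolComparisonGrid(
        folds=pd.DataFrame(folds),
        pvals=pd.DataFrame(pvals),
        cells=tuple(cells),
    )


def conjunctive_fold_filter(folds, threshold: float = 1.5,
                            require_direction_consistency: bool = True):
    """True iff the fold criterion holds in *every* comparison.

    With direction consistency, all folds must be >= threshold (up) or
    all <= 1/threshold (down); without it, |log2 fold| >= log2 threshold
    in every comparison regardless of direction.  Accepts a 1-D vector
    (returns bool) or a genes x cells array (returns a bool vector).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    f = np.asarray(folds, dtype=float)
    if not np.all(f > 0):
        raise ValueError("folds must be > 0")
    squeeze = f.ndim == 1
    if squeeze:
        f = f[np.newaxis, :]
    if require_direction_consistency:
        up = (f >= threshold).all(axis=1)
        down = (f <= 1.0 / threshold).all(axis=1)
        out = up | down
    else:
        out = (np.abs(np.log2(f)) >= math.log2(threshold)).all(axis=1)
    return bool(out[0]) if squeeze else out


def fdr_step_up(p, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up on a vector of p-values.

    Sort p ascending and find the largest rank i with
    p(i) <= (i/m) * q; every gene with p <= p(i) passes (so tied
    p-values share the better outcome).  Returns a DataFrame aligned
    with the input order: columns p, rank, fdr_threshold, passes_fdr.
    """
    if isinstance(p, pd.Series):
        index = p.index
        pv = p.to_numpy(dtype=float)
    else:
        pv = np.asarray(p, dtype=float)
        index = pd.RangeIndex(pv.size)
    if pv.size == 0:
        raise ValueError("need at least one p-value")
    if not (np.all(pv > 0) and np.all(pv <= 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    m = pv.size
    order = np.argsort(pv, kind="stable")
    sorted_p = pv[order]
    thresholds = (np.arange(1, m + 1) / m) * q
    ok = sorted_p <= thresholds
    if ok.any():
        crit = sorted_p[np.nonzero(ok)[0].max()]
        passes = pv <= crit
    else:
        passes = np.zeros(m, dtype=bool)
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    return pd.DataFrame({
        "p": pv,
        "rank": rank,
        "fdr_threshold": (rank / m) * q,
        "passes_fdr": passes,
    }, index=index)


def _present_matrix(detections: Mapping[str, pd.DataFrame],
                    chip_ids: Sequence[str],
                    genes: pd.Index) -> np.ndarray:
    """genes x chips boolean Present matrix from per-chip detection tables."""
    cols = []
    for cid in chip_ids:
        det = detections[cid].set_index("gene_id")["call"].reindex(genes)
        if det.isna().any():
            raise ValueError(f"detections for chip {cid} do not cover all genes")
        cols.append((det == CALL_PRESENT).to_numpy())
    return np.column_stack(cols)


def _passes_present(detections: Mapping[str, pd.DataFrame],
                    treatment_ids: Sequence[str],
                    control_ids: Sequence[str],
                    genes: pd.Index,
                    rule: str) -> np.ndarray:
    pres_t = _present_matrix(detections, treatment_ids, genes)
    pres_c = _present_matrix(detections, control_ids, genes)
    if rule == "either_side":
        return pres_t.all(axis=1) | pres_c.all(axis=1)
    if rule == "any":
        return pres_t.any(axis=1) | pres_c.any(axis=1)
    return pres_t.all(axis=1) & pres_c.all(axis=1)


def pooled_de(grid: PoolComparisonGrid,
              detections: Mapping[str, pd.DataFrame],
              params: DEParamsPooled = DEParamsPooled()) -> pd.DataFrame:
    """Pooled-design differential-expression decisions per gene.

    The per-gene mean comparison p is ranked against BH step-up
    thresholds; the final decision additionally requires the conjunctive
    fold filter and (optionally) the Present-call filter.
    """
    genes = grid.pvals.index
    pv = grid.pvals.to_numpy(dtype=float)
    if params.mean_p_method == "arithmetic":
        mean_p = pv.mean(axis=1)
    else:
        mean_p = np.exp(np.log(pv).mean(axis=1))
    fdr = fdr_step_up(pd.Series(mean_p, index=genes), q=params.fdr_q)

    folds = grid.folds.to_numpy(dtype=float)
    passes_fold = conjunctive_fold_filter(
        folds, params.fold_threshold, params.require_direction_consistency
    )
    mean_fold = np.exp(np.log(folds).mean(axis=1))

    treatment_ids = list(dict.fromkeys(t for t, _ in grid.cells))
    control_ids = list(dict.fromkeys(c for _, c in grid.cells))
    if params.require_present:
        passes_present = _passes_present(
            detections, treatment_ids, control_ids, genes, params.present_rule
        )
    else:
        passes_present = np.ones(len(genes), dtype=bool)

    de = fdr["passes_fdr"].to_numpy() & passes_fold & passes_present
    return pd.DataFrame({
        "mean_p": mean_p,
        "rank": fdr["rank"],
        "fdr_threshold_at_rank": fdr["fdr_threshold"],
        "passes_fdr": fdr["passes_fdr"],
        "passes_fold_all": passes_fold,
        "passes_present": passes_present,
        "mean_fold": mean_fold,
        "differentially_expressed": de,
    }, index=genes)


def _paired_t_p(diffs: np.ndarray) -> np.ndarray:
    """Two-sided paired t p-values per row of log2 differences.

    Rows with zero-variance differences: p = 1 when the mean is also
    zero (identity inputs are a legitimate null), otherwise the p-value
    degenerates to the smallest positive float.
    """
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    p = np.ones(diffs.shape[0])
    regular = sd > 0
    t = np.zeros_like(mean)
    t[regular] = mean[regular] / (sd[regular] / math.sqrt(n))
    p[regular] = 2.0 * stats.t.sf(np.abs(t[regular]), df=n - 1)
    degenerate = (~regular) & (mean != 0)
    p[degenerate] = np.finfo(float).tiny
    return np.minimum(p, 1.0)


def paired_de(subject_signals: Mapping[str, tuple[pd.Series, pd.Series]],
              detections: Mapping[str, pd.DataFrame] | None = None,
              fold_threshold: float = 1.5,
              alpha: float = 0.05,
              expressed: pd.Series | None = None) -> pd.DataFrame:
    """Paired-design DE: per-subject folds + two-sided paired t-test.

    ``subject_signals`` maps subject id -> (treatment signal, control
    signal) as normalized log2 Series over genes.  ``expressed`` marks
    genes significantly expressed; if omitted it is derived from
    ``detections`` (Present on every chip of at least one condition) or
    defaults to all True.  A gene is differentially expressed iff it is
    expressed, every subject's fold clears the threshold, and the paired
    t p-value is below alpha.
    """
    if len(subject_signals) < 2:
        raise ValueError("paired t-test requires at least two subjects")
    if fold_threshold < 1:
        raise ValueError("fold_threshold must be >= 1")
    subjects = list(subject_signals)
    genes = subject_signals[subjects[0]][0].index
    t_mat = np.column_stack([
        subject_signals[s][0].reindex(genes).to_numpy() for s in subjects
    ])
    c_mat = np.column_stack([
        subject_signals[s][1].reindex(genes).to_numpy() for s in subjects
    ])
    if not (np.isfinite(t_mat).all() and np.isfinite(c_mat).all()):
        raise ValueError("subject signals do not cover a common gene set")
    diffs = t_mat - c_mat               # log2 fold per subject
    folds = np.power(2.0, diffs)
    all_pass = conjunctive_fold_filter(folds, fold_threshold)
    p = _paired_t_p(diffs)
    percent = 100.0 * folds
    pct_mean = percent.mean(axis=1)
    pct_sem = percent.std(axis=1, ddof=1) / math.sqrt(len(subjects))

    if expressed is None:
        if detections is not None:
            expressed_arr = _detections_expressed(detections, genes)
        else:
            expressed_arr = np.ones(len(genes), dtype=bool)
    else:
        expressed_arr = expressed.reindex(genes).fillna(False).to_numpy(dtype=bool)

    out = pd.DataFrame({
        "paired_t_p": p,
        "all_subjects_pass_fold": all_pass,
        "expressed": expressed_arr,
        "percent_of_control_mean": pct_mean,
        "percent_of_control_sem": pct_sem,
        "differentially_expressed": expressed_arr & all_pass & (p < alpha),
    }, index=genes)
    for j, s in enumerate(subjects):
        out[f"fold_{s}"] = folds[:, j]
    return out


def _detections_expressed(detections: Mapping[str, pd.DataFrame],
                          genes: pd.Index) -> np.ndarray:
    """Present on every chip of at least one condition-agnostic grouping.

    Without condition labels here, use: Present on at least half of all
    chips; pipelines that know conditions should pass ``expressed``.
    """
    pres = _present_matrix(detections, list(detections), genes)
    return pres.sum(axis=1) * 2 >= pres.shape[1]


def classify_catalog(detections: Mapping[str, pd.DataFrame],
                     strong_p: float = 0.01,
                     moderate_p: float | None = None) -> pd.DataFrame:
    """Detection-catalogue classification across chips.

    frequency = number of chips with a Present call; NotDetected when
    zero; Strong when Present on all chips and the mean detection p is
    <= strong_p; otherwise Moderate.  ``moderate_p``, when given, caps
    Moderate: genes detected somewhere but with mean p above it still
    classify Moderate (kept for config symmetry; the boundary between
    Strong and Moderate is the configurable part).
    """
    if len(detections) == 0:
        raise ValueError("need at least one chip")
    chip_ids = list(detections)
    frames = [detections[c].set_index("gene_id") for c in chip_ids]
    genes = frames[0].index.sort_values()
    for f in frames[1:]:
        if not f.index.sort_values().equals(genes):
            raise ValueError("chips cover different gene sets")
    present = np.column_stack([
        (f["call"].reindex(genes) == CALL_PRESENT).to_numpy() for f in frames
    ])
    mean_p = np.column_stack([
        f["p_detect"].reindex(genes).to_numpy() for f in frames
    ]).mean(axis=1)
    n_chips = len(chip_ids)
    count = present.sum(axis=1)
    cls = np.where(
        count == 0,
        "NotDetected",
        np.where((count == n_chips) & (mean_p <= strong_p), "Strong", "Moderate"),
    )
    return pd.DataFrame({
        "present_count": count,
        "chip_count": n_chips,
        "frequency": [f"{c}/{n_chips}" for c in count],
        "mean_p_detect": mean_p,
        "class": cls,
    }, index=genes)
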