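"""RT-PCR gel densitometry quantification.

Band densities are normalized to a housekeeping control (GAPDH) per
sample, expressed per subject as a percent of the control condition,
summarised as mean +/- SEM with a two-sided paired t-test, and checked
for technical reproducibility via the duplicate-biopsy coefficient of
variation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalized_expression",
    "percent_of_control",
    "summarize_percents",
    "paired_t",
    "duplicate_cv",
    "PcrResult",
    "analyze_bands",
]


def normalized_expression(target_density: float, gapdh_density: float) -> float:
    """Target band density divided by the housekeeping (GAPDH) band."""
    if not target_density > 0:
        raise ValueError("target density must be > 0")
    if not gapdh_density > 0:
        raise ValueError("GAPDH density must be > 0")
    return float(target_density) / float(gapdh_density)


def percent_of_control(treated: float, control: float) -> float:
    """100 * treated / control (both normalized expressions)."""
    if not control > 0:
        raise ValueError("control expression must be > 0")
    if not treated > 0:
        raise ValueError("treated expression must be > 0")
    return 100.0 * float(treated) / float(control)


def summarize_percents(percents: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean +/- SEM of per-subject percent-of-control values."""
    x = np.asarray(percents, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one value")
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else float("nan")
    return mean, sem


def paired_t(values_a, values_b) -> tuple[float, float]:
    """Two-sided paired t-test; returns (t statistic, p-value).

    Computed from the closed form t = mean(d) / (sd(d)/sqrt(n)) on the
    paired differences d = a - b, referred to a t distribution with
    n - 1 degrees of freedom.  Degenerate cases: all differences zero
    gives p = 1 (identity inputs are a legitimate null); zero-variance
    nonzero differences give the smallest positive float with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = a - b
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        warnings.warn(
            "zero-variance nonzero paired differences: p degenerates below "
            "machine precision",
            RuntimeWarning,
        )
        t = math.inf if mean > 0 else -math.inf
        return t, float(np.finfo(float).tiny)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return float(t), min(p, 1.0)


def duplicate_cv(duplicate_pairs: Sequence[tuple[float, float]]) -> float:
    """Mean duplicate coefficient of variation, in percent.

    Per pair, CV = sample sd / mean * 100 with the two-point convention
    sd = |v1 - v2| / sqrt(2); the mean across pairs is returned.
    """
    if len(duplicate_pairs) == 0:
        raise ValueError("need at least one duplicate pair")
    cvs = []
    for v1, v2 in duplicate_pairs:
        if not (v1 > 0 and v2 > 0):
            raise ValueError("duplicate values must be > 0")
        sd = abs(v1 - v2) / math.sqrt(2.0)
        mean = (v1 + v2) / 2.0
        cvs.append(100.0 * sd / mean)
    return float(np.mean(cvs))


@dataclass
class PcrResult:
    """GAPDH-normalized relative expression summary for one target."""

    target: str
    control_condition: str
    treated_condition: str
    per_sample: pd.DataFrame               # sample_id, subject, condition, normalized
    per_subject_percent: pd.Series         # percent of control per subject
    percent_mean: float
    percent_sem: float
    paired_t_stat: float
    paired_t_p: float
    duplicate_cv_percent: float | None = None
    warnings: list[str] = field(default_factory=list)


def _normalized_per_sample(bands: pd.DataFrame, target: str,
                           reference: str) -> pd.DataFrame:
    required = {"sample_id", "subject", "condition", "target", "density"}
    missing = required.difference(bands.columns)
    if missing:
        raise ValueError(f"band table missing columns: {sorted(missing)}")
    if (bands["density"] <= 0).any():
        raise ValueError("band densities must be > 0")
    rows = []
    for sample_id, sub in bands.groupby("sample_id", sort=True):
        tgt = sub.loc[sub["target"] == target, "density"]
        ref = sub.loc[sub["target"] == reference, "density"]
        if len(tgt) != 1 or len(ref) != 1:
            raise ValueError(
                f"sample {sample_id}: need exactly one {target} and one "
                f"{reference} band"
            )
        rows.append((
            sample_id,
            sub["subject"].iloc[0],
            sub["condition"].iloc[0],
            normalized_expression(float(tgt.iloc[0]), float(ref.iloc[0])),
        ))
    return pd.DataFrame(rows, columns=["sample_id", "subject", "condition",
                                       "normalized"])


def analyze_bands(bands: pd.DataFrame,
                  control_label: str,
                  treated_label: str | None = None,
                  target: str = "LPP1",
                  reference: str = "GAPDH") -> PcrResult:
    """Full densitometry analysis of a tidy band table.

    Expects columns sample_id, subject, condition, target, density; a
    sample is one gel lane pair (target + reference band).  Duplicate
    samples of the same subject x condition are averaged for the paired
    comparison and feed the duplicate-biopsy CV.
    """
    per_sample = _normalized_per_sample(bands, target, reference)
    conditions = sorted(per_sample["condition"].unique())
    if control_label not in conditions:
        raise ValueError(f"control condition {control_label!r} not in data")
    if treated_label is None:
        others = [c for c in conditions if c != control_label]
        if len(others) != 1:
            raise ValueError(
                "treated_label required when more than one non-control condition"
            )
        treated_label = others[0]

    dup_pairs = []
    for (_, _), sub in per_sample.groupby(["subject", "condition"], sort=True):
        vals = sub["normalized"].to_numpy()
        if vals.size == 2:
            dup_pairs.append((float(vals[0]), float(vals[1])))
    dup_cv = duplicate_cv(dup_pairs) if dup_pairs else None

    by_subject = (
        per_sample.groupby(["subject", "condition"], sort=True)["normalized"]
        .mean().unstack("condition")
    )
    if by_subject[[control_label, treated_label]].isna().any().any():
        raise ValueError("every subject needs both conditions")
    percents = pd.Series({
        subj: percent_of_control(row[treated_label], row[control_label])
        for subj, row in by_subject.iterrows()
    }, name="percent_of_control")
    mean, sem = summarize_percents(percents.to_numpy())
    t_stat, t_p = paired_t(
        by_subject[treated_label].to_numpy(),
        by_subject[control_label].to_numpy(),
    )
    return PcrResult(
        target=target,
        control_condition=control_label,
        treated_condition=treated_label,
        per_sample=per_sample,
        per_subject_percent=percents,
        percent_mean=mean,
        percent_sem=sem,
        paired_t_stat=t_stat,
        paired_t_p=t_p,
        duplicate_cv_percent=dup_cv,
    )
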