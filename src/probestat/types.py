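"""Shared domain containers for probe-level microarray analysis.

The unit of everything here is the probe *pair*: a perfect-match (PM)
oligo complementary to the target transcript and a mismatch (MM) oligo
with a single central base change.  A probe set of 11 (human-style) or
16-20 (rat-style) pairs interrogates one transcript per chip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneTruth",
    "NoiseModel",
    "ChipDesign",
    "PoolSpec",
    "SubjectSpec",
    "SimulationScenario",
    "ProbePairMatrix",
    "Chip",
    "ChipSet",
    "DetectionParams",
    "DEParamsPooled",
]


@dataclass(frozen=True)
class GeneTruth:
    """Ground-truth expression state of one gene in a simulation.

    ``fold_by_condition`` maps condition labels to the true fold change
    relative to baseline (1.0 = unchanged); ``expressed=False`` marks a
    transcript with no target present (should be called Absent).
    """

    gene_id: str
    baseline_expression: float
    fold_by_condition: Mapping[str, float]
    expressed: bool = True

    def __post_init__(self):
        if self.expressed and not self.baseline_expression > 0:
            raise ValueError(
                f"{self.gene_id}: baseline_expression must be > 0 when expressed"
            )
        for cond, f in self.fold_by_condition.items():
            if not f > 0:
                raise ValueError(f"{self.gene_id}: fold for {cond!r} must be > 0")

    def fold(self, condition: str) -> float:
        return float(self.fold_by_condition.get(condition, 1.0))


@dataclass(frozen=True)
class NoiseModel:
    """Generative noise parameters for the chip simulator.

    background_mean/background_sd: additive optical background per probe
    (scanner units).  biological_cv: animal-to-animal lognormal scale
    (sigma of log expression).  technical_cv: probe-level lognormal scale.
    crosshyb_fraction: fraction of the specific signal that also binds the
    MM probe; must stay below 1 so PM stochastically dominates MM for
    expressed targets.  saturation_cap: optional scanner ceiling.
    """

    background_mean: float = 100.0
    background_sd: float = 20.0
    biological_cv: float = 0.25
    technical_cv: float = 0.15
    crosshyb_fraction: float = 0.35
    saturation_cap: Optional[float] = None

    def __post_init__(self):
        if not self.background_mean > 0:
            raise ValueError("background_mean must be > 0")
        if self.background_sd < 0 or self.biological_cv < 0 or self.technical_cv < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0.0 <= self.crosshyb_fraction < 1.0):
            raise ValueError("crosshyb_fraction must be in [0, 1)")
        if self.saturation_cap is not None and not self.saturation_cap > 0:
            raise ValueError("saturation_cap must be > 0 when set")


@dataclass(frozen=True)
class ChipDesign:
    """Probe layout shared by every chip of an experiment.

    ``probe_counts`` maps gene_id -> number of probe pairs (>= 3);
    ``affinities`` maps gene_id -> per-probe affinity phi_p (> 0), drawn
    once per design and frozen across chips.
    """

    probe_counts: Mapping[str, int]
    affinities: Mapping[str, np.ndarray]

    def __post_init__(self):
        for g, k in self.probe_counts.items():
            if k < 3:
                raise ValueError(f"{g}: need >= 3 probe pairs, got {k}")
            phi = np.asarray(self.affinities[g], dtype=float)
            if phi.shape != (k,):
                raise ValueError(f"{g}: affinities must have length {k}")
            if not np.all(phi > 0):
                raise ValueError(f"{g}: affinities must be > 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.probe_counts)


@dataclass(frozen=True)
class PoolSpec:
    """One RNA pool: equal-mass mix of ``size`` animals in one condition."""

    pool_id: str
    condition: str
    size: int

    def __post_init__(self):
        if self.size < 1:
            raise ValueError(f"{self.pool_id}: pool size must be >= 1")


@dataclass(frozen=True)
class SubjectSpec:
    """One human subject measured under every condition (paired design)."""

    subject_id: str


@dataclass(frozen=True)
class SimulationScenario:
    """A named experimental layout: which chips exist and for whom."""

    name: str
    conditions: tuple[str, ...]
    pools: tuple[PoolSpec, ...] = ()
    subjects: tuple[SubjectSpec, ...] = ()
    duplicate_biopsies: bool = False
    seed: int = 0

    def __post_init__(self):
        if not self.conditions:
            raise ValueError("scenario needs at least one condition")
        if not self.pools and not self.subjects:
            raise ValueError("scenario needs pools or subjects")
        if self.pools and self.subjects:
            raise ValueError("scenario cannot mix pools and subjects")

    @property
    def is_paired(self) -> bool:
        return bool(self.subjects)


class ProbePairMatrix:
    """Per-chip PM/MM intensities for every gene, grouped by probe count.

    Internally genes sharing a probe-set size are stored as 2-D arrays so
    per-chip statistics vectorise; :meth:`to_frame` round-trips to the
    tidy (gene_id, probe_index, PM, MM) table used on disk.
    """

    def __init__(self, groups: Mapping[int, tuple[Sequence[str], np.ndarray, np.ndarray]]):
        self._groups: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        seen: set[str] = set()
        for count in sorted(groups):
            genes, pm, mm = groups[count]
            genes = np.asarray(genes, dtype=object)
            pm = np.asarray(pm, dtype=float)
            mm = np.asarray(mm, dtype=float)
            if pm.shape != mm.shape or pm.ndim != 2 or pm.shape[1] != count:
                raise ValueError("PM/MM arrays must be (n_genes, probe_count) and paired")
            if pm.shape[0] != genes.size:
                raise ValueError("gene list and intensity rows disagree")
            if not (np.all(pm > 0) and np.all(mm > 0)):
                raise ValueError("intensities must be strictly positive")
            dup = seen.intersection(genes.tolist())
            if dup:
                raise ValueError(f"duplicate gene ids: {sorted(dup)[:3]}")
            seen.update(genes.tolist())
            self._groups[count] = (genes, pm, mm)
        if not self._groups:
            raise ValueError("empty probe matrix")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ProbePairMatrix":
        required = {"gene_id", "probe_index", "PM", "MM"}
        missing = required.difference(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        groups: dict[int, tuple[list[str], list[np.ndarray], list[np.ndarray]]] = {}
        for gene, sub in frame.groupby("gene_id", sort=True):
            sub = sub.sort_values("probe_index")
            count = len(sub)
            bucket = groups.setdefault(count, ([], [], []))
            bucket[0].append(str(gene))
            bucket[1].append(sub["PM"].to_numpy(dtype=float))
            bucket[2].append(sub["MM"].to_numpy(dtype=float))
        return cls({
            count: (genes, np.vstack(pms), np.vstack(mms))
            for count, (genes, pms, mms) in groups.items()
        })

    def groups(self) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Yield (gene_ids, PM, MM) per probe-count group, ascending count."""
        for count in sorted(self._groups):
            yield self._groups[count]

    @property
    def gene_ids(self) -> list[str]:
        out: list[str] = []
        for genes, _, _ in self.groups():
            out.extend(genes.tolist())
        return out

    @property
    def n_genes(self) -> int:
        return sum(g.size for g, _, _ in self.groups())

    def probe_counts(self) -> dict[str, int]:
        return {
            str(g): pm.shape[1]
            for genes, pm, _ in self.groups()
            for g in genes
        }

    def for_gene(self, gene_id: str) -> tuple[np.ndarray, np.ndarray]:
        for genes, pm, mm in self.groups():
            hit = np.nonzero(genes == gene_id)[0]
            if hit.size:
                i = hit[0]
                return pm[i].copy(), mm[i].copy()
        raise KeyError(gene_id)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for genes, pm, mm in self.groups():
            count = pm.shape[1]
            parts.append(pd.DataFrame({
                "gene_id": np.repeat(genes, count),
                "probe_index": np.tile(np.arange(count), genes.size),
                "PM": pm.ravel(),
                "MM": mm.ravel(),
            }))
        out = pd.concat(parts, ignore_index=True)
        return out.sort_values(["gene_id", "probe_index"], kind="stable").reset_index(drop=True)

    def same_design(self, other: "ProbePairMatrix") -> bool:
        if sorted(self._groups) != sorted(other._groups):
            return False
        return all(
            np.array_equal(self._groups[c][0], other._groups[c][0])
            for c in self._groups
        )


@dataclass(frozen=True)
class Chip:
    """One hybridised array: a probe matrix plus its experimental labels.

    ``unit`` is the pool id (rat designs) or subject id (human designs);
    ``replicate`` distinguishes duplicate biopsies from one unit/condition.
    """

    chip_id: str
    condition: str
    unit: str
    matrix: ProbePairMatrix
    pool_size: int = 1
    replicate: int = 1


@dataclass
class ChipSet:
    """All chips of one simulated experiment plus the generating truth."""

    chips: list[Chip]
    truth: list[GeneTruth]
    design: ChipDesign
    scenario: SimulationScenario

    def __post_init__(self):
        ids = [c.chip_id for c in self.chips]
        if len(set(ids)) != len(ids):
            raise ValueError("chip_ids must be unique")

    def chips_for(self, condition: str) -> list[Chip]:
        return [c for c in self.chips if c.condition == condition]

    @property
    def gene_ids(self) -> list[str]:
        return [t.gene_id for t in self.truth]


@dataclass(frozen=True)
class DetectionParams:
    """Present/Marginal/Absent call thresholds.

    tau: discrimination-score null center; alpha1: Present cutoff on the
    one-sided signed-rank p (p <= alpha1); alpha2: Marginal cutoff
    (alpha1 < p <= alpha2).
    """

    tau: float = 0.015
    alpha1: float = 0.04
    alpha2: float = 0.06

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not (0.0 < self.alpha1 < self.alpha2 < 1.0):
            raise ValueError("need 0 < alpha1 < alpha2 < 1")


@dataclass(frozen=True)
class DEParamsPooled:
    """Filters for the pooled all-pairs differential-expression decision."""

    fold_threshold: float = 1.5
    fdr_q: float = 0.05
    require_direction_consistency: bool = True
    require_present: bool = True
    present_rule: str = "either_side"  # either_side | any | all
    mean_p_method: str = "arithmetic"  # arithmetic | geometric

    def __post_init__(self):
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError("fdr_q must be in (0, 1)")
        if self.present_rule not in ("either_side", "any", "all"):
            raise ValueError("present_rule must be either_side, any or all")
        if self.mean_p_method not in ("arithmetic", "geometric"):
            raise ValueError("mean_p_method must be arithmetic or geometric")
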