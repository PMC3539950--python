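"""Synthetic probe-level chip data with known ground truth.

The generative model is lognormal-multiplicative with additive optical
background, which reproduces the positive, right-skewed intensities and
the PM > MM structure the detection statistic assumes:

    animal expression   e_g = baseline_g * fold_{g,cond} * LN(0, sigma_bio)
    pooled expression   mean over the k animals of a pool
    PM_{g,p}            bg + phi_p * e_g * LN(0, sigma_tech)
    MM_{g,p}            bg' + c * phi_p * e_g * LN(0, sigma_tech)

with independently drawn backgrounds bg, bg' ~ N(B, sd_B) (floored to
stay positive) and probe affinities phi_p drawn once per chip design and
frozen across chips.  Unexpressed genes have e_g = 0, so their PM and MM
are background-only and PM - MM is symmetric about zero.

Preset scenarios emulate four study layouts: an acute cross-sectional
rat design (3 control + 3 inactive + 2 exercise pools of 8-10 animals),
a chronic rat design (2 + 2 pools of 4), a paired 3-subject human
sitting-vs-ambulatory design, and a single-subject repeated-measures
case study with duplicate biopsies.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np

from .types import (
    Chip,
    ChipDesign,
    ChipSet,
    GeneTruth,
    NoiseModel,
    PoolSpec,
    ProbePairMatrix,
    SimulationScenario,
    SubjectSpec,
)

__all__ = [
    "SCENARIO_NAMES",
    "make_scenario",
    "make_design",
    "make_default_truth",
    "simulate_animal_expression",
    "pool_rna",
    "simulate_chip",
    "simulate_experiment",
    "simulate_gel_bands",
]

SCENARIO_NAMES = ("rat_acute", "rat_chronic", "human_sitting", "case_study")

# Probe-set sizes: 11 pairs on human-style arrays, 16-20 on rat-style.
HUMAN_PROBE_PAIRS = 11
RAT_PROBE_PAIRS = (16, 20)

# Affinity spread across probes of a set (lognormal CV 0.5, mean 1).
_AFFINITY_SIGMA = math.sqrt(math.log(1.25))

# Case-study conditions and the true suppression of the affected gene in
# each (fractions of ambulatory control).
CASE_STUDY_FOLDS = {
    "ambulatory": 1.0,
    "exercise_day": 1.0,
    "sitting_1d": 0.41,
    "sitting_15d": 0.49,
    "sitting_15d_trained_leg": 0.49,
    "ambulatory_recovery": 0.56,
}

# Default true suppression of the designated affected gene ("LPP1"):
# microarray-scale effect in rats, PCR-scale effect in the paired human
# design; exercise leaves the suppression largely in place.
RAT_INACTIVE_FOLD = 0.57
RAT_EXERCISE_FOLD = 0.60
HUMAN_SITTING_FOLD = 0.55

# Null genes named after catalogued transcripts so rendered reports look
# like the field's detection tables; the rest get generic ids.
NAMED_EXPRESSED_NULLS = (
    "LPP3", "LYPLA1", "AGPAT1", "ANXA2", "ANXA5", "PLAT", "PLAU",
    "CLEC3B", "TFPI", "PROCR", "PROS1", "THBD", "GGCX", "VKORC1", "F7", "VWF",
)
NAMED_ABSENT_NULLS = ("LPP2", "SGPL1", "SPHK1", "EDG3")


def _apply_overrides(base: dict, overrides: Optional[Mapping]) -> dict:
    if overrides:
        unknown = set(overrides).difference(base)
        if unknown:
            raise ValueError(f"unknown scenario overrides: {sorted(unknown)}")
        base = {**base, **overrides}
    return base


def make_scenario(name: str,
                  overrides: Optional[Mapping] = None,
                  seed: int = 0) -> SimulationScenario:
    """Build a preset experimental layout.

    ``overrides`` may adjust preset knobs (e.g. n_subjects, pool counts,
    seed); identical inputs always yield identical scenarios.  Acute-rat
    pool sizes are drawn uniformly from {8, 9, 10} from the scenario
    seed and recorded on the PoolSpecs.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(
            f"unknown scenario {name!r}; valid presets: {', '.join(SCENARIO_NAMES)}"
        )
    if name == "rat_acute":
        knobs = _apply_overrides(
            {"seed": seed, "n_control": 3, "n_inactive": 3, "n_exercise": 2},
            overrides,
        )
        counts = {
            "control": int(knobs["n_control"]),
            "inactive": int(knobs["n_inactive"]),
            "exercise": int(knobs["n_exercise"]),
        }
        if any(c < 1 for c in counts.values()):
            raise ValueError("rat_acute requires at least one pool per condition")
        rng = np.random.default_rng(int(knobs["seed"]))
        pools = []
        for cond, n in counts.items():
            sizes = rng.integers(8, 11, size=n)  # pooled from 8-10 animals
            pools.extend(
                PoolSpec(f"{cond}_pool{i + 1}", cond, int(sizes[i]))
                for i in range(n)
            )
        return SimulationScenario(
            name=name,
            conditions=tuple(counts),
            pools=tuple(pools),
            seed=int(knobs["seed"]),
        )
    if name == "rat_chronic":
        knobs = _apply_overrides(
            {"seed": seed, "n_control": 2, "n_inactive": 2, "pool_size": 4},
            overrides,
        )
        if knobs["n_control"] < 1 or knobs["n_inactive"] < 1:
            raise ValueError("rat_chronic requires at least one pool per condition")
        pools = tuple(
            PoolSpec(f"{cond}_pool{i + 1}", cond, int(knobs["pool_size"]))
            for cond, n in (("control", knobs["n_control"]),
                            ("inactive", knobs["n_inactive"]))
            for i in range(int(n))
        )
        return SimulationScenario(
            name=name,
            conditions=("control", "inactive"),
            pools=pools,
            seed=int(knobs["seed"]),
        )
    if name == "human_sitting":
        knobs = _apply_overrides({"seed": seed, "n_subjects": 3}, overrides)
        n = int(knobs["n_subjects"])
        if n < 2:
            raise ValueError("human_sitting requires at least two subjects")
        return SimulationScenario(
            name=name,
            conditions=("ambulatory", "sitting"),
            subjects=tuple(SubjectSpec(f"S{i + 1}") for i in range(n)),
            seed=int(knobs["seed"]),
        )
    # case_study: one subject, repeated measures, duplicate biopsies
    knobs = _apply_overrides({"seed": seed}, overrides)
    return SimulationScenario(
        name=name,
        conditions=tuple(CASE_STUDY_FOLDS),
        subjects=(SubjectSpec("CS1"),),
        duplicate_biopsies=True,
        seed=int(knobs["seed"]),
    )


def make_design(gene_ids: Sequence[str], kind: str, seed: int) -> ChipDesign:
    """Draw a frozen chip design (probe counts + affinities) for ``gene_ids``.

    kind: "human" gives 11 probe pairs per gene, "rat" draws 16-20 per
    gene.  Affinities are lognormal with CV 0.5 and unit mean, drawn
    once here and reused for every chip of the experiment.
    """
    if kind not in ("human", "rat"):
        raise ValueError("design kind must be 'human' or 'rat'")
    rng = np.random.default_rng(seed)
    probe_counts: dict[str, int] = {}
    affinities: dict[str, np.ndarray] = {}
    for g in gene_ids:
        if kind == "human":
            k = HUMAN_PROBE_PAIRS
        else:
            k = int(rng.integers(RAT_PROBE_PAIRS[0], RAT_PROBE_PAIRS[1] + 1))
        probe_counts[str(g)] = k
        affinities[str(g)] = np.exp(
            rng.normal(-0.5 * _AFFINITY_SIGMA**2, _AFFINITY_SIGMA, size=k)
        )
    return ChipDesign(probe_counts=probe_counts, affinities=affinities)


def _scenario_folds(scenario_name: str) -> dict[str, float]:
    if scenario_name in ("rat_acute", "rat_chronic"):
        folds = {"control": 1.0, "inactive": RAT_INACTIVE_FOLD}
        if scenario_name == "rat_acute":
            folds["exercise"] = RAT_EXERCISE_FOLD
        return folds
    if scenario_name == "human_sitting":
        return {"ambulatory": 1.0, "sitting": HUMAN_SITTING_FOLD}
    return dict(CASE_STUDY_FOLDS)


def make_default_truth(scenario: SimulationScenario,
                       n_genes: int = 500,
                       absent_fraction: float = 0.2,
                       affected_gene: str = "LPP1",
                       affected_folds: Optional[Mapping[str, float]] = None,
                       baseline_median: float = 300.0,
                       baseline_sigma: float = 0.5,
                       seed: Optional[int] = None) -> list[GeneTruth]:
    """Ground truth with one affected gene among expressed/absent nulls.

    The affected gene carries the suppression folds appropriate to the
    scenario (overridable); every other gene is a null (fold 1 in every
    condition).  ``absent_fraction`` of the nulls have no target present.
    Baselines are lognormal around ``baseline_median``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0.0 <= absent_fraction < 1.0):
        raise ValueError("absent_fraction must be in [0, 1)")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    folds = dict(_scenario_folds(scenario.name))
    if affected_folds is not None:
        folds.update(affected_folds)
    missing = set(scenario.conditions).difference(folds)
    if missing:
        raise ValueError(f"affected_folds missing conditions: {sorted(missing)}")

    n_null = n_genes - 1
    n_absent = int(round(absent_fraction * n_null))
    n_expressed_null = n_null - n_absent
    width = max(4, len(str(n_genes)))
    null_ids = [f"gene_{i + 1:0{width}d}" for i in range(n_null)]
    # Name leading expressed nulls / trailing absent nulls after
    # catalogued transcripts for readable reports.
    for j, name in enumerate(NAMED_EXPRESSED_NULLS[:n_expressed_null]):
        null_ids[j] = name
    for j, name in enumerate(NAMED_ABSENT_NULLS[:n_absent]):
        null_ids[n_expressed_null + j] = name
    baselines = baseline_median * np.exp(
        rng.normal(0.0, baseline_sigma, size=n_genes)
    )
    # Last n_absent null genes carry no target.
    truth = [
        GeneTruth(
            gene_id=affected_gene,
            baseline_expression=float(baselines[0]),
            fold_by_condition=folds,
        )
    ]
    for i, gid in enumerate(null_ids):
        absent = i >= n_null - n_absent
        truth.append(GeneTruth(
            gene_id=gid,
            baseline_expression=float(baselines[i + 1]),
            fold_by_condition={c: 1.0 for c in scenario.conditions},
            expressed=not absent,
        ))
    return truth


def simulate_animal_expression(truth: Sequence[GeneTruth],
                               condition: str,
                               noise: NoiseModel,
                               rng: np.random.Generator) -> np.ndarray:
    """True per-gene expression of one animal under ``condition``.

    Lognormal biological variation with zero-mean log, so the geometric
    mean over many animals converges to baseline * fold.  Unexpressed
    genes return 0.
    """
    base = np.array([
        t.baseline_expression * t.fold(condition) if t.expressed else 0.0
        for t in truth
    ])
    noise_mult = np.exp(rng.normal(0.0, noise.biological_cv, size=base.size))
    return base * noise_mult


def pool_rna(animal_expressions: Sequence[np.ndarray]) -> np.ndarray:
    """Equal-mass RNA pooling: the arithmetic mean across animals."""
    if len(animal_expressions) == 0:
        raise ValueError("cannot pool zero animals")
    stacked = np.vstack([np.asarray(a, dtype=float) for a in animal_expressions])
    return stacked.mean(axis=0)


def simulate_chip(pooled_expression: np.ndarray,
                  design: ChipDesign,
                  noise: NoiseModel,
                  rng: np.random.Generator) -> ProbePairMatrix:
    """Hybridise one expression vector onto one chip.

    ``pooled_expression`` is aligned with ``design.gene_ids``.
    """
    e = np.asarray(pooled_expression, dtype=float)
    gene_ids = design.gene_ids
    if e.size != len(gene_ids):
        raise ValueError("expression vector and design cover different genes")

    by_count: dict[int, tuple[list[str], list[int]]] = {}
    for i, g in enumerate(gene_ids):
        bucket = by_count.setdefault(design.probe_counts[g], ([], []))
        bucket[0].append(g)
        bucket[1].append(i)

    groups = {}
    for count in sorted(by_count):
        genes, idx = by_count[count]
        phi = np.vstack([design.affinities[g] for g in genes])
        eg = e[idx][:, np.newaxis]
        shape = (len(genes), count)

        def draw_background() -> np.ndarray:
            bg = rng.normal(noise.background_mean, noise.background_sd, size=shape)
            return np.maximum(bg, 1e-3)

        def draw_tech() -> np.ndarray:
            return np.exp(rng.normal(0.0, noise.technical_cv, size=shape))

        pm = draw_background() + phi * eg * draw_tech()
        mm = draw_background() + noise.crosshyb_fraction * phi * eg * draw_tech()
        if noise.saturation_cap is not None:
            pm = np.minimum(pm, noise.saturation_cap)
            mm = np.minimum(mm, noise.saturation_cap)
        groups[count] = (genes, pm, mm)
    return ProbePairMatrix(groups)


def simulate_experiment(scenario: SimulationScenario,
                        truth: Sequence[GeneTruth],
                        noise: NoiseModel = NoiseModel()) -> ChipSet:
    """One chip per pool (rat) or per subject x condition biopsy (human).

    Fully reproducible from ``scenario.seed``.  Human subjects carry a
    subject-level biological effect shared across their conditions (the
    repeated-measures structure the paired analysis exploits); duplicate
    biopsies share the subject x condition expression and differ only in
    chip-level technical noise.
    """
    truth = list(truth)
    rng = np.random.default_rng(scenario.seed)
    kind = "rat" if scenario.name.startswith("rat") else "human"
    gene_ids = [t.gene_id for t in truth]
    design = make_design(gene_ids, kind, seed=int(rng.integers(2**31 - 1)))

    chips: list[Chip] = []
    if scenario.pools:
        for pool in scenario.pools:
            animals = [
                simulate_animal_expression(truth, pool.condition, noise, rng)
                for _ in range(pool.size)
            ]
            pooled = pool_rna(animals)
            chips.append(Chip(
                chip_id=pool.pool_id,
                condition=pool.condition,
                unit=pool.pool_id,
                matrix=simulate_chip(pooled, design, noise, rng),
                pool_size=pool.size,
            ))
    else:
        base = np.array([
            t.baseline_expression if t.expressed else 0.0 for t in truth
        ])
        n_biopsies = 2 if scenario.duplicate_biopsies else 1
        for subject in scenario.subjects:
            subject_effect = np.exp(
                rng.normal(0.0, noise.biological_cv, size=len(truth))
            )
            for condition in scenario.conditions:
                fold = np.array([t.fold(condition) for t in truth])
                expression = base * fold * subject_effect
                for rep in range(1, n_biopsies + 1):
                    suffix = f"_b{rep}" if n_biopsies > 1 else ""
                    chips.append(Chip(
                        chip_id=f"{subject.subject_id}_{condition}{suffix}",
                        condition=condition,
                        unit=subject.subject_id,
                        matrix=simulate_chip(expression, design, noise, rng),
                        pool_size=1,
                        replicate=rep,
                    ))
    return ChipSet(chips=chips, truth=truth, design=design, scenario=scenario)


def simulate_gel_bands(subjects: Sequence[str],
                       true_percent_of_control: float = 55.0,
                       technical_cv: float = 0.065,
                       gapdh_level: float = 1000.0,
                       duplicate_conditions: Sequence[str] = (),
                       rng: Optional[np.random.Generator] = None,
                       seed: int = 0):
    """Synthetic densitometry table for the RT-PCR arm.

    Emulates gel bands for a target transcript and the GAPDH loading
    control under paired sitting/ambulatory conditions.  ``technical_cv``
    is the technical coefficient of variation of the *normalized*
    expression (target/GAPDH); each band carries lognormal noise of
    scale technical_cv / sqrt(2) so the ratio has the stated CV.
    Conditions listed in ``duplicate_conditions`` get duplicate samples
    (two biopsies).  Returns a tidy DataFrame with columns sample_id,
    subject, condition, target, density.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(seed)
    band_sigma = technical_cv / math.sqrt(2.0)
    rows = []
    for subject in subjects:
        subject_scale = float(np.exp(rng.normal(0.0, 0.25)))
        for condition, rel in (("ambulatory", 1.0),
                               ("sitting", true_percent_of_control / 100.0)):
            n_rep = 2 if condition in duplicate_conditions else 1
            for rep in range(1, n_rep + 1):
                suffix = f"_b{rep}" if n_rep > 1 else ""
                sample_id = f"{subject}_{condition}{suffix}"
                gapdh = gapdh_level * subject_scale * float(
                    np.exp(rng.normal(0.0, band_sigma))
                )
                target = gapdh_level * subject_scale * rel * float(
                    np.exp(rng.normal(0.0, band_sigma))
                )
                rows.append((sample_id, subject, condition, "GAPDH", gapdh))
                rows.append((sample_id, subject, condition, "LPP1", target))
    return pd.DataFrame(
        rows, columns=["sample_id", "subject", "condition", "target", "density"]
    )
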