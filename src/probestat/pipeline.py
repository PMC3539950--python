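"""End-to-end orchestration: simulate -> detect -> DE -> report.

A run is fully reconstructible from its config and seed: every module
parameter lives in :class:`RunConfig`, is serialized into the run
directory as flat YAML, and all randomness flows from the single seed.
Outputs are plain TSV/JSON written deterministically, so two runs with
the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de import (
    AnalyzedChip,
    all_pairs_comparisons,
    classify_catalog,
    paired_de,
    pooled_de,
)
from .detection import CALL_PRESENT, detect_chip, scale_normalize, signal_chip
from .io import write_chipset, write_tsv
from .pcr import analyze_bands
from .simulate import (
    make_default_truth,
    make_scenario,
    simulate_experiment,
    simulate_gel_bands,
)
from .types import ChipSet, DEParamsPooled, DetectionParams, NoiseModel

logger = logging.getLogger("probestat")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "render_catalog",
            "analyze_chipset", "load_annotation"]


@dataclass(frozen=True)
class RunConfig:
    """Every knob of a pipeline run; flat-serializable to YAML."""

    scenario: str = "rat_acute"
    seed: int = 0
    n_genes: int = 500
    absent_fraction: float = 0.2
    # noise model
    background_mean: float = 100.0
    background_sd: float = 20.0
    biological_cv: float = 0.25
    technical_cv: float = 0.15
    crosshyb_fraction: float = 0.35
    saturation_cap: Optional[float] = None
    # detection
    tau: float = 0.015
    alpha1: float = 0.04
    alpha2: float = 0.06
    # signal summary / normalization
    signal_floor: float = 1.0
    norm_target: float = 500.0
    norm_trim: float = 0.02
    # differential expression
    fold_threshold: float = 1.5
    fdr_q: float = 0.05
    require_direction_consistency: bool = True
    require_present: bool = True
    present_rule: str = "either_side"
    mean_p_method: str = "arithmetic"
    paired_alpha: float = 0.05
    # catalogue
    strong_p: float = 0.01
    # PCR arm (paired human scenarios)
    pcr_true_percent: float = 55.0
    pcr_technical_cv: float = 0.065
    annotation_path: Optional[str] = None

    def noise_model(self) -> NoiseModel:
        return NoiseModel(
            background_mean=self.background_mean,
            background_sd=self.background_sd,
            biological_cv=self.biological_cv,
            technical_cv=self.technical_cv,
            crosshyb_fraction=self.crosshyb_fraction,
            saturation_cap=self.saturation_cap,
        )

    def detection_params(self) -> DetectionParams:
        return DetectionParams(tau=self.tau, alpha1=self.alpha1, alpha2=self.alpha2)

    def de_params(self) -> DEParamsPooled:
        return DEParamsPooled(
            fold_threshold=self.fold_threshold,
            fdr_q=self.fdr_q,
            require_direction_consistency=self.require_direction_consistency,
            require_present=self.require_present,
            present_rule=self.present_rule,
            mean_p_method=self.mean_p_method,
        )

    def to_mapping(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_mapping(), sort_keys=True)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping).difference(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_mapping(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything a run produced, plus provenance."""

    config: RunConfig
    catalog: pd.DataFrame
    de_tables: dict[str, pd.DataFrame]
    confusion: dict[str, int]
    pcr: Optional[dict] = None
    out_dir: Optional[Path] = None
    provenance: dict = field(default_factory=dict)


def load_annotation(path: Optional[str] = None) -> pd.DataFrame:
    """Gene annotation table (gene_id, accession, functional_class,
    function); defaults to the packaged hemostasis fixture."""
    if path is not None:
        return pd.read_csv(path, sep="\t")
    ref = resources.files("probestat").joinpath("data/hemostasis_annotation.tsv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def analyze_chipset(chipset: ChipSet, config: RunConfig):
    """Detection + signals + normalization for every chip of a set.

    Returns (analyzed chips, detections dict, signal frame).  The
    detection statistic is scale-invariant and computed on raw
    intensities; the signals carried by the analyzed chips are
    scale-normalized.
    """
    det_params = config.detection_params()
    detections = {c.chip_id: detect_chip(c.matrix, det_params)
                  for c in chipset.chips}
    raw_signals = pd.DataFrame({
        c.chip_id: signal_chip(c.matrix, floor=config.signal_floor)
        for c in chipset.chips
    })
    normalized, factors = scale_normalize(
        raw_signals, target=config.norm_target, trim=config.norm_trim
    )
    # Flag detection p-values below each gene's attainable exact minimum
    # (0.5^n for an n-pair probe set): such values cannot arise from a
    # single-chip exact test and indicate an aggregation elsewhere.
    counts = pd.Series(chipset.chips[0].matrix.probe_counts())
    for cid, det in detections.items():
        floor_p = np.power(0.5, counts.reindex(det["gene_id"]).to_numpy(float))
        too_small = det["p_detect"].to_numpy() < floor_p
        if too_small.any():
            logger.warning(
                "chip %s: %d detection p-values below the single-chip exact "
                "minimum", cid, int(too_small.sum()),
            )
    analyzed = [
        AnalyzedChip(chip=c, signal=normalized[c.chip_id],
                     scale_factor=float(factors[c.chip_id]))
        for c in chipset.chips
    ]
    return analyzed, detections, normalized


def _expressed_mask(detections, chips_by_condition, genes) -> pd.Series:
    """Present on every chip of at least one condition."""
    out = np.zeros(len(genes), dtype=bool)
    for _, chip_ids in chips_by_condition.items():
        pres = np.ones(len(genes), dtype=bool)
        for cid in chip_ids:
            det = detections[cid].set_index("gene_id")["call"].reindex(genes)
            pres &= (det == CALL_PRESENT).to_numpy()
        out |= pres
    return pd.Series(out, index=genes)


def _truth_de_mask(chipset: ChipSet, condition: str, control: str,
                   threshold: float) -> pd.Series:
    genes, flags = [], []
    for t in chipset.truth:
        ratio = t.fold(condition) / t.fold(control)
        flags.append(t.expressed and (ratio >= threshold or ratio <= 1 / threshold))
        genes.append(t.gene_id)
    return pd.Series(flags, index=pd.Index(genes, name="gene_id")).sort_index()


def _confusion(truth_de: pd.Series, called: pd.Series) -> dict[str, int]:
    truth_de, called = truth_de.align(called, join="inner")
    tp = int((truth_de & called).sum())
    fp = int((~truth_de & called).sum())
    fn = int((truth_de & ~called).sum())
    tn = int((~truth_de & ~called).sum())
    return {"true_positive": tp, "false_positive": fp,
            "false_negative": fn, "true_negative": tn}


def run_pipeline(config: RunConfig, out_dir: Path | str | None = None) -> RunReport:
    """Execute simulate -> detect -> DE -> catalogue for one config."""
    try:
        scenario = make_scenario(config.scenario, seed=config.seed)
        truth = make_default_truth(
            scenario, n_genes=config.n_genes,
            absent_fraction=config.absent_fraction,
        )
        chipset = simulate_experiment(scenario, truth, config.noise_model())
    except Exception as exc:
        raise RuntimeError(f"[simulate] {exc}") from exc

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        write_chipset(chipset, out_path / "chips")

    try:
        analyzed, detections, signals = analyze_chipset(chipset, config)
    except Exception as exc:
        raise RuntimeError(f"[detect] {exc}") from exc

    genes = signals.index
    chips_by_condition = {
        cond: [c.chip_id for c in chipset.chips_for(cond)]
        for cond in scenario.conditions
    }

    de_tables: dict[str, pd.DataFrame] = {}
    confusion: dict[str, int] = {}
    try:
        if scenario.pools:
            control = [a for a in analyzed if a.condition == "control"]
            for cond in scenario.conditions:
                if cond == "control":
                    continue
                treat = [a for a in analyzed if a.condition == cond]
                grid = all_pairs_comparisons(treat, control,
                                             floor=config.signal_floor)
                de_tables[f"{cond}_vs_control"] = pooled_de(
                    grid, detections, config.de_params()
                )
            primary = "inactive_vs_control"
            truth_de = _truth_de_mask(chipset, "inactive", "control",
                                      config.fold_threshold)
            confusion = _confusion(
                truth_de, de_tables[primary]["differentially_expressed"]
            )
        elif len(scenario.subjects) >= 2:
            treated_cond, control_cond = "sitting", "ambulatory"
            subject_signals = {}
            for s in scenario.subjects:
                t_chips = [a for a in analyzed
                           if a.chip.unit == s.subject_id
                           and a.condition == treated_cond]
                c_chips = [a for a in analyzed
                           if a.chip.unit == s.subject_id
                           and a.condition == control_cond]
                t_sig = pd.concat([a.signal for a in t_chips], axis=1).mean(axis=1)
                c_sig = pd.concat([a.signal for a in c_chips], axis=1).mean(axis=1)
                subject_signals[s.subject_id] = (t_sig, c_sig)
            expressed = _expressed_mask(detections, chips_by_condition, genes)
            de_tables["sitting_vs_ambulatory"] = paired_de(
                subject_signals,
                fold_threshold=config.fold_threshold,
                alpha=config.paired_alpha,
                expressed=expressed,
            )
            truth_de = _truth_de_mask(chipset, treated_cond, control_cond,
                                      config.fold_threshold)
            confusion = _confusion(
                truth_de,
                de_tables["sitting_vs_ambulatory"]["differentially_expressed"],
            )
        else:
            # Single-subject case study: per-condition percent of control.
            control_cond = scenario.conditions[0]
            ref = pd.concat([
                a.signal for a in analyzed if a.condition == control_cond
            ], axis=1).mean(axis=1)
            rows = {}
            for cond in scenario.conditions:
                if cond == control_cond:
                    continue
                sig = pd.concat([
                    a.signal for a in analyzed if a.condition == cond
                ], axis=1).mean(axis=1)
                rows[cond] = 100.0 * np.power(2.0, sig - ref)
            de_tables["percent_of_control"] = pd.DataFrame(rows)
            truth_de = _truth_de_mask(
                chipset, "sitting_1d", control_cond, config.fold_threshold
            )
            confusion = _confusion(
                truth_de, pd.Series(False, index=truth_de.index)
            )
    except Exception as exc:
        raise RuntimeError(f"[differential_expression] {exc}") from exc

    try:
        catalog = classify_catalog(detections, strong_p=config.strong_p)
    except Exception as exc:
        raise RuntimeError(f"[catalog] {exc}") from exc

    pcr_summary = None
    if scenario.is_paired and len(scenario.subjects) >= 2:
        try:
            bands = simulate_gel_bands(
                [s.subject_id for s in scenario.subjects],
                true_percent_of_control=config.pcr_true_percent,
                technical_cv=config.pcr_technical_cv,
                duplicate_conditions=("ambulatory",),
                seed=config.seed + 1,
            )
            pcr = analyze_bands(bands, control_label="ambulatory")
            pcr_summary = {
                "percent_mean": pcr.percent_mean,
                "percent_sem": pcr.percent_sem,
                "paired_t_p": pcr.paired_t_p,
                "duplicate_cv_percent": pcr.duplicate_cv_percent,
            }
        except Exception as exc:
            raise RuntimeError(f"[pcr] {exc}") from exc

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
    }
    report = RunReport(
        config=config,
        catalog=catalog,
        de_tables=de_tables,
        confusion=confusion,
        pcr=pcr_summary,
        out_dir=out_path,
        provenance=provenance,
    )
    if out_path is not None:
        _write_report(report, detections, signals)
    return report


def _write_report(report: RunReport, detections, signals) -> None:
    out = report.out_dir
    assert out is not None
    (out / "config.yaml").write_text(report.config.to_yaml())
    det_tidy = pd.concat(
        [d.assign(chip_id=cid) for cid, d in sorted(detections.items())],
        ignore_index=True,
    )[["chip_id", "gene_id", "p_detect", "call"]]
    write_tsv(det_tidy, out / "detections.tsv")
    write_tsv(signals.round(6).rename_axis("gene_id").reset_index(),
              out / "signals.tsv")
    write_tsv(report.catalog.rename_axis("gene_id").reset_index(),
              out / "catalog.tsv")
    for name, table in report.de_tables.items():
        write_tsv(table.round(10).rename_axis("gene_id").reset_index(),
                  out / f"de_{name}.tsv")
    annotation = load_annotation(report.config.annotation_path)
    (out / "catalog_report.txt").write_text(
        render_catalog(report.catalog, annotation)
    )
    summary = {
        "confusion": report.confusion,
        "pcr": report.pcr,
        "provenance": report.provenance,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )


def render_catalog(catalog: pd.DataFrame, annotation: pd.DataFrame) -> str:
    """Human-readable detection catalogue grouped by functional class.

    Columns mirror the field's detection tables (gene, accession,
    expression class, frequency, mean detection p, function); Strong
    entries are marked with '*'.  Genes missing from the annotation get
    a blank function column and a logged warning.
    """
    ann = annotation.set_index("gene_id")
    missing = [g for g in catalog.index if g not in ann.index]
    if missing:
        logger.warning("%d catalogued genes lack annotation (e.g. %s)",
                       len(missing), ", ".join(map(str, missing[:3])))
    class_order = ["coagulant", "anti-coagulant", "fibrinolytic",
                   "lysophospholipid", "unannotated"]
    lines = []
    header = (f"{'GENE':<14}{'ACCESSION':<14}{'EXPRESSION':<14}"
              f"{'FREQ':>6}  {'P-VALUE':>9}  FUNCTION")
    lines.append(header)
    lines.append("-" * len(header))
    by_class: dict[str, list[str]] = {c: [] for c in class_order}
    for gene, row in catalog.sort_index().iterrows():
        if gene in ann.index:
            a = ann.loc[gene]
            fclass = str(a["functional_class"])
            accession, function = str(a["accession"]), str(a["function"])
        else:
            fclass, accession, function = "unannotated", "", ""
        mark = "*" if row["class"] == "Strong" else " "
        by_class.setdefault(fclass, []).append(
            f"{mark}{gene:<13}{accession:<14}{row['class']:<14}"
            f"{row['frequency']:>6}  {row['mean_p_detect']:>9.5f}  {function}"
        )
    for fclass in by_class:
        if not by_class[fclass]:
            continue
        lines.append("")
        lines.append(f"[{fclass.upper()}]")
        lines.extend(by_class[fclass])
    return "\n".join(lines) + "\n"
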