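"""Plain-text table formats: chips, manifests, truth, results.

One TSV per chip (gene_id, probe_index, PM, MM), a manifest listing the
chips of an experiment, and a truth table carrying the generative
ground truth of simulated runs.  All files are UTF-8 TSV with header
rows; floats are written with full repr so round-trips are exact.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .types import Chip, ChipSet, GeneTruth, ProbePairMatrix, SimulationScenario

__all__ = [
    "write_chip",
    "read_chip",
    "write_chipset",
    "read_chipset_frames",
    "write_truth",
    "read_truth",
    "write_tsv",
]


def write_tsv(frame: pd.DataFrame, path: Path | str, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def write_chip(matrix: ProbePairMatrix, path: Path | str) -> None:
    write_tsv(matrix.to_frame(), path)


def read_chip(path: Path | str) -> ProbePairMatrix:
    return ProbePairMatrix.from_frame(pd.read_csv(path, sep="\t", float_precision="round_trip"))


def write_chipset(chipset: ChipSet, outdir: Path | str) -> Path:
    """Write per-chip TSVs, a manifest, and the truth table; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for chip in chipset.chips:
        fname = f"chip_{chip.chip_id}.tsv"
        write_chip(chip.matrix, outdir / fname)
        rows.append((chip.chip_id, fname, chip.condition, chip.unit,
                     chip.pool_size, chip.replicate))
    manifest = pd.DataFrame(
        rows,
        columns=["chip_id", "file", "condition", "unit", "pool_size", "replicate"],
    )
    manifest_path = outdir / "manifest.tsv"
    write_tsv(manifest, manifest_path)
    write_truth(chipset.truth, chipset.scenario, outdir / "truth.tsv")
    return manifest_path


def read_chipset_frames(manifest_path: Path | str) -> list[Chip]:
    """Load every chip listed in a manifest TSV."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t", float_precision="round_trip")
    required = {"chip_id", "file", "condition", "unit"}
    missing = required.difference(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    chips = []
    for _, row in manifest.iterrows():
        matrix = read_chip(manifest_path.parent / row["file"])
        chips.append(Chip(
            chip_id=str(row["chip_id"]),
            condition=str(row["condition"]),
            unit=str(row["unit"]),
            matrix=matrix,
            pool_size=int(row.get("pool_size", 1)),
            replicate=int(row.get("replicate", 1)),
        ))
    return chips


def write_truth(truth: Sequence[GeneTruth],
                scenario: SimulationScenario,
                path: Path | str) -> None:
    conditions = list(scenario.conditions)
    rows = []
    for t in truth:
        rows.append([t.gene_id, t.baseline_expression, t.expressed]
                    + [t.fold(c) for c in conditions])
    frame = pd.DataFrame(
        rows, columns=["gene_id", "baseline", "expressed"]
        + [f"fold_{c}" for c in conditions],
    )
    write_tsv(frame, path)


def read_truth(path: Path | str) -> list[GeneTruth]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    fold_cols = [c for c in frame.columns if c.startswith("fold_")]
    truth = []
    for _, row in frame.iterrows():
        truth.append(GeneTruth(
            gene_id=str(row["gene_id"]),
            baseline_expression=float(row["baseline"]),
            fold_by_condition={c[len("fold_"):]: float(row[c]) for c in fold_cols},
            expressed=bool(row["expressed"]),
        ))
    return truth
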