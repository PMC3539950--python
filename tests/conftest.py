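"""Shared fixtures: tiny deterministic chip sets built through the
package's own simulator."""

import numpy as np
import pandas as pd
import pytest

from probestat.de import AnalyzedChip
from probestat.detection import signal_chip
from probestat.types import Chip, ProbePairMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def matrix_from_arrays(gene_ids, pm, mm) -> ProbePairMatrix:
    """Build a single-group probe matrix from 2-D PM/MM arrays."""
    pm = np.asarray(pm, dtype=float)
    return ProbePairMatrix({pm.shape[1]: (list(gene_ids), pm, mm)})


def analyzed(chip_id, matrix, condition="control", unit=None,
             signal=None, scale_factor=1.0) -> AnalyzedChip:
    """Wrap a matrix as an AnalyzedChip, default un-normalized signals."""
    if signal is None:
        signal = signal_chip(matrix)
    chip = Chip(chip_id=chip_id, condition=condition,
                unit=unit or chip_id, matrix=matrix)
    return AnalyzedChip(chip=chip, signal=signal, scale_factor=scale_factor)


@pytest.fixture
def small_pair(rng):
    """Two chips over 6 genes x 8 probe pairs: control and a 2x-up
    treatment copy (same design, shared probe structure)."""
    genes = [f"g{i}" for i in range(6)]
    base = rng.uniform(200, 2000, size=(6, 8))
    mm = rng.uniform(50, 150, size=(6, 8))
    control = matrix_from_arrays(genes, base + mm, mm)
    treatment = matrix_from_arrays(genes, 2 * (base + mm), 2 * mm)
    return genes, control, treatment
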