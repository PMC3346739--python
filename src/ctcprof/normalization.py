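"""Balanced subsampling, -dCt reference normalization and gene selection.

Expression of gene *g* in cell *c* is summarized on a log2-like scale as
the negative delta Ct,

    -dCt(c, g) = -(Ct(c, g) - mean_r Ct(c, r)),

the difference to the mean Ct of a reference panel (UBB/ACTB/GAPDH for
patient analyses; UBB alone for cell-line analyses), so that higher
values mean more transcript.  Values are then median-centered per gene
over observed measurements; missing calls stay missing until the
clustering stage imputes them.

To avoid over-representing prolific samples, the analysis set is first
balanced: at most ``max_per_patient`` CTCs per patient (uniform random
without replacement) and exactly ``per_cell_line`` cells per cell line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .qpcr_io import CtMatrix
from .quality_control import ExpressionCalls

DEFAULT_MAX_PER_PATIENT = 5
DEFAULT_PER_CELL_LINE = 7
DEFAULT_REFERENCE_PANEL = ("UBB", "ACTB", "GAPDH")
DEFAULT_MIN_DETECTABLE_FRAC = 0.15


@dataclass
class AnalysisSet:
    """Balanced cell selection with the rule echo and seed."""

    cells: tuple[str, ...]
    max_per_patient: int
    per_cell_line: int
    seed: int


def subsample(
    ctc_cells: Sequence[str],
    meta: pd.DataFrame,
    *,
    cell_line_cells: Sequence[str] = (),
    max_per_patient: int = DEFAULT_MAX_PER_PATIENT,
    per_cell_line: int = DEFAULT_PER_CELL_LINE,
    seed: int = 0,
) -> AnalysisSet:
    """Balance the analysis set across patients and cell lines.

    Patients contribute at most ``max_per_patient`` of their CTCs
    (patients at or under the cap contribute all); each cell line must
    contribute exactly ``per_cell_line`` cells, sampled uniformly
    without replacement.  Deterministic under ``seed``; selected cells
    keep their input order.
    """
    if max_per_patient < 1 or per_cell_line < 1:
        raise ConfigError("subsampling caps must be positive")
    subject_of = meta.set_index("cell_id")["subject_id"]
    rng = np.random.default_rng(seed)

    selected: list[str] = []
    ctc_cells = list(ctc_cells)
    by_patient = pd.Series(
        [subject_of[c] for c in ctc_cells], index=ctc_cells, dtype=object
    )
    for patient in pd.unique(by_patient):
        cells = [c for c in ctc_cells if by_patient[c] == patient]
        if len(cells) > max_per_patient:
            keep = set(rng.choice(len(cells), size=max_per_patient, replace=False))
            cells = [c for i, c in enumerate(cells) if i in keep]
        selected.extend(cells)

    line_cells = list(cell_line_cells)
    by_line = pd.Series(
        [subject_of[c] for c in line_cells], index=line_cells, dtype=object
    )
    for line in pd.unique(by_line):
        cells = [c for c in line_cells if by_line[c] == line]
        if len(cells) < per_cell_line:
            raise DataError(
                f"cell line {line!r} has only {len(cells)} eligible cells; "
                f"{per_cell_line} required"
            )
        if len(cells) > per_cell_line:
            keep = set(rng.choice(len(cells), size=per_cell_line, replace=False))
            cells = [c for i, c in enumerate(cells) if i in keep]
        selected.extend(cells)

    return AnalysisSet(
        cells=tuple(selected),
        max_per_patient=max_per_patient,
        per_cell_line=per_cell_line,
        seed=seed,
    )


@dataclass
class NormalizedMatrix:
    """Median-centered -dCt values (higher = more expressed).

    ``values`` holds NaN where a gene was not expressed in a cell;
    ``gene_medians`` are the pre-centering per-gene medians;
    ``pooled_sd`` is the standard deviation of all observed centered
    values pooled across genes (used for imputation and truncation).
    """

    values: pd.DataFrame
    gene_medians: pd.Series
    reference_panel: tuple[str, ...]
    pooled_sd: float


def normalize(
    ct: CtMatrix,
    calls: ExpressionCalls,
    analysis_set: AnalysisSet | Sequence[str],
    reference_panel: Sequence[str] = DEFAULT_REFERENCE_PANEL,
) -> NormalizedMatrix:
    """Reference-panel -dCt normalization with per-gene median centering.

    Every analysis cell must have expressed calls for every reference
    assay.  Reference assays are normalized like any other gene and stay
    in the matrix.  Genes with no observed value in the analysis set get
    a median of 0 by convention and stay all-missing.
    """
    cells = list(analysis_set.cells if isinstance(analysis_set, AnalysisSet) else analysis_set)
    refs = list(reference_panel)
    if not refs:
        raise ConfigError("empty reference panel")
    for ref in refs:
        if ref not in calls.retained.columns:
            raise ConfigError(f"reference assay {ref!r} not among retained assays")

    expressed = calls.retained.loc[cells]
    for cell in cells:
        missing = [r for r in refs if not expressed.loc[cell, r]]
        if missing:
            raise DataError(
                f"cell {cell!r} lacks expressed reference calls for {missing}"
            )

    raw_ct = ct.ct.loc[cells, expressed.columns]
    ref_mean = ct.ct.loc[cells, refs].mean(axis=1)
    neg_dct = -(raw_ct.sub(ref_mean, axis=0))
    neg_dct = neg_dct.where(expressed)

    medians = neg_dct.median(axis=0, skipna=True).fillna(0.0)
    centered = neg_dct.sub(medians, axis=1)
    observed = centered.to_numpy()[np.isfinite(centered.to_numpy())]
    pooled_sd = float(np.std(observed, ddof=1)) if observed.size > 1 else 0.0
    return NormalizedMatrix(
        values=centered,
        gene_medians=medians,
        reference_panel=tuple(refs),
        pooled_sd=pooled_sd,
    )


def select_detectable_genes(
    calls: ExpressionCalls,
    ctc_cells: Sequence[str],
    min_frac: float = DEFAULT_MIN_DETECTABLE_FRAC,
) -> list[str]:
    """Genes expressed in at least ``min_frac`` of the CTC analysis cells.

    The threshold is boundary-inclusive ("at least"): a gene expressed
    in exactly ``min_frac`` of cells is retained.
    """
    cells = list(ctc_cells)
    if not cells:
        raise DataError("empty CTC analysis set")
    if not 0.0 <= min_frac <= 1.0:
        raise ConfigError("min_frac outside [0, 1]")
    frac = calls.retained.loc[cells].mean(axis=0)
    return list(frac.index[frac >= min_frac])
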