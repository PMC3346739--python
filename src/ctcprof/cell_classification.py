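"""Rule-based gating of patient-derived cells into CTC / WBC / other.

A captured cell qualifies as a circulating tumor cell (CTC) only under
a stringent marker definition: intact reference-gene RNA, expression of
at least one cytokeratin (KRT7/KRT8/KRT18/KRT19) and *no* detectable
CD45 (PTPRC), the leukocyte-common antigen.  Cells expressing CD45
alone are white blood cells; keratin/CD45 double positives are an
"unknown"/ambiguous category reported separately (never counted as
WBC); cells with degraded reference RNA are flagged regardless of
markers; the keratin-/CD45- remainder falls into a residual
non-epithelial bucket.

The classifier is a pure function of a cell's expression calls and its
integrity flag, evaluated in a fixed gate order with a recorded trail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection

import pandas as pd

from .errors import ConfigError
from .qpcr_io import GenePanel
from .quality_control import ExpressionCalls

LABEL_CTC = "CTC"
LABEL_WBC = "WBC"
LABEL_AMBIGUOUS = "AMBIGUOUS_KRT_CD45"
LABEL_DEGRADED = "DEGRADED"
LABEL_NON_EPITHELIAL = "NON_EPITHELIAL"
ALL_LABELS = (LABEL_CTC, LABEL_WBC, LABEL_AMBIGUOUS, LABEL_DEGRADED, LABEL_NON_EPITHELIAL)


@dataclass
class CellClassification:
    """Per-cell gating outcome with the fired-rule trail."""

    cell_id: str
    label: str
    trail: tuple[str, ...]
    keratins_expressed: tuple[str, ...]
    cd45_expressed: bool


def _marker_assays(panel: GenePanel, columns: pd.Index) -> tuple[list[str], str]:
    keratins = [k for k in panel.epithelial_markers if k not in panel.excluded_assays]
    missing = [k for k in keratins if k not in columns]
    if not keratins or missing:
        raise ConfigError(f"epithelial marker assays unavailable: missing {missing}")
    leuko = [g for g in panel.leukocyte_assays if g not in panel.excluded_assays]
    if len(leuko) != 1 or leuko[0] not in columns:
        raise ConfigError("leukocyte (CD45) assay unavailable in panel/calls")
    return keratins, leuko[0]


def classify_cell(
    calls_row: pd.Series, panel: GenePanel, integrity_pass: bool
) -> CellClassification:
    """Gate one patient-derived cell.

    Gate order: degraded RNA, then keratin+CD45 double positive, then
    CD45 only (WBC), then any keratin (CTC), else non-epithelial.
    """
    keratins, cd45 = _marker_assays(panel, calls_row.index)
    krt_on = tuple(k for k in keratins if bool(calls_row[k]))
    cd45_on = bool(calls_row[cd45])

    trail = [f"reference_integrity={'pass' if integrity_pass else 'fail'}"]
    if not integrity_pass:
        label = LABEL_DEGRADED
    else:
        trail.append(f"cd45_expressed={cd45_on}")
        trail.append(f"keratins_expressed={','.join(krt_on) if krt_on else 'none'}")
        if cd45_on and krt_on:
            label = LABEL_AMBIGUOUS
        elif cd45_on:
            label = LABEL_WBC
        elif krt_on:
            label = LABEL_CTC
        else:
            label = LABEL_NON_EPITHELIAL
    trail.append(f"label={label}")
    return CellClassification(
        cell_id=str(calls_row.name),
        label=label,
        trail=tuple(trail),
        keratins_expressed=krt_on,
        cd45_expressed=cd45_on,
    )


def classify_all(
    calls: ExpressionCalls,
    meta: pd.DataFrame,
    panel: GenePanel,
    integrity_pass: Collection[str],
) -> tuple[pd.DataFrame, dict]:
    """Classify every patient-derived cell and summarize label fractions.

    ``integrity_pass`` is the retained set of the reference-integrity
    gate.  Cell-line cells and NTC wells bypass classification.  The
    summary reports per-label fractions among integrity-passing patient
    cells and among all patient cells.
    """
    patient_cells = meta.loc[meta["source"] == "patient", "cell_id"]
    patient_cells = [c for c in patient_cells if c in calls.expressed.index]
    passing = set(integrity_pass)

    rows = []
    for cell in patient_cells:
        cls = classify_cell(calls.expressed.loc[cell], panel, cell in passing)
        rows.append(
            {
                "cell_id": cls.cell_id,
                "label": cls.label,
                "cd45_expressed": cls.cd45_expressed,
                "keratins_expressed": ",".join(cls.keratins_expressed),
                "trail": " -> ".join(cls.trail),
            }
        )
    table = pd.DataFrame(
        rows, columns=["cell_id", "label", "cd45_expressed", "keratins_expressed", "trail"]
    )

    n_all = len(table)
    intact = table[table["label"] != LABEL_DEGRADED]
    n_intact = len(intact)
    summary = {
        "n_patient_cells": n_all,
        "n_integrity_pass": n_intact,
        "fraction_of_intact": {
            label: (float((intact["label"] == label).sum()) / n_intact if n_intact else 0.0)
            for label in ALL_LABELS
            if label != LABEL_DEGRADED
        },
        "fraction_of_all": {
            label: (float((table["label"] == label).sum()) / n_all if n_all else 0.0)
            for label in ALL_LABELS
        },
    }
    return table, summary
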