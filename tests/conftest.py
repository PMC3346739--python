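"""Shared fixtures: tiny hand-built datasets and one cached default run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ctcprof import qpcr_io as io
from ctcprof.cli_report import PipelineConfig, run_pipeline


@pytest.fixture
def small_panel() -> io.GenePanel:
    """Panel with references, keratins, CD45 and three cancer genes."""
    cats = {g: "reference" for g in ("UBB", "ACTB", "GAPDH")}
    cats.update({g: "epithelial" for g in ("KRT7", "KRT8", "KRT18", "KRT19")})
    cats["PTPRC"] = "leukocyte"
    cats.update({g: "cancer_associated" for g in ("VIM", "CD24", "S100A9")})
    return io.GenePanel.from_categories(cats)


def make_ct_matrix(
    ct_rows: dict[str, list[float]],
    assays: list[str],
    quality: dict[str, list[float]] | None = None,
    chips: dict[str, str] | None = None,
) -> io.CtMatrix:
    """Build a CtMatrix from per-cell Ct lists (NaN = absent)."""
    cells = list(ct_rows)
    ct = pd.DataFrame([ct_rows[c] for c in cells], index=cells, columns=assays,
                      dtype=float)
    if quality is None:
        q = pd.DataFrame(1.0, index=cells, columns=assays)
    else:
        q = pd.DataFrame([quality[c] for c in cells], index=cells, columns=assays,
                         dtype=float)
    chip = pd.Series({c: (chips or {}).get(c, "chipA") for c in cells})
    return io.CtMatrix(ct=ct, quality=q, chip_of_cell=chip)


@pytest.fixture
def tiny_ct(small_panel) -> io.CtMatrix:
    assays = small_panel.assays
    rng = np.random.default_rng(0)
    rows = {f"c{i}": list(rng.uniform(15, 30, len(assays))) for i in range(3)}
    return make_ct_matrix(rows, assays)


@pytest.fixture(scope="session")
def default_run():
    """One full default-configuration pipeline run shared across tests."""
    return run_pipeline(PipelineConfig(seed=1, render_heatmaps=False))
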