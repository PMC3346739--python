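"""Reading, writing and validation of single-cell qPCR chip data.

The central container is :class:`CtMatrix`: a cells x assays matrix of raw
PCR cycle-threshold (Ct) values together with per-measurement quality
scores, the chip each cell was run on, and a ``measured`` mask that
distinguishes "reaction was run but produced no amplification" (Ct absent)
from "this assay was never loaded for this chip" (entry not measured).
That distinction feeds the cross-chip gene-exclusion rule downstream.

Chip exports are long-format delimited text (one row per cell x assay
reaction).  Because real-time PCR instruments do not share a standard
export schema, the expected column names and no-amplification sentinels
are configurable through :class:`Dialect`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .errors import DataError, FormatError, IntegrityError, RangeError

#: Housekeeping assays used for normalization and RNA-integrity gating.
REFERENCE_GENES = ("UBB", "ACTB", "GAPDH")
#: Cytokeratin assays whose expression defines an epithelial cell.
EPITHELIAL_KERATINS = ("KRT7", "KRT8", "KRT18", "KRT19")
#: Leukocyte-common antigen (CD45); expression marks a white blood cell.
LEUKOCYTE_GENE = "PTPRC"

#: Allowed assay categories in a :class:`GenePanel`.
PANEL_CATEGORIES = ("reference", "epithelial", "leukocyte", "cancer_associated")
#: Allowed exclusion annotations.
EXCLUSION_REASONS = ("not_on_all_chips", "ntc_positive", "none")

#: Columns required in a cell metadata table.
META_COLUMNS = (
    "cell_id",
    "source",
    "subject_id",
    "sample_id",
    "stage",
    "er_status",
    "pr_status",
    "her2_status",
    "age_at_diagnosis",
)


class Dialect(BaseModel):
    """Schema of a long-format chip export.

    ``na_values`` are Ct field contents meaning "no amplification"; the
    first entry is used when writing.  With ``quality_optional`` a table
    lacking the quality column is accepted and all scores default to 1.0
    (pass), so Ct-only tables remain usable.
    """

    chip_col: str = "Chip"
    cell_col: str = "Sample"
    assay_col: str = "Assay"
    ct_col: str = "Ct"
    quality_col: str = "Quality"
    replicate_col: str | None = None
    na_values: tuple[str, ...] = ("999", "No Call", "")
    quality_optional: bool = True
    sep: str = "\t"


DEFAULT_DIALECT = Dialect()


@dataclass
class CtMatrix:
    """Raw Ct values and quality scores for cells x assays.

    ``ct`` holds cycle-threshold values (NaN = absent), ``quality``
    per-measurement quality scores in [0, 1] (1.0 where the instrument
    reported none), ``measured`` whether the reaction was physically run.
    """

    ct: pd.DataFrame
    quality: pd.DataFrame
    chip_of_cell: pd.Series
    measured: pd.DataFrame | None = None
    replicate_of_cell: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.measured is None:
            self.measured = pd.DataFrame(
                True, index=self.ct.index, columns=self.ct.columns
            )
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        ct, q = self.ct, self.quality
        if ct.shape != q.shape or self.measured.shape != ct.shape:
            raise IntegrityError("ct, quality and measured shapes differ")
        if not (ct.index.equals(q.index) and ct.columns.equals(q.columns)):
            raise IntegrityError("ct and quality are not aligned")
        if ct.index.has_duplicates:
            raise IntegrityError("duplicate cell ids")
        if ct.columns.has_duplicates:
            raise IntegrityError("duplicate assay ids")
        if (ct.to_numpy() < 0).any():
            raise RangeError("negative Ct value")
        qv = q.to_numpy(dtype=float)
        if np.nanmin(qv, initial=1.0) < 0 or np.nanmax(qv, initial=0.0) > 1:
            raise RangeError("quality score outside [0, 1]")
        missing_chip = [c for c in ct.index if c not in self.chip_of_cell.index]
        if missing_chip:
            raise IntegrityError(f"cells without chip assignment: {missing_chip[:5]}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def chips(self) -> list[str]:
        return list(pd.unique(self.chip_of_cell.loc[self.ct.index]))

    def cells_on_chip(self, chip: str) -> pd.Index:
        on = self.chip_of_cell.loc[self.ct.index] == chip
        return self.ct.index[on.to_numpy()]

    def subset_cells(self, cells: Sequence[str]) -> "CtMatrix":
        cells = pd.Index(cells)
        return CtMatrix(
            ct=self.ct.loc[cells],
            quality=self.quality.loc[cells],
            chip_of_cell=self.chip_of_cell.loc[cells],
            measured=self.measured.loc[cells],
            replicate_of_cell=(
                None
                if self.replicate_of_cell is None
                else self.replicate_of_cell.loc[cells]
            ),
        )

    def equals(self, other: "CtMatrix") -> bool:
        return (
            self.ct.equals(other.ct)
            and self.quality.equals(other.quality)
            and self.measured.equals(other.measured)
            and self.chip_of_cell.loc[self.ct.index].equals(
                other.chip_of_cell.loc[other.ct.index]
            )
        )


# ---------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------


@dataclass
class GenePanel:
    """Assay catalogue with functional roles and exclusion annotations.

    ``table`` is indexed by assay name with columns ``category``,
    ``excluded`` (bool) and ``exclusion_reason``.  Excluded assays stay in
    the table as an audit trail; downstream analyses use :attr:`retained`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise IntegrityError("duplicate assay names in panel")
        bad = set(t["category"]) - set(PANEL_CATEGORIES)
        if bad:
            raise IntegrityError(f"unknown panel categories: {sorted(bad)}")
        if "excluded" not in t.columns:
            t["excluded"] = False
        if "exclusion_reason" not in t.columns:
            t["exclusion_reason"] = "none"
        if not len(self.reference_assays):
            raise IntegrityError("panel has no reference assay")

    @classmethod
    def from_categories(cls, categories: Mapping[str, str]) -> "GenePanel":
        table = pd.DataFrame(
            {
                "category": pd.Series(dict(categories)),
                "excluded": False,
                "exclusion_reason": "none",
            }
        )
        table.index.name = "assay"
        return cls(table)

    @property
    def assays(self) -> list[str]:
        return list(self.table.index)

    @property
    def reference_assays(self) -> list[str]:
        return list(self.table.index[self.table["category"] == "reference"])

    @property
    def epithelial_markers(self) -> list[str]:
        return list(self.table.index[self.table["category"] == "epithelial"])

    @property
    def leukocyte_assays(self) -> list[str]:
        return list(self.table.index[self.table["category"] == "leukocyte"])

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[~self.table["excluded"]])

    @property
    def excluded_assays(self) -> list[str]:
        return list(self.table.index[self.table["excluded"]])

    def with_exclusions(self, reasons: Mapping[str, str]) -> "GenePanel":
        """Return a new panel with ``reasons`` (assay -> reason) applied."""
        table = self.table.copy()
        for assay, reason in reasons.items():
            if assay not in table.index:
                raise IntegrityError(f"cannot exclude unknown assay {assay!r}")
            if reason not in EXCLUSION_REASONS:
                raise IntegrityError(f"unknown exclusion reason {reason!r}")
            table.loc[assay, ["excluded", "exclusion_reason"]] = (
                reason != "none",
                reason,
            )
        return GenePanel(table)

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        records = [
            {
                "name": name,
                "category": row["category"],
                "excluded": bool(row["excluded"]),
                "exclusion_reason": row["exclusion_reason"],
            }
            for name, row in self.table.iterrows()
        ]
        Path(path).write_text(json.dumps({"assays": records}, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GenePanel":
        payload = json.loads(Path(path).read_text())
        try:
            records = payload["assays"]
            table = pd.DataFrame(records).set_index("name")
        except (KeyError, TypeError) as exc:
            raise FormatError(f"malformed panel file {path}: {exc}") from exc
        table.index.name = "assay"
        return cls(table[["category", "excluded", "exclusion_reason"]])


# ---------------------------------------------------------------------
# Long-format chip tables
# ---------------------------------------------------------------------


def read_ct_table(path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> CtMatrix:
    """Read a long-format chip export into a :class:`CtMatrix`.

    Row and column order of the matrix follow first appearance in the
    file.  Ct fields matching ``dialect.na_values`` map to absent entries;
    (cell, assay) pairs with no row at all are marked unmeasured.
    """
    raw = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    required = [dialect.chip_col, dialect.cell_col, dialect.assay_col, dialect.ct_col]
    if not dialect.quality_optional:
        required.append(dialect.quality_col)
    for col in required:
        if col not in raw.columns:
            raise FormatError(f"missing required column {col!r} in {path}")

    keys = [dialect.cell_col, dialect.assay_col]
    if dialect.replicate_col is not None and dialect.replicate_col in raw.columns:
        keys.append(dialect.replicate_col)
    if raw.duplicated(subset=keys).any():
        dup = raw[raw.duplicated(subset=keys)].iloc[0]
        raise IntegrityError(
            f"duplicate measurement for cell {dup[dialect.cell_col]!r}, "
            f"assay {dup[dialect.assay_col]!r}"
        )

    # Replicated designs are folded into distinct matrix rows per replicate.
    if len(keys) == 3:
        row_id = raw[dialect.cell_col] + "#" + raw[dialect.replicate_col]
        replicate_of_cell = pd.Series(
            pd.to_numeric(raw[dialect.replicate_col]).to_numpy(), index=row_id.to_numpy()
        )
        replicate_of_cell = replicate_of_cell[~replicate_of_cell.index.duplicated()]
    else:
        row_id = raw[dialect.cell_col]
        replicate_of_cell = None

    ct_str = raw[dialect.ct_col].str.strip()
    ct_vals = pd.to_numeric(ct_str.where(~ct_str.isin(dialect.na_values)), errors="raise")
    if (ct_vals.dropna() < 0).any():
        raise RangeError("negative Ct value in table")

    if dialect.quality_col in raw.columns:
        q_str = raw[dialect.quality_col].str.strip()
        q_vals = pd.to_numeric(q_str.where(q_str != ""), errors="raise").fillna(1.0)
        if ((q_vals < 0) | (q_vals > 1)).any():
            raise RangeError("quality score outside [0, 1]")
    else:
        q_vals = pd.Series(1.0, index=raw.index)

    cells = pd.unique(row_id)
    assays = pd.unique(raw[dialect.assay_col])
    shape = (len(cells), len(assays))
    ridx = pd.Index(cells).get_indexer(row_id)
    cidx = pd.Index(assays).get_indexer(raw[dialect.assay_col])

    ct = np.full(shape, np.nan)
    quality = np.full(shape, 1.0)
    measured = np.zeros(shape, dtype=bool)
    ct[ridx, cidx] = ct_vals.to_numpy()
    quality[ridx, cidx] = q_vals.to_numpy()
    measured[ridx, cidx] = True

    chip_per_row = pd.Series(raw[dialect.chip_col].to_numpy(), index=row_id.to_numpy())
    conflicts = chip_per_row.groupby(level=0).nunique()
    if (conflicts > 1).any():
        raise IntegrityError(
            f"cell assigned to multiple chips: {conflicts.index[conflicts > 1][0]!r}"
        )
    chip_of_cell = chip_per_row[~chip_per_row.index.duplicated()].loc[cells]

    return CtMatrix(
        ct=pd.DataFrame(ct, index=cells, columns=assays),
        quality=pd.DataFrame(quality, index=cells, columns=assays),
        chip_of_cell=chip_of_cell,
        measured=pd.DataFrame(measured, index=cells, columns=assays),
        replicate_of_cell=replicate_of_cell,
    )


def write_ct_table(
    matrix: CtMatrix, path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> None:
    """Write a :class:`CtMatrix` as a long-format chip export.

    Only measured reactions produce rows; absent Ct values are written as
    the dialect's first no-amplification sentinel.  ``read_ct_table``
    round-trips the result exactly (floats use shortest-repr formatting).
    """
    sentinel = dialect.na_values[0]
    lines = [
        dialect.sep.join(
            [
                dialect.chip_col,
                dialect.cell_col,
                dialect.assay_col,
                dialect.ct_col,
                dialect.quality_col,
            ]
        )
    ]
    measured = matrix.measured.to_numpy()
    ct = matrix.ct.to_numpy()
    quality = matrix.quality.to_numpy()
    for i, cell in enumerate(matrix.cell_ids):
        chip = matrix.chip_of_cell.loc[cell]
        for j, assay in enumerate(matrix.assay_ids):
            if not measured[i, j]:
                continue
            ct_field = sentinel if math.isnan(ct[i, j]) else repr(float(ct[i, j]))
            lines.append(
                dialect.sep.join(
                    [str(chip), str(cell), str(assay), ct_field, repr(float(quality[i, j]))]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------
# Generic matrices and metadata
# ---------------------------------------------------------------------


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a cells x genes matrix as TSV; absent values become ``NA``."""
    vals = matrix.to_numpy(dtype=float)
    if np.isinf(vals).any():
        raise DataError("matrix contains non-finite values")
    out = matrix.copy()
    out.index.name = out.index.name or "cell_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix`."""
    return pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False
    )


def write_cell_meta(meta: pd.DataFrame, path: str | Path) -> None:
    validate_cell_meta(meta)
    meta.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    validate_cell_meta(meta)
    return meta


def validate_cell_meta(meta: pd.DataFrame) -> None:
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise FormatError(f"cell metadata missing column {col!r}")
    if meta["cell_id"].duplicated().any():
        raise IntegrityError("duplicate cell_id in metadata")


# ---------------------------------------------------------------------
# Cross-file validation
# ---------------------------------------------------------------------


@dataclass
class ValidationIssue:
    code: str
    severity: str  # "fatal" | "warning" | "info"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "fatal" for i in self.issues)

    def add(self, code: str, severity: str, message: str) -> None:
        self.issues.append(ValidationIssue(code, severity, message))

    def by_code(self, code: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.code == code]


def validate_dataset(
    ct: CtMatrix, panel: GenePanel, meta: pd.DataFrame
) -> ValidationReport:
    """Check cross-file consistency of a chip dataset.

    Fatal issues: assays absent from the panel, cells without metadata.
    Informational: assays not measured on every chip (these feed the
    cross-chip gene-exclusion rule).
    """
    report = ValidationReport()
    unknown = [a for a in ct.assay_ids if a not in panel.table.index]
    for assay in unknown:
        report.add("unknown_assay", "fatal", f"assay {assay!r} not in panel")

    meta_cells = set(meta["cell_id"])
    for cell in ct.cell_ids:
        if cell not in meta_cells:
            report.add("missing_metadata", "fatal", f"cell {cell!r} has no metadata row")
    for cell in meta_cells - set(ct.cell_ids):
        report.add("unused_metadata", "warning", f"metadata cell {cell!r} not in Ct table")

    for assay in ct.assay_ids:
        absent_chips = [
            chip
            for chip in ct.chips
            if not ct.measured.loc[ct.cells_on_chip(chip), assay].any()
        ]
        if absent_chips:
            report.add(
                "assay_not_on_all_chips",
                "info",
                f"assay {assay!r} has no measurements on chips {absent_chips}",
            )
    return report
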