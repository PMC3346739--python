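"""Measurement-, gene- and cell-level quality-control gates.

The gates implement the study's filtering rules in order:

1. **Measurement QC** -- a reaction counts as *expressed* only if its Ct
   is present, below ``ct_max`` (default 35 cycles) and its quality
   score is at least ``quality_min`` (default 0.65); everything else is
   missing/immeasurable.
2. **Gene exclusion** -- assays whose primer sets were not loaded on
   every chip, or that amplified in a no-template control (NTC) on at
   least one chip, are excluded from the panel (annotations are kept as
   an audit trail).
3. **Minimum expression screen** -- cells must express at least
   ``min_genes`` (default 10) of the retained assays.
4. **Reference-integrity gate** -- a cell's RNA counts as intact only if
   UBB is expressed with Ct strictly below 25 cycles and both ACTB and
   GAPDH are expressed; failures are flagged as degraded RNA.

A :class:`FunnelReport` chains the per-stage counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigError, IntegrityError
from .qpcr_io import CtMatrix, GenePanel

DEFAULT_QUALITY_MIN = 0.65
DEFAULT_CT_MAX = 35.0
DEFAULT_UBB_MAX_CT = 25.0
DEFAULT_MIN_GENES = 10


@dataclass
class ExpressionCalls:
    """Boolean expressed/missing matrix after measurement QC.

    ``expressed`` covers every assay of the source matrix; assays listed
    in ``excluded_assays`` carry no usable calls and are dropped by
    :attr:`retained`.
    """

    expressed: pd.DataFrame
    quality_min: float
    ct_max: float
    excluded_assays: tuple[str, ...] = ()

    @property
    def retained(self) -> pd.DataFrame:
        """Calls restricted to non-excluded assays."""
        keep = [a for a in self.expressed.columns if a not in set(self.excluded_assays)]
        return self.expressed[keep]

    def with_exclusions(self, excluded: Sequence[str]) -> "ExpressionCalls":
        return ExpressionCalls(
            expressed=self.expressed,
            quality_min=self.quality_min,
            ct_max=self.ct_max,
            excluded_assays=tuple(excluded),
        )


def apply_measurement_qc(
    ct: CtMatrix,
    quality_min: float = DEFAULT_QUALITY_MIN,
    ct_max: float = DEFAULT_CT_MAX,
) -> ExpressionCalls:
    """Call each measurement expressed or missing/immeasurable.

    Expressed iff the reaction was run, Ct present and < ``ct_max``, and
    quality >= ``quality_min``.  Both boundaries follow the study rules:
    Ct exactly at the ceiling is *not* expressed, quality exactly at the
    floor *is* acceptable.
    """
    if not 0.0 <= quality_min <= 1.0:
        raise ConfigError("quality_min outside [0, 1]")
    if not pd.notna(ct_max):
        raise ConfigError("ct_max must be finite")
    expressed = (
        ct.measured & ct.ct.notna() & (ct.ct < ct_max) & (ct.quality >= quality_min)
    )
    return ExpressionCalls(expressed=expressed, quality_min=quality_min, ct_max=ct_max)


def exclude_genes(
    panel: GenePanel,
    ct: CtMatrix,
    ntc_cells: Sequence[str],
    calls: ExpressionCalls | None = None,
) -> GenePanel:
    """Apply the two gene-exclusion rules and annotate the panel.

    Rule 1 excludes assays with no measurement rows on at least one
    chip; rule 2 excludes assays with an expressed call in any NTC well.
    When both fire, the first (cross-chip) reason is stored.  With no
    NTC wells, rule 2 is skipped with a warning.
    """
    if calls is None:
        calls = apply_measurement_qc(ct)
    ntc_cells = [c for c in ntc_cells]
    unknown = [c for c in ntc_cells if c not in ct.ct.index]
    if unknown:
        raise IntegrityError(f"NTC cells not in Ct matrix: {unknown[:5]}")
    if not ntc_cells:
        warnings.warn(
            "no NTC cells available; skipping false-positive exclusion rule",
            stacklevel=2,
        )

    reasons: dict[str, str] = {}
    chips = ct.chips
    chip_cells = {chip: ct.cells_on_chip(chip) for chip in chips}
    for assay in ct.assay_ids:
        if assay not in panel.table.index:
            continue
        on_all = all(ct.measured.loc[chip_cells[chip], assay].any() for chip in chips)
        if not on_all:
            reasons[assay] = "not_on_all_chips"
        elif ntc_cells and calls.expressed.loc[ntc_cells, assay].any():
            reasons[assay] = "ntc_positive"
    return panel.with_exclusions(reasons)


def filter_cells_min_genes(
    calls: ExpressionCalls, min_genes: int = DEFAULT_MIN_GENES
) -> pd.Index:
    """Cells expressing at least ``min_genes`` retained assays (boundary inclusive)."""
    counts = calls.retained.sum(axis=1)
    return counts.index[counts >= min_genes]


def reference_integrity_gate(
    ct: CtMatrix,
    calls: ExpressionCalls,
    panel: GenePanel | None = None,
    ubb_max_ct: float = DEFAULT_UBB_MAX_CT,
) -> pd.Index:
    """Cells whose reference-gene RNA is intact.

    Requires UBB expressed with Ct strictly below ``ubb_max_ct`` plus
    expressed ACTB and GAPDH calls (no extra Ct ceiling beyond the
    global measurement rule).  Cells failing are degraded RNA.
    """
    refs = ("UBB", "ACTB", "GAPDH") if panel is None else tuple(panel.reference_assays)
    for ref in refs + (("UBB",) if "UBB" not in refs else ()):
        if ref not in calls.expressed.columns:
            raise ConfigError(f"reference assay {ref!r} missing from calls")
        if ref in calls.excluded_assays:
            raise ConfigError(
                f"reference assay {ref!r} was excluded by the gene-exclusion rules; "
                "the pipeline cannot proceed"
            )
    ok = calls.expressed["UBB"] & (ct.ct["UBB"] < ubb_max_ct)
    for ref in refs:
        if ref != "UBB":
            ok &= calls.expressed[ref]
    return ok.index[ok]


# ---------------------------------------------------------------------
# Filter funnel
# ---------------------------------------------------------------------


@dataclass
class FunnelStage:
    name: str
    n_in: int
    n_out: int
    removal_reasons: Mapping[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


@dataclass
class FunnelReport:
    """Chained per-stage cell counts with removal reasons."""

    stages: list[FunnelStage]

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage.n_out > stage.n_in or stage.n_out < 0:
                raise IntegrityError(f"stage {stage.name!r}: n_out outside [0, n_in]")
            reason_total = sum(stage.removal_reasons.values())
            if stage.removal_reasons and reason_total != stage.n_removed:
                raise IntegrityError(
                    f"stage {stage.name!r}: removal reasons sum to {reason_total}, "
                    f"expected {stage.n_removed}"
                )
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if nxt.n_in != prev.n_out:
                raise IntegrityError(
                    f"funnel stages do not chain: {prev.name!r} out {prev.n_out} "
                    f"!= {nxt.name!r} in {nxt.n_in}"
                )

    @property
    def n_initial(self) -> int:
        return self.stages[0].n_in if self.stages else 0

    @property
    def n_final(self) -> int:
        return self.stages[-1].n_out if self.stages else 0

    def stage(self, name: str) -> FunnelStage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        """Counts plus percentages relative to stage input and initial count."""
        n0 = self.n_initial
        rows = []
        for s in self.stages:
            rows.append(
                {
                    "stage": s.name,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "n_removed": s.n_removed,
                    "pct_of_stage_in": 100.0 * s.n_out / s.n_in if s.n_in else 0.0,
                    "pct_of_initial": 100.0 * s.n_out / n0 if n0 else 0.0,
                    "removal_reasons": ";".join(
                        f"{k}={v}" for k, v in sorted(s.removal_reasons.items())
                    ),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        frame = self.to_frame()
        return {
            "n_initial": self.n_initial,
            "n_final": self.n_final,
            "stages": frame.to_dict(orient="records"),
        }


def build_funnel(
    stages: Sequence[tuple[str, int, int, Mapping[str, int] | None]]
) -> FunnelReport:
    """Assemble and validate a funnel from (name, n_in, n_out, reasons) tuples."""
    return FunnelReport(
        [FunnelStage(name, n_in, n_out, dict(reasons or {})) for name, n_in, n_out, reasons in stages]
    )
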