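"""Synthetic chip-like Ct datasets with known ground truth.

The generator emulates the structure of a single-cell qRT-PCR study of
circulating tumor cells (CTCs): 96.96 dynamic-array chips measuring an
87-assay panel of cancer-associated and reference genes on a mixture of

* clonal breast-cancer cell lines (tight, line-specific programs),
* two CTC subpopulations differing in a ten-gene expression program,
* CD45-positive leukocytes (WBCs),
* keratin/CD45 double-positive ("ambiguous") cells,
* RNA-degraded cells whose reference genes have shifted far above the
  UBB integrity threshold, and
* no-template controls (NTCs) that amplify only configured
  false-positive assays.

Measurement noise combines Gaussian Ct variation around each
population's per-assay mean, a logistic dropout whose failure
probability rises with true Ct (low-abundance transcripts fail more
often), hard censoring at the instrument detection limit, and a
quality-score channel in which a small fraction of reactions receive a
failing score regardless of Ct.

Every population draws from its own random stream (split per cell), so
adding or resizing one population does not perturb the draws of any
other, and regeneration under a fixed seed is bit-identical.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .qpcr_io import CtMatrix, GenePanel, META_COLUMNS

# ---------------------------------------------------------------------
# Population and noise models
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """A homogeneous cell population with a per-assay mean Ct program.

    Assays not in ``mean_ct`` (or listed in ``never_expressed``) are
    structural zeros: the reaction runs but never amplifies.  Cells are
    assigned to ``subjects`` in order, ``cells_per_subject`` each,
    cycling if the pool is exhausted.
    """

    label: str
    n_cells: int
    source: str  # "patient" | "cell_line" | "ntc"
    mean_ct: Mapping[str, float]
    subjects: tuple[str, ...]
    cells_per_subject: int
    sd_ct: float | Mapping[str, float] = 1.0
    never_expressed: frozenset[str] = frozenset()
    dropout_multiplier: float = 1.0
    subject_attrs: Mapping[str, Mapping[str, object]] | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ConfigError(f"population {self.label!r}: negative n_cells")
        if self.source not in ("patient", "cell_line", "ntc"):
            raise ConfigError(f"population {self.label!r}: bad source {self.source!r}")
        if not self.subjects or self.cells_per_subject < 1:
            raise ConfigError(f"population {self.label!r}: invalid subject rule")
        for assay, mu in self.mean_ct.items():
            if not 5.0 <= mu <= 45.0:
                raise ConfigError(
                    f"population {self.label!r}: mean Ct {mu} for {assay!r} "
                    "outside [5, 45]"
                )
        sds = (
            self.sd_ct.values() if isinstance(self.sd_ct, Mapping) else [self.sd_ct]
        )
        if any(sd < 0 for sd in sds):
            raise ConfigError(f"population {self.label!r}: negative SD")

    def sd_for(self, assay: str) -> float:
        if isinstance(self.sd_ct, Mapping):
            return float(self.sd_ct.get(assay, 1.0))
        return float(self.sd_ct)


@dataclass(frozen=True)
class NoiseModel:
    """Observation model for a single qPCR reaction.

    ``censor_ct`` is the instrument detection limit (cycles): true Ct
    beyond it is reported at the limit.  Reaction failure (no
    amplification) follows a logistic in true Ct with midpoint
    ``dropout_midpoint`` and scale ``dropout_slope`` (slope 0 = hard
    step).  Quality scores of successful reactions follow
    Beta(``quality_alpha``, ``quality_beta``); with probability
    ``low_quality_rate`` a reaction instead receives a failing score
    drawn uniformly below 0.65, independent of Ct.
    """

    censor_ct: float = 40.0
    dropout_midpoint: float = 33.0
    dropout_slope: float = 1.0
    quality_alpha: float = 50.0
    quality_beta: float = 2.0
    low_quality_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.censor_ct <= 0:
            raise ConfigError("censor_ct must be positive")
        if not 0.0 <= self.low_quality_rate <= 1.0:
            raise ConfigError("low_quality_rate outside [0, 1]")
        if self.dropout_slope < 0:
            raise ConfigError("dropout_slope must be >= 0")

    def dropout_prob(self, true_ct: np.ndarray) -> np.ndarray:
        """Probability that a reaction at ``true_ct`` fails to amplify."""
        true_ct = np.asarray(true_ct, dtype=float)
        if math.isinf(self.dropout_midpoint):
            return np.zeros_like(true_ct)
        if self.dropout_slope == 0:
            return (true_ct >= self.dropout_midpoint).astype(float)
        z = (true_ct - self.dropout_midpoint) / self.dropout_slope
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class SyntheticTruth:
    """Ground-truth labels for generated cells, plus the generator echo."""

    table: pd.DataFrame  # columns: cell_id, label, subject_id
    seed: int
    config_echo: str

    def labels(self) -> pd.Series:
        return self.table.set_index("cell_id")["label"]


# ---------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------


def _assign_subjects(spec: PopulationSpec) -> list[str]:
    out: list[str] = []
    i = 0
    while len(out) < spec.n_cells:
        subject = spec.subjects[i % len(spec.subjects)]
        take = min(spec.cells_per_subject, spec.n_cells - len(out))
        out.extend([subject] * take)
        i += 1
    return out


def _patient_attrs(rng: np.random.Generator) -> dict[str, object]:
    """Draw tumor phenotype metadata for one patient.

    Marginals approximate a mixed primary/metastatic breast-cancer
    cohort: 40% primary, ER+ 45%, PR+ 40%, HER2+ 17%.
    """
    return {
        "stage": "primary" if rng.random() < 0.40 else "metastatic",
        "er_status": "pos" if rng.random() < 0.45 else "neg",
        "pr_status": "pos" if rng.random() < 0.40 else "neg",
        "her2_status": "pos" if rng.random() < 0.17 else "neg",
        "age_at_diagnosis": float(round(np.clip(rng.normal(50, 10), 25, 85))),
    }


def generate(
    populations: Sequence[PopulationSpec],
    noise: NoiseModel,
    panel: GenePanel,
    seed: int,
    *,
    chip_size: int = 96,
    assays_missing_on_chips: Mapping[str, Sequence[str]] | None = None,
) -> tuple[CtMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate a chip dataset from population specs and a noise model.

    Returns the Ct matrix, a cell metadata table and the ground truth.
    Cells are assigned round-robin to ``ceil(n/chip_size)`` chips;
    ``assays_missing_on_chips`` marks (assay, chip) combinations as never
    loaded (unmeasured), emulating primer sets absent from some chips.
    """
    if not populations:
        raise ConfigError("no populations specified")
    assay_set = set(panel.assays)
    for spec in populations:
        unknown = (set(spec.mean_ct) | set(spec.never_expressed)) - assay_set
        if unknown:
            raise ConfigError(
                f"population {spec.label!r} references unknown assays {sorted(unknown)}"
            )
    assays_missing_on_chips = dict(assays_missing_on_chips or {})
    for assay in assays_missing_on_chips:
        if assay not in assay_set:
            raise ConfigError(f"missing-assay rule references unknown assay {assay!r}")

    assays = panel.assays
    n_assays = len(assays)
    total = sum(s.n_cells for s in populations)
    n_chips = max(1, math.ceil(total / chip_size))
    chip_names = [f"chip{i + 1}" for i in range(n_chips)]

    root = np.random.SeedSequence(seed)
    pop_streams = root.spawn(len(populations) + 1)
    meta_rng = np.random.default_rng(pop_streams[-1])

    cell_ids: list[str] = []
    labels: list[str] = []
    subjects: list[str] = []
    sources: list[str] = []
    ct_rows: list[np.ndarray] = []
    q_rows: list[np.ndarray] = []

    for spec, stream in zip(populations, pop_streams):
        mean_vec = np.full(n_assays, np.nan)
        sd_vec = np.ones(n_assays)
        structural = np.ones(n_assays, dtype=bool)
        for j, assay in enumerate(assays):
            if assay in spec.never_expressed:
                continue
            if assay in spec.mean_ct:
                mean_vec[j] = spec.mean_ct[assay]
                sd_vec[j] = spec.sd_for(assay)
                structural[j] = False

        cell_subjects = _assign_subjects(spec)
        for k, child in enumerate(stream.spawn(spec.n_cells)):
            rng = np.random.default_rng(child)
            true_ct = rng.normal(np.where(structural, 30.0, mean_vec), sd_vec)
            p_drop = np.clip(
                noise.dropout_prob(true_ct) * spec.dropout_multiplier, 0.0, 1.0
            )
            dropped = rng.random(n_assays) < p_drop
            quality = rng.beta(noise.quality_alpha, noise.quality_beta, n_assays)
            low_q = rng.random(n_assays) < noise.low_quality_rate
            quality = np.where(low_q, rng.uniform(0.0, 0.65, n_assays), quality)

            absent = structural | dropped
            observed = np.where(
                absent, np.nan, np.clip(np.minimum(true_ct, noise.censor_ct), 0.0, None)
            )
            cell_ids.append(f"{spec.label}_{k:03d}")
            labels.append(spec.label)
            subjects.append(cell_subjects[k])
            sources.append(spec.source)
            ct_rows.append(observed)
            q_rows.append(quality)

    ct = pd.DataFrame(np.array(ct_rows).reshape(total, n_assays), index=cell_ids,
                      columns=assays)
    quality = pd.DataFrame(np.array(q_rows).reshape(total, n_assays), index=cell_ids,
                           columns=assays)
    chip_of_cell = pd.Series(
        [chip_names[i % n_chips] for i in range(total)], index=cell_ids
    )
    measured = pd.DataFrame(True, index=ct.index, columns=ct.columns)
    for assay, chips in assays_missing_on_chips.items():
        on = chip_of_cell.isin(list(chips)).to_numpy()
        measured.loc[measured.index[on], assay] = False
        ct.loc[ct.index[on], assay] = np.nan

    # -- metadata (one draw per subject, shared across populations) ----
    fixed_attrs: dict[str, Mapping[str, object]] = {}
    for spec in populations:
        if spec.subject_attrs:
            fixed_attrs.update(spec.subject_attrs)
    subject_rows: dict[str, dict[str, object]] = {}
    source_of_subject = {}
    for subj, src in zip(subjects, sources):
        source_of_subject.setdefault(subj, src)
    for subj in sorted(source_of_subject):
        src = source_of_subject[subj]
        if subj in fixed_attrs:
            attrs = dict(fixed_attrs[subj])
        elif src == "patient":
            attrs = _patient_attrs(meta_rng)
        else:
            attrs = {
                "stage": "not_applicable",
                "er_status": "unknown",
                "pr_status": "unknown",
                "her2_status": "unknown",
                "age_at_diagnosis": np.nan,
            }
        subject_rows[subj] = attrs

    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "source": sources,
            "subject_id": subjects,
            "sample_id": [
                "control" if src == "ntc" else f"{s}-draw1"
                for s, src in zip(subjects, sources)
            ],
        }
    )
    for col in ("stage", "er_status", "pr_status", "her2_status", "age_at_diagnosis"):
        meta[col] = [subject_rows[s][col] for s in subjects]
    meta.loc[meta["source"] == "ntc", "subject_id"] = "control"
    meta = meta[list(META_COLUMNS)]

    truth = SyntheticTruth(
        table=pd.DataFrame(
            {"cell_id": cell_ids, "label": labels, "subject_id": subjects}
        ),
        seed=seed,
        config_echo=repr((populations, noise)),
    )
    matrix = CtMatrix(ct=ct, quality=quality, chip_of_cell=chip_of_cell,
                      measured=measured)
    return matrix, meta, truth


# ---------------------------------------------------------------------
# Default study configuration
# ---------------------------------------------------------------------

#: Assays dropped from one chip (cross-chip exclusion rule 1).
RULE1_GENES = ("HGF", "RPS11", "RPS18", "RPS27A")
#: Assays that amplify in no-template controls (exclusion rule 2).
RULE2_GENES = ("BMI1", "EIF4E", "EIF4EBP1", "MED1", "POU5F1", "RPLPO")

#: Ten-gene program distinguishing the two CTC subpopulations.
CTC_PROGRAM_GENES = (
    "S100A9", "CD24", "VIM", "CXCR4", "MAPK14",
    "AKT2", "PIK3R1", "CTNNB1", "CD44", "ZEB2",
)

#: Genes expressed at moderate level in both CTC subgroups (with the
#: references, keratins KRT8/18/19 and the ten program genes these form
#: the commonly detectable set).
CTC_COMMON_GENES = (
    "TGFB1", "FOXC1", "NFKB1", "NPTN", "S100A4", "AKT1", "PTEN", "BAX",
    "CASP3", "CD53", "CD59", "RRM1", "PARP1", "SLC2A1", "TFRC",
)

_CANCER_ASSOCIATED = (
    RULE1_GENES
    + RULE2_GENES
    + CTC_PROGRAM_GENES
    + CTC_COMMON_GENES
    + (
        "CDH1", "ESR1", "PGR", "ERBB2", "EGFR", "VEGFA", "MET", "MYC",
        "ATF3", "TERT", "RAC1", "FOXA1", "CCNB1", "BIRC5", "EPCAM",
        "S100P", "PLAUR",
        "BRCA1", "BRCA2", "TP53", "MKI67", "CCND1", "CDK4", "CDK6",
        "ERBB3", "GRB7", "IGF1R", "KIT", "MMP1", "MMP9", "PLAU",
        "SERPINE1", "SNAI1", "SNAI2", "TWIST1", "ALDH1A1", "PROM1",
        "MUC1", "SCGB2A2", "TFF1", "TFF3", "GATA3", "XBP1", "SLPI",
    )
)

_CELL_LINES = ("MCF7", "T47D", "SKBR3", "MDA-MB-231", "CCdl054", "CCdl672", "CCdl675")
_ER_POS_LINES = ("MCF7", "T47D", "CCdl054", "CCdl672", "CCdl675")
_METASTATIC_LINES = ("MCF7", "T47D", "SKBR3", "MDA-MB-231")

#: Line-specific signature genes (high expression) giving each clonal
#: line a separable program.
_LINE_SIGNATURES = {
    "MCF7": ("TFF1", "TFF3", "GATA3", "XBP1", "SCGB2A2"),
    "T47D": ("MUC1", "CCND1", "FOXA1", "PGR", "TFF3"),
    "SKBR3": ("ERBB2", "GRB7", "EGFR", "MYC", "CDK4"),
    "MDA-MB-231": ("VIM", "SNAI2", "TWIST1", "MMP1", "PLAU"),
    "CCdl054": ("S100A9", "SLPI", "KIT", "ALDH1A1", "SERPINE1"),
    "CCdl672": ("S100A9", "PROM1", "MMP9", "IGF1R", "BRCA1"),
    "CCdl675": ("S100A9", "CD24", "TP53", "CDK6", "ERBB3"),
}

_REF_MEANS = {"UBB": 17.0, "ACTB": 18.0, "GAPDH": 19.0}
#: Housekeeping assays are selected for expression stability; their Ct
#: SD is half that of ordinary cancer-panel genes.
_REF_SDS = {"UBB": 0.5, "ACTB": 0.5, "GAPDH": 0.5}
#: Cycle shift applied to reference genes of RNA-degraded cells; places
#: degraded UBB (mean 31) ~6 SD above the Ct 25 integrity threshold.
DEGRADATION_SHIFT = 14.0


def _profile_sds(profile: Mapping[str, float]) -> dict[str, float]:
    """Per-assay SDs: 1 cycle for panel genes, 0.5 for reference genes."""
    sds = {g: 1.0 for g in profile}
    sds.update({g: sd for g, sd in _REF_SDS.items() if g in profile})
    return sds


def build_default_panel() -> GenePanel:
    """The 87-assay panel: 3 references, 4 keratins, CD45, 79 cancer genes."""
    categories: dict[str, str] = {}
    for g in _REF_MEANS:
        categories[g] = "reference"
    for g in ("KRT7", "KRT8", "KRT18", "KRT19"):
        categories[g] = "epithelial"
    categories["PTPRC"] = "leukocyte"
    for g in _CANCER_ASSOCIATED:
        categories[g] = "cancer_associated"
    panel = GenePanel.from_categories(categories)
    assert len(panel.assays) == 87
    return panel


def _ctc_profile(program_mean: float) -> dict[str, float]:
    prof = dict(_REF_MEANS)
    prof.update({"KRT8": 22.0, "KRT18": 21.0, "KRT19": 21.0, "KRT7": 36.0})
    for g in CTC_PROGRAM_GENES:
        prof[g] = program_mean
    for g in CTC_COMMON_GENES:
        prof[g] = 27.0
    for g in RULE1_GENES + RULE2_GENES:
        prof[g] = 26.0
    # Rarely detected flavor genes (growth-factor receptors, CDH1).
    for g in ("CDH1", "ESR1", "PGR", "ERBB2", "EGFR", "VEGFA", "MET"):
        prof[g] = 38.0
    return prof


def _line_profile(line: str) -> dict[str, float]:
    """Per-assay mean Ct program of one clonal cell line.

    On top of a shared epithelial baseline, each line carries its
    ER-program state, a small set of hallmark signature genes, and a
    stable line-specific quantitative offset (+/-3 cycles) on the
    non-reference genes it expresses -- distinct tumors differ
    quantitatively across most of a cancer panel, not just in a few
    markers, and this is what makes clonal lines cluster tightly by
    line.  The offsets are a deterministic function of the line name.
    """
    prof = dict(_REF_MEANS)
    prof.update({"KRT7": 22.0, "KRT8": 21.0, "KRT18": 21.0, "KRT19": 21.0})
    prof.update({"CDH1": 24.0, "EPCAM": 22.0, "MUC1": 26.0})
    for g in ("RRM1", "AKT1", "AKT2", "MYC", "CCNB1", "BIRC5", "CCND1",
              "MKI67", "TERT", "RAC1", "FOXA1", "ATF3"):
        prof[g] = 24.0
    for g in ("EGFR", "MET", "VEGFA", "CTNNB1", "BAX", "CASP3", "SLC2A1",
              "TFRC", "PARP1", "NFKB1", "MAPK14", "PIK3R1", "PTEN", "CD59"):
        prof[g] = 26.0
    for g in RULE1_GENES + RULE2_GENES:
        prof[g] = 26.0
    if line in _ER_POS_LINES:
        prof.update({"ESR1": 23.0, "PGR": 25.0, "GATA3": 24.0, "XBP1": 24.0})
    else:
        prof.update({"VIM": 22.0, "SNAI1": 26.0})
    for g in _LINE_SIGNATURES[line]:
        prof[g] = 19.0
    jitter_rng = np.random.default_rng(zlib.crc32(line.encode()))
    for g in sorted(prof):
        if g in _REF_MEANS:
            continue
        prof[g] = float(np.clip(prof[g] + jitter_rng.choice((-3.0, 0.0, 3.0)), 5.0, 33.0))
    return prof


def _wbc_profile() -> dict[str, float]:
    prof = dict(_REF_MEANS)
    prof["PTPRC"] = 20.0
    for g in ("CD53", "S100A9", "S100A4", "CD44", "CD24", "BAX", "CASP3",
              "CD59", "SLC2A1", "TFRC", "NFKB1", "MAPK14", "RAC1"):
        prof[g] = 25.0
    for g in RULE1_GENES + RULE2_GENES:
        prof[g] = 27.0
    return prof


@dataclass
class StudyDesign:
    """A complete generator configuration (populations, noise, panel, chips)."""

    populations: tuple[PopulationSpec, ...]
    noise: NoiseModel
    panel: GenePanel
    chip_size: int = 96
    assays_missing_on_chips: Mapping[str, tuple[str, ...]] = field(default_factory=dict)


def default_study_config() -> StudyDesign:
    """Generator configuration mirroring the study's structure.

    510 patient-derived cells whose composition follows the observed
    filter funnel -- 63% with intact reference-gene RNA, and of those 60%
    CTCs (split ~1:4 between the two CTC programs), 21% CD45+ leukocytes
    and 19% keratin/CD45 double positives -- plus 12 profiled cells from
    each of 7 clonal cell lines (an ER+/ER- split of 5/2) and one NTC
    well per chip.  Four assays are left off one chip and six amplify in
    NTCs, so the cross-chip/NTC exclusion rules remove exactly ten genes.
    """
    keratins = frozenset(("KRT7", "KRT8", "KRT18", "KRT19"))
    patients = tuple(f"P{i:02d}" for i in range(1, 32))

    pops: list[PopulationSpec] = []
    pops.append(
        PopulationSpec(
            label="ctc_cluster_I",
            n_cells=39,
            source="patient",
            mean_ct=_ctc_profile(program_mean=24.0),
            sd_ct=_profile_sds(_ctc_profile(program_mean=24.0)),
            subjects=patients[:13],
            cells_per_subject=3,
            never_expressed=frozenset(["PTPRC"]),
        )
    )
    pops.append(
        PopulationSpec(
            label="ctc_cluster_II",
            n_cells=154,
            source="patient",
            mean_ct=_ctc_profile(program_mean=28.0),
            sd_ct=_profile_sds(_ctc_profile(program_mean=28.0)),
            subjects=patients[5:],
            cells_per_subject=6,
            never_expressed=frozenset(["PTPRC"]),
        )
    )
    pops.append(
        PopulationSpec(
            label="wbc",
            n_cells=67,
            source="patient",
            mean_ct=_wbc_profile(),
            sd_ct=_profile_sds(_wbc_profile()),
            subjects=patients,
            cells_per_subject=3,
            never_expressed=keratins,
        )
    )
    ambiguous_profile = _ctc_profile(program_mean=28.0)
    ambiguous_profile["PTPRC"] = 22.0
    pops.append(
        PopulationSpec(
            label="ambiguous",
            n_cells=61,
            source="patient",
            mean_ct=ambiguous_profile,
            sd_ct=_profile_sds(ambiguous_profile),
            subjects=patients,
            cells_per_subject=2,
        )
    )
    degraded_profile = {
        g: mu + (DEGRADATION_SHIFT if g in _REF_MEANS else 6.0)
        for g, mu in _ctc_profile(program_mean=28.0).items()
        if mu + 6.0 <= 45.0 or g in _REF_MEANS
    }
    pops.append(
        PopulationSpec(
            label="degraded",
            n_cells=189,
            source="patient",
            mean_ct=degraded_profile,
            subjects=patients,
            cells_per_subject=7,
            never_expressed=frozenset(["PTPRC"]),
            dropout_multiplier=2.0,
        )
    )
    for line in _CELL_LINES:
        pops.append(
            PopulationSpec(
                label=f"line_{line}",
                n_cells=12,
                source="cell_line",
                mean_ct=_line_profile(line),
                sd_ct=_profile_sds(_line_profile(line)),
                subjects=(line,),
                cells_per_subject=12,
                never_expressed=frozenset(["PTPRC"]),
                subject_attrs={
                    line: {
                        "stage": "metastatic" if line in _METASTATIC_LINES else "primary",
                        "er_status": "pos" if line in _ER_POS_LINES else "neg",
                        "pr_status": "pos" if line in ("MCF7", "T47D") else "neg",
                        "her2_status": "pos" if line == "SKBR3" else "neg",
                        "age_at_diagnosis": np.nan,
                    }
                },
            )
        )
    pops.append(
        PopulationSpec(
            label="ntc",
            n_cells=7,
            source="ntc",
            mean_ct={g: 28.0 for g in RULE2_GENES},
            sd_ct=1.5,
            subjects=("control",),
            cells_per_subject=7,
        )
    )

    design = StudyDesign(
        populations=tuple(pops),
        noise=NoiseModel(),
        panel=build_default_panel(),
        chip_size=96,
        assays_missing_on_chips={g: ("chip1",) for g in RULE1_GENES},
    )
    total = sum(p.n_cells for p in design.populations)
    assert total == 510 + 7 * 12 + 7
    return design


def planted_ctc_design(
    n_small: int = 20,
    n_large: int = 80,
    program_delta: float = 4.0,
    noise: NoiseModel | None = None,
) -> StudyDesign:
    """Two planted CTC subpopulations differing only in the ten-gene program.

    The smaller population expresses the program ``program_delta`` cycles
    more strongly (default +4).  Patients carry five cells each so the
    per-patient cap does not bite.
    """
    base = _ctc_profile(program_mean=28.0)
    strong = dict(base)
    for g in CTC_PROGRAM_GENES:
        strong[g] = base[g] - program_delta
    pops = (
        PopulationSpec(
            label="ctc_cluster_I",
            n_cells=n_small,
            source="patient",
            mean_ct=strong,
            sd_ct=_profile_sds(strong),
            subjects=tuple(f"PS{i:02d}" for i in range(max(1, math.ceil(n_small / 5)))),
            cells_per_subject=5,
            never_expressed=frozenset(["PTPRC"]),
        ),
        PopulationSpec(
            label="ctc_cluster_II",
            n_cells=n_large,
            source="patient",
            mean_ct=base,
            sd_ct=_profile_sds(base),
            subjects=tuple(f"PL{i:02d}" for i in range(max(1, math.ceil(n_large / 5)))),
            cells_per_subject=5,
            never_expressed=frozenset(["PTPRC"]),
        ),
    )
    return StudyDesign(
        populations=pops, noise=noise or NoiseModel(), panel=build_default_panel()
    )


def cell_line_design(
    cells_per_line: int = 7, noise: NoiseModel | None = None
) -> StudyDesign:
    """Seven clonal cell-line populations at tight within-line spread.

    Defaults to a clean noise model (no Ct-independent quality failures)
    so that exactly ``cells_per_line`` cells per line survive QC.
    """
    pops = tuple(
        PopulationSpec(
            label=f"line_{line}",
            n_cells=cells_per_line,
            source="cell_line",
            mean_ct=_line_profile(line),
            sd_ct=_profile_sds(_line_profile(line)),
            subjects=(line,),
            cells_per_subject=cells_per_line,
            never_expressed=frozenset(["PTPRC"]),
        )
        for line in _CELL_LINES
    )
    return StudyDesign(
        populations=pops,
        noise=noise or NoiseModel(low_quality_rate=0.0),
        panel=build_default_panel(),
    )


def simulate_study(
    design: StudyDesign, seed: int
) -> tuple[CtMatrix, pd.DataFrame, SyntheticTruth]:
    """Run :func:`generate` for a :class:`StudyDesign`."""
    return generate(
        design.populations,
        design.noise,
        design.panel,
        seed,
        chip_size=design.chip_size,
        assays_missing_on_chips=design.assays_missing_on_chips,
    )
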