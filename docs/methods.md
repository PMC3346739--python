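# Methods

`ctcprof` implements a single-cell qRT-PCR analysis of circulating tumor
cells (CTCs): from raw dynamic-array Ct tables through measurement QC,
gene exclusion, cell-quality gating, rule-based CTC/WBC classification,
balanced subsampling, reference-panel normalization, detectability-based
gene selection, and missing-value-aware hierarchical clustering. This
note records the model, its assumptions, the parameters that matter, and
the design choices made where the design was genuinely open.

## Measurement model and QC

A 96.96 dynamic array yields, per cell x assay reaction, a cycle
threshold Ct (lower = more transcript) and an instrument quality score
in [0, 1]. A reaction counts as *expressed* iff its Ct is present,
Ct < 35 cycles, and quality >= 0.65. Both boundaries are sharp and
deliberate: Ct exactly 35 is immeasurable, quality exactly 0.65 passes.
Tables lacking a quality column are usable (scores default to 1.0), in
which case the Ct ceiling is the only measurement gate.

Two gene-level exclusion rules mirror common chip pathologies:

1. *not_on_all_chips* — an assay with no measurement rows on at least
   one chip (primer set not loaded there). This requires distinguishing
   "reaction ran, no amplification" from "reaction never ran", which the
   `CtMatrix.measured` mask carries through the I/O layer.
2. *ntc_positive* — an assay with an expressed call in any no-template
   control well. One NTC hit on one chip suffices.

When both rules match, the cross-chip reason is stored. A reference
assay matching either rule is a fatal configuration error: the pipeline
cannot normalize without its references.

Cell-level gates, in pipeline order: a cell must express at least 10
retained assays ("minimum expression screen"); its RNA counts as intact
only if UBB is expressed at Ct strictly below 25 *and* ACTB and GAPDH
are expressed. The UBB boundary reads the retention rule as "Ct < 25",
so a cell at exactly 25 is excluded; ACTB/GAPDH carry no Ct ceiling
beyond the global 35. Whether the >= 10-gene screen counts over the
original or post-exclusion panel is a genuine open point; we count over
the 77 retained assays, since excluded assays are declared unreliable
(configurable).

## Gating classifier

Patient-derived cells are partitioned by a fixed gate order:

1. integrity fail → `DEGRADED`;
2. CD45 (PTPRC) expressed and ≥1 keratin (KRT7/8/18/19) expressed →
   `AMBIGUOUS_KRT_CD45`;
3. CD45 expressed → `WBC`;
4. any keratin expressed → `CTC`;
5. otherwise → `NON_EPITHELIAL`.

Placing the double-positive gate before WBC keeps "unknown" cells out of
the WBC count, matching how such cells are reported separately.
`NON_EPITHELIAL` is a residual bucket: keratin-negative, CD45-negative
cells with intact RNA. The classifier is a pure function of the call row
and the integrity flag, and every gate evaluation is recorded in a
trail. Note one subtlety: making expression calling stricter (lower Ct
ceiling) is *not* globally monotone on labels — silencing the CD45 call
of a double positive re-gates it as CTC. The monotonicity that does hold
(and is tested): cells called CTC under a stricter ceiling were
keratin-positive (CTC or ambiguous) under the laxer one, and DEGRADED
only grows.

## Normalization

To balance patients and lines, the analysis set takes at most 5 CTCs per
patient and exactly 7 cells per cell line, uniformly at random without
replacement (deterministic under seed; patients at or under the cap
contribute everything; a line with fewer than 7 eligible cells is an
error). Expression is summarized as the negative delta Ct,

    -dCt(c, g) = -(Ct(c, g) - mean_r Ct(c, r)),

against a reference panel: UBB/ACTB/GAPDH for patient analyses, UBB
alone for cell-line analyses (a config switch). Values are then
median-centered per gene over observed measurements only — imputation
happens later, at clustering — and reference assays stay in the matrix
like any other gene (their variability across cells is itself
informative). Genes with no observed value keep median 0 and stay
all-missing. The transformation is exactly invariant to per-cell
additive Ct shifts.

Genes are retained for clustering if expressed in at least 15% of the
CTC analysis cells, boundary inclusive.

## Clustering

The pooled SD is the standard deviation of all observed centered values,
all genes pooled, computed before imputation. Missing values are then
replaced by -3 pooled SD (the floor expression they represent); observed
values are *not* clipped for clustering. For display, observed values
are truncated to +/-3 SD and missing entries are rendered black, with a
blue–gray–yellow diverging scale centered at the per-gene median.
Truncation for display and imputation for clustering are deliberately
separate steps; a switch allows clipping for clustering too.

Cells are clustered agglomeratively on Euclidean distances. The linkage
is not dictated by the method description; the default is **complete**
linkage — the historical default of R's `hclust`, the environment such
analyses are usually run in — configurable among
single/complete/average/ward. Ties break toward the lowest-index pair;
for n <= 8 the merge sequence is tested against an independent O(n^3)
brute-force agglomeration oracle. A k-cut (default k = 2 for CTCs,
k = 7 for cell lines) labels clusters in ascending size order, so
"Cluster I" is the smaller subgroup. Gene ordering in heatmaps applies
the same algorithm to the transpose.

Cluster composition is reported per distinct case (patient): a case
belongs to a cluster iff at least one of its cells carries the label;
percentages (primary/metastatic, ER-or-PR-positive, HER2-positive,
triple-negative) use the cluster's case count as denominator and round
half up to integers; unknown receptor status never counts as positive or
as triple-negative. Cross-cluster case overlap is reported alongside.

## Synthetic data generator

No raw chip data are publicly deposited for this study design, so the
generator is a first-class module that emulates the study's structure
with known ground truth:

* **Populations.** 510 patient-derived cells — 39 + 154 CTCs in two
  expression programs (63%/37% of CTCs' 1:4 split mirrors the observed
  subgroup sizes), 67 CD45+ leukocytes (21% of the 321 RNA-intact
  cells), 61 keratin/CD45 double positives, and 189 RNA-degraded cells
  (37% of captured) — plus 12 profiled cells from each of 7 clonal
  breast-cancer lines (5 ER+, 2 ER−) and one NTC well per chip. Cells
  are assigned round-robin to 7 chips of 96 wells.
* **Expression programs.** All intact populations share reference means
  (UBB 17, ACTB 18, GAPDH 19 cycles). CTCs express KRT8/18/19 near Ct
  21–22 and a common set of 25 cancer-associated genes near 27; the two
  CTC subgroups differ by 4 cycles on a ten-gene program (S100A9, CD24,
  VIM, CXCR4, MAPK14, AKT2, PIK3R1, CTNNB1, CD44, ZEB2). Together with
  the references this yields exactly 31 genes above the 15%
  detectability threshold. Cell lines share an epithelial baseline plus
  per-line hallmark signatures and a deterministic per-gene ±3-cycle
  offset keyed on the line name — distinct tumor lines differ
  quantitatively across most of a cancer panel, which is what makes
  clones cluster tightly by line. Four assays are left off one chip and
  six amplify in NTCs, so the exclusion rules remove exactly ten genes.
* **Noise.** Observed Ct = true Ct ~ Normal(mean, SD), censored at the
  detection limit (40 cycles), with logistic dropout in true Ct
  (midpoint 33, scale 1): low-abundance transcripts fail more often.
  Quality scores follow Beta(50, 2); independently, 1% of reactions
  receive a failing score (< 0.65) regardless of Ct, modeling chip
  artifacts. Reference assays use SD 0.5 versus 1.0 for other genes:
  housekeeping genes are chosen precisely for expression stability, and
  an unstable reference would contradict the premise of reference-panel
  normalization. Degradation shifts reference means by +14 cycles
  (placing degraded UBB ~6 SD above the Ct-25 gate) and doubles dropout.
* **Reproducibility.** One random stream per population, split per cell,
  so resizing one population never perturbs another; regeneration under
  a fixed seed is bit-identical.

What the generator does *not* emulate: amplification-efficiency
differences, chip spatial effects, cross-well contamination, doublets,
or fitted real-chip noise distributions. Passing tests therefore
demonstrate the correctness and calibration of the *analysis* under a
plausible observation model, not performance on real chips.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 601-cell default study
(seconds per run), 20-seed recovery experiments at 100 cells (planted
CTC programs) and 49 cells (lines), and a 200-instance oracle comparison
at n <= 8 — sizes chosen so the whole suite completes in well under a
minute of compute while keeping binomial test intervals meaningful.
Floats round-trip through text via shortest-repr formatting; delimited
outputs use `NA` for missing; the end-to-end pipeline is bit-identical
under a fixed seed (content hashes recorded in a manifest). k for the
CTC cut is a parameter (default 2, chosen by the study's two observed
subgroups, not by an internal criterion — a known limitation).

## Known limitations

* The gating definition is operational, not biological: keratin-low
  CTCs (e.g. deep EMT) are invisible to it by construction.
* The detectability threshold interacts with the analysis-set size; the
  15% rule is applied after subsampling, so prolific patients influence
  gene selection only through their 5 retained cells.
* Composition percentages use small case denominators; rounding to
  integers (half up) matches reporting convention but discards
  precision.
* With ties in merge heights (duplicate cells), the k-cut may not be
  unique; the implementation is deterministic but the partition depends
  on input order in degenerate cases.
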