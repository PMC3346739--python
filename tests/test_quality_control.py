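"""QC gate boundaries, gene exclusion rules, and funnel accounting."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ctcprof import quality_control as qc
from ctcprof import synthetic_data as sd
from ctcprof.errors import ConfigError, IntegrityError

from conftest import make_ct_matrix


class TestMeasurementQc:
    @pytest.mark.parametrize(
        "ct_val,quality,expected",
        [
            (34.2, 0.80, True),   # both conditions pass
            (35.0, 0.99, False),  # Ct boundary: >= 35 is immeasurable
            (34.999, 0.99, True),
            (20.0, 0.64, False),  # quality boundary: < 0.65 fails
            (20.0, 0.65, True),   # exactly 0.65 passes
            (np.nan, 0.99, False),
        ],
    )
    def test_expression_call_boundaries(self, small_panel, ct_val, quality, expected):
        assays = small_panel.assays
        row = [18.0] * len(assays)
        qrow = [0.9] * len(assays)
        row[assays.index("VIM")] = ct_val
        qrow[assays.index("VIM")] = quality
        m = make_ct_matrix({"c0": row}, assays, quality={"c0": qrow})
        calls = qc.apply_measurement_qc(m)
        assert bool(calls.expressed.loc["c0", "VIM"]) is expected

    def test_unmeasured_entry_never_expressed(self, small_panel):
        assays = small_panel.assays
        m = make_ct_matrix({"c0": [18.0] * len(assays)}, assays)
        m.measured.loc["c0", "VIM"] = False
        calls = qc.apply_measurement_qc(m)
        assert not calls.expressed.loc["c0", "VIM"]

    def test_bad_thresholds_rejected(self, tiny_ct):
        with pytest.raises(ConfigError):
            qc.apply_measurement_qc(tiny_ct, quality_min=1.5)


def _chip_fixture(small_panel, drop_on_chip_c=False, ntc_amplifies=False):
    assays = small_panel.assays
    rows = {f"c{i}": [20.0] * len(assays) for i in range(3)}
    rows["ntc0"] = [np.nan] * len(assays)
    if ntc_amplifies:
        rows["ntc0"][assays.index("S100A9")] = 28.0
    m = make_ct_matrix(
        rows, assays, chips={"c0": "A", "c1": "B", "c2": "C", "ntc0": "A"}
    )
    if drop_on_chip_c:
        m.measured.loc["c2", "VIM"] = False
        m.ct.loc["c2", "VIM"] = np.nan
    return m


class TestExcludeGenes:
    def test_assay_off_one_chip_excluded(self, small_panel):
        m = _chip_fixture(small_panel, drop_on_chip_c=True)
        panel = qc.exclude_genes(small_panel, m, ["ntc0"])
        assert panel.table.loc["VIM", "exclusion_reason"] == "not_on_all_chips"
        assert "VIM" in panel.excluded_assays

    def test_ntc_amplification_excluded(self, small_panel):
        m = _chip_fixture(small_panel, ntc_amplifies=True)
        panel = qc.exclude_genes(small_panel, m, ["ntc0"])
        assert panel.table.loc["S100A9", "exclusion_reason"] == "ntc_positive"

    def test_no_ntc_warns_and_skips_rule2(self, small_panel):
        m = _chip_fixture(small_panel, ntc_amplifies=True)
        m2 = m.subset_cells([c for c in m.cell_ids if c != "ntc0"])
        with pytest.warns(UserWarning, match="NTC"):
            panel = qc.exclude_genes(small_panel, m2, [])
        assert panel.excluded_assays == []

    def test_default_config_excludes_the_ten_unreliable_genes(self, default_run):
        panel = default_run.panel
        assert sorted(panel.excluded_assays) == sorted(
            sd.RULE1_GENES + sd.RULE2_GENES
        )
        assert len(panel.retained) == 77
        for g in sd.RULE1_GENES:
            assert panel.table.loc[g, "exclusion_reason"] == "not_on_all_chips"
        for g in sd.RULE2_GENES:
            assert panel.table.loc[g, "exclusion_reason"] == "ntc_positive"

    def test_order_independence_with_measurement_qc(self, small_panel):
        """Excluding genes before or after measurement QC yields identical calls."""
        m = _chip_fixture(small_panel, drop_on_chip_c=True, ntc_amplifies=True)
        calls_first = qc.apply_measurement_qc(m)
        panel_a = qc.exclude_genes(small_panel, m, ["ntc0"], calls_first)
        a = calls_first.with_exclusions(panel_a.excluded_assays).retained

        panel_b = qc.exclude_genes(small_panel, m, ["ntc0"])  # recomputes calls
        b = qc.apply_measurement_qc(m).with_exclusions(panel_b.excluded_assays).retained
        pd.testing.assert_frame_equal(a, b)


class TestCellGates:
    def _calls(self, small_panel, n_expressed):
        assays = small_panel.assays
        row = [18.0 if i < n_expressed else np.nan for i in range(len(assays))]
        m = make_ct_matrix({"c0": row}, assays)
        return qc.apply_measurement_qc(m)

    @pytest.mark.parametrize("n,kept", [(10, True), (9, False), (0, False)])
    def test_min_genes_boundary(self, small_panel, n, kept):
        calls = self._calls(small_panel, n)
        retained = qc.filter_cells_min_genes(calls, min_genes=10)
        assert ("c0" in retained) is kept

    @pytest.mark.parametrize(
        "ubb,actb_ok,gapdh_ok,kept",
        [
            (24.9, True, True, True),    # strongly expressed UBB
            (25.0, True, True, False),   # boundary: Ct 25 is excluded
            (18.0, True, False, False),  # must express GAPDH too
            (18.0, False, True, False),
        ],
    )
    def test_reference_integrity_boundaries(self, small_panel, ubb, actb_ok, gapdh_ok, kept):
        assays = small_panel.assays
        row = [20.0] * len(assays)
        row[assays.index("UBB")] = ubb
        row[assays.index("ACTB")] = 20.0 if actb_ok else np.nan
        row[assays.index("GAPDH")] = 20.0 if gapdh_ok else np.nan
        m = make_ct_matrix({"c0": row}, assays)
        calls = qc.apply_measurement_qc(m)
        retained = qc.reference_integrity_gate(m, calls, small_panel)
        assert ("c0" in retained) is kept

    def test_excluded_reference_is_fatal(self, small_panel, tiny_ct):
        calls = qc.apply_measurement_qc(tiny_ct).with_exclusions(["UBB"])
        with pytest.raises(ConfigError, match="UBB"):
            qc.reference_integrity_gate(tiny_ct, calls, small_panel)

    def test_degraded_cells_recovered_exactly(self):
        """Reference gate recovers ground-truth degraded labels with zero errors."""
        from dataclasses import replace

        design = sd.default_study_config()
        design = sd.StudyDesign(
            populations=design.populations,
            noise=replace(design.noise, low_quality_rate=0.0),
            panel=design.panel,
            chip_size=design.chip_size,
            assays_missing_on_chips=design.assays_missing_on_chips,
        )
        ct, meta, truth = sd.simulate_study(design, seed=3)
        calls = qc.apply_measurement_qc(ct)
        intact = set(qc.reference_integrity_gate(ct, calls))
        labels = truth.labels()
        patient = meta.loc[meta["source"] == "patient", "cell_id"]
        for cell in patient:
            assert (labels[cell] == "degraded") == (cell not in intact)


class TestFunnel:
    def test_single_stage_nothing_removed(self):
        report = qc.build_funnel([("only", 10, 10, None)])
        assert report.stages[0].n_removed == 0
        assert report.n_initial == report.n_final == 10

    def test_conservation_and_chaining(self):
        report = qc.build_funnel(
            [
                ("captured", 510, 510, None),
                ("screen", 510, 321, {"degraded_rna": 189}),
                ("markers", 321, 193, {"wbc": 67, "ambiguous": 61}),
            ]
        )
        removed = sum(s.n_removed for s in report.stages)
        assert report.n_initial == report.n_final + removed

    def test_broken_chain_rejected(self):
        with pytest.raises(IntegrityError, match="chain"):
            qc.build_funnel([("a", 10, 8, None), ("b", 9, 9, None)])

    def test_mismatched_reasons_rejected(self):
        with pytest.raises(IntegrityError, match="reasons"):
            qc.build_funnel([("a", 10, 8, {"x": 1})])

    def test_percentages_recompute_from_counts(self):
        report = qc.build_funnel(
            [("a", 200, 100, None), ("b", 100, 25, None)]
        )
        frame = report.to_frame().set_index("stage")
        assert frame.loc["b", "pct_of_stage_in"] == pytest.approx(25.0)
        assert frame.loc["b", "pct_of_initial"] == pytest.approx(12.5)

    def test_default_run_funnel_conserves_cells(self, default_run):
        f = default_run.funnel
        removed = sum(s.n_removed for s in f.stages)
        assert f.n_initial == f.n_final + removed
        assert f.n_initial == 510
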