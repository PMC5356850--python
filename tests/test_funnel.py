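"""Candidate funnel: criterion semantics, the published evidence matrix,
panel-size rescaling and monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from cgiscreen.funnel import (
    EXPRESSED,
    VERY_LOW,
    CandidateFunnel,
    cellline_silencing,
    classify_normal_expression,
    evaluate_evidence,
    load_evidence_table,
    required_count,
    restoration,
    run_funnel,
    tumor_silencing,
)


def _expr(records):
    return pd.DataFrame(records, columns=["gene", "sample", "context", "rel_expr"])


class TestClassifyNormalExpression:
    def test_all_zero_is_very_low(self):
        expr = _expr([("G", "NL", "normal_reference", 0.0)])
        assert classify_normal_expression(expr, "G") == VERY_LOW

    def test_one_detectable_value_is_expressed(self):
        expr = _expr(
            [("G", "NL", "normal_reference", 0.8), ("G", "E1", "normal_pair", 0.0)]
        )
        assert classify_normal_expression(expr, "G") == EXPRESSED

    def test_absent_gene_is_very_low(self):
        assert classify_normal_expression(_expr([]), "G") == VERY_LOW


class TestTumorSilencing:
    def test_fraction_below_half(self):
        records = []
        for i, (t, n) in enumerate([(0.4, 1.0), (0.6, 1.0), (0.3, 1.0)]):
            records += [
                ("G", f"E{i}", "tumor", t),
                ("G", f"E{i}", "normal_pair", n),
            ]
        assert tumor_silencing(_expr(records), "G") == (2, 3)

    def test_unchanged_expression_counts_zero(self):
        records = []
        for i in range(4):
            records += [("G", f"E{i}", "tumor", 1.0), ("G", f"E{i}", "normal_pair", 1.0)]
        assert tumor_silencing(_expr(records), "G") == (0, 4)

    def test_nondetect_normal_excluded_from_denominator(self):
        records = [
            ("G", "E0", "tumor", 0.1),
            ("G", "E0", "normal_pair", 0.0),  # ratio vs non-detect: excluded
            ("G", "E1", "tumor", 0.1),
            ("G", "E1", "normal_pair", 1.0),
        ]
        assert tumor_silencing(_expr(records), "G") == (1, 1)

    def test_ratio_exactly_at_cut_not_counted(self):
        records = [("G", "E0", "tumor", 0.5), ("G", "E0", "normal_pair", 1.0)]
        assert tumor_silencing(_expr(records), "G") == (0, 1)


class TestCelllineSilencing:
    def test_fraction_below_fifth_of_reference(self):
        expr = _expr(
            [
                ("G", "NL", "normal_reference", 1.0),
                ("G", "CL1", "cell_line", 0.1),
                ("G", "CL2", "cell_line", 0.3),
            ]
        )
        assert cellline_silencing(expr, "G") == (1, 2)

    def test_exactly_at_cut_not_counted(self):
        expr = _expr(
            [("G", "NL", "normal_reference", 1.0), ("G", "CL1", "cell_line", 0.2)]
        )
        assert cellline_silencing(expr, "G") == (0, 1)

    def test_missing_reference_not_evaluable(self):
        expr = _expr([("G", "CL1", "cell_line", 0.1)])
        assert cellline_silencing(expr, "G") == (0, 0)


class TestRestoration:
    def test_fold_changes(self):
        records = []
        for i, fold in enumerate([5.0, 3.0, 4.1]):
            records += [
                ("G", f"CL{i}", "vehicle", 0.01),
                ("G", f"CL{i}", "treated", 0.01 * fold),
            ]
        assert restoration(_expr(records), "G") == (2, 3)

    def test_exactly_fourfold_not_counted(self):
        records = [("G", "CL0", "vehicle", 0.01), ("G", "CL0", "treated", 0.04)]
        assert restoration(_expr(records), "G") == (0, 1)

    def test_no_treated_lines_not_evaluable(self):
        assert restoration(_expr([("G", "CL0", "vehicle", 0.01)]), "G") == (0, 0)


class TestRequiredCount:
    @pytest.mark.parametrize(
        "mc,panel,n,expected",
        [
            (6, 11, 11, 6),
            (8, 14, 14, 8),
            (2, 3, 3, 2),
            (6, 11, 22, 12),
            (8, 14, 7, 4),
            (2, 3, 5, 4),
        ],
    )
    def test_proportional_ceiling(self, mc, panel, n, expected):
        assert required_count(mc, panel, n) == expected


class TestPublishedEvidenceMatrix:
    def test_single_passing_candidate(self):
        """The nine-gene evidence matrix yields exactly one gene passing all
        four criteria."""
        funnel = CandidateFunnel().fit_evidence(load_evidence_table())
        assert funnel.candidates_ == ["TRIM58"]

    def test_failure_modes_per_gene(self):
        report = (
            CandidateFunnel().fit_evidence(load_evidence_table()).report_.set_index("gene")
        )
        # frequently silenced everywhere but not restored by demethylation
        dpp6 = report.loc["DPP6"]
        assert dpp6[["pass_normal", "pass_tumor", "pass_cell"]].all()
        assert not dpp6["pass_restore"]
        # infrequent tumor and/or cell-line silencing
        assert not report.loc["PEAR1", "pass_tumor"]
        assert not report.loc["MEIS2", "pass_tumor"]
        assert not report.loc["MEIS2", "pass_cell"]
        assert not report.loc["PTPRN2", "pass_tumor"]
        assert not report.loc["PTPRN2", "pass_cell"]

    def test_very_low_genes_short_circuit(self):
        report = (
            CandidateFunnel().fit_evidence(load_evidence_table()).report_.set_index("gene")
        )
        for gene in ("DDX25", "FEZF2", "C12orf42"):
            row = report.loc[gene]
            assert row["normal_expression"] == VERY_LOW
            assert not row[["pass_normal", "pass_tumor", "pass_cell", "pass_restore"]].any()
            assert pd.isna(row["tumor_k"])

    def test_extended_panel_kept_as_metadata(self):
        ev = load_evidence_table().set_index("gene")
        assert ev.loc["TRIM58", "tumor_k"] == 10 and ev.loc["TRIM58", "tumor_n"] == 11
        assert ev.loc["TRIM58", "tumor_ext_k"] == 36
        assert ev.loc["TRIM58", "tumor_ext_n"] == 37


class TestEvaluateEvidence:
    def _evidence(self, **kw):
        base = {
            "gene": "G",
            "normal_expression": EXPRESSED,
            "tumor_k": 10,
            "tumor_n": 11,
            "cell_k": 10,
            "cell_n": 14,
            "restore_k": 3,
            "restore_n": 3,
        }
        base.update(kw)
        return pd.DataFrame([base])

    def test_conjunction_of_four_criteria(self):
        report = evaluate_evidence(self._evidence())
        assert bool(report.loc[0, "passes_all"])
        report = evaluate_evidence(self._evidence(restore_k=1))
        assert not report.loc[0, "passes_all"]
        assert report.loc[0, "n_criteria_passed"] == 3

    def test_empty_candidate_list(self):
        expr = _expr([])
        evidence, report = run_funnel([], expr)
        assert len(evidence) == 0 and len(report) == 0

    def test_zero_denominator_not_evaluable(self):
        report = evaluate_evidence(self._evidence(tumor_k=0, tumor_n=0))
        assert not report.loc[0, "pass_tumor"]

    @given(
        hst.integers(0, 11),
        hst.integers(0, 14),
        hst.integers(0, 3),
    )
    @settings(derandomize=True, max_examples=60)
    def test_passes_all_monotone_in_counts(self, tk, ck, rk):
        """Increasing any k never turns a passing gene into a failing one."""
        rep = evaluate_evidence(self._evidence(tumor_k=tk, cell_k=ck, restore_k=rk))
        if bool(rep.loc[0, "passes_all"]):
            bumped = evaluate_evidence(
                self._evidence(
                    tumor_k=min(tk + 1, 11),
                    cell_k=min(ck + 1, 14),
                    restore_k=min(rk + 1, 3),
                )
            )
            assert bool(bumped.loc[0, "passes_all"])

    def test_report_sorted_best_first_and_deterministic(self):
        ev = pd.concat(
            [
                self._evidence(gene="A", restore_k=1),
                self._evidence(gene="B"),
                self._evidence(gene="C", tumor_k=5, restore_k=1),
            ]
        )
        r1 = evaluate_evidence(ev)
        r2 = evaluate_evidence(ev)
        assert list(r1["gene"]) == ["B", "A", "C"]
        pd.testing.assert_frame_equal(r1, r2)


class TestFunnelOnExpression:
    def test_threshold_cuts_monotone(self):
        """Raising a ratio cut can only increase k."""
        records = []
        for i, r in enumerate([0.1, 0.45, 0.55, 0.9]):
            records += [("G", f"E{i}", "tumor", r), ("G", f"E{i}", "normal_pair", 1.0)]
        expr = _expr(records)
        k_low, _ = tumor_silencing(expr, "G", ratio_cut=0.5)
        k_high, _ = tumor_silencing(expr, "G", ratio_cut=0.6)
        assert k_high >= k_low == 2

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            CandidateFunnel(tumor_min_count=12, tumor_panel=11).fit(_expr([]), [])
        with pytest.raises(ValueError):
            CandidateFunnel(cell_ratio_cut=0.0).fit(_expr([]), [])
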