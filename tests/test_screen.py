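"""Region screen: probe assignment, aggregation, testing, selection."""

import numpy as np
import pandas as pd
import pytest

from cgiscreen.screen import (
    RegionMethylationScreen,
    assign_probes,
    differential_test,
    paired_differences,
    select_and_rank,
    summarize_regions,
)
from cgiscreen import io as cio

from conftest import paired_t_oracle


@pytest.fixture
def manifest():
    return pd.DataFrame(
        {
            "probe_id": ["cgA", "cgB", "cgC", "cgD", "cgE"],
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr1"],
            "pos": [248020330, 248020500, 248021252, 248020500, 248021253],
        }
    )


@pytest.fixture
def regions():
    return pd.DataFrame(
        {
            "region_id": ["R1"],
            "chrom": ["chr1"],
            "start": [248020329],
            "end": [248021252],
            "gene": ["TRIM58"],
            "gene_context": ["exon1"],
        }
    )


class TestAssignProbes:
    def test_boundary_containment_one_based_start(self, manifest, regions):
        """Probes at the 1-based display start and end of the region are
        members; the probe one past the end is not (3 inside, 1 outside)."""
        mapping = assign_probes(manifest, regions)
        assert mapping == {"R1": ["cgA", "cgB", "cgC"]}

    def test_chromosome_mismatch_excludes(self, manifest, regions):
        mapping = assign_probes(manifest, regions)
        assert "cgD" not in mapping["R1"]

    def test_empty_regions_dropped(self, manifest):
        empty = pd.DataFrame(
            {
                "region_id": ["R9"],
                "chrom": ["chr9"],
                "start": [0],
                "end": [100],
                "gene": [None],
                "gene_context": [None],
            }
        )
        assert assign_probes(manifest, empty) == {}


class TestSummarizeRegions:
    def test_median_of_member_probes(self):
        beta = pd.DataFrame(
            {"S1": [0.1, 0.2, 0.9]},
            index=pd.Index(["a", "b", "c"], name="probe_id"),
        )
        out = summarize_regions(beta, {"R": ["a", "b", "c"]})
        assert out.loc["R", "S1"] == pytest.approx(0.2)

    def test_single_probe_passthrough(self):
        beta = pd.DataFrame({"S1": [0.7]}, index=pd.Index(["a"], name="probe_id"))
        assert summarize_regions(beta, {"R": ["a"]}).loc["R", "S1"] == pytest.approx(0.7)

    def test_median_of_available_respects_min_probes(self):
        beta = pd.DataFrame(
            {"S1": [0.1, np.nan, 0.3]},
            index=pd.Index(["a", "b", "c"], name="probe_id"),
        )
        out = summarize_regions(beta, {"R": ["a", "b", "c"]}, min_probes=2)
        assert out.loc["R", "S1"] == pytest.approx(0.2)
        out3 = summarize_regions(beta, {"R": ["a", "b", "c"]}, min_probes=3)
        assert np.isnan(out3.loc["R", "S1"])


class TestPairedDifferences:
    def _design(self):
        return pd.DataFrame(
            {
                "patient_id": ["P1"],
                "tumor_sample": ["T1"],
                "normal_sample": ["N1"],
                "smoking_status": ["S"],
            }
        )

    def test_tumor_minus_normal(self):
        summary = pd.DataFrame({"T1": [0.5], "N1": [0.2]}, index=["R"])
        out = paired_differences(summary, self._design())
        assert out.loc["R", "P1"] == pytest.approx(0.3)

    def test_label_swap_negates(self):
        summary = pd.DataFrame({"T1": [0.5], "N1": [0.2]}, index=["R"])
        swapped = self._design().rename(
            columns={"tumor_sample": "normal_sample", "normal_sample": "tumor_sample"}
        )
        a = paired_differences(summary, self._design())
        b = paired_differences(summary, swapped)
        assert np.allclose(a.to_numpy(), -b.to_numpy())

    def test_missing_sample_column_errors(self):
        summary = pd.DataFrame({"T1": [0.5]}, index=["R"])
        with pytest.raises(cio.ValidationError, match="N1"):
            paired_differences(summary, self._design())


class TestDifferentialTest:
    def test_planted_region_matches_t_oracle(self):
        rng = np.random.default_rng(42)
        d = rng.normal(0.3, 0.05, size=12)
        diffs = pd.DataFrame([d], index=["R"])
        out = differential_test(diffs)
        t, p = paired_t_oracle(d)
        assert out.loc["R", "t_stat"] == pytest.approx(t, abs=1e-10)
        assert out.loc["R", "raw_p"] == pytest.approx(p, abs=1e-12)
        assert out.loc["R", "raw_p"] < 1e-4
        assert out.loc["R", "delta_beta"] == pytest.approx(d.mean())

    def test_zero_variance_region_excluded_with_warning(self):
        diffs = pd.DataFrame(
            [[0.0] * 6, [0.1, 0.2, 0.15, 0.3, 0.25, 0.1]], index=["null", "ok"]
        )
        with pytest.warns(UserWarning, match="excluded"):
            out = differential_test(diffs)
        assert list(out.index) == ["ok"]

    def test_below_min_pairs_excluded(self):
        diffs = pd.DataFrame([[0.1, 0.2, np.nan, np.nan]], index=["R"])
        with pytest.warns(UserWarning, match="excluded"):
            out = differential_test(diffs, min_pairs=3)
        assert len(out) == 0

    def test_pair_order_permutation_invariant(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.2, 0.1, size=12)
        a = differential_test(pd.DataFrame([d], index=["R"]))
        b = differential_test(pd.DataFrame([rng.permutation(d)], index=["R"]))
        assert a.loc["R", "t_stat"] == pytest.approx(b.loc["R", "t_stat"])
        assert a.loc["R", "raw_p"] == pytest.approx(b.loc["R", "raw_p"])

    def test_bh_one_family(self):
        rng = np.random.default_rng(10)
        diffs = pd.DataFrame(rng.normal(0, 0.05, size=(20, 12)))
        out = differential_test(diffs)
        assert (out["adjusted_p"] >= out["raw_p"] - 1e-15).all()


class TestSelectAndRank:
    def _records(self):
        return pd.DataFrame(
            {
                "delta_beta": [0.26, 0.24, 0.40, -0.30],
                "adjusted_p": [0.04, 0.04, 0.06, 0.01],
            },
            index=["kept", "small_delta", "big_q", "hypo"],
        )

    def test_strict_threshold_semantics(self):
        out = select_and_rank(self._records())
        assert list(out.index) == ["kept"]

    def test_boundary_values_excluded(self):
        rec = pd.DataFrame(
            {"delta_beta": [0.25, 0.26], "adjusted_p": [0.04, 0.05]},
            index=["at_delta", "at_q"],
        )
        assert len(select_and_rank(rec)) == 0

    def test_hypo_direction(self):
        out = select_and_rank(self._records(), direction="hypo")
        assert list(out.index) == ["hypo"]

    def test_ordering_and_ties(self):
        rec = pd.DataFrame(
            {
                "delta_beta": [0.30, 0.35, 0.30],
                "adjusted_p": [0.02, 0.01, 0.01],
            },
            index=["c", "b", "a"],
        )
        out = select_and_rank(rec)
        # ascending q; tie at q=0.01 broken by larger |Δβ| (b before a)
        assert list(out.index) == ["b", "a", "c"]
        assert list(out["rank"]) == [1, 2, 3]


class TestScreenEstimator:
    def test_recovers_planted_regions(self, small_cohort):
        scr = RegionMethylationScreen().fit(
            small_cohort.beta,
            small_cohort.manifest,
            small_cohort.regions,
            small_cohort.design,
        )
        planted = set(small_cohort.truth.planted_region_ids)
        selected = set(scr.selected_.index)
        assert planted <= selected
        assert len(selected - planted) <= max(1, len(selected) // 10)

    def test_direction_symmetry_on_label_swap(self, small_cohort):
        """Running direction=hypo with tumor/normal labels swapped reproduces
        the hyper result set with negated Δβ."""
        swapped = small_cohort.design.rename(
            columns={"tumor_sample": "normal_sample", "normal_sample": "tumor_sample"}
        )
        hyper = RegionMethylationScreen(direction="hyper").fit(
            small_cohort.beta,
            small_cohort.manifest,
            small_cohort.regions,
            small_cohort.design,
        )
        hypo = RegionMethylationScreen(direction="hypo").fit(
            small_cohort.beta, small_cohort.manifest, small_cohort.regions, swapped
        )
        assert set(hyper.selected_.index) == set(hypo.selected_.index)
        assert np.allclose(
            hyper.selected_["delta_beta"].sort_index(),
            -hypo.selected_["delta_beta"].sort_index(),
        )

    def test_candidate_genes_rank_order_unique(self, small_cohort):
        scr = RegionMethylationScreen(top_k=5).fit(
            small_cohort.beta,
            small_cohort.manifest,
            small_cohort.regions,
            small_cohort.design,
        )
        genes = scr.candidate_genes()
        assert len(genes) == len(set(genes)) <= 5
        assert genes == scr.top()["gene"].dropna().tolist()

    def test_probe_level_aggregation_mode_agrees(self, small_cohort):
        """Per-probe-difference-then-median aggregation ranks the same
        planted regions."""
        alt = RegionMethylationScreen(aggregation="diff_then_median").fit(
            small_cohort.beta,
            small_cohort.manifest,
            small_cohort.regions,
            small_cohort.design,
        )
        assert set(small_cohort.truth.planted_region_ids) <= set(alt.selected_.index)

    def test_volcano_export_axes(self, small_cohort):
        scr = RegionMethylationScreen().fit(
            small_cohort.beta,
            small_cohort.manifest,
            small_cohort.regions,
            small_cohort.design,
        )
        v = scr.volcano_data()
        assert {"delta_beta", "neg_log10_adjusted_p", "selected"} <= set(v.columns)
        assert len(v) == scr.n_regions_tested_

    def test_sklearn_params_round_trip(self):
        scr = RegionMethylationScreen(fdr_cut=0.01, top_k=3)
        clone_params = scr.get_params()
        assert clone_params["fdr_cut"] == 0.01
        scr.set_params(delta_cut=0.3)
        assert scr.delta_cut == 0.3
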