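"""Genome-wide region-level differential-methylation screen.

Pipeline: probes are assigned to CpG-island regions by coordinate
containment; each region's methylation per sample is the median β of its
member probes ("median-averaged"); paired tumor − normal differences (Δβ) are
computed per patient; each region is tested with a paired t-test against
zero; p-values are Benjamini–Hochberg adjusted across all tested regions as
one family; regions pass the screen when adjusted p < ``fdr_cut`` and Δβ
exceeds ``delta_cut`` in the requested direction (both strict), and are
ranked by adjusted p.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import io as _io
from .stats import DegenerateDataError, bh_adjust, paired_t

__all__ = [
    "RegionMethylationScreen",
    "assign_probes",
    "summarize_regions",
    "paired_differences",
    "differential_test",
    "select_and_rank",
    "screen_regions",
]

logger = logging.getLogger(__name__)

AGGREGATIONS = ("median_then_diff", "diff_then_median")
DIRECTIONS = ("hyper", "hypo", "both")


def assign_probes(manifest: pd.DataFrame, regions: pd.DataFrame) -> dict[str, list[str]]:
    """Map region_id → member probe ids by coordinate containment.

    A probe at 1-based position ``pos`` belongs to a region when
    ``start ≤ pos − 1 < end`` on the same chromosome (half-open 0-based
    interval). Regions with no probes are dropped (count logged).
    """
    mapping: dict[str, list[str]] = {}
    by_chrom = dict(tuple(manifest.groupby("chrom", sort=False)))
    n_empty = 0
    for row in regions.itertuples(index=False):
        probes_here = by_chrom.get(row.chrom)
        if probes_here is None:
            n_empty += 1
            continue
        pos0 = probes_here["pos"].to_numpy() - 1
        inside = (pos0 >= row.start) & (pos0 < row.end)
        ids = probes_here.loc[inside, "probe_id"].tolist()
        if ids:
            mapping[row.region_id] = ids
        else:
            n_empty += 1
    if n_empty:
        logger.info("dropped %d region(s) with no assigned probes", n_empty)
    return mapping


def _expanded(beta: pd.DataFrame, mapping: dict[str, list[str]]):
    """Member-probe rows of ``beta`` stacked per region, with region labels."""
    missing = sorted(
        {p for probes in mapping.values() for p in probes} - set(beta.index)
    )
    if missing:
        raise _io.ValidationError(
            f"mapping references probes absent from the β matrix: {missing[:5]}"
        )
    probe_rows = [p for probes in mapping.values() for p in probes]
    labels = np.repeat(
        list(mapping.keys()), [len(v) for v in mapping.values()]
    )
    return beta.loc[probe_rows], labels


def summarize_regions(
    beta: pd.DataFrame, mapping: dict[str, list[str]], min_probes: int = 1
) -> pd.DataFrame:
    """Per-(region, sample) median β over non-missing member probes.

    An entry is missing when fewer than ``min_probes`` member probes have a
    value for that sample. Returns a region × sample DataFrame.
    """
    if not mapping:
        raise ValueError("empty probe→region mapping")
    sub, labels = _expanded(beta, mapping)
    grouped = sub.groupby(labels, sort=False)
    med = grouped.median()
    counts = grouped.count()
    med[counts < min_probes] = np.nan
    med.index.name = "region_id"
    return med


def paired_differences(summary: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Δβ(region, pair) = tumor summary β − normal summary β.

    Columns are patient ids; an entry is missing when either side is missing.
    """
    _io.validate_design(design, summary.columns)
    tumor = summary[list(design["tumor_sample"])].to_numpy()
    normal = summary[list(design["normal_sample"])].to_numpy()
    return pd.DataFrame(
        tumor - normal, index=summary.index, columns=list(design["patient_id"])
    )


def differential_test(diffs: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Paired t-test per region with BH adjustment across all tested regions.

    Regions with fewer than ``min_pairs`` complete pairs, or with zero
    variance and zero mean (no data signal at all), are excluded with a
    warning rather than silently scored.

    Returns columns: region_id (index), n_pairs, delta_beta, t_stat, raw_p,
    adjusted_p.
    """
    records = []
    excluded = []
    for region_id, row in diffs.iterrows():
        d = row.to_numpy(dtype=float)
        d = d[np.isfinite(d)]
        if d.size < min_pairs:
            excluded.append((region_id, "insufficient pairs"))
            continue
        try:
            res = paired_t(d)
        except DegenerateDataError:
            excluded.append((region_id, "degenerate (no variance, no effect)"))
            continue
        records.append(
            {
                "region_id": region_id,
                "n_pairs": int(d.size),
                "delta_beta": float(d.mean()),
                "t_stat": res.statistic,
                "raw_p": res.p_value,
            }
        )
    if excluded:
        warnings.warn(
            f"{len(excluded)} region(s) excluded from testing "
            f"(e.g. {excluded[0][0]!r}: {excluded[0][1]})",
            stacklevel=2,
        )
    out = pd.DataFrame(
        records, columns=["region_id", "n_pairs", "delta_beta", "t_stat", "raw_p"]
    ).set_index("region_id")
    out["adjusted_p"] = bh_adjust(out["raw_p"].to_numpy()) if len(out) else []
    return out


def select_and_rank(
    records: pd.DataFrame,
    fdr_cut: float = 0.05,
    delta_cut: float = 0.25,
    direction: str = "hyper",
) -> pd.DataFrame:
    """Apply the screen thresholds and rank the selected regions.

    Keeps regions with adjusted p strictly below ``fdr_cut`` and Δβ strictly
    beyond ``delta_cut`` in the requested direction (``both`` accepts either
    tail). Sorted ascending by adjusted p, ties broken by descending |Δβ|,
    then region id. Returns the selected subset with a 1-based ``rank``.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if not 0 < fdr_cut < 1:
        raise ValueError("fdr_cut must be in (0, 1)")
    if not 0 < delta_cut < 1:
        raise ValueError("delta_cut must be in (0, 1)")
    q_ok = records["adjusted_p"] < fdr_cut
    d = records["delta_beta"]
    if direction == "hyper":
        d_ok = d > delta_cut
    elif direction == "hypo":
        d_ok = d < -delta_cut
    else:
        d_ok = d.abs() > delta_cut
    kept = records[q_ok & d_ok].copy()
    kept["_absd"] = -kept["delta_beta"].abs()
    kept["_rid"] = kept.index.astype(str)
    kept = kept.sort_values(["adjusted_p", "_absd", "_rid"], kind="mergesort").drop(
        columns=["_absd", "_rid"]
    )
    kept["rank"] = np.arange(1, len(kept) + 1)
    return kept


class RegionMethylationScreen(BaseEstimator):
    """Paired tumor/normal differential-methylation screen over CpG islands.

    Parameters
    ----------
    fdr_cut : float, default 0.05
        Strict upper bound on the BH-adjusted p-value.
    delta_cut : float, default 0.25
        Strict lower bound on |Δβ| in the screened direction.
    direction : {'hyper', 'hypo', 'both'}, default 'hyper'
        Methylation change direction to select.
    top_k : int, default 10
        Size of the default top view (:meth:`top` / :meth:`candidate_genes`).
    min_probes : int, default 1
        Minimum non-missing member probes per (region, sample) summary.
    min_pairs : int, default 3
        Minimum complete pairs for a region to be tested.
    aggregation : {'median_then_diff', 'diff_then_median'}, default 'median_then_diff'
        'median_then_diff': per-sample median over probes, then per-pair
        difference (region summaries are interpretable per sample).
        'diff_then_median': per-probe paired differences, then the median
        over probes per pair.

    Attributes
    ----------
    mapping_ : dict of region_id → probe ids
    region_summaries_ : DataFrame (region × sample), median β — only for the
        default aggregation.
    paired_deltas_ : DataFrame (region × patient), Δβ per pair.
    results_ : DataFrame with delta_beta, t_stat, raw_p, adjusted_p, selected,
        rank (rank is NaN for unselected regions).
    selected_ : the selected subset, ranked.
    """

    def __init__(
        self,
        fdr_cut: float = 0.05,
        delta_cut: float = 0.25,
        direction: str = "hyper",
        top_k: int = 10,
        min_probes: int = 1,
        min_pairs: int = 3,
        aggregation: str = "median_then_diff",
    ):
        self.fdr_cut = fdr_cut
        self.delta_cut = delta_cut
        self.direction = direction
        self.top_k = top_k
        self.min_probes = min_probes
        self.min_pairs = min_pairs
        self.aggregation = aggregation

    def _check_params(self) -> None:
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not 0 < self.fdr_cut < 1:
            raise ValueError("fdr_cut must be in (0, 1)")
        if not 0 < self.delta_cut < 1:
            raise ValueError("delta_cut must be in (0, 1)")
        if self.min_pairs < 2 or self.min_probes < 1 or self.top_k < 1:
            raise ValueError("min_pairs ≥ 2, min_probes ≥ 1, top_k ≥ 1 required")

    def fit(
        self,
        beta: pd.DataFrame,
        manifest: pd.DataFrame,
        regions: pd.DataFrame,
        design: pd.DataFrame,
    ):
        self._check_params()
        _io.validate_design(design, beta.columns)
        self.mapping_ = assign_probes(manifest, regions)
        if self.aggregation == "median_then_diff":
            self.region_summaries_ = summarize_regions(
                beta, self.mapping_, self.min_probes
            )
            self.paired_deltas_ = paired_differences(self.region_summaries_, design)
        else:
            self.paired_deltas_ = self._probe_diff_median(beta, design)
        results = differential_test(self.paired_deltas_, self.min_pairs)
        selected = select_and_rank(
            results, self.fdr_cut, self.delta_cut, self.direction
        )
        results.insert(
            0, "n_probes", pd.Series({r: len(p) for r, p in self.mapping_.items()})
        )
        results["selected"] = results.index.isin(selected.index)
        results["rank"] = selected["rank"].reindex(results.index)
        self.results_ = results.join(
            regions.set_index("region_id")[["chrom", "start", "end", "gene", "gene_context"]],
            how="left",
        )
        self.selected_ = self.results_[self.results_["selected"]].sort_values("rank")
        self.n_regions_tested_ = len(results)
        return self

    def _probe_diff_median(self, beta: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
        _io.validate_design(design, beta.columns)
        probe_diffs = pd.DataFrame(
            beta[list(design["tumor_sample"])].to_numpy()
            - beta[list(design["normal_sample"])].to_numpy(),
            index=beta.index,
            columns=list(design["patient_id"]),
        )
        sub, labels = _expanded(probe_diffs, self.mapping_)
        grouped = sub.groupby(labels, sort=False)
        med = grouped.median()
        med[grouped.count() < self.min_probes] = np.nan
        med.index.name = "region_id"
        return med

    def top(self, k: int | None = None) -> pd.DataFrame:
        """The ``k`` best-ranked selected regions (default ``top_k``)."""
        self._check_fitted()
        return self.selected_.head(self.top_k if k is None else k)

    def candidate_genes(self, k: int | None = None) -> list[str]:
        """Unique gene symbols of the top-``k`` regions, rank order preserved."""
        genes = self.top(k)["gene"].dropna().tolist()
        return list(dict.fromkeys(genes))

    def volcano_data(self) -> pd.DataFrame:
        """Δβ vs −log10 adjusted p for every tested region (volcano plot axes)."""
        self._check_fitted()
        out = self.results_[["delta_beta", "adjusted_p", "selected"]].copy()
        with np.errstate(divide="ignore"):
            out["neg_log10_adjusted_p"] = -np.log10(out.pop("adjusted_p"))
        return out

    def _check_fitted(self):
        if not hasattr(self, "results_"):
            raise RuntimeError("screen has not been fitted")


def screen_regions(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    regions: pd.DataFrame,
    design: pd.DataFrame,
    **params,
) -> RegionMethylationScreen:
    """One-call convenience wrapper: fit a :class:`RegionMethylationScreen`."""
    return RegionMethylationScreen(**params).fit(beta, manifest, regions, design)
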