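"""Validation analyses downstream of the candidate funnel.

Three analyses: paired tumor/normal comparison of site-level percent
methylation (pyrosequencing-style panels), methylation–expression inverse
correlation, and smoking-status stratification of methylation levels within
a tissue compartment.

Normality is never auto-tested: the caller chooses parametric (paired t /
Welch) versus rank (Wilcoxon signed-rank / Mann–Whitney U) tests explicitly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import io as _io
from .stats import (
    DegenerateDataError,
    TestResult,
    bh_adjust,
    mann_whitney_u,
    paired_t,
    pearson_r,
    welch_t,
    wilcoxon_signed_rank,
)

__all__ = [
    "paired_site_comparison",
    "methylation_expression_correlation",
    "smoking_stratified_comparison",
]


def _site_pivot(sites: pd.DataFrame) -> pd.DataFrame:
    return sites.pivot(index="site_id", columns="sample", values="percent_meth")


def paired_site_comparison(
    sites: pd.DataFrame,
    design: pd.DataFrame,
    use_rank_test: bool = False,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-site paired test of tumor − normal percent methylation.

    Pairs with either side missing are dropped per site; sites with fewer
    than ``min_pairs`` complete pairs or with all-zero differences are
    excluded with a warning. P-values are BH-adjusted across the tested
    sites. Returns one row per site: n_pairs, mean_tumor_pct,
    mean_normal_pct, mean_paired_difference_pct, statistic, df, raw_p,
    adjusted_p, method.
    """
    wide = _site_pivot(sites)
    missing = [
        s
        for s in pd.concat([design["tumor_sample"], design["normal_sample"]])
        if s not in wide.columns
    ]
    if missing:
        raise _io.ValidationError(
            f"design references samples absent from the site table: {sorted(set(missing))[:5]}"
        )
    rows = []
    excluded = []
    for site_id, row in wide.iterrows():
        tumor = row[list(design["tumor_sample"])].to_numpy(dtype=float)
        normal = row[list(design["normal_sample"])].to_numpy(dtype=float)
        ok = np.isfinite(tumor) & np.isfinite(normal)
        t, n = tumor[ok], normal[ok]
        d = t - n
        if d.size < min_pairs:
            excluded.append((site_id, "insufficient complete pairs"))
            continue
        try:
            res = wilcoxon_signed_rank(d) if use_rank_test else paired_t(d)
        except DegenerateDataError:
            excluded.append((site_id, "degenerate differences (all zero)"))
            continue
        rows.append(
            {
                "site_id": site_id,
                "n_pairs": int(d.size),
                "mean_tumor_pct": float(t.mean()),
                "mean_normal_pct": float(n.mean()),
                "mean_paired_difference_pct": float(d.mean()),
                "statistic": res.statistic,
                "df": res.df,
                "raw_p": res.p_value,
                "method": res.method,
            }
        )
    if excluded:
        warnings.warn(
            f"{len(excluded)} site(s) excluded from paired comparison "
            f"(e.g. {excluded[0][0]!r}: {excluded[0][1]})",
            stacklevel=2,
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "n_pairs",
            "mean_tumor_pct",
            "mean_normal_pct",
            "mean_paired_difference_pct",
            "statistic",
            "df",
            "raw_p",
            "method",
        ],
    ).set_index("site_id")
    out["adjusted_p"] = bh_adjust(out["raw_p"].to_numpy()) if len(out) else []
    return out


def methylation_expression_correlation(
    sites: pd.DataFrame,
    expr: pd.DataFrame,
    gene_site_map: dict[str, list[str]],
    contexts: tuple[str, ...] = ("tumor", "normal_pair"),
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of percent methylation vs. relative expression.

    For each (gene, site) pair in ``gene_site_map``, samples present in both
    tables (expression restricted to ``contexts``, pooled) are correlated.
    Methylation-silenced genes are expected to show a negative correlation.
    Pairs with a constant vector or fewer than ``min_n`` joint samples are
    flagged not-evaluable (r and p NaN, a note in ``status``).
    """
    wide = _site_pivot(sites)
    rows = []
    for gene, site_ids in gene_site_map.items():
        e = expr[(expr["gene"] == gene) & expr["context"].isin(contexts)]
        e = e.set_index("sample")["rel_expr"]
        for site_id in site_ids:
            if site_id not in wide.index:
                rows.append(_corr_row(gene, site_id, 0, "site absent"))
                continue
            meth = wide.loc[site_id].dropna()
            common = meth.index.intersection(e.index)
            n = len(common)
            if n < min_n:
                rows.append(_corr_row(gene, site_id, n, "too few joint samples"))
                continue
            try:
                r, p = pearson_r(meth[common].to_numpy(), e[common].to_numpy())
            except DegenerateDataError:
                rows.append(_corr_row(gene, site_id, n, "constant vector"))
                continue
            rows.append(
                {
                    "gene": gene,
                    "site_id": site_id,
                    "n": n,
                    "r": r,
                    "p": p,
                    "status": "ok",
                }
            )
    return pd.DataFrame(rows, columns=["gene", "site_id", "n", "r", "p", "status"])


def _corr_row(gene, site_id, n, status):
    return {"gene": gene, "site_id": site_id, "n": n, "r": np.nan, "p": np.nan, "status": status}


def smoking_stratified_comparison(
    values: pd.Series,
    design: pd.DataFrame,
    tissue: str = "normal",
    use_rank_test: bool = False,
) -> tuple[TestResult, pd.DataFrame]:
    """Compare smokers vs. never-smokers within one tissue compartment.

    ``values`` is a per-sample measurement (e.g. percent methylation at a
    site, or a region summary β) indexed by sample id; ``tissue`` selects the
    tumor or normal member of each pair. Welch's t by default, Mann–Whitney U
    with ``use_rank_test``. Returns the test result and per-group summaries.
    """
    if tissue not in ("tumor", "normal"):
        raise ValueError("tissue must be 'tumor' or 'normal'")
    col = "tumor_sample" if tissue == "tumor" else "normal_sample"
    groups = {}
    for status in ("S", "NS"):
        samples = design.loc[design["smoking_status"] == status, col]
        missing = [s for s in samples if s not in values.index]
        if missing:
            raise _io.ValidationError(
                f"samples absent from the measurement vector: {missing[:5]}"
            )
        v = values[list(samples)].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            raise ValueError(f"group {status} has fewer than 2 usable values")
        groups[status] = v
    res = (
        mann_whitney_u(groups["S"], groups["NS"])
        if use_rank_test
        else welch_t(groups["S"], groups["NS"])
    )
    summary = pd.DataFrame(
        {
            "smoking_status": ["S", "NS"],
            "n": [groups["S"].size, groups["NS"].size],
            "mean": [groups["S"].mean(), groups["NS"].mean()],
            "sd": [groups["S"].std(ddof=1), groups["NS"].std(ddof=1)],
        }
    )
    return res, summary
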