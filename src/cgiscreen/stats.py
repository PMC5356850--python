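"""Statistical primitives used throughout the screen.

Conventions: every test is two-sided; directionality (hyper- vs
hypo-methylation) is enforced downstream by the sign of the effect, never by
one-sided testing. Rank tests use the exact small-sample null distribution
when feasible (n ≤ 25 and no ties) and the normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats as st

__all__ = [
    "TestResult",
    "DegenerateDataError",
    "beta_value",
    "paired_t",
    "welch_t",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "bh_adjust",
    "pearson_r",
    "log2_fold_change",
]

#: Largest sample size for which rank tests use the exact permutation null.
EXACT_RANK_TEST_MAX_N = 25

#: Default detection floor for expression fold changes (qRT-PCR non-detects).
DEFAULT_EXPRESSION_FLOOR = 1e-3


class DegenerateDataError(ValueError):
    """Raised when a test's input carries no usable signal (e.g. zero variance
    and zero effect, or an all-zero difference vector)."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test.

    ``df`` is None for rank tests; it is fractional for Welch's t.
    ``degenerate`` flags the zero-variance / nonzero-mean convention where the
    p-value is set to 0 by continuity.
    """

    statistic: float
    df: float | None
    p_value: float
    method: str
    degenerate: bool = False


def beta_value(m_intensity, u_intensity):
    """Methylation fraction β = M / (M + U) from probe channel intensities.

    Accepts scalars or arrays; returns NaN where both channels are zero
    (no signal, β undefined).
    """
    m = np.asarray(m_intensity, dtype=float)
    u = np.asarray(u_intensity, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be non-negative")
    total = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, m / np.where(total > 0, total, 1.0), np.nan)
    if np.isscalar(m_intensity) and np.isscalar(u_intensity):
        return float(beta) if not np.isnan(beta) else float("nan")
    return beta


def paired_t(differences) -> TestResult:
    """One-sample t-test of paired differences against zero.

    t = mean(d) / (sd(d) / √n), two-sided p from Student's t with n − 1 df.
    Zero variance with a nonzero mean returns the degenerate convention
    (infinite statistic, p = 0); zero variance with zero mean is an error.
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    n = d.size
    if n < 2:
        raise ValueError(f"paired t-test needs ≥ 2 finite differences, got {n}")
    mean = d.mean()
    sd = d.std(ddof=1)
    if np.ptp(d) == 0.0:  # exact: all differences identical
        mean = d[0]
        if mean == 0.0:
            raise DegenerateDataError(
                "all differences identical and zero: no variance and no effect"
            )
        return TestResult(
            statistic=math.copysign(math.inf, mean),
            df=float(n - 1),
            p_value=0.0,
            method="paired_t",
            degenerate=True,
        )
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * st.t.sf(abs(t), n - 1)
    return TestResult(statistic=t, df=float(n - 1), p_value=min(p, 1.0), method="paired_t")


def welch_t(x, y) -> TestResult:
    """Welch's unequal-variance t-test with Welch–Satterthwaite df."""
    x = _finite(x, "x", 2)
    y = _finite(y, "y", 2)
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, float(nx + ny - 2), 1.0, "welch_t", degenerate=True)
        return TestResult(
            math.copysign(math.inf, x.mean() - y.mean()),
            float(nx + ny - 2),
            0.0,
            "welch_t",
            degenerate=True,
        )
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * st.t.sf(abs(t), df)
    return TestResult(statistic=t, df=df, p_value=min(p, 1.0), method="welch_t")


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact null when both groups have ≤ 25 observations and there are no ties
    across the pooled sample; tie-corrected normal approximation otherwise.
    """
    x = _finite(x, "x", 2)
    y = _finite(y, "y", 2)
    pooled = np.concatenate([x, y])
    exact = (
        max(x.size, y.size) <= EXACT_RANK_TEST_MAX_N
        and np.unique(pooled).size == pooled.size
    )
    res = st.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        method="mann_whitney_u_exact" if exact else "mann_whitney_u_normal",
    )


def wilcoxon_signed_rank(differences) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of paired differences.

    Zero differences are dropped before ranking; an all-zero vector is an
    error. Exact sign-flip null for ≤ 25 nonzero tie-free differences, normal
    approximation otherwise.
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateDataError("all differences are zero")
    exact = d.size <= EXACT_RANK_TEST_MAX_N and np.unique(np.abs(d)).size == d.size
    res = st.wilcoxon(
        d,
        alternative="two-sided",
        zero_method="wilcox",
        method="exact" if exact else "approx",
    )
    return TestResult(
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        method="wilcoxon_exact" if exact else "wilcoxon_normal",
    )


def bh_adjust(raw_p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR q-values).

    Sorted ascending, p(k) is scaled by m/k and a running minimum is taken
    from the largest p downwards; results are capped at 1 and returned in the
    input order. Adjusted values never fall below the raw ones and preserve
    their ordering up to ties.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.ndim != 1:
        raise ValueError("raw p-values must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("raw p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted_sorted, 1.0)
    return out


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t transform (n − 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"Pearson correlation needs ≥ 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    res = st.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def log2_fold_change(
    treated: float, control: float, floor: float = DEFAULT_EXPRESSION_FLOOR
) -> float:
    """log2 of treated/control after flooring both at a detection limit.

    The floor keeps non-detects (zeros) from producing infinite fold changes;
    it should be set at the assay's practical detection limit.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    if treated < 0 or control < 0:
        raise ValueError("expression values must be non-negative")
    return math.log2(max(treated, floor) / max(control, floor))


def _finite(v, name: str, min_n: int) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < min_n:
        raise ValueError(f"{name} needs ≥ {min_n} finite values, got {arr.size}")
    return arr
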