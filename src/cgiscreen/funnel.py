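"""Four-criterion expression funnel for silenced tumor-suppressor candidates.

A gene associated with a hypermethylated CpG island is a candidate when it

1. is expressed in normal lung (not below the qRT-PCR detection floor),
2. is frequently downregulated in tumors vs. paired non-tumorous tissue
   (tumor/normal ratio strictly < 0.5, i.e. > 50% reduction, in ≥ 6 of 11
   cases by default),
3. is frequently silenced in tumor cell lines vs. a normal-tissue reference
   (ratio strictly < 0.2, i.e. > 80% reduction, in ≥ 8 of 14 lines), and
4. is re-expressed by demethylating treatment (5-aza-dC) with a strictly
   > 4-fold (log2 > 2) increase over vehicle in ≥ 2 of 3 lines.

All ratio/fold comparisons are strict; when a panel's actual size differs
from the defaults, the required count rescales proportionally (ceiling).
Genes that are not expressed in normal tissue short-circuit: the remaining
criteria are reported as missing and can never pass.
"""

from __future__ import annotations

import math
import re
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .stats import DEFAULT_EXPRESSION_FLOOR, log2_fold_change

__all__ = [
    "CandidateFunnel",
    "classify_normal_expression",
    "tumor_silencing",
    "cellline_silencing",
    "restoration",
    "required_count",
    "evaluate_evidence",
    "run_funnel",
    "load_evidence_table",
    "packaged_evidence_path",
]

EXPRESSED = "expressed"
VERY_LOW = "very_low"

_FRACTION_RE = re.compile(r"^\s*(\d+)\s*/\s*(\d+)\s*(?:\((\d+)\s*/\s*(\d+)\))?\s*$")
_DASHES = {"-", "−", "–", ""}


def classify_normal_expression(
    expr: pd.DataFrame, gene: str, detect_floor: float = DEFAULT_EXPRESSION_FLOOR
) -> str:
    """'expressed' if any normal-reference or paired-normal value reaches the
    detection floor; 'very_low' otherwise (including genes with no records)."""
    vals = expr.loc[
        (expr["gene"] == gene)
        & expr["context"].isin(["normal_reference", "normal_pair"]),
        "rel_expr",
    ]
    if len(vals) == 0 or (vals < detect_floor).all():
        return VERY_LOW
    return EXPRESSED


def tumor_silencing(
    expr: pd.DataFrame,
    gene: str,
    ratio_cut: float = 0.5,
    detect_floor: float = DEFAULT_EXPRESSION_FLOOR,
) -> tuple[int, int]:
    """(k, n): pairs with tumor/paired-normal ratio strictly below ``ratio_cut``.

    Tumor and normal records are matched by case id (the ``sample`` field).
    Pairs whose normal-side expression is below the detection floor are
    excluded from the denominator — a ratio against a non-detect is
    meaningless. n = 0 renders the criterion not-evaluable.
    """
    g = expr[expr["gene"] == gene]
    tumor = g[g["context"] == "tumor"].set_index("sample")["rel_expr"]
    normal = g[g["context"] == "normal_pair"].set_index("sample")["rel_expr"]
    cases = tumor.index.intersection(normal.index)
    normal = normal[cases]
    usable = normal[normal >= detect_floor]
    ratios = tumor[usable.index] / usable
    return int((ratios < ratio_cut).sum()), int(len(ratios))


def cellline_silencing(
    expr: pd.DataFrame,
    gene: str,
    ratio_cut: float = 0.2,
    detect_floor: float = DEFAULT_EXPRESSION_FLOOR,
) -> tuple[int, int]:
    """(k, n): cell lines with expression strictly below ``ratio_cut`` × the
    normal-tissue reference. Missing or non-detect reference → (0, 0),
    not-evaluable."""
    g = expr[expr["gene"] == gene]
    ref = g.loc[g["context"] == "normal_reference", "rel_expr"]
    if len(ref) == 0 or not (ref >= detect_floor).any():
        return 0, 0
    reference = float(ref[ref >= detect_floor].mean())
    lines = g.loc[g["context"] == "cell_line", "rel_expr"]
    ratios = lines / reference
    return int((ratios < ratio_cut).sum()), int(len(ratios))


def restoration(
    expr: pd.DataFrame,
    gene: str,
    log2_cut: float = 2.0,
    detect_floor: float = DEFAULT_EXPRESSION_FLOOR,
) -> tuple[int, int]:
    """(k, n): treated cell lines with a strictly > ``2**log2_cut``-fold
    expression increase over the matched vehicle control.

    Treated and vehicle records are matched by cell-line id; lines lacking
    either arm are skipped. No evaluable lines → (0, 0), not-evaluable.
    """
    g = expr[expr["gene"] == gene]
    treated = g[g["context"] == "treated"].set_index("sample")["rel_expr"]
    vehicle = g[g["context"] == "vehicle"].set_index("sample")["rel_expr"]
    lines = treated.index.intersection(vehicle.index)
    k = 0
    for line in lines:
        if log2_fold_change(treated[line], vehicle[line], detect_floor) > log2_cut:
            k += 1
    return k, int(len(lines))


def required_count(min_count_default: int, panel_default: int, n_actual: int) -> int:
    """Rescale a 'frequently' count threshold to a different panel size.

    ceil(min_count_default / panel_default × n_actual); identity when
    ``n_actual == panel_default``. With the default panels this gives the
    published ≥ 6/11, ≥ 8/14 and ≥ 2/3 rules.
    """
    if n_actual <= 0:
        return 1  # unreachable threshold: a 0-size panel can never pass
    return math.ceil(min_count_default / panel_default * n_actual)


def evaluate_evidence(
    evidence: pd.DataFrame,
    tumor_min_count: int = 6,
    tumor_panel: int = 11,
    cell_min_count: int = 8,
    cell_panel: int = 14,
    restore_min_count: int = 2,
    restore_panel: int = 3,
) -> pd.DataFrame:
    """Apply the pass/fail count rules to a per-gene evidence matrix.

    ``evidence`` needs columns gene, normal_expression, tumor_k, tumor_n,
    cell_k, cell_n, restore_k, restore_n (k/n may be missing for
    not-evaluable criteria). Returns the funnel report, one row per gene,
    sorted by (passes_all, number of criteria passed, tumor fraction, gene).
    """
    rows = []
    for rec in evidence.to_dict("records"):
        expressed = rec["normal_expression"] == EXPRESSED
        flags = {"pass_normal": bool(expressed)}
        fracs = {}
        for crit, mc, panel in (
            ("tumor", tumor_min_count, tumor_panel),
            ("cell", cell_min_count, cell_panel),
            ("restore", restore_min_count, restore_panel),
        ):
            k, n = rec.get(f"{crit}_k"), rec.get(f"{crit}_n")
            evaluable = expressed and pd.notna(k) and pd.notna(n) and n > 0
            if evaluable:
                need = required_count(mc, panel, int(n))
                flags[f"pass_{crit}"] = int(k) >= need
                fracs[f"{crit}_fraction"] = int(k) / int(n)
            else:
                flags[f"pass_{crit}"] = False
                fracs[f"{crit}_fraction"] = np.nan
        n_passed = sum(flags.values())
        rows.append(
            {
                "gene": rec["gene"],
                "normal_expression": rec["normal_expression"],
                "tumor_k": rec.get("tumor_k"),
                "tumor_n": rec.get("tumor_n"),
                "cell_k": rec.get("cell_k"),
                "cell_n": rec.get("cell_n"),
                "restore_k": rec.get("restore_k"),
                "restore_n": rec.get("restore_n"),
                **fracs,
                **flags,
                "n_criteria_passed": n_passed,
                "passes_all": n_passed == 4,
            }
        )
    columns = [
        "gene", "normal_expression",
        "tumor_k", "tumor_n", "cell_k", "cell_n", "restore_k", "restore_n",
        "tumor_fraction", "cell_fraction", "restore_fraction",
        "pass_normal", "pass_tumor", "pass_cell", "pass_restore",
        "n_criteria_passed", "passes_all",
    ]
    report = pd.DataFrame(rows, columns=columns)
    if len(report):
        report = report.sort_values(
            by=["passes_all", "n_criteria_passed", "tumor_fraction", "gene"],
            ascending=[False, False, False, True],
            na_position="last",
            kind="mergesort",
        ).reset_index(drop=True)
    return report


class CandidateFunnel(BaseEstimator):
    """Estimator applying the four-criterion candidate funnel to expression data.

    Parameters mirror the published thresholds: strict ratio cuts 0.5
    (tumor vs. paired normal) and 0.2 (cell line vs. normal reference), a
    strict log2 > 2 restoration cut, and 'frequently' counts ≥ 6/11, ≥ 8/14
    and ≥ 2/3 that rescale with the actual panel sizes. ``detect_floor`` is
    the qRT-PCR detection limit used both to call 'very low' normal
    expression and to floor fold-change denominators.

    Attributes
    ----------
    evidence_ : per-gene evidence matrix (status and k/n fractions).
    report_ : funnel report with pass flags, sorted best-first.
    candidates_ : genes with ``passes_all``.
    """

    def __init__(
        self,
        tumor_ratio_cut: float = 0.5,
        tumor_min_count: int = 6,
        tumor_panel: int = 11,
        cell_ratio_cut: float = 0.2,
        cell_min_count: int = 8,
        cell_panel: int = 14,
        restore_log2_cut: float = 2.0,
        restore_min_count: int = 2,
        restore_panel: int = 3,
        detect_floor: float = DEFAULT_EXPRESSION_FLOOR,
    ):
        self.tumor_ratio_cut = tumor_ratio_cut
        self.tumor_min_count = tumor_min_count
        self.tumor_panel = tumor_panel
        self.cell_ratio_cut = cell_ratio_cut
        self.cell_min_count = cell_min_count
        self.cell_panel = cell_panel
        self.restore_log2_cut = restore_log2_cut
        self.restore_min_count = restore_min_count
        self.restore_panel = restore_panel
        self.detect_floor = detect_floor

    def _validate(self):
        for name in ("tumor_ratio_cut", "cell_ratio_cut", "restore_log2_cut", "detect_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for mc, panel in (
            ("tumor_min_count", "tumor_panel"),
            ("cell_min_count", "cell_panel"),
            ("restore_min_count", "restore_panel"),
        ):
            if getattr(self, mc) > getattr(self, panel):
                raise ValueError(f"{mc} exceeds {panel}")

    def fit(self, expression: pd.DataFrame, genes: list[str]):
        """Compute evidence for ``genes`` from an expression table and score it."""
        self._validate()
        rows = []
        for gene in genes:
            status = classify_normal_expression(expression, gene, self.detect_floor)
            if status == VERY_LOW:
                # not expressed in normal tissue: remaining criteria moot
                rows.append(
                    {
                        "gene": gene,
                        "normal_expression": status,
                        "tumor_k": np.nan,
                        "tumor_n": np.nan,
                        "cell_k": np.nan,
                        "cell_n": np.nan,
                        "restore_k": np.nan,
                        "restore_n": np.nan,
                    }
                )
                continue
            tk, tn = tumor_silencing(
                expression, gene, self.tumor_ratio_cut, self.detect_floor
            )
            ck, cn = cellline_silencing(
                expression, gene, self.cell_ratio_cut, self.detect_floor
            )
            rk, rn = restoration(
                expression, gene, self.restore_log2_cut, self.detect_floor
            )
            rows.append(
                {
                    "gene": gene,
                    "normal_expression": status,
                    "tumor_k": tk,
                    "tumor_n": tn,
                    "cell_k": ck,
                    "cell_n": cn,
                    "restore_k": rk,
                    "restore_n": rn,
                }
            )
        self.evidence_ = pd.DataFrame(
            rows,
            columns=[
                "gene",
                "normal_expression",
                "tumor_k",
                "tumor_n",
                "cell_k",
                "cell_n",
                "restore_k",
                "restore_n",
            ],
        )
        return self._score()

    def fit_evidence(self, evidence: pd.DataFrame):
        """Score a pre-computed evidence matrix (e.g. a published table)."""
        self._validate()
        self.evidence_ = evidence.reset_index(drop=True)
        return self._score()

    def _score(self):
        self.report_ = evaluate_evidence(
            self.evidence_,
            self.tumor_min_count,
            self.tumor_panel,
            self.cell_min_count,
            self.cell_panel,
            self.restore_min_count,
            self.restore_panel,
        )
        self.candidates_ = self.report_.loc[self.report_["passes_all"], "gene"].tolist()
        return self


def run_funnel(
    candidate_genes: list[str], expression: pd.DataFrame, **thresholds
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: (evidence, report) for a candidate gene list."""
    funnel = CandidateFunnel(**thresholds).fit(expression, candidate_genes)
    return funnel.evidence_, funnel.report_


# ---------------------------------------------------------------------------
# published evidence matrix fixture


def packaged_evidence_path():
    """Path to the packaged published candidate-evidence matrix (nine genes
    at the top ten hypermethylated CpG islands of the stage-I lung
    adenocarcinoma discovery cohort)."""
    return resources.files("cgiscreen") / "data" / "ladc_candidate_evidence.tsv"


def load_evidence_table(path=None) -> pd.DataFrame:
    """Parse an evidence-matrix TSV with printed fraction cells.

    Cells like ``10/11`` are parsed into k/n; an extended-panel annotation
    such as ``10/11 (36/37)`` is retained as metadata columns; dashes mean
    not-evaluable.
    """
    if path is None:
        path = packaged_evidence_path()
    with resources.as_file(path) if hasattr(path, "is_file") and not isinstance(
        path, str
    ) else _nullcontext(path) as p:
        raw = pd.read_csv(p, sep="\t", dtype=str, comment="#")
    rows = []
    for rec in raw.to_dict("records"):
        row = {
            "gene": rec["gene"],
            "normal_expression": EXPRESSED
            if rec["normal_expression"].strip().lower() == "yes"
            else VERY_LOW,
        }
        for crit in ("tumor", "cell", "restore"):
            cell = (rec[crit] or "").strip()
            if cell in _DASHES:
                row[f"{crit}_k"] = np.nan
                row[f"{crit}_n"] = np.nan
                continue
            m = _FRACTION_RE.match(cell)
            if not m:
                raise ValueError(f"cannot parse fraction cell {cell!r} for {rec['gene']}")
            row[f"{crit}_k"] = int(m.group(1))
            row[f"{crit}_n"] = int(m.group(2))
            if m.group(3):
                row[f"{crit}_ext_k"] = int(m.group(3))
                row[f"{crit}_ext_n"] = int(m.group(4))
        rows.append(row)
    return pd.DataFrame(rows)


class _nullcontext:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False
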