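"""Seeded synthetic cohorts with the statistical structure the screen assumes.

The generator emulates a paired tumor/normal methylation-array discovery
cohort: CpG-island regions each carry a handful of probes; non-tumorous
baseline methylation is Beta-distributed with mean ≈ 0.15 (the 0.1–0.2 range
typical of unmethylated CpG islands); a configurable fraction of regions is
planted with tumor-specific hypermethylation whose per-pair effect is drawn
from N(effect_delta, effect_sd²). Expression panels couple to the planted
regions: silenced genes are downregulated in tumors and cell lines and
re-expressed several-fold under simulated demethylating treatment. A
site-level percent-methylation panel emulates pyrosequencing validation in a
larger cohort where smoking status has no effect by construction.

All randomness flows from one master seed through named
:class:`numpy.random.SeedSequence` streams, so each table can be regenerated
independently and reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as _io

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "MethylationCohort",
    "SitePanel",
    "generate_methylation_cohort",
    "generate_expression_panels",
    "generate_site_panel",
    "write_cohort",
]

_CLIP = (0.001, 0.999)
_CHROMS = [f"chr{i}" for i in range(1, 23)]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic discovery cohort.

    Defaults mirror the emulated study: 12 tumor/normal pairs split 6
    smokers / 6 never-smokers, 1000 CpG-island regions of 3–15 probes,
    Beta(3, 17) baseline (mean 0.15), 5% of regions planted with a mean
    tumor-specific Δβ of 0.3 (per-pair SD 0.05), probe-level noise SD 0.03,
    and expression panels of 11 cases, 14 cell lines (10 silenced for
    planted genes) and 3 treated lines with 5–50-fold restoration.
    """

    n_pairs: int = 12
    n_regions: int = 1000
    probes_per_region: tuple[int, int] = (3, 15)
    baseline_a: float = 3.0
    baseline_b: float = 17.0
    planted_fraction: float = 0.05
    effect_delta: float = 0.3
    effect_sd: float = 0.05
    probe_noise_sd: float = 0.03
    smoking_split: tuple[int, int] = (6, 6)
    coupling: bool = True
    restore_fold_range: tuple[float, float] = (5.0, 50.0)
    n_expr_pairs: int = 11
    n_cell_lines: int = 14
    cell_silenced_lines: int = 10
    n_restore_lines: int = 3
    tumor_silenced_prob: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 2 or self.n_regions < 1:
            raise ValueError("need ≥ 2 pairs and ≥ 1 region")
        lo, hi = self.probes_per_region
        if not (1 <= lo <= hi):
            raise ValueError("invalid probes_per_region range")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must be in [0, 1]")
        baseline_mean = self.baseline_a / (self.baseline_a + self.baseline_b)
        if baseline_mean + self.effect_delta > 1.0:
            raise ValueError(
                "infeasible effect: baseline mean + effect_delta exceeds 1 "
                f"({baseline_mean:.3f} + {self.effect_delta:.3f})"
            )
        if sum(self.smoking_split) != self.n_pairs:
            raise ValueError("smoking_split must sum to n_pairs")
        if self.effect_sd < 0 or self.probe_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.cell_silenced_lines > self.n_cell_lines:
            raise ValueError("cell_silenced_lines exceeds n_cell_lines")

    def streams(self) -> dict[str, np.random.Generator]:
        """Named child RNGs derived from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        names = ("methylation", "expression", "sites")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class TruthLabels:
    """Ground truth of a generated cohort, for recovery tests."""

    planted_region_ids: list[str]
    planted_gene_ids: list[str]
    true_delta: dict[str, float]  # realized mean per-pair Δβ, 0 for null regions
    silenced_genes: list[str]     # genes silenced in the expression model
    all_gene_ids: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MethylationCohort:
    beta: pd.DataFrame
    manifest: pd.DataFrame
    regions: pd.DataFrame
    design: pd.DataFrame
    truth: TruthLabels


@dataclass
class SitePanel:
    sites: pd.DataFrame
    design: pd.DataFrame
    expression: pd.DataFrame
    gene_site_map: dict[str, list[str]] = field(default_factory=dict)


def generate_methylation_cohort(config: SimulationConfig) -> MethylationCohort:
    """Generate β matrix, manifest, regions, paired design and truth labels.

    Per (region, patient): a shared baseline β is drawn from
    Beta(baseline_a, baseline_b); each normal probe value is the baseline
    plus probe noise, clipped to (0.001, 0.999); each tumor probe value adds
    the pair's hypermethylation effect (N(effect_delta, effect_sd²) for
    planted regions, 0 otherwise) before noise and clipping. Deterministic
    given the seed.
    """
    config.validate()
    rng = config.streams()["methylation"]
    R, P = config.n_regions, config.n_pairs
    lo, hi = config.probes_per_region
    probes_per_region = rng.integers(lo, hi + 1, size=R)
    T = int(probes_per_region.sum())

    # layout: regions cycle over chromosomes, spaced 100 kb apart
    region_ids = [f"CGI_{i + 1:05d}" for i in range(R)]
    genes = [f"GENE{i + 1:05d}" for i in range(R)]
    chroms = [_CHROMS[i % len(_CHROMS)] for i in range(R)]
    offsets = np.arange(R) // len(_CHROMS)
    starts = 100_000 + offsets * 100_000
    ends = starts + 100 + probes_per_region * 60
    contexts = [
        _io.GENE_CONTEXTS[int(i)] for i in rng.integers(0, len(_io.GENE_CONTEXTS), R)
    ]
    regions = pd.DataFrame(
        {
            "region_id": region_ids,
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "gene": genes,
            "gene_context": contexts,
        }
    )

    probe_region_idx = np.repeat(np.arange(R), probes_per_region)
    within = np.concatenate([np.arange(n) for n in probes_per_region])
    manifest = pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(T)],
            "chrom": np.asarray(chroms)[probe_region_idx],
            # 1-based CpG positions strictly inside the half-open interval
            "pos": starts[probe_region_idx] + 51 + within * 60,
        }
    )

    n_planted = round(config.planted_fraction * R)
    planted_idx = rng.choice(R, size=n_planted, replace=False)
    planted_mask = np.zeros(R, dtype=bool)
    planted_mask[planted_idx] = True

    baseline = rng.beta(config.baseline_a, config.baseline_b, size=(R, P))
    effects = np.zeros((R, P))
    effects[planted_mask] = rng.normal(
        config.effect_delta, config.effect_sd, size=(n_planted, P)
    )
    sigma = config.probe_noise_sd
    normal = np.clip(
        baseline[probe_region_idx] + rng.normal(0.0, sigma, size=(T, P)), *_CLIP
    )
    tumor = np.clip(
        baseline[probe_region_idx]
        + effects[probe_region_idx]
        + rng.normal(0.0, sigma, size=(T, P)),
        *_CLIP,
    )

    patients = [f"P{i + 1:02d}" for i in range(P)]
    design = pd.DataFrame(
        {
            "patient_id": patients,
            "tumor_sample": [f"{p}_T" for p in patients],
            "normal_sample": [f"{p}_N" for p in patients],
            "smoking_status": ["S"] * config.smoking_split[0]
            + ["NS"] * config.smoking_split[1],
        }
    )
    beta = pd.DataFrame(
        np.concatenate([tumor, normal], axis=1),
        index=pd.Index(manifest["probe_id"], name="probe_id"),
        columns=list(design["tumor_sample"]) + list(design["normal_sample"]),
    )

    planted_region_ids = [region_ids[i] for i in sorted(planted_idx)]
    planted_gene_ids = [genes[i] for i in sorted(planted_idx)]
    true_delta = {
        region_ids[i]: float(effects[i].mean()) for i in range(R)
    }
    if config.coupling:
        silenced = list(planted_gene_ids)
    else:
        silenced = sorted(rng.choice(genes, size=n_planted, replace=False).tolist())
    truth = TruthLabels(
        planted_region_ids=planted_region_ids,
        planted_gene_ids=planted_gene_ids,
        true_delta=true_delta,
        silenced_genes=silenced,
        all_gene_ids=genes,
    )
    return MethylationCohort(beta, manifest, regions, design, truth)


def generate_expression_panels(
    truth: TruthLabels, config: SimulationConfig
) -> pd.DataFrame:
    """Generate qRT-PCR-style relative-expression panels for every gene.

    Silenced genes (per ``truth``): tumor/paired-normal ratios fall below 0.5
    with probability ``tumor_silenced_prob``; exactly
    ``cell_silenced_lines`` of the cell lines express below 0.2 of the
    normal reference; all treated restoration lines show a fold change drawn
    from ``restore_fold_range`` (above the 4-fold cut). Non-silenced genes
    fluctuate around parity everywhere. Deterministic given the seed.
    """
    config.validate()
    rng = config.streams()["expression"]
    genes = list(truth.all_gene_ids)
    if not genes:
        raise ValueError("truth labels carry no gene ids")
    silenced = set(truth.silenced_genes)
    G = len(genes)
    is_sil = np.array([g in silenced for g in genes])

    npairs, nlines, nrest = config.n_expr_pairs, config.n_cell_lines, config.n_restore_lines
    case_ids = [f"E{i + 1:02d}" for i in range(npairs)]
    line_ids = [f"CL{i + 1:02d}" for i in range(nlines)]
    rest_ids = line_ids[:nrest]

    records = []

    # commercial normal-lung reference: every gene detectably expressed
    ref_vals = rng.lognormal(0.0, 0.1, size=G)
    records.append(
        pd.DataFrame(
            {"gene": genes, "sample": "normal_lung", "context": "normal_reference",
             "rel_expr": ref_vals}
        )
    )

    # tumor / paired-normal panel
    normal_vals = rng.lognormal(0.0, 0.2, size=(G, npairs))
    ratios = rng.lognormal(0.0, 0.25, size=(G, npairs))
    sil_hit = rng.random(size=(G, npairs)) < config.tumor_silenced_prob
    low = rng.uniform(0.05, 0.45, size=(G, npairs))
    high = rng.uniform(0.55, 1.2, size=(G, npairs))
    ratios = np.where(is_sil[:, None], np.where(sil_hit, low, high), ratios)
    tumor_vals = normal_vals * ratios
    for j, case in enumerate(case_ids):
        records.append(
            pd.DataFrame(
                {"gene": genes, "sample": case, "context": "normal_pair",
                 "rel_expr": normal_vals[:, j]}
            )
        )
        records.append(
            pd.DataFrame(
                {"gene": genes, "sample": case, "context": "tumor",
                 "rel_expr": tumor_vals[:, j]}
            )
        )

    # cell-line panel, relative to the same normal reference
    cell_vals = rng.lognormal(0.0, 0.25, size=(G, nlines)) * ref_vals[:, None]
    sil_lines = np.zeros((G, nlines), dtype=bool)
    for i in np.flatnonzero(is_sil):
        chosen = rng.choice(nlines, size=config.cell_silenced_lines, replace=False)
        sil_lines[i, chosen] = True
    low_cell = rng.uniform(0.01, 0.15, size=(G, nlines)) * ref_vals[:, None]
    mid_cell = rng.uniform(0.3, 1.2, size=(G, nlines)) * ref_vals[:, None]
    cell_vals = np.where(
        is_sil[:, None], np.where(sil_lines, low_cell, mid_cell), cell_vals
    )
    for j, line in enumerate(line_ids):
        records.append(
            pd.DataFrame(
                {"gene": genes, "sample": line, "context": "cell_line",
                 "rel_expr": cell_vals[:, j]}
            )
        )

    # demethylating-treatment arm on the first n_restore_lines lines
    f_lo, f_hi = config.restore_fold_range
    vehicle = np.where(
        is_sil[:, None],
        rng.uniform(0.001, 0.01, size=(G, nrest)),
        rng.lognormal(0.0, 0.2, size=(G, nrest)),
    )
    folds = np.where(
        is_sil[:, None],
        rng.uniform(f_lo, f_hi, size=(G, nrest)),
        rng.lognormal(0.0, 0.5, size=(G, nrest)),
    )
    treated = vehicle * folds
    for j, line in enumerate(rest_ids):
        records.append(
            pd.DataFrame(
                {"gene": genes, "sample": line, "context": "vehicle",
                 "rel_expr": vehicle[:, j]}
            )
        )
        records.append(
            pd.DataFrame(
                {"gene": genes, "sample": line, "context": "treated",
                 "rel_expr": treated[:, j]}
            )
        )

    expr = pd.concat(records, ignore_index=True)
    return expr[["gene", "sample", "context", "rel_expr"]]


def generate_site_panel(
    truth: TruthLabels,
    config: SimulationConfig,
    n_pairs: int = 46,
    n_sites: int = 5,
    smoking_split: tuple[int, int] = (25, 21),
) -> SitePanel:
    """Generate a pyrosequencing-style validation panel for one silenced gene.

    Percent methylation is 100 × the β model at single sites: non-tumorous
    baseline Beta(baseline_a, baseline_b) plus noise, tumors shifted by a
    per-(site, patient) effect N(effect_delta, effect_sd²). Smoking status
    is assigned (default 25 S / 21 NS) but has zero effect by construction.
    A coupled expression table (one value per sample, decreasing in the
    sample's mean methylation) supports inverse-correlation analysis.
    """
    config.validate()
    if sum(smoking_split) != n_pairs:
        raise ValueError("smoking_split must sum to n_pairs")
    rng = config.streams()["sites"]
    gene = truth.silenced_genes[0] if truth.silenced_genes else "GENE00001"
    site_ids = [f"site_{i + 1}" for i in range(n_sites)]
    patients = [f"V{i + 1:02d}" for i in range(n_pairs)]
    design = pd.DataFrame(
        {
            "patient_id": patients,
            "tumor_sample": [f"{p}_T" for p in patients],
            "normal_sample": [f"{p}_N" for p in patients],
            "smoking_status": ["S"] * smoking_split[0] + ["NS"] * smoking_split[1],
        }
    )
    baseline = rng.beta(config.baseline_a, config.baseline_b, size=(n_sites, n_pairs))
    sigma = config.probe_noise_sd
    normal = np.clip(baseline + rng.normal(0.0, sigma, size=(n_sites, n_pairs)), *_CLIP)
    effect = rng.normal(config.effect_delta, config.effect_sd, size=(n_sites, n_pairs))
    tumor = np.clip(
        baseline + effect + rng.normal(0.0, sigma, size=(n_sites, n_pairs)), *_CLIP
    )
    rows = []
    for i, site in enumerate(site_ids):
        for j, p in enumerate(patients):
            rows.append((site, f"{p}_T", 100.0 * tumor[i, j]))
            rows.append((site, f"{p}_N", 100.0 * normal[i, j]))
    sites = pd.DataFrame(rows, columns=["site_id", "sample", "percent_meth"])

    # expression decreases with the sample's mean methylation (silencing link)
    expr_rows = []
    for j, p in enumerate(patients):
        for sample, pct, context in (
            (f"{p}_T", 100.0 * tumor[:, j].mean(), "tumor"),
            (f"{p}_N", 100.0 * normal[:, j].mean(), "normal_pair"),
        ):
            rel = float(
                np.exp(-(pct - 15.0) / 20.0 + rng.normal(0.0, 0.3))
            )
            expr_rows.append((gene, sample, context, rel))
    expression = pd.DataFrame(
        expr_rows, columns=["gene", "sample", "context", "rel_expr"]
    )
    return SitePanel(sites, design, expression, {gene: site_ids})


def write_cohort(out_dir: str | os.PathLike, config: SimulationConfig) -> dict[str, str]:
    """Generate a full cohort and write it via the package's own writers.

    Emits beta.tsv, manifest.tsv, regions.bed, samples.tsv, expression.tsv,
    sites.tsv, site_samples.tsv, site_expression.tsv and truth.json into
    ``out_dir``; returns the path map.
    """
    os.makedirs(out_dir, exist_ok=True)
    cohort = generate_methylation_cohort(config)
    expression = generate_expression_panels(cohort.truth, config)
    panel = generate_site_panel(cohort.truth, config)
    paths = {
        "beta": os.path.join(out_dir, "beta.tsv"),
        "manifest": os.path.join(out_dir, "manifest.tsv"),
        "regions": os.path.join(out_dir, "regions.bed"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "expression": os.path.join(out_dir, "expression.tsv"),
        "sites": os.path.join(out_dir, "sites.tsv"),
        "site_samples": os.path.join(out_dir, "site_samples.tsv"),
        "site_expression": os.path.join(out_dir, "site_expression.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    _io.write_beta_matrix(cohort.beta, paths["beta"])
    _io.write_probe_manifest(cohort.manifest, paths["manifest"])
    _io.write_regions_bed(cohort.regions, paths["regions"])
    _io.write_sample_sheet(cohort.design, paths["samples"])
    _io.write_expression(expression, paths["expression"])
    _io.write_site_methylation(panel.sites, paths["sites"])
    _io.write_sample_sheet(panel.design, paths["site_samples"])
    _io.write_expression(panel.expression, paths["site_expression"])
    truth_payload = cohort.truth.to_json()
    truth_payload["gene_site_map"] = panel.gene_site_map
    with open(paths["truth"], "w") as fh:
        json.dump(truth_payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
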