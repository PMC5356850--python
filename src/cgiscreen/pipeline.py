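"""End-to-end orchestration: config, screen → funnel → validation, reports.

A run is driven by a YAML config naming the input files and the screen /
funnel parameters. Every output file records the thresholds that produced
it; the final report embeds a provenance block (config hash, seed, threshold
versions) so identical configs yield byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from . import io as _io
from .funnel import CandidateFunnel, load_evidence_table
from .integration import methylation_expression_correlation, paired_site_comparison
from .screen import RegionMethylationScreen
from .simulate import SimulationConfig

__all__ = ["PipelineConfig", "load_config", "run_screen", "run_funnel_stage", "run_full"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Methylation inputs (beta/manifest/regions/samples) drive the screen;
    ``expression`` feeds the funnel; ``evidence`` switches the funnel to
    pre-computed-evidence mode; site inputs enable the validation stage.
    """

    out_dir: str = "results"
    seed: int = 0
    beta: str | None = None
    manifest: str | None = None
    regions: str | None = None
    samples: str | None = None
    expression: str | None = None
    evidence: str | None = None
    sites: str | None = None
    site_samples: str | None = None
    site_expression: str | None = None
    gene_site_map: dict[str, list[str]] = field(default_factory=dict)
    candidate_source: str = "selected"  # or "top_k"
    screen: dict = field(default_factory=dict)
    funnel: dict = field(default_factory=dict)
    simulate: dict | None = None
    use_rank_test: bool = False

    def validate(self, require_methylation: bool = False) -> None:
        if self.candidate_source not in ("selected", "top_k"):
            raise _io.ValidationError("candidate_source must be 'selected' or 'top_k'")
        needed = []
        if require_methylation or any(
            (self.beta, self.manifest, self.regions, self.samples)
        ):
            needed += ["beta", "manifest", "regions", "samples"]
        for name in needed + [
            n for n in ("expression", "evidence", "sites", "site_samples",
                        "site_expression") if getattr(self, n)
        ]:
            path = getattr(self, name)
            if path is None:
                raise _io.ValidationError(f"config is missing required input '{name}'")
            if not os.path.exists(path):
                raise FileNotFoundError(f"input '{name}' not found: {path}")
        # construct parameter objects early so bad values fail before any I/O
        RegionMethylationScreen(**self.screen)._check_params()
        CandidateFunnel(**self.funnel)._validate()
        if self.simulate is not None:
            SimulationConfig(**self.simulate).validate()

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | os.PathLike) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise _io.ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)


def _write_tsv(df: pd.DataFrame, path: str, index: bool, header_meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in header_meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=_FLOAT_FMT, na_rep="NA")


def run_screen(config: PipelineConfig) -> RegionMethylationScreen:
    """Run the differential-methylation screen and write its outputs."""
    config.validate(require_methylation=True)
    os.makedirs(config.out_dir, exist_ok=True)
    beta = _io.read_beta_matrix(config.beta)
    manifest = _io.read_probe_manifest(config.manifest)
    regions = _io.read_regions_bed(config.regions)
    design = _io.read_sample_sheet(config.samples)
    screen = RegionMethylationScreen(**config.screen).fit(beta, manifest, regions, design)

    meta = {"tool": f"cgiscreen {__version__}", **screen.get_params()}
    out = screen.results_.copy()
    out["label"] = [
        _io.region_label(r.chrom, int(r.start), int(r.end))
        if pd.notna(r.start)
        else ""
        for r in out.itertuples()
    ]
    _write_tsv(out, os.path.join(config.out_dir, "screen.tsv"), True, meta)
    _write_tsv(
        screen.volcano_data(),
        os.path.join(config.out_dir, "volcano.tsv"),
        True,
        meta,
    )
    logger.info(
        "screen: %d regions tested, %d selected; top-%d genes: %s",
        screen.n_regions_tested_,
        len(screen.selected_),
        screen.top_k,
        ", ".join(screen.candidate_genes()) or "(none)",
    )
    return screen


def run_funnel_stage(
    config: PipelineConfig, candidate_genes: list[str] | None = None
) -> CandidateFunnel:
    """Run the candidate funnel, from expression data or a fixed evidence table."""
    os.makedirs(config.out_dir, exist_ok=True)
    funnel = CandidateFunnel(**config.funnel)
    if config.evidence:
        funnel.fit_evidence(load_evidence_table(config.evidence))
    else:
        if config.expression is None:
            raise _io.ValidationError(
                "funnel needs either 'expression' data or an 'evidence' table"
            )
        expression = _io.read_expression(config.expression)
        if candidate_genes is None:
            candidate_genes = sorted(expression["gene"].unique())
        funnel.fit(expression, candidate_genes)
    meta = {"tool": f"cgiscreen {__version__}", **funnel.get_params()}
    _write_tsv(
        funnel.evidence_, os.path.join(config.out_dir, "funnel_evidence.tsv"), False, meta
    )
    _write_tsv(
        funnel.report_, os.path.join(config.out_dir, "funnel_report.tsv"), False, meta
    )
    logger.info(
        "funnel: %d gene(s) evaluated, %d candidate(s): %s",
        len(funnel.report_),
        len(funnel.candidates_),
        ", ".join(funnel.candidates_) or "(none)",
    )
    return funnel


def run_validation(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Paired site-level comparison and methylation–expression correlation."""
    os.makedirs(config.out_dir, exist_ok=True)
    sites = _io.read_site_methylation(config.sites)
    design = _io.read_sample_sheet(config.site_samples)
    out: dict[str, pd.DataFrame] = {}
    out["site_comparison"] = paired_site_comparison(
        sites, design, use_rank_test=config.use_rank_test
    )
    meta = {"tool": f"cgiscreen {__version__}", "use_rank_test": config.use_rank_test}
    _write_tsv(
        out["site_comparison"],
        os.path.join(config.out_dir, "site_comparison.tsv"),
        True,
        meta,
    )
    if config.site_expression and config.gene_site_map:
        expr = _io.read_expression(config.site_expression)
        out["correlation"] = methylation_expression_correlation(
            sites, expr, config.gene_site_map
        )
        _write_tsv(
            out["correlation"],
            os.path.join(config.out_dir, "correlation.tsv"),
            False,
            meta,
        )
    return out


def run_full(config: PipelineConfig) -> dict:
    """Screen → funnel → validation; returns and writes the candidate report."""
    config.validate(require_methylation=True)
    stage = "screen"
    try:
        screen = run_screen(config)
        stage = "funnel"
        if config.candidate_source == "top_k":
            genes = screen.candidate_genes()
        else:
            genes = list(dict.fromkeys(screen.selected_["gene"].dropna()))
        funnel = run_funnel_stage(config, candidate_genes=genes)
        validation = None
        if config.sites and config.site_samples:
            stage = "validation"
            validation = run_validation(config)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    report = {
        "provenance": {
            "tool": "cgiscreen",
            "version": __version__,
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "screen_params": screen.get_params(),
            "funnel_params": funnel.get_params(),
        },
        "n_regions_tested": int(screen.n_regions_tested_),
        "n_regions_selected": int(len(screen.selected_)),
        "top_regions": screen.top()
        .reset_index()[["region_id", "gene", "delta_beta", "adjusted_p", "rank"]]
        .to_dict("records"),
        "candidate_genes": funnel.candidates_,
        "n_genes_evaluated": int(len(funnel.report_)),
    }
    if validation is not None and "correlation" in validation:
        ok = validation["correlation"].query("status == 'ok'")
        report["inverse_correlations"] = ok[["gene", "site_id", "n", "r", "p"]].to_dict(
            "records"
        )
    path = os.path.join(config.out_dir, "report.json")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    return report
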