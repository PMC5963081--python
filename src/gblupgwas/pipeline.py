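"""End-to-end orchestration: simulate/load -> QC -> GRM -> REML fits ->
window GWAS -> region selection -> gene annotation -> summary.

A run directory receives every stage's serialized output (TSV/BED/JSON), a
log with the package version, config hash and seed, and a machine-readable
``summary.json``.  Stage failures leave partial outputs plus a ``FAILED``
marker naming the stage.  Bivariate fits run one trait at a time against the
anchor, each anchored at the anchor's univariate variance components.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import hits_to_frame, overlap_genes, read_annotation
from .grm import grm_from_genotypes
from .gwas import backsolve_snp_effects, regions_to_bed, select_regions, window_variances
from .io import GenotypeMatrix, read_genotypes, read_phenotypes
from .qc import QCThresholds, apply_qc
from .reml import FitOptions, fit_bivariate_anchored, fit_univariate, make_model_data
from .sim import SimulationConfig, TraitSpec, simulate_genotypes, simulate_phenotypes, study_config

__all__ = ["PipelineConfig", "run_pipeline", "report_manhattan"]


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_run"
    seed: int = 0
    # either simulate (overrides for study_config) or explicit input paths
    simulate: dict[str, Any] | None = None
    genotypes: str | None = None
    genotype_dialect: str = "plink_text"
    genotype_map: str | None = None
    phenotypes: str | None = None
    annotation: str | None = None
    annotation_format: str = "bed"
    anchor_trait: str = "IMF"
    trait_list: list[str] = field(default_factory=list)
    qc: dict[str, Any] = field(default_factory=dict)
    window_size: int = 10
    window_mode: str = "sliding"
    threshold_pct: float = 0.30
    grm_blend: float = 0.01
    reml: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # analysis-irrelevant; keeps reruns comparable
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        overrides = dict(config.simulate)
        overrides.setdefault("seed", config.seed)
        if "trait_specs" in overrides:
            overrides["trait_specs"] = tuple(
                TraitSpec(**t) for t in overrides["trait_specs"]
            )
        sim_cfg = study_config(**overrides)
        genotypes = simulate_genotypes(sim_cfg)
        phenotypes, _truth = simulate_phenotypes(genotypes, sim_cfg)
        return genotypes, phenotypes
    if not config.genotypes or not config.phenotypes:
        raise ValueError("config needs either 'simulate' or genotype+phenotype paths")
    genotypes = read_genotypes(
        config.genotypes, dialect=config.genotype_dialect, map_path=config.genotype_map
    )
    phenotypes = read_phenotypes(config.phenotypes)
    return genotypes, phenotypes


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    log_lines = [
        f"gblupgwas {__version__}",
        f"config_hash {config.config_hash()}",
        f"seed {config.seed}",
    ]
    summary: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    stage = "inputs"
    try:
        genotypes, phenotypes = _load_inputs(config)
        traits = config.trait_list or [
            c for c in phenotypes.columns if c not in ("id", "group")
        ]
        if config.anchor_trait not in traits:
            raise ValueError(f"anchor trait {config.anchor_trait!r} not among traits {traits}")
        for t in traits:
            if t not in phenotypes.columns:
                raise ValueError(f"unknown trait {t!r} in trait_list")

        stage = "qc"
        g_qc, report = apply_qc(genotypes, QCThresholds(**config.qc))
        report.to_tsv(outdir / "qc_snp_fate.tsv")
        (outdir / "qc_report.txt").write_text(report.summary() + "\n")
        summary["qc"] = {
            "n_snps_in": report.n_snps_in,
            "n_snps_out": report.n_snps_out,
            "n_individuals": report.n_individuals,
            "removals": report.removal_counts,
        }

        stage = "grm"
        grm, centered = grm_from_genotypes(g_qc, blend_weight=config.grm_blend)
        grm.to_tsv(outdir / "grm.tsv")
        off = grm.matrix[~np.eye(grm.matrix.shape[0], dtype=bool)]
        summary["grm"] = {
            "mean_diagonal": float(np.mean(np.diag(grm.matrix))),
            "mean_offdiagonal": float(off.mean()),
            "sd_offdiagonal": float(off.std(ddof=1)),
            "max_offdiagonal": float(off.max()),
            "min_offdiagonal": float(off.min()),
        }

        opts = FitOptions(**config.reml)
        stage = f"fit_univariate[{config.anchor_trait}]"
        data_anchor = make_model_data(phenotypes, grm, config.anchor_trait)
        vc_anchor, gebv_anchor = fit_univariate(data_anchor, opts)
        vc_anchor.to_frame().to_csv(outdir / f"components_{config.anchor_trait}.tsv", sep="\t", index=False)
        gebv_anchor.u_hat.rename_axis("id").to_csv(outdir / f"gebv_{config.anchor_trait}.tsv", sep="\t")
        anchor_name = config.anchor_trait
        summary["traits"] = {
            anchor_name: {
                "model": "univariate",
                "sigma2_u": vc_anchor.sigma2_u,
                "sigma2_e": vc_anchor.sigma2_e,
                "h2": vc_anchor.h2[anchor_name],
                "h2_se": vc_anchor.h2_se[anchor_name],
                "n_iter": vc_anchor.n_iter,
            }
        }

        all_windows: dict[str, pd.DataFrame] = {}
        all_regions: dict[str, list] = {}
        gebv_by_trait = {anchor_name: gebv_anchor.u_hat[anchor_name].to_numpy()}
        sigma2_by_trait = {anchor_name: vc_anchor.sigma2_u}
        for trait in traits:
            if trait == anchor_name:
                continue
            stage = f"fit_bivariate[{trait}]"
            data2 = make_model_data(phenotypes, grm, [anchor_name, trait])
            vc2, gebv2 = fit_bivariate_anchored(
                data2, (vc_anchor.sigma2_u, vc_anchor.sigma2_e), opts
            )
            vc2.to_frame().to_csv(outdir / f"components_{trait}.tsv", sep="\t", index=False)
            gebv2.u_hat.rename_axis("id").to_csv(outdir / f"gebv_{trait}.tsv", sep="\t")
            summary["traits"][trait] = {
                "model": "bivariate_anchored",
                "sigma2_u": float(vc2.H[1, 1]),
                "sigma2_e": float(vc2.R[1, 1]),
                "h2": vc2.h2[trait],
                "h2_se": vc2.h2_se[trait],
                "genetic_corr_with_anchor": vc2.genetic_corr,
                "n_iter": vc2.n_iter,
            }
            gebv_by_trait[trait] = gebv2.u_hat[trait].to_numpy()
            sigma2_by_trait[trait] = float(vc2.H[1, 1])

        for trait in traits:
            stage = f"gwas[{trait}]"
            eff = backsolve_snp_effects(centered, gebv_by_trait[trait])
            windows = window_variances(
                centered, eff, sigma2_by_trait[trait],
                window_size=config.window_size, mode=config.window_mode,
            )
            windows.to_csv(outdir / f"windows_{trait}.tsv", sep="\t", index=False)
            regions = select_regions(windows, config.threshold_pct)
            regions_to_bed(regions).to_csv(
                outdir / f"regions_{trait}.bed", sep="\t", index=False, header=False
            )
            report_manhattan(windows, outdir / f"manhattan_{trait}",
                             threshold_pct=config.threshold_pct)
            all_windows[trait] = windows
            all_regions[trait] = regions
            summary["traits"][trait]["n_windows"] = int(len(windows))
            summary["traits"][trait]["max_window_pct"] = float(windows["pct"].max())
            summary["traits"][trait]["n_qtl_regions"] = len(regions)

        if config.annotation:
            stage = "annotation"
            genes = read_annotation(config.annotation, format=config.annotation_format)
            for trait in traits:
                hits = overlap_genes(all_regions[trait], genes)
                hits_to_frame(hits).to_csv(outdir / f"gene_hits_{trait}.tsv", sep="\t", index=False)
                summary["traits"][trait]["n_gene_hits"] = len(hits)

        stage = "summary"
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        (outdir / "run.log").write_text("\n".join(log_lines + ["status OK"]) + "\n")
        return outdir
    except Exception as err:
        failed_marker.write_text(f"stage: {stage}\nerror: {err}\n")
        (outdir / "run.log").write_text("\n".join(log_lines + [f"status FAILED at {stage}: {err}"]) + "\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err


def report_manhattan(
    windows: pd.DataFrame, outprefix: str | Path, threshold_pct: float = 0.30
) -> Path:
    """Write a Manhattan-style table (and PNG) of window variance percentages.

    The TSV carries one row per window (chrom, midpoint bp, cumulative
    genome position, pct) and records the suprathreshold line in its header
    comment; the plot alternates shading by chromosome and draws the
    threshold line.
    """
    if windows.empty:
        raise ValueError("no windows to report")
    outprefix = Path(outprefix)
    outprefix.parent.mkdir(parents=True, exist_ok=True)
    df = windows.copy()
    df["midpoint_bp"] = (df["start_bp"] + df["end_bp"]) // 2
    offset = 0
    cum = []
    for chrom, sub in df.groupby("chrom", sort=False):
        cum.append(sub["midpoint_bp"] + offset)
        offset += int(sub["end_bp"].max()) + 1
    df["cumulative_bp"] = pd.concat(cum)
    tsv = outprefix.with_suffix(".tsv")
    with open(tsv, "w") as fh:
        fh.write(f"# threshold_pct={threshold_pct}\n")
        df[["chrom", "midpoint_bp", "cumulative_bp", "pct"]].to_csv(fh, sep="\t", index=False)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 3))
        for i, (chrom, sub) in enumerate(df.groupby("chrom", sort=False)):
            ax.scatter(sub["cumulative_bp"], sub["pct"], s=4,
                       color="steelblue" if i % 2 == 0 else "darkorange")
        ax.axhline(threshold_pct, color="red", linestyle="--", linewidth=0.8)
        ax.set_xlabel("genome position")
        ax.set_ylabel("% additive genetic variance")
        fig.tight_layout()
        fig.savefig(outprefix.with_suffix(".png"), dpi=120)
        plt.close(fig)
    except Exception:
        pass  # the TSV is the contract; plotting is best-effort
    return tsv
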