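"""End-to-end orchestration: QC -> normalise -> cell-type correction ->
association -> diagnostics -> window DMRs -> bump hunting -> enrichment.

`run_analysis` is the in-memory engine (dataset in, result bundle out);
`run_pipeline` wraps it with file IO, logging, a config hash for
reproducibility, and all-or-nothing output semantics (a stage failure
removes partial outputs and re-raises tagged with the stage name).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .association import genome_scan, inflation_lambda, qq_band
from .bumphunter import BumpHunter
from .celltype import ReFACTor
from .datatypes import MethylationDataset
from .enrichment import feature_enrichment, geneset_enrichment
from .preprocessing import CovariateNormalizer, ProbeFilter, DEFAULT_COVARIATES
from .windows import SlidingWindowDMR, region_overlap, regions_to_frame

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_analysis", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Global pipeline constants (defaults follow the study's settings)."""

    data_dir: Optional[str] = None
    out_dir: str = "results"
    gmt_path: Optional[str] = None

    max_missing: int = 11
    max_detection_fail: int = 5
    detection_alpha: float = 0.001
    covariates: Sequence[str] = DEFAULT_COVARIATES

    refactor_k: int = 5
    refactor_t: int = 500

    window_width: int = 1000
    window_fdr: float = 0.05
    genomewide_p: float = 1.09e-7

    bootstrap_b: int = 1000
    fwer_threshold: float = 0.1

    min_overlap: int = 2
    pathway_fdr: float = 0.05

    seed: int = 0
    plots: bool = False

    def __post_init__(self) -> None:
        for name in ("window_fdr", "detection_alpha", "genomewide_p", "fwer_threshold", "pathway_fdr"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.window_width < 1:
            raise ValueError("window_width must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_analysis(ds: MethylationDataset, config: Optional[PipelineConfig] = None) -> dict:
    """Run every stage in memory and return the result bundle as a dict."""
    cfg = config or PipelineConfig()
    out: dict = {"config": cfg}

    logger.info("stage qc: %d probes, %d samples", ds.n_probes, ds.n_samples)
    filt = ProbeFilter(
        max_missing=cfg.max_missing,
        max_detection_fail=cfg.max_detection_fail,
        detection_alpha=cfg.detection_alpha,
    ).fit(ds)
    ds_qc = filt.transform(ds)
    out["qc_report"] = filt.report_

    logger.info("stage normalise: covariates %s", list(cfg.covariates))
    needs = {"age2": ["age"], "sex_age": ["sex", "age"], "sex_age2": ["sex", "age"]}
    covs = [
        c for c in cfg.covariates
        if all(col in ds.samples.columns for col in needs.get(c, [c]))
    ]
    ds_norm = CovariateNormalizer(covariates=covs).fit(ds_qc).transform(ds_qc)

    logger.info("stage celltype: K=%d t=%d", cfg.refactor_k, cfg.refactor_t)
    ref = ReFACTor(K=cfg.refactor_k, t=min(cfg.refactor_t, ds_norm.n_probes)).fit(ds_norm)
    ds_corr = ref.transform(ds_norm)
    out["celltype_components"] = ref.components_
    out["corrected"] = ds_corr

    logger.info("stage associate: logistic LRT per probe, cohort-adjusted")
    results = genome_scan(ds_corr, covariates=("cohort",))
    out["association"] = results

    valid_p = results["p"].to_numpy(dtype=float)
    valid_p = valid_p[np.isfinite(valid_p)]
    infl = inflation_lambda(valid_p)
    out["inflation"] = infl
    out["qq"] = qq_band(valid_p.size) if valid_p.size else None
    out["n_genomewide"] = int((valid_p < cfg.genomewide_p).sum())
    logger.info("diagnostics: lambda=%.3f over %d tests", infl.lambda_, infl.n_tests)

    probes = ds_corr.manifest.copy()
    probes["p"] = results["p"].to_numpy()
    probes["delta_beta"] = results["delta_beta"].to_numpy()
    dmr = SlidingWindowDMR(width=cfg.window_width, q_threshold=cfg.window_fdr).fit(probes)
    out["windows"] = dmr.windows_
    out["regions"] = dmr.regions_
    logger.info("stage window_dmr: %d significant window(s) merged to %d region(s)",
                int((dmr.windows_["q"] < cfg.window_fdr).sum()), len(dmr.regions_))

    logger.info("stage bumphunter: B=%d", cfg.bootstrap_b)
    bh = BumpHunter(maxgap=cfg.window_width, B=cfg.bootstrap_b, seed=cfg.seed).fit(ds_corr)
    out["bumps"] = bh.table_
    out["bump_candidates"] = bh.candidates_
    sig_bumps = bh.table_[bh.table_["fwer"] < cfg.fwer_threshold]

    out["overlap"] = region_overlap(regions_to_frame(dmr.regions_), sig_bumps) if len(dmr.regions_) and len(sig_bumps) else pd.DataFrame(columns=["index_a", "index_b", "overlap_bp"])

    out["enrichment"] = {}
    if dmr.regions_:
        dmr_probes = sorted({p for r in dmr.regions_ for p in r.probe_ids})
        for fieldname in ("island_relation", "gene_feature", "dnase_hs"):
            out["enrichment"][fieldname] = feature_enrichment(dmr_probes, ds_corr.manifest, fieldname)
        genes = sorted({g for r in dmr.regions_ for g in r.nearest_genes})
        background = sorted(set(ds_corr.manifest["nearest_gene"].dropna()))
        out["dmr_genes"] = genes
        if cfg.gmt_path:
            gmt = mio.read_gmt(cfg.gmt_path)
            out["enrichment"]["pathways"] = geneset_enrichment(
                genes, gmt, background, min_overlap=cfg.min_overlap, fdr=cfg.pathway_fdr
            )
    return out


def _write_outputs(out: dict, cfg: PipelineConfig, created: list[str]) -> None:
    def path(name: str) -> str:
        p = os.path.join(cfg.out_dir, name)
        created.append(p)
        return p

    mio.write_qc_report(out["qc_report"], path("qc_report.tsv"))
    out["association"].to_csv(path("association.tsv"), sep="\t", index=False, float_format="%.6g")
    infl = out["inflation"]
    with open(path("diagnostics.json"), "w") as fh:
        json.dump(
            {
                "lambda": infl.lambda_,
                "expected_median_chisq": infl.expected_median,
                "n_tests": infl.n_tests,
                "n_genomewide_significant": out["n_genomewide"],
                "genomewide_threshold": cfg.genomewide_p,
                "config_hash": cfg.hash(),
                "seed": cfg.seed,
            },
            fh,
            indent=2,
        )
    out["windows"].to_csv(path("windows.tsv"), sep="\t", index=False, float_format="%.6g")
    mio.write_regions_bed(out["regions"], path("dmr.bed"))
    mio.write_regions_tsv(out["regions"], path("dmr.tsv"))
    out["bumps"].to_csv(path("bumps.tsv"), sep="\t", index=False, float_format="%.6g")
    out["overlap"].to_csv(path("overlap.tsv"), sep="\t", index=False)
    for name, table in out.get("enrichment", {}).items():
        table.to_csv(path(f"enrichment_{name}.tsv"), sep="\t", index=False, float_format="%.6g")
    if cfg.plots and out.get("qq") is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        qq = out["qq"]
        obs = -np.log10(np.sort(out["association"]["p"].dropna().to_numpy()))
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.fill_between(qq["expected"], qq["lower"], qq["upper"], color="0.85", label="95% band")
        ax.plot(qq["expected"], qq["expected"], color="white", lw=1)
        ax.plot(qq["expected"][::-1], obs, ".", ms=2, color="C0")
        ax.set_xlabel("expected -log10 P")
        ax.set_ylabel("observed -log10 P")
        ax.legend()
        fig.savefig(path("qq.png"), dpi=150)
        plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based pipeline: read the dataset, run all stages, write outputs.

    Outputs carry the config hash and seed; any stage failure removes the
    partially written outputs and re-raises with the stage name.
    """
    cfg = config
    os.makedirs(cfg.out_dir, exist_ok=True)
    log_path = os.path.join(cfg.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("methdmr")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    created: list[str] = [log_path]
    stage = "read_inputs"
    try:
        logger.info("config hash %s; full config: %s", cfg.hash(), dataclasses.asdict(cfg))
        if cfg.data_dir is None:
            raise ValueError("config.data_dir is required")
        ds = mio.read_dataset(cfg.data_dir)
        stage = "analysis"
        out = run_analysis(ds, cfg)
        stage = "write_outputs"
        _write_outputs(out, cfg, created)
        with open(os.path.join(cfg.out_dir, "run_info.json"), "w") as fh:
            json.dump({"config": dataclasses.asdict(cfg), "config_hash": cfg.hash()}, fh, indent=2, default=str)
        return out
    except Exception as exc:
        for p in created:
            if os.path.exists(p) and p != log_path:
                os.remove(p)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
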