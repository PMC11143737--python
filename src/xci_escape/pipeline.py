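"""End-to-end orchestration: simulate -> ASE -> lines -> genes -> DE ->
enrichment, with a YAML-serializable run manifest.

Each stage writes its result tables under the run directory; a failure
halts the run with the failing stage named while earlier outputs are
kept.  With a fixed seed the whole run is deterministic.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (ase_core, diffexpr, enrichment, gene_escape, io_formats,
               line_state, synthetic_data)
from .thresholds import Thresholds

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "xci_escape_run"
    seed: int = 0
    # input paths; all None means "simulate a cohort first"
    allelic_counts: str | None = None
    gene_counts: str | None = None
    gene_models: str | None = None
    sample_meta: str | None = None
    thresholds: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)        # SimConfig overrides
    stages: tuple[str, ...] = ("simulate", "ase", "lines", "genes", "de",
                               "enrich")
    gap_k_max: int = 6
    gap_b_ref: int = 100
    n_permutations: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        external = [cfg.allelic_counts, cfg.gene_counts, cfg.gene_models,
                    cfg.sample_meta]
        if "simulate" not in cfg.stages:
            missing = [n for n, p in zip(
                ["allelic_counts", "gene_counts", "gene_models",
                 "sample_meta"], external) if p is None]
            if missing:
                raise ValueError(
                    f"stage 'simulate' disabled but input path(s) missing: "
                    f"{', '.join(missing)}")
        return cfg


def _config_hash(cfg: RunConfig) -> str:
    text = yaml.safe_dump(cfg.__dict__, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest dict (also written to ``manifest.yaml``).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = Thresholds.from_dict(cfg.thresholds)
    manifest: dict = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                      "stages": {}, "row_counts": {}}
    state: dict = {}

    stage_fns = {
        "simulate": _stage_simulate,
        "ase": _stage_ase,
        "lines": _stage_lines,
        "genes": _stage_genes,
        "de": _stage_de,
        "enrich": _stage_enrich,
    }
    for stage in cfg.stages:
        t0 = time.perf_counter()
        logger.info("stage %s ...", stage)
        try:
            stage_fns[stage](cfg, thresholds, outdir, state, manifest)
        except Exception:
            logger.error("stage %s failed; earlier outputs kept in %s",
                         stage, outdir)
            raise
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)
    (outdir / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True))
    return manifest


def _stage_simulate(cfg, thresholds, outdir, state, manifest):
    sim_cfg = synthetic_data.SimConfig(**cfg.sim)
    cohort = synthetic_data.simulate_cohort(sim_cfg, seed=cfg.seed)
    synthetic_data.write_cohort(cohort, outdir / "synthetic")
    state["cohort"] = cohort
    state["allelic"] = cohort.allelic_counts
    state["counts"] = cohort.expr_counts
    state["gene_models"] = cohort.gene_models
    state["meta"] = cohort.meta
    state["annotations"] = cohort.annotations
    manifest["row_counts"]["allelic_counts"] = len(cohort.allelic_counts)
    manifest["row_counts"]["genes"] = len(cohort.gene_models)


def _load_inputs(cfg, state):
    if "allelic" not in state:
        state["allelic"] = io_formats.read_allelic_counts(cfg.allelic_counts)
        state["counts"] = io_formats.read_gene_counts(cfg.gene_counts)
        state["gene_models"] = io_formats.read_gene_models(cfg.gene_models)
        state["meta"] = io_formats.read_sample_meta(cfg.sample_meta)


def _stage_ase(cfg, thresholds, outdir, state, manifest):
    _load_inputs(cfg, state)
    records = ase_core.run_ase_pipeline(state["allelic"],
                                        state["gene_models"], thresholds)
    io_formats.write_table(records, outdir / "gene_ase.tsv")
    state["ase"] = records
    manifest["row_counts"]["gene_ase"] = len(records)


def _stage_lines(cfg, thresholds, outdir, state, manifest):
    counts = diffexpr.filter_low_counts(state["counts"])
    factors = diffexpr.tmm_factors(counts)
    logcpm = diffexpr.log2cpm(counts, factors)
    state["logcpm"] = logcpm
    x_rec = state["ase"][state["ase"]["chrom"].isin(["chrX", "X"])]
    profiles = line_state.summarize_lines(x_rec, logcpm, state["meta"],
                                          thresholds)
    feats = line_state.standardize_features(profiles)
    k, gap_table = line_state.choose_k_gap(feats, k_max=cfg.gap_k_max,
                                           b_ref=cfg.gap_b_ref,
                                           seed=cfg.seed)
    groups = line_state.kmeans_groups(feats, k=3, seed=cfg.seed)
    profiles["erosion_group"] = profiles["line_id"].map(groups)
    fem = profiles[(profiles["sex"] == "female")
                   & profiles["frac_biallelic"].notna()]
    fits = {"gap_k": int(k)}
    if len(fem) >= 10:
        sig = line_state.fit_sigmoid(fem["xist_log2cpm"], fem["mean_ase"])
        fits.update({"sigmoid_asymptote": float(sig.asymptote),
                     "sigmoid_inflection": float(sig.inflection),
                     "sigmoid_slope": float(sig.slope)})
        low = line_state.lowess_curve(fem["xist_log2cpm"],
                                      fem["frac_biallelic"])
        io_formats.write_table(low, outdir / "lowess_curve.tsv")
    x_genes = state["gene_models"].loc[
        state["gene_models"]["chrom"].isin(["chrX", "X"]), "gene_id"]
    pca = line_state.pca_variance_explained(
        logcpm.loc[logcpm.index.intersection(x_genes)])
    fits["pc1_variance_pct"] = float(100 * pca[0])
    io_formats.write_table(profiles, outdir / "line_profiles.tsv")
    io_formats.write_table(gap_table, outdir / "gap_statistic.tsv")
    (outdir / "fits.yaml").write_text(yaml.safe_dump(fits))
    state["profiles"] = profiles
    state["fits"] = fits
    manifest["row_counts"]["line_profiles"] = len(profiles)


def _stage_genes(cfg, thresholds, outdir, state, manifest):
    x_rec = state["ase"][state["ase"]["chrom"].isin(["chrX", "X"])]
    calls = gene_escape.call_gene_escape(x_rec, state["profiles"],
                                         state["gene_models"], thresholds)
    io_formats.write_table(calls, outdir / "gene_escape_calls.tsv")
    state["escape_calls"] = calls
    manifest["row_counts"]["gene_escape_calls"] = len(calls)


def _stage_de(cfg, thresholds, outdir, state, manifest):
    meta = state["meta"]
    profiles = state["profiles"]
    logcpm = state["logcpm"]
    males = meta.loc[meta["sex"] == "male", "line_id"].tolist()
    de_tables = {}
    for g in (1, 2, 3):
        fem = profiles.loc[profiles["erosion_group"] == g, "line_id"]
        fem = [l for l in fem if l in logcpm.columns]
        if len(fem) < 3:
            continue
        tab = diffexpr.de_two_group(logcpm, meta, fem, males,
                                    contrast=(f"group{g}", "male"))
        de_tables[f"group{g}_vs_male"] = tab
        io_formats.write_table(tab, outdir / f"de_group{g}_vs_male.tsv")
    if len(de_tables) >= 2:
        io_formats.write_table(diffexpr.overlap_summary(de_tables),
                               outdir / "de_overlap_summary.tsv")
    state["de_tables"] = de_tables
    manifest["row_counts"]["de_contrasts"] = len(de_tables)


def _stage_enrich(cfg, thresholds, outdir, state, manifest):
    annotations = state.get("annotations", {})
    gene_models = state["gene_models"]
    results = []
    for name, tab in state.get("de_tables", {}).items():
        universe = tab.loc[tab["p"].notna(), "gene_id"].tolist()
        for direction, mask in (
                ("female_biased", (tab["q"] < 0.05) & (tab["log2fc"] > 0)),
                ("male_biased", (tab["q"] < 0.05) & (tab["log2fc"] < 0))):
            de_set = set(tab.loc[mask, "gene_id"])
            if not de_set:
                continue
            for ann_name, ann in annotations.items():
                if isinstance(ann, pd.DataFrame):
                    genes = enrichment.intervals_to_genes(
                        ann, gene_models,
                        mode=enrichment.PROMOTER_3000_BODY)
                else:
                    genes = set(ann)
                if not genes & set(universe):
                    continue
                results.append(enrichment.test_gene_set(
                    genes, de_set, universe,
                    annotation_name=f"{name}:{direction}:{ann_name}",
                    n_permutations=cfg.n_permutations, seed=cfg.seed))
    tab = enrichment.results_table(results)
    io_formats.write_table(tab, outdir / "enrichment_results.tsv")
    state["enrichment"] = tab
    manifest["row_counts"]["enrichment_results"] = len(tab)
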