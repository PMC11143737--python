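"""Synthetic cohorts with the statistical structure of clonal-Xi iPSC lines.

The generator emulates the *derived* tables of a bulk RNA-seq ASE study
of X-chromosome inactivation (XCI) erosion, not raw reads:

* each female line carries a latent erosion level ``e`` drawn from one
  of three group-specific ranges;
* XIST expression (log2 CPM) decays as a decreasing logistic in ``e``;
* each X gene belongs to a class (PAR / escape / variable / inactive)
  with a baseline inactive-X expression fraction ``f_g``, and its
  per-line Xi fraction is ``f_gl = min(0.5, f_g + s_class * e)``;
* allelic counts at heterozygous sites are binomial draws of depth
  sampled from a zero-truncated negative binomial, with the minor
  haplotype assigned to ref/alt at random (unphased input);
* gene expression counts are negative binomial with planted sex-biased
  autosomal effects and an XIST-bound autosomal gene set whose
  male-biased fold change decays with erosion.

Default cohort sizes mirror the study design (117 males; 74/45/46
females per erosion group); gene counts are scaled to desk size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats

X_CLASSES = ("par", "escape", "variable", "inactive")


@dataclass
class SimConfig:
    """Generative parameters of the synthetic cohort."""

    n_males: int = 117
    n_females_per_group: tuple[int, int, int] = (74, 45, 46)
    n_x_genes: int = 120          # excluding XIST, which is always added
    n_auto_genes: int = 400
    n_par: int = 8
    n_escape: int = 20
    n_variable: int = 22
    # latent erosion ranges for female groups 1..3
    erosion_range_per_group: tuple[tuple[float, float], ...] = (
        (0.0, 0.1), (0.25, 0.5), (0.45, 0.8))
    # XIST log2CPM = max / (1 + exp(steepness * (e - inflection))) + noise
    xist_curve: tuple[float, float, float] = (10.0, 0.40, 14.0)
    xist_noise_sd: float = 0.4
    # Beta(a, b) for the baseline Xi fraction f_g per class
    base_xi_fraction: dict = field(default_factory=lambda: {
        "escape": (4.0, 16.0), "variable": (2.0, 30.0)})
    # erosion response scale s_class
    susceptibility: dict = field(default_factory=lambda: {
        "par": 0.0, "escape": 0.5, "variable": 0.5, "inactive": 0.2})
    mean_depth: float = 80.0
    depth_dispersion: float = 5.0      # NB size parameter for depth
    het_prob: float = 0.7              # P(gene informative in a line)
    extra_variants_mean: float = 1.0   # n_variants = 1 + Poisson(this)
    ref_bias: float = 0.0              # shift of read prob toward reference
    exact_fractions: bool = False      # depth -> infinity switch (no noise)
    expr_baseline: float = 150.0       # mean counts per gene
    expr_dispersion: float = 10.0      # NB size parameter for expression
    n_sex_biased_auto: int = 40
    sex_effect_sizes: tuple[float, ...] = (0.5, 1.0)   # |log2FC| magnitudes
    xist_bound_frac: float = 0.10
    xist_bound_lfc: float = 0.3        # male-biased log2FC at e = 0
    xist_het_prob: float = 0.5         # P(XIST has a usable het variant)
    xist_trace_ase: float = 0.01       # trace minor fraction of XIST
    n_auto_ase_genes: int = 40         # autosomal genes with allelic counts
    seed: int = 0

    def validate(self) -> None:
        if self.n_par + self.n_escape + self.n_variable > self.n_x_genes:
            raise ValueError("n_par + n_escape + n_variable exceeds "
                             "n_x_genes")
        los = [lo for lo, _ in self.erosion_range_per_group]
        if sorted(los) != list(los):
            raise ValueError("group erosion lower bounds must be ordered")
        for lo, hi in self.erosion_range_per_group:
            if not (0 <= lo <= hi <= 1):
                raise ValueError("erosion ranges must lie in [0, 1]")
        for p in (self.het_prob, self.xist_het_prob, self.xist_bound_frac):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    lines: pd.DataFrame        # line_id, sex, erosion, true_group
    genes: pd.DataFrame        # gene_id, x_class, base_fraction, sex_lfc,
                               # xist_bound
    f_gl: pd.DataFrame         # X genes x female lines true Xi fraction
    de_genes: pd.DataFrame     # planted sex-biased genes with true log2FC


@dataclass
class SimCohort:
    allelic_counts: pd.DataFrame
    expr_counts: pd.DataFrame
    gene_models: pd.DataFrame
    meta: pd.DataFrame
    annotations: dict
    truth: SimTruth
    config: SimConfig


def _truncated_nb(rng, mean, size_param, n):
    """Zero-truncated negative binomial draws (depth >= 1)."""
    p = size_param / (size_param + mean)
    out = rng.negative_binomial(size_param, p, size=n)
    zero = out == 0
    while zero.any():
        out[zero] = rng.negative_binomial(size_param, p, size=int(zero.sum()))
        zero = out == 0
    return out


def _make_gene_models(cfg: SimConfig, rng) -> tuple[pd.DataFrame, pd.Series]:
    """Gene table plus per-gene X class assignment."""
    rows = []
    classes = {}
    n_inactive = cfg.n_x_genes - cfg.n_par - cfg.n_escape - cfg.n_variable
    class_list = (["par"] * cfg.n_par + ["escape"] * cfg.n_escape
                  + ["variable"] * cfg.n_variable + ["inactive"] * n_inactive)
    # PAR genes sit at the chromosome tip; the rest are interleaved so
    # escape/variable/inactive genes are spread along the chromosome
    body = class_list[cfg.n_par:]
    rng.shuffle(body)
    class_list = class_list[:cfg.n_par] + body
    pos = 100_000
    for i, x_class in enumerate(class_list):
        gid = f"geneX{i + 1:03d}"
        length = int(rng.integers(2_000, 20_000))
        start = pos
        end = pos + length
        strand = "+" if rng.random() < 0.5 else "-"
        status = {"par": "escape", "escape": "escape",
                  "variable": "variable", "inactive": "inactive"}[x_class]
        rows.append((gid, "chrX", strand,
                     start if strand == "+" else end, start, end,
                     x_class == "par", status))
        classes[gid] = x_class
        pos = end + int(rng.integers(30_000, 80_000))
    # XIST
    length = int(rng.integers(15_000, 30_000))
    rows.append(("XIST", "chrX", "-", pos + length, pos, pos + length,
                 False, "escape"))
    classes["XIST"] = "xist"
    pos += length + 50_000
    for i in range(cfg.n_auto_genes):
        gid = f"geneA{i + 1:03d}"
        chrom = f"chr{(i % 22) + 1}"
        start = 100_000 + (i // 22) * 60_000
        end = start + int(rng.integers(2_000, 20_000))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((gid, chrom, strand,
                     start if strand == "+" else end, start, end,
                     False, "unknown"))
        classes[gid] = "autosomal"
    gm = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss",
                                     "start", "end", "is_par",
                                     "human_escape_status"])
    return gm, pd.Series(classes, name="x_class")


def xist_log2cpm_curve(erosion, curve):
    """Deterministic part of the XIST expression model."""
    max_l2, e0, steep = curve
    erosion = np.asarray(erosion, dtype=float)
    return max_l2 / (1.0 + np.exp(steep * (erosion - e0)))


def simulate_cohort(config: SimConfig | None = None,
                    seed: int | None = None) -> SimCohort:
    """Generate a full synthetic cohort (counts, expression, truth).

    `seed` overrides ``config.seed``; a fixed seed gives bit-identical
    output.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    gene_models, classes = _make_gene_models(cfg, rng)

    # --- lines -----------------------------------------------------------
    male_ids = [f"male{i + 1:03d}" for i in range(cfg.n_males)]
    female_ids, erosions, groups = [], [], []
    k = 0
    for g, (n_g, (lo, hi)) in enumerate(
            zip(cfg.n_females_per_group, cfg.erosion_range_per_group),
            start=1):
        for _ in range(n_g):
            k += 1
            female_ids.append(f"fem{k:03d}")
            erosions.append(float(rng.uniform(lo, hi)))
            groups.append(g)
    erosions = np.array(erosions)
    all_ids = male_ids + female_ids
    # one donor per line except a minority of donors with 2 lines,
    # mimicking replicate lines per donor
    donor_of = {}
    i_donor = 0
    for j, lid in enumerate(all_ids):
        if j % 7 == 6:      # every 7th line shares the previous donor
            donor_of[lid] = f"donor{i_donor:03d}"
        else:
            i_donor += 1
            donor_of[lid] = f"donor{i_donor:03d}"
    meta = pd.DataFrame({
        "line_id": all_ids,
        "donor_id": [donor_of[l] for l in all_ids],
        "sex": ["male"] * cfg.n_males + ["female"] * len(female_ids),
    })

    lines_truth = pd.DataFrame({
        "line_id": all_ids,
        "sex": meta["sex"],
        "erosion": [0.0] * cfg.n_males + list(erosions),
        "true_group": [0] * cfg.n_males + groups,
    })

    # --- per-gene baseline Xi fractions and susceptibilities -------------
    x_genes = gene_models.loc[(gene_models["chrom"] == "chrX")
                              & (gene_models["gene_id"] != "XIST"),
                              "gene_id"].tolist()
    base_f = {}
    for gid in x_genes:
        cls = classes[gid]
        if cls == "par":
            base_f[gid] = 0.5
        elif cls in cfg.base_xi_fraction:
            a, b = cfg.base_xi_fraction[cls]
            base_f[gid] = float(rng.beta(a, b))
        else:
            base_f[gid] = 0.0
    # true Xi fraction per X gene x female line
    s = np.array([cfg.susceptibility[classes[g]] for g in x_genes])
    f0 = np.array([base_f[g] for g in x_genes])
    f_gl = np.minimum(0.5, f0[:, None] + s[:, None] * erosions[None, :])
    f_gl[np.array([classes[g] == "par" for g in x_genes]), :] = 0.5
    f_gl_df = pd.DataFrame(f_gl, index=x_genes, columns=female_ids)

    # --- allelic counts --------------------------------------------------
    spans = {r.gene_id: (r.start, r.end)
             for r in gene_models.itertuples(index=False)}
    rows = []

    def _emit_variants(line_id, gid, frac):
        n_var = 1 + int(rng.poisson(cfg.extra_variants_mean))
        start, end = spans[gid]
        positions = np.sort(rng.integers(start, end + 1, size=n_var))
        totals = _truncated_nb(rng, cfg.mean_depth, cfg.depth_dispersion,
                               n_var)
        for pos_v, tot in zip(positions, totals):
            if cfg.exact_fractions:
                minor = int(round(tot * frac))
            else:
                minor = int(rng.binomial(tot, frac))
            minor_is_ref = rng.random() < 0.5
            p_ref = frac if minor_is_ref else 1.0 - frac
            p_ref = min(1.0, max(0.0, p_ref + cfg.ref_bias))
            if cfg.exact_fractions:
                ref = minor if minor_is_ref else int(tot) - minor
            else:
                ref = int(rng.binomial(tot, p_ref))
            alt = int(tot) - ref
            rows.append((line_id, "", int(pos_v), ref, alt, int(tot), gid))

    chrom_of = gene_models.set_index("gene_id")["chrom"]
    # X genes in female lines
    for j, lid in enumerate(female_ids):
        for i, gid in enumerate(x_genes):
            if rng.random() < cfg.het_prob:
                _emit_variants(lid, gid, f_gl[i, j])
        # XIST: monoallelic trace from the inactive X
        if rng.random() < cfg.xist_het_prob:
            _emit_variants(lid, "XIST", cfg.xist_trace_ase)
    # PAR genes in male lines (X/Y shared, diploid-like)
    par_genes = [g for g in x_genes if classes[g] == "par"]
    for lid in male_ids:
        for gid in par_genes:
            if rng.random() < cfg.het_prob:
                _emit_variants(lid, gid, 0.5)
    # balanced autosomal genes in all lines
    auto_ase_genes = gene_models.loc[
        gene_models["chrom"] != "chrX", "gene_id"].tolist()
    auto_ase_genes = auto_ase_genes[:cfg.n_auto_ase_genes]
    for lid in all_ids:
        for gid in auto_ase_genes:
            if rng.random() < cfg.het_prob:
                _emit_variants(lid, gid, 0.5)
    allelic = pd.DataFrame(rows, columns=io_formats.VARIANT_COLUMNS)
    allelic["contig"] = allelic["gene_id"].map(chrom_of)

    # --- expression matrix ----------------------------------------------
    gene_ids = gene_models["gene_id"].tolist()
    n_genes, n_lines = len(gene_ids), len(all_ids)
    base = rng.lognormal(mean=np.log(cfg.expr_baseline), sigma=1.0,
                         size=n_genes)
    mean_mat = np.tile(base[:, None], (1, n_lines))
    is_female = np.array([s == "female" for s in meta["sex"]])
    gi = {g: i for i, g in enumerate(gene_ids)}
    li = {l: j for j, l in enumerate(all_ids)}

    # X dosage: females express Xa plus the Xi fraction
    x_rows = np.array([gi[g] for g in x_genes])
    fem_cols = np.array([li[l] for l in female_ids])
    mean_mat[np.ix_(x_rows, fem_cols)] = \
        base[x_rows][:, None] * (1.0 + f_gl)
    # planted sex-biased autosomal genes
    auto_genes = [g for g in gene_ids if classes[g] == "autosomal"]
    n_xb = int(round(cfg.xist_bound_frac * len(auto_genes)))
    xb_genes = list(rng.choice(auto_genes, size=n_xb, replace=False))
    remaining = [g for g in auto_genes if g not in set(xb_genes)]
    de_genes = list(rng.choice(remaining, size=cfg.n_sex_biased_auto,
                               replace=False))
    de_rows = []
    for idx, gid in enumerate(de_genes):
        mag = cfg.sex_effect_sizes[idx % len(cfg.sex_effect_sizes)]
        lfc = mag if idx % 2 == 0 else -mag     # female-vs-male log2FC
        mean_mat[gi[gid], is_female] *= 2.0 ** lfc
        de_rows.append((gid, lfc))
    # XIST-bound autosomal genes: male-biased effect decaying with erosion
    for gid in xb_genes:
        for lid, e in zip(female_ids, erosions):
            mean_mat[gi[gid], li[lid]] *= 2.0 ** (
                -cfg.xist_bound_lfc * (1.0 - e))

    # XIST expression follows the logistic erosion curve
    lib_target = float(base.sum())
    xist_l2 = (xist_log2cpm_curve(erosions, cfg.xist_curve)
               + rng.normal(0.0, cfg.xist_noise_sd, size=len(erosions)))
    xist_l2 = np.clip(xist_l2, 0.0, None)
    for lid, l2 in zip(female_ids, xist_l2):
        mean_mat[gi["XIST"], li[lid]] = max(
            0.05, (2.0 ** l2 - 0.5) * lib_target / 1e6)
    for lid in male_ids:
        mean_mat[gi["XIST"], li[lid]] = 0.05

    p = cfg.expr_dispersion / (cfg.expr_dispersion + mean_mat)
    counts = rng.negative_binomial(cfg.expr_dispersion, p)
    expr = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                        columns=all_ids)

    genes_truth = pd.DataFrame({
        "gene_id": gene_ids,
        "x_class": [classes[g] for g in gene_ids],
        "base_fraction": [base_f.get(g, np.nan) for g in gene_ids],
        "sex_lfc": [dict(de_rows).get(g, 0.0) for g in gene_ids],
        "xist_bound": [g in set(xb_genes) for g in gene_ids],
    })
    truth = SimTruth(
        lines=lines_truth,
        genes=genes_truth,
        f_gl=f_gl_df,
        de_genes=pd.DataFrame(de_rows, columns=["gene_id", "log2fc"]),
    )
    cohort = SimCohort(
        allelic_counts=allelic, expr_counts=expr, gene_models=gene_models,
        meta=meta, annotations={}, truth=truth, config=cfg)
    cohort.annotations = simulate_annotations(cfg, cohort, rng)
    return cohort


def simulate_annotations(cfg: SimConfig, cohort: SimCohort, rng=None) -> dict:
    """Annotation sets consistent with the cohort's ground truth.

    Returns a dict with five disjoint methylation-transition gene sets
    (ordered from erosion-prone to erosion-resistant X genes), histone
    mark interval tables over the promoters of de-repressible genes,
    and the XIST-bound autosomal gene set.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    genes = cohort.truth.genes
    x = genes[genes["x_class"].isin(["escape", "variable", "inactive"])]
    # order X genes by how readily they de-repress; earliest methylation
    # transitions hit the most erosion-prone genes
    suscept = x["x_class"].map(cfg.susceptibility)
    order = x.assign(_s=suscept + x["base_fraction"].fillna(0)) \
             .sort_values("_s", ascending=False)["gene_id"].tolist()
    n_per = max(1, len(order) // 5)
    transitions = {f"methylation_transition_{t + 1}":
                   set(order[t * n_per:(t + 1) * n_per]) for t in range(5)}

    derepressible = genes.loc[
        genes["x_class"].isin(["escape", "variable"]), "gene_id"]
    gm = cohort.gene_models.set_index("gene_id")
    rows = []
    for gid in derepressible:
        tss = int(gm.loc[gid, "tss"])
        rows.append(("chrX", max(1, tss - 100), tss + 100, f"peak_{gid}"))
    histone = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    n_xb = int(genes["xist_bound"].sum())
    xist_bound = set(genes.loc[genes["xist_bound"], "gene_id"]) \
        if n_xb else set()
    return {**transitions,
            "h3k27me3_xaxi": histone,
            "xist_bound_autosomal": xist_bound}


def write_cohort(cohort: SimCohort, outdir) -> dict:
    """Write every table in the formats the readers consume.

    Returns a dict of output paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["allelic_counts"] = outdir / "allelic_counts.tsv"
    io_formats.write_table(cohort.allelic_counts, paths["allelic_counts"])
    paths["gene_counts"] = outdir / "gene_counts.tsv"
    io_formats.write_table(cohort.expr_counts, paths["gene_counts"],
                           index=True)
    paths["gene_models"] = outdir / "gene_models.tsv"
    io_formats.write_table(cohort.gene_models, paths["gene_models"])
    paths["sample_meta"] = outdir / "sample_meta.tsv"
    io_formats.write_table(cohort.meta, paths["sample_meta"])
    for name, ann in cohort.annotations.items():
        if isinstance(ann, pd.DataFrame):
            paths[name] = outdir / f"{name}.bed"
            io_formats.write_intervals_bed(ann, paths[name])
        else:
            paths[name] = outdir / f"{name}.txt"
            io_formats.write_gene_list(sorted(ann), paths[name])
    return paths
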