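"""Gene-level allele-specific expression from variant allelic counts.

The ASE of a gene in a line is the fraction of reads mapping to the
minor alleles of its heterozygous variants:

    ASE = sum_v min(ref_v, alt_v) / sum_v (ref_v + alt_v)   in [0, 0.5]

with 0 meaning monoallelic and 0.5 balanced bi-allelic expression.
Minor alleles are assumed to lie on the same haplotype (the silenced X
in a clonal-Xi line), so no phasing is required.  Before aggregation,
variants under the read-depth floor are removed and variants closer
than one read length are collapsed so that a read pair spanning two
variants is not double counted.

Bi-allelic expression is called per gene x line with a one-sided exact
binomial test against a null allelic fraction of 0.1, followed by
Benjamini-Hochberg correction; XIST clonality is tested with a stricter
lower-tail test against 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .thresholds import Thresholds

XIST_GENE = "XIST"


def filter_variants(variants: pd.DataFrame,
                    thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Keep variants with total depth >= ``min_variant_reads`` (default 20)."""
    thresholds = thresholds or Thresholds()
    out = variants[variants["total_count"] >= thresholds.min_variant_reads]
    return out.reset_index(drop=True)


def collapse_linked_variants(positions: np.ndarray, totals: np.ndarray,
                             gap_bp: int = 100,
                             method: str = "chain") -> np.ndarray:
    """Indices of variants retained after collapsing read-length-linked sites.

    Variants of one gene in one line are chained into clusters wherever
    the gap between consecutive positions is < `gap_bp` (one read
    length); from each cluster only the variant with the largest total
    count survives (ties: smaller position).

    Parameters
    ----------
    positions, totals
        Same-length arrays for one gene in one line; need not be sorted.
    method
        ``chain`` (single-linkage on consecutive gaps, default) or
        ``greedy`` (scan in genomic order, compare each variant with the
        last *retained* one).

    Returns
    -------
    Integer indices into the input arrays, in position order.
    """
    positions = np.asarray(positions)
    totals = np.asarray(totals)
    if positions.size == 0:
        return np.array([], dtype=int)
    order = np.argsort(positions, kind="stable")
    pos = positions[order]
    tot = totals[order]

    if method == "chain":
        # cluster breaks where the consecutive gap reaches gap_bp
        breaks = np.flatnonzero(np.diff(pos) >= gap_bp) + 1
        kept = []
        for cluster in np.split(np.arange(pos.size), breaks):
            best = cluster[np.argmax(tot[cluster])]  # argmax -> first max,
            kept.append(best)                        # i.e. smaller position
        return order[np.array(kept, dtype=int)]
    elif method == "greedy":
        kept = [0]
        for i in range(1, pos.size):
            if pos[i] - pos[kept[-1]] < gap_bp:
                if tot[i] > tot[kept[-1]]:
                    kept[-1] = i
            else:
                kept.append(i)
        return order[np.array(kept, dtype=int)]
    raise ValueError(f"unknown collapse method {method!r}")


def compute_gene_ase(variants: pd.DataFrame) -> pd.DataFrame:
    """Aggregate retained variants to per gene x line minor-allele ASE.

    Returns one row per (gene_id, line_id) with ``minor_reads``,
    ``total_reads``, ``ase`` and ``n_variants_used``.  The denominator is
    ref + alt (a two-allele fraction); reads on other alleles are
    excluded.
    """
    df = variants.copy()
    df["minor"] = np.minimum(df["ref_count"], df["alt_count"])
    df["both"] = df["ref_count"] + df["alt_count"]
    grouped = df.groupby(["gene_id", "line_id"], sort=True).agg(
        minor_reads=("minor", "sum"),
        total_reads=("both", "sum"),
        n_variants_used=("both", "size"),
    ).reset_index()
    grouped["ase"] = grouped["minor_reads"] / grouped["total_reads"]
    return grouped


def test_biallelic(minor: int, total: int, p0: float = 0.1) -> float:
    """One-sided exact binomial p-value for ASE > `p0`.

    Upper tail: P(X >= minor | n=total, p=p0).
    """
    if not 0 <= minor <= total or total < 1:
        raise ValueError("need 0 <= minor <= total, total >= 1")
    return float(stats.binom.sf(minor - 1, total, p0))


def call_biallelic_matrix(records: pd.DataFrame,
                          thresholds: Thresholds | None = None,
                          bh_family: str = "global") -> pd.DataFrame:
    """Attach bi-allelic p/q-values and calls to a gene ASE table.

    The one-sided binomial p-values (alternative ASE > ``biallelic_ase``)
    are BH-adjusted either jointly over all gene x line tests
    (``bh_family='global'``, default) or within each line
    (``'per-line'``); a test is called bi-allelic when
    q < ``biallelic_fdr_q``.
    """
    thresholds = thresholds or Thresholds()
    out = records.copy()
    out["biallelic_p"] = stats.binom.sf(
        out["minor_reads"].to_numpy() - 1,
        out["total_reads"].to_numpy(),
        thresholds.biallelic_ase)
    if bh_family == "global":
        out["biallelic_q"] = multipletests(
            out["biallelic_p"], method="fdr_bh")[1]
    elif bh_family == "per-line":
        out["biallelic_q"] = (
            out.groupby("line_id")["biallelic_p"]
               .transform(lambda p: multipletests(p, method="fdr_bh")[1]))
    else:
        raise ValueError(f"unknown bh_family {bh_family!r}")
    out["is_biallelic"] = out["biallelic_q"] < thresholds.biallelic_fdr_q
    return out


def xist_clonality_call(minor: int | None, total: int | None,
                        thresholds: Thresholds | None = None
                        ) -> tuple[str, float]:
    """Classify XIST allelic expression for one line.

    Tests the null ASE >= 0.05 with a one-sided lower-tail exact
    binomial test; rejection means XIST is monoallelic, consistent with
    a clonal Xi.  Returns ``(call, p)`` where call is ``monoallelic``,
    ``biallelic_trace`` or ``undefined`` (no counts; p is NaN).
    """
    thresholds = thresholds or Thresholds()
    if minor is None or total is None or total < 1:
        return "undefined", float("nan")
    p = float(stats.binom.cdf(minor, total, thresholds.xist_mono_ase))
    call = "monoallelic" if p < thresholds.xist_mono_alpha else \
        "biallelic_trace"
    return call, p


def reference_allele_fraction(variants: pd.DataFrame,
                              by: str | list[str] | None = None,
                              alpha: float = 0.05) -> pd.DataFrame:
    """QC diagnostic: pooled fraction of reads on the reference allele.

    Without SNP-aware realignment, mapping favours the reference allele;
    a pooled fraction above 0.5 quantifies that bias.  Returns one row
    per group (or one overall row) with a Wilson binomial CI.
    """
    df = variants.copy()
    if by is None:
        df["_all"] = "all"
        by = "_all"
    rows = []
    for key, grp in df.groupby(by, sort=True):
        ref = int(grp["ref_count"].sum())
        both = int((grp["ref_count"] + grp["alt_count"]).sum())
        frac = ref / both if both else float("nan")
        lo, hi = proportion_confint(ref, both, alpha=alpha, method="wilson") \
            if both else (float("nan"), float("nan"))
        rows.append({"group": key, "ref_reads": ref, "both_reads": both,
                     "ref_fraction": frac, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def run_ase_pipeline(variants: pd.DataFrame, gene_models: pd.DataFrame,
                     thresholds: Thresholds | None = None,
                     bh_family: str = "global",
                     collapse_method: str = "chain",
                     x_only_bh: bool = True) -> pd.DataFrame:
    """Full variant -> gene ASE -> bi-allelic call pipeline.

    Steps: assign gene chromosome, drop variants below the depth floor,
    collapse linked variants per gene x line, aggregate to minor-allele
    ASE, then test/call bi-allelic expression.  BH is applied over
    X-chromosome gene x line tests (autosomal records keep raw p-values
    and NA calls) unless `x_only_bh` is False.
    """
    thresholds = thresholds or Thresholds()
    if variants["gene_id"].isna().any():
        raise ValueError("all variants must carry a gene_id")
    flt = filter_variants(variants, thresholds)
    if collapse_method == "chain" and len(flt):
        # vectorized chaining: cluster breaks where gene/line changes or
        # the consecutive gap reaches the collapse width
        srt = flt.sort_values(["gene_id", "line_id", "position"],
                              kind="stable")
        new_cluster = ((srt["gene_id"] != srt["gene_id"].shift())
                       | (srt["line_id"] != srt["line_id"].shift())
                       | (srt["position"].diff()
                          >= thresholds.collapse_gap_bp))
        srt = srt.assign(_cluster=new_cluster.cumsum())
        kept = (srt.sort_values(["_cluster", "total_count", "position"],
                                ascending=[True, False, True],
                                kind="stable")
                .drop_duplicates("_cluster").drop(columns="_cluster"))
        kept_parts = [kept]
    else:
        kept_parts = []
        for _, grp in flt.groupby(["gene_id", "line_id"], sort=False):
            idx = collapse_linked_variants(
                grp["position"].to_numpy(), grp["total_count"].to_numpy(),
                gap_bp=thresholds.collapse_gap_bp, method=collapse_method)
            kept_parts.append(grp.iloc[idx])
    if not kept_parts:
        cols = ["gene_id", "line_id", "minor_reads", "total_reads",
                "n_variants_used", "ase", "biallelic_p", "biallelic_q",
                "is_biallelic", "chrom"]
        return pd.DataFrame(columns=cols)
    kept = pd.concat(kept_parts, ignore_index=True)
    records = compute_gene_ase(kept)
    chrom_map = gene_models.set_index("gene_id")["chrom"]
    records["chrom"] = records["gene_id"].map(chrom_map)
    if x_only_bh:
        is_x = records["chrom"].isin(["chrX", "X"])
        x_rec = call_biallelic_matrix(records[is_x], thresholds, bh_family)
        a_rec = records[~is_x].copy()
        a_rec["biallelic_p"] = stats.binom.sf(
            a_rec["minor_reads"].to_numpy() - 1,
            a_rec["total_reads"].to_numpy(), thresholds.biallelic_ase)
        a_rec["biallelic_q"] = np.nan
        a_rec["is_biallelic"] = pd.NA
        records = pd.concat([x_rec, a_rec], ignore_index=True)
        records = records.sort_values(["gene_id", "line_id"],
                                      ignore_index=True)
    else:
        records = call_biallelic_matrix(records, thresholds, bh_family)
    return records
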