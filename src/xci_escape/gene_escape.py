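"""Gene-wise escape classification and low- vs high-XIST contrasts.

A gene eligible in both XIST groups (>= 10 informative lines each) is
classed by how often it is called bi-allelic across informative lines:
``biallelic`` (> 80% of lines), ``monoallelic`` (no line), otherwise
``variably_biallelic``.  Per gene, de-repression in low-XIST lines is
tested with a one-sided Fisher exact test on the 2x2 bi-allelic x group
table, and the ASE shift with a one-sided Wilcoxon rank-sum test.  The
resulting class proportions are compared with human tissue escape
categories by a chi-squared test of equal proportions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ase_core import XIST_GENE
from .thresholds import Thresholds

GENE_CLASSES = ("biallelic", "variably_biallelic", "monoallelic")


def eligible_genes(ase_records: pd.DataFrame, profiles: pd.DataFrame,
                   thresholds: Thresholds | None = None) -> list[str]:
    """Genes with >= ``min_lines_per_group`` informative lines in each of
    the low- and high-XIST female groups."""
    thresholds = thresholds or Thresholds()
    xist_class = profiles.set_index("line_id")["xist_class"]
    rec = ase_records.copy()
    rec["xist_class"] = rec["line_id"].map(xist_class)
    rec = rec[rec["xist_class"].isin(["low", "high"])]
    counts = (rec.groupby(["gene_id", "xist_class"], observed=True)
              .size().unstack(fill_value=0)
              .reindex(columns=["low", "high"], fill_value=0))
    ok = (counts["low"] >= thresholds.min_lines_per_group) & \
         (counts["high"] >= thresholds.min_lines_per_group)
    return sorted(counts.index[ok])


def classify_gene(is_biallelic: pd.Series | np.ndarray,
                  thresholds: Thresholds | None = None) -> str:
    """Class of one gene from its per-line bi-allelic calls."""
    thresholds = thresholds or Thresholds()
    calls = np.asarray(is_biallelic, dtype=bool)
    if calls.size == 0:
        raise ValueError("no informative lines")
    n_bi = int(calls.sum())
    if n_bi == 0:
        return "monoallelic"
    if n_bi / calls.size > thresholds.biallelic_gene_line_frac:
        return "biallelic"
    return "variably_biallelic"


def fisher_derepression(n_biallelic_low: int, n_lines_low: int,
                        n_biallelic_high: int, n_lines_high: int) -> float:
    """One-sided Fisher exact p for enrichment of bi-allelic lines in the
    low-XIST group (2x2: bi-allelic yes/no x low/high)."""
    table = [[n_biallelic_low, n_lines_low - n_biallelic_low],
             [n_biallelic_high, n_lines_high - n_biallelic_high]]
    if min(n_lines_low, n_lines_high) == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="greater")[1])


def wilcoxon_ase_shift(ase_low, ase_high,
                       min_n: int = 1) -> float:
    """One-sided Wilcoxon rank-sum p that ASE is higher in low-XIST lines.

    Exact when both groups have n <= 50 and there are no ties; the
    tie-corrected normal approximation (with continuity correction)
    otherwise.
    """
    low = np.asarray(ase_low, dtype=float)
    high = np.asarray(ase_high, dtype=float)
    if low.size < min_n or high.size < min_n:
        raise ValueError(f"need >= {min_n} values per group")
    exact = (low.size <= 50 and high.size <= 50
             and np.unique(np.concatenate([low, high])).size
             == low.size + high.size)
    res = stats.mannwhitneyu(low, high, alternative="greater",
                             method="exact" if exact else "asymptotic")
    return float(res.pvalue)


def human_concordance_chi2(hipsc_counts, human_counts
                           ) -> tuple[float, float, pd.DataFrame]:
    """Chi-squared test of equal class proportions, hiPSC vs human.

    Both inputs are 3-vectors of gene counts over the matching
    categories (bi-allelic/escape, variably bi-allelic/variable,
    monoallelic/inactive).  Returns ``(statistic, p, proportions)``.
    """
    obs = np.asarray([list(hipsc_counts), list(human_counts)], dtype=float)
    if (obs.sum(axis=1) == 0).any():
        raise ValueError("a group has zero total genes")
    stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
    props = pd.DataFrame(obs / obs.sum(axis=1, keepdims=True),
                         index=["hipsc", "human"],
                         columns=["biallelic_or_escape",
                                  "variable", "monoallelic_or_inactive"])
    return float(stat), float(p), props


def call_gene_escape(ase_records: pd.DataFrame, profiles: pd.DataFrame,
                     gene_models: pd.DataFrame,
                     thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Build the per-gene escape call table over eligible genes.

    One row per eligible X gene with line counts, class, the one-sided
    Fisher de-repression p, the one-sided Wilcoxon ASE-shift p, the
    low-minus-high median ASE difference, and the human tissue escape
    status.
    """
    thresholds = thresholds or Thresholds()
    xist_class = profiles.set_index("line_id")["xist_class"]
    human = gene_models.set_index("gene_id")["human_escape_status"]
    is_par = gene_models.set_index("gene_id")["is_par"]
    rec = ase_records.copy()
    rec["xist_class"] = rec["line_id"].map(xist_class)
    rec = rec[rec["xist_class"].isin(["low", "high"])
              & rec["is_biallelic"].notna()]
    rows = []
    # eligibility over records with calls (X genes in the BH family)
    for gid in eligible_genes(rec, profiles, thresholds):
        sub = rec[rec["gene_id"] == gid]
        low = sub[sub["xist_class"] == "low"]
        high = sub[sub["xist_class"] == "high"]
        n_bi_low = int(low["is_biallelic"].sum())
        n_bi_high = int(high["is_biallelic"].sum())
        rows.append({
            "gene_id": gid,
            "n_lines_low": len(low),
            "n_lines_high": len(high),
            "n_biallelic_low": n_bi_low,
            "n_biallelic_high": n_bi_high,
            "gene_class": classify_gene(
                sub["is_biallelic"].astype(bool), thresholds),
            "fisher_p": fisher_derepression(n_bi_low, len(low),
                                            n_bi_high, len(high)),
            "wilcoxon_p": wilcoxon_ase_shift(low["ase"], high["ase"]),
            "median_ase_diff": float(low["ase"].median()
                                     - high["ase"].median()),
            "human_escape_status": human.get(gid, "unknown"),
            "is_par": bool(is_par.get(gid, False)),
        })
    return pd.DataFrame(rows)


def category_biallelic_fractions(escape_calls: pd.DataFrame
                                 ) -> tuple[pd.DataFrame, dict]:
    """Per-gene bi-allelic line fractions grouped by human escape status.

    PAR genes and XIST are excluded.  Returns the per-gene table and
    one-sided Wilcoxon p-values testing that inactive genes have lower
    fractions than escape and than variable genes.
    """
    df = escape_calls[(~escape_calls["is_par"])
                      & (escape_calls["gene_id"] != XIST_GENE)
                      & escape_calls["human_escape_status"]
                      .isin(["escape", "variable", "inactive"])].copy()
    n_lines = df["n_lines_low"] + df["n_lines_high"]
    n_bi = df["n_biallelic_low"] + df["n_biallelic_high"]
    df["frac_lines_biallelic"] = n_bi / n_lines
    by = {s: df.loc[df["human_escape_status"] == s, "frac_lines_biallelic"]
          .to_numpy() for s in ("escape", "variable", "inactive")}
    pvals = {}
    for other in ("escape", "variable"):
        if by["inactive"].size and by[other].size:
            pvals[f"inactive_lt_{other}"] = float(stats.mannwhitneyu(
                by["inactive"], by[other], alternative="less").pvalue)
        else:
            pvals[f"inactive_lt_{other}"] = float("nan")
    return df, pvals
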