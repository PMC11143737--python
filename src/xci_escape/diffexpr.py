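"""Expression normalization and sex-contrast differential expression.

Counts are filtered (genes with fewer than 10 reads in total removed),
TMM-normalized and converted to log2(CPM + 0.5).  The two-group test
collapses replicate lines of a donor by averaging, then applies a Welch
t-test per gene with Benjamini-Hochberg correction.  This is a
deliberately simple fixed-effects analysis: it preserves the contrast
structure of a donor-aware mixed model while remaining fully
reproducible, and is documented as such in the methods note.

TMM (trimmed mean of M-values) is implemented with the canonical
parameters: reference sample by upper-quartile closeness to the mean,
30% two-sided trim on log-ratios, 5% on average intensity, inverse
delta-method precision weights, factors normalized to geometric mean 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG2_FC_THRESHOLD_DEFAULT = 1.5


def filter_low_counts(counts: pd.DataFrame, min_total: int = 10
                      ) -> pd.DataFrame:
    """Drop genes whose total count across samples is below `min_total`."""
    return counts[counts.sum(axis=1) >= min_total]


def _quantile_factor(counts: np.ndarray, lib: np.ndarray, p: float = 0.75
                     ) -> np.ndarray:
    return np.quantile(counts / lib, p, axis=0)


def tmm_factors(counts: pd.DataFrame, log_ratio_trim: float = 0.30,
                abs_expr_trim: float = 0.05) -> pd.Series:
    """Per-sample TMM scaling factors (geometric mean 1).

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean across samples.  For each sample, gene-wise
    log2 ratios M and average log2 intensities A against the reference
    are double-trimmed (30% on M, 5% on A) and combined with binomial
    delta-method precision weights.
    """
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    f75 = _quantile_factor(y, lib)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    yr, nr = y[:, ref_idx], lib[ref_idx]

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        yj, nj = y[:, j], lib[j]
        ok = (yj > 0) & (yr > 0)
        if not ok.any():
            continue
        m = np.log2((yj[ok] / nj) / (yr[ok] / nr))
        a = 0.5 * np.log2((yj[ok] / nj) * (yr[ok] / nr))
        w = (nj - yj[ok]) / (nj * yj[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        finite = np.isfinite(m) & np.isfinite(a)
        m, a, w = m[finite], a[finite], w[finite]
        n = m.size
        if n == 0:
            continue
        if np.max(np.abs(m)) < 1e-6:     # identical up to depth
            continue
        lo_m = np.floor(n * log_ratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abs_expr_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & \
               (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0:
            continue
        wsum = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        if np.isfinite(wsum):
            factors[j] = 2.0 ** wsum
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log2cpm(counts: pd.DataFrame, factors: pd.Series | None = None,
            prior: float = 0.5) -> pd.DataFrame:
    """log2(CPM + 0.5) on TMM-effective library sizes."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns)
    cpm = counts.div(lib, axis=1) * 1e6
    return np.log2(cpm + prior)


def _collapse_donors(logcpm: pd.DataFrame, meta: pd.DataFrame,
                     lines: list[str]) -> pd.DataFrame:
    """Average replicate lines of one donor into a single column."""
    donor = meta.set_index("line_id")["donor_id"]
    sub = logcpm[lines]
    return sub.T.groupby(sub.columns.map(donor)).mean().T


def de_two_group(logcpm: pd.DataFrame, meta: pd.DataFrame,
                 group_a: list[str], group_b: list[str],
                 contrast: tuple[str, str] = ("A", "B"),
                 q_threshold: float = 0.05) -> pd.DataFrame:
    """Welch-test differential expression between two sets of lines.

    Donor replicates are averaged before testing so each donor
    contributes one observation.  ``log2fc`` is mean(A) - mean(B).
    Genes with zero variance in both groups are flagged with NA
    statistics and excluded from the BH family.
    """
    a = _collapse_donors(logcpm, meta, group_a).to_numpy(dtype=float)
    b = _collapse_donors(logcpm, meta, group_b).to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 3 or n2 < 3:
        raise ValueError("need >= 3 donors per group after collapsing")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = np.full(t.shape, np.nan)
    ok = ~degenerate
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    q = np.full(p.shape, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    # standardized per-group means for reporting
    pooled = np.concatenate([a, b], axis=1)
    mu = pooled.mean(axis=1)
    sd = pooled.std(axis=1, ddof=0)
    sd[sd == 0] = np.nan
    out = pd.DataFrame({
        "gene_id": logcpm.index,
        "contrast_a": contrast[0],
        "contrast_b": contrast[1],
        "log2fc": m1 - m2,
        "se_log2fc": np.where(degenerate, np.nan, se),
        "p": p,
        "q": q,
        "mean_z_a": (m1 - mu) / sd,
        "mean_z_b": (m2 - mu) / sd,
    })
    out["significant"] = out["q"] < q_threshold
    return out


def fc_ci_screen(de_table: pd.DataFrame, gene_list: list[str] | None = None,
                 fc_threshold: float = LOG2_FC_THRESHOLD_DEFAULT,
                 q_threshold: float = 0.05) -> pd.DataFrame:
    """Screen for genes whose |fold change| plausibly reaches `fc_threshold`.

    Keeps significant genes (q < `q_threshold`) whose 95% normal CI of
    |log2fc| covers log2(`fc_threshold`); a de-repression of that size
    can mask a heterozygous loss-of-function effect.  `gene_list`
    restricts the screen (e.g. to disease genes).
    """
    log2_thr = np.log2(fc_threshold)
    df = de_table.copy()
    if gene_list is not None:
        df = df[df["gene_id"].isin(set(gene_list))]
    lo = np.abs(df["log2fc"]) - 1.96 * df["se_log2fc"]
    hi = np.abs(df["log2fc"]) + 1.96 * df["se_log2fc"]
    covers = (lo <= log2_thr) & (hi >= log2_thr)
    reaches = np.abs(df["log2fc"]) >= log2_thr
    keep = (df["q"] < q_threshold) & (covers | reaches)
    return df[keep.fillna(False)].reset_index(drop=True)


def overlap_summary(de_tables: dict[str, pd.DataFrame],
                    q_threshold: float = 0.05) -> pd.DataFrame:
    """Intersection-pattern counts of significant genes across contrasts.

    For every non-empty membership pattern over the given contrasts,
    counts genes split by direction: ``concordant_up`` / ``down`` when
    all member contrasts agree in log2fc sign, else ``discordant``.
    """
    names = list(de_tables)
    sig = {}
    sign = {}
    for name, tab in de_tables.items():
        s = tab[tab["q"] < q_threshold]
        sig[name] = set(s["gene_id"])
        sign[name] = dict(zip(s["gene_id"], np.sign(s["log2fc"])))
    universe = set().union(*sig.values()) if sig else set()
    patterns = {}
    for g in universe:
        members = tuple(n for n in names if g in sig[n])
        signs = {sign[n][g] for n in members}
        if len(signs) == 1:
            direction = "concordant_up" if signs == {1.0} \
                else "concordant_down"
        else:
            direction = "discordant"
        patterns.setdefault((members, direction), 0)
        patterns[(members, direction)] += 1
    rows = [{"contrasts": "&".join(members), "direction": direction,
             "n_genes": n}
            for (members, direction), n in sorted(patterns.items())]
    return pd.DataFrame(rows, columns=["contrasts", "direction", "n_genes"])
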