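"""Per-line XCI summaries and staging of female lines into erosion groups.

A female line is summarized by its XIST expression (log2 CPM) and the
fraction of its informative X genes called bi-allelic.  Lines are
staged by k-means (k chosen with the gap statistic) on the two
standardized features; the erosion trajectory is described with a
LOWESS curve and a three-parameter decreasing logistic (sigmoid) fit of
mean ASE against XIST expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.cluster import KMeans
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .ase_core import XIST_GENE
from .thresholds import Thresholds


@dataclass
class SigmoidFit:
    """Fitted logistic decay of mean ASE with XIST expression.

    ``asymptote`` is the plateau mean ASE at vanishing XIST,
    ``inflection`` the XIST log2CPM of half-decay, and ``slope`` the
    (negative) rate parameter, sign-matched to a decreasing curve.
    """

    asymptote: float
    inflection: float
    slope: float
    residual_se: float
    identifiable: bool = True

    def predict(self, x):
        b = -self.slope
        return self.asymptote / (1.0 + np.exp(b * (np.asarray(x, float)
                                                   - self.inflection)))


def classify_xist_level(xist_log2cpm: float, sex: str = "female",
                        thresholds: Thresholds | None = None) -> str:
    """Classify a line's XIST level as ``low`` or ``high`` (``NA`` for
    males).  Low means strictly below the 1.5 log2(CPM+0.5) threshold."""
    thresholds = thresholds or Thresholds()
    if sex != "female":
        return "NA"
    return "low" if xist_log2cpm < thresholds.low_xist_log2cpm else "high"


def summarize_lines(ase_records: pd.DataFrame, logcpm: pd.DataFrame,
                    meta: pd.DataFrame,
                    thresholds: Thresholds | None = None,
                    include_xist: bool = False) -> pd.DataFrame:
    """Build one LineProfile row per line.

    Parameters
    ----------
    ase_records
        Gene x line ASE table with ``is_biallelic`` calls (X genes).
    logcpm
        log2(CPM+0.5) expression matrix containing XIST.
    meta
        Sample metadata with ``line_id`` and ``sex``.
    include_xist
        Whether XIST itself counts as an informative X gene in the
        per-line summaries (excluded by default).

    Returns
    -------
    DataFrame with xist_log2cpm, xist_class, n_informative_genes,
    frac_biallelic, mean_ase and median_ase per line.
    """
    thresholds = thresholds or Thresholds()
    rec = ase_records
    if not include_xist:
        rec = rec[rec["gene_id"] != XIST_GENE]
    rows = []
    for _, line in meta.iterrows():
        lid = line["line_id"]
        sub = rec[rec["line_id"] == lid]
        xist = float(logcpm.loc[XIST_GENE, lid]) \
            if XIST_GENE in logcpm.index and lid in logcpm.columns \
            else float("nan")
        n_inf = len(sub)
        informative = n_inf > 0
        rows.append({
            "line_id": lid,
            "sex": line["sex"],
            "xist_log2cpm": xist,
            "xist_class": classify_xist_level(xist, line["sex"], thresholds),
            "n_informative_genes": n_inf,
            "frac_biallelic": (sub["is_biallelic"].sum() / n_inf)
            if informative else float("nan"),
            "mean_ase": sub["ase"].mean() if informative else float("nan"),
            "median_ase": sub["ase"].median() if informative
            else float("nan"),
        })
    return pd.DataFrame(rows)


def standardize_features(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-score (XIST log2CPM, frac bi-allelic) over female lines only."""
    fem = profiles[(profiles["sex"] == "female")
                   & profiles["frac_biallelic"].notna()
                   & profiles["xist_log2cpm"].notna()]
    feats = fem[["xist_log2cpm", "frac_biallelic"]].astype(float)
    z = (feats - feats.mean()) / feats.std(ddof=0)
    z.index = fem["line_id"].to_numpy()
    return z


def _within_ss(features: np.ndarray, k: int, seed: int,
               n_restarts: int = 10) -> float:
    km = KMeans(n_clusters=k, n_init=n_restarts,
                random_state=seed).fit(features)
    return float(km.inertia_)


def choose_k_gap(features: pd.DataFrame | np.ndarray, k_max: int = 6,
                 b_ref: int = 100, seed: int = 0) -> tuple[int, pd.DataFrame]:
    """Choose the number of clusters with the gap statistic.

    Gap(k) compares log within-cluster dispersion against `b_ref`
    uniform reference draws over the feature bounding box; the chosen k
    is the smallest k with ``Gap(k) >= Gap(k+1) - SE(k+1)``
    (the "first SE max" rule).

    Returns ``(k, table)`` where the table carries Gap and SE per k.
    """
    x = np.asarray(features, dtype=float)
    if x.shape[0] < k_max + 1:
        raise ValueError(f"need more than k_max={k_max} observations, "
                         f"got {x.shape[0]}")
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    ks = np.arange(1, k_max + 1)
    log_w = np.array([np.log(_within_ss(x, k, seed)) for k in ks])
    log_w_ref = np.empty((b_ref, k_max))
    for b in range(b_ref):
        ref = rng.uniform(lo, hi, size=x.shape)
        ref_seed = int(rng.integers(0, 2**31 - 1))
        log_w_ref[b] = [np.log(_within_ss(ref, k, ref_seed)) for k in ks]
    gap = log_w_ref.mean(axis=0) - log_w
    se = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / b_ref)
    table = pd.DataFrame({"k": ks, "gap": gap, "se": se})
    chosen = int(ks[-1])
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            chosen = int(ks[i])
            break
    return chosen, table


def kmeans_groups(features: pd.DataFrame, k: int = 3, seed: int = 0,
                  n_restarts: int = 50) -> pd.Series:
    """Stage female lines into erosion groups 1..k by k-means.

    Clusters are relabeled deterministically by phenotype: group 1 has
    the highest mean XIST (and lowest fraction bi-allelic), group k the
    lowest mean XIST.  The labeling is invariant to input row order.

    Raises if the points are degenerate (fewer than k distinct rows).
    """
    x = features[["xist_log2cpm", "frac_biallelic"]].to_numpy(dtype=float)
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError("degenerate clustering: fewer distinct points "
                         "than clusters")
    # sort rows so the fit is independent of input ordering
    order = np.lexsort((x[:, 1], x[:, 0]))
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels_sorted = km.fit_predict(x[order])
    labels = np.empty(len(x), dtype=int)
    labels[order] = labels_sorted
    # phenotype relabeling
    mean_xist = np.array([x[labels == c, 0].mean() for c in range(k)])
    mean_frac = np.array([x[labels == c, 1].mean() for c in range(k)])
    if k == 3:
        # group 3: lowest XIST; group 1: lowest fraction bi-allelic of
        # the rest; group 2: remainder
        g3 = int(np.argmin(mean_xist))
        rest = [c for c in range(3) if c != g3]
        g1 = rest[int(np.argmin(mean_frac[rest]))]
        g2 = [c for c in rest if c != g1][0]
        remap = {g1: 1, g2: 2, g3: 3}
    else:
        rank = np.argsort(-mean_xist)  # descending mean XIST => 1..k
        remap = {int(c): g + 1 for g, c in enumerate(rank)}
    out = pd.Series([remap[int(c)] for c in labels], index=features.index,
                    name="erosion_group")
    return out


def lowess_curve(x, y, frac: float = 2.0 / 3.0, it: int = 3) -> pd.DataFrame:
    """LOWESS fit of y on x, evaluated at the observed x values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points for a LOWESS fit")
    fitted = _sm_lowess(y, x, frac=frac, it=it, return_sorted=True)
    return pd.DataFrame({"x": fitted[:, 0], "fitted": fitted[:, 1]})


def _logistic(x, a, x0, b):
    return a / (1.0 + np.exp(b * (x - x0)))


def fit_sigmoid(x, y, max_asymptote: float = 0.5) -> SigmoidFit:
    """Least-squares fit of a decreasing logistic y = A/(1+exp(b(x-x0))).

    Multi-start initialization over a grid of inflection points and
    rates; ``slope`` in the result is reported as ``-b`` (negative for a
    decreasing curve).  A near-constant response leaves the inflection
    unidentifiable and is flagged via ``identifiable=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points for a sigmoid fit")
    if np.ptp(y) < 1e-12:
        return SigmoidFit(asymptote=float(y.mean()), inflection=float("nan"),
                          slope=0.0, residual_se=0.0, identifiable=False)
    bounds = ([1e-6, x.min() - np.ptp(x), 1e-4],
              [max_asymptote, x.max() + np.ptp(x), 100.0])
    best = None
    for x0 in np.quantile(x, [0.25, 0.5, 0.75]):
        for b0 in (0.3, 0.8, 2.0, 5.0):
            a0 = min(max(float(np.max(y)), 1e-3), max_asymptote)
            try:
                popt, _ = curve_fit(_logistic, x, y, p0=[a0, x0, b0],
                                    bounds=bounds, maxfev=20_000)
            except RuntimeError:
                continue
            rss = float(np.sum((y - _logistic(x, *popt)) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        raise RuntimeError("sigmoid fit failed to converge from any start; "
                           "check that the data span both plateaus")
    popt, rss = best
    dof = max(1, x.size - 3)
    return SigmoidFit(asymptote=float(popt[0]), inflection=float(popt[1]),
                      slope=-float(popt[2]),
                      residual_se=float(np.sqrt(rss / dof)))


def pca_variance_explained(logcpm: pd.DataFrame) -> np.ndarray:
    """Fractions of variance explained by each PC of a genes x lines
    log-expression matrix (variables = genes, centered and scaled)."""
    x = logcpm.to_numpy(dtype=float).T     # lines x genes
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    x = x[:, keep] / sd[keep]
    sv = np.linalg.svd(x, compute_uv=False)
    var = sv ** 2
    return var / var.sum()
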