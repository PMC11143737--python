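"""Gene-set enrichment of DE lists against epigenomic annotations.

Interval annotations (methylation probes, histone-mark peaks) are
mapped to genes through promoter windows (TSS +/- 1500 bp) or promoter
(TSS +/- 3000 bp) plus gene body.  Over- and under-representation of a
DE gene list in an annotation set is tested with a hypergeometric test,
and effect size is reported as the relative enrichment

    RE = (n_overlap / n_annotation) / (n_de / n_universe)

whose null expectation is ~1; a permutation distribution over random
same-sized gene sets locates the observed RE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PROMOTER_1500 = "promoter1500"
PROMOTER_3000_BODY = "promoter3000_plus_body"


@dataclass
class EnrichmentResult:
    annotation_name: str
    n_annotation_genes: int
    n_de_genes: int
    n_universe: int
    n_overlap: int
    relative_enrichment: float
    p_over: float
    p_under: float
    perm_quantile: float
    n_permutations: int


def intervals_to_genes(intervals: pd.DataFrame, gene_models: pd.DataFrame,
                       mode: str = PROMOTER_1500) -> set[str]:
    """Genes whose window overlaps at least one interval.

    `intervals` uses the internal 1-based closed convention.  Windows
    are symmetric around the strand-aware TSS: +/- 1500 bp
    (``promoter1500``) or +/- 3000 bp plus the full gene span
    (``promoter3000_plus_body``).  Overlap is closed-interval overlap.
    """
    if mode == PROMOTER_1500:
        half = 1500
        with_body = False
    elif mode == PROMOTER_3000_BODY:
        half = 3000
        with_body = True
    else:
        raise ValueError(f"unknown mode {mode!r}")
    hits: set[str] = set()
    by_chrom = {c: grp for c, grp in intervals.groupby("chrom")}
    for _, g in gene_models.iterrows():
        grp = by_chrom.get(g["chrom"])
        if grp is None:
            continue
        windows = [(g["tss"] - half, g["tss"] + half)]
        if with_body:
            windows.append((g["start"], g["end"]))
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        for lo, hi in windows:
            if np.any((s <= hi) & (e >= lo)):
                hits.add(g["gene_id"])
                break
    return hits


def relative_enrichment(n_overlap: int, n_annotation: int, n_de: int,
                        n_universe: int) -> float:
    """(n_overlap / n_annotation) / (n_de / n_universe)."""
    if n_universe <= 0 or n_de <= 0 or n_annotation <= 0:
        raise ValueError("universe, DE and annotation sizes must be > 0")
    return (n_overlap / n_annotation) / (n_de / n_universe)


def hypergeom_test(n_overlap: int, n_annotation: int, n_de: int,
                   n_universe: int) -> tuple[float, float]:
    """Hypergeometric p-values for over-/under-representation.

    X ~ Hypergeom(N=n_universe, K=n_annotation, n=n_de);
    p_over = P(X >= n_overlap), p_under = P(X <= n_overlap).
    """
    rv = stats.hypergeom(n_universe, n_annotation, n_de)
    p_over = float(rv.sf(n_overlap - 1))
    p_under = float(rv.cdf(n_overlap))
    return p_over, p_under


def permutation_null(annotation: set[str], n_de: int,
                     universe: list[str], n_permutations: int = 1000,
                     seed: int = 0) -> np.ndarray:
    """Relative-enrichment values for random DE sets of size `n_de`.

    Each permutation draws `n_de` genes from the universe without
    replacement and recomputes RE against the same annotation set.
    """
    universe = list(universe)
    ann_mask = np.fromiter((g in annotation for g in universe), dtype=bool,
                           count=len(universe))
    n_ann_in_univ = int(ann_mask.sum())
    if n_ann_in_univ == 0:
        raise ValueError("annotation set does not intersect the universe")
    rng = np.random.default_rng(seed)
    res = np.empty(n_permutations)
    for b in range(n_permutations):
        pick = rng.choice(len(universe), size=n_de, replace=False)
        overlap = int(ann_mask[pick].sum())
        res[b] = relative_enrichment(overlap, n_ann_in_univ, n_de,
                                     len(universe))
    return res


def test_gene_set(annotation: set[str], de_genes: set[str],
                  universe: list[str], annotation_name: str = "annotation",
                  n_permutations: int = 1000, seed: int = 0
                  ) -> EnrichmentResult:
    """Full enrichment test of one DE list against one annotation set.

    The annotation is intersected with the universe (the genes analyzed
    in the DE contrast) before testing.
    """
    universe = list(universe)
    uni = set(universe)
    ann = annotation & uni
    de = de_genes & uni
    overlap = ann & de
    re_obs = relative_enrichment(len(overlap), len(ann), len(de), len(uni))
    p_over, p_under = hypergeom_test(len(overlap), len(ann), len(de),
                                     len(uni))
    perm = permutation_null(ann, len(de), universe,
                            n_permutations=n_permutations, seed=seed)
    quantile = float(np.mean(perm >= re_obs))
    return EnrichmentResult(
        annotation_name=annotation_name,
        n_annotation_genes=len(ann), n_de_genes=len(de),
        n_universe=len(uni), n_overlap=len(overlap),
        relative_enrichment=re_obs, p_over=p_over, p_under=p_under,
        perm_quantile=quantile, n_permutations=n_permutations)


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
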