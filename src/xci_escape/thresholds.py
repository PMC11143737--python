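"""Analysis thresholds with their published defaults.

Every cutoff used by the pipeline lives here so a single object can be
threaded through all stages and overridden from a YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass
class Thresholds:
    """Cutoffs for ASE filtering, bi-allelic calling and line grouping.

    Attributes
    ----------
    min_variant_reads
        Minimum total read depth (ASEReadCounter ``totalCount``) for a
        heterozygous variant to enter the gene-level ASE computation.
    collapse_gap_bp
        Variants closer than this (one read length) are assumed to share
        reads; only one variant per linked cluster is kept.
    biallelic_ase
        Null allelic fraction for the one-sided binomial test of
        bi-allelic expression (alternative: ASE > this value).
    biallelic_fdr_q
        Benjamini-Hochberg q-value cutoff for calling a gene x line
        bi-allelic.
    xist_mono_ase
        Null allelic fraction for the XIST clonality test (null:
        ASE >= this value; rejection means monoallelic XIST).
    xist_mono_alpha
        Significance level for the XIST clonality test.
    low_xist_log2cpm
        XIST expression below this log2(CPM + 0.5) marks a low-XIST
        (putatively eroded) female line.
    min_lines_per_group
        Minimum informative lines in *each* of the low- and high-XIST
        groups for a gene to be eligible for escape classification.
    biallelic_gene_line_frac
        A gene bi-allelic in more than this fraction of informative
        lines is classed ``biallelic``.
    """

    min_variant_reads: int = 20
    collapse_gap_bp: int = 100
    biallelic_ase: float = 0.1
    biallelic_fdr_q: float = 0.01
    xist_mono_ase: float = 0.05
    xist_mono_alpha: float = 0.05
    low_xist_log2cpm: float = 1.5
    min_lines_per_group: int = 10
    biallelic_gene_line_frac: float = 0.80

    @classmethod
    def from_dict(cls, overrides: dict) -> "Thresholds":
        known = {f.name for f in fields(cls)}
        bad = set(overrides) - known
        if bad:
            raise ValueError(f"unknown threshold names: {sorted(bad)}")
        return cls(**overrides)
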