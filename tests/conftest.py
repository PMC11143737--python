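import numpy as np
import pandas as pd
import pytest

from xci_escape import ase_core, diffexpr, line_state, synthetic_data


def small_sim_config(**overrides):
    """A fast, reduced cohort for unit tests."""
    defaults = dict(
        n_males=10,
        n_females_per_group=(12, 10, 10),
        n_x_genes=40,
        n_auto_genes=80,
        n_par=4,
        n_escape=8,
        n_variable=8,
        n_sex_biased_auto=10,
        n_auto_ase_genes=10,
    )
    defaults.update(overrides)
    return synthetic_data.SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return synthetic_data.simulate_cohort(small_sim_config(), seed=7)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    """ASE records, log-CPM matrix and line profiles for the small cohort."""
    records = ase_core.run_ase_pipeline(small_cohort.allelic_counts,
                                        small_cohort.gene_models)
    counts = diffexpr.filter_low_counts(small_cohort.expr_counts)
    logcpm = diffexpr.log2cpm(counts, diffexpr.tmm_factors(counts))
    x_records = records[records["chrom"] == "chrX"]
    profiles = line_state.summarize_lines(x_records, logcpm,
                                          small_cohort.meta)
    return {"records": records, "x_records": x_records, "logcpm": logcpm,
            "profiles": profiles}


def make_variants(rows):
    """Variant table from (line, gene, pos, ref, alt[, total]) tuples."""
    out = []
    for row in rows:
        line, gene, pos, ref, alt = row[:5]
        total = row[5] if len(row) > 5 else ref + alt
        out.append({"line_id": line, "contig": "chrX", "position": pos,
                    "ref_count": ref, "alt_count": alt,
                    "total_count": total, "gene_id": gene})
    columns = ["line_id", "contig", "position", "ref_count", "alt_count",
               "total_count", "gene_id"]
    return pd.DataFrame(out, columns=columns)


def toy_gene_models(gene_ids, chrom="chrX"):
    rows = []
    for i, g in enumerate(gene_ids):
        start = 1000 + i * 10_000
        rows.append({"gene_id": g, "chrom": chrom, "strand": "+",
                     "tss": start, "start": start, "end": start + 5000,
                     "is_par": False, "human_escape_status": "unknown"})
    return pd.DataFrame(rows)
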