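import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from xci_escape import diffexpr


def _counts(mat, genes=None, samples=None):
    mat = np.asarray(mat)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    samples = samples or [f"s{j}" for j in range(mat.shape[1])]
    return pd.DataFrame(mat, index=genes, columns=samples)


def _meta(samples, donors=None, sex=None):
    return pd.DataFrame({
        "line_id": samples,
        "donor_id": donors or [f"d{i}" for i in range(len(samples))],
        "sex": sex or ["female"] * len(samples)})


class TestFilterLowCounts:
    def test_ten_count_boundary(self):
        m = _counts([[4, 6], [5, 5], [9, 0]])
        out = diffexpr.filter_low_counts(m)
        assert list(out.index) == ["g0", "g1"]

    def test_identity_and_empty(self):
        m = _counts([[10, 10]])
        assert diffexpr.filter_low_counts(m).equals(m)
        empty = _counts(np.empty((0, 2), dtype=int))
        assert len(diffexpr.filter_low_counts(empty)) == 0


class TestTmm:
    def test_identical_libraries_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(10, 1000, size=60)
        m = _counts(np.column_stack([col, col]))
        f = diffexpr.tmm_factors(m)
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(1)
        col = rng.integers(10, 1000, size=60)
        m = _counts(np.column_stack([col, 2 * col]))
        assert np.allclose(diffexpr.tmm_factors(m), 1.0)

    def test_composition_outlier_shrinks_factor(self):
        rng = np.random.default_rng(2)
        col = rng.integers(50, 500, size=50)
        col_b = col.copy()
        col_b[0] *= 100
        f = diffexpr.tmm_factors(_counts(np.column_stack([col, col_b])))
        assert f.iloc[1] < 1.0
        assert f.iloc[0] > 1.0

    def test_geometric_mean_one_and_sample_relabeling(self):
        rng = np.random.default_rng(3)
        m = _counts(rng.integers(0, 800, size=(80, 5)))
        f = diffexpr.tmm_factors(m)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)
        perm = ["s3", "s0", "s4", "s1", "s2"]
        f2 = diffexpr.tmm_factors(m[perm])
        assert np.allclose(f2.reindex(f.index).to_numpy(), f.to_numpy())

    def test_zero_library_rejected(self):
        m = _counts([[0, 5], [0, 5]])
        with pytest.raises(ValueError, match="zero total"):
            diffexpr.tmm_factors(m)

    def test_matches_edger_reference_implementation(self, tmp_path):
        """Cross-check against edgeR::calcNormFactors on a small matrix."""
        rng = np.random.default_rng(42)
        base = rng.lognormal(5, 1, size=100)
        mat = rng.poisson(np.column_stack([
            base, base * 1.5, base * 0.7, base])).astype(int)
        mat[:10, 1] *= 8      # composition outliers in sample 2
        m = _counts(mat)
        ours = diffexpr.tmm_factors(m)
        csv = tmp_path / "counts.csv"
        m.to_csv(csv)
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.csv("{csv}", row.names=1))
            cat(calcNormFactors(x, method="TMM"), sep="\\n")
        """)
        res = subprocess.run(["Rscript", "-e", script],
                             capture_output=True, text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        ref = np.array([float(v) for v in res.stdout.split()])
        assert np.allclose(ours.to_numpy(), ref, rtol=0.02)


class TestLog2Cpm:
    def test_closed_forms(self):
        m = _counts([[0, 0], [999_999, 999_999], [1, 1]])
        lib = m.sum(axis=0)
        out = diffexpr.log2cpm(m)
        assert np.allclose(out.loc["g0"], -1.0)  # log2(0 + 0.5)
        expected = np.log2(1 / lib.iloc[0] * 1e6 + 0.5)
        assert out.loc["g2", "s0"] == pytest.approx(expected)

    def test_depth_scaling_invariance(self):
        rng = np.random.default_rng(5)
        m = _counts(rng.integers(1, 500, size=(40, 3)))
        assert np.allclose(diffexpr.log2cpm(m), diffexpr.log2cpm(2 * m))


class TestDeTwoGroup:
    def _simulate(self, seed, n_per=20, n_genes=300, n_de=30, lfc=1.0,
                  sigma=0.5):
        rng = np.random.default_rng(seed)
        samples = [f"a{i}" for i in range(n_per)] + \
                  [f"b{i}" for i in range(n_per)]
        x = rng.normal(0, sigma, size=(n_genes, 2 * n_per))
        x[:n_de, :n_per] += lfc
        logcpm = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)],
                              columns=samples)
        meta = _meta(samples)
        return logcpm, meta, samples[:n_per], samples[n_per:]

    def test_planted_effect_recovered_with_power(self):
        logcpm, meta, a, b = self._simulate(0)
        res = diffexpr.de_two_group(logcpm, meta, a, b)
        planted = res.iloc[:30]
        assert planted["log2fc"].mean() == pytest.approx(1.0, abs=0.1)
        assert (planted["q"] < 0.05).mean() > 0.99

    def test_donor_replicates_averaged_before_testing(self):
        samples = [f"s{i}" for i in range(9)]
        donors = ["dA0", "dA0", "dA1", "dA2", "dA2", "dB0", "dB1", "dB2",
                  "dB3"]
        # donor dA0 replicates at 0 and 2 (mean 1), dA1 at 4, dA2 at 0, 2
        vals = np.array([[0.0, 2.0, 4.0, 0.0, 2.0, 0.0, 0.0, 0.0, 0.0],
                         [1.0, 1.0, 1.0, 1.0, 1.0, 0.0, 1.0, 0.0, 1.0]])
        logcpm = pd.DataFrame(vals, columns=samples)
        meta = _meta(samples, donors=donors)
        res = diffexpr.de_two_group(logcpm, meta, samples[:5], samples[5:])
        # group A donor means (1, 4, 1) -> mean 2; group B mean 0
        assert res.iloc[0]["log2fc"] == pytest.approx(2.0)
        assert res.iloc[1]["log2fc"] == pytest.approx(1.0 - 0.5)

    def test_requires_three_donors_per_group(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(6)]
        donors = ["d0", "d0", "d1", "d2", "d3", "d4"]
        logcpm = pd.DataFrame(rng.normal(size=(10, 6)), columns=samples)
        meta = _meta(samples, donors=donors)
        with pytest.raises(ValueError, match="3 donors"):
            diffexpr.de_two_group(logcpm, meta, samples[:3], samples[3:])

    def test_constant_gene_flagged_na(self):
        samples = [f"s{i}" for i in range(8)]
        rng = np.random.default_rng(3)
        x = rng.normal(size=(5, 8))
        x[0] = 1.0
        logcpm = pd.DataFrame(x, columns=samples)
        meta = _meta(samples)
        res = diffexpr.de_two_group(logcpm, meta, samples[:4], samples[4:])
        assert np.isnan(res.iloc[0]["p"])
        assert res.iloc[1:]["p"].notna().all()


class TestFcCiScreen:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "log2fc",
                                           "se_log2fc", "q"])

    def test_boundary_and_exclusion_rules(self):
        log2_15 = np.log2(1.5)
        tab = self._table([
            ("hit_boundary", log2_15, 1e-12, 0.001),
            ("small_effect", 0.2, 0.05, 0.001),
            ("wide_ci", 1.0, 0.25, 0.001),
            ("not_significant", 1.0, 0.25, 0.2)])
        out = diffexpr.fc_ci_screen(tab)
        assert set(out["gene_id"]) == {"hit_boundary", "wide_ci"}

    def test_monotone_in_se(self):
        for se in (0.05, 0.1, 0.3, 0.6):
            tab = self._table([("g", 1.0, se, 0.01)])
            included = len(diffexpr.fc_ci_screen(tab)) == 1
            if se >= 0.3:
                assert included
        # once included at some se, larger se keeps it included
        included = [len(diffexpr.fc_ci_screen(
            self._table([("g", 0.4, se, 0.01)]))) for se in
            np.linspace(0.01, 1.0, 30)]
        assert sorted(included) == included

    def test_gene_list_restriction(self):
        tab = self._table([("a", 0.6, 0.1, 0.01), ("b", 0.6, 0.1, 0.01)])
        out = diffexpr.fc_ci_screen(tab, gene_list=["b"])
        assert list(out["gene_id"]) == ["b"]


class TestOverlapSummary:
    def _tab(self, sig_genes, lfc_sign=1.0):
        return pd.DataFrame({
            "gene_id": sig_genes, "q": [0.01] * len(sig_genes),
            "log2fc": [lfc_sign] * len(sig_genes)})

    def test_disjoint_and_identical_sets(self):
        res = diffexpr.overlap_summary(
            {"c1": self._tab(["a", "b"]), "c2": self._tab(["c"])})
        assert set(res["contrasts"]) == {"c1", "c2"}
        res2 = diffexpr.overlap_summary(
            {"c1": self._tab(["a", "b"]), "c2": self._tab(["a", "b"])})
        assert list(res2["contrasts"]) == ["c1&c2"]
        assert res2.iloc[0]["n_genes"] == 2
        assert res2.iloc[0]["direction"] == "concordant_up"

    def test_opposite_signs_counted_discordant(self):
        res = diffexpr.overlap_summary(
            {"c1": self._tab(["a"], 1.0), "c2": self._tab(["a"], -1.0)})
        assert res.iloc[0]["direction"] == "discordant"
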