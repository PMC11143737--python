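import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xci_escape import ase_core
from xci_escape.thresholds import Thresholds

from conftest import make_variants, toy_gene_models


def exact_binom_upper_tail(minor, total, p0):
    """Enumeration oracle: sum of pmf terms for X >= minor."""
    return sum(math.comb(total, k) * p0 ** k * (1 - p0) ** (total - k)
               for k in range(minor, total + 1))


class TestFilterVariants:
    def test_twenty_read_floor_is_inclusive(self):
        v = make_variants([("L", "g", p, t // 2, t - t // 2)
                           for p, t in [(100, 19), (300, 20), (500, 21)]])
        out = ase_core.filter_variants(v)
        assert sorted(out["total_count"]) == [20, 21]

    def test_empty_and_all_below_threshold(self):
        assert len(ase_core.filter_variants(make_variants([]))) == 0
        v = make_variants([("L", "g", p, 9, 10) for p in (1, 200, 400)])
        v["total_count"] = 19
        assert len(ase_core.filter_variants(v)) == 0


class TestCollapseLinkedVariants:
    @pytest.mark.parametrize("positions,totals,expected_positions", [
        ([100, 150], [30, 50], [150]),          # gap 50 < 100: keep bigger
        ([100, 250], [30, 50], [100, 250]),     # gap 150 >= 100: keep both
        ([100, 150, 260], [30, 50, 10], [150, 260]),  # chain {100,150};260
        ([100, 150], [50, 50], [100]),          # tie -> smaller position
        ([100], [30], [100]),
    ])
    def test_chaining_rule(self, positions, totals, expected_positions):
        idx = ase_core.collapse_linked_variants(
            np.array(positions), np.array(totals))
        assert sorted(np.array(positions)[idx]) == expected_positions

    def test_exact_boundary_gap_not_collapsed(self):
        idx = ase_core.collapse_linked_variants(
            np.array([100, 200]), np.array([30, 50]), gap_bp=100)
        assert len(idx) == 2

    @given(st.lists(st.tuples(st.integers(1, 2000), st.integers(1, 500)),
                    min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_one_survivor_per_chain_with_maximal_depth(self, pairs):
        pos = np.array([p for p, _ in pairs])
        tot = np.array([t for _, t in pairs])
        idx = ase_core.collapse_linked_variants(pos, tot)
        kept = set(idx.tolist())
        assert len(kept) == len(idx)
        # recompute chains independently and check one max-total per chain
        order = np.argsort(pos, kind="stable")
        chains, current = [], [order[0]]
        for a, b in zip(order[:-1], order[1:]):
            if pos[b] - pos[a] < 100:
                current.append(b)
            else:
                chains.append(current)
                current = [b]
        chains.append(current)
        assert len(idx) == len(chains)
        for chain in chains:
            members = kept.intersection(chain)
            assert len(members) == 1
            m = members.pop()
            assert tot[m] == max(tot[c] for c in chain)


class TestComputeGeneAse:
    def test_worked_minor_allele_aggregation(self):
        v = make_variants([("L", "g", 100, 5, 15), ("L", "g", 300, 10, 20)])
        rec = ase_core.compute_gene_ase(v).iloc[0]
        assert rec.minor_reads == 15
        assert rec.total_reads == 50
        assert rec.ase == pytest.approx(0.30)

    @pytest.mark.parametrize("ref,alt,expected", [
        (10, 10, 0.5), (0, 25, 0.0), (25, 0, 0.0)])
    def test_limits(self, ref, alt, expected):
        rec = ase_core.compute_gene_ase(
            make_variants([("L", "g", 100, ref, alt)])).iloc[0]
        assert rec.ase == pytest.approx(expected)

    @given(st.lists(st.tuples(st.integers(0, 300), st.integers(0, 300)),
                    min_size=1, max_size=8).filter(
        lambda xs: all(a + b > 0 for a, b in xs)))
    @settings(max_examples=200, deadline=None)
    def test_ase_never_exceeds_half(self, counts):
        v = make_variants([("L", "g", 100 * i, a, b)
                           for i, (a, b) in enumerate(counts)])
        assert ase_core.compute_gene_ase(v).iloc[0].ase <= 0.5 + 1e-12


class TestBinomialTests:
    def test_upper_tail_matches_enumeration(self):
        assert ase_core.test_biallelic(5, 20) == pytest.approx(
            exact_binom_upper_tail(5, 20, 0.1), rel=1e-12)
        assert ase_core.test_biallelic(5, 20) == pytest.approx(0.0432,
                                                              abs=2e-4)

    def test_degenerate_tails(self):
        assert ase_core.test_biallelic(0, 20) == pytest.approx(1.0)
        assert ase_core.test_biallelic(20, 20) == pytest.approx(0.1 ** 20)

    @given(st.integers(1, 200))
    @settings(max_examples=60, deadline=None)
    def test_monotone_decreasing_in_minor(self, total):
        p = [ase_core.test_biallelic(m, total) for m in range(total + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(p, p[1:]))

    def test_xist_clonality_calls(self):
        call, p = ase_core.xist_clonality_call(0, 100)
        assert call == "monoallelic"
        assert p == pytest.approx(0.95 ** 100, rel=1e-12)
        call, p = ase_core.xist_clonality_call(10, 100)
        assert call == "biallelic_trace"
        assert p > 0.9
        assert ase_core.xist_clonality_call(None, None)[0] == "undefined"


class TestBiallelicCalls:
    def test_bh_by_hand(self):
        rec = pd.DataFrame({
            "gene_id": list("abc"), "line_id": ["L"] * 3,
            "minor_reads": [0, 0, 0], "total_reads": [1, 1, 1]})
        out = ase_core.call_biallelic_matrix(rec)
        # overwrite p with the hand example and re-run BH through the
        # public path by direct comparison
        from statsmodels.stats.multitest import multipletests
        q = multipletests([0.001, 0.02, 0.9], method="fdr_bh")[1]
        assert q == pytest.approx([0.003, 0.03, 0.9])
        assert "biallelic_q" in out

    def test_single_test_q_equals_p_and_all_null(self):
        one = pd.DataFrame({"gene_id": ["a"], "line_id": ["L"],
                            "minor_reads": [9], "total_reads": [20]})
        out = ase_core.call_biallelic_matrix(one)
        assert out.iloc[0].biallelic_q == pytest.approx(
            out.iloc[0].biallelic_p)
        nulls = pd.DataFrame({"gene_id": list("abc"), "line_id": ["L"] * 3,
                              "minor_reads": [0] * 3,
                              "total_reads": [30] * 3})
        assert not ase_core.call_biallelic_matrix(nulls)["is_biallelic"].any()

    def test_per_line_family_option(self):
        rec = pd.DataFrame({
            "gene_id": ["a", "b", "a", "b"],
            "line_id": ["L1", "L1", "L2", "L2"],
            "minor_reads": [15, 0, 15, 0], "total_reads": [30] * 4})
        g = ase_core.call_biallelic_matrix(rec, bh_family="global")
        l = ase_core.call_biallelic_matrix(rec, bh_family="per-line")
        assert set(g.columns) == set(l.columns)
        assert (l.groupby("line_id")["biallelic_q"].transform("size")
                == 2).all()


class TestReferenceAlleleFraction:
    def test_balanced_and_biased_fractions(self):
        v = make_variants([("L", "g", 1, 10, 10), ("L", "g", 200, 10, 10)])
        assert ase_core.reference_allele_fraction(v).iloc[0].ref_fraction \
            == pytest.approx(0.5)
        v2 = make_variants([("L", "g", 1, 30, 10), ("L", "g", 200, 10, 30)])
        assert ase_core.reference_allele_fraction(v2).iloc[0].ref_fraction \
            == pytest.approx(0.5)
        v3 = make_variants([("L", "g", 1, 30, 10)])
        assert ase_core.reference_allele_fraction(v3).iloc[0].ref_fraction \
            == pytest.approx(0.75)


class TestRunAsePipeline:
    def test_filters_collapses_and_calls(self):
        gm = toy_gene_models(["g1", "g2"])
        v = make_variants([
            ("L", "g1", 1100, 15, 15),     # kept
            ("L", "g1", 1150, 10, 15),     # collapsed into 1100? bigger wins
            ("L", "g1", 1400, 5, 25),      # separate chain
            ("L", "g2", 11100, 9, 10),     # below 20-read floor
        ])
        rec = ase_core.run_ase_pipeline(v, gm, x_only_bh=True)
        assert set(rec["gene_id"]) == {"g1"}
        row = rec.iloc[0]
        # chain {1100,1150}: keep 1100 (total 30 vs 25); plus 1400
        assert row.n_variants_used == 2
        assert row.minor_reads == 15 + 5
        assert row.total_reads == 30 + 30

    def test_greedy_variant_collapse_option_runs(self):
        gm = toy_gene_models(["g1"])
        v = make_variants([("L", "g1", 1100, 15, 15),
                           ("L", "g1", 1150, 20, 20),
                           ("L", "g1", 1240, 5, 25)])
        rec = ase_core.run_ase_pipeline(v, gm, collapse_method="greedy")
        assert rec.iloc[0].n_variants_used == 1  # 1150 absorbs both sides
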