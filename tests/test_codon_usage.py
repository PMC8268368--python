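"""Codon-usage statistics against straight-from-formula oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaoxkit.codon_usage import (
    SYNONYMOUS_FAMILIES,
    base_composition_3s,
    batch_summary,
    correlation_analysis,
    count_codons,
    enc,
    enc_expected,
    enc_plot_table,
    gc_partition,
    pr2_coordinates,
    rscu,
    rscu_matrix,
    summarize_gene,
    summary_frame,
)
from gaoxkit.simulate import simulate_cds

# ---------------------------------------------------------------------------
# independent oracles: written straight from the defining formulas, using
# their own codon bookkeeping


def oracle_rscu(codon_counts: dict[str, int]) -> dict[str, float]:
    out = {}
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        if len(fam) == 1:
            continue
        total = sum(codon_counts.get(c, 0) for c in fam)
        for c in fam:
            out[c] = (codon_counts.get(c, 0) * len(fam) / total) if total else float("nan")
    return out


def oracle_enc(codon_counts: dict[str, int]) -> float:
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        if len(fam) == 1:
            continue
        ns = [codon_counts.get(c, 0) for c in fam]
        n = sum(ns)
        if n < 2:
            continue
        f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
        if f > 0:
            per_class[len(fam)].append(f)
    means = {k: sum(v) / len(v) for k, v in per_class.items() if v}
    fbar = {}
    for k in (2, 3, 4, 6):
        if k in means:
            fbar[k] = means[k]
        elif k == 3 and 2 in means and 4 in means:
            fbar[k] = (means[2] + means[4]) / 2
        else:
            fbar[k] = sum(means.values()) / len(means)
    return min(61.0, 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6])


def random_genes(n=20, n_codons=300, seed=0):
    return simulate_cds(n_genes=n, n_codons=n_codons, gc3_target=0.75,
                        bias_strength=1.0, seed=seed)


# ---------------------------------------------------------------------------


class TestCountCodons:
    def test_basic(self):
        t = count_codons("ATGTGG", "g")
        assert t.counts == {"ATG": 1, "TGG": 1} and t.n_codons == 2

    def test_n_codons_skipped(self):
        t = count_codons("ATGNNNTGG", "g")
        assert t.counts == {"ATG": 1, "TGG": 1} and t.n_skipped == 1

    def test_long_gene_vs_sliding_window_count(self, rng):
        (gid, seq), = simulate_cds(1, 1000, seed=3)
        t = count_codons(seq, gid)
        for codon, n in t.counts.items():
            brute = sum(seq[i:i + 3] == codon for i in range(0, len(seq), 3))
            assert n == brute
        assert t.n_codons == 1000


class TestRscu:
    def test_equal_use_gives_all_ones(self):
        seq = "".join(c for fam in SYNONYMOUS_FAMILIES.values() for c in fam)
        values = rscu(count_codons(seq, "g"))
        assert all(v == pytest.approx(1.0) for v in values.values())

    def test_exclusive_codon_gets_family_size(self):
        values = rscu(count_codons("CTG" * 4, "g"))
        assert values["CTG"] == pytest.approx(6.0)
        assert all(values[c] == 0 for c in SYNONYMOUS_FAMILIES["L"] if c != "CTG")

    def test_matches_oracle_on_random_tables(self):
        for gid, seq in random_genes(seed=11):
            t = count_codons(seq, gid)
            expected = oracle_rscu(t.counts)
            got = rscu(t)
            assert set(got) == set(expected)
            for c in got:
                if math.isnan(expected[c]):
                    assert math.isnan(got[c])
                else:
                    assert got[c] == pytest.approx(expected[c], abs=1e-9)

    def test_family_sums_equal_family_size(self):
        for gid, seq in random_genes(5, seed=12):
            values = rscu(count_codons(seq, gid))
            for aa, fam in SYNONYMOUS_FAMILIES.items():
                if len(fam) == 1:
                    continue
                s = sum(values[c] for c in fam)
                if not math.isnan(s):
                    assert s == pytest.approx(len(fam), abs=1e-9)


class TestComposition3s:
    def test_all_t_ending(self):
        a, t, g, c, gc3s = base_composition_3s(count_codons("GGTCCTACT", "g"))
        assert (a, t, g, c) == (0.0, 1.0, 0.0, 0.0) and gc3s == 0.0

    def test_only_single_codon_families_undefined(self):
        with pytest.raises(ValueError, match="no synonymous"):
            base_composition_3s(count_codons("ATGTGGATG", "g"))

    def test_matches_per_codon_enumeration(self):
        for gid, seq in random_genes(5, seed=13):
            table = count_codons(seq, gid)
            tallies = {"A": 0, "T": 0, "G": 0, "C": 0}
            for codon, n in table.counts.items():
                if codon not in ("ATG", "TGG"):
                    tallies[codon[2]] += n
            total = sum(tallies.values())
            a, t, g, c, gc3s = base_composition_3s(table)
            assert a == pytest.approx(tallies["A"] / total, abs=1e-12)
            assert gc3s == pytest.approx((tallies["G"] + tallies["C"]) / total, abs=1e-12)
            assert a + t + g + c == pytest.approx(1.0, abs=1e-12)


class TestGcPartition:
    def test_all_ggc(self):
        gc, gc1, gc2, gc3, gc12 = gc_partition(count_codons("GGCGGC", "g"))
        assert (gc, gc1, gc2, gc3, gc12) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_counted_example(self):
        # ATG GAT: pos1 A,G -> 0.5; pos2 T,A -> 0; pos3 G,T -> 0.5
        gc, gc1, gc2, gc3, gc12 = gc_partition(count_codons("ATGGAT", "g"))
        assert (gc1, gc2, gc3) == (0.5, 0.0, 0.5)
        assert gc12 == pytest.approx((gc1 + gc2) / 2)

    def test_positionwise_oracle(self):
        for gid, seq in random_genes(5, seed=14):
            table = count_codons(seq, gid)
            gc, gc1, gc2, gc3, gc12 = gc_partition(table)
            for pos, got in ((0, gc1), (1, gc2), (2, gc3)):
                brute = sum(seq[i + pos] in "GC" for i in range(0, len(seq), 3))
                assert got == pytest.approx(brute / (len(seq) // 3), abs=1e-12)
            assert gc == pytest.approx((gc1 + gc2 + gc3) / 3, abs=1e-12)


class TestEnc:
    def test_one_codon_per_amino_acid_gives_20(self):
        seq = "".join(fam[0] * 3 for fam in SYNONYMOUS_FAMILIES.values())
        assert enc(count_codons(seq, "g")) == pytest.approx(20.0, abs=1e-9)

    def test_uniform_usage_caps_at_61(self):
        seq = "".join(c * 50 for fam in SYNONYMOUS_FAMILIES.values() for c in fam)
        assert enc(count_codons(seq, "g")) == pytest.approx(61.0)

    def test_matches_formula_oracle(self):
        for gid, seq in random_genes(20, seed=15):
            t = count_codons(seq, gid)
            assert enc(t) == pytest.approx(oracle_enc(t.counts), abs=1e-9)

    def test_bounds_on_random_genes(self):
        for gid, seq in random_genes(10, 80, seed=16):
            assert 20.0 <= enc(count_codons(seq, gid)) <= 61.0


class TestEncExpected:
    @pytest.mark.parametrize("s,expected", [(0.5, 60.5), (1.0, 32.0), (0.25, 48.65)])
    def test_closed_form(self, s, expected):
        assert enc_expected(s) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_about_half_after_linear_term(self, s):
        assert enc_expected(s) - s == pytest.approx(enc_expected(1 - s) - (1 - s), abs=1e-9)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            enc_expected(1.2)


class TestPr2:
    def test_balanced_composition_is_center(self):
        # equal numbers of each third base over synonymous codons
        seq = "GGA" + "GGT" + "GGG" + "GGC"
        assert pr2_coordinates(count_codons(seq, "g")) == (0.5, 0.5)

    def test_direct_ratio_oracle(self):
        for gid, seq in random_genes(5, seed=17):
            t = count_codons(seq, gid)
            a, tt, g, c, _ = base_composition_3s(t)
            x, y = pr2_coordinates(t)
            assert x == pytest.approx(g / (g + c), abs=1e-12)
            assert y == pytest.approx(a / (a + tt), abs=1e-12)

    def test_gc_biased_panel_sits_left_low(self):
        # strongly C/T-shifted third positions: x < 0.5 and y < 0.5
        seq = ("TTC" + "AAC" + "GAC" + "CAC") * 5 + "TTT" + "AAT"
        x, y = pr2_coordinates(count_codons(seq, "g"))
        assert x < 0.5 and y < 0.5


class TestCorrelation:
    def test_identical_columns_r_one(self):
        genes = random_genes(6, seed=18)
        df = summary_frame(batch_summary(genes))
        df["gc12"] = df["gc3s"]  # force x = y
        res = correlation_analysis(df)
        row = res[(res.index_a == "gc3s") & (res.index_b == "gc12")].iloc[0]
        assert row.pearson_r == pytest.approx(1.0)

    def test_anticorrelated_columns(self):
        genes = random_genes(6, seed=19)
        df = summary_frame(batch_summary(genes))
        df["gc12"] = 1.0 - df["gc3s"]
        res = correlation_analysis(df)
        row = res[(res.index_a == "gc3s") & (res.index_b == "gc12")].iloc[0]
        assert row.pearson_r == pytest.approx(-1.0)

    def test_gc3_driven_bias_yields_positive_significant_r(self):
        # genes spanning a gradient of GC3 bias: gc3s and gc must co-vary
        genes = []
        for i, strength in enumerate(np.linspace(0.0, 3.0, 50)):
            genes += simulate_cds(1, 200, 0.9, float(strength), seed=100 + i,
                                  prefix=f"g{i}_")
        res = correlation_analysis(summary_frame(batch_summary(genes)))
        row = res[(res.index_a == "gc3s") & (res.index_b == "gc")].iloc[0]
        assert row.pearson_r > 0.5 and row.p_value < 1e-6

    def test_symmetry_and_unit_diagonal(self):
        res = correlation_analysis(summary_frame(batch_summary(random_genes(6, seed=20))))
        piv = res.pivot(index="index_a", columns="index_b", values="pearson_r")
        assert np.allclose(piv.values, piv.values.T, equal_nan=True)
        assert np.allclose(np.diag(piv.values), 1.0)

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            correlation_analysis(summary_frame(batch_summary(random_genes(2, seed=21))))


class TestBatch:
    def test_three_toy_genes_fully_populated(self):
        summaries = batch_summary(random_genes(3, seed=22))
        df = summary_frame(summaries)
        assert len(df) == 3 and not df.drop(columns=["group", "taxon"]).isna().any().any()

    def test_unlabeled_gene_warns_and_defaults(self):
        genes = random_genes(2, seed=23)
        with pytest.warns(UserWarning, match="no label"):
            summaries = batch_summary(genes, {genes[0][0]: ("A", "x")})
        assert summaries[1].group_label == "unlabeled"

    def test_deterministic_tables(self):
        genes = random_genes(4, seed=24)
        a = summary_frame(batch_summary(genes)).to_csv()
        b = summary_frame(batch_summary(genes)).to_csv()
        assert a == b

    def test_rscu_matrix_order_and_na(self):
        summaries = batch_summary([("g1", "CTG" * 60)])  # only leucine
        mat = rscu_matrix(summaries)
        fams_sorted = [c for aa in sorted(aa for aa in SYNONYMOUS_FAMILIES
                                          if len(SYNONYMOUS_FAMILIES[aa]) > 1)
                       for c in SYNONYMOUS_FAMILIES[aa]]
        assert list(mat.columns) == fams_sorted
        assert mat.loc["g1", "CTG"] == pytest.approx(6.0)
        assert math.isnan(mat.loc["g1", "GGG"])  # unused family exported as NA

    def test_enc_plot_table_has_observed_and_curve(self):
        tab = enc_plot_table(batch_summary(random_genes(3, seed=25)), curve_points=11)
        assert (tab["kind"] == "observed").sum() == 3
        assert (tab["kind"] == "expected").sum() == 11
        mid = tab[(tab.kind == "expected") & (tab.gc3s == 0.5)]
        assert mid["enc"].iloc[0] == pytest.approx(60.5)


def test_full_pipeline_agrees_with_bruteforce_on_small_genes():
    """End-to-end index agreement with enumerate-everything oracles."""
    for gid, seq in simulate_cds(20, 60, 0.8, 1.5, seed=30):
        s = summarize_gene(seq, gid)
        t = count_codons(seq, gid)
        assert s.enc == pytest.approx(oracle_enc(t.counts), abs=1e-9)
        expected_rscu = oracle_rscu(t.counts)
        for c, v in s.rscu.items():
            if not math.isnan(v):
                assert v == pytest.approx(expected_rscu[c], abs=1e-9)
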