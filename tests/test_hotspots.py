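"""Cis/trans classification, top-SNP selection, the three hotspot tiers,
effect-direction concordance, and sign-divergence tabulation."""

import numpy as np
import pandas as pd
import pytest

from teqhot import hotspots as hs
from tests.conftest import make_assoc


@pytest.fixture
def one_gene_panel():
    return pd.DataFrame([{
        "gene": "gA", "chrom": "1", "start": 100_000, "end": 105_000,
        "strand": "+", "tss": 100_000, "branch": "porphyrin",
    }])


def rec(snp_pos, gene="gA", tissue="T1", beta=1.0, p=1e-5, chrom="1"):
    return (f"{chrom}-{snp_pos}", chrom, snp_pos, gene, tissue, beta, p)


class TestClassify:
    @pytest.mark.parametrize("pos,expected_class,expected_dist", [
        (60_000, hs.CIS, 40_000),          # within 50 kb of the gene start
        (1_200_000, hs.TRANS, 1_095_000),  # >= 1 Mb from the gene end
        (500_000, hs.PROXIMAL, 395_000),   # the in-between band
        (102_000, hs.CIS, 0),              # inside the gene body
    ])
    def test_distance_rules(self, one_gene_panel, pos, expected_class, expected_dist):
        out = hs.classify_cis_trans(make_assoc([rec(pos)]), one_gene_panel)
        assert out["class"].iloc[0] == expected_class
        assert out["distance"].iloc[0] == expected_dist

    def test_different_chromosome_is_trans(self, one_gene_panel):
        out = hs.classify_cis_trans(make_assoc([rec(100_000, chrom="9")]),
                                    one_gene_panel)
        assert out["class"].iloc[0] == hs.TRANS
        assert np.isnan(out["distance"].iloc[0])

    def test_classes_partition_table(self, one_gene_panel):
        rng = np.random.default_rng(0)
        rows = [rec(int(p)) for p in rng.integers(1, 3_000_000, size=200)]
        out = hs.classify_cis_trans(make_assoc(rows), one_gene_panel)
        assert set(out["class"]) <= {hs.CIS, hs.TRANS, hs.PROXIMAL}
        assert out["class"].notna().all() and len(out) == 200

    def test_unknown_gene_errors(self, one_gene_panel):
        with pytest.raises(KeyError, match="gB"):
            hs.classify_cis_trans(make_assoc([rec(1, gene="gB")]), one_gene_panel)


class TestTopSnps:
    def test_lowest_p_wins_within_window(self):
        table = make_assoc([rec(10_000, p=1e-5), rec(20_000, p=1e-6)])
        out = hs.select_top_snps(table)
        assert list(out["pos"]) == [20_000]

    def test_tie_breaks_to_smaller_position(self):
        table = make_assoc([rec(20_000, p=1e-6), rec(10_000, p=1e-6)])
        out = hs.select_top_snps(table)
        assert list(out["pos"]) == [10_000]

    def test_window_tiling_boundary(self):
        # 240,000 and 260,000 fall in different 250 kb tiles: both kept
        table = make_assoc([rec(240_000, p=1e-5), rec(260_000, p=1e-5)])
        out = hs.select_top_snps(table)
        assert sorted(out["pos"]) == [240_000, 260_000]

    def test_top_snp_p_is_window_minimum(self):
        rng = np.random.default_rng(1)
        rows = [rec(int(pos), gene=g, p=float(p))
                for g in ("gA", "gB")
                for pos, p in zip(rng.integers(1, 1_000_000, 40),
                                  rng.uniform(1e-8, 1e-4, 40))]
        table = make_assoc(rows)
        out = hs.select_top_snps(table)
        w = 250_000
        for row in out.itertuples():
            window = table[(table["gene"] == row.gene)
                           & (table["pos"] // w == row.pos // w)]
            assert row.p_value <= window["p_value"].min() + 0.0

    def test_empty_in_empty_out(self):
        out = hs.select_top_snps(make_assoc([]))
        assert out.empty


class TestHotSnps:
    def test_eight_genes_is_hot(self):
        rows = [rec(50_000, gene=f"g{i}", p=5e-5) for i in range(8)]
        calls = hs.detect_hot_snps(make_assoc(rows))
        assert len(calls) == 1 and calls[0].n_genes == 8
        assert calls[0].tier == "hot_snp" and calls[0].snp == "1-50000"

    def test_seven_significant_is_not_hot(self):
        rows = [rec(50_000, gene=f"g{i}", p=5e-5) for i in range(7)]
        rows.append(rec(50_000, gene="g7", p=2e-4))  # above the cutoff
        assert hs.detect_hot_snps(make_assoc(rows)) == []

    def test_gene_counting_is_distinct(self):
        # duplicate associations to one gene count once
        rows = [rec(50_000, gene="g0", p=5e-5)] * 5
        rows += [rec(50_000, gene=f"g{i}", p=5e-5) for i in range(1, 8)]
        calls = hs.detect_hot_snps(make_assoc(rows))
        assert len(calls) == 1 and calls[0].n_genes == 8


class TestHotTopSnps:
    def _top(self, rows):
        t = make_assoc(rows)
        t["window_index"] = t["pos"] // 250_000
        return t

    def test_position_topping_eight_genes(self):
        top = self._top([rec(9_000, gene=f"g{i}") for i in range(8)])
        calls = hs.detect_hot_top_snps(top)
        assert len(calls) == 1 and calls[0].tier == "hot_top_snp"

    def test_counting_is_per_tissue(self):
        rows = [rec(9_000, gene=f"g{i}", tissue="T1") for i in range(5)]
        rows += [rec(9_000, gene=f"g{i}", tissue="T2") for i in range(5, 8)]
        assert hs.detect_hot_top_snps(self._top(rows)) == []

    def test_hot_top_snps_subset_of_hot_snps(self):
        # random trans tables: every hot top SNP position is also a hot SNP
        rng = np.random.default_rng(5)
        for _ in range(10):
            rows = [rec(int(rng.choice([10_000, 20_000, 400_000])),
                        gene=f"g{rng.integers(12)}", p=5e-5)
                    for _ in range(60)]
            table = make_assoc(rows).drop_duplicates(["snp", "gene"])
            hot = {(c.snp, c.tissue) for c in hs.detect_hot_snps(table)}
            top = hs.select_top_snps(table)
            hot_top = {(c.snp, c.tissue) for c in hs.detect_hot_top_snps(top)}
            assert hot_top <= hot


class TestHotspotWindows:
    def _top(self, rows):
        t = make_assoc(rows)
        t["window_index"] = t["pos"] // 250_000
        return t

    def test_eight_genes_one_window(self):
        top = self._top([rec(5_000 + 4_000 * i, gene=f"g{i}") for i in range(8)])
        calls = hs.detect_hotspot_windows(top)
        assert len(calls) == 1
        call = calls[0]
        assert (call.tier, call.start, call.end) == ("window_hotspot", 0, 40_000)

    def test_split_across_windows_no_call(self):
        rows = [rec(30_000 + 1_000 * i, gene=f"g{i}") for i in range(4)]
        rows += [rec(50_000 + 1_000 * i, gene=f"g{i + 4}") for i in range(4)]
        assert hs.detect_hotspot_windows(self._top(rows)) == []

    def test_maize_scale_window_count(self):
        # a 2.5 Gb genome tiles into 62,500 exclusive 40 kb windows
        lengths = {str(i): 250_000_000 for i in range(1, 11)}
        assert hs.n_windows_in_genome(lengths, window_kb=40) == 62_500

    def test_remainder_window_counts(self):
        assert hs.n_windows_in_genome({"1": 100_001}, window_kb=40) == 3

    def test_shift_by_window_multiple_preserves_calls(self):
        rows = [rec(5_000 + 4_000 * i, gene=f"g{i}") for i in range(8)]
        top = self._top(rows)
        shifted = top.copy()
        shifted["pos"] += 3 * 40_000
        a = hs.detect_hotspot_windows(top)
        b = hs.detect_hotspot_windows(shifted)
        assert len(a) == len(b) == 1
        assert b[0].start == a[0].start + 3 * 40_000
        assert a[0].genes == b[0].genes

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        rows = [rec(int(rng.integers(1, 200_000)), gene=f"g{rng.integers(12)}")
                for _ in range(50)]
        top = self._top(rows).drop_duplicates(["snp", "gene"])
        base = hs.detect_hotspot_windows(top)
        perm = hs.detect_hotspot_windows(top.sample(frac=1, random_state=3))
        assert [(c.chrom, c.start, c.genes) for c in base] == \
               [(c.chrom, c.start, c.genes) for c in perm]


class TestEffectMatrix:
    @staticmethod
    def _call(tag, effects, tissue="T1"):
        return hs.HotspotCall(tier="hot_snp", chrom="1", start=tag, end=tag,
                              tissue=tissue, genes=tuple(sorted(effects)),
                              signed_effects=effects, snp=f"1-{tag}")

    def test_all_positive_concordant(self):
        mat, conc, _ = hs.effect_direction_matrix(
            [self._call(1, {"gA": 0.5, "gB": 1.2})])
        assert conc.all()

    def test_one_negative_flags_divergent_gene(self):
        mat, conc, _ = hs.effect_direction_matrix(
            [self._call(1, {"gA": 0.5, "gB": -0.3, "gC": 0.8})])
        assert not conc.iloc[0]
        row = mat.iloc[0]
        assert list(row[row < 0].index) == ["gB"]

    def test_identical_rows_adjacent_in_dendrogram_order(self):
        eff = {"gA": 0.5, "gB": 0.5}
        calls = [self._call(1, eff), self._call(99, {"gA": -3.0, "gB": 4.0}),
                 self._call(2, eff)]
        _, _, order = hs.effect_direction_matrix(calls)
        i1, i2 = order.index("hot_snp:1:1-1:T1"), order.index("hot_snp:1:2-2:T1")
        assert abs(i1 - i2) == 1

    def test_empty_calls_error(self):
        with pytest.raises(ValueError):
            hs.effect_direction_matrix([])


class TestDivergence:
    @staticmethod
    def _window_call(tissue="T1"):
        return hs.HotspotCall(tier="window_hotspot", chrom="1", start=0,
                              end=40_000, tissue=tissue,
                              genes=("gA", "gB", "gC"))

    def test_focal_opposite_everywhere_fraction_one(self):
        rows = [rec(5_000, gene="focal", beta=-1.0),
                rec(5_000, gene="gB", beta=1.0),
                rec(5_000, gene="gC", beta=0.7)]
        table, summary = hs.divergence_tabulation(
            [self._window_call()], make_assoc(rows), "focal")
        assert summary == {"T1": 1.0}

    def test_single_other_gene_excluded(self):
        rows = [rec(5_000, gene="focal", beta=-1.0),
                rec(5_000, gene="gB", beta=1.0)]
        table, summary = hs.divergence_tabulation(
            [self._window_call()], make_assoc(rows), "focal")
        assert table.empty and summary == {}

    def test_snp_outside_window_excluded(self):
        rows = [rec(90_000, gene="focal", beta=-1.0),
                rec(90_000, gene="gB", beta=1.0),
                rec(90_000, gene="gC", beta=1.0)]
        table, _ = hs.divergence_tabulation(
            [self._window_call()], make_assoc(rows), "focal")
        assert table.empty

    def test_missing_focal_gene_errors(self):
        with pytest.raises(KeyError, match="nope"):
            hs.divergence_tabulation([self._window_call()],
                                     make_assoc([rec(1)]), "nope")
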