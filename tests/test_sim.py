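"""Synthetic-data generator: determinism, sampling distributions, planted
architecture, and file round trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from teqhot import genotypes as gtio
from teqhot import sim
from teqhot.sim import (
    PhenotypeSimSpec,
    PlantedRegulator,
    SimConfig,
    simulate_expression,
    simulate_gene_panel,
    simulate_genotypes,
    simulate_phenotypes,
)


def small_config(**kw):
    defaults = dict(n_lines=50, n_chromosomes=3, chrom_length_bp=2_000_000,
                    n_snps=60, n_panel_genes=9, cis_effect_sd=0.0,
                    noise_sd=0.0, seed=11)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestGenotypes:
    def test_same_seed_bit_identical(self):
        a = simulate_genotypes(small_config())
        b = simulate_genotypes(small_config())
        np.testing.assert_array_equal(a.dosage, b.dosage)
        pd.testing.assert_frame_equal(a.snp_map, b.snp_map)

    def test_different_seed_differs(self):
        a = simulate_genotypes(small_config(seed=1))
        b = simulate_genotypes(small_config(seed=2))
        assert not np.array_equal(a.dosage, b.dosage)

    def test_allele_frequency_matches_binomial_sampling(self):
        # at f = 0.5 the empirical alt frequency is Binomial(2n, 0.5)/2n;
        # each of 30 SNPs should land within 3 binomial SEs of 0.5
        cfg = small_config(n_lines=10_000, n_snps=30, maf_range=(0.5, 0.5))
        gt = simulate_genotypes(cfg)
        f = gt.alt_freq()
        se = np.sqrt(0.5 * 0.5 / (2 * cfg.n_lines))
        assert np.all(np.abs(f - 0.5) <= 3 * se)

    def test_forced_frequency_one_gives_all_twos(self):
        rng = np.random.default_rng(0)
        d = sim._draw_dosages(rng, np.array([1.0]), n_lines=2)
        assert (d == 2).all()

    def test_dosages_in_range_and_positions_increasing(self):
        gt = simulate_genotypes(small_config(seed=3))
        assert set(np.unique(gt.dosage)) <= {0, 1, 2}
        for _, grp in gt.snp_map.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing
            assert grp["pos"].is_unique

    def test_too_many_snps_errors_with_limit(self):
        cfg = small_config(chrom_length_bp=10, n_snps=60)
        with pytest.raises(ValueError, match="length 10"):
            simulate_genotypes(cfg)


class TestGenePanel:
    def test_single_gene_plus_strand_tss(self):
        panel = simulate_gene_panel(small_config(n_panel_genes=1, n_chromosomes=1))
        assert len(panel) == 1
        rec = panel.iloc[0]
        assert rec["strand"] == "+" and rec["tss"] == rec["start"] < rec["end"]

    def test_minus_strand_tss_is_end(self):
        panel = simulate_gene_panel(small_config(n_panel_genes=4, n_chromosomes=1))
        minus = panel[panel["strand"] == "-"]
        assert len(minus) > 0
        assert (minus["tss"] == minus["end"]).all()

    def test_70_genes_10_chromosomes_disjoint(self):
        panel = simulate_gene_panel(SimConfig(n_panel_genes=70, n_chromosomes=10))
        for _, grp in panel.groupby("chrom"):
            ivals = sorted(zip(grp["start"], grp["end"]))
            for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
                assert e1 < s2, "gene bodies overlap"

    def test_branches_cycle(self):
        panel = simulate_gene_panel(small_config(n_panel_genes=9))
        assert list(panel["branch"][:6]) == list(sim.BRANCHES)

    def test_genome_too_small_errors(self):
        with pytest.raises(ValueError, match="genome too small"):
            simulate_gene_panel(small_config(chrom_length_bp=5_000, n_panel_genes=9))


class TestExpression:
    def test_no_effects_no_noise_constant(self):
        cfg = small_config()
        gt = simulate_genotypes(cfg)
        panel = simulate_gene_panel(cfg)
        expr = simulate_expression(gt, panel, cfg, "L3Base")
        assert (expr.to_numpy() == 0).all()

    def test_noiseless_regulator_equals_dosage(self):
        cfg = small_config()
        gt = simulate_genotypes(cfg)
        panel = simulate_gene_panel(cfg)
        reg = PlantedRegulator(snp_index=5, effect_sizes={"g001": 1.0})
        cfg = dataclasses.replace(cfg, regulator_spec=(reg,))
        expr = simulate_expression(gt, panel, cfg, "L3Base")
        np.testing.assert_allclose(expr.loc["g001"].to_numpy(),
                                   gt.dosage[:, 5].astype(float))
        assert (expr.drop(index="g001").to_numpy() == 0).all()

    def test_noiseless_linear_in_all_planted_dosages(self):
        # exact superposition of cis and trans terms at machine precision
        cfg = small_config(cis_effect_sd=0.7)
        gt = simulate_genotypes(cfg)
        panel = simulate_gene_panel(cfg)
        reg = PlantedRegulator(snp_index=2, effect_sizes={"g000": -0.4, "g003": 0.9})
        cfg = dataclasses.replace(cfg, regulator_spec=(reg,))
        expr, cis = simulate_expression(gt, panel, cfg, "x", return_truth=True)
        expected = np.zeros(expr.shape)
        gene_pos = {g: i for i, g in enumerate(panel["gene"])}
        for rec in cis.itertuples():
            if rec.cis_snp_index >= 0:
                expected[gene_pos[rec.gene]] += rec.cis_effect * gt.dosage[:, rec.cis_snp_index]
        for g, b in reg.effect_sizes.items():
            expected[gene_pos[g]] += b * gt.dosage[:, 2]
        np.testing.assert_array_equal(expr.to_numpy(), expected)

    def test_sign_flip_only_in_designated_tissue(self):
        cfg = small_config()
        gt = simulate_genotypes(cfg)
        panel = simulate_gene_panel(cfg)
        reg = PlantedRegulator(snp_index=1, effect_sizes={"g000": 0.5, "g001": 0.5},
                               sign_flip_genes=frozenset({"g000"}),
                               flip_tissue="LMAD")
        cfg = dataclasses.replace(cfg, regulator_spec=(reg,))
        day = simulate_expression(gt, panel, cfg, "LMAD")
        night = simulate_expression(gt, panel, cfg, "LMAN")
        np.testing.assert_array_equal(day.loc["g000"], -night.loc["g000"])
        np.testing.assert_array_equal(day.loc["g001"], night.loc["g001"])

    def test_missing_regulator_snp_errors(self):
        cfg = small_config()
        gt = simulate_genotypes(cfg)
        panel = simulate_gene_panel(cfg)
        reg = PlantedRegulator(snp_index=10_000, effect_sizes={"g000": 1.0})
        cfg = dataclasses.replace(cfg, regulator_spec=(reg,))
        with pytest.raises(ValueError, match="does not exist"):
            simulate_expression(gt, panel, cfg, "x")

    def test_zero_effect_regulator_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            PlantedRegulator(snp_index=0, effect_sizes={"g000": 0.0})


class TestPhenotypes:
    def test_no_effect_no_noise_equals_mean(self):
        gt = simulate_genotypes(small_config())
        spec = PhenotypeSimSpec(focal_snp=0, mutant_effect=0.0, wt_effect=0.0,
                                trait_mean=30.0, trait_sd=0.0)
        ph = simulate_phenotypes(gt, spec, seed=1)
        for col in ("MT_CCMI", "WT_CCMI", "MT_CCMII", "WT_CCMII"):
            assert (ph[col] == 30.0).all()

    def test_mutant_only_effect(self):
        # wild type is invariant to dosage; mutant increases with it
        gt = simulate_genotypes(small_config())
        spec = PhenotypeSimSpec(focal_snp=3, mutant_effect=5.0, trait_sd=0.0)
        ph = simulate_phenotypes(gt, spec, seed=1)
        d = gt.dosage[:, 3]
        assert ph["WT_CCMI"].nunique() == 1
        mt_by_dosage = ph.groupby(d)["MT_CCMI"].mean()
        assert mt_by_dosage.is_monotonic_increasing and mt_by_dosage.nunique() > 1

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeSimSpec(focal_snp=0, mutant_effect=1.0, trait_sd=-1.0)


class TestTransCandidates:
    def test_candidates_are_trans_to_all_targets(self):
        cfg = small_config(n_snps=200, cis_effect_sd=0.0)
        gt = simulate_genotypes(cfg)
        panel = simulate_gene_panel(cfg)
        targets = list(panel["gene"][:4])
        pool = sim.trans_snp_candidates(gt, panel, targets, min_maf=0.0)
        tpanel = panel[panel["gene"].isin(targets)]
        for j in pool:
            chrom, pos = gt.snp_map.loc[j, ["chrom", "pos"]]
            for rec in tpanel.itertuples():
                if str(rec.chrom) == str(chrom):
                    d = min(abs(pos - rec.start), abs(pos - rec.end))
                    assert d >= 1_000_000

    def test_unknown_target_errors(self):
        cfg = small_config()
        gt = simulate_genotypes(cfg)
        panel = simulate_gene_panel(cfg)
        with pytest.raises(ValueError, match="absent"):
            sim.trans_snp_candidates(gt, panel, ["nope"])


class TestWriters:
    def test_vcf_round_trip_via_pysam(self, tmp_path):
        cfg = small_config(n_snps=20)
        gt = simulate_genotypes(cfg)
        path = tmp_path / "g.vcf"
        gtio.write_vcf(gt, path, cfg.chrom_lengths)
        back = gtio.read_vcf(path)
        np.testing.assert_array_equal(back.dosage, gt.dosage)
        assert list(back.snp_map["pos"]) == list(gt.snp_map["pos"])
        assert back.line_ids == gt.line_ids

    def test_dosage_tsv_round_trip(self, tmp_path):
        gt = simulate_genotypes(small_config(n_snps=10))
        path = tmp_path / "g.tsv"
        gtio.write_dosage_tsv(gt, path)
        back = gtio.read_dosage_tsv(path)
        np.testing.assert_array_equal(back.dosage, gt.dosage)
        assert list(back.snp_map["snp"]) == list(gt.snp_map["snp"])

    def test_panel_bed_round_trip(self, tmp_path):
        panel = simulate_gene_panel(small_config())
        path = tmp_path / "p.bed"
        sim.write_panel_bed(panel, path)
        back = sim.read_panel_bed(path)
        pd.testing.assert_frame_equal(back, panel[back.columns])

    def test_gff3_has_header_and_branch_attrs(self, tmp_path):
        panel = simulate_gene_panel(small_config(n_panel_genes=3))
        path = tmp_path / "p.gff3"
        sim.write_panel_gff3(panel, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        assert len(lines) == 4
        assert "ID=g000;branch=porphyrin" in lines[1]

    def test_phenotype_tsv_round_trip(self, tmp_path):
        gt = simulate_genotypes(small_config())
        ph = simulate_phenotypes(
            gt, PhenotypeSimSpec(focal_snp=0, mutant_effect=1.0), seed=4)
        path = tmp_path / "ph.tsv"
        sim.write_phenotypes_tsv(ph, path)
        back = sim.read_phenotypes_tsv(path)
        pd.testing.assert_frame_equal(back, ph)
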