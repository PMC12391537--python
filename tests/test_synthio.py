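"""Synthetic-data generator: distributional contracts and determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spliceqtl import synthio as si
from spliceqtl.junctions import read_junc, write_junc


class TestConfigValidation:
    def test_zero_maf_rejected(self):
        with pytest.raises(ValueError, match="maf_range"):
            si.SynthConfig(maf_range=(0.0, 0.3))

    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError):
            si.SynthConfig(prop_sqtl_genes=1.2)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            si.SynthConfig(n_samples=1)


class TestSimulateGenotypes:
    def test_allele_frequency_matches_request(self):
        cfg = si.SynthConfig(n_samples=800, n_genes=4, maf_range=(0.3, 0.3), ld_rho=0.0, seed=1)
        g = si.simulate_genotypes(cfg)
        af = g.allele_freq()
        # binomial sampling error on 2*800 draws: sd ~ 0.0115
        assert np.all(np.abs(af - 0.3) < 5 * np.sqrt(0.3 * 0.7 / 1600))

    def test_hwe_holds_marginally(self):
        cfg = si.SynthConfig(n_samples=5000, n_genes=2, maf_range=(0.3, 0.3), ld_rho=0.4, seed=2)
        g = si.simulate_genotypes(cfg)
        assert (g.hwe_pvalues() > 1e-3).all()

    def test_ld_between_adjacent_variants(self):
        cfg = si.SynthConfig(n_samples=3000, n_genes=1, ld_rho=0.8, maf_range=(0.4, 0.4), seed=3)
        g = si.simulate_genotypes(cfg)
        d = g.dosages.to_numpy(float)
        rs = [np.corrcoef(d[i], d[i + 1])[0, 1] for i in range(len(d) - 1)]
        assert 0.5 < np.mean(rs) < 0.9

    def test_deterministic_under_seed(self):
        cfg = si.SynthConfig(n_samples=50, n_genes=3, seed=9)
        a = si.simulate_genotypes(cfg)
        b = si.simulate_genotypes(cfg)
        pd.testing.assert_frame_equal(a.dosages, b.dosages)


class TestSimulateJunctionCounts:
    def test_null_genes_show_no_dosage_trend(self):
        cfg = si.SynthConfig(n_samples=150, n_genes=200, n_conditions=1,
                             prop_sqtl_genes=0.0, seed=4)
        g = si.simulate_genotypes(cfg)
        truth = si.make_truth_table(cfg, g)
        tab = si.simulate_junction_counts(cfg, g, truth)["Ctrl"]
        gm = si.gene_of_intron(cfg, truth)
        slopes = []
        for gene in truth.index:
            introns = gm.index[gm == gene]
            counts = tab.counts.loc[introns].to_numpy(float)
            totals = counts.sum(axis=0)
            ok = totals > 0
            iur = counts[0, ok] / totals[ok]
            dosage = g.dosages.loc[f"{gene}_v000"].to_numpy(float)[ok]
            if dosage.std() == 0:
                continue
            slopes.append(np.polyfit(dosage, iur, 1)[0])
        mean = np.mean(slopes)
        mc_se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(mean) < 3 * mc_se + 1e-4

    def test_target_intron_usage_monotone_in_dosage(self):
        cfg = si.SynthConfig(n_samples=500, n_genes=6, n_conditions=1,
                             prop_sqtl_genes=1.0, effect_size=0.75,
                             target_baseline_usage=0.3, seed=5)
        g = si.simulate_genotypes(cfg)
        truth = si.make_truth_table(cfg, g)
        tab = si.simulate_junction_counts(cfg, g, truth)["Ctrl"]
        gm = si.gene_of_intron(cfg, truth)
        for gene in truth.index:
            introns = gm.index[gm == gene]
            counts = tab.counts.loc[introns].to_numpy(float)
            totals = counts.sum(axis=0)
            tgt = si.target_intron_id(cfg, truth, gene)
            iur = tab.counts.loc[tgt].to_numpy(float) / np.where(totals > 0, totals, np.nan)
            dosage = g.dosages.loc[truth.loc[gene, "causal_variant_id"]].to_numpy(float)
            sign = np.sign(truth.loc[gene, "effect_size"])
            means = [np.nanmean(iur[dosage == d]) for d in (0, 1, 2)]
            oriented = means if sign > 0 else means[::-1]
            assert oriented[0] <= oriented[1] <= oriented[2]

    def test_large_concentration_approaches_multinomial(self):
        base = dict(n_samples=400, n_genes=3, n_conditions=1, prop_sqtl_genes=0.0,
                    introns_per_cluster=(2, 2), depth_mean=200.0, depth_dispersion=1e6)
        cfg_dm = si.SynthConfig(**base, concentration=5.0, seed=6)
        cfg_mn = si.SynthConfig(**base, concentration=1e6, seed=6)
        for cfg, overdispersed in ((cfg_dm, True), (cfg_mn, False)):
            g = si.simulate_genotypes(cfg)
            truth = si.make_truth_table(cfg, g)
            tab = si.simulate_junction_counts(cfg, g, truth)["Ctrl"]
            gm = si.gene_of_intron(cfg, truth)
            gene = truth.index[0]
            introns = gm.index[gm == gene]
            counts = tab.counts.loc[introns].to_numpy(float)
            totals = counts.sum(axis=0)
            phat = counts[0] / totals
            pbar = counts[0].sum() / totals.sum()
            mult_var = np.mean(pbar * (1 - pbar) / totals)
            ratio = phat.var() / mult_var
            if overdispersed:
                assert ratio > 2.0
            else:
                assert ratio < 1.5

    def test_deterministic_and_roundtrip(self, tiny_scenario, tmp_path):
        cfg = tiny_scenario["config"]
        tabs2 = si.simulate_junction_counts(
            cfg, tiny_scenario["genotypes"], tiny_scenario["truth"]
        )
        tab = tiny_scenario["tables"]["Ctrl"]
        pd.testing.assert_frame_equal(tab.counts, tabs2["Ctrl"].counts)
        # .junc round trip for one sample
        sample = tab.samples[0]
        write_junc(tab, tmp_path / "s.junc", sample)
        back = read_junc(tmp_path / "s.junc", sample=sample)
        nz = tab.counts[tab.counts[sample] > 0][sample]
        assert back.counts[sample].sort_index().to_dict() == nz.sort_index().to_dict()

    def test_unknown_gene_in_truth_rejected(self, tiny_scenario):
        cfg = tiny_scenario["config"]
        truth = tiny_scenario["truth"].copy()
        truth.loc["G9999"] = truth.iloc[0]
        with pytest.raises(ValueError, match="unknown"):
            si.simulate_junction_counts(cfg, tiny_scenario["genotypes"], truth)


class TestSimulateGwasStats:
    def test_null_zscores_standard_normal(self):
        cfg = si.SynthConfig(n_samples=50, n_genes=120, variants_per_gene=20,
                             prop_sqtl_genes=0.0, gwas_n=2000, seed=8)
        g = si.simulate_genotypes(cfg)
        truth = si.make_truth_table(cfg, g)
        gw = si.simulate_gwas_stats(cfg, truth, g)
        z = np.concatenate([s.table["beta"] / s.table["se"] for s in gw.values()])
        assert len(z) >= 2000
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_causal_chisq_matches_noncentrality(self):
        cfg = si.SynthConfig(n_samples=50, n_genes=30, prop_sqtl_genes=1.0,
                             gwas_scenario_mix=(0.0, 0.0, 1.0), gwas_n=10_000,
                             gwas_var_explained=0.01, seed=10)
        g = si.simulate_genotypes(cfg)
        truth = si.make_truth_table(cfg, g)
        gw = si.simulate_gwas_stats(cfg, truth, g)
        chis = []
        for gene, s in gw.items():
            vid = truth.loc[gene, "gwas_causal_variant_id"]
            row = s.table[s.table["id"] == vid].iloc[0]
            chis.append((row["beta"] / row["se"]) ** 2)
        expect = 1 + 10_000 * 0.01
        se_mc = np.std(chis) / np.sqrt(len(chis))
        assert np.mean(chis) == pytest.approx(expect, abs=4 * se_mc + 5)

    def test_h4_rows_share_causal_variant(self, tiny_scenario):
        truth = tiny_scenario["truth"]
        h4 = truth[truth["gwas_scenario"] == "H4"]
        assert (h4["gwas_causal_variant_id"] == h4["causal_variant_id"]).all()
        h3 = truth[truth["gwas_scenario"] == "H3"]
        assert (h3["gwas_causal_variant_id"] != h3["causal_variant_id"]).all()

    def test_zero_variance_explained_rejected(self):
        cfg = si.SynthConfig(n_samples=50, n_genes=10, prop_sqtl_genes=1.0,
                             gwas_scenario_mix=(0.0, 0.0, 1.0), gwas_var_explained=0.0,
                             seed=11)
        g = si.simulate_genotypes(cfg)
        truth = si.make_truth_table(cfg, g)
        with pytest.raises(ValueError, match="variance explained"):
            si.simulate_gwas_stats(cfg, truth, g)


class TestRoundTrips:
    def test_truth_roundtrip(self, tiny_scenario, tmp_path):
        truth = tiny_scenario["truth"]
        si.write_truth(truth, tmp_path / "t.tsv", tmp_path / "t.json")
        back = si.read_truth(tmp_path / "t.tsv")
        assert back["sqtl_flag"].equals(truth["sqtl_flag"])
        assert back["causal_variant_id"].equals(truth["causal_variant_id"].astype(str))
        assert np.allclose(back["effect_size"], truth["effect_size"])

    def test_dosage_tsv_roundtrip(self, tiny_scenario, tmp_path):
        g = tiny_scenario["genotypes"]
        g.write_dosage_tsv(tmp_path / "d.tsv")
        back = type(g).read_dosage_tsv(tmp_path / "d.tsv")
        assert np.array_equal(back.dosages.to_numpy(), g.dosages.to_numpy())
        assert list(back.variants["pos"]) == list(g.variants["pos"])

    def test_vcf_is_valid_text(self, tiny_scenario, tmp_path):
        si.write_vcf(tiny_scenario["genotypes"], tmp_path / "g.vcf")
        lines = (tmp_path / "g.vcf").read_text().splitlines()
        assert lines[0].startswith("##fileformat")
        header = [l for l in lines if l.startswith("#CHROM")][0]
        assert len(header.split("\t")) == 9 + len(tiny_scenario["genotypes"].samples)


class TestExchangeability:
    def test_null_cluster_counts_exchangeable_within_genotype(self, tiny_scenario):
        # permutation p-values on null genes should not concentrate near 0
        cfg = si.SynthConfig(n_samples=80, n_genes=30, n_conditions=1,
                             prop_sqtl_genes=0.0, seed=12)
        g = si.simulate_genotypes(cfg)
        truth = si.make_truth_table(cfg, g)
        tab = si.simulate_junction_counts(cfg, g, truth)["Ctrl"]
        gm = si.gene_of_intron(cfg, truth)
        rng = np.random.default_rng(0)
        ps = []
        for gene in truth.index:
            introns = gm.index[gm == gene]
            counts = tab.counts.loc[introns].to_numpy(float)
            totals = counts.sum(axis=0)
            ok = totals > 0
            iur = counts[0, ok] / totals[ok]
            dosage = g.dosages.loc[f"{gene}_v000"].to_numpy(float)[ok]
            obs = abs(np.corrcoef(iur, dosage)[0, 1])
            hits = sum(
                abs(np.corrcoef(iur, rng.permutation(dosage))[0, 1]) >= obs
                for _ in range(99)
            )
            ps.append((1 + hits) / 100)
        assert stats.kstest(ps, "uniform").pvalue > 0.001
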