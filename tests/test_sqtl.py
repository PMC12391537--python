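"""Genotype QC, cis windows, association scans, grouped permutations, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from spliceqtl import sqtl as sq
from spliceqtl.normalize import CovariateTable


def geno(dosage_rows, pos=None, chrom="chr1", **meta_cols):
    d = pd.DataFrame(np.asarray(dosage_rows, float))
    d.index = [f"v{k}" for k in range(d.shape[0])]
    d.columns = [f"s{k}" for k in range(d.shape[1])]
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": pos or list(range(1, d.shape[0] + 1)), **meta_cols},
        index=d.index,
    )
    return sq.GenotypeMatrix(dosages=d, variants=variants)


def empty_cov(n):
    return CovariateTable.empty([f"s{k}" for k in range(n)])


class TestQcGenotypes:
    def test_low_maf_removed(self):
        # MAF 0.04 in 50 samples: four heterozygotes
        row = [1] * 4 + [0] * 46
        g = geno([row, [0, 1, 2] * 16 + [1, 1]])
        out = sq.qc_genotypes(g)
        assert "v0" not in out.variants.index

    def test_hwe_outlier_removed(self):
        # all heterozygotes: maximal HWE departure
        n = 200
        bad = [1] * n
        rng = np.random.default_rng(0)
        good = rng.binomial(2, 0.4, size=n)
        out = sq.qc_genotypes(geno([bad, good]))
        assert list(out.variants.index) == ["v1"]

    def test_missingness_removed(self):
        rng = np.random.default_rng(2)
        row = rng.binomial(2, 0.3, size=1000).astype(float)
        row_missing = row.copy()
        row_missing[:2] = np.nan  # missingness 0.002 > 0.001
        out = sq.qc_genotypes(geno([row_missing, row]))
        assert list(out.variants.index) == ["v1"]

    def test_info_filter(self):
        rng = np.random.default_rng(1)
        rows = rng.binomial(2, 0.3, size=(2, 400))
        g = geno(list(rows), info=[0.3, 0.9])
        out = sq.qc_genotypes(g)
        assert list(out.variants.index) == ["v1"]


class TestCisWindow:
    @pytest.mark.parametrize("offset,included", [(1_000_000, True), (1_000_001, False), (-1_000_000, True)])
    def test_boundary_inclusive(self, offset, included):
        g = geno([[0, 1, 2]], pos=[5_000_000 + offset])
        got = sq.cis_window_variants(("chr1", 5_000_000), g)
        assert (len(got) == 1) == included

    def test_empty_window(self):
        g = geno([[0, 1, 2]], pos=[10])
        assert len(sq.cis_window_variants(("chr2", 10), g)) == 0


class TestMarginalAssociation:
    def test_exact_linear_relation(self):
        dosage = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2], float)
        y = 0.7 * dosage
        rec = sq.marginal_association(y, dosage, empty_cov(9))
        assert rec.beta == pytest.approx(0.7)
        assert rec.nominal_p < 1e-12

    def test_matches_normal_equations_oracle(self):
        y = np.array([0.2, -0.1, 0.5, 0.3, -0.4, 0.1])
        dosage = np.array([0, 1, 2, 1, 0, 2], float)
        x = np.column_stack([np.ones(6), dosage])
        beta_hat = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta_hat
        sigma2 = resid @ resid / (6 - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(x.T @ x)[1, 1])
        t = beta_hat[1] / se
        p = 2 * stats.t.sf(abs(t), df=4)
        rec = sq.marginal_association(y, dosage, empty_cov(6))
        assert rec.beta == pytest.approx(beta_hat[1])
        assert rec.se == pytest.approx(se)
        assert rec.nominal_p == pytest.approx(p)

    def test_collinear_dosage_skipped(self):
        y = np.random.default_rng(0).standard_normal(8)
        dosage = np.array([0, 1, 2, 1, 0, 2, 1, 1], float)
        cov = CovariateTable(pd.DataFrame({"c": dosage}, index=[f"s{k}" for k in range(8)]))
        assert sq.marginal_association(y, dosage, cov) is None

    def test_constant_dosage_skipped(self):
        y = np.random.default_rng(0).standard_normal(8)
        assert sq.marginal_association(y, np.ones(8), empty_cov(8)) is None


def perm_inputs(n=40, n_introns=2, n_variants=3, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    samples = [f"s{k}" for k in range(n)]
    g = pd.DataFrame(
        rng.binomial(2, 0.4, size=(n_variants, n)).astype(float),
        index=[f"v{k}" for k in range(n_variants)], columns=samples,
    )
    y = rng.standard_normal((n_introns, n))
    y[0] += effect * g.iloc[0].to_numpy()
    usage = pd.DataFrame(y, index=[f"i{k}" for k in range(n_introns)], columns=samples)
    return usage, g, CovariateTable.empty(samples)


class TestGroupedPermutationPass:
    def test_minimum_empirical_p_formula(self):
        usage, g, cov = perm_inputs(n=60, effect=3.0)
        res = sq.grouped_permutation_pass("G", usage, g, cov, n_perm=1000, seed=1)
        assert res.empirical_p == pytest.approx(1 / 1001)

    def test_agrees_with_direct_permutation_oracle(self):
        # single intron, single variant: reduces to a plain label permutation test
        usage, g, cov = perm_inputs(n=30, n_introns=1, n_variants=1, seed=3, effect=0.35)
        res = sq.grouped_permutation_pass("G", usage, g, cov, n_perm=2000, seed=5)
        rng = np.random.default_rng(99)
        y = usage.iloc[0].to_numpy()
        x = g.iloc[0].to_numpy()
        obs = abs(stats.pearsonr(y, x).statistic)
        hits = sum(
            abs(stats.pearsonr(y, rng.permutation(x)).statistic) >= obs - 1e-15
            for _ in range(2000)
        )
        oracle = (1 + hits) / 2001
        assert res.empirical_p == pytest.approx(oracle, abs=0.05)

    def test_invariant_to_intron_order(self):
        usage, g, cov = perm_inputs(n=50, n_introns=3, seed=7)
        a = sq.grouped_permutation_pass("G", usage, g, cov, n_perm=300, seed=2)
        b = sq.grouped_permutation_pass("G", usage.iloc[::-1], g, cov, n_perm=300, seed=2)
        assert a.empirical_p == b.empirical_p
        assert a.min_nominal_p == pytest.approx(b.min_nominal_p)

    def test_deterministic_under_seed_and_gene_order_independent(self):
        usage, g, cov = perm_inputs(n=40, seed=11)
        a = sq.grouped_permutation_pass("GENE_A", usage, g, cov, n_perm=200, seed=9)
        b = sq.grouped_permutation_pass("GENE_A", usage, g, cov, n_perm=200, seed=9)
        assert a.empirical_p == b.empirical_p
        # a different gene id draws a different permutation stream
        c = sq.grouped_permutation_pass("GENE_B", usage, g, cov, n_perm=200, seed=9)
        assert c.empirical_p != a.empirical_p or c.min_nominal_p == a.min_nominal_p

    def test_short_permutation_run_warns(self):
        usage, g, cov = perm_inputs(n=30)
        warnings: list = []
        sq.grouped_permutation_pass("G", usage, g, cov, n_perm=50, seed=0, warnings=warnings)
        assert warnings


class TestQvalueFdr:
    def test_pi0_one_equals_bh(self):
        p = np.random.default_rng(0).uniform(size=100)
        assert sq.qvalue_fdr(p, pi0=1.0) == pytest.approx(
            multipletests(p, method="fdr_bh")[1]
        )

    def test_all_ones(self):
        assert (sq.qvalue_fdr(np.ones(30)) == 1.0).all()

    def test_pi0_estimate_on_mixture(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.uniform(0, 1e-5, 50), rng.uniform(0, 1, 450)])
        # back out the pi0 actually used: q = pi0 * BH
        q = sq.qvalue_fdr(p)
        bh = multipletests(p, method="fdr_bh")[1]
        ratio = q[bh > 0.2] / bh[bh > 0.2]
        pi0 = ratio.mean()
        assert 0.8 <= pi0 <= 1.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sq.qvalue_fdr(np.array([0.0, 0.5]))

    def test_small_sets_fall_back_to_bh(self):
        p = np.random.default_rng(2).uniform(size=10)
        assert sq.qvalue_fdr(p) == pytest.approx(multipletests(p, method="fdr_bh")[1])


class TestPcSweep:
    def test_confounded_data_prefers_pcs(self, tiny_scenario):
        from spliceqtl import normalize as nz, synthio as si
        from spliceqtl.junctions import cluster_introns, compute_iur, filter_junctions

        cfg = tiny_scenario["config"]
        tab = tiny_scenario["tables"]["Ctrl"]
        filt = filter_junctions(tab)
        raw = compute_iur(cluster_introns(filt), filt)
        norm = nz.inverse_normal_transform(
            nz.quantile_normalize(nz.impute_missing(nz.filter_low_information(raw)))
        )
        # plant a strong shared confounder across all introns
        rng = np.random.default_rng(0)
        conf = rng.standard_normal(len(norm.samples))
        vals = norm.values + 1.5 * pd.DataFrame(
            np.outer(np.ones(norm.values.shape[0]), conf),
            index=norm.values.index, columns=norm.values.columns,
        )
        confounded = type(norm)(values=vals, cluster_of=norm.cluster_of, stage="normalized")
        gm = si.gene_of_intron(cfg, tiny_scenario["truth"])
        chosen, counts, _ = sq.pc_sweep(
            confounded, tiny_scenario["genotypes"], CovariateTable.empty(norm.samples),
            gm, cfg.gene_tss(), k_grid=(0, 1), n_perm=100, seed=1,
        )
        assert counts.loc[1] >= counts.loc[0]

    def test_tie_breaks_to_smallest_k(self, tiny_scenario, tiny_normalized):
        from spliceqtl import synthio as si

        cfg = tiny_scenario["config"]
        norm = tiny_normalized["norm"]
        gm = si.gene_of_intron(cfg, tiny_scenario["truth"])
        chosen, counts, _ = sq.pc_sweep(
            norm, tiny_scenario["genotypes"], CovariateTable.empty(norm.samples),
            gm, cfg.gene_tss(), k_grid=(0, 1), n_perm=60, seed=1,
        )
        if counts.loc[0] == counts.max():
            assert chosen == 0
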