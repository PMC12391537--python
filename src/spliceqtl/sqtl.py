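"""cis-sQTL mapping from normalised intron usage ratios.

Each gene's introns form a phenotype group.  Per gene, every intron is tested
against every variant within a ±1 Mb cis-window around the TSS by linear
regression (dosage + covariates); the group-level statistic is the minimum
nominal p over all intron x variant pairs.  Significance is calibrated by
permutations applied to the genotype sample labels — one permutation per
round, shared by every intron of the gene, so the intron-intron correlation
structure is preserved — and gene-level empirical p-values enter a Storey
q-value FDR across genes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .junctions import UsageMatrix
from .normalize import CovariateTable

__all__ = [
    "GenotypeMatrix",
    "AssociationRecord",
    "GenePermResult",
    "qc_genotypes",
    "cis_window_variants",
    "marginal_association",
    "grouped_permutation_pass",
    "qvalue_fdr",
    "map_sqtls",
    "pc_sweep",
]


@dataclass
class GenotypeMatrix:
    """Variants x samples dosage matrix with per-variant metadata.

    ``dosages`` holds allele dosages in [0, 2] (NaN = missing genotype);
    ``variants`` is indexed by variant id with columns chrom, pos and
    optionally info (imputation quality).
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.variants.index):
            raise ValueError("dosages and variants must share an index")

    @property
    def samples(self) -> list[str]:
        return list(self.dosages.columns)

    def allele_freq(self) -> pd.Series:
        return self.dosages.mean(axis=1) / 2.0

    def maf(self) -> pd.Series:
        af = self.allele_freq()
        return np.minimum(af, 1.0 - af)

    def missingness(self) -> pd.Series:
        return self.dosages.isna().mean(axis=1)

    def hwe_pvalues(self) -> pd.Series:
        """Chi-square (1 df) goodness-of-fit of hard genotype counts against
        Hardy-Weinberg proportions p^2 : 2pq : q^2."""
        hard = self.dosages.round().clip(0, 2)
        out = np.ones(len(hard))
        arr = hard.to_numpy(float)
        for i in range(arr.shape[0]):
            g = arr[i][~np.isnan(arr[i])]
            n = len(g)
            if n == 0:
                continue
            counts = np.array([(g == 0).sum(), (g == 1).sum(), (g == 2).sum()], float)
            p = (2 * counts[2] + counts[1]) / (2 * n)
            exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            if (exp < 1e-12).any():
                continue  # monomorphic: HWE trivially satisfied
            chi2 = ((counts - exp) ** 2 / exp).sum()
            out[i] = stats.chi2.sf(chi2, df=1)
        return pd.Series(out, index=self.dosages.index)

    def write_dosage_tsv(self, path) -> None:
        out = self.variants[["chrom", "pos"]].join(self.dosages)
        out.index.name = "variant_id"
        out.to_csv(path, sep="\t")

    @staticmethod
    def read_dosage_tsv(path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        variants = df[["chrom", "pos"]].copy()
        variants["chrom"] = variants["chrom"].astype(str)
        dosages = df.drop(columns=["chrom", "pos"])
        return GenotypeMatrix(dosages=dosages, variants=variants)


@dataclass
class AssociationRecord:
    intron_id: str
    variant_id: str
    beta: float
    se: float
    nominal_p: float
    n: int


@dataclass
class GenePermResult:
    gene_id: str
    best_intron_id: str
    best_variant_id: str
    min_nominal_p: float
    empirical_p: float
    beta_approx_p: float | None = None
    qvalue: float = np.nan
    n_introns: int = 0
    n_variants: int = 0
    beta: float = np.nan


# ---------------------------------------------------------------------------
# Genotype QC and windows


def qc_genotypes(
    g: GenotypeMatrix,
    min_info: float = 0.4,
    max_hwe_p: float = 1e-6,
    min_maf: float = 0.05,
    max_miss: float = 0.001,
) -> GenotypeMatrix:
    """Drop variants with low imputation INFO, Hardy-Weinberg departure
    (chi-square p < ``max_hwe_p``), MAF < ``min_maf`` or missingness above
    ``max_miss``."""
    keep = pd.Series(True, index=g.variants.index)
    if "info" in g.variants.columns:
        keep &= g.variants["info"] >= min_info
    keep &= g.maf() >= min_maf
    keep &= g.missingness() <= max_miss
    keep &= g.hwe_pvalues() >= max_hwe_p
    return GenotypeMatrix(dosages=g.dosages.loc[keep].copy(), variants=g.variants.loc[keep].copy())


def cis_window_variants(
    gene_tss: tuple[str, int], g: GenotypeMatrix, half_width: int = 1_000_000
) -> pd.Index:
    """Variant ids with |pos - TSS| <= half_width on the gene's chromosome
    (both boundaries inclusive)."""
    chrom, tss = gene_tss
    v = g.variants
    mask = (v["chrom"].astype(str) == str(chrom)) & ((v["pos"] - tss).abs() <= half_width)
    return v.index[mask]


# ---------------------------------------------------------------------------
# Association scans


def _residual_block(x: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Residualise rows of x (k x n) against covariate columns + intercept."""
    n = x.shape[1]
    design = np.column_stack([np.ones(n), cov]) if cov.size else np.ones((n, 1))
    q, _ = np.linalg.qr(design)
    return x - (x @ q) @ q.T


def marginal_association(
    y: np.ndarray | pd.Series,
    dosage: np.ndarray | pd.Series,
    covariates: CovariateTable,
    intron_id: str = "",
    variant_id: str = "",
) -> AssociationRecord | None:
    """Single intron-variant linear scan: OLS of normalised usage on dosage
    plus covariates; returns beta, se and the t-test p for the dosage term.
    Constant (or covariate-collinear) dosage yields ``None``."""
    y = np.asarray(y, float)
    g = np.asarray(dosage, float)
    n = len(y)
    cov = covariates.values.to_numpy(float)
    k = cov.shape[1] if cov.size else 0
    if n < k + 3:
        raise ValueError("not enough samples for the model")
    yr = _residual_block(y[None, :], cov)[0]
    gr = _residual_block(g[None, :], cov)[0]
    gss = gr @ gr
    if gss < 1e-12 * max(1.0, g.var() * n):
        return None  # dosage constant or absorbed by covariates
    beta = (gr @ yr) / gss
    dof = n - 2 - k
    resid = yr - beta * gr
    sigma2 = (resid @ resid) / dof
    se = float(np.sqrt(sigma2 / gss))
    tstat = beta / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(tstat), df=dof))
    return AssociationRecord(
        intron_id=intron_id, variant_id=variant_id, beta=float(beta), se=se,
        nominal_p=max(p, np.nextafter(0, 1)), n=n,
    )


def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.sqrt((x**2).sum(axis=1, keepdims=True))
    norms[norms == 0] = np.inf
    return x / norms


def _gene_rng(master_seed: int, gene_id: str) -> np.random.Generator:
    # counter scheme: per-gene stream keyed by (master seed, crc32 of gene id)
    # so results do not depend on gene iteration order
    return np.random.default_rng([master_seed, zlib.crc32(gene_id.encode())])


def _corr_p(r: np.ndarray, dof: int) -> np.ndarray:
    r = np.clip(np.abs(r), 0, 1 - 1e-15)
    t = r * np.sqrt(dof / (1 - r**2))
    return 2 * stats.t.sf(t, df=dof)


def grouped_permutation_pass(
    gene_id: str,
    usage_rows: pd.DataFrame,
    dosages: pd.DataFrame,
    covariates: CovariateTable,
    n_perm: int = 1000,
    seed: int = 0,
    variant_pos: pd.Series | None = None,
    fit_beta: bool = True,
    warnings: list | None = None,
) -> GenePermResult | None:
    """Gene-grouped permutation pass.

    The observed statistic is the minimum nominal p over all intron x variant
    pairs.  Each permutation shuffles the genotype sample labels once and
    applies the same shuffle to every intron of the gene, then records the
    permutation's minimum p.  empirical_p = (1 + #{perm_min <= obs_min}) /
    (n_perm + 1).  A Beta distribution fitted by ML to the permutation minima
    supplies ``beta_approx_p``.

    Best-pair tie-break: smallest nominal p, then smallest variant position,
    then lexicographic intron id.
    """
    if n_perm < 100 and warnings is not None:
        warnings.append(f"{gene_id}: n_perm={n_perm} < 100; empirical p coarse")
    samples = list(usage_rows.columns)
    y = usage_rows.to_numpy(float)
    g = dosages[samples].to_numpy(float)
    n = len(samples)
    cov = covariates.values.reindex(samples).to_numpy(float)
    k = cov.shape[1] if cov.size else 0
    dof = n - 2 - k
    if dof < 1:
        raise ValueError("not enough samples for the covariate model")

    yr = _unit_rows(_residual_block(y, cov))
    gr = _residual_block(g, cov)
    ok = (gr**2).sum(axis=1) > 1e-12 * n  # drop constant / absorbed variants
    if not ok.any():
        return None
    gr = _unit_rows(gr[ok])
    kept_variants = dosages.index[ok]

    r_obs = yr @ gr.T  # introns x variants correlations
    obs_stat = float(np.abs(r_obs).max())

    # tie-break on (p asc, variant pos asc, intron id asc)
    ii, jj = np.where(np.abs(r_obs) >= obs_stat - 1e-15)
    pos = (
        variant_pos.reindex(kept_variants).to_numpy(float)[jj]
        if variant_pos is not None
        else jj.astype(float)
    )
    order = sorted(range(len(ii)), key=lambda t: (pos[t], usage_rows.index[ii[t]]))
    bi, bj = ii[order[0]], jj[order[0]]
    min_p = float(_corr_p(np.array([obs_stat]), dof)[0])

    rng = _gene_rng(seed, gene_id)
    perm_max = np.empty(n_perm)
    chunk = 200
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        idx = np.array([rng.permutation(n) for _ in range(m)])
        gp = gr[:, idx]  # variants x m x n
        # correlations for all perms at once: introns x variants x m
        rr = np.einsum("in,vmn->mvi", yr, gp, optimize=True)
        perm_max[done : done + m] = np.abs(rr).reshape(m, -1).max(axis=1)
        done += m

    empirical_p = float((1 + (perm_max >= obs_stat - 1e-15).sum()) / (n_perm + 1))
    beta_p = None
    if fit_beta:
        perm_pmin = _corr_p(perm_max, dof)
        perm_pmin = np.clip(perm_pmin, 1e-300, 1 - 1e-12)
        try:
            a, b, *_ = stats.beta.fit(perm_pmin, floc=0, fscale=1)
            beta_p = float(stats.beta.cdf(min_p, a, b))
        except Exception:  # pragma: no cover - degenerate fit
            beta_p = None

    # slope of normalised usage on dosage for the best pair (covariate-adjusted)
    yr_raw = _residual_block(y, cov)[bi]
    grb = _residual_block(dosages.loc[[kept_variants[bj]], samples].to_numpy(float), cov)[0]
    best_beta = float((grb @ yr_raw) / (grb @ grb))

    return GenePermResult(
        gene_id=gene_id,
        best_intron_id=str(usage_rows.index[bi]),
        best_variant_id=str(kept_variants[bj]),
        min_nominal_p=min_p,
        empirical_p=empirical_p,
        beta_approx_p=beta_p,
        n_introns=y.shape[0],
        n_variants=int(ok.sum()),
        beta=best_beta,
    )


# ---------------------------------------------------------------------------
# FDR


def qvalue_fdr(pvalues: np.ndarray | pd.Series, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    pi0 (the null proportion) is estimated on the lambda grid 0.05..0.95 with
    a cubic-smoother extrapolation to lambda = 0.95, as in the qvalue package;
    with fewer than 20 p-values the estimate falls back to pi0 = 1 (in which
    case the result equals Benjamini-Hochberg adjusted p-values).
    """
    p = np.asarray(pvalues, float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = len(p)
    if pi0 is None:
        if n < 20:
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.96, 0.05)
            pi0_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
            # cubic least-squares smoother evaluated at the largest lambda
            coef = np.polyfit(lam, pi0_lam, deg=3)
            pi0 = float(np.polyval(coef, lam[-1]))
            pi0 = min(max(pi0, 1.0 / n), 1.0)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    ranked = p[order] * pi0 * n / np.arange(1, n + 1)
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    return np.clip(q, 0, 1)


# ---------------------------------------------------------------------------
# Whole-map orchestration


def map_sqtls(
    usage: UsageMatrix,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    gene_of_intron: pd.Series,
    gene_tss: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    cis_half_width: int = 1_000_000,
    fit_beta: bool = False,
) -> pd.DataFrame:
    """Run the grouped permutation pass for every gene and attach q-values.

    ``gene_of_intron`` maps intron id -> gene id; ``gene_tss`` is indexed by
    gene id with columns chrom, tss.  Returns one row per testable gene.
    """
    if usage.stage != "normalized":
        raise ValueError("sQTL scan expects normalised usage")
    results: list[GenePermResult] = []
    samples = usage.samples
    genes = sorted(gene_of_intron.reindex(usage.values.index).dropna().unique())
    for gene in genes:
        introns = gene_of_intron.index[gene_of_intron == gene]
        introns = usage.values.index.intersection(introns)
        if len(introns) == 0 or gene not in gene_tss.index:
            continue
        tss = (str(gene_tss.loc[gene, "chrom"]), int(gene_tss.loc[gene, "tss"]))
        vidx = cis_window_variants(tss, genotypes, half_width=cis_half_width)
        if len(vidx) == 0:
            continue
        res = grouped_permutation_pass(
            gene,
            usage.values.loc[introns, samples],
            genotypes.dosages.loc[vidx],
            covariates,
            n_perm=n_perm,
            seed=seed,
            variant_pos=genotypes.variants["pos"],
            fit_beta=fit_beta,
        )
        if res is not None:
            results.append(res)
    if not results:
        return pd.DataFrame(
            columns=["gene_id", "best_intron_id", "best_variant_id", "min_nominal_p",
                     "empirical_p", "beta_approx_p", "qvalue", "beta"]
        ).set_index("gene_id")
    df = pd.DataFrame([vars(r) for r in results]).set_index("gene_id")
    df["qvalue"] = qvalue_fdr(df["empirical_p"].to_numpy())
    return df


def pc_sweep(
    usage: UsageMatrix,
    genotypes: GenotypeMatrix,
    base_covariates: CovariateTable,
    gene_of_intron: pd.Series,
    gene_tss: pd.DataFrame,
    k_grid: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 20, 50),
    n_perm: int = 200,
    seed: int = 0,
    max_fdr: float = 0.05,
) -> tuple[int, pd.Series, dict[int, pd.DataFrame]]:
    """Sweep usage-PC counts and keep the k maximising sGene yield.

    Runs the permutation pass with k usage PCs appended to the base
    covariates for each k in the grid; returns (chosen k, per-k sGene counts,
    per-k result frames).  Ties break to the smallest k.
    """
    from .normalize import compute_usage_pcs

    kmax = min(len(usage.samples) - 1, usage.values.shape[0])
    counts: dict[int, int] = {}
    frames: dict[int, pd.DataFrame] = {}
    for k in k_grid:
        if k > kmax:
            continue
        cov = base_covariates.concat(compute_usage_pcs(usage, k))
        res = map_sqtls(
            usage, genotypes, cov, gene_of_intron, gene_tss, n_perm=n_perm, seed=seed
        )
        frames[k] = res
        counts[k] = int((res["qvalue"] <= max_fdr).sum()) if len(res) else 0
    series = pd.Series(counts).sort_index()
    chosen = int(series.index[np.argmax(series.to_numpy())])  # argmax takes first max
    return chosen, series, frames
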