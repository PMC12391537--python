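"""Synthetic data with the statistical structure the sQTL analysis assumes.

The generator plants known effects so every downstream stage can be tested
for recovery:

* genotypes — biallelic, in Hardy-Weinberg equilibrium at a drawn MAF, with
  optional local LD from a latent AR(1) Gaussian copula thresholded to
  genotype classes;
* junction counts — per cluster and sample, a negative-binomial total
  allocated to introns by a Dirichlet-multinomial; for sQTL genes the target
  intron's logit proportion is shifted by effect_size x dosage, modulated per
  condition by a response factor (0 = absent, 1 = shared, >1 = amplified);
* GWAS summary statistics — a quantitative trait simulated on an independent
  panel sharing the variant set and LD, whose causal variant is the planted
  sQTL variant (H4), a distinct-but-linked variant (H3), or absent (H0-like);
  marginal statistics come from per-variant OLS so LD leakage is realistic.

All randomness flows from ``config.seed`` through fixed per-operation
streams: identical seed + config gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import SummaryStats
from .junctions import JunctionTable, junction_id
from .sqtl import GenotypeMatrix

__all__ = [
    "SynthConfig",
    "simulate_genotypes",
    "make_truth_table",
    "simulate_junction_counts",
    "simulate_gwas_stats",
    "simulate_effect_panel",
    "marginal_stats_for_trait",
    "SyntheticGenome",
    "write_truth",
    "read_truth",
    "write_vcf",
    "write_mini_gtf",
]

# distinct substreams off the master seed, one per generator
_STREAM_GENO, _STREAM_TRUTH, _STREAM_COUNTS, _STREAM_GWAS, _STREAM_GENOME = 1, 2, 3, 4, 5

_GENE_SPACING = 3_000_000
_CHROM = "chr1"


@dataclass
class SynthConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults describe a desk-scale version of a stimulated-macrophage sQTL
    study: a couple of hundred donors, a control plus stimulated conditions,
    deep-ish junction coverage, and per-allele logit shifts of 0.75 on the
    target intron of sQTL genes.
    """

    n_samples: int = 200
    n_conditions: int = 3  # condition 0 is the control/baseline
    n_genes: int = 100
    introns_per_cluster: tuple[int, int] = (2, 5)
    variants_per_gene: int = 20
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_rho: float = 0.5
    depth_mean: float = 100.0
    depth_dispersion: float = 10.0  # negative-binomial size
    concentration: float = 30.0  # Dirichlet overdispersion alpha
    effect_size: float = 0.75  # per-allele logit shift on the target intron
    effect_sign: str = "random"  # "random" or "positive" (usage-increasing)
    prop_sqtl_genes: float = 0.1
    prop_response: float = 0.2  # fraction of sQTL genes with condition-specific effects
    response_factor: float = 1.0  # multiplier in response conditions
    baseline_response_factor: float = 0.0  # multiplier elsewhere for response genes
    target_baseline_usage: float | None = None  # pin target-intron baseline proportion
    gwas_n: int = 10_000
    gwas_var_explained: float = 0.01
    gwas_scenario_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # none/H3/H4
    noncanonical_frac: float = 0.007  # splice sites lacking GT..AG in the toy genome
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        for name in ("prop_sqtl_genes", "prop_response"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        if abs(sum(self.gwas_scenario_mix) - 1) > 1e-9:
            raise ValueError("gwas_scenario_mix must sum to 1")
        if self.introns_per_cluster[0] < 2:
            raise ValueError("clusters need at least two introns")
        if self.effect_sign not in ("random", "positive"):
            raise ValueError("effect_sign must be 'random' or 'positive'")

    @property
    def conditions(self) -> list[str]:
        return ["Ctrl"] + [f"Stim{i}" for i in range(1, self.n_conditions)]

    @property
    def baseline_map(self) -> dict[str, str]:
        return {c: "Ctrl" for c in self.conditions if c != "Ctrl"}

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def gene_tss(self) -> pd.DataFrame:
        tss = [1_000_000 + i * _GENE_SPACING for i in range(self.n_genes)]
        return pd.DataFrame({"chrom": _CHROM, "tss": tss}, index=pd.Index(self.gene_ids()))


def _sample_ids(config: SynthConfig) -> list[str]:
    return [f"S{i:04d}" for i in range(config.n_samples)]


# ---------------------------------------------------------------------------
# Genotypes


def _threshold_genotypes(u: np.ndarray, maf: np.ndarray) -> np.ndarray:
    """Map uniforms (variants x samples) to HWE genotype classes per MAF."""
    p = maf[:, None]
    c0 = (1 - p) ** 2
    c1 = c0 + 2 * p * (1 - p)
    return (u >= c0).astype(np.int8) + (u >= c1).astype(np.int8)


def _latent_uniforms(rng: np.random.Generator, n_variants: int, n_samples: int, rho: float) -> np.ndarray:
    z = np.empty((n_variants, n_samples))
    z[0] = rng.standard_normal(n_samples)
    for v in range(1, n_variants):
        z[v] = rho * z[v - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n_samples)
    return stats.norm.cdf(z)


def _variant_meta(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    tss = config.gene_tss()
    step = max(1, 200_000 // max(1, config.variants_per_gene - 1))
    for gene in config.gene_ids():
        t = int(tss.loc[gene, "tss"])
        for j in range(config.variants_per_gene):
            rows.append(
                {
                    "variant_id": f"{gene}_v{j:03d}",
                    "chrom": _CHROM,
                    "pos": t - 100_000 + j * step,
                    "gene_id": gene,
                    "maf": rng.uniform(*config.maf_range),
                }
            )
    return pd.DataFrame(rows).set_index("variant_id")


def simulate_genotypes(config: SynthConfig) -> GenotypeMatrix:
    """Biallelic dosages in {0,1,2}, HWE marginally at a MAF drawn within
    ``maf_range``; adjacent variants within a gene window correlated through
    a latent AR(1) Gaussian copula with coefficient ``ld_rho``."""
    rng = np.random.default_rng([config.seed, _STREAM_GENO])
    meta = _variant_meta(config, rng)
    blocks = []
    for gene in config.gene_ids():
        vmask = meta["gene_id"] == gene
        maf = meta.loc[vmask, "maf"].to_numpy()
        u = _latent_uniforms(rng, len(maf), config.n_samples, config.ld_rho)
        blocks.append(_threshold_genotypes(u, maf))
    dosages = pd.DataFrame(
        np.vstack(blocks), index=meta.index, columns=_sample_ids(config), dtype=np.int8
    )
    return GenotypeMatrix(dosages=dosages, variants=meta)


def _simulate_panel(
    config: SynthConfig, meta: pd.DataFrame, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """An independent genotype panel sharing variant set, MAFs and LD."""
    blocks = []
    for gene in dict.fromkeys(meta["gene_id"]):
        maf = meta.loc[meta["gene_id"] == gene, "maf"].to_numpy()
        u = _latent_uniforms(rng, len(maf), n, config.ld_rho)
        blocks.append(_threshold_genotypes(u, maf))
    return pd.DataFrame(np.vstack(blocks), index=meta.index, dtype=np.int8)


# ---------------------------------------------------------------------------
# Truth table


def make_truth_table(config: SynthConfig, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Plant per-gene effects: which genes carry an sQTL, on which intron and
    variant, with which response conditions and GWAS sharing scenario.

    H4 genes reuse the sQTL causal variant for the GWAS trait; H3 genes use
    the variant in the window least correlated with it (distinct but linked).
    """
    rng = np.random.default_rng([config.seed, _STREAM_TRUTH])
    genes = config.gene_ids()
    n_sqtl = int(round(config.prop_sqtl_genes * len(genes)))
    sqtl_genes = set(rng.choice(genes, size=n_sqtl, replace=False))
    n_resp = int(round(config.prop_response * n_sqtl))
    resp_genes = set(rng.choice(sorted(sqtl_genes), size=n_resp, replace=False)) if n_resp else set()
    stim = [c for c in config.conditions if c != "Ctrl"]
    lo, hi = config.introns_per_cluster

    rows = []
    for gene in genes:
        n_introns = int(rng.integers(lo, hi + 1))
        is_sqtl = gene in sqtl_genes
        vids = genotypes.variants.index[genotypes.variants["gene_id"] == gene]
        causal = str(rng.choice(vids)) if is_sqtl else ""
        target = int(rng.integers(0, n_introns)) if is_sqtl else -1
        sign = 1.0 if (config.effect_sign == "positive" or rng.random() < 0.5) else -1.0
        effect = sign * config.effect_size if is_sqtl else 0.0
        response = sorted(rng.choice(stim, size=1)) if (gene in resp_genes and stim) else []
        if is_sqtl:
            scenario = str(rng.choice(["none", "H3", "H4"], p=config.gwas_scenario_mix))
        else:
            scenario = "none"
        gwas_causal = ""
        if scenario == "H4":
            gwas_causal = causal
        elif scenario == "H3":
            gsub = genotypes.dosages.loc[vids].to_numpy(float)
            r = np.corrcoef(gsub)[list(vids).index(causal)]
            gwas_causal = str(vids[int(np.argmin(np.abs(r)))])
        rows.append(
            {
                "gene_id": gene,
                "sqtl_flag": is_sqtl,
                "causal_variant_id": causal,
                "n_introns": n_introns,
                "target_intron": target,
                "effect_size": effect,
                "response_conditions": ",".join(response),
                "gwas_scenario": scenario,
                "gwas_causal_variant_id": gwas_causal,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Junction counts


def _gene_intron_coords(config: SynthConfig, gene: str, n_introns: int) -> list[tuple[int, int]]:
    tss = int(config.gene_tss().loc[gene, "tss"])
    start = tss + 500
    return [(start, start + 100 + 150 * j) for j in range(n_introns)]


def _baseline_pi(
    rng: np.random.Generator, n_introns: int, target: int, pinned: float | None
) -> np.ndarray:
    pi = rng.dirichlet(np.full(n_introns, 2.0))
    pi = np.clip(pi, 0.01, None)
    pi /= pi.sum()
    if pinned is not None and target >= 0:
        others = np.delete(pi, target)
        pi = np.insert(others / others.sum() * (1 - pinned), target, pinned)
    return pi


def _condition_factor(config: SynthConfig, response_conditions: str, condition: str) -> float:
    resp = set(response_conditions.split(",")) if response_conditions else set()
    if not resp:
        return 1.0
    return config.response_factor if condition in resp else config.baseline_response_factor


def simulate_junction_counts(
    config: SynthConfig, genotypes: GenotypeMatrix, truth: pd.DataFrame
) -> dict[str, JunctionTable]:
    """One JunctionTable per condition.

    Per sample and cluster the split-read total is negative binomial
    (mean ``depth_mean``, size ``depth_dispersion``); intron allocation is
    Dirichlet-multinomial around baseline proportions pi with concentration
    ``concentration``, after shifting the target intron's logit proportion by
    effect_size x dosage x condition factor.
    """
    unknown = truth.index.difference(config.gene_ids())
    if len(unknown):
        raise ValueError(f"truth references unknown genes: {list(unknown)[:3]}")
    samples = _sample_ids(config)
    pi_rng = np.random.default_rng([config.seed, _STREAM_COUNTS, 0])
    gene_pi = {
        gene: _baseline_pi(
            pi_rng,
            int(truth.loc[gene, "n_introns"]),
            int(truth.loc[gene, "target_intron"]),
            config.target_baseline_usage if truth.loc[gene, "sqtl_flag"] else None,
        )
        for gene in truth.index
    }
    size = config.depth_dispersion
    nb_p = size / (size + config.depth_mean)
    out: dict[str, JunctionTable] = {}
    for ci, condition in enumerate(config.conditions):
        rng = np.random.default_rng([config.seed, _STREAM_COUNTS, 1 + ci])
        meta_rows: list[dict] = []
        count_rows: list[np.ndarray] = []
        for gene in truth.index:
            row = truth.loc[gene]
            pi = gene_pi[gene]
            n_introns = len(pi)
            coords = _gene_intron_coords(config, gene, n_introns)
            delta = 0.0
            if row["sqtl_flag"]:
                delta = float(row["effect_size"]) * _condition_factor(
                    config, row["response_conditions"], condition
                )
                dosage = genotypes.dosages.loc[row["causal_variant_id"], samples].to_numpy(float)
            else:
                dosage = np.zeros(len(samples))
            totals = rng.negative_binomial(size, nb_p, size=len(samples))
            counts = np.zeros((n_introns, len(samples)), dtype=np.int64)
            logit_shift = delta * dosage  # per sample
            for s in range(len(samples)):
                p = pi.copy()
                if row["sqtl_flag"] and logit_shift[s] != 0.0:
                    t = int(row["target_intron"])
                    odds = p[t] / (1 - p[t]) * np.exp(logit_shift[s])
                    pt = odds / (1 + odds)
                    others = np.delete(p, t)
                    p = np.insert(others / others.sum() * (1 - pt), t, pt)
                if totals[s] > 0:
                    alloc = rng.dirichlet(config.concentration * p)
                    counts[:, s] = rng.multinomial(totals[s], alloc)
            for j, (a, b) in enumerate(coords):
                meta_rows.append(
                    {"chrom": _CHROM, "start": a, "end": b, "strand": "+", "anchor_len": 8}
                )
                count_rows.append(counts[j])
        meta = pd.DataFrame(meta_rows)
        meta.index = pd.Index(
            [junction_id(r["chrom"], r["start"], r["end"], r["strand"]) for r in meta_rows]
        )
        counts_df = pd.DataFrame(np.vstack(count_rows), index=meta.index, columns=samples)
        out[condition] = JunctionTable(meta=meta, counts=counts_df)
    return out


def gene_of_intron(config: SynthConfig, truth: pd.DataFrame) -> pd.Series:
    """Map simulated junction ids to their gene."""
    ids, genes = [], []
    for gene in truth.index:
        n_introns = int(truth.loc[gene, "n_introns"])
        for a, b in _gene_intron_coords(config, gene, n_introns):
            ids.append(junction_id(_CHROM, a, b, "+"))
            genes.append(gene)
    return pd.Series(genes, index=pd.Index(ids), name="gene_id")


def target_intron_id(config: SynthConfig, truth: pd.DataFrame, gene: str) -> str:
    row = truth.loc[gene]
    coords = _gene_intron_coords(config, gene, int(row["n_introns"]))
    a, b = coords[int(row["target_intron"])]
    return junction_id(_CHROM, a, b, "+")


# ---------------------------------------------------------------------------
# GWAS summary statistics


def marginal_stats_for_trait(
    panel: pd.DataFrame, y: np.ndarray, meta: pd.DataFrame, n_label: int | None = None
) -> SummaryStats:
    """Per-variant OLS of a trait on each dosage column: beta, se, p, n."""
    g = panel.to_numpy(float)
    n = g.shape[1]
    gc = g - g.mean(axis=1, keepdims=True)
    yc = np.asarray(y, float) - np.mean(y)
    gss = (gc**2).sum(axis=1)
    gss[gss == 0] = np.nan
    beta = gc @ yc / gss
    resid_ss = (yc @ yc) - beta**2 * gss
    sigma2 = resid_ss / (n - 2)
    se = np.sqrt(sigma2 / gss)
    with np.errstate(invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    tab = pd.DataFrame(
        {
            "chrom": meta.loc[panel.index, "chrom"].to_numpy(),
            "pos": meta.loc[panel.index, "pos"].to_numpy(),
            "id": panel.index.to_numpy(),
            "beta": beta,
            "se": se,
            "p": np.clip(p, np.nextafter(0, 1), 1.0),
            "n": n_label or n,
        }
    )
    return SummaryStats(tab.dropna(subset=["beta", "se"]).reset_index(drop=True))


def simulate_gwas_stats(
    config: SynthConfig, truth: pd.DataFrame, genotypes: GenotypeMatrix
) -> dict[str, SummaryStats]:
    """Per-gene-locus GWAS summary statistics on an independent panel of
    ``gwas_n`` individuals sharing the variant set and LD structure.

    H4 loci place the causal variant at the planted sQTL variant, H3 at a
    distinct linked variant, and "none" simulates pure noise.  The causal
    variant explains ``gwas_var_explained`` of trait variance.
    """
    if config.gwas_n < 1000:
        raise ValueError("gwas_n must be at least 1000")
    has_signal = truth["gwas_scenario"].isin(["H3", "H4"])
    if has_signal.any() and config.gwas_var_explained <= 0:
        raise ValueError("H3/H4 scenarios require positive variance explained")
    missing = truth.loc[has_signal, "gwas_causal_variant_id"]
    unknown = set(missing) - set(genotypes.variants.index)
    if unknown:
        raise ValueError(f"scenario references unknown variants: {sorted(unknown)[:3]}")

    rng = np.random.default_rng([config.seed, _STREAM_GWAS])
    meta = genotypes.variants
    out: dict[str, SummaryStats] = {}
    for gene in truth.index:
        vids = meta.index[meta["gene_id"] == gene]
        panel = _simulate_panel(config, meta.loc[vids], config.gwas_n, rng)
        scenario = truth.loc[gene, "gwas_scenario"]
        y = rng.standard_normal(config.gwas_n)
        if scenario in ("H3", "H4"):
            gz = panel.loc[truth.loc[gene, "gwas_causal_variant_id"]].to_numpy(float)
            sd = gz.std()
            if sd > 0:
                gz = (gz - gz.mean()) / sd
            v = config.gwas_var_explained
            y = np.sqrt(v) * gz + np.sqrt(1 - v) * y
        out[gene] = marginal_stats_for_trait(panel, y, meta, n_label=config.gwas_n)
    return out


# ---------------------------------------------------------------------------
# Direct effect-panel simulation (for the multi-condition shrinkage stage)


def simulate_effect_panel(
    n_tests: int,
    conditions: list[str],
    prop_shared: float = 0.6,
    prop_specific: float = 0.2,
    effect_range: tuple[float, float] = (0.5, 1.0),
    se: float = 0.1,
    baseline: str = "Ctrl",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-condition effect estimates with planted sharing structure.

    Each test is shared (one effect in every condition), condition-specific
    (effect in a single stimulated condition, none elsewhere) or null.
    Effect magnitudes are uniform over ``effect_range`` with random sign,
    emulating lead-SNP effects of genes that passed a significance screen
    (hence bounded away from zero).  Returns (betas, ses, truth) frames
    indexed by test id; truth carries the true effects and the specific
    condition label.
    """
    rng = np.random.default_rng([seed, 7])
    stim = [c for c in conditions if c != baseline]
    kinds = rng.choice(
        ["shared", "specific", "null"],
        size=n_tests,
        p=[prop_shared, prop_specific, 1 - prop_shared - prop_specific],
    )
    true = np.zeros((n_tests, len(conditions)))
    spec_cond = []

    def _draw() -> float:
        return float(rng.choice([-1, 1]) * rng.uniform(*effect_range))

    for i, kind in enumerate(kinds):
        if kind == "shared":
            true[i, :] = _draw()
            spec_cond.append("")
        elif kind == "specific":
            c = str(rng.choice(stim))
            true[i, conditions.index(c)] = _draw()
            spec_cond.append(c)
        else:
            spec_cond.append("")
    betas = true + rng.normal(0, se, size=true.shape)
    idx = pd.Index([f"T{i:05d}" for i in range(n_tests)], name="test_id")
    truth = pd.DataFrame(
        {"kind": kinds, "specific_condition": spec_cond}, index=idx
    ).join(pd.DataFrame(true, index=idx, columns=[f"true_{c}" for c in conditions]))
    return (
        pd.DataFrame(betas, index=idx, columns=conditions),
        pd.DataFrame(np.full(true.shape, se), index=idx, columns=conditions),
        truth,
    )


# ---------------------------------------------------------------------------
# Toy genome for splice-site dinucleotides


class SyntheticGenome:
    """Procedural genome exposing ``fetch(chrom, start, end)`` (0-based,
    half-open).  Splice sites of the simulated introns carry canonical GT..AG
    dinucleotides except for a seeded fraction; elsewhere the sequence is a
    deterministic function of position."""

    _BASES = "ACGT"

    def __init__(
        self, intron_coords: list[tuple[str, int, int]], noncanonical_frac: float = 0.0,
        seed: int = 0,
    ) -> None:
        rng = np.random.default_rng([seed, _STREAM_GENOME])
        self._special: dict[tuple[str, int], str] = {}
        for chrom, start, end in intron_coords:
            if rng.random() < noncanonical_frac:
                donor, acceptor = "CC", "TT"
            else:
                donor, acceptor = "GT", "AG"
            self._special[(chrom, start)] = donor[0]
            self._special[(chrom, start + 1)] = donor[1]
            self._special[(chrom, end - 2)] = acceptor[0]
            self._special[(chrom, end - 1)] = acceptor[1]

    def _base(self, chrom: str, pos: int) -> str:
        key = (chrom, pos)
        if key in self._special:
            return self._special[key]
        return self._BASES[(pos * 2654435761) % 4]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0:
            raise ValueError("fetch before chromosome start")
        return "".join(self._base(chrom, p) for p in range(start, end))


# ---------------------------------------------------------------------------
# Writers / readers (round-trip safe)


def write_truth(truth: pd.DataFrame, tsv_path, json_path=None) -> None:
    truth.to_csv(tsv_path, sep="\t")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(truth.reset_index().to_dict(orient="records"), fh, indent=1)


def read_truth(tsv_path) -> pd.DataFrame:
    df = pd.read_csv(tsv_path, sep="\t", index_col=0, keep_default_na=False)
    df["sqtl_flag"] = df["sqtl_flag"].astype(str).isin(("True", "true", "1"))
    for col in ("n_introns", "target_intron"):
        df[col] = df[col].astype(int)
    df["effect_size"] = df["effect_size"].astype(float)
    return df


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Plain-text VCF with hard GT calls (dosages rounded to 0/1/2)."""
    samples = genotypes.samples
    gtmap = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={_CHROM}>\n")
        fh.write("##FORMAT=<ID=GT,Number=1,Type=String,Description=\"Genotype\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for vid, row in genotypes.variants.iterrows():
            dos = genotypes.dosages.loc[vid]
            gts = "\t".join(gtmap[int(round(d))] for d in dos)
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_gwas_tsv(stats: SummaryStats, path) -> None:
    stats.table.to_csv(path, sep="\t", index=False)


def write_mini_gtf(
    config: SynthConfig, truth: pd.DataFrame, path, annotate_targets: bool = False
) -> None:
    """GTF with one gene per simulated cluster and one two-exon transcript
    per annotated intron; sQTL target introns are left unannotated unless
    ``annotate_targets`` (novel junctions are the interesting case)."""
    with open(path, "w") as fh:
        for gene in truth.index:
            row = truth.loc[gene]
            coords = _gene_intron_coords(config, gene, int(row["n_introns"]))
            gstart = min(a for a, _ in coords) - 100
            gend = max(b for _, b in coords) + 100
            attrs = f'gene_id "{gene}"; gene_name "{gene}";'
            fh.write(
                f"{_CHROM}\tsynth\tgene\t{gstart + 1}\t{gend}\t.\t+\t.\t{attrs}\n"
            )
            for j, (a, b) in enumerate(coords):
                if (not annotate_targets) and row["sqtl_flag"] and j == int(row["target_intron"]):
                    continue
                tid = f"{gene}.t{j}"
                tattrs = f'gene_id "{gene}"; transcript_id "{tid}";'
                fh.write(f"{_CHROM}\tsynth\ttranscript\t{a - 99}\t{b + 100}\t.\t+\t.\t{tattrs}\n")
                fh.write(f"{_CHROM}\tsynth\texon\t{a - 99}\t{a}\t.\t+\t.\t{tattrs}\n")
                fh.write(f"{_CHROM}\tsynth\texon\t{b + 1}\t{b + 100}\t.\t+\t.\t{tattrs}\n")
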