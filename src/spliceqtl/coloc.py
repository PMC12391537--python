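"""Bayesian pairwise colocalisation from summary statistics.

Under the single-causal-variant assumption, each variant's evidence for
association with a trait is summarised by a Wakefield approximate Bayes
factor computed from (beta, se) and a prior effect-size SD.  Enumerating
causal configurations over the shared variant set yields posteriors over
five hypotheses:

    H0 no association with either trait      H1 trait 1 only
    H2 trait 2 only                          H3 two distinct causal variants
    H4 one shared causal variant

Also here: the greedy definition of genome-wide significant GWAS loci
(1 Mbp windows seeded by ascending p-value) and the attribution of each
locus to sQTL and/or eQTL signals by their maximum PP4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "SummaryStats",
    "ColocResult",
    "GwasLocus",
    "wakefield_labf",
    "coloc_abf",
    "define_gwas_loci",
    "attribute_locus",
    "coloc_sqtl_vs_eqtl",
]

#: documented prior effect-size SDs: quantitative traits / case-control log-odds
PRIOR_SD_QUANT = 0.15
PRIOR_SD_CC = 0.2


@dataclass
class SummaryStats:
    """Per-variant marginal association summaries for one trait at one locus.

    ``table`` requires columns chrom, pos, beta, se (p and n optional);
    variants are matched across traits by (chrom, pos) only, so positions
    must be unique within the slice.
    """

    table: pd.DataFrame
    trait_type: str = "quantitative"
    prior_sd: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case-control"):
            raise ValueError(f"unknown trait type {self.trait_type!r}")
        if (self.table["se"] <= 0).any():
            raise ValueError("standard errors must be positive")
        if self.table.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("duplicate variant positions within a locus slice")
        if self.prior_sd is None:
            self.prior_sd = PRIOR_SD_QUANT if self.trait_type == "quantitative" else PRIOR_SD_CC

    @staticmethod
    def read_tsv(path, trait_type: str = "quantitative") -> "SummaryStats":
        return SummaryStats(pd.read_csv(path, sep="\t"), trait_type=trait_type)


@dataclass
class ColocResult:
    pp: np.ndarray  # pp0..pp4
    n_shared_variants: int
    trait1: str = ""
    trait2: str = ""
    condition: str = ""

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


@dataclass
class GwasLocus:
    lead_variant: str
    chrom: str
    pos: int
    p: float
    window: tuple[int, int]
    attribution: str = "untested"


def wakefield_labf(beta, se, prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor for association at a single variant.

    With z = beta/se, V = se^2, W = prior_sd^2 and r = W / (V + W):
    labf = 0.5 * (log(1 - r) + r * z^2).
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if (se <= 0).any():
        raise ValueError("se must be positive")
    if prior_sd < 0:
        raise ValueError("prior_sd must be non-negative")
    z = beta / se
    r = prior_sd**2 / (se**2 + prior_sd**2)
    return 0.5 * (np.log1p(-r) + r * z**2)


def coloc_abf(
    s1: SummaryStats,
    s2: SummaryStats,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    min_shared: int = 20,
    trait1: str = "",
    trait2: str = "",
    condition: str = "",
) -> ColocResult | None:
    """Five-hypothesis colocalisation over the variants shared by two traits.

    Variants are joined on (chrom, pos).  Pairs sharing fewer than
    ``min_shared`` variants are skipped (``None``), not errors.  All sums run
    in log space via log-sum-exp, so extreme z-scores cannot overflow.
    """
    m = s1.table.merge(s2.table, on=["chrom", "pos"], suffixes=("_1", "_2"))
    n_shared = len(m)
    if n_shared < min_shared:
        return None
    l1 = wakefield_labf(m["beta_1"], m["se_1"], s1.prior_sd)
    l2 = wakefield_labf(m["beta_2"], m["se_2"], s2.prior_sd)

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + lsum1
    lh[2] = np.log(p2) + lsum2
    # H3: ordered pairs of distinct variants = (sum1 * sum2) - sum of same-variant
    # products; the difference can cancel to 0 (e.g. a single variant), so clamp
    both, sign = logsumexp([lsum1 + lsum2, lsum12], b=[1.0, -1.0], return_sign=True)
    lh[3] = (np.log(p1) + np.log(p2) + both) if sign > 0 else -np.inf
    lh[4] = np.log(p12) + lsum12
    pp = np.exp(lh - logsumexp(lh))
    return ColocResult(
        pp=pp, n_shared_variants=n_shared, trait1=trait1, trait2=trait2, condition=condition
    )


def define_gwas_loci(
    stats: SummaryStats | pd.DataFrame,
    p_thresh: float = 5e-8,
    window: int = 1_000_000,
) -> list[GwasLocus]:
    """Greedy genome-wide-significant locus definition.

    Significant variants are visited in ascending p-value order; each defines
    a window of ``window`` bp centred on it unless it already falls inside a
    previously defined locus on the same chromosome.
    """
    tab = stats.table if isinstance(stats, SummaryStats) else stats
    if "p" not in tab.columns:
        raise ValueError("p-values required to define loci")
    sig = tab[tab["p"] < p_thresh]
    sig = sig.sort_values(["p", "chrom", "pos"], kind="mergesort")
    half = window // 2
    loci: list[GwasLocus] = []
    for row in sig.itertuples():
        chrom, pos = str(row.chrom), int(row.pos)
        if any(l.chrom == chrom and l.window[0] <= pos <= l.window[1] for l in loci):
            continue
        vid = str(getattr(row, "id", f"{chrom}:{pos}"))
        loci.append(
            GwasLocus(lead_variant=vid, chrom=chrom, pos=pos, p=float(row.p),
                      window=(pos - half, pos + half))
        )
    return loci


def attribute_locus(
    locus: GwasLocus,
    sqtl_pp4s,
    eqtl_pp4s,
    pp4_thresh: float = 0.75,
) -> str:
    """Attribute a GWAS locus to molecular QTL signals by maximum PP4.

    With S = max sQTL PP4 and E = max eQTL PP4 over colocalisations at the
    locus: "both" when both reach the threshold; "sQTL-only" when
    S >= thresh > E (and S > E); symmetrically "eQTL-only"; else "neither".
    """
    s = float(max(sqtl_pp4s)) if len(sqtl_pp4s) else 0.0
    e = float(max(eqtl_pp4s)) if len(eqtl_pp4s) else 0.0
    if s >= pp4_thresh and e >= pp4_thresh:
        att = "both"
    elif s >= pp4_thresh and s > e:
        att = "sQTL-only"
    elif e >= pp4_thresh and e > s:
        att = "eQTL-only"
    else:
        att = "neither"
    locus.attribution = att
    return att


def coloc_sqtl_vs_eqtl(
    sqtl_stats: SummaryStats,
    eqtl_stats: SummaryStats,
    permissive_pp4: float = 0.1,
    **kwargs,
) -> tuple[ColocResult | None, bool]:
    """Colocalise a gene's top sQTL intron against its eQTL signal in the
    same condition; the flag marks PP4 at or above the permissive cutoff."""
    res = coloc_abf(sqtl_stats, eqtl_stats, **kwargs)
    return res, bool(res is not None and res.pp4 >= permissive_pp4)
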