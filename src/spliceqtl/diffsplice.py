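"""Differential splicing between a stimulated and a control condition.

Per intron cluster, split-read counts are compared between the two groups
with a multinomial-logit likelihood-ratio test: the alternative fits one
proportion vector per group, the null a pooled vector, giving an LRT with
(#introns - 1) degrees of freedom.  This is a simplified surrogate for the
Dirichlet-multinomial model used by dedicated differential-splicing tools;
because plain multinomial likelihoods ignore biological overdispersion, a
dispersion-moderated (Williams-type) correction divides the statistic by the
Pearson overdispersion factor when it exceeds 1 (the default).  Reported per
intron: the log-odds change between groups and the difference in mean raw
usage (delta PSI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["DiffSpliceResult", "differential_splicing_test", "diff_splice_all", "classify_differential"]


@dataclass
class DiffSpliceResult:
    cluster_id: str
    gene_id: str
    lrt_statistic: float
    df: int
    p: float
    fdr_adjusted_p: float
    effects: pd.DataFrame  # per intron: log_odds_effect, delta_psi
    skipped: str = ""  # reason code when filters fail


def _multinomial_loglik(counts: np.ndarray, p: np.ndarray) -> float:
    """Sum over samples of log multinomial likelihood (constant terms dropped)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(p)[:, None]
    return float(np.nansum(np.where(counts > 0, terms, 0.0)))


def differential_splicing_test(
    cluster_counts: pd.DataFrame,
    group_labels: pd.Series,
    cluster_id: str = "",
    gene_id: str = "",
    min_samples_per_intron: int = 50,
    min_samples_per_group: int = 50,
    min_coverage: int = 30,
    dispersion_correction: bool = True,
) -> DiffSpliceResult:
    """LRT for a group effect on one cluster's intron proportions.

    ``cluster_counts`` is introns x samples; ``group_labels`` assigns each
    sample to one of exactly two groups.  Samples only count toward the
    group-size filter when the cluster total reaches ``min_coverage``; each
    intron must be observed (non-zero) in at least ``min_samples_per_intron``
    samples.  Failing clusters are returned with a reason code, not raised.
    """
    groups = pd.unique(group_labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    counts = cluster_counts.to_numpy(float)
    j = counts.shape[0]
    covered = counts.sum(axis=0) >= min_coverage

    def _skip(reason: str) -> DiffSpliceResult:
        eff = pd.DataFrame(
            {"log_odds_effect": np.nan, "delta_psi": np.nan}, index=cluster_counts.index
        )
        return DiffSpliceResult(cluster_id, gene_id, np.nan, j - 1, np.nan, np.nan, eff, reason)

    for g in groups:
        if (covered & (group_labels == g).to_numpy()).sum() < min_samples_per_group:
            return _skip(f"min_samples_per_group<{min_samples_per_group} in {g}")
    if ((counts[:, covered] > 0).sum(axis=1) < min_samples_per_intron).any():
        return _skip(f"min_samples_per_intron<{min_samples_per_intron}")

    use = counts[:, covered]
    lab = group_labels.to_numpy()[covered]
    masks = [lab == g for g in groups]
    pooled = use.sum(axis=1)
    p0 = pooled / pooled.sum()
    ll0 = _multinomial_loglik(use, p0)
    ll1 = 0.0
    group_p = []
    for m in masks:
        tot = use[:, m].sum(axis=1)
        pg = tot / tot.sum() if tot.sum() > 0 else p0
        group_p.append(pg)
        ll1 += _multinomial_loglik(use[:, m], pg)
    lrt = 2.0 * (ll1 - ll0)

    if dispersion_correction:
        # Pearson overdispersion of per-sample counts around group proportions
        chi2 = 0.0
        dof = 0
        for m, pg in zip(masks, group_p):
            tots = use[:, m].sum(axis=0)
            exp = pg[:, None] * tots[None, :]
            ok = exp > 0
            chi2 += float(((use[:, m] - exp) ** 2 / np.where(ok, exp, 1.0))[ok].sum())
            dof += int(m.sum()) * (j - 1)
        phi = chi2 / dof if dof > 0 else 1.0
        lrt = lrt / max(1.0, phi)

    df = j - 1
    p = float(stats.chi2.sf(lrt, df=df))

    eps = 0.5  # Haldane continuity for empty cells
    g1, g2 = [use[:, m].sum(axis=1) for m in masks]
    t1, t2 = g1.sum(), g2.sum()
    lo1 = np.log((g1 + eps) / (t1 - g1 + eps))
    lo2 = np.log((g2 + eps) / (t2 - g2 + eps))
    ratios = counts / np.where(counts.sum(axis=0) > 0, counts.sum(axis=0), np.nan)
    m1 = np.nanmean(ratios[:, (group_labels == groups[0]).to_numpy() & covered], axis=1)
    m2 = np.nanmean(ratios[:, (group_labels == groups[1]).to_numpy() & covered], axis=1)
    eff = pd.DataFrame(
        {"log_odds_effect": lo1 - lo2, "delta_psi": m1 - m2}, index=cluster_counts.index
    )
    return DiffSpliceResult(cluster_id, gene_id, float(lrt), df, p, np.nan, eff)


def diff_splice_all(
    counts_by_cluster: dict[str, pd.DataFrame],
    group_labels: pd.Series,
    gene_of_cluster: dict[str, str] | None = None,
    **kwargs,
) -> list[DiffSpliceResult]:
    """Run the cluster test across clusters and BH-adjust p-values."""
    results = [
        differential_splicing_test(
            tab, group_labels, cluster_id=cid,
            gene_id=(gene_of_cluster or {}).get(cid, ""), **kwargs,
        )
        for cid, tab in counts_by_cluster.items()
    ]
    tested = [r for r in results if not r.skipped]
    if tested:
        adj = multipletests([r.p for r in tested], method="fdr_bh")[1]
        for r, q in zip(tested, adj):
            r.fdr_adjusted_p = float(q)
    return results


def classify_differential(
    results: list[DiffSpliceResult],
    max_fdr: float = 0.05,
    min_abs_logef: float = 0.5,
) -> pd.DataFrame:
    """Flag genes with any cluster passing both thresholds (adjusted p below
    ``max_fdr`` AND absolute log effect above ``min_abs_logef``); the
    per-gene reported effect is the intron with the largest |effect|."""
    rows = []
    for r in results:
        if r.skipped or not np.isfinite(r.fdr_adjusted_p):
            continue
        best = r.effects["log_odds_effect"].abs().idxmax()
        rows.append(
            {
                "gene_id": r.gene_id,
                "cluster_id": r.cluster_id,
                "fdr_adjusted_p": r.fdr_adjusted_p,
                "top_intron": best,
                "log_odds_effect": r.effects.loc[best, "log_odds_effect"],
                "delta_psi": r.effects.loc[best, "delta_psi"],
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(flagged=pd.Series(dtype=bool))
    df["flagged"] = (df["fdr_adjusted_p"] < max_fdr) & (
        df["log_odds_effect"].abs() > min_abs_logef
    )
    gene = (
        df.sort_values("log_odds_effect", key=lambda s: s.abs(), ascending=False)
        .groupby("gene_id", as_index=False)
        .agg({"flagged": "any", "cluster_id": "first", "log_odds_effect": "first",
              "delta_psi": "first", "fdr_adjusted_p": "min", "top_intron": "first"})
    )
    return gene
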