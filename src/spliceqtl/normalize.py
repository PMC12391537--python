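"""Usage-ratio quality control and normalisation.

The pipeline from raw ratios to QTL-ready phenotypes is: drop uninformative
introns (too many zeros, or near-constant), fill cluster-total-zero gaps with
the intron mean, quantile-normalise samples to a common distribution, then
rank-based inverse-normal transform each intron across samples.  Principal
components of the normalised matrix serve as nuisance covariates in the
cis-QTL scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .junctions import UsageMatrix

__all__ = [
    "CovariateTable",
    "filter_low_information",
    "impute_missing",
    "quantile_normalize",
    "inverse_normal_transform",
    "compute_usage_pcs",
    "residualize",
]


@dataclass
class CovariateTable:
    """Samples x covariates design block (numeric; categoricals one-hot)."""

    values: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def concat(self, other: "CovariateTable") -> "CovariateTable":
        if not self.values.index.equals(other.values.index):
            other_vals = other.values.reindex(self.values.index)
        else:
            other_vals = other.values
        return CovariateTable(pd.concat([self.values, other_vals], axis=1))

    @staticmethod
    def empty(samples: list[str]) -> "CovariateTable":
        return CovariateTable(pd.DataFrame(index=pd.Index(samples)))


def filter_low_information(
    usage: UsageMatrix,
    max_zero_frac: float = 0.40,
    min_sd: float = 0.005,
    cluster_missing_frac: float | None = None,
) -> UsageMatrix:
    """Remove introns with a zero ratio in more than ``max_zero_frac`` of
    samples or with an across-sample standard deviation below ``min_sd``.

    Both thresholds are strict: an intron zero in exactly 40% of samples is
    retained.  ``cluster_missing_frac``, if given, additionally drops whole
    clusters whose total is missing (zero split reads) in more than that
    fraction of samples — a cluster-level variant of the zero filter.
    """
    if usage.stage != "raw":
        raise ValueError("low-information filter applies to raw ratios")
    vals = usage.values
    keep = pd.Series(True, index=vals.index)
    if cluster_missing_frac is not None:
        miss = vals.isna().groupby(usage.cluster_of).transform("max").mean(axis=1)
        keep &= miss <= cluster_missing_frac
    zero_frac = (vals == 0).sum(axis=1) / vals.shape[1]
    keep &= zero_frac <= max_zero_frac
    keep &= vals.std(axis=1, ddof=1) >= min_sd
    return UsageMatrix(
        values=vals.loc[keep].copy(),
        cluster_of=usage.cluster_of.reindex(vals.index[keep]),
        stage="raw",
    )


def impute_missing(usage: UsageMatrix) -> UsageMatrix:
    """Replace missing entries by the intron's mean over observed samples."""
    vals = usage.values
    all_missing = vals.isna().all(axis=1)
    if all_missing.any():
        raise ValueError(
            f"introns with no observed values: {list(vals.index[all_missing])[:3]}"
        )
    filled = vals.T.fillna(vals.mean(axis=1)).T
    return UsageMatrix(values=filled, cluster_of=usage.cluster_of, stage=usage.stage)


def quantile_normalize(usage: UsageMatrix) -> UsageMatrix:
    """Force every sample column onto the across-sample mean order-statistic
    vector; ties within a column receive the mean of their target quantiles."""
    vals = usage.values
    if vals.isna().any().any():
        raise ValueError("quantile normalisation requires a complete matrix")
    arr = vals.to_numpy(float)
    order = np.sort(arr, axis=0)
    target = order.mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, arr.shape[0] + 1), target)
    return UsageMatrix(
        values=pd.DataFrame(out, index=vals.index, columns=vals.columns),
        cluster_of=usage.cluster_of,
        stage=usage.stage,
    )


def inverse_normal_transform(usage: UsageMatrix, c: float = 3.0 / 8.0) -> UsageMatrix:
    """Rank-based inverse normal transform per intron across samples.

    value -> Phi^-1((rank - c) / (n - 2c + 1)) with the Blom offset c = 3/8;
    ties get the average rank and hence equal transformed values.  Each row is
    recentred to exact zero mean afterwards: without ties the Blom quantiles
    are already symmetric and this is a no-op, with ties it removes the small
    offset the averaged ranks introduce.
    """
    vals = usage.values
    if vals.isna().any().any():
        raise ValueError("inverse normal transform requires a complete matrix")
    arr = vals.to_numpy(float)
    n = arr.shape[1]
    ranks = np.apply_along_axis(stats.rankdata, 1, arr)
    out = stats.norm.ppf((ranks - c) / (n - 2 * c + 1))
    out = out - out.mean(axis=1, keepdims=True)
    return UsageMatrix(
        values=pd.DataFrame(out, index=vals.index, columns=vals.columns),
        cluster_of=usage.cluster_of,
        stage="normalized",
    )


def compute_usage_pcs(usage: UsageMatrix, k: int) -> CovariateTable:
    """Top-k principal components of the (centred) sample x intron matrix.

    Sign convention: within each component the loading of largest magnitude
    is positive, making the output deterministic across runs and libraries.
    """
    samples = usage.samples
    if k == 0:
        return CovariateTable.empty(samples)
    x = usage.values.to_numpy(float).T  # samples x introns
    kmax = min(x.shape[0] - 1, x.shape[1])
    if k > kmax:
        raise ValueError(f"requested {k} PCs but at most {kmax} are available")
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        if vt[j, np.argmax(np.abs(vt[j]))] < 0:
            scores[:, j] = -scores[:, j]
    cols = [f"usagePC{i + 1}" for i in range(k)]
    return CovariateTable(pd.DataFrame(scores, index=pd.Index(samples), columns=cols))


def _prune_collinear(x: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Drop columns that are numerically in the span of earlier ones."""
    keep: list[int] = []
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) > len(keep):
            keep.append(j)
    return x[:, keep]


def residualize(values: np.ndarray | pd.Series, covariates: CovariateTable) -> np.ndarray:
    """OLS residuals of ``values`` on the covariates (plus intercept), with
    the mean added back so the location of the trait is preserved."""
    y = np.asarray(values, float)
    c = covariates.values.to_numpy(float)
    x = np.column_stack([np.ones(len(y)), c]) if c.size else np.ones((len(y), 1))
    x = _prune_collinear(x)
    if x.shape[1] >= len(y):
        raise ValueError("design matrix rank-deficient for the sample size")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return resid + y.mean()
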