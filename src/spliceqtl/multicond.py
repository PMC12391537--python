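"""Multi-condition effect-size shrinkage and response-sQTL calling.

Effects estimated separately per stimulation condition are noisy and
correlated; empirical-Bayes multivariate shrinkage borrows strength across
conditions by modelling z-scores as a mixture of zero-mean multivariate
normals over a library of covariance patterns (null, independent,
condition-specific, fully shared, and data-driven components from the
strongest signals), each over a grid of scales.  Mixture weights are fitted
by EM on a random subset of associations; posteriors for any query set
follow by conjugate updates.  Significance is summarised by the local false
sign rate (LFSR): the posterior probability that the sign of an effect is
wrong.

Response sQTLs are effects that *differ* between a stimulated condition and
its matched control, so the analysis runs on baseline-contrast coordinates
(stimulated minus control); a test is a response in condition c when the
contrast's LFSR falls below the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectPanel",
    "ShrinkageModel",
    "PosteriorEffects",
    "build_effect_panel",
    "to_contrasts",
    "fit_shrinkage_model",
    "posterior_effects",
    "call_response_sqtls",
]

_BIG_SE = 1e6  # convention for missing condition cells: beta 0, se huge


@dataclass
class EffectPanel:
    """Tests x conditions effect estimates with matching standard errors."""

    betas: pd.DataFrame
    ses: pd.DataFrame
    subset: str = "query"  # strong | random | query

    def __post_init__(self) -> None:
        if not self.betas.index.equals(self.ses.index) or list(self.betas.columns) != list(
            self.ses.columns
        ):
            raise ValueError("betas and ses must be aligned")
        if (self.ses.to_numpy() <= 0).any():
            raise ValueError("standard errors must be positive")

    @property
    def conditions(self) -> list[str]:
        return list(self.betas.columns)

    def zscores(self) -> np.ndarray:
        return (self.betas.to_numpy(float) / self.ses.to_numpy(float))


@dataclass
class ShrinkageModel:
    components: list[np.ndarray]  # prior covariance patterns (R x R, PSD)
    component_names: list[str]
    scales: np.ndarray  # s^2 grid applied to non-null components
    weights: np.ndarray  # flattened over (component, scale), sums to 1
    residual_corr: np.ndarray  # V
    loglik_path: list[float] = field(default_factory=list)
    converged: bool = True

    def expanded(self) -> list[tuple[str, np.ndarray]]:
        """(name, s^2 * U) for every mixture slot, in weight order."""
        out: list[tuple[str, np.ndarray]] = [("null", np.zeros_like(self.residual_corr))]
        for name, u in zip(self.component_names, self.components):
            for s2 in self.scales:
                out.append((f"{name}@{s2:.4g}", s2 * u))
        return out

    def to_json_dict(self) -> dict:
        return {
            "component_names": self.component_names,
            "components": [u.tolist() for u in self.components],
            "scales": self.scales.tolist(),
            "weights": self.weights.tolist(),
            "residual_corr": self.residual_corr.tolist(),
            "converged": self.converged,
        }


@dataclass
class PosteriorEffects:
    post_mean: pd.DataFrame  # posterior mean betas (original scale)
    post_sd: pd.DataFrame
    lfsr: pd.DataFrame


# ---------------------------------------------------------------------------
# Panel construction


def build_effect_panel(
    perm_results: dict[str, pd.DataFrame],
    nominal: dict[str, pd.DataFrame],
    subset: str,
    n_random: int = 1_000_000,
    max_fdr: float = 0.05,
    seed: int = 0,
) -> EffectPanel:
    """Assemble the strong or random training panel across conditions.

    ``nominal[c]`` is indexed by test id (e.g. ``intron|variant``) with
    columns beta and se.  The strong subset keeps the lead association per
    gene significant (q <= ``max_fdr``) in any condition; the random subset
    samples test ids uniformly without replacement (capped at ``n_random``).
    Cells absent in a condition get beta 0 with a very large se, so they
    carry no likelihood weight.
    """
    conditions = list(nominal.keys())
    if subset == "strong":
        ids: list[str] = []
        for c in conditions:
            res = perm_results[c]
            sig = res[res["qvalue"] <= max_fdr]
            ids.extend(sig["best_intron_id"].astype(str) + "|" + sig["best_variant_id"].astype(str))
        test_ids = pd.Index(sorted(set(ids)))
    elif subset == "random":
        pool = pd.Index(sorted(set().union(*[set(nominal[c].index) for c in conditions])))
        if len(pool) == 0:
            raise ValueError("no associations to sample from")
        rng = np.random.default_rng([seed, 11])
        if len(pool) > n_random:
            test_ids = pd.Index(sorted(rng.choice(pool, size=n_random, replace=False)))
        else:
            test_ids = pool
    else:
        raise ValueError("subset must be 'strong' or 'random'")
    if len(test_ids) == 0:
        raise ValueError("empty panel: no overlapping tests across conditions")
    betas = pd.DataFrame(0.0, index=test_ids, columns=conditions)
    ses = pd.DataFrame(_BIG_SE, index=test_ids, columns=conditions)
    for c in conditions:
        tab = nominal[c]
        hit = test_ids.intersection(tab.index)
        betas.loc[hit, c] = tab.loc[hit, "beta"].to_numpy(float)
        ses.loc[hit, c] = tab.loc[hit, "se"].to_numpy(float)
    return EffectPanel(betas=betas, ses=ses, subset=subset)


def to_contrasts(panel: EffectPanel, baseline_map: dict[str, str]) -> EffectPanel:
    """Re-express effects as stimulated-minus-control contrasts.

    Each stimulated condition c with baseline b becomes the coordinate
    beta_c - beta_b with se = sqrt(se_c^2 + se_b^2) (estimates from disjoint
    scans are treated as independent).
    """
    cols = [c for c in panel.conditions if c in baseline_map]
    betas = pd.DataFrame(index=panel.betas.index)
    ses = pd.DataFrame(index=panel.betas.index)
    for c in cols:
        b = baseline_map[c]
        betas[c] = panel.betas[c] - panel.betas[b]
        ses[c] = np.sqrt(panel.ses[c] ** 2 + panel.ses[b] ** 2)
    return EffectPanel(betas=betas, ses=ses, subset=panel.subset)


# ---------------------------------------------------------------------------
# Model fitting


def _canonical_components(r: int) -> tuple[list[np.ndarray], list[str]]:
    comps = [np.eye(r)]
    names = ["identity"]
    for j in range(r):
        u = np.zeros((r, r))
        u[j, j] = 1.0
        comps.append(u)
        names.append(f"singleton_{j}")
    comps.append(np.ones((r, r)))
    names.append("shared")
    return comps, names


def _data_driven_components(
    strong_z: np.ndarray, n_pcs: int = 3
) -> tuple[list[np.ndarray], list[str]]:
    if strong_z.shape[0] < 2:
        return [], []
    x = strong_z - strong_z.mean(axis=0)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    comps, names = [], []
    for j in range(min(n_pcs, len(s))):
        v = vt[j]
        comps.append(np.outer(v, v))
        names.append(f"pc{j + 1}")
    return comps, names


def _mvn_logpdf(z: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Rows of z under N(0, cov); cov is jittered to be safely PD."""
    r = cov.shape[0]
    jitter = 1e-8 * max(1.0, np.trace(cov) / r)
    l = np.linalg.cholesky(cov + jitter * np.eye(r))
    sol = np.linalg.solve(l, z.T)
    quad = (sol**2).sum(axis=0)
    logdet = 2 * np.log(np.diag(l)).sum()
    return -0.5 * (quad + logdet + r * np.log(2 * np.pi))


def fit_shrinkage_model(
    random_panel: EffectPanel,
    strong_panel: EffectPanel | None = None,
    residual_corr: np.ndarray | None = None,
    scale_grid: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0),
    n_pcs: int = 3,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> ShrinkageModel:
    """EM fit of mixture weights over covariance patterns x scales.

    Marginally z_i ~ sum_kl w_kl N(0, s_l^2 U_k + V).  The scale grid is
    ``scale_grid`` times the median squared z of the strong subset (or of the
    random subset when no strong panel is given), anchoring the grid to the
    observed effect range.  The log-likelihood is non-decreasing across EM
    iterations; non-convergence returns the best iterate with
    ``converged=False``.
    """
    z = random_panel.zscores()
    n, r = z.shape
    v = residual_corr if residual_corr is not None else np.eye(r)
    comps, names = _canonical_components(r)
    strong_z = strong_panel.zscores() if strong_panel is not None else None
    if strong_z is not None:
        dd, dd_names = _data_driven_components(strong_z, n_pcs=n_pcs)
        comps += dd
        names += dd_names
    anchor_z = strong_z if strong_z is not None and strong_z.size else z
    base = float(np.median(anchor_z**2))
    base = max(base, 1e-3)
    scales = np.array(scale_grid) * base

    slots = [np.zeros((r, r))] + [s2 * u for u in comps for s2 in scales]
    k = len(slots)
    logp = np.empty((n, k))
    for j, u in enumerate(slots):
        logp[:, j] = _mvn_logpdf(z, u + v)

    w = np.full(k, 1.0 / k)
    path: list[float] = []
    converged = False
    for _ in range(max_iter):
        a = logp + np.log(np.maximum(w, 1e-300))
        m = a.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(a - m).sum(axis=1))
        ll = float(lse.sum())
        path.append(ll)
        gamma = np.exp(a - lse[:, None])
        w = gamma.mean(axis=0)
        if len(path) > 1 and abs(path[-1] - path[-2]) < tol * (1 + abs(path[-2])):
            converged = True
            break
    return ShrinkageModel(
        components=comps,
        component_names=names,
        scales=scales,
        weights=w,
        residual_corr=v,
        loglik_path=path,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Posteriors and LFSR


def posterior_effects(query: EffectPanel, model: ShrinkageModel) -> PosteriorEffects:
    """Mixture-of-normals posterior per test.

    Per component with prior covariance U (on the z scale) and noise V:
    posterior mean U(U+V)^-1 z and covariance U - U(U+V)^-1 U, mixed with
    weights proportional to prior weight times marginal likelihood.  LFSR per
    coordinate is min(P(effect >= 0), P(effect <= 0)), with degenerate
    (point-mass-at-zero) posteriors counting toward both signs.  Posterior
    betas are mapped back to the original scale by the per-test ses.
    """
    z = query.zscores()
    ses = query.ses.to_numpy(float)
    n, r = z.shape
    v = model.residual_corr
    slots = model.expanded()
    k = len(slots)
    w = np.maximum(model.weights, 0)
    w = w / w.sum()

    logp = np.empty((n, k))
    mus = np.empty((k, n, r))
    sds = np.empty((k, r))
    for j, (_, u) in enumerate(slots):
        omega = u + v
        logp[:, j] = _mvn_logpdf(z, omega)
        gain = np.linalg.solve(omega.T, u.T).T  # U (U+V)^-1
        mus[j] = z @ gain.T
        pvar = np.clip(np.diag(u - gain @ u), 0.0, None)
        sds[j] = np.sqrt(pvar)

    a = logp + np.log(np.maximum(w, 1e-300))
    m = a.max(axis=1, keepdims=True)
    gamma = np.exp(a - m)
    gamma /= gamma.sum(axis=1, keepdims=True)

    post_mean_z = np.einsum("nk,knr->nr", gamma, mus)
    second = np.einsum("nk,knr->nr", gamma, mus**2 + sds[:, None, :] ** 2)
    post_var_z = np.clip(second - post_mean_z**2, 0.0, None)

    # sign probabilities: P(effect <= 0) and P(effect >= 0) per coordinate
    p_neg = np.zeros((n, r))
    p_pos = np.zeros((n, r))
    for j in range(k):
        sd = sds[j]
        mu = mus[j]
        point = sd < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            cdf0 = stats.norm.cdf(0.0, loc=mu, scale=np.where(point, 1.0, sd))
        cdf0 = np.where(point[None, :], (mu <= 0).astype(float), cdf0)
        sf0 = np.where(point[None, :], (mu >= 0).astype(float), 1.0 - cdf0)
        # a point mass exactly at zero supports both signs
        zero_mass = point[None, :] & (np.abs(mu) < 1e-12)
        cdf0 = np.where(zero_mass, 1.0, cdf0)
        sf0 = np.where(zero_mass, 1.0, sf0)
        p_neg += gamma[:, j : j + 1] * cdf0
        p_pos += gamma[:, j : j + 1] * sf0
    lfsr = np.minimum(p_neg, p_pos)

    idx, cols = query.betas.index, query.betas.columns
    return PosteriorEffects(
        post_mean=pd.DataFrame(post_mean_z * ses, index=idx, columns=cols),
        post_sd=pd.DataFrame(np.sqrt(post_var_z) * ses, index=idx, columns=cols),
        lfsr=pd.DataFrame(np.clip(lfsr, 0, 1), index=idx, columns=cols),
    )


def call_response_sqtls(post: PosteriorEffects, max_lfsr: float = 0.05) -> pd.DataFrame:
    """Flag responses: contrast LFSR strictly below ``max_lfsr`` per
    condition, plus an any-condition gene-level flag."""
    flags = post.lfsr < max_lfsr
    flags["any_response"] = flags.any(axis=1)
    return flags
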