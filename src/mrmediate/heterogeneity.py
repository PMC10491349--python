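"""Decomposition of per-SNP heterogeneity in univariable MR.

Three complementary views of the same question — which instruments do not
share the common causal slope:

* :class:`RadialMR` — radial reparameterization making each SNP's
  contribution to Cochran's Q explicit; SNPs with an improbably large
  contribution (chi-square(1) tail, Bonferroni by default) are flagged and
  an outlier-corrected IVW estimate is reported.
* :class:`MRPresso` — simulation-based global heterogeneity test on the
  leave-one-out residual sum of squares, per-SNP outlier tests against each
  SNP's simulated null, and a distortion test comparing the outlier-removed
  estimate against removal of random subsets.
* :class:`RatioClustering` — EM fit of a mixture over the per-SNP ratio
  estimates (K free Normal components plus a zero-mean null component and a
  broad uniform junk component), assigning SNPs to putative causal
  mechanisms by conditional probability.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

from .data import HarmonizedDataset
from .univariable import MRResults, cochran_q, ivw

logger = logging.getLogger(__name__)

RADIAL_TOL = 1e-8
RADIAL_MAX_ITER = 100


@dataclass
class OutlierReport:
    """Per-SNP outlier diagnosis plus original and corrected estimates."""

    method: str  # "radial" | "presso"
    per_snp: pd.DataFrame  # snp_id, ratio, weight, Q_contribution, outlier_pval, flagged
    estimate_original: MRResults
    estimate_corrected: MRResults
    global_test_pval: float = np.nan
    distortion_pval: float = np.nan

    @property
    def flagged_ids(self) -> list:
        return self.per_snp.loc[self.per_snp["flagged"], "snp_id"].tolist()

    @property
    def n_flagged(self) -> int:
        return int(self.per_snp["flagged"].sum())

    @property
    def total_Q(self) -> float:
        return float(self.per_snp["Q_contribution"].sum())

    def to_frame(self) -> pd.DataFrame:
        return self.per_snp.copy()

    def summary(self) -> str:
        o, c = self.estimate_original, self.estimate_corrected
        lines = [
            f"Outlier analysis ({self.method}): {self.n_flagged} of "
            f"{len(self.per_snp)} instruments flagged",
        ]
        if self.flagged_ids:
            lines.append(f"  flagged     : {', '.join(self.flagged_ids)}")
        if np.isfinite(self.global_test_pval):
            lines.append(f"  global test : p = {self.global_test_pval:.3g}")
        if np.isfinite(self.distortion_pval):
            lines.append(f"  distortion  : p = {self.distortion_pval:.3g}")
        lines.append(f"  original    : beta {o.beta: .4f} (se {o.se:.4f})")
        lines.append(f"  corrected   : beta {c.beta: .4f} (se {c.se:.4f})")
        return "\n".join(lines)


def _corrected_estimate(data: HarmonizedDataset, flagged: np.ndarray) -> MRResults:
    if flagged.all():
        return ivw(data, "mre")
    return ivw(data.subset(~flagged), "mre")


def radial_outliers(
    data: HarmonizedDataset,
    alpha: float | str = "bonferroni",
    weights: str = "first",
) -> OutlierReport:
    """Radial-regression outlier detection via per-SNP Q contributions.

    The radial estimate is the weight-mean of the per-SNP ratios,
    ratio_j * sqrt(w_j) regressed on sqrt(w_j) through the origin. Weight
    choices: "first" (bx^2/se_Y^2, under which per-SNP contributions sum
    exactly to Cochran's Q), "second" (full second-order delta variance),
    or "modified_second" (iterated w_j = bx_j^2 / (se_Yj^2 + b^2 se_Xj^2),
    updated with the estimate until convergence). A SNP is flagged when the
    chi-square(1) upper tail of its Q contribution falls below ``alpha``
    (default: Bonferroni, 0.05 / L).
    """
    if data.K != 1:
        raise ValueError("radial outlier analysis requires a single exposure")
    L = data.n_snps
    if L < 3:
        raise ValueError("radial outlier analysis requires >= 3 instruments")
    if weights not in ("first", "second", "modified_second"):
        raise ValueError("weights must be first|second|modified_second")
    bx, by = data.beta_X[:, 0], data.beta_Y
    sx, sy = data.se_X[:, 0], data.se_Y
    ratio = by / bx

    if weights == "first":
        w = bx**2 / sy**2
        beta = float(np.sum(w * ratio) / np.sum(w))
    elif weights == "second":
        var = sy**2 / bx**2 + by**2 * sx**2 / bx**4
        w = 1.0 / var
        beta = float(np.sum(w * ratio) / np.sum(w))
    else:
        w = bx**2 / sy**2
        beta = float(np.sum(w * ratio) / np.sum(w))
        trace = [beta]
        for _ in range(RADIAL_MAX_ITER):
            w = bx**2 / (sy**2 + beta**2 * sx**2)
            new = float(np.sum(w * ratio) / np.sum(w))
            delta, beta = abs(new - beta), new
            trace.append(beta)
            if delta < RADIAL_TOL:
                break
        else:
            raise RuntimeError(
                "modified second-order radial weights did not converge after "
                f"{RADIAL_MAX_ITER} iterations; estimate trace: {trace}"
            )

    Q_j = w * (ratio - beta) ** 2
    pvals = sps.chi2.sf(Q_j, 1)
    a = 0.05 / L if alpha == "bonferroni" else float(alpha)
    flagged = pvals < a
    Q_total = float(Q_j.sum())
    per_snp = pd.DataFrame(
        {
            "snp_id": data.snp_ids,
            "ratio": ratio,
            "weight": w,
            "Q_contribution": Q_j,
            "outlier_pval": pvals,
            "flagged": flagged,
        }
    )
    return OutlierReport(
        method="radial",
        per_snp=per_snp,
        estimate_original=ivw(data, "mre"),
        estimate_corrected=_corrected_estimate(data, flagged),
        global_test_pval=float(sps.chi2.sf(Q_total, L - 1)),
    )


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes; supports (L,) vectors or (n_sim, L) matrices."""
    Sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    Sxx = np.sum(w * bx**2, axis=-1, keepdims=True)
    out = (Sxy - w * bx * by) / (Sxx - w * bx**2)
    return out


def presso(
    data: HarmonizedDataset,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
) -> OutlierReport:
    """Simulation-based global, per-SNP outlier and distortion tests.

    Observed statistic: the sum over SNPs of squared leave-one-out
    residuals (by_j minus the LOO IVW prediction, standardized by the
    delta-method residual SD). Its null distribution is built from ``n_sim``
    parametric draws under the LOO-fitted model with each SNP's own SEs, the
    statistic recomputed identically on each draw. Per-SNP outlier tests
    compare each observed squared residual with its own simulated null
    (Bonferroni at ``outlier_alpha``). When outliers are flagged, the
    distortion test compares the change in estimate after their removal with
    removal of random subsets of the same size.
    """
    if data.K != 1:
        raise ValueError("presso requires a single exposure")
    L = data.n_snps
    if L < 4:
        raise ValueError("presso requires >= 4 instruments")
    if n_sim < 100:
        raise ValueError("insufficient simulations: n_sim must be >= 100")
    if n_sim < L / outlier_alpha:
        logger.warning(
            "n_sim=%d gives an empirical p-value floor of %.2g, above the "
            "Bonferroni outlier threshold %.2g — no SNP can be flagged; "
            "increase n_sim", n_sim, 1 / (n_sim + 1), outlier_alpha / L,
        )
    rng = np.random.default_rng(seed)
    bx, by = data.beta_X[:, 0], data.beta_Y
    sx, sy = data.se_X[:, 0], data.se_Y
    w = 1.0 / sy**2

    b_loo = _loo_slopes(bx, by, w)
    resid_sd = np.sqrt(sy**2 + b_loo**2 * sx**2)
    e_obs = ((by - b_loo * bx) / resid_sd) ** 2
    rss_obs = float(e_obs.sum())

    bx_sim = rng.normal(bx, sx, size=(n_sim, L))
    by_sim = rng.normal(b_loo * bx, sy, size=(n_sim, L))
    b_loo_sim = _loo_slopes(bx_sim, by_sim, w)
    sd_sim = np.sqrt(sy**2 + b_loo_sim**2 * sx**2)
    e_sim = ((by_sim - b_loo_sim * bx_sim) / sd_sim) ** 2
    rss_sim = e_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    pvals = (1 + np.sum(e_sim >= e_obs, axis=0)) / (n_sim + 1)
    flagged = pvals < outlier_alpha / L

    original = ivw(data, "mre")
    corrected = _corrected_estimate(data, flagged)

    distortion_p = np.nan
    k = int(flagged.sum())
    if 0 < k < L - 1:
        d_obs = corrected.beta - original.beta
        d_null = np.empty(n_sim)
        for i in range(n_sim):
            drop = rng.choice(L, size=k, replace=False)
            keep = np.ones(L, dtype=bool)
            keep[drop] = False
            b_sub = float(
                np.sum(w[keep] * bx[keep] * by[keep]) / np.sum(w[keep] * bx[keep] ** 2)
            )
            d_null[i] = b_sub - original.beta
        distortion_p = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))

    per_snp = pd.DataFrame(
        {
            "snp_id": data.snp_ids,
            "ratio": by / bx,
            "weight": bx**2 / sy**2,
            "Q_contribution": e_obs,
            "outlier_pval": pvals,
            "flagged": flagged,
        }
    )
    return OutlierReport(
        method="presso",
        per_snp=per_snp,
        estimate_original=original,
        estimate_corrected=corrected,
        global_test_pval=global_p,
        distortion_pval=distortion_p,
    )


# ---------------------------------------------------------------------------
# Mixture-model clustering of ratio estimates
# ---------------------------------------------------------------------------

EM_TOL = 1e-8
EM_MAX_ITER = 500


@dataclass
class ClusterResults:
    """Mixture-model assignment of instruments to causal-mechanism clusters."""

    n_components: int  # K (substantive clusters, excluding null and junk)
    assignments: pd.DataFrame  # snp_id, ratio, se, label, inclusion_probability
    cluster_table: pd.DataFrame  # label, mean, size, ivw_beta, ivw_se
    posterior: np.ndarray  # (L, K+2) columns: clusters..., null, junk
    log_likelihood: float
    bic: float
    seed: int | None = None
    prob_threshold: float = 0.9
    component_means: np.ndarray = field(default_factory=lambda: np.array([]))
    mixing_proportions: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        return self.assignments.copy()

    def summary(self) -> str:
        lines = [
            f"Ratio-estimate clustering: K = {self.n_components} substantive "
            f"cluster(s) (BIC {self.bic:.1f})"
        ]
        for _, row in self.cluster_table.iterrows():
            mean = "" if np.isnan(row["mean"]) else f" mean slope {row['mean']: .3f}"
            est = (
                ""
                if np.isnan(row["ivw_beta"])
                else f"  IVW {row['ivw_beta']: .3f} (se {row['ivw_se']:.3f})"
            )
            lines.append(f"  {row['label']:<12s} size {int(row['size'])}{mean}{est}")
        return "\n".join(lines)


def _em_fit(r, s, K, mu_init, max_iter=EM_MAX_ITER, tol=EM_TOL):
    """EM for K free Normals + null (mean 0) + uniform junk; returns fit dict."""
    L = len(r)
    lo = float(np.min(r - 10 * s))
    hi = float(np.max(r + 10 * s))
    log_junk = -np.log(hi - lo)
    n_comp = K + 2
    mu = np.array(mu_init, float)
    pi = np.full(n_comp, 1.0 / n_comp)
    prec = 1.0 / s**2

    def log_dens(mu_now):
        cols = []
        for k in range(K):
            cols.append(sps.norm.logpdf(r, mu_now[k], s))
        cols.append(sps.norm.logpdf(r, 0.0, s))  # null
        cols.append(np.where((r >= lo) & (r <= hi), log_junk, -np.inf))  # junk
        return np.column_stack(cols)

    prev = -np.inf
    for _ in range(max_iter):
        ld = log_dens(mu) + np.log(np.maximum(pi, 1e-300))
        norm = logsumexp(ld, axis=1)
        resp = np.exp(ld - norm[:, None])
        loglik = float(norm.sum())
        pi = resp.mean(axis=0)
        for k in range(K):
            denom = np.sum(resp[:, k] * prec)
            if denom > 1e-12:
                mu[k] = np.sum(resp[:, k] * prec * r) / denom
        if abs(loglik - prev) < tol:
            prev = loglik
            break
        prev = loglik
    else:
        return None  # no convergence
    n_params = 2 * K + 1  # K means + (K+2-1) free mixing proportions... see note
    # Note: parameter count = K means + (n_comp - 1) proportions = 2K + 1.
    bic = -2.0 * prev + n_params * np.log(L)
    return {"mu": mu, "pi": pi, "resp": resp, "loglik": prev, "bic": bic, "K": K}


def cluster_ratios(
    data: HarmonizedDataset,
    max_K: int = 5,
    prob_threshold: float = 0.9,
    seed: int | None = None,
    n_restarts: int = 20,
) -> ClusterResults:
    """Cluster instruments by their ratio estimates via an EM mixture fit.

    The observation model for SNP j is its Wald ratio with known first-order
    SE. Components: K free Normal means (putative mechanisms), a null
    component fixed at 0, and a junk component uniform over the observed
    ratio range +- 10 SDs. K is chosen in 0..``max_K`` by BIC over seeded
    random restarts. A SNP is labeled with its highest-posterior component
    only when that probability reaches ``prob_threshold``, else
    "unassigned".
    """
    if data.K != 1:
        raise ValueError("clustering requires a single exposure")
    L = data.n_snps
    if L < 3:
        raise ValueError("clustering requires >= 3 instruments")
    if max_K < 1:
        raise ValueError("max_K must be >= 1")
    bx = data.beta_X[:, 0]
    r = data.beta_Y / bx
    s = data.se_Y / np.abs(bx)
    rng = np.random.default_rng(seed)
    r_sorted = np.sort(r)

    best = None
    for K in range(0, max_K + 1):
        best_K = None
        restarts = 1 if K == 0 else n_restarts
        for rep in range(restarts):
            if K == 0:
                mu0 = []
            elif rep == 0:
                # deterministic quantile init (invariant to SNP order)
                qs = (np.arange(K) + 0.5) / K
                mu0 = np.quantile(r_sorted, qs)
            else:
                mu0 = rng.uniform(r_sorted[0], r_sorted[-1], size=K)
            fit = _em_fit(r, s, K, mu0)
            if fit is None:
                continue
            if best_K is None or fit["loglik"] > best_K["loglik"]:
                best_K = fit
        if best_K is None:
            continue
        if best is None or best_K["bic"] < best["bic"]:
            best = best_K
    if best is None:
        raise RuntimeError("EM failed to converge in all restarts for every K")

    K = best["K"]
    resp = best["resp"]
    # order substantive clusters by descending size for stable naming
    order = np.argsort(-resp[:, :K].sum(axis=0), kind="mergesort") if K else np.array([], int)
    names = [f"cluster_{i + 1}" for i in range(K)]
    col_names = [""] * (K + 2)
    for new_i, old_k in enumerate(order):
        col_names[old_k] = names[new_i]
    col_names[K] = "null"
    col_names[K + 1] = "junk"

    top = resp.argmax(axis=1)
    top_p = resp[np.arange(L), top]
    labels = [
        col_names[t] if p >= prob_threshold else "unassigned"
        for t, p in zip(top, top_p)
    ]
    assignments = pd.DataFrame(
        {
            "snp_id": data.snp_ids,
            "ratio": r,
            "se": s,
            "label": labels,
            "inclusion_probability": top_p,
        }
    )

    rows = []
    for ci, cname in enumerate(col_names):
        members = [j for j in range(L) if labels[j] == cname]
        mean = float(best["mu"][ci]) if ci < K else (0.0 if cname == "null" else np.nan)
        ivw_beta = ivw_se = np.nan
        if members and cname not in ("junk",):
            sub = data.subset(np.asarray(members))
            est = ivw(sub, "mre")
            ivw_beta, ivw_se = est.beta, est.se
        rows.append(
            {"label": cname, "mean": mean, "size": len(members),
             "ivw_beta": ivw_beta, "ivw_se": ivw_se}
        )
    cluster_table = pd.DataFrame(rows)

    return ClusterResults(
        n_components=K,
        assignments=assignments,
        cluster_table=cluster_table,
        posterior=resp[:, list(order) + [K, K + 1]] if K else resp,
        log_likelihood=best["loglik"],
        bic=best["bic"],
        seed=seed,
        prob_threshold=prob_threshold,
        component_means=np.asarray([best["mu"][k] for k in order]) if K else np.array([]),
        mixing_proportions=best["pi"],
    )


class RadialMR:
    """Model wrapper for radial outlier analysis."""

    def __init__(self, data: HarmonizedDataset):
        self.data = data

    def fit(self, alpha: float | str = "bonferroni", weights: str = "first") -> OutlierReport:
        return radial_outliers(self.data, alpha=alpha, weights=weights)


class MRPresso:
    """Model wrapper for the simulation-based outlier/distortion analysis."""

    def __init__(self, data: HarmonizedDataset):
        self.data = data

    def fit(self, n_sim: int = 1000, outlier_alpha: float = 0.05, seed: int | None = None) -> OutlierReport:
        return presso(self.data, n_sim=n_sim, outlier_alpha=outlier_alpha, seed=seed)


class RatioClustering:
    """Model wrapper for mixture-model clustering of ratio estimates."""

    def __init__(self, data: HarmonizedDataset):
        self.data = data

    def fit(self, max_K: int = 5, prob_threshold: float = 0.9, seed: int | None = None,
            n_restarts: int = 20) -> ClusterResults:
        return cluster_ratios(
            self.data, max_K=max_K, prob_threshold=prob_threshold,
            seed=seed, n_restarts=n_restarts,
        )
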