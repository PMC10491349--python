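"""Multivariable MR: direct effects of K >= 2 exposures with diagnostics.

The model regresses outcome associations on the K columns of exposure
associations (no intercept) with inverse-variance weights, giving each
exposure's direct effect conditional on the others. Diagnostics follow the
two-sample, non-overlapping design: conditional instrument-strength F per
exposure and the adapted heterogeneity statistic Q_A on L - K degrees of
freedom. Cross-exposure sampling covariances are taken as zero — the
non-overlapping-samples assumption; results for overlapping GWAS samples
would need the covariance terms this package deliberately omits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .data import HarmonizedDataset


@dataclass
class MVMRResults:
    """Direct-effect estimates from a multivariable MR fit."""

    exposure_names: list
    betas: np.ndarray
    ses: np.ndarray
    n_snps: int
    conditional_F: np.ndarray
    Q_A: float
    Q_A_df: int
    Q_A_pval: float
    outcome: str = ""
    alpha_level: float = 0.05

    @property
    def pvals(self) -> np.ndarray:
        return 2.0 * sps.norm.sf(np.abs(self.betas / self.ses))

    def conf_int(self, alpha: float | None = None) -> np.ndarray:
        a = self.alpha_level if alpha is None else alpha
        z = sps.norm.ppf(1 - a / 2)
        return np.column_stack([self.betas - z * self.ses, self.betas + z * self.ses])

    @property
    def ci_lows(self) -> np.ndarray:
        return self.conf_int()[:, 0]

    @property
    def ci_highs(self) -> np.ndarray:
        return self.conf_int()[:, 1]

    def effect(self, exposure: str) -> tuple[float, float]:
        """(beta, se) of the named exposure's direct effect."""
        k = list(self.exposure_names).index(exposure)
        return float(self.betas[k]), float(self.ses[k])

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "exposure": self.exposure_names,
                "beta": self.betas,
                "se": self.ses,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "pval": self.pvals,
                "conditional_F": self.conditional_F,
                "n_snps": self.n_snps,
                "Q_A": self.Q_A,
                "Q_A_df": self.Q_A_df,
                "Q_A_pval": self.Q_A_pval,
            }
        )

    def summary(self) -> str:
        lines = [
            f"Multivariable MR -> {self.outcome or 'outcome'}  "
            f"({self.n_snps} instruments, {len(self.exposure_names)} exposures)"
        ]
        ci = self.conf_int()
        for k, name in enumerate(self.exposure_names):
            warn = "" if self.conditional_F[k] >= 10 else "  [weak: cond. F < 10]"
            lines.append(
                f"  {name:<20s} beta {self.betas[k]: .4f} (se {self.ses[k]:.4f}) "
                f"CI [{ci[k, 0]: .4f}, {ci[k, 1]: .4f}] p = {self.pvals[k]:.3g} "
                f"cond. F = {self.conditional_F[k]:.1f}{warn}"
            )
        lines.append(
            f"  Q_A = {self.Q_A:.2f} on {self.Q_A_df} df (p = {self.Q_A_pval:.3g})"
        )
        return "\n".join(lines)


def q_a(data: HarmonizedDataset, betas: np.ndarray) -> tuple[float, int, float]:
    """Adapted heterogeneity statistic for MVMR at plug-in direct effects.

    Q_A = sum_j (beta_Yj - sum_k beta_Xjk * beta_k)^2 / se_Yj^2, referred to
    chi-square on L - K degrees of freedom.
    """
    if data.K < 2:
        raise ValueError("Q_A is defined for K >= 2 exposures")
    betas = np.asarray(betas, float)
    resid = data.beta_Y - data.beta_X @ betas
    Q = float(np.sum(resid**2 / data.se_Y**2))
    df = data.n_snps - data.K
    return Q, df, float(sps.chi2.sf(Q, df)) if df > 0 else np.nan


def conditional_f(data: HarmonizedDataset, exposure_index: int) -> float:
    """Conditional instrument strength of one exposure given the others.

    Computed as the heterogeneity-form statistic: regress the chosen
    exposure's associations on the remaining exposures' associations with
    weights 1/se^2 of the chosen exposure (cross-trait sampling covariance
    zero under non-overlapping samples), and divide the weighted residual
    sum of squares by L - K + 1.
    """
    if data.K < 2:
        raise ValueError("conditional F requires K >= 2 exposures")
    k = exposure_index
    y = data.beta_X[:, k]
    X = np.delete(data.beta_X, k, axis=1)
    w = 1.0 / data.se_X[:, k] ** 2
    fit = sm.WLS(y, X, weights=w).fit()
    Q_x = float(np.sum(w * (y - fit.fittedvalues) ** 2))
    return Q_x / (data.n_snps - data.K + 1)


def mvmr_ivw(data: HarmonizedDataset) -> MVMRResults:
    """Direct effects of all exposures by inverse-variance-weighted MVMR.

    Weighted least squares of beta_Y on the K exposure columns (no
    intercept), weights 1/se_Y^2. SEs carry the multiplicative heterogeneity
    scaling max(1, sqrt(Q_A / (L - K))).
    """
    K, L = data.K, data.n_snps
    if K < 2:
        raise ValueError("MVMR requires K >= 2 exposures")
    if L < K + 1:
        raise ValueError(f"MVMR requires at least K+1 = {K + 1} instruments, got {L}")
    w = 1.0 / data.se_Y**2
    Xw = np.sqrt(w)[:, None] * data.beta_X
    if np.linalg.matrix_rank(Xw) < K:
        raise ValueError("collinear exposures: the exposure-association matrix is rank deficient")
    fit = sm.WLS(data.beta_Y, data.beta_X, weights=w).fit()
    betas = np.asarray(fit.params, float)
    Q_A, df, Q_p = q_a(data, betas)
    cov = np.linalg.inv(data.beta_X.T @ (w[:, None] * data.beta_X))
    scale = max(1.0, np.sqrt(Q_A / df)) if df > 0 else 1.0
    ses = np.sqrt(np.diag(cov)) * scale
    cond_F = np.array([conditional_f(data, k) for k in range(K)])
    return MVMRResults(
        exposure_names=list(data.exposure_names),
        betas=betas, ses=ses, n_snps=L,
        conditional_F=cond_F, Q_A=Q_A, Q_A_df=df, Q_A_pval=Q_p,
        outcome=data.outcome_name,
    )


class MultivariableMR:
    """Multivariable MR model over a harmonized dataset with K >= 2 exposures."""

    def __init__(self, data: HarmonizedDataset):
        if data.K < 2:
            raise ValueError("MultivariableMR requires K >= 2 exposures")
        self.data = data

    def fit(self) -> MVMRResults:
        return mvmr_ivw(self.data)

    def conditional_f(self, exposure_index: int) -> float:
        return conditional_f(self.data, exposure_index)

    def q_a(self, betas: np.ndarray):
        return q_a(self.data, betas)
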