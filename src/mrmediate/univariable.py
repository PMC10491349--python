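"""Univariable two-sample MR estimators and instrument diagnostics.

:class:`UnivariableMR` is the model object: construct it from a
:class:`~mrmediate.data.HarmonizedDataset` with one exposure and call
:meth:`~UnivariableMR.fit` with the estimator of choice. Results objects
carry the causal estimate, its uncertainty, heterogeneity (Cochran's Q) and
instrument-strength diagnostics, and render a text ``summary()``.

Estimators
----------
ivw_fe / ivw_mre
    Inverse-variance-weighted slope of outcome on exposure associations
    through the origin (fixed effects, or multiplicative random effects
    scaling the SE by sqrt(Q / (L-1)) when Q exceeds its degrees of freedom).
egger
    Weighted regression with an intercept; the intercept estimates average
    directional horizontal pleiotropy. Inputs are first oriented so all
    exposure associations are non-negative.
weighted_median
    Weighted median of the per-SNP Wald ratios; consistent when at least half
    of the total instrument weight comes from valid instruments. SE by
    seeded parametric bootstrap.
wald
    Single-instrument ratio estimate (requires exactly one SNP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .data import HarmonizedDataset

METHOD_LABELS = {
    "wald": "Wald ratio",
    "ivw_fe": "IVW (fixed effects)",
    "ivw_mre": "IVW (multiplicative random effects)",
    "egger": "MR-Egger",
    "weighted_median": "Weighted median",
}


@dataclass
class MRResults:
    """Causal-effect estimate from one univariable MR estimator."""

    method: str
    beta: float
    se: float
    n_snps: int
    Q: float = np.nan
    Q_df: int = 0
    Q_pval: float = np.nan
    mean_F: float = np.nan
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    exposure: str = ""
    outcome: str = ""
    alpha_level: float = 0.05

    @property
    def zvalue(self) -> float:
        return self.beta / self.se if self.se > 0 else np.inf * np.sign(self.beta)

    @property
    def pval(self) -> float:
        return float(2.0 * sps.norm.sf(abs(self.zvalue)))

    def conf_int(self, alpha: float | None = None) -> tuple[float, float]:
        a = self.alpha_level if alpha is None else alpha
        z = sps.norm.ppf(1 - a / 2)
        return (self.beta - z * self.se, self.beta + z * self.se)

    @property
    def ci_low(self) -> float:
        return self.conf_int()[0]

    @property
    def ci_high(self) -> float:
        return self.conf_int()[1]

    def odds_ratio(self) -> tuple[float, float, float]:
        """OR with CI — meaningful only for log-odds scale outcomes."""
        lo, hi = self.conf_int()
        return (float(np.exp(self.beta)), float(np.exp(lo)), float(np.exp(hi)))

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.conf_int()
        row = {
            "method": self.method, "beta": self.beta, "se": self.se,
            "ci_low": lo, "ci_high": hi, "pval": self.pval,
            "n_snps": self.n_snps, "Q": self.Q, "Q_df": self.Q_df,
            "Q_pval": self.Q_pval, "mean_F": self.mean_F,
        }
        if self.intercept is not None:
            row.update(
                intercept=self.intercept,
                intercept_se=self.intercept_se,
                intercept_pval=self.intercept_pval,
            )
        return pd.DataFrame([row])

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            f"Univariable MR: {self.exposure or 'exposure'} -> {self.outcome or 'outcome'}",
            f"  method      : {METHOD_LABELS.get(self.method, self.method)}",
            f"  n_snps      : {self.n_snps}",
            f"  beta        : {self.beta: .4f}  (se {self.se:.4f})",
            f"  95% CI      : [{lo: .4f}, {hi: .4f}]   p = {self.pval:.3g}",
        ]
        if np.isfinite(self.Q):
            lines.append(
                f"  Cochran's Q : {self.Q:.2f} on {self.Q_df} df  (p = {self.Q_pval:.3g})"
            )
        if np.isfinite(self.mean_F):
            flag = "" if self.mean_F >= 10 else "  [weak instruments: F < 10]"
            lines.append(f"  mean F      : {self.mean_F:.1f}{flag}")
        if self.intercept is not None:
            lines.append(
                f"  Egger intercept: {self.intercept: .5f} "
                f"(se {self.intercept_se:.5f}, p = {self.intercept_pval:.3g})"
            )
        return "\n".join(lines)


@dataclass
class SteigerResult:
    """Per-SNP directionality test: variance explained in exposure vs outcome."""

    snp_ids: list
    r2_exposure: np.ndarray
    r2_outcome: np.ndarray
    direction_correct: np.ndarray
    steiger_pval: np.ndarray
    retained_snp_ids: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "r2_exposure": self.r2_exposure,
                "r2_outcome": self.r2_outcome,
                "direction_correct": self.direction_correct,
                "steiger_pval": self.steiger_pval,
            }
        )


def _require_single_exposure(data: HarmonizedDataset) -> None:
    if data.K != 1:
        raise ValueError(f"univariable MR requires a single exposure, got K={data.K}")


def wald_ratios(data: HarmonizedDataset, second_order: bool = False) -> pd.DataFrame:
    """Per-SNP ratio estimates beta_Y / beta_X with delta-method SEs.

    The default SE is the first-order approximation se_Y/|beta_X|;
    ``second_order`` adds the exposure-uncertainty term. SNPs with
    beta_X = 0 are excluded (logged in the returned frame's attrs).
    """
    _require_single_exposure(data)
    bx = data.beta_X[:, 0]
    nonzero = bx != 0
    if not nonzero.any():
        raise ValueError("all exposure associations are zero; Wald ratios undefined")
    d = data.subset(nonzero)
    bx = d.beta_X[:, 0]
    ratio = d.beta_Y / bx
    var = d.se_Y**2 / bx**2
    if second_order:
        var = var + d.beta_Y**2 * d.se_X[:, 0] ** 2 / bx**4
    out = pd.DataFrame(
        {"snp_id": d.snp_ids, "ratio": ratio, "se": np.sqrt(var)}
    )
    out.attrs["n_excluded_zero_beta_x"] = int((~nonzero).sum())
    return out


def cochran_q(
    data: HarmonizedDataset, beta_hat: float | None = None
) -> tuple[float, int, float]:
    """Cochran's Q over per-SNP ratios, weights beta_X^2 / se_Y^2."""
    _require_single_exposure(data)
    L = data.n_snps
    if L < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    bx, by, sy = data.beta_X[:, 0], data.beta_Y, data.se_Y
    w = bx**2 / sy**2
    if beta_hat is None:
        beta_hat = float(np.sum(by * bx / sy**2) / np.sum(bx**2 / sy**2))
    ratio = by / bx
    Q = float(np.sum(w * (ratio - beta_hat) ** 2))
    df = L - 1
    return Q, df, float(sps.chi2.sf(Q, df))


def mean_f_statistic(data: HarmonizedDataset) -> float:
    """Mean per-SNP instrument-strength F, i.e. mean of (beta_X/se_X)^2."""
    _require_single_exposure(data)
    return float(np.mean((data.beta_X[:, 0] / data.se_X[:, 0]) ** 2))


def ivw(data: HarmonizedDataset, mode: str = "mre") -> MRResults:
    """Inverse-variance-weighted estimate (regression through the origin).

    ``mode="fe"`` reports the analytic fixed-effect SE; ``mode="mre"``
    multiplies it by max(1, sqrt(Q/(L-1))) — the multiplicative
    random-effects model, the package default.
    """
    _require_single_exposure(data)
    if mode not in ("fe", "mre"):
        raise ValueError("mode must be 'fe' or 'mre'")
    L = data.n_snps
    if L == 0:
        raise ValueError("no instruments")
    bx, by, sy = data.beta_X[:, 0], data.beta_Y, data.se_Y
    w = 1.0 / sy**2
    fit = sm.WLS(by, bx[:, None], weights=w).fit()
    beta = float(fit.params[0])
    se_fe = float(np.sqrt(1.0 / np.sum(w * bx**2)))
    if L >= 2:
        Q, Q_df, Q_p = cochran_q(data, beta)
    else:
        Q, Q_df, Q_p = 0.0, 0, np.nan
    scale = max(1.0, np.sqrt(Q / Q_df)) if Q_df > 0 else 1.0
    se = se_fe if mode == "fe" else se_fe * scale
    return MRResults(
        method=f"ivw_{mode}", beta=beta, se=se, n_snps=L,
        Q=Q, Q_df=Q_df, Q_pval=Q_p, mean_F=mean_f_statistic(data),
        exposure=data.exposure_names[0], outcome=data.outcome_name,
    )


def egger(data: HarmonizedDataset) -> MRResults:
    """MR-Egger regression: weighted fit with intercept, exposure-oriented.

    Inputs are oriented so every exposure association is non-negative (the
    outcome association's sign flips with it); the intercept then estimates
    average directional pleiotropy. Both SEs carry the multiplicative
    heterogeneity scaling max(1, sqrt(Q/(L-2))).
    """
    _require_single_exposure(data)
    L = data.n_snps
    if L < 3:
        raise ValueError("insufficient instruments for Egger (need >= 3)")
    sign = np.where(data.beta_X[:, 0] >= 0, 1.0, -1.0)
    bx = data.beta_X[:, 0] * sign
    by = data.beta_Y * sign
    sy = data.se_Y
    w = 1.0 / sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    intercept, beta = (float(v) for v in fit.params)
    resid = by - fit.fittedvalues
    Q = float(np.sum(w * resid**2))
    Q_df = L - 2
    scale = max(1.0, np.sqrt(Q / Q_df)) if Q_df > 0 else 1.0
    # analytic (unscaled) WLS covariance, then multiplicative heterogeneity scaling
    XtWX_inv = np.linalg.inv(X.T @ (w[:, None] * X))
    se_int, se_beta = np.sqrt(np.diag(XtWX_inv)) * scale
    int_p = float(2.0 * sps.norm.sf(abs(intercept / se_int)))
    return MRResults(
        method="egger", beta=beta, se=float(se_beta), n_snps=L,
        Q=Q, Q_df=Q_df, Q_pval=float(sps.chi2.sf(Q, Q_df)),
        mean_F=mean_f_statistic(data),
        intercept=intercept, intercept_se=float(se_int), intercept_pval=int_p,
        exposure=data.exposure_names[0], outcome=data.outcome_name,
    )


def _weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio, kind="mergesort")
    r, w = ratio[order], weight[order]
    w = w / w.sum()
    cum = np.cumsum(w)
    p = cum - w / 2.0  # cumulative midpoints
    return float(np.interp(0.5, p, r))


def weighted_median(
    data: HarmonizedDataset, n_boot: int = 1000, seed: int | None = None
) -> MRResults:
    """Weighted median of Wald ratios; SE by seeded parametric bootstrap."""
    _require_single_exposure(data)
    L = data.n_snps
    if L < 3:
        raise ValueError("insufficient instruments for weighted median (need >= 3)")
    bx, by = data.beta_X[:, 0], data.beta_Y
    sx, sy = data.se_X[:, 0], data.se_Y
    ratio = by / bx
    weight = bx**2 / sy**2  # inverse variance of first-order ratio SE
    beta = _weighted_median_point(ratio, weight)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, L))
    by_b = rng.normal(by, sy, size=(n_boot, L))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        r_b = by_b[i] / bx_b[i]
        w_b = bx_b[i] ** 2 / sy**2
        boots[i] = _weighted_median_point(r_b, w_b)
    se = float(np.std(boots, ddof=1))
    Q, Q_df, Q_p = cochran_q(data) if L >= 2 else (np.nan, 0, np.nan)
    return MRResults(
        method="weighted_median", beta=beta, se=se, n_snps=L,
        Q=Q, Q_df=Q_df, Q_pval=Q_p, mean_F=mean_f_statistic(data),
        exposure=data.exposure_names[0], outcome=data.outcome_name,
    )


def steiger_filter(
    data: HarmonizedDataset, alpha: float = 0.05
) -> tuple[SteigerResult, HarmonizedDataset]:
    """Directionality (Steiger) filtering of instruments.

    Per-SNP variance explained is r^2 = t^2 / (t^2 + n - 2) with t = beta/se
    for each trait (for a binary outcome this is on the observed log-odds
    scale and approximate). A SNP is flagged direction-incorrect — and
    removed from the returned dataset — when it explains more variance in
    the outcome than in the exposure and the one-sided two-sample test of
    the correlation difference rejects at ``alpha``.
    """
    _require_single_exposure(data)
    nx, ny = data.n_X[:, 0], data.n_Y
    if np.any(nx <= 3) or np.any(ny <= 3):
        raise ValueError("Steiger filtering requires per-trait sample sizes > 3")
    tx = data.beta_X[:, 0] / data.se_X[:, 0]
    ty = data.beta_Y / data.se_Y
    r2x = tx**2 / (tx**2 + nx - 2)
    r2y = ty**2 / (ty**2 + ny - 2)
    zx = np.arctanh(np.sqrt(r2x))
    zy = np.arctanh(np.sqrt(r2y))
    z = (zy - zx) / np.sqrt(1.0 / (nx - 3) + 1.0 / (ny - 3))
    pval = sps.norm.sf(z)  # small when outcome r2 significantly larger
    incorrect = (r2y > r2x) & (pval < alpha)
    result = SteigerResult(
        snp_ids=list(data.snp_ids),
        r2_exposure=r2x, r2_outcome=r2y,
        direction_correct=~incorrect, steiger_pval=pval,
        retained_snp_ids=[s for s, ok in zip(data.snp_ids, ~incorrect) if ok],
    )
    return result, data.subset(~incorrect)


class UnivariableMR:
    """Univariable two-sample MR model for one exposure and one outcome.

    Parameters
    ----------
    data
        Harmonized dataset with a single exposure (K = 1).

    Examples
    --------
    >>> model = UnivariableMR(harmonized)          # doctest: +SKIP
    >>> res = model.fit(method="ivw_mre")          # doctest: +SKIP
    >>> print(res.summary())                       # doctest: +SKIP
    """

    def __init__(self, data: HarmonizedDataset):
        _require_single_exposure(data)
        self.data = data

    def fit(self, method: str = "ivw_mre", n_boot: int = 1000, seed: int | None = None) -> MRResults:
        if method in ("ivw_fe", "ivw_mre"):
            return ivw(self.data, mode=method.split("_")[1])
        if method == "egger":
            return egger(self.data)
        if method == "weighted_median":
            return weighted_median(self.data, n_boot=n_boot, seed=seed)
        if method == "wald":
            if self.data.n_snps != 1:
                raise ValueError("method 'wald' requires exactly one instrument")
            return ivw(self.data, mode="fe")
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHOD_LABELS)}")

    def fit_all(self, n_boot: int = 1000, seed: int | None = None) -> pd.DataFrame:
        """IVW (both flavors), Egger and weighted median, as one table."""
        rows = [self.fit("ivw_fe"), self.fit("ivw_mre")]
        if self.data.n_snps >= 3:
            rows.append(self.fit("egger"))
            rows.append(self.fit("weighted_median", n_boot=n_boot, seed=seed))
        return pd.concat([r.to_frame() for r in rows], ignore_index=True)

    def wald_ratios(self, second_order: bool = False) -> pd.DataFrame:
        return wald_ratios(self.data, second_order=second_order)

    def cochran_q(self, beta_hat: float | None = None):
        return cochran_q(self.data, beta_hat)

    def mean_f_statistic(self) -> float:
        return mean_f_statistic(self.data)

    def steiger_filter(self, alpha: float = 0.05):
        return steiger_filter(self.data, alpha)
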