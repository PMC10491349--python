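"""Two-step MR mediation: product and difference decompositions.

Given the total effect of the exposure on the outcome (univariable MR), the
exposure's effect on the mediator (univariable MR), and the exposure's and
mediator's direct effects on the outcome (multivariable MR with both), the
indirect effect is estimated two ways:

* product of coefficients — beta_EM * beta_MY, SE by the delta method
  (Sobel), optionally with the exact second-order term;
* difference — beta_total - beta_direct, SE by propagation of errors with
  the total/direct covariance ignored (the two estimates share instruments,
  so this is anti-conservative; see docs/methods.md).

The proportion mediated is indirect/total with a delta-method CI. On a
binary (log-odds) outcome both decompositions are reported with a
non-collapsibility caveat; exact agreement between them is a property of
the collapsible, continuous scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .multivariable import MVMRResults, MultivariableMR
from .univariable import MRResults, UnivariableMR

logger = logging.getLogger(__name__)


def _norm_ci(est: float, se: float, alpha: float = 0.05) -> tuple[float, float]:
    z = sps.norm.ppf(1 - alpha / 2)
    return est - z * se, est + z * se


def product_method(
    beta_em: float, se_em: float, beta_my: float, se_my: float, exact: bool = False
) -> tuple[float, float]:
    """Indirect effect by product of coefficients with Sobel (delta) SE.

    ``beta_em``: exposure -> mediator effect; ``beta_my``: mediator -> outcome
    direct effect (from MVMR conditioning on the exposure). The default Sobel
    SE omits the second-order se_a^2 * se_b^2 term; ``exact=True`` adds it.
    """
    indirect = beta_em * beta_my
    var = beta_em**2 * se_my**2 + beta_my**2 * se_em**2
    if exact:
        var += se_em**2 * se_my**2
    return float(indirect), float(np.sqrt(var))


def difference_method(
    beta_total: float, se_total: float, beta_direct: float, se_direct: float
) -> tuple[float, float]:
    """Indirect effect as total minus direct, SE by propagation of errors.

    The covariance between the total and direct estimates (which share
    instruments) is ignored.
    """
    indirect = beta_total - beta_direct
    se = np.sqrt(se_total**2 + se_direct**2)
    return float(indirect), float(se)


def proportion_mediated(
    indirect: float,
    se_indirect: float,
    total: float,
    se_total: float,
    cov: float = 0.0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Proportion mediated = indirect/total with a delta-method ratio CI.

    ``cov`` is the covariance between the indirect and total estimates
    (zero unless the caller can supply it). Values outside [0, 1] are
    reported as computed, with a warning. A weakly determined total effect
    (|total| < 10 * se_total) triggers an instability warning.
    """
    if total == 0:
        raise ValueError("undefined proportion: total effect is zero")
    if abs(total) < 10 * se_total:
        warnings.warn(
            "total effect is weakly determined (|beta| < 10*SE); the "
            "proportion-mediated CI may be unstable",
            stacklevel=2,
        )
    prop = indirect / total
    var = prop**2 * (
        se_indirect**2 / indirect**2 + se_total**2 / total**2
        - 2.0 * cov / (indirect * total)
    ) if indirect != 0 else se_indirect**2 / total**2
    se = float(np.sqrt(max(var, 0.0)))
    lo, hi = _norm_ci(prop, se, alpha)
    if not 0 <= prop <= 1:
        warnings.warn(
            f"proportion mediated {prop:.3f} outside [0, 1]; reported as computed",
            stacklevel=2,
        )
    return float(prop), lo, hi


@dataclass
class MediationResult:
    """Full mediation decomposition on one exposure/mediator/outcome triple."""

    exposure: str
    mediator: str
    outcome: str
    scale: str  # "continuous" | "log_odds"
    total_effect: float
    total_se: float
    direct_exposure_effect: float
    direct_exposure_se: float
    exposure_to_mediator: float
    exposure_to_mediator_se: float
    mediator_direct_effect: float
    mediator_direct_se: float
    indirect_product: float
    indirect_product_se: float
    indirect_difference: float
    indirect_difference_se: float
    proportion_mediated: float
    proportion_ci_low: float
    proportion_ci_high: float

    def conf_int(self, which: str = "product", alpha: float = 0.05) -> tuple[float, float]:
        est, se = {
            "product": (self.indirect_product, self.indirect_product_se),
            "difference": (self.indirect_difference, self.indirect_difference_se),
            "total": (self.total_effect, self.total_se),
        }[which]
        return _norm_ci(est, se, alpha)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total", self.total_effect, self.total_se),
            ("direct_exposure", self.direct_exposure_effect, self.direct_exposure_se),
            ("exposure_to_mediator", self.exposure_to_mediator, self.exposure_to_mediator_se),
            ("mediator_direct", self.mediator_direct_effect, self.mediator_direct_se),
            ("indirect_product", self.indirect_product, self.indirect_product_se),
            ("indirect_difference", self.indirect_difference, self.indirect_difference_se),
        ]
        df = pd.DataFrame(rows, columns=["quantity", "beta", "se"])
        ci = np.array([_norm_ci(b, s) for _, b, s in rows])
        df["ci_low"], df["ci_high"] = ci[:, 0], ci[:, 1]
        prop = pd.DataFrame(
            [
                {
                    "quantity": "proportion_mediated",
                    "beta": self.proportion_mediated,
                    "se": np.nan,
                    "ci_low": self.proportion_ci_low,
                    "ci_high": self.proportion_ci_high,
                }
            ]
        )
        return pd.concat([df, prop], ignore_index=True)

    def summary(self) -> str:
        caveat = (
            "\n  note: log-odds scale — product and difference decompositions "
            "need not agree exactly (non-collapsibility)"
            if self.scale == "log_odds"
            else ""
        )
        p_lo, p_hi = self.conf_int("product")
        d_lo, d_hi = self.conf_int("difference")
        return (
            f"Mediation: {self.exposure} -> {self.mediator} -> {self.outcome} "
            f"({self.scale} scale)\n"
            f"  total effect        : {self.total_effect: .4f} (se {self.total_se:.4f})\n"
            f"  direct (exposure)   : {self.direct_exposure_effect: .4f} "
            f"(se {self.direct_exposure_se:.4f})\n"
            f"  exposure->mediator  : {self.exposure_to_mediator: .4f} "
            f"(se {self.exposure_to_mediator_se:.4f})\n"
            f"  mediator->outcome   : {self.mediator_direct_effect: .4f} "
            f"(se {self.mediator_direct_se:.4f})  [direct, from MVMR]\n"
            f"  indirect (product)  : {self.indirect_product: .4f} "
            f"[{p_lo: .4f}, {p_hi: .4f}]\n"
            f"  indirect (difference): {self.indirect_difference: .4f} "
            f"[{d_lo: .4f}, {d_hi: .4f}]\n"
            f"  proportion mediated : {self.proportion_mediated:.3f} "
            f"[{self.proportion_ci_low:.3f}, {self.proportion_ci_high:.3f}]"
            f"{caveat}"
        )


class MediationAnalysis:
    """Assemble a mediation decomposition from fitted MR results.

    Parameters
    ----------
    total
        Univariable MR result, exposure -> outcome (the total effect).
    exposure_to_mediator
        Univariable MR result, exposure -> mediator (step 1 of two-step MR).
    mvmr
        Multivariable MR result on exposure + mediator -> outcome; supplies
        the exposure's direct effect and the mediator's direct effect.
    """

    def __init__(
        self,
        total: MRResults,
        exposure_to_mediator: MRResults,
        mvmr: MVMRResults,
        scale: str = "log_odds",
        exact_sobel: bool = False,
    ):
        if scale not in ("continuous", "log_odds"):
            raise ValueError("scale must be continuous|log_odds")
        self.total = total
        self.step1 = exposure_to_mediator
        self.mvmr = mvmr
        self.scale = scale
        self.exact_sobel = exact_sobel

    def fit(self) -> MediationResult:
        exposure = self.total.exposure or self.step1.exposure
        mediator = self.step1.outcome
        outcome = self.total.outcome
        b_dir, se_dir = self.mvmr.effect(exposure) if exposure in self.mvmr.exposure_names \
            else (float(self.mvmr.betas[0]), float(self.mvmr.ses[0]))
        b_my, se_my = self.mvmr.effect(mediator) if mediator in self.mvmr.exposure_names \
            else (float(self.mvmr.betas[1]), float(self.mvmr.ses[1]))

        ind_p, se_p = product_method(
            self.step1.beta, self.step1.se, b_my, se_my, exact=self.exact_sobel
        )
        ind_d, se_d = difference_method(self.total.beta, self.total.se, b_dir, se_dir)
        prop, lo, hi = proportion_mediated(ind_p, se_p, self.total.beta, self.total.se)
        return MediationResult(
            exposure=exposure, mediator=mediator, outcome=outcome, scale=self.scale,
            total_effect=self.total.beta, total_se=self.total.se,
            direct_exposure_effect=b_dir, direct_exposure_se=se_dir,
            exposure_to_mediator=self.step1.beta, exposure_to_mediator_se=self.step1.se,
            mediator_direct_effect=b_my, mediator_direct_se=se_my,
            indirect_product=ind_p, indirect_product_se=se_p,
            indirect_difference=ind_d, indirect_difference_se=se_d,
            proportion_mediated=prop, proportion_ci_low=lo, proportion_ci_high=hi,
        )


def two_step_mediation(
    exposure,
    mediator,
    outcome,
    p_threshold: float = 5e-8,
    ivw_mode: str = "mre",
    palindrome_window: float = 0.08,
):
    """Run the full two-step MR mediation pipeline on three traits.

    Selects instruments for the exposure and the mediator at ``p_threshold``,
    fits the total effect (exposure -> outcome), step 1 (exposure ->
    mediator) and the joint MVMR (exposure + mediator -> outcome on the
    instrument union), and assembles the mediation decomposition.

    Returns a :class:`MediationResult`; the underlying fits are attached as
    ``result_total``/``result_step1``/``result_mvmr`` attributes on it.
    """
    from .data import harmonize, select_instruments

    exp_ins = select_instruments(exposure, p_threshold)
    med_ins = select_instruments(mediator, p_threshold)
    total = UnivariableMR(
        harmonize(exp_ins, outcome, palindrome_window)
    ).fit(f"ivw_{ivw_mode}")
    step1 = UnivariableMR(
        harmonize(exp_ins, mediator, palindrome_window)
    ).fit(f"ivw_{ivw_mode}")
    seen = set(exp_ins.snp_ids)
    union = list(exp_ins.snp_ids) + [s for s in med_ins.snp_ids if s not in seen]
    joint = harmonize(
        [exposure.subset(union), mediator.subset(union)], outcome, palindrome_window
    )
    mvmr_res = MultivariableMR(joint).fit()
    scale = "log_odds" if outcome.trait_type == "binary" else "continuous"
    result = MediationAnalysis(total, step1, mvmr_res, scale=scale).fit()
    result.result_total = total
    result.result_step1 = step1
    result.result_mvmr = mvmr_res
    return result
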