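"""Synthetic two-sample GWAS summary statistics with a known causal structure.

The generator draws per-SNP effects under an exposure -> mediator -> outcome
structural model (plus an optional direct path, horizontal pleiotropy,
planted heterogeneity outliers and effect-mechanism clusters) and emits one
set of summary statistics per trait, each with independent sampling noise —
the non-overlapping-samples regime two-sample MR assumes. Summary statistics
are produced directly from the asymptotic sampling distribution of GWAS
effect estimates rather than via individual-level genotypes: the estimators
consume only summary data, and the noise model is then exact by construction.

Every run is reproducible: one master seed, per-trait child streams derived
deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import HarmonizedDataset, SummaryStats

# ordered, non-palindromic allele pairs used for synthetic variants
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]

_MIN_PVAL = 1e-300


@dataclass
class SimulationConfig:
    """Parameters of the structural model and of the three GWAS samples.

    Effects are per effect-allele copy, in SD units of the continuous traits
    and on the log-odds scale for a binary outcome. ``gamma_sd`` (and, for
    ``gamma_dist="uniform_magnitude"``, ``gamma_range``) governs the direct
    SNP -> exposure effects; ``delta_sd`` the direct SNP -> mediator effects,
    which make the mediator separately instrumented (required for joint
    multivariable analysis of exposure and mediator).
    """

    seed: int = 0
    n_snps: int = 100
    maf_range: tuple = (0.1, 0.45)
    n_exposure: int = 50_000
    n_mediator: int = 50_000
    n_outcome: int = 50_000
    gamma_sd: float = 0.08
    gamma_dist: str = "normal"            # "normal" | "uniform_magnitude"
    gamma_range: tuple = (0.2, 0.4)       # |gamma| bounds for uniform_magnitude
    delta_sd: float = 0.0                 # SD of direct SNP->mediator effects
    mediator_snp_fraction: float = 0.0    # fraction of SNPs instrumenting only the mediator
    alpha: float = 0.0                    # exposure -> mediator
    beta_med: float = 0.0                 # mediator -> outcome
    beta_direct: float = 0.0              # exposure -> outcome, not via mediator
    pleiotropy_mean: float = 0.0          # directional component, exposure-increasing orientation
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 1.0      # fraction of SNPs carrying pleiotropy
    outlier_fraction: float = 0.0
    outlier_effect: float = 0.0           # shift of theta_j in units of that SNP's outcome SE
    cluster_spec: Sequence[tuple] | None = None  # [(proportion, slope), ...]
    outcome_type: str = "binary"
    case_fraction: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high < 0.5")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if not 0 <= self.pleiotropy_fraction <= 1:
            raise ValueError("pleiotropy_fraction must be in [0, 1]")
        if self.cluster_spec is not None:
            props = [p for p, _ in self.cluster_spec]
            if any(p < 0 for p in props) or sum(props) > 1 + 1e-12:
                raise ValueError("cluster proportions must be >= 0 and sum to <= 1")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError("outcome_type must be continuous|binary")
        if self.outcome_type == "binary" and not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.gamma_dist not in ("normal", "uniform_magnitude"):
            raise ValueError("gamma_dist must be normal|uniform_magnitude")
        if not 0 <= self.mediator_snp_fraction < 1:
            raise ValueError("mediator_snp_fraction must be in [0, 1)")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass
class SimulatedTruth:
    """Ground truth behind one generated dataset."""

    snp_ids: list
    maf: np.ndarray
    gamma: np.ndarray            # true SNP -> exposure effects
    beta_m_true: np.ndarray      # true SNP -> mediator effects
    beta_y_true: np.ndarray      # true SNP -> outcome effects (incl. pleiotropy/outliers)
    theta: np.ndarray            # horizontal-pleiotropy + outlier component
    alpha: float
    beta_med: float
    beta_direct: float
    outlier_ids: list = field(default_factory=list)
    cluster_labels: np.ndarray | None = None

    @property
    def total_effect(self) -> float:
        return self.beta_direct + self.alpha * self.beta_med

    @property
    def indirect_effect(self) -> float:
        return self.alpha * self.beta_med

    @property
    def proportion_mediated_true(self) -> float:
        if self.total_effect == 0:
            return float("nan")
        return self.indirect_effect / self.total_effect


def _se_continuous(maf: np.ndarray, n: int) -> np.ndarray:
    # sampling SE of a standardized per-allele effect estimate
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _se_binary(maf: np.ndarray, n: int, case_fraction: float) -> np.ndarray:
    # logistic-score approximation on the log-odds scale
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * case_fraction * (1.0 - case_fraction))


def _observe(
    truth: np.ndarray, se: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    beta = truth + rng.normal(0.0, se)
    pval = np.maximum(2.0 * sps.norm.sf(np.abs(beta / se)), _MIN_PVAL)
    return beta, pval


def _trait_table(
    snp_ids, chrom, pos, ea, oa, maf, beta, se, pval, n
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        }
    )


def generate_dataset(
    config: SimulationConfig,
) -> tuple[SummaryStats, SummaryStats, SummaryStats, SimulatedTruth]:
    """Generate exposure, mediator and outcome summary statistics plus truth.

    Structural model, per SNP j with exposure effect gamma_j and direct
    mediator effect delta_j:

    * mediator:  beta_Mj = alpha * gamma_j + delta_j
    * outcome:   beta_Yj = beta_direct * gamma_j + beta_med * beta_Mj + theta_j

    where theta_j collects horizontal pleiotropy (directional component
    applied in the exposure-increasing orientation, i.e. sign-aligned with
    gamma_j) and planted outlier shifts of ``outlier_effect`` outcome-SE
    units. When ``cluster_spec`` is given it replaces the single-mechanism
    outcome slope: each SNP's outcome effect is slope_k * gamma_j for its
    assigned mechanism (remaining SNPs are null).

    The same seed always yields byte-identical output; the three traits use
    independent child noise streams (non-overlapping samples).
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_struct, rng_x, rng_m, rng_y = (np.random.default_rng(s) for s in ss.spawn(4))
    L = cfg.n_snps

    snp_ids = [f"snp_{j + 1:05d}" for j in range(L)]
    chrom = [str(j % 22 + 1) for j in range(L)]
    pos = [20_000_001 * (j // 22) + 1_000_000 for j in range(L)]  # > any pruning window apart
    pair_idx = rng_struct.integers(0, len(_ALLELE_PAIRS), size=L)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]

    maf = rng_struct.uniform(*cfg.maf_range, size=L)
    if cfg.gamma_dist == "normal":
        gamma = rng_struct.normal(0.0, cfg.gamma_sd, size=L)
    else:
        lo, hi = cfg.gamma_range
        gamma = rng_struct.uniform(lo, hi, size=L) * rng_struct.choice([-1.0, 1.0], size=L)
    delta = (
        rng_struct.normal(0.0, cfg.delta_sd, size=L) if cfg.delta_sd > 0 else np.zeros(L)
    )
    # Mediator-specific instruments (distinct sets, as in curated GWAS
    # instrument lists): those SNPs act on the mediator only.
    n_med_snps = int(round(cfg.mediator_snp_fraction * L))
    if n_med_snps:
        med_idx = rng_struct.permutation(L)[:n_med_snps]
        med_mask = np.zeros(L, dtype=bool)
        med_mask[med_idx] = True
        gamma = np.where(med_mask, 0.0, gamma)
        delta = np.where(med_mask, delta, 0.0)

    beta_m_true = cfg.alpha * gamma + delta

    theta = np.zeros(L)
    sign = np.where(gamma >= 0, 1.0, -1.0)
    if cfg.pleiotropy_mean != 0.0 or cfg.pleiotropy_sd != 0.0:
        n_pleio = int(round(cfg.pleiotropy_fraction * L))
        pleio_idx = rng_struct.permutation(L)[:n_pleio]
        draws = rng_struct.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_pleio)
        theta[pleio_idx] += sign[pleio_idx] * draws

    se_y = (
        _se_binary(maf, cfg.n_outcome, cfg.case_fraction)
        if cfg.outcome_type == "binary"
        else _se_continuous(maf, cfg.n_outcome)
    )

    outlier_ids: list = []
    if cfg.outlier_fraction > 0 and cfg.outlier_effect != 0.0:
        n_out = int(round(cfg.outlier_fraction * L))
        out_idx = rng_struct.permutation(L)[:n_out]
        theta[out_idx] += cfg.outlier_effect * se_y[out_idx] * sign[out_idx]
        outlier_ids = [snp_ids[i] for i in sorted(out_idx)]

    cluster_labels = None
    if cfg.cluster_spec is not None:
        cluster_labels = np.zeros(L, dtype=int)  # 0 = null mechanism
        perm = rng_struct.permutation(L)
        start = 0
        slopes = np.zeros(L)
        for k, (prop, slope) in enumerate(cfg.cluster_spec, start=1):
            size = int(round(prop * L))
            idx = perm[start:start + size]
            cluster_labels[idx] = k
            slopes[idx] = slope
            start += size
        beta_y_true = slopes * gamma + theta
    else:
        beta_y_true = cfg.beta_direct * gamma + cfg.beta_med * beta_m_true + theta

    se_x = _se_continuous(maf, cfg.n_exposure)
    se_m = _se_continuous(maf, cfg.n_mediator)

    bx, px = _observe(gamma, se_x, rng_x)
    bm, pm = _observe(beta_m_true, se_m, rng_m)
    by, py = _observe(beta_y_true, se_y, rng_y)

    exposure = SummaryStats(
        "exposure", "continuous",
        _trait_table(snp_ids, chrom, pos, ea, oa, maf, bx, se_x, px, cfg.n_exposure),
    )
    mediator = SummaryStats(
        "mediator", "continuous",
        _trait_table(snp_ids, chrom, pos, ea, oa, maf, bm, se_m, pm, cfg.n_mediator),
    )
    outcome = SummaryStats(
        "outcome", cfg.outcome_type,
        _trait_table(snp_ids, chrom, pos, ea, oa, maf, by, se_y, py, cfg.n_outcome),
    )
    truth = SimulatedTruth(
        snp_ids=snp_ids, maf=maf, gamma=gamma, beta_m_true=beta_m_true,
        beta_y_true=beta_y_true, theta=theta, alpha=cfg.alpha,
        beta_med=cfg.beta_med, beta_direct=cfg.beta_direct,
        outlier_ids=outlier_ids, cluster_labels=cluster_labels,
    )
    return exposure, mediator, outcome, truth


#: Named study conditions. "dense_area_default" mirrors the mediation setting
#: the package is built around: a protective exposure acting on a binary
#: outcome partly through a continuous mediator, with total effect -0.41 on
#: the log-odds scale and true proportion mediated 0.56.
_PRESETS = {
    "dense_area_default": dict(
        n_snps=100,
        n_exposure=50_000, n_mediator=50_000, n_outcome=50_000,
        gamma_sd=0.08, delta_sd=0.08, mediator_snp_fraction=0.25,
        alpha=-0.56, beta_med=0.41, beta_direct=-0.1804,
        outcome_type="binary", case_fraction=0.5,
    ),
    "null_mediation": dict(
        n_snps=100,
        n_exposure=50_000, n_mediator=50_000, n_outcome=50_000,
        gamma_sd=0.08, delta_sd=0.08, mediator_snp_fraction=0.25,
        alpha=0.0, beta_med=0.41, beta_direct=-0.41,
        outcome_type="binary", case_fraction=0.5,
    ),
    "continuous_mediation": dict(
        n_snps=100,
        n_exposure=50_000, n_mediator=50_000, n_outcome=50_000,
        gamma_sd=0.08, delta_sd=0.08, mediator_snp_fraction=0.25,
        alpha=-0.56, beta_med=0.41, beta_direct=-0.1804,
        outcome_type="continuous",
    ),
    "invalid_40pct": dict(
        n_snps=100,
        n_exposure=300_000, n_mediator=300_000, n_outcome=300_000,
        gamma_sd=0.08, delta_sd=0.0,
        alpha=0.0, beta_med=0.0, beta_direct=0.4,
        pleiotropy_mean=0.04, pleiotropy_sd=0.005, pleiotropy_fraction=0.4,
        outcome_type="continuous",
    ),
    "outliers_21": dict(
        n_snps=21,
        # exposure GWAS much larger than the outcome sample, as in curated
        # instrument lists: exposure-side noise then barely dilutes the
        # planted outcome-SE-unit outlier shifts
        n_exposure=1_000_000, n_mediator=1_000_000, n_outcome=100_000,
        gamma_dist="uniform_magnitude", gamma_range=(0.1, 0.25),
        alpha=0.0, beta_med=0.0, beta_direct=0.4,
        outlier_fraction=3 / 21, outlier_effect=5.0,
        outcome_type="continuous",
    ),
    "clustered_dense_area": dict(
        n_snps=25,
        n_exposure=80_000, n_mediator=80_000, n_outcome=80_000,
        gamma_dist="uniform_magnitude", gamma_range=(0.2, 0.4),
        cluster_spec=[(0.4, 0.4), (0.4, -0.3)],
        outcome_type="continuous",
    ),
}


def mediation_scenario(preset_name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Return a fully populated :class:`SimulationConfig` for a named preset.

    ``dense_area_default`` plants indirect effect alpha*beta_med = -0.2296 and
    direct effect -0.1804, i.e. total effect -0.41 (log-odds) with proportion
    mediated exactly 0.56. Keyword overrides replace individual fields.
    """
    if preset_name not in _PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; available: {sorted(_PRESETS)}"
        )
    params = dict(_PRESETS[preset_name])
    params.update(overrides)
    return SimulationConfig(seed=seed, **params)


def reverse_causation_dataset(
    n_snps: int = 40,
    n_reverse: int = 20,
    seed: int = 0,
    n_sample: int = 50_000,
    forward_effect: float = 0.4,
    reverse_effect: float = 0.3,
) -> tuple[HarmonizedDataset, list]:
    """Harmonized dataset with planted reverse-causation instruments.

    ``n_snps - n_reverse`` genuine instruments act on the exposure (with the
    outcome effect ``forward_effect`` per exposure SD); the remaining
    ``n_reverse`` SNPs act on the outcome first, their apparent exposure
    effect being ``reverse_effect`` times the outcome effect. Returns the
    dataset and the planted reverse SNP ids, for testing directionality
    (Steiger) filtering.
    """
    ss = np.random.SeedSequence(seed)
    rng_struct, rng_x, rng_y = (np.random.default_rng(s) for s in ss.spawn(3))
    L, Lr = n_snps, n_reverse
    maf = rng_struct.uniform(0.1, 0.45, size=L)
    se = _se_continuous(maf, n_sample)

    effect = rng_struct.uniform(0.05, 0.15, size=L) * rng_struct.choice([-1, 1], size=L)
    is_rev = np.zeros(L, dtype=bool)
    is_rev[rng_struct.permutation(L)[:Lr]] = True

    bx_true = np.where(is_rev, reverse_effect * effect, effect)
    by_true = np.where(is_rev, effect, forward_effect * effect)
    bx = bx_true + rng_x.normal(0.0, se)
    by = by_true + rng_y.normal(0.0, se)

    snp_ids = [f"snp_{j + 1:05d}" for j in range(L)]
    data = HarmonizedDataset(
        snp_ids=snp_ids,
        beta_X=bx[:, None], se_X=se[:, None], beta_Y=by, se_Y=se,
        eaf=maf, n_X=np.full((L, 1), float(n_sample)), n_Y=np.full(L, float(n_sample)),
        exposure_names=["exposure"], outcome_name="outcome",
        outcome_type="continuous",
    )
    return data, [snp_ids[i] for i in np.flatnonzero(is_rev)]
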