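import numpy as np
import pandas as pd
import pytest

from mrmediate import HarmonizedDataset, SummaryStats


def make_dataset(
    bx, by, se_x=None, se_y=None, n_x=50_000, n_y=50_000, eaf=None, outcome_type="continuous"
) -> HarmonizedDataset:
    """Hand-rolled harmonized dataset for unit tests."""
    bx = np.atleast_2d(np.asarray(bx, float))
    if bx.shape[0] == 1 and len(np.ravel(by)) != 1:
        bx = bx.T
    L, K = bx.shape
    by = np.asarray(by, float)
    se_x = np.full_like(bx, 0.01) if se_x is None else np.asarray(se_x, float).reshape(bx.shape)
    se_y = np.full(L, 0.01) if se_y is None else np.asarray(se_y, float).ravel()
    eaf = np.full(L, 0.3) if eaf is None else np.asarray(eaf, float)
    return HarmonizedDataset(
        snp_ids=[f"snp_{j + 1:03d}" for j in range(L)],
        beta_X=bx, se_X=se_x, beta_Y=by, se_Y=se_y, eaf=eaf,
        n_X=np.full((L, K), float(n_x)), n_Y=np.full(L, float(n_y)),
        exposure_names=[f"exposure_{k + 1}" for k in range(K)],
        outcome_name="outcome", outcome_type=outcome_type,
    )


@pytest.fixture
def fixture20() -> HarmonizedDataset:
    """Fixed 20-SNP dataset (seeded, heterogeneous SEs) for oracle checks."""
    rng = np.random.default_rng(20240917)
    L = 20
    bx = rng.uniform(0.04, 0.15, L) * rng.choice([-1, 1], L)
    se_x = rng.uniform(0.004, 0.01, L)
    se_y = rng.uniform(0.008, 0.02, L)
    by = 0.35 * bx + rng.normal(0, se_y)
    return make_dataset(bx, by, se_x, se_y)


def make_summary_stats(name="trait", trait_type="continuous", rows=None) -> SummaryStats:
    if rows is None:
        rows = [
            ("rs1", "1", 1000, "A", "G", 0.30, 0.10, 0.010, 1e-20, 50_000),
            ("rs2", "2", 2000, "C", "T", 0.20, -0.08, 0.012, 1e-12, 50_000),
            ("rs3", "3", 3000, "G", "A", 0.40, 0.05, 0.011, 1e-9, 50_000),
        ]
    df = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                 "eaf", "beta", "se", "pval", "n"],
    )
    return SummaryStats(name, trait_type, df)
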