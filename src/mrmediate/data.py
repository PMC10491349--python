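"""GWAS summary-statistic containers, I/O, harmonization and instrument selection.

Summary statistics for one trait are held as a validated :class:`SummaryStats`
(a thin wrapper around a pandas DataFrame). Joining one or more exposures with
an outcome, with alleles aligned to the first exposure's effect allele, yields
a :class:`HarmonizedDataset` — the input to every estimator in this package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
#: A/T and C/G pairs: the strand cannot be resolved from allele labels alone.
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

STANDARD_COLUMNS = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")
OPTIONAL_COLUMNS = ("chrom", "pos")


class GwasInputError(ValueError):
    """A summary-statistics file violates the input contract."""


@dataclass
class SummaryStats:
    """Per-SNP association estimates for a single trait.

    ``table`` holds one row per variant with the standard columns
    (snp_id, effect_allele, other_allele, eaf, beta, se, pval, n and,
    optionally, chrom/pos). For binary traits ``beta`` is on the log-odds
    scale; for continuous traits it is in SD units of the trait.
    """

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    table: pd.DataFrame
    drop_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        if self.table["snp_id"].duplicated().any():
            dups = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"].tolist()
            raise GwasInputError(f"duplicate snp_id within trait {self.trait_name!r}: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> pd.Series:
        return self.table["snp_id"]

    def subset(self, snp_ids: Sequence[str]) -> "SummaryStats":
        keep = self.table[self.table["snp_id"].isin(set(snp_ids))].reset_index(drop=True)
        return SummaryStats(self.trait_name, self.trait_type, keep, dict(self.drop_counts))


def _validate_rows(df: pd.DataFrame, trait_name: str) -> tuple[pd.DataFrame, dict]:
    """Drop rows violating the per-variant invariants, counting reasons."""
    reasons = {}

    def drop(mask: pd.Series, reason: str) -> pd.Series:
        k = int(mask.sum())
        if k:
            reasons[reason] = reasons.get(reason, 0) + k
            logger.info("%s: dropped %d row(s): %s", trait_name, k, reason)
        return ~mask

    num = df[["eaf", "beta", "se", "pval", "n"]].apply(pd.to_numeric, errors="coerce")
    df = df.assign(**{c: num[c] for c in num.columns})
    keep = drop(num.isna().any(axis=1), "non_numeric_or_missing")
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    df = df.assign(effect_allele=ea, other_allele=oa)
    keep &= drop(keep & ~(ea.isin(VALID_ALLELES) & oa.isin(VALID_ALLELES)), "non_snv_allele")
    keep &= drop(keep & (ea == oa), "identical_alleles")
    keep &= drop(keep & ~(df["se"] > 0), "nonpositive_se")
    keep &= drop(keep & ~((df["eaf"] > 0) & (df["eaf"] < 1)), "eaf_out_of_range")
    keep &= drop(keep & ~((df["pval"] > 0) & (df["pval"] <= 1)), "pval_out_of_range")
    keep &= drop(keep & ~(df["n"] > 0), "nonpositive_n")

    out = df.loc[keep].reset_index(drop=True)
    # p-value vs |beta/se| consistency: warn (not drop) when off by >10x either way.
    if len(out):
        implied = 2.0 * sps.norm.sf(np.abs(out["beta"] / out["se"]))
        with np.errstate(divide="ignore"):
            ratio = np.where(implied > 0, out["pval"] / implied, np.inf)
        bad = (ratio > 10) | (ratio < 0.1)
        # extremely small p-values underflow the normal sf; do not warn there
        bad &= implied > 1e-300
        if bad.any():
            logger.warning(
                "%s: %d row(s) have p-values inconsistent with beta/se by >10x",
                trait_name, int(bad.sum()),
            )
    return out, reasons


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    trait_name: str | None = None,
    delimiter: str = "\t",
) -> SummaryStats:
    """Read one trait's GWAS summary statistics from delimited text.

    Parameters
    ----------
    path
        Delimited text file with a header row; gzip accepted transparently.
    column_map
        Mapping from standard names (snp_id, effect_allele, other_allele, eaf,
        beta, se, pval, n, and optionally chrom, pos) to the file's column
        names. Standard names already present in the file need no entry.
    trait_type
        "continuous" (beta in SD units) or "binary" (beta on log-odds scale).

    Rows violating the per-variant invariants (se <= 0, eaf outside (0,1),
    non-SNV alleles, ...) are dropped with a logged reason and counted in
    ``drop_counts``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, compression="infer")
    if df.empty:
        raise GwasInputError(f"{path}: file contains no data rows")
    column_map = dict(column_map or {})
    rename = {}
    for std in STANDARD_COLUMNS + OPTIONAL_COLUMNS:
        src = column_map.get(std, std)
        if src in df.columns:
            rename[src] = std
        elif std in STANDARD_COLUMNS:
            raise GwasInputError(f"{path}: missing mandatory column {std!r} (mapped from {src!r})")
    df = df.rename(columns=rename)
    canonical = ("snp_id", "chrom", "pos", "effect_allele", "other_allele",
                 "eaf", "beta", "se", "pval", "n")
    df = df[[c for c in canonical if c in df.columns]]
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)
    name = trait_name or path.name.split(".")[0]
    clean, reasons = _validate_rows(df, name)
    return SummaryStats(name, trait_type, clean, reasons)


@dataclass
class HarmonizedDataset:
    """Allele-aligned joint table of K >= 1 exposures and one outcome.

    All effects are oriented to the first exposure's effect allele. Arrays are
    row-aligned with ``snp_ids``; ``beta_X``/``se_X``/``n_X`` have one column
    per exposure.
    """

    snp_ids: list
    beta_X: np.ndarray  # (L, K)
    se_X: np.ndarray    # (L, K)
    beta_Y: np.ndarray  # (L,)
    se_Y: np.ndarray    # (L,)
    eaf: np.ndarray     # (L,) on the reference effect allele
    n_X: np.ndarray     # (L, K)
    n_Y: np.ndarray     # (L,)
    exposure_names: list
    outcome_name: str
    outcome_type: str = "continuous"
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.beta_X = np.atleast_2d(np.asarray(self.beta_X, float))
        if self.beta_X.shape[0] == 1 and len(self.snp_ids) != 1:
            self.beta_X = self.beta_X.T
        self.se_X = np.asarray(self.se_X, float).reshape(self.beta_X.shape)
        self.n_X = np.asarray(self.n_X, float).reshape(self.beta_X.shape)
        for name in ("beta_Y", "se_Y", "eaf", "n_Y"):
            setattr(self, name, np.asarray(getattr(self, name), float).ravel())
        L = len(self.snp_ids)
        if not (self.beta_X.shape[0] == L == len(self.beta_Y)):
            raise ValueError("row-count mismatch in HarmonizedDataset")
        arrays = [self.beta_X, self.se_X, self.beta_Y, self.se_Y, self.eaf, self.n_X, self.n_Y]
        if not all(np.isfinite(a).all() for a in arrays):
            raise ValueError("HarmonizedDataset requires complete, finite values")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def K(self) -> int:
        return self.beta_X.shape[1]

    def subset(self, mask: np.ndarray) -> "HarmonizedDataset":
        """Row subset by boolean mask or integer index array."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HarmonizedDataset(
            [self.snp_ids[i] for i in idx],
            self.beta_X[idx], self.se_X[idx], self.beta_Y[idx], self.se_Y[idx],
            self.eaf[idx], self.n_X[idx], self.n_Y[idx],
            list(self.exposure_names), self.outcome_name, self.outcome_type,
            self.provenance,
        )

    def single_exposure(self, index: int = 0) -> "HarmonizedDataset":
        """View with one exposure column (K=1)."""
        return HarmonizedDataset(
            list(self.snp_ids),
            self.beta_X[:, [index]], self.se_X[:, [index]], self.beta_Y, self.se_Y,
            self.eaf, self.n_X[:, [index]], self.n_Y,
            [self.exposure_names[index]], self.outcome_name, self.outcome_type,
            self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"snp_id": self.snp_ids}
        for k, name in enumerate(self.exposure_names):
            d[f"beta_{name}"] = self.beta_X[:, k]
            d[f"se_{name}"] = self.se_X[:, k]
        d["beta_outcome"] = self.beta_Y
        d["se_outcome"] = self.se_Y
        d["eaf"] = self.eaf
        return pd.DataFrame(d)


def _orient_trait(
    ref: pd.DataFrame, other: pd.DataFrame, window: float
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.Series]:
    """Align ``other`` to ``ref``'s effect allele.

    Returns the oriented table (beta/eaf adjusted in place), plus boolean
    Series (flipped, palindromic_inferred) and a drop-reason Series (empty
    string = retained), all indexed like ``ref``.
    """
    m = ref.merge(other, on="snp_id", suffixes=("_r", "_o"), how="inner").set_index("snp_id")
    ea_r, oa_r = m["effect_allele_r"], m["other_allele_r"]
    ea_o, oa_o = m["effect_allele_o"], m["other_allele_o"]

    same = (ea_o == ea_r) & (oa_o == oa_r)
    swapped = (ea_o == oa_r) & (oa_o == ea_r)
    pal = pd.Series(
        [(a, b) in PALINDROMIC_PAIRS for a, b in zip(ea_r, oa_r)], index=m.index
    )

    reason = pd.Series("", index=m.index)
    reason[~(same | swapped)] = "allele_mismatch"

    flipped = swapped & ~pal
    # Palindromic variants: allele labels cannot distinguish a swap from a
    # strand flip; keep only when both frequencies are informative (outside
    # the ambiguity window around 0.5) and concordant, oriented as-is.
    lo, hi = 0.5 - window, 0.5 + window
    f_r, f_o = m["eaf_r"], m["eaf_o"]
    informative = ((f_r < lo) | (f_r > hi)) & ((f_o < lo) | (f_o > hi))
    concordant = (f_r < 0.5) == (f_o < 0.5)
    pal_ok = pal & (same | swapped) & informative & concordant
    reason[pal & (same | swapped) & ~pal_ok] = "palindromic_ambiguous"

    beta = m["beta_o"].where(~flipped, -m["beta_o"])
    eaf = m["eaf_o"].where(~flipped, 1.0 - m["eaf_o"])
    out = pd.DataFrame(
        {"beta": beta, "se": m["se_o"], "eaf": eaf, "pval": m["pval_o"], "n": m["n_o"]}
    )
    return out, flipped, pal_ok, reason


def harmonize(
    exposures: SummaryStats | Sequence[SummaryStats],
    outcome: SummaryStats,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedDataset:
    """Align alleles across exposures and outcome; return the joint dataset.

    Orientation is to the first exposure's effect allele. Where another
    trait's effect/other alleles are swapped, its beta is negated and its
    frequency complemented. Palindromic (A/T, C/G) variants are retained only
    when every trait's effect-allele frequency lies outside
    [0.5-w, 0.5+w] on the same side; otherwise dropped with reason
    "palindromic_ambiguous". Variants absent from any trait are dropped with
    reason "missing".
    """
    if isinstance(exposures, SummaryStats):
        exposures = [exposures]
    exposures = list(exposures)
    if not exposures:
        raise ValueError("at least one exposure required")
    ref = exposures[0].table

    all_ids = ref["snp_id"]
    shared = set(all_ids)
    for t in exposures[1:] + [outcome]:
        shared &= set(t.table["snp_id"])
    order = [s for s in all_ids if s in shared]

    prov = pd.DataFrame(
        {"snp_id": list(all_ids)},
    ).set_index("snp_id")
    prov["flipped"] = False
    prov["palindromic_inferred"] = False
    prov["dropped_reason"] = ""
    prov.loc[~prov.index.isin(shared), "dropped_reason"] = "missing"

    if not order:
        raise GwasInputError("no harmonizable instruments: no shared variants")

    refq = ref[ref["snp_id"].isin(shared)]
    oriented = {}
    for t in exposures[1:] + [outcome]:
        tab, flipped, pal_ok, reason = _orient_trait(refq, t.table, palindrome_eaf_window)
        oriented[t.trait_name] = tab
        prov.loc[flipped.index[flipped], "flipped"] = True
        prov.loc[pal_ok.index[pal_ok], "palindromic_inferred"] = True
        bad = reason[reason != ""]
        for sid, r in bad.items():
            if prov.at[sid, "dropped_reason"] == "":
                prov.at[sid, "dropped_reason"] = r

    keep = [s for s in order if prov.at[s, "dropped_reason"] == ""]
    if not keep:
        raise GwasInputError("no harmonizable instruments")

    refk = refq.set_index("snp_id").loc[keep]
    cols_b = [refk["beta"].to_numpy()]
    cols_s = [refk["se"].to_numpy()]
    cols_n = [refk["n"].to_numpy()]
    for t in exposures[1:]:
        tab = oriented[t.trait_name].loc[keep]
        cols_b.append(tab["beta"].to_numpy())
        cols_s.append(tab["se"].to_numpy())
        cols_n.append(tab["n"].to_numpy())
    out_tab = oriented[outcome.trait_name].loc[keep]

    return HarmonizedDataset(
        snp_ids=list(keep),
        beta_X=np.column_stack(cols_b),
        se_X=np.column_stack(cols_s),
        beta_Y=out_tab["beta"].to_numpy(),
        se_Y=out_tab["se"].to_numpy(),
        eaf=refk["eaf"].to_numpy(),
        n_X=np.column_stack(cols_n),
        n_Y=out_tab["n"].to_numpy(),
        exposure_names=[e.trait_name for e in exposures],
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
        provenance=prov.reset_index(),
    )


def select_instruments(
    stats: SummaryStats,
    p_threshold: float = 5e-8,
    prune_window_bp: int = 10_000_000,
) -> SummaryStats:
    """Keep genome-wide-significant variants, positionally pruned.

    Retains variants with p < ``p_threshold``. When chrom/pos are available,
    greedily keeps the smallest-p variant and drops all others within
    ``prune_window_bp`` of it on the same chromosome (ties on p broken by
    snp_id). Without positions all threshold-passing variants are retained
    and a warning notes that LD pruning was skipped.
    """
    if len(stats) == 0:
        raise GwasInputError("select_instruments: empty summary statistics")
    t = stats.table
    passing = t[t["pval"] < p_threshold].copy()
    if passing.empty:
        raise GwasInputError(
            f"no instruments: no variant passes p < {p_threshold:g} for {stats.trait_name!r}"
        )
    have_pos = {"chrom", "pos"} <= set(passing.columns) and passing[["chrom", "pos"]].notna().all().all()
    if not have_pos:
        logger.warning(
            "%s: positions unavailable — LD-proxy positional pruning skipped", stats.trait_name
        )
        kept = passing
    else:
        passing = passing.sort_values(["pval", "snp_id"], kind="mergesort")
        kept_rows = []
        occupied: dict = {}
        for _, row in passing.iterrows():
            c, p = row["chrom"], int(row["pos"])
            if any(abs(p - q) <= prune_window_bp for q in occupied.get(c, [])):
                continue
            occupied.setdefault(c, []).append(p)
            kept_rows.append(row)
        kept = pd.DataFrame(kept_rows)
    kept = kept.sort_index().reset_index(drop=True)
    drops = dict(stats.drop_counts)
    drops["below_threshold_or_pruned"] = len(stats) - len(kept)
    return SummaryStats(stats.trait_name, stats.trait_type, kept, drops)


def _to_jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_results(results, path: str | Path, metadata: Mapping | None = None) -> None:
    """Write a results object as TSV plus a full-precision JSON sidecar.

    Any object exposing ``to_frame()`` is accepted (estimator results,
    outlier and cluster reports, mediation results). The sidecar
    (``<path>.json``) carries every numeric field at full precision together
    with run metadata (package version plus caller-supplied entries such as
    seed and config hash).
    """
    path = Path(path)
    frame = results.to_frame() if hasattr(results, "to_frame") else pd.DataFrame(results)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)

    from . import __version__

    meta = {"package_version": __version__}
    if metadata:
        meta.update(metadata)
    payload = {"metadata": _to_jsonable(meta), "results": _to_jsonable(results)}
    blob = json.dumps(payload, indent=1, sort_keys=True, default=str)
    meta_path = path.with_suffix(path.suffix + ".json")
    meta_path.write_text(blob)


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping, for sidecar metadata."""
    blob = json.dumps(_to_jsonable(dict(config)), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
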