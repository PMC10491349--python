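"""Analysis-plan orchestration: run a configured sequence of MR analyses.

A plan is an ordered list of steps (mr, mvmr, radial, presso, cluster,
steiger, mediation) over named traits, with global settings (seed, output
directory, IVW flavor, instrument p-value threshold, palindrome window).
Plans come from YAML via :func:`validate_config` or are built in code.
Running a plan executes every step in order, reusing harmonized datasets
where possible, writes per-step TSV/JSON through
:func:`mrmediate.data.write_results`, and returns a consolidated report.

Reproducibility: the plan's single global seed is expanded into one child
seed per step (deterministically, by step position), so re-running an
identical plan reproduces every numeric output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import simulate
from .data import (
    GwasInputError,
    HarmonizedDataset,
    SummaryStats,
    config_hash,
    harmonize,
    read_summary_stats,
    select_instruments,
    write_results,
)
from .heterogeneity import MRPresso, RadialMR, RatioClustering
from .mediation import MediationAnalysis
from .multivariable import MultivariableMR
from .univariable import UnivariableMR, steiger_filter

logger = logging.getLogger(__name__)

ANALYSES = ("mr", "mvmr", "radial", "presso", "cluster", "steiger", "mediation")

GLOBAL_DEFAULTS = {
    "seed": 0,
    "output_dir": "mrmediate_output",
    "ivw_mode": "mre",
    "palindrome_window": 0.08,
    "p_threshold": 5e-8,
    "prune_window_bp": 10_000_000,
    "prob_threshold": 0.9,
}


@dataclass
class AnalysisStep:
    step_id: str
    analysis: str
    exposures: list = field(default_factory=list)
    mediator: str | None = None
    outcome: str | None = None
    options: dict = field(default_factory=dict)
    # mediation steps reference prior steps:
    total_step: str | None = None
    step1_step: str | None = None
    mvmr_step: str | None = None


@dataclass
class AnalysisPlan:
    steps: list
    seed: int = 0
    output_dir: str = "mrmediate_output"
    ivw_mode: str = "mre"
    palindrome_window: float = 0.08
    p_threshold: float = 5e-8
    prune_window_bp: int = 10_000_000
    prob_threshold: float = 0.9
    synthetic_preset: str | None = None

    def validate(self, trait_names: set | None = None) -> list:
        """Return a complete list of violations (empty = valid)."""
        problems = []
        seen = set()
        ids = set()
        for st in self.steps:
            if st.step_id in seen:
                problems.append(f"duplicate step_id {st.step_id!r}")
            seen.add(st.step_id)
        ids = seen
        if self.seed < 0:
            problems.append("negative seed")
        if self.ivw_mode not in ("fe", "mre"):
            problems.append(f"ivw_mode must be fe|mre, got {self.ivw_mode!r}")
        if not 0 < self.p_threshold < 1:
            problems.append("p_threshold must be in (0, 1)")
        for st in self.steps:
            if st.analysis not in ANALYSES:
                problems.append(f"step {st.step_id!r}: unknown analysis {st.analysis!r}")
            if st.analysis == "mediation":
                for ref, name in (
                    (st.total_step, "total_step"),
                    (st.step1_step, "step1_step"),
                    (st.mvmr_step, "mvmr_step"),
                ):
                    if ref is None:
                        problems.append(f"step {st.step_id!r}: mediation needs {name}")
                    elif ref not in ids:
                        problems.append(
                            f"step {st.step_id!r}: dangling reference {ref!r} in {name}"
                        )
            else:
                if not st.exposures:
                    problems.append(f"step {st.step_id!r}: no exposure given")
                if st.outcome is None:
                    problems.append(f"step {st.step_id!r}: no outcome given")
                if trait_names is not None:
                    for t in list(st.exposures) + [st.outcome]:
                        if t is not None and t not in trait_names:
                            problems.append(
                                f"step {st.step_id!r}: undefined trait {t!r}"
                            )
        return problems


def validate_config(path: str | Path) -> AnalysisPlan:
    """Parse a YAML plan file; raise with the complete violation list."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        mark = getattr(e, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark else ""
        raise GwasInputError(f"{path}: unparseable config{line}: {e}") from e
    if not isinstance(raw, dict):
        raise GwasInputError(f"{path}: config must be a mapping")
    g = {**GLOBAL_DEFAULTS, **(raw.get("global") or {})}
    steps = []
    for item in raw.get("steps") or []:
        exposures = item.get("exposures") or item.get("exposure") or []
        if isinstance(exposures, str):
            exposures = [exposures]
        steps.append(
            AnalysisStep(
                step_id=str(item.get("step_id", "")),
                analysis=str(item.get("analysis", "")),
                exposures=list(exposures),
                mediator=item.get("mediator"),
                outcome=item.get("outcome"),
                options=dict(item.get("options") or {}),
                total_step=item.get("total_step"),
                step1_step=item.get("step1_step"),
                mvmr_step=item.get("mvmr_step"),
            )
        )
    plan = AnalysisPlan(
        steps=steps,
        seed=int(g["seed"]),
        output_dir=str(g["output_dir"]),
        ivw_mode=str(g["ivw_mode"]),
        palindrome_window=float(g["palindrome_window"]),
        p_threshold=float(g["p_threshold"]),
        prune_window_bp=int(g["prune_window_bp"]),
        prob_threshold=float(g["prob_threshold"]),
        synthetic_preset=raw.get("synthetic_preset"),
    )
    problems = plan.validate()
    if problems:
        raise GwasInputError(
            f"{path}: invalid plan:\n  " + "\n  ".join(problems)
        )
    return plan


def _load_traits(plan: AnalysisPlan, inputs: dict | None) -> dict:
    """Resolve trait name -> SummaryStats from files and/or a synthetic preset."""
    traits: dict[str, SummaryStats] = {}
    if plan.synthetic_preset:
        cfg = simulate.mediation_scenario(plan.synthetic_preset, seed=plan.seed)
        exp, med, out, truth = simulate.generate_dataset(cfg)
        traits.update({"exposure": exp, "mediator": med, "outcome": out})
        traits["_truth"] = truth  # type: ignore[assignment]
    for name, src in (inputs or {}).items():
        if isinstance(src, SummaryStats):
            traits[name] = src
        else:
            src = dict(src) if isinstance(src, dict) else {"path": src}
            traits[name] = read_summary_stats(
                src["path"],
                column_map=src.get("column_map"),
                trait_type=src.get("trait_type", "continuous"),
                trait_name=name,
                delimiter=src.get("delimiter", "\t"),
            )
    return traits


def _step_seed(global_seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence([global_seed, index]).generate_state(1)[0] % (2**31)
    )


def _harmonized(plan, traits, exposures, outcome, cache) -> HarmonizedDataset:
    key = (tuple(exposures), outcome)
    if key not in cache:
        instruments = [
            select_instruments(traits[e], plan.p_threshold, plan.prune_window_bp)
            for e in exposures
        ]
        if len(instruments) > 1:
            # union of per-exposure instruments, looked up in every trait
            union: list = []
            for ins in instruments:
                union.extend(s for s in ins.snp_ids if s not in union)
            instruments = [traits[e].subset(union) for e in exposures]
        cache[key] = harmonize(instruments, traits[outcome], plan.palindrome_window)
    return cache[key]


def run_pipeline(plan: AnalysisPlan, inputs: dict | None = None) -> dict:
    """Execute a validated plan; write per-step outputs and one report.

    Returns the consolidated report dict (also written to
    ``<output_dir>/report.json`` with a human-readable ``report.txt``).
    Raises before executing anything if the plan is invalid.
    """
    traits = _load_traits(plan, inputs)
    trait_names = {k for k in traits if not k.startswith("_")}
    problems = plan.validate(trait_names)
    if problems:
        raise GwasInputError("invalid plan:\n  " + "\n  ".join(problems))

    outdir = Path(plan.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache: dict = {}
    results: dict = {}
    report: dict = {"steps": {}, "seed": plan.seed}
    texts: list[str] = []
    manifest: list[str] = []

    for idx, st in enumerate(plan.steps):
        seed = _step_seed(plan.seed, idx)
        meta = {"seed": seed, "step_id": st.step_id,
                "config_hash": config_hash({"plan_seed": plan.seed, "step": st.step_id})}
        if st.analysis == "mediation":
            analysis = MediationAnalysis(
                total=results[st.total_step],
                exposure_to_mediator=results[st.step1_step],
                mvmr=results[st.mvmr_step],
                scale=st.options.get("scale", "log_odds"),
            )
            res = analysis.fit()
        else:
            data = _harmonized(plan, traits, st.exposures, st.outcome, cache)
            if st.analysis == "mr":
                method = st.options.get("method", f"ivw_{plan.ivw_mode}")
                res = UnivariableMR(data.single_exposure()).fit(
                    method=method, seed=seed,
                    n_boot=int(st.options.get("n_boot", 1000)),
                )
            elif st.analysis == "mvmr":
                res = MultivariableMR(data).fit()
            elif st.analysis == "radial":
                res = RadialMR(data.single_exposure()).fit(
                    alpha=st.options.get("alpha", "bonferroni"),
                    weights=st.options.get("weights", "modified_second"),
                )
            elif st.analysis == "presso":
                res = MRPresso(data.single_exposure()).fit(
                    n_sim=int(st.options.get("n_sim", 1000)),
                    outlier_alpha=float(st.options.get("outlier_alpha", 0.05)),
                    seed=seed,
                )
            elif st.analysis == "cluster":
                res = RatioClustering(data.single_exposure()).fit(
                    max_K=int(st.options.get("max_K", 5)),
                    prob_threshold=float(st.options.get("prob_threshold", plan.prob_threshold)),
                    seed=seed,
                )
            elif st.analysis == "steiger":
                res, filtered = steiger_filter(
                    data.single_exposure(), alpha=float(st.options.get("alpha", 0.05))
                )
                cache[(tuple(st.exposures), st.outcome)] = filtered

        results[st.step_id] = res
        out_path = outdir / f"{st.step_id}.tsv"
        write_results(res, out_path, metadata=meta)
        manifest.extend([out_path.name, out_path.name + ".json"])
        summary = res.summary() if hasattr(res, "summary") else repr(res)
        texts.append(f"[{st.step_id}] ({st.analysis})\n{summary}\n")
        report["steps"][st.step_id] = {
            "analysis": st.analysis,
            "status": "ok",
            "output": out_path.name,
        }
        logger.info("step %s (%s): done", st.step_id, st.analysis)

    report["manifest"] = manifest + ["report.json", "report.txt"]
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (outdir / "report.txt").write_text("\n".join(texts))
    report["results"] = results
    return report
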