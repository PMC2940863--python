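"""End-to-end pipeline: split -> balance -> screen -> build -> CIs -> pool.

Produces a machine-readable report bundle — the tabular twins of the
selection-curve and whisker-diagram figures a scoring-system study
reports — plus the serialized model, pooling plan and a run log with
every seed and decision, so each number can be recomputed from (cohort,
config).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .bootstrap import class_table, score_class_cis
from .cohort import Cohort, balance_report, read_cohort, stratified_split
from .model import ForwardScoreSelection
from .pooling import pool_scores
from .screening import screen_predictors, screening_table

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; defaults follow the method's stated values:
    equal split, five-step window, 1% minimum cumulative AUC gain, 1000
    bootstrap replicates, 95% confidence level."""

    cohort_path: str
    outcome: str
    out_dir: str
    fraction: float = 0.5
    split_seed: int = 0
    window: int = 5
    min_increment: float = 0.01
    B: int = 1000
    level: float = 0.95
    boot_seed: int = 0
    pooling_strategy: str = "greedy-top-down"
    min_class_frac: float = 0.02
    final_step: int | None = None  # None: earliest test-AUC-maximizing step

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**d)


@dataclass
class PipelineResult:
    config: RunConfig
    train: Cohort
    test: Cohort
    results: object
    final_step: int
    pooling: object
    files: dict[str, Path] = field(default_factory=dict)


def _write_tsv(frame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Identical configs produce byte-identical bundles.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    logged_config = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    log: dict = {"version": __version__, "config": logged_config, "stages": {}}

    def stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    cohort = stage("read")(read_cohort, config.cohort_path, config.outcome)
    log["stages"]["read"] = {"n": cohort.n, "n_variables": len(cohort.variables),
                             "n_morbid": cohort.n_morbid}

    train, test = stage("split")(
        stratified_split, cohort, config.fraction, config.split_seed
    )
    log["stages"]["split"] = {
        "seed": config.split_seed,
        "train_n": train.n, "train_morbid": train.n_morbid,
        "test_n": test.n, "test_morbid": test.n_morbid,
    }

    balance = stage("balance")(balance_report, train, test)
    files["balance"] = out / "balance.tsv"
    _write_tsv(balance, files["balance"])
    log["stages"]["balance"] = {
        "n_significant": int(balance["significant"].sum()),
        "n_variables": len(balance),
    }

    predictors = stage("screen")(screen_predictors, train)
    files["screening"] = out / "screening.tsv"
    _write_tsv(screening_table(predictors), files["screening"])
    log["stages"]["screen"] = {
        "n_candidates": len(predictors),
        "n_passed": sum(p.passed_screen for p in predictors),
    }

    selection = stage("build")(
        lambda: ForwardScoreSelection(
            train, predictors, test=test,
            window=config.window, min_increment=config.min_increment,
        ).fit()
    )
    files["trace"] = out / "trace.tsv"
    _write_tsv(selection.trace.to_frame(), files["trace"])
    log["stages"]["build"] = {
        "stop_step": selection.trace.stop_step,
        "stop_reason": selection.trace.stop_reason,
        "n_steps": selection.n_steps,
    }

    per_step_beff: dict[int, dict] = {}
    for step in range(1, selection.n_steps + 1):
        stats = stage("ci")(
            score_class_cis,
            train, selection.model_at(step),
            B=config.B, level=config.level, seed=config.boot_seed, test=test,
        )
        f = out / f"classes_step_{step:02d}.tsv"
        files[f"classes_step_{step}"] = f
        _write_tsv(class_table(stats), f)
        per_step_beff[step] = {s.label: s.B_effective for s in stats}
    log["stages"]["ci"] = {"seed": config.boot_seed, "B": config.B,
                           "B_effective": per_step_beff}

    final_step = config.final_step or selection.final_step("test-auc")
    final_model = selection.model_at(final_step)
    files["model"] = out / "model.json"
    final_model.save(files["model"])

    base_stats = score_class_cis(
        train, final_model, B=config.B, level=config.level,
        seed=config.boot_seed, test=test,
    )
    pooled = stage("pool")(
        pool_scores,
        train, final_model, base_stats,
        strategy=config.pooling_strategy,
        B=config.B, level=config.level, seed=config.boot_seed,
        test=test, min_class_frac=config.min_class_frac,
    )
    files["pooled"] = out / "pooled.tsv"
    pooled_tab = class_table(pooled.stats)
    _write_tsv(pooled_tab, files["pooled"])
    files["plan"] = out / "pooling_plan.json"
    with open(files["plan"], "w") as fh:
        json.dump(pooled.plan.to_dict(), fh, indent=2)
    log["stages"]["pool"] = {
        "final_step": final_step,
        "merges": list(pooled.merges),
        "train_auc_before": pooled.train_auc_before,
        "train_auc_after": pooled.train_auc_after,
        "test_auc_before": pooled.test_auc_before,
        "test_auc_after": pooled.test_auc_after,
    }

    files["log"] = out / "run_log.json"
    with open(files["log"], "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)

    return PipelineResult(
        config=config, train=train, test=test, results=selection,
        final_step=final_step, pooling=pooled, files=files,
    )
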