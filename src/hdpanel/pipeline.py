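"""End-to-end run configuration and orchestration.

``run_pipeline`` composes the stages — synthetic cohort generation,
univariate group statistics, logistic coefficient ranking, and
permutation stability selection — from a single validated
:class:`RunConfig`, writes all tabular artifacts (CSV/JSON) plus a
human-readable summary, and is byte-reproducible from the master seed.
Stage seeds are derived from the master seed by stable counters so each
stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .analyze import BiomarkerStats, StatsConfig
from .cohort import BiomarkerTable, CohortConfig, generate_cohort, inject_contamination
from .panel import FeatureSpec, default_panel
from .selection import (
    COMBOS,
    GENOTYPE_TASK,
    TREATMENT_TASK,
    ModelCombo,
    StabilitySelection,
    compare_models,
    logistic_rank,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "stage_seed"]

logger = logging.getLogger("hdpanel.pipeline")

_TASKS = {"genotype": GENOTYPE_TASK, "treatment": TREATMENT_TASK}
_COMBO_BY_LABEL = {c.label: c for c in COMBOS}


def stage_seed(master_seed: int, stage: int) -> int:
    """Derive a stage seed (< 2^31) from the master seed by counter."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2**31))


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    ``cohort`` options configure the generator (group sizes, correlation,
    contamination, per-feature effect overrides); ``stats`` the univariate
    pipeline; ``ml`` the stability-selection stage. Unknown keys anywhere
    are rejected.
    """

    seed: int = 0
    cohort: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    ml: dict = field(default_factory=dict)

    _COHORT_KEYS = {
        "group_sizes", "correlation_rho", "outlier_rate", "outlier_scale",
        "detection_floor", "lognormal", "feature_overrides", "effect_scale",
    }
    _STATS_KEYS = {"alpha", "q", "outlier_removal"}
    _ML_KEYS = {
        "tasks", "combos", "n_permutations", "k_range", "zscore_scope",
        "refit_per_step", "n_test_per_group", "max_train_per_group",
    }

    def __post_init__(self) -> None:
        _check_keys(self.cohort, self._COHORT_KEYS, "cohort")
        _check_keys(self.stats, self._STATS_KEYS, "stats")
        _check_keys(self.ml, self._ML_KEYS, "ml")
        for t in self.ml.get("tasks", []):
            if t not in _TASKS:
                raise ValueError(f"unknown task {t!r}")
        for c in self.ml.get("combos", []):
            if c not in _COMBO_BY_LABEL:
                raise ValueError(f"unknown model combo {c!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys(d, {"seed", "cohort", "stats", "ml"}, "config")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    # -- stage configs -----------------------------------------------------

    def cohort_config(self) -> CohortConfig:
        opts = dict(self.cohort)
        overrides = opts.pop("feature_overrides", {})
        effect_scale = float(opts.pop("effect_scale", 1.0))
        features = []
        for spec in default_panel():
            if spec.name in overrides:
                spec = dataclasses.replace(spec, **overrides[spec.name])
            if effect_scale != 1.0:
                spec = dataclasses.replace(
                    spec,
                    d_genotype=spec.d_genotype * effect_scale,
                    d_treatment=spec.d_treatment * effect_scale,
                    d_wt_treatment=spec.d_wt_treatment * effect_scale,
                )
            features.append(spec)
        return CohortConfig(features=features, seed=stage_seed(self.seed, 0), **opts)

    def stats_config(self) -> StatsConfig:
        return StatsConfig(**self.stats)

    def ml_tasks(self) -> list:
        return [_TASKS[t] for t in self.ml.get("tasks", ["genotype", "treatment"])]

    def ml_combos(self) -> list[ModelCombo]:
        return [_COMBO_BY_LABEL[c] for c in self.ml.get("combos", list(_COMBO_BY_LABEL))]

    def to_dict(self) -> dict:
        return {"seed": self.seed, "cohort": self.cohort, "stats": self.stats, "ml": self.ml}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """All artifacts of one pipeline run plus provenance."""

    config: RunConfig
    table: BiomarkerTable
    stats_results: object
    logistic: dict
    stability: dict
    comparison: dict

    def provenance(self) -> dict:
        return {"config": self.config.to_dict(), "config_digest": self.config.digest(),
                "seed": self.config.seed}


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Run generate -> univariate stats -> ML selection; write artifacts.

    Any stage failure is re-raised with the stage name prepended so the
    offending step is identifiable from the CLI.
    """
    stage = "simulate"
    try:
        cohort_cfg = config.cohort_config()
        table = generate_cohort(cohort_cfg)
        if cohort_cfg.outlier_rate > 0 or cohort_cfg.detection_floor:
            table = inject_contamination(table, cohort_cfg)

        stage = "stats"
        stats_results = BiomarkerStats(table, config.stats_config()).fit()

        stage = "select"
        ml = config.ml
        n_perm = int(ml.get("n_permutations", 1000))
        k_range = ml.get("k_range")
        logistic, stability, comparison = {}, {}, {}
        counter = 1
        for task in config.ml_tasks():
            logistic[task.name] = logistic_rank(table, task)
            per_task = []
            for combo in config.ml_combos():
                model = StabilitySelection(
                    table, task, combo,
                    n_permutations=n_perm,
                    seed=stage_seed(config.seed, counter),
                    k_range=range(k_range[0], k_range[1] + 1) if k_range else None,
                    zscore_scope=ml.get("zscore_scope", "full"),
                    refit_per_step=bool(ml.get("refit_per_step", False)),
                    n_test_per_group=int(ml.get("n_test_per_group", 6)),
                    max_train_per_group=int(ml.get("max_train_per_group", 7)),
                )
                res = model.fit()
                stability[(task.name, combo.label)] = res
                per_task.append(res)
                counter += 1
            if len(per_task) >= 2:
                comparison[task.name] = compare_models(per_task)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    report = RunReport(config, table, stats_results, logistic, stability, comparison)
    if outdir is not None:
        write_report(report, Path(outdir))
    return report


def write_report(report: RunReport, outdir: Path) -> None:
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(outdir / "cohort.csv")
    stats_df = report.stats_results.to_frame()
    stats_df.to_csv(outdir / "stats.csv", index=False)

    if report.stability:
        curves = pd.concat([r.curves for r in report.stability.values()], ignore_index=True)
        curves.to_csv(outdir / "curves.csv", index=False)
        occ_rows = []
        for (task, combo), r in report.stability.items():
            for feat, pct in r.occurrence.items():
                occ_rows.append({"task": task, "combo": combo, "feature": feat, "percent": pct})
        pd.DataFrame(occ_rows).to_csv(outdir / "occurrence.csv", index=False)
    if report.logistic:
        pd.concat(report.logistic.values(), ignore_index=True).to_csv(
            outdir / "logistic_coefficients.csv", index=False
        )
    if report.comparison:
        pd.concat(report.comparison.values(), ignore_index=True).to_csv(
            outdir / "model_comparison.csv", index=False
        )

    payload = {
        "provenance": report.provenance(),
        "excluded_features": report.stats_results.excluded,
        "n_contrast_results": len(report.stats_results.results),
        "significant_features": report.stats_results.significant_features(),
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))

    lines = [report.stats_results.summary(), ""]
    for r in report.stability.values():
        lines += [r.summary(), ""]
    for task, cmp_df in report.comparison.items():
        lines += [f"Model comparison ({task}):", cmp_df.round(3).to_string(index=False), ""]
    (outdir / "summary.txt").write_text("\n".join(lines))
    logger.info("report written to %s", outdir)
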