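"""End-to-end orchestration: simulate → extract → validate → profile → optimize.

A single :class:`RunConfig` (serializable to/from YAML) drives every
stage; every intermediate is persisted in the run directory so a later
stage can be rerun from disk, and a run is reproducible from its config
alone. The run directory contains exactly::

    cohort/            subject/session/movement.csv signal files
    features.csv       windowed, peak-normalized RMS feature table
    cv_report.json     fold results, summaries, hyperparameter record
    profile.json       per-exercise superficial/deep activation means
    plan_<case>.json   one optimized allocation per weighting case
    run.log            versions, seeds, per-stage wall time
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as _cohort
from . import crossval as _crossval
from . import dosage as _dosage
from . import features as _features
from . import signal_io as _sio

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "render_report"]

PLAN_FILE_CASES = {"70/30": "plan_case_70_30.json",
                   "50/50": "plan_case_50_50.json",
                   "30/70": "plan_case_30_70.json"}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one full pipeline run."""

    cohort: _cohort.CohortConfig = field(default_factory=_cohort.CohortConfig)
    window_len: int = 250
    stride: int | None = None
    models: tuple[str, ...] = ("svr", "knn", "adaboost", "xgboost")
    selected_model: str = "xgboost"
    sign_mode: str = "goal-consistent"
    constraints: _dosage.AllocationConstraints = field(
        default_factory=_dosage.AllocationConstraints
    )
    seed: int = 0
    out_dir: str = "emgdose_run"

    def model_specs(self) -> list[_crossval.ModelSpec]:
        return [_crossval.ModelSpec(kind=k, seed=self.seed) for k in self.models]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["gain_table"] = {
            f"{m}|{v}": g for (m, v), g in self.cohort.gain_table.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            cd = dict(d["cohort"])
            if "gain_table" in cd and cd["gain_table"] is not None:
                cd["gain_table"] = {
                    tuple(k.split("|", 1)): float(v)
                    for k, v in cd["gain_table"].items()
                }
            for key in ("movements", "muscles", "band"):
                if key in cd and cd[key] is not None:
                    cd[key] = tuple(cd[key])
            d["cohort"] = _cohort.CohortConfig(**cd)
        if "constraints" in d and isinstance(d["constraints"], dict):
            d["constraints"] = _dosage.AllocationConstraints(**d["constraints"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), allow_unicode=True))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _setup_logger(run_dir: Path) -> logging.Logger:
    logger = logging.getLogger(f"emgdose.run.{run_dir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(run_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.propagate = False
    return logger


def _stage(logger: logging.Logger, name: str):
    class _StageCtx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _StageCtx()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order, persisting every intermediate.

    Returns the run directory. Any stage error aborts with the stage name
    while keeping the outputs of completed stages on disk.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logger = _setup_logger(run_dir)
    import sklearn
    import xgboost

    logger.info(
        "versions: numpy=%s pandas=%s scikit-learn=%s xgboost=%s",
        np.__version__, pd.__version__, sklearn.__version__, xgboost.__version__,
    )
    logger.info("root seed: %s (cohort seed %s)", config.seed, config.cohort.seed)
    config.to_yaml(run_dir / "config.yaml")

    with _stage(logger, "simulate"):
        recordings = _cohort.generate_cohort(config.cohort)
        _sio.write_cohort(recordings, run_dir / "cohort")
        logger.info("simulate: %d recordings", len(recordings))

    with _stage(logger, "extract"):
        table = _features.build_feature_table(
            recordings, window_len=config.window_len, stride=config.stride
        )
        table.to_csv(run_dir / "features.csv", index=False)
        logger.info("extract: %d windows x %d muscles", len(table),
                    len(table.attrs["muscles"]))

    with _stage(logger, "validate"):
        report = _crossval.run_comparison(table, config.model_specs())
        logger.info("validate: hyperparameters %s", json.dumps(report.hyperparameters))
        _write_cv_report(report, run_dir / "cv_report.json")
        logger.info("validate: ranking %s", report.ranking())

    with _stage(logger, "profile"):
        preds = report.predictions[config.selected_model].copy()
        preds["movement_code"] = table["movement_code"]
        profile = _dosage.activation_profile(preds, layer_map=report.layer_map)
        (run_dir / "profile.json").write_text(
            json.dumps(
                {
                    "model": config.selected_model,
                    "exercises": list(profile.exercises),
                    "s": [float(v) for v in profile.s],
                    "d": [float(v) for v in profile.d],
                },
                indent=1,
                ensure_ascii=False,
            )
        )

    with _stage(logger, "optimize"):
        plans = _dosage.run_cases(
            profile, config.constraints, sign_mode=config.sign_mode
        )
        for plan in plans:
            fname = PLAN_FILE_CASES.get(
                plan.weights.case_label,
                f"plan_{plan.weights.case_label.replace('/', '_')}.json",
            )
            (run_dir / fname).write_text(
                json.dumps(plan.as_dict(), indent=1, ensure_ascii=False)
            )
            logger.info(
                "optimize case %s: minutes %s objective %.4f",
                plan.weights.case_label,
                [round(float(v), 2) for v in plan.x],
                plan.objective_value,
            )
    return run_dir


def _write_cv_report(report: _crossval.CVReport, path: Path) -> None:
    per_model = report.per_model_summary().reset_index()
    payload = {
        "folds": [vars(f) for f in report.folds],
        "per_model": per_model.to_dict(orient="records"),
        "per_muscle": {
            model: report.per_muscle_summary(model).to_dict(orient="records")
            for model in per_model["model"]
        },
        "ranking": report.ranking(),
        "aggregate": report.aggregate,
        "hyperparameters": report.hyperparameters,
    }
    path.write_text(json.dumps(payload, indent=1, ensure_ascii=False))


def render_report(run_dir: Path | str) -> dict:
    """Summarize a completed run as plain-text tables plus structured data.

    Returns a dict with ``comparison`` (per-model grand metrics),
    ``per_muscle`` (selected model, grouped by layer), ``allocations``
    (per-case minutes) and a preformatted ``text`` rendering. Raises if a
    required artifact is missing, naming it.
    """
    run_dir = Path(run_dir)
    required = ["features.csv", "cv_report.json", "profile.json", "run.log"]
    for name in required:
        if not (run_dir / name).exists():
            raise FileNotFoundError(f"incomplete run: missing artifact {name!r}")
    cv = json.loads((run_dir / "cv_report.json").read_text())
    profile = json.loads((run_dir / "profile.json").read_text())
    comparison = pd.DataFrame(cv["per_model"])
    best = cv["ranking"][0]
    per_muscle = pd.DataFrame(cv["per_muscle"][best])

    plan_files = sorted(run_dir.glob("plan_*.json"))
    if not plan_files:
        raise FileNotFoundError("incomplete run: missing artifact 'plan_*.json'")
    plans = [json.loads(p.read_text()) for p in plan_files]
    alloc = pd.DataFrame(
        [
            {"case": p["case"], **dict(zip(p["exercises"], p["minutes_rounded"])),
             "total": float(np.sum(p["minutes"]))}
            for p in plans
        ]
    )

    lines = [
        "Model comparison (grand means over fold x muscle cells):",
        comparison.to_string(index=False),
        "",
        f"Per-muscle metrics for {best} (grouped by anatomical layer):",
        per_muscle.to_string(index=False),
        "",
        "Predicted activation profile (s = superficial, d = deep):",
        pd.DataFrame(
            {"exercise": profile["exercises"], "s": profile["s"], "d": profile["d"]}
        ).to_string(index=False),
        "",
        "Optimized session plans (minutes, rounded for display):",
        alloc.to_string(index=False),
    ]
    return {
        "comparison": comparison,
        "per_muscle": per_muscle,
        "allocations": alloc,
        "profile": profile,
        "text": "\n".join(lines),
    }
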