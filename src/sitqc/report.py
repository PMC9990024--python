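"""Pipeline orchestration: run the three analyses and write a report bundle.

The bundle contains tidy CSV tables for each figure-style summary (KM
curves and mean survival, escape rates and GLM, hatch rates, C and IS
with letters), a machine-readable ``report.json`` with every number, an
optional set of plots, and a ``run.log`` recording the seed, bootstrap
size, library versions and the design options in force. Given identical
inputs, configuration and seed, ``report.json`` is byte-identical across
runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .competitiveness import CompetitivenessModel
from .escape import EscapeModel
from .survival import SurvivalModel

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("sitqc")


@dataclass
class PipelineConfig:
    """Inputs, options and seed for a full pipeline run."""

    outdir: str
    lifespans: str | None = None
    flight: str | None = None
    competition: str | None = None
    alpha: float = 0.05
    B: int = 5000
    seed: int | None = None
    pooling: str = "weighted"  # hatch-rate convention: weighted | per_cage
    influence_dummies: bool = False
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.competition is not None and self.seed is None:
            raise ValueError(
                "a seed is required for the bootstrap (stochastic) stage"
            )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        d.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**d)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float):
        return None if not np.isfinite(obj) else obj
    return obj


def _survival_stage(config: PipelineConfig, outdir: Path) -> dict:
    results = SurvivalModel.from_csv(config.lifespans).fit(alpha=config.alpha)
    results.curves_frame().to_csv(outdir / "km_curves.csv", index=False)
    summary = pd.DataFrame(
        {
            "treatment": list(results.curves),
            "n": [c.n for c in results.curves.values()],
            "mean_survival_days": [c.mean_survival for c in results.curves.values()],
            "letters": [results.letters.get(t, "") for t in results.curves],
        }
    )
    summary.to_csv(outdir / "survival_summary.csv", index=False)
    results.pairwise.to_csv(outdir / "survival_pairwise.csv", index=False)
    if config.make_plots:
        from . import plotting

        plotting.save(plotting.plot_km(results), outdir / "survival_km.png")
    return {
        "mean_survival_days": dict(results.mean_survival),
        "letters": results.letters,
        "pairwise": results.pairwise.to_dict(orient="records"),
    }


def _escape_stage(config: PipelineConfig, outdir: Path) -> dict:
    results = EscapeModel.from_csv(config.flight).fit(
        alpha=config.alpha, include_influence_dummies=config.influence_dummies
    )
    rates = results.rates.copy()
    rates["letters"] = rates["treatment"].map(results.letters)
    rates.to_csv(outdir / "escape_rates.csv", index=False)
    results.lsd.to_csv(outdir / "escape_pairwise.csv", index=False)
    glm = results.glm
    pd.DataFrame(
        [
            {"term": "intercept", "estimate": glm.intercept, "se": glm.se_intercept},
            {"term": "second_chill_min", "estimate": glm.slope, "se": glm.se_slope},
        ]
        + [
            {"term": name, "estimate": coef, "se": float("nan")}
            for name, coef in glm.dummy_coefs.items()
        ]
    ).to_csv(outdir / "escape_glm.csv", index=False)
    if config.make_plots:
        from . import plotting

        plotting.save(plotting.plot_escape_rates(results), outdir / "escape_rates.png")
        if glm.converged:
            plotting.save(plotting.plot_escape_glm(results), outdir / "escape_glm.png")
    return {
        "rates": rates.to_dict(orient="records"),
        "kruskal_wallis": {"H": results.kw_h, "p": results.kw_p},
        "letters": results.letters,
        "glm": {
            "intercept": glm.intercept,
            "slope": glm.slope,
            "se_intercept": glm.se_intercept,
            "se_slope": glm.se_slope,
            "deviance": glm.deviance,
            "null_deviance": glm.null_deviance,
            "converged": glm.converged,
            "dummy_columns": glm.dummy_columns,
        },
    }


def _competition_stage(config: PipelineConfig, outdir: Path) -> dict:
    results = CompetitivenessModel.from_csv(config.competition).fit(
        B=config.B, seed=config.seed, alpha=config.alpha, pooling=config.pooling
    )
    results.hatch_table.to_csv(outdir / "hatch_rates.csv", index=False)
    results.fried_table().to_csv(outdir / "fried.csv", index=False)
    if results.comparisons:
        for metric, (table, _) in results.comparisons.items():
            table.to_csv(
                outdir / f"competitiveness_pairwise_{metric}.csv", index=False
            )
    if config.make_plots:
        from . import plotting

        plotting.save(plotting.plot_hatch(results), outdir / "hatch_rates.png")
        plotting.save(plotting.plot_fried(results), outdir / "fried.png")
    return {
        "hatch": results.hatch_table.to_dict(orient="records"),
        "betabinom": {
            arm: {
                "mean_hatch": bb.mean_hatch,
                "overdispersion": bb.overdispersion,
                "log_likelihood": bb.log_likelihood,
                "converged": bb.converged,
            }
            for arm, bb in results.betabinom.items()
        },
        "fried": {
            arm: {
                "C_point": r.C_point,
                "C_mean": r.C_mean,
                "C_se": r.C_se,
                "C_ci95": list(r.C_ci95),
                "IS_point": r.IS_point,
                "IS_mean": r.IS_mean,
                "IS_se": r.IS_se,
                "IS_ci95": list(r.IS_ci95),
                "n_undefined": r.n_undefined,
            }
            for arm, r in results.fried.items()
        },
        "letters_C": results.letters_C,
        "letters_IS": results.letters_IS,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage with an input file, write the bundle, return it.

    Stages without an input path are skipped with a logged reason; a
    stage that raises is recorded in the failure manifest and the other
    stages still produce their outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    import lifelines
    import scipy
    import statsmodels

    logger.info(
        "versions: numpy %s scipy %s pandas %s lifelines %s statsmodels %s",
        np.__version__, scipy.__version__, pd.__version__,
        lifelines.__version__, statsmodels.__version__,
    )
    logger.info(
        "options: seed=%s B=%d alpha=%g pooling=%s influence_dummies=%s",
        config.seed, config.B, config.alpha, config.pooling,
        config.influence_dummies,
    )

    report: dict[str, Any] = {
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
        "skipped": {},
        "failures": {},
    }
    stages = {
        "survival": (config.lifespans, _survival_stage),
        "escape": (config.flight, _escape_stage),
        "competitiveness": (config.competition, _competition_stage),
    }
    for name, (path, stage) in stages.items():
        if path is None:
            report["skipped"][name] = "no input file configured"
            logger.info("stage %s skipped: no input file", name)
            continue
        if not Path(path).exists():
            report["skipped"][name] = f"input file not found: {path}"
            logger.warning("stage %s skipped: %s missing", name, path)
            continue
        try:
            report["stages"][name] = stage(config, outdir)
            logger.info("stage %s completed", name)
        except Exception as err:  # surface per stage, keep the rest running
            report["failures"][name] = f"{type(err).__name__}: {err}"
            logger.error("stage %s failed: %s", name, err)

    payload = json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n"
    (outdir / "report.json").write_text(payload)
    logger.removeHandler(handler)
    handler.close()
    return report
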