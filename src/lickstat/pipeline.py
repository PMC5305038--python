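"""End-to-end orchestration: simulate -> summarize -> compare -> report.

A run is driven by a single :class:`RunConfig` (loadable from TOML) and is
fully deterministic given its contents, including the master seed.  Every
default standing in for an unreported analysis parameter (pause criterion,
artifact floor, Bayes prior scale) is echoed into the run log so the
assumptions travel with the results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy

from . import __version__
from . import inference, microstructure
from . import simulate as sim
from .inference import MEASURE_TESTS
from .microstructure import MEASURES

try:  # Python >= 3.11
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    import tomli as tomllib

__all__ = ["RunConfig", "PipelineError", "run_analysis", "render_report", "run"]

logger = logging.getLogger("lickstat")

REPORT_COLUMNS = [
    "measure",
    "test",
    "statistic",
    "df",
    "p_two_tailed",
    "bonferroni_alpha",
    "significant",
    "K",
    "K_direction",
]


class PipelineError(RuntimeError):
    """A stage failure; the message names the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run.

    Either ``events_path``/``sessions_path`` point at an existing dataset,
    or ``simulate=True`` generates one from ``cohort`` under ``out_dir``.
    """

    out_dir: str = "lickstat_run"
    simulate: bool = True
    events_path: str | None = None
    sessions_path: str | None = None
    cohort: sim.CohortConfig = field(default_factory=sim.CohortConfig)
    pause_criterion: float = microstructure.DEFAULT_PAUSE_CRITERION
    artifact_floor: float = microstructure.DEFAULT_ARTIFACT_FLOOR
    family: int = 7
    alpha: float = 0.05
    rscale: float = inference.DEFAULT_RSCALE
    measure_tests: dict[str, str] = field(
        default_factory=lambda: dict(MEASURE_TESTS)
    )
    covariates_path: str | None = None

    def __post_init__(self) -> None:
        if self.pause_criterion <= 0 or self.artifact_floor < 0:
            raise ValueError("pause_criterion must be > 0, artifact_floor >= 0")
        if self.family < 1:
            raise ValueError("family size must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.rscale <= 0:
            raise ValueError("rscale must be positive")
        unknown = set(self.measure_tests) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures in measure_tests: {sorted(unknown)}")
        if not self.simulate and (self.events_path is None or self.sessions_path is None):
            raise ValueError(
                "events_path and sessions_path are required when simulate=False"
            )

    def to_canonical_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_canonical_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cohort_raw = raw.pop("cohort", {})
    control_raw = cohort_raw.pop("control_params", {})
    mcao_raw = cohort_raw.pop("mcao_params", {})
    cohort = sim.CohortConfig(
        control_params=sim.GroupParams(**control_raw),
        mcao_params=(
            sim.GroupParams(**mcao_raw)
            if mcao_raw
            else sim.default_mcao_params()
        ),
        **cohort_raw,
    )
    return RunConfig(cohort=cohort, **raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("simulate")
def _stage_dataset(config: RunConfig, out_dir: Path):
    if config.simulate:
        records = sim.simulate_cohort(config.cohort)
        sim.write_dataset(
            records, out_dir, config.cohort.timestamp_resolution_s
        )
        return out_dir / "events.csv", out_dir / "sessions.csv"
    return Path(config.events_path), Path(config.sessions_path)


@_stage("summarize")
def _stage_summaries(config: RunConfig, events_path, sessions_path) -> pd.DataFrame:
    records = microstructure.read_lick_events(events_path, sessions_path)
    return microstructure.summarize_cohort(
        records, config.pause_criterion, config.artifact_floor
    )


@_stage("compare")
def _stage_battery(config: RunConfig, summaries: pd.DataFrame) -> list[dict]:
    return inference.run_battery(
        summaries,
        family=config.family,
        alpha=config.alpha,
        rscale=config.rscale,
        measure_tests=config.measure_tests,
    )


@_stage("anova")
def _stage_anova(summaries: pd.DataFrame) -> dict[str, Any]:
    """Lesion-subtype one-way ANOVA on lick volume and consumption."""
    out: dict[str, Any] = {}
    subtypes = ["none", "striatal", "striatal_cortical"]
    present = [
        s for s in subtypes if (summaries["lesion_subtype"] == s).sum() >= 2
    ]
    if len(present) < 3:
        return out
    for measure in ("lick_volume_ml_per_1000", "consumption_ml"):
        groups = [
            summaries.loc[summaries["lesion_subtype"] == s, measure]
            .dropna()
            .to_numpy()
            for s in present
        ]
        main, posthoc = inference.one_way_anova(
            groups, measure_name=measure, group_names=present
        )
        out[measure] = {"anova": main, "posthoc": posthoc}
    return out


@_stage("correlations")
def _stage_correlations(
    config: RunConfig, summaries: pd.DataFrame
) -> list[inference.TestResult]:
    """Correlate lick volume with each supplied per-subject covariate."""
    if config.covariates_path is None:
        return []
    cov = pd.read_csv(config.covariates_path, dtype={"subject_id": str})
    merged = summaries.merge(cov, on="subject_id", how="inner")
    results = []
    for col in cov.columns:
        if col == "subject_id":
            continue
        sub = merged[["lick_volume_ml_per_1000", col]].dropna()
        results.append(
            inference.pearson_r(
                sub["lick_volume_ml_per_1000"],
                sub[col],
                measure_name=f"lick_volume_vs_{col}",
            )
        )
    return results


@_stage("cv_table")
def _stage_cv(summaries: pd.DataFrame) -> dict[str, float]:
    """Per-measure coefficient of variation within the control group."""
    control = summaries[summaries["group"] == "control"]
    out = {}
    for measure in MEASURES:
        vals = control[measure].dropna().to_numpy()
        if vals.size >= 2 and vals.mean() != 0:
            out[measure] = inference.coefficient_of_variation(vals)
    return out


def run_analysis(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns the report bundle.

    On any stage failure, files created under ``out_dir`` by this run are
    removed and a stage-named :class:`PipelineError` is raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    logger.info(
        "run config: pause_criterion=%s artifact_floor=%s rscale=%s family=%s "
        "(defaults stand in for unreported analysis parameters)",
        config.pause_criterion,
        config.artifact_floor,
        config.rscale,
        config.family,
    )
    try:
        events_path, sessions_path = _stage_dataset(config, out_dir)
        if config.simulate:
            created += [events_path, sessions_path]
        summaries = _stage_summaries(config, events_path, sessions_path)
        summaries_path = out_dir / "subject_summaries.csv"
        microstructure.write_subject_summaries(summaries, summaries_path)
        created.append(summaries_path)

        battery = _stage_battery(config, summaries)
        anova = _stage_anova(summaries)
        correlations = _stage_correlations(config, summaries)
        cv_table = _stage_cv(summaries)
    except PipelineError:
        for path in created:
            path.unlink(missing_ok=True)
        raise

    bundle = {
        "measures": battery,
        "anova": anova,
        "correlations": correlations,
        "cv_table": cv_table,
        "summaries": summaries,
        "provenance": {
            "config_hash": config.config_hash(),
            "lickstat_version": __version__,
            "numpy_version": np.__version__,
            "scipy_version": scipy.__version__,
            "pandas_version": pd.__version__,
        },
    }
    return bundle


def _df_repr(df) -> str:
    if df is None:
        return ""
    if isinstance(df, tuple):
        return f"{df[0]:g},{df[1]:g}"
    return f"{df:g}"


def render_report(bundle: dict[str, Any]) -> pd.DataFrame:
    """One row per measure: statistic, df, p, verdict, and K.

    The K column follows reporting convention: bf01 when the null is
    supported (bf10 < 1), bf10 otherwise.
    """
    rows = []
    for entry in bundle.get("measures", []):
        res: inference.TestResult = entry["test"]
        bf: inference.BayesFactorResult | None = entry.get("bayes_factor")
        rows.append(
            {
                "measure": res.measure_name,
                "test": res.test_name,
                "statistic": res.statistic,
                "df": _df_repr(res.df),
                "p_two_tailed": res.p_two_tailed,
                "bonferroni_alpha": res.bonferroni_alpha,
                "significant": res.significant,
                "K": bf.k if bf is not None else float("nan"),
                "K_direction": bf.direction_reported if bf is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, inference.TestResult):
        return {
            "measure": obj.measure_name,
            "test": obj.test_name,
            "statistic": obj.statistic,
            "df": obj.df,
            "p_two_tailed": obj.p_two_tailed,
            "bonferroni_alpha": obj.bonferroni_alpha,
            "significant": obj.significant,
        }
    if isinstance(obj, inference.BayesFactorResult):
        return {
            "bf10": obj.bf10,
            "bf01": obj.bf01,
            "K": obj.k,
            "direction": obj.direction_reported,
            "rscale": obj.rscale,
        }
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def run(config: RunConfig) -> dict[str, Any]:
    """run_analysis plus report files (report.json, report.csv)."""
    bundle = run_analysis(config)
    out_dir = Path(config.out_dir)
    report = render_report(bundle)
    report.to_csv(out_dir / "report.csv", index=False)

    serializable = {
        k: _jsonify(v) for k, v in bundle.items() if k != "summaries"
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(serializable, fh, indent=2)
    return bundle
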