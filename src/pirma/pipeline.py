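"""End-to-end orchestration: simulate/load -> validate -> panels -> fit -> report.

A run is fully described by a :class:`RunConfig`; re-running with the same
configuration and seed reproduces every artifact.  Tabular artifacts:

* ``panel_table.csv``        - per-(arm, month) summary (the cohort table),
* ``panel_observations.csv`` - per-(prescription, arm, month) evaluations,
* ``adjusted_means.csv``     - modeled probabilities with SE/CI/letters,
* ``contrasts.csv``          - between-panel comparisons,
* ``manifest.json``          - configuration, seed, versions, artifact list.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .estimation import DEFAULT_PROFILE, arm_adjusted_table, compare_panels
from .panels import PanelConfig, build_panel_table
from .plots import render_error_bar_plot
from .registry import Registry, read_registry, validate_registry, write_registry
from .simulate import GeneratorConfig, default_config, generate_registry

__all__ = ["RunConfig", "PipelineError", "ValidationFailure", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class ValidationFailure(PipelineError):
    """The registry failed structural validation."""


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``input_path`` (a registry bundle directory) or
    ``generator`` (a simulation configuration) must be provided.
    """

    out_dir: Path
    input_path: Path | None = None
    generator: GeneratorConfig | None = None
    seed: int = 0
    arms: tuple[str, ...] = ("R1-", "R1+", "R0", "R0+MRI0", "R1", "R2")
    responses: tuple[str, ...] = ("worse",)
    profile: dict = field(default_factory=lambda: dict(DEFAULT_PROFILE))
    panel_config: PanelConfig = field(default_factory=PanelConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError(
                "provide exactly one of input_path or generator config"
            )
        self.out_dir = Path(self.out_dir)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ValidationFailure, PipelineError):
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the artifact manifest (also written)."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {
        "pirma_version": __version__,
        "seed": config.seed,
        "stages": [],
        "artifacts": [],
    }

    registry = _load(config)
    manifest["stages"].append({"stage": "load", "counts": registry.counts()})
    logger.info("load: %s", registry.counts())

    report = validate_registry(registry)
    manifest["stages"].append(
        {"stage": "validate", "violations": len(report)}
    )
    if not report.ok:
        raise ValidationFailure(
            f"stage 'validate' failed: {len(report)} violation(s); first: "
            f"{report.violations[0]}"
        )
    if config.generator is not None:
        write_registry(registry, out / "registry")
        manifest["artifacts"].append("registry/")

    if registry.prescriptions.empty:
        _write_empty_tables(out, manifest)
        _write_manifest(out, config, manifest)
        raise PipelineError("stage 'panels' failed: registry is empty")

    panel_table, observations = _panels(registry, config)
    panel_table.to_csv(out / "panel_table.csv", index=False)
    observations.to_csv(out / "panel_observations.csv", index=False)
    manifest["artifacts"] += ["panel_table.csv", "panel_observations.csv"]
    manifest["stages"].append(
        {
            "stage": "panels",
            "evaluations": int(len(observations)),
            "arms": sorted(observations["arm"].unique().tolist()),
        }
    )
    logger.info("panels: %d evaluations", len(observations))

    adjusted = _fit(observations, config)
    adjusted.to_csv(out / "adjusted_means.csv", index=False)
    contrasts = compare_panels(observations, seed=config.seed)
    contrasts.to_csv(out / "contrasts.csv", index=False)
    manifest["artifacts"] += ["adjusted_means.csv", "contrasts.csv"]
    manifest["stages"].append(
        {"stage": "fit", "adjusted_rows": int(len(adjusted)),
         "contrast_rows": int(len(contrasts))}
    )
    logger.info("fit: %d adjusted means, %d contrasts",
                len(adjusted), len(contrasts))

    plot_files = _report(observations, panel_table, out)
    manifest["artifacts"] += plot_files
    manifest["stages"].append({"stage": "report", "plots": plot_files})

    _write_manifest(out, config, manifest)
    return manifest


@_stage("load")
def _load(config: RunConfig) -> Registry:
    if config.input_path is not None:
        return read_registry(config.input_path)
    generator = config.generator or default_config()
    return generate_registry(generator, seed=config.seed)


@_stage("panels")
def _panels(registry: Registry, config: RunConfig):
    return build_panel_table(registry, config.panel_config)


@_stage("fit")
def _fit(observations: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    frames = []
    for response in config.responses:
        table = arm_adjusted_table(
            observations,
            arms=config.arms,
            response=response,
            profile=config.profile,
            seed=config.seed,
        )
        table.insert(0, "Response", response)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


@_stage("report")
def _report(
    observations: pd.DataFrame, panel_table: pd.DataFrame, out: Path
) -> list[str]:
    files = []
    specs = [
        ("worsening_R0.png", "R0", "worse",
         "Worsening frequency, no relapse on treatment"),
        ("mri_activity_R0.png", "R0", "mri_active",
         "Brain MRI activity frequency, no relapse on treatment"),
        ("worsening_R0_MRI0.png", "R0+MRI0", "worse",
         "Progression frequency, no relapse and no MRI activity"),
    ]
    for filename, arm, response, title in specs:
        sub = observations[observations["arm"] == arm]
        if sub.empty:
            continue
        freq = (
            sub.assign(flag=sub[response].astype(int))
            .groupby(["month", "treatment_line", "drug"], as_index=False)
            .agg(n=("flag", "size"), positives=("flag", "sum"))
        )
        render_error_bar_plot(freq, out / filename, title=title)
        files.append(filename)
    return files


def _write_empty_tables(out: Path, manifest: dict) -> None:
    from .panels import OBS_COLUMNS

    pd.DataFrame(
        columns=[
            "arm", "month", "n", "f_to_m", "median_age", "median_age_symptoms",
            "median_symptom_duration", "relapse_count", "median_baseline_edss",
            "worsening_count",
        ]
    ).to_csv(out / "panel_table.csv", index=False)
    pd.DataFrame(columns=OBS_COLUMNS).to_csv(
        out / "panel_observations.csv", index=False
    )
    pd.DataFrame(
        columns=["Response", "Arm", "Time", "Covariate", "Prob", "SE",
                 "Asymp.LCL", "Asymp.UCL", "Group"]
    ).to_csv(out / "adjusted_means.csv", index=False)
    pd.DataFrame(
        columns=["lhs_arm", "lhs_month", "rhs_arm", "rhs_month",
                 "log_odds_diff", "se", "z", "p_unadjusted", "p_adjusted",
                 "significant"]
    ).to_csv(out / "contrasts.csv", index=False)
    manifest["artifacts"] += [
        "panel_table.csv", "panel_observations.csv", "adjusted_means.csv",
        "contrasts.csv",
    ]


def _write_manifest(out: Path, config: RunConfig, manifest: dict) -> None:
    import numpy
    import scipy
    import statsmodels

    manifest["versions"] = {
        "pandas": pd.__version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
    manifest["config"] = {
        "input_path": str(config.input_path) if config.input_path else None,
        "generator": (
            None
            if config.generator is None
            else {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(config.generator).items()
            }
        ),
        "seed": config.seed,
        "arms": list(config.arms),
        "responses": list(config.responses),
        "profile": config.profile,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["artifacts"].append("manifest.json")
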