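"""End-to-end run: design -> simulate -> trim -> summarize -> patterns.

Writes plain-text artifacts (CSV/JSON) plus a manifest with the seeds and
a parameter hash, so any run can be replayed bit-for-bit from its output
directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

from .experiment import (
    EXP2_CONTROL,
    EXP2_EXPERIMENTAL,
    EXPERIMENTS,
    check_patterns,
    generate_design,
    results_to_frame,
    run_virtual_experiment,
    summarize,
    trim_outliers,
)
from .params import ModelParams, default_params, load_params

__all__ = ["RunConfig", "run_pipeline", "params_hash"]

log = logging.getLogger("primevoice")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    experiment: str
    participants: int
    seed: int
    out_dir: str | Path
    params_path: str | Path | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.participants <= 0:
            raise ValueError("participants must be > 0")
        if self.params_path is not None and not Path(self.params_path).exists():
            raise FileNotFoundError(self.params_path)

    def resolve_params(self) -> ModelParams:
        if self.params_path is not None:
            return load_params(self.params_path)
        return default_params(self.experiment)


def params_hash(params: ModelParams) -> str:
    """Stable hash of a parameter set (canonical JSON, SHA-256)."""
    canon = json.dumps(params.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _package_version() -> str:
    try:
        return version("primevoice")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def run_pipeline(config: RunConfig) -> Path:
    """Run one experiment end to end; returns the artifact directory.

    Artifacts: ``design.csv``, ``trials.csv``, ``summary_tendencies.csv``,
    ``summary_latencies.csv``, ``patterns.json``, ``manifest.json``.  For
    the Experiment-2 experimental group a control-group companion run (same
    seed and size) is simulated as well so the group contrast (p5) can be
    evaluated.
    """
    logging.basicConfig(level=config.log_level.upper())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.resolve_params()

    log.info("generating %s design for %d participants", config.experiment,
             config.participants)
    design = generate_design(config.experiment, config.participants, config.seed)
    design.to_frame().to_csv(out / "design.csv", index=False)

    log.info("simulating virtual participants (seed %d)", config.seed)
    results = run_virtual_experiment(design, params, config.seed)
    trim_outliers(results)
    results_to_frame(results).to_csv(out / "trials.csv", index=False)

    summary = summarize(results, config.experiment)
    summary.tendencies.to_csv(out / "summary_tendencies.csv", index=False)
    summary.latencies.to_csv(out / "summary_latencies.csv", index=False)

    control_summary = None
    if config.experiment == EXP2_EXPERIMENTAL:
        log.info("simulating control-group companion run for the group contrast")
        c_design = generate_design(EXP2_CONTROL, config.participants, config.seed)
        c_results = run_virtual_experiment(c_design, params, config.seed)
        trim_outliers(c_results)
        control_summary = summarize(c_results, EXP2_CONTROL)

    report = check_patterns(summary, config.experiment, control_summary)
    (out / "patterns.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")

    manifest = {
        "experiment": config.experiment,
        "participants": config.participants,
        "seed": config.seed,
        "params": params.to_dict(),
        "params_sha256": params_hash(params),
        "package_version": _package_version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
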