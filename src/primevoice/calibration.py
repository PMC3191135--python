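"""Calibration: grid search of parameter space against summary-level targets.

The printed results a calibration can anchor on are summary statistics
(baseline structure rates) and the qualitative priming signature (pattern
booleans), so the objective is a weighted least-squares loss over numeric
targets plus a hard all-patterns-true constraint, evaluated over replicate
simulations.  Grid or random enumeration is used rather than gradients:
the objective is stochastic and cheap at these problem sizes, and exact
reproducibility of the search matters more than efficiency.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .experiment import (
    EXP2_CONTROL,
    EXP2_EXPERIMENTAL,
    EXPERIMENTS,
    PatternReport,
    SummaryTable,
    check_patterns,
    generate_design,
    run_virtual_experiment,
    summarize,
    trim_outliers,
)
from .params import ModelParams, ParamError, save_params

__all__ = [
    "CalibrationTarget",
    "GridSpec",
    "CandidateResult",
    "load_targets",
    "load_grid",
    "evaluate_candidate",
    "search",
]

#: statistic accessors usable in numeric calibration targets (percent scale)
_STATISTICS: dict[str, Callable[[SummaryTable], float]] = {
    "baseline_passive_pct": lambda s: 100.0 * s.baseline_passive_rate(),
    "baseline_active_pct": lambda s: 100.0 * (1.0 - s.baseline_passive_rate()),
}

_MAX_TIMEOUT_RATE = 0.10


@dataclass(frozen=True)
class CalibrationTarget:
    """One calibration constraint.

    Either a numeric target (``statistic`` with ``target_value`` and
    ``tolerance``) or a pattern constraint (``pattern`` names a
    :class:`PatternReport` boolean that must be true).
    """

    name: str
    experiment: str
    statistic: str | None = None
    target_value: float | None = None
    tolerance: float | None = None
    pattern: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if (self.statistic is None) == (self.pattern is None):
            raise ValueError(
                f"target {self.name!r} must set exactly one of statistic/pattern"
            )
        if self.statistic is not None:
            if self.statistic not in _STATISTICS:
                raise ValueError(f"unknown statistic {self.statistic!r}")
            if self.target_value is None or self.tolerance is None:
                raise ValueError(f"numeric target {self.name!r} needs value+tolerance")
            if self.tolerance <= 0:
                raise ValueError(f"target {self.name!r}: tolerance must be > 0")


@dataclass
class GridSpec:
    """Finite candidate grid: base parameters plus per-parameter value lists."""

    base: ModelParams
    values: dict[str, list[float]]
    n_participants: int = 10
    n_reps: int = 5

    def candidates(self) -> list[ModelParams]:
        names = sorted(self.values)
        out = []
        for combo in itertools.product(*(self.values[n] for n in names)):
            try:
                out.append(self.base.replace(**dict(zip(names, combo))))
            except ParamError:
                continue  # invariant-violating corner of the grid
        return out


@dataclass
class CandidateResult:
    params: ModelParams
    loss: float
    pattern_pass: bool
    valid: bool
    pattern_rates: dict[str, float] = field(default_factory=dict)
    stats: dict[str, float] = field(default_factory=dict)


def load_targets(path: str | Path) -> list[CalibrationTarget]:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, list):
        raise ValueError("targets file must contain a list of targets")
    return [CalibrationTarget(**item) for item in data]


def load_grid(path: str | Path, base: ModelParams) -> GridSpec:
    data = yaml.safe_load(Path(path).read_text())
    return GridSpec(
        base=base,
        values={k: list(v) for k, v in data["values"].items()},
        n_participants=int(data.get("n_participants", 10)),
        n_reps=int(data.get("n_reps", 5)),
    )


def _default_runner(
    params: ModelParams, experiment: str, n_participants: int, seed: int
) -> tuple[SummaryTable, float]:
    """Simulate one experiment; returns (summary, timeout rate)."""
    design = generate_design(experiment, n_participants, seed)
    results = run_virtual_experiment(design, params, seed)
    trim_outliers(results)
    timeouts = float(np.mean([r.timed_out for r in results])) if results else 0.0
    return summarize(results, experiment), timeouts


Runner = Callable[[ModelParams, str, int, int], tuple[SummaryTable, float]]


def evaluate_candidate(
    params: ModelParams,
    targets: Sequence[CalibrationTarget],
    n_participants: int,
    n_reps: int,
    seed: int,
    runner: Runner = _default_runner,
) -> CandidateResult:
    """Score one candidate against the calibration targets.

    Loss is the replicate-average of sum(((statistic - target)/tolerance)^2)
    over numeric targets; pattern constraints must all hold in a majority
    of replicates.  Candidates whose simulations time out on more than 10%
    of trials are marked invalid.  Deterministic given ``seed``.
    """
    if not targets:
        raise ValueError("need at least one calibration target")
    experiments = sorted({t.experiment for t in targets})
    if any(
        t.pattern == "p5" for t in targets
    ) and EXP2_CONTROL not in experiments:
        experiments.append(EXP2_CONTROL)

    losses = []
    pattern_ok = []
    timeout_rates = []
    last_stats: dict[str, float] = {}
    pattern_counts: dict[str, list[bool]] = {}
    for rep in range(n_reps):
        rep_seed = seed + 1009 * rep
        summaries: dict[str, SummaryTable] = {}
        for exp in experiments:
            summary, to_rate = runner(params, exp, n_participants, rep_seed)
            summaries[exp] = summary
            timeout_rates.append(to_rate)
        reports: dict[str, PatternReport] = {
            exp: check_patterns(
                summaries[exp], exp, summaries.get(EXP2_CONTROL)
                if exp == EXP2_EXPERIMENTAL else None,
            )
            for exp in experiments
        }
        loss = 0.0
        ok = True
        for t in targets:
            if t.statistic is not None:
                value = _STATISTICS[t.statistic](summaries[t.experiment])
                last_stats[t.name] = value
                loss += ((value - t.target_value) / t.tolerance) ** 2
            else:
                flag = reports[t.experiment].checks.get(t.pattern)
                pattern_counts.setdefault(t.name, []).append(flag is True)
                ok = ok and flag is True
        losses.append(loss)
        pattern_ok.append(ok)

    timeout_rate = float(np.mean(timeout_rates)) if timeout_rates else 0.0
    return CandidateResult(
        params=params,
        loss=float(np.mean(losses)),
        pattern_pass=sum(pattern_ok) > n_reps / 2,
        valid=timeout_rate <= _MAX_TIMEOUT_RATE,
        pattern_rates={k: float(np.mean(v)) for k, v in pattern_counts.items()},
        stats=dict(last_stats),
    )


def search(
    grid: GridSpec,
    targets: Sequence[CalibrationTarget],
    seed: int,
    runner: Runner = _default_runner,
    best_out: str | Path | None = None,
) -> tuple[pd.DataFrame, ModelParams | None]:
    """Evaluate every grid candidate and rank the passing ones by loss.

    Returns a report frame (one row per candidate: parameters, loss,
    pattern pass, validity, per-pattern pass rates) and the best passing
    candidate's parameters (written to ``best_out`` when given).  When no
    candidate passes, the report still carries per-pattern pass rates as
    diagnostics and the best params are ``None``.  The ranking is invariant
    to candidate enumeration order (ties broken on the parameter values).
    """
    names = sorted(grid.values)
    rows = []
    scored: list[CandidateResult] = []
    for cand in grid.candidates():
        res = evaluate_candidate(
            cand, targets, grid.n_participants, grid.n_reps, seed, runner
        )
        scored.append(res)
        row = {n: getattr(cand, n) for n in names}
        row.update(
            loss=res.loss,
            pattern_pass=res.pattern_pass,
            valid=res.valid,
        )
        for k, v in res.pattern_rates.items():
            row[f"rate_{k}"] = v
        for k, v in res.stats.items():
            row[f"stat_{k}"] = v
        rows.append(row)
    report = pd.DataFrame(rows)
    if not report.empty:
        report = report.sort_values(
            ["pattern_pass", "valid", "loss"] + names,
            ascending=[False, False, True] + [True] * len(names),
        ).reset_index(drop=True)

    passing = [r for r in scored if r.pattern_pass and r.valid]
    if not passing:
        return report, None
    best = min(
        passing,
        key=lambda r: (r.loss, tuple(getattr(r.params, n) for n in names)),
    )
    if best_out is not None:
        save_params(best.params, best_out)
    return report, best.params
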