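"""Model parameters: the dynamical constants of the competition model.

All tunable constants of the selection stage (decay, thresholds, weights,
noise, input drive), the planning stage (baseline durations and practice
reductions), the cycle-to-millisecond mapping, and the learning rule live in
a single flat :class:`ModelParams` record.  Parameter files are flat YAML or
JSON mappings with exactly these field names; unknown or missing keys are
rejected so that a configuration can never silently drift from the schema.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ModelParams", "ParamError", "load_params", "save_params", "default_params"]


class ParamError(ValueError):
    """Raised for malformed parameter files or invariant violations."""


_INT_FIELDS = frozenset({"settle_cycles", "max_cycles"})


@dataclass(frozen=True)
class ModelParams:
    """All dynamical constants of the competition model.

    Attributes
    ----------
    decay:
        Per-cycle decay factor ``d`` applied to the excursion of a node's
        activation from its resting level (in (0, 1); e.g. .95).
    theta_exc:
        Excitation threshold: below it a node is dormant and emits neither
        activation nor inhibition (e.g. .3).
    theta_sel:
        Selection threshold: reaching it means the node fires and its
        construction is selected (e.g. .9).
    rest_active, rest_passive:
        Resting (base) activation levels of Active and Passive Voice nodes.
        Both sit below ``theta_exc``; the active level is higher, reflecting
        the higher corpus frequency of active transitives.
    w_inhib:
        Inhibitory weight between a verb's two voice nodes (symmetric).
    w_cross:
        Excitatory weight from a fired voice node to same-voice nodes of
        other verbs (the one-shot cross-verb spread behind the lexical boost).
    noise_sd:
        Standard deviation of the i.i.d. Gaussian noise added to every node
        on every cycle (pre-squash).
    input_drive:
        Per-cycle feedforward input delivered to voice nodes during
        selection (both nodes on free-choice targets, the cued node only on
        color-coded primes).
    settle_cycles:
        Number of drive-free decay cycles applied to the whole lexicon
        between a prime's firing and target onset (and between trials).
    max_cycles:
        Selection timeout; on timeout the higher node wins and the trial is
        flagged, never raised.
    ms_per_cycle, latency_intercept_ms:
        Linear mapping from selection cycles to milliseconds; the intercept
        absorbs articulation and voice-key delay.
    plan_base_active_ms, plan_base_passive_ms:
        Baseline planning-stage durations per structure.
    practice_reduction:
        Proportional planning speed-up when the same structure was produced
        on the preceding trial (the practice effect).
    lexical_plan_reduction:
        Additional planning speed-up for full (verb + noun) word repetition;
        verb-only repetition leaves planning untouched.
    learn_increment:
        Resting-level increment per forced production of a structure,
        applied globally to all nodes of that voice.
    learn_ceiling_margin:
        Resting levels are capped at ``theta_exc - learn_ceiling_margin``.
    """

    decay: float
    theta_exc: float
    theta_sel: float
    rest_active: float
    rest_passive: float
    w_inhib: float
    w_cross: float
    noise_sd: float
    input_drive: float
    settle_cycles: int
    max_cycles: int
    ms_per_cycle: float
    latency_intercept_ms: float
    plan_base_active_ms: float
    plan_base_passive_ms: float
    practice_reduction: float
    lexical_plan_reduction: float
    learn_increment: float
    learn_ceiling_margin: float

    def __post_init__(self) -> None:
        violations = self.violations()
        if violations:
            raise ParamError(
                "invalid ModelParams:\n  - " + "\n  - ".join(violations)
            )

    def violations(self) -> list[str]:
        """Return every violated invariant (empty list when valid)."""
        v: list[str] = []
        p = self
        if not (0.0 < p.decay < 1.0):
            v.append(f"decay must be in (0,1), got {p.decay}")
        if not (0.0 < p.theta_exc < p.theta_sel <= 1.0):
            v.append(
                "threshold ordering 0 < theta_exc < theta_sel <= 1 violated "
                f"(theta_exc={p.theta_exc}, theta_sel={p.theta_sel})"
            )
        for name in ("rest_active", "rest_passive"):
            r = getattr(p, name)
            if not (0.0 <= r < p.theta_exc):
                v.append(
                    f"{name}={r} must lie in [0, theta_exc): resting levels "
                    "of both competitor nodes sit below the excitation threshold"
                )
        if not p.rest_active > p.rest_passive:
            v.append(
                "rest_active must exceed rest_passive (resting level tracks "
                f"frequency of occurrence); got {p.rest_active} <= {p.rest_passive}"
            )
        for name in ("w_inhib", "w_cross", "noise_sd", "input_drive"):
            if getattr(p, name) < 0.0:
                v.append(f"{name} must be >= 0, got {getattr(p, name)}")
        if p.settle_cycles < 0:
            v.append(f"settle_cycles must be >= 0, got {p.settle_cycles}")
        if p.max_cycles <= 0:
            v.append(f"max_cycles must be > 0, got {p.max_cycles}")
        if p.ms_per_cycle <= 0.0:
            v.append(f"ms_per_cycle must be > 0, got {p.ms_per_cycle}")
        if p.latency_intercept_ms < 0.0:
            v.append(f"latency_intercept_ms must be >= 0, got {p.latency_intercept_ms}")
        for name in ("plan_base_active_ms", "plan_base_passive_ms"):
            if getattr(p, name) <= 0.0:
                v.append(f"{name} must be > 0, got {getattr(p, name)}")
        for name in ("practice_reduction", "lexical_plan_reduction"):
            x = getattr(p, name)
            if not (0.0 <= x < 1.0):
                v.append(f"{name} must be in [0,1), got {x}")
        if p.learn_increment < 0.0:
            v.append(f"learn_increment must be >= 0, got {p.learn_increment}")
        if p.learn_ceiling_margin <= 0.0:
            v.append(f"learn_ceiling_margin must be > 0, got {p.learn_ceiling_margin}")
        return v

    @property
    def rest_ceiling(self) -> float:
        """Upper cap on resting levels reachable through learning."""
        return self.theta_exc - self.learn_ceiling_margin

    def rest(self, voice: str) -> float:
        return self.rest_active if voice == "active" else self.rest_passive

    def plan_base(self, structure: str) -> float:
        return (
            self.plan_base_active_ms
            if structure == "active"
            else self.plan_base_passive_ms
        )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)


def _coerce(mapping: dict[str, Any]) -> ModelParams:
    field_names = [f.name for f in dataclasses.fields(ModelParams)]
    unknown = set(mapping) - set(field_names)
    missing = set(field_names) - set(mapping)
    problems = []
    if unknown:
        problems.append(f"unknown field(s): {sorted(unknown)}")
    if missing:
        problems.append(f"missing field(s): {sorted(missing)}")
    if problems:
        raise ParamError("bad parameter mapping: " + "; ".join(problems))
    coerced: dict[str, Any] = {}
    for name in field_names:
        raw = mapping[name]
        if isinstance(raw, bool) or not isinstance(raw, (int, float)):
            raise ParamError(f"field {name} must be a number, got {raw!r}")
        if name in _INT_FIELDS:
            if int(raw) != raw:
                raise ParamError(f"field {name} must be an integer, got {raw!r}")
            coerced[name] = int(raw)
        else:
            coerced[name] = float(raw)
    return ModelParams(**coerced)


def load_params(path: str | Path) -> ModelParams:
    """Load and validate a parameter file (flat YAML or JSON mapping).

    Every violated invariant is listed in the raised :class:`ParamError`.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ParamError(f"cannot read parameter file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)  # JSON is a YAML subset
    except yaml.YAMLError as exc:
        raise ParamError(f"cannot parse parameter file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ParamError(f"parameter file {path} must contain a flat mapping")
    return _coerce(data)


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write a parameter file; .json extension selects JSON, otherwise YAML."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def default_params(experiment: str = "exp1") -> ModelParams:
    """Load the shipped default calibration for an experiment.

    ``experiment`` may be ``exp1``, ``exp2``, ``exp2_control`` or
    ``exp2_experimental`` (the two groups share one calibration file).
    """
    key = "exp2" if experiment.startswith("exp2") else "exp1"
    ref = resources.files("primevoice.data") / f"defaults_{key}.yaml"
    with resources.as_file(ref) as path:
        return load_params(path)
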