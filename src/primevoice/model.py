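"""Activation-competition dynamics of transitive-voice selection.

Grammatical encoding of a transitive event runs in two sequential stages.
In the *selection* stage an Active Voice node and a Passive Voice node (one
pair per verb) race toward a selection threshold: each cycle a node decays
toward its resting level, receives feedforward drive, receives inhibition
from its competitor (once that competitor is above the excitation
threshold), and is perturbed by Gaussian noise.  The first node to reach
the selection threshold fires and its construction is produced.  In the
*planning* stage the selected construction is prepared for articulation;
practice (producing the same structure on the preceding trial) and full
lexical repetition shorten planning.  Response latency is the additive sum
of the selection time (cycles mapped linearly to ms), the planning time and
a fixed articulatory intercept.

Production also feeds back on the network: each forced production nudges
the produced structure's resting level upward (capped below the excitation
threshold), which is how a training block of 90% passives durably shifts
the preference bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .params import ModelParams, ParamError

__all__ = [
    "ACTIVE",
    "PASSIVE",
    "VoiceNodeState",
    "SelectionOutcome",
    "squash",
    "emitted_signal",
    "update_activation",
    "run_selection",
    "settle",
    "settle_array",
    "planning_time",
    "apply_learning",
]

ACTIVE = "active"
PASSIVE = "passive"
VOICES = (ACTIVE, PASSIVE)


@dataclass
class VoiceNodeState:
    """Current activation and resting level of one voice node of one verb."""

    verb_id: str
    voice: str
    activation: float
    rest: float

    def dormant(self, theta_exc: float) -> bool:
        """Dormant nodes (below the excitation threshold) emit nothing."""
        return self.activation < theta_exc


@dataclass
class SelectionOutcome:
    """Result of one selection-stage competition.

    The trajectory holds one ``(cycle, activation_active,
    activation_passive)`` triple per cycle, including cycle 0 (the state at
    competition onset).
    """

    winner: str
    n_cycles: int
    trajectory: list[tuple[int, float, float]]
    timed_out: bool

    def trajectory_array(self) -> np.ndarray:
        return np.asarray(self.trajectory, dtype=float)


def squash(x: float) -> float:
    """Clip an activation to the admissible band [0, 1].

    Keeps every updated activation between the lower and upper bounds; hard
    clipping is used so the zero-noise dynamics stay piecewise linear and
    exactly reproducible.  Idempotent.  Non-finite input signals corrupted
    dynamics and raises.
    """
    if not math.isfinite(x):
        raise ValueError(f"non-finite activation {x!r}: corrupted dynamics")
    return min(1.0, max(0.0, x))


def emitted_signal(sender_activation: float, weight: float, theta_exc: float) -> float:
    """Signal a node transmits to a neighbour: 0 while dormant, else weight x activation.

    The transfer function is linear in the sender's activation and gated by
    the excitation threshold (a node at exactly ``theta_exc`` does emit).
    """
    if weight < 0.0:
        raise ParamError(f"negative transmission weight {weight}")
    if sender_activation < theta_exc:
        return 0.0
    return weight * sender_activation


def update_activation(
    node: VoiceNodeState,
    excit_in: float,
    inhib_in: float,
    noise_draw: float,
    params: ModelParams,
) -> float:
    """One-cycle activation update for a single node.

    The excursion from the resting level decays by the factor ``decay``;
    incoming excitation is added, inhibition subtracted, noise added, and
    the result squashed to [0, 1].  With no input and no noise the fixed
    point is the resting level.
    """
    pre = (
        node.rest
        + params.decay * (node.activation - node.rest)
        + excit_in
        - inhib_in
        + noise_draw
    )
    return squash(pre)


def _pick_winner(a_act: float, a_pas: float, rng: np.random.Generator) -> str:
    if a_act > a_pas:
        return ACTIVE
    if a_pas > a_act:
        return PASSIVE
    return ACTIVE if rng.integers(2) == 0 else PASSIVE


def run_selection(
    active_node: VoiceNodeState,
    passive_node: VoiceNodeState,
    drive: tuple[float, float],
    params: ModelParams,
    rng: np.random.Generator,
) -> SelectionOutcome:
    """Race the two voice nodes of one verb until one fires.

    ``drive`` is the per-cycle feedforward input ``(to_active, to_passive)``:
    equal drive on free-choice targets, drive to the cued node only on
    color-coded primes.  Each cycle both nodes are updated simultaneously
    from the previous cycle's state, each receiving the other's inhibition.
    The first node at or above ``theta_sel`` wins; if both cross on the same
    cycle the higher one wins (an exact tie is broken by a uniform draw).
    On timeout the currently higher node is declared winner and the outcome
    flagged, never raised.  Node states are updated in place so that
    residual activation persists after firing.
    """
    if params.max_cycles <= 0:
        raise ParamError(f"max_cycles must be > 0, got {params.max_cycles}")
    if active_node.verb_id != passive_node.verb_id:
        raise ValueError("selection competitors must belong to the same verb")
    drive_a, drive_p = drive
    if drive_a < 0.0 or drive_p < 0.0:
        raise ParamError("per-cycle drive must be nonnegative")

    a_act = active_node.activation
    a_pas = passive_node.activation
    trajectory: list[tuple[int, float, float]] = [(0, a_act, a_pas)]

    if a_act >= params.theta_sel or a_pas >= params.theta_sel:
        winner = _pick_winner(
            a_act if a_act >= params.theta_sel else -math.inf,
            a_pas if a_pas >= params.theta_sel else -math.inf,
            rng,
        )
        return SelectionOutcome(winner, 0, trajectory, False)

    timed_out = False
    t = 0
    while True:
        t += 1
        inhib_to_active = emitted_signal(a_pas, params.w_inhib, params.theta_exc)
        inhib_to_passive = emitted_signal(a_act, params.w_inhib, params.theta_exc)
        noise_a = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
        noise_p = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
        a_act = squash(
            active_node.rest
            + params.decay * (a_act - active_node.rest)
            + drive_a
            - inhib_to_active
            + noise_a
        )
        a_pas = squash(
            passive_node.rest
            + params.decay * (a_pas - passive_node.rest)
            + drive_p
            - inhib_to_passive
            + noise_p
        )
        trajectory.append((t, a_act, a_pas))
        if a_act >= params.theta_sel or a_pas >= params.theta_sel:
            winner = _pick_winner(
                a_act if a_act >= params.theta_sel else -math.inf,
                a_pas if a_pas >= params.theta_sel else -math.inf,
                rng,
            )
            break
        if t >= params.max_cycles:
            timed_out = True
            winner = _pick_winner(a_act, a_pas, rng)
            break

    active_node.activation = a_act
    passive_node.activation = a_pas
    return SelectionOutcome(winner, t, trajectory, timed_out)


def settle_array(
    activations: np.ndarray,
    rests: np.ndarray,
    n_cycles: int,
    params: ModelParams,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Drive-free decay of an array of activations toward their resting levels.

    Vectorized core of :func:`settle`: each cycle the excursion from rest
    shrinks by ``decay``, per-node Gaussian noise is added (when
    ``noise_sd > 0`` and an rng is supplied) and the result is clipped to
    [0, 1].  No node interacts with any other during settling.
    """
    if n_cycles < 0:
        raise ValueError(f"n_cycles must be >= 0, got {n_cycles}")
    act = np.asarray(activations, dtype=float).copy()
    rests = np.broadcast_to(np.asarray(rests, dtype=float), act.shape)
    for _ in range(n_cycles):
        act = rests + params.decay * (act - rests)
        if params.noise_sd > 0 and rng is not None:
            act = act + rng.normal(0.0, params.noise_sd, size=act.shape)
        np.clip(act, 0.0, 1.0, out=act)
    return act


def settle(
    nodes: Iterable[VoiceNodeState],
    n_cycles: int,
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> None:
    """Let nodes decay toward rest for ``n_cycles`` drive-free cycles (in place).

    With ``noise_sd = 0`` each node's excursion from rest shrinks
    geometrically at rate ``decay`` and never crosses its resting level.
    """
    node_list = list(nodes)
    if not node_list:
        return
    act = np.array([n.activation for n in node_list])
    rest = np.array([n.rest for n in node_list])
    act = settle_array(act, rest, n_cycles, params, rng)
    for node, a in zip(node_list, act):
        node.activation = float(a)


def planning_time(
    structure: str,
    prev_structure: str | None,
    word_repetition: str,
    params: ModelParams,
) -> float:
    """Planning-stage duration in ms for the selected structure.

    The structure's baseline planning time is reduced proportionally by
    practice when the same structure was produced on the preceding trial,
    and further by full lexical repetition (verb and nouns).  Verb-only
    repetition leaves planning unchanged.
    """
    if structure not in VOICES:
        raise ValueError(f"unknown structure {structure!r}")
    if prev_structure not in (ACTIVE, PASSIVE, None, "none"):
        raise ValueError(f"unknown prev_structure {prev_structure!r}")
    if word_repetition not in ("none", "verb", "full"):
        raise ValueError(f"unknown word_repetition {word_repetition!r}")
    t = params.plan_base(structure)
    if prev_structure == structure:
        t *= 1.0 - params.practice_reduction
    if word_repetition == "full":
        t *= 1.0 - params.lexical_plan_reduction
    return t


def apply_learning(rest: float, params: ModelParams) -> float:
    """Increment a resting level after a production, capped below theta_exc.

    Monotone nondecreasing in ``rest``; a level already at or above the cap
    is left unchanged.
    """
    return max(rest, min(rest + params.learn_increment, params.rest_ceiling))
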