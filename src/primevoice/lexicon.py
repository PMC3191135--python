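"""Lexicalized voice network: one Active/Passive node pair per verb.

The grammar is lexicalized: every transitive verb owns an Active Voice node
and a Passive Voice node.  Within a verb the two nodes inhibit each other
during selection; across verbs a node that has just fired passes a one-shot
excitatory boost to the same-voice nodes of every other verb (weight
``w_cross``), which is weaker than the residual activation left on the
fired verb's own node — the mechanism behind the lexical boost of
syntactic priming.  Resting levels are structure-level: all active nodes
share ``rest_active`` and all passive nodes share ``rest_passive``, and
learning shifts them globally.

Activations are stored in a dense ``(n_verbs, 2)`` array (column 0 active,
column 1 passive) so whole-lexicon settling is vectorized; node views are
materialized as :class:`~primevoice.model.VoiceNodeState` on demand.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .model import ACTIVE, PASSIVE, VoiceNodeState, apply_learning, settle_array
from .params import ModelParams

__all__ = ["Lexicon", "build_lexicon", "spread_residual"]

_COL = {ACTIVE: 0, PASSIVE: 1}


class Lexicon:
    """Dense store of per-verb voice-node activations plus shared resting levels."""

    def __init__(self, verb_ids: Sequence[str], params: ModelParams):
        verb_ids = list(verb_ids)
        if not verb_ids:
            raise ValueError("lexicon needs at least one verb")
        if len(set(verb_ids)) != len(verb_ids):
            raise ValueError("duplicate verb ids in lexicon")
        self.verbs: list[str] = verb_ids
        self._index = {v: i for i, v in enumerate(verb_ids)}
        # Structure-level resting levels, shared by every verb and shifted
        # globally by learning.
        self.rest = np.array([params.rest_active, params.rest_passive])
        self.activations = np.tile(self.rest, (len(verb_ids), 1))

    # -- node access ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return 2 * len(self.verbs)

    def __contains__(self, verb_id: str) -> bool:
        return verb_id in self._index

    def node(self, verb_id: str, voice: str) -> VoiceNodeState:
        i = self._index[verb_id]
        c = _COL[voice]
        return VoiceNodeState(
            verb_id=verb_id,
            voice=voice,
            activation=float(self.activations[i, c]),
            rest=float(self.rest[c]),
        )

    def pair(self, verb_id: str) -> tuple[VoiceNodeState, VoiceNodeState]:
        """The (active, passive) node pair of one verb, as mutable views."""
        return self.node(verb_id, ACTIVE), self.node(verb_id, PASSIVE)

    def write_back(self, *nodes: VoiceNodeState) -> None:
        """Store mutated node states back into the dense array."""
        for n in nodes:
            self.activations[self._index[n.verb_id], _COL[n.voice]] = n.activation

    # -- whole-network events -------------------------------------------

    def learn(self, structure: str, params: ModelParams) -> None:
        """Shift the produced structure's resting level globally (capped)."""
        c = _COL[structure]
        self.rest[c] = apply_learning(float(self.rest[c]), params)

    def settle_all(
        self, n_cycles: int, params: ModelParams, rng: np.random.Generator | None
    ) -> None:
        """Drive-free decay of every node toward its resting level."""
        self.activations = settle_array(
            self.activations, self.rest, n_cycles, params, rng
        )

    def snapshot(self) -> pd.DataFrame:
        """Lexicon state as a tidy frame: verb_id, voice, activation, rest."""
        rows = []
        for voice, c in _COL.items():
            for verb, i in self._index.items():
                rows.append(
                    {
                        "verb_id": verb,
                        "voice": voice,
                        "activation": float(self.activations[i, c]),
                        "rest": float(self.rest[c]),
                    }
                )
        return pd.DataFrame(rows).sort_values(["verb_id", "voice"]).reset_index(drop=True)


def build_lexicon(verb_ids: Sequence[str], params: ModelParams) -> Lexicon:
    """Create a lexicon with every node initialized at its resting level."""
    return Lexicon(verb_ids, params)


def spread_residual(
    lexicon: Lexicon, fired: tuple[str, str], params: ModelParams
) -> Lexicon:
    """One-shot cross-verb spread after a node fires.

    Every same-voice node of every *other* verb receives excitation
    ``w_cross x fired_activation`` (then squashed); the fired verb's own
    nodes and all opposite-voice nodes are untouched.  Applied once per
    prime production, not per cycle.
    """
    verb, voice = fired
    if verb not in lexicon:
        raise KeyError(f"verb {verb!r} not in lexicon")
    i = lexicon._index[verb]
    c = _COL[voice]
    boost = params.w_cross * float(lexicon.activations[i, c])
    col = lexicon.activations[:, c]
    own = col[i]
    np.clip(col + boost, 0.0, 1.0, out=col)
    col[i] = own
    return lexicon
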