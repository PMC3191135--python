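"""Virtual picture-description experiments: design, simulation, summaries.

Regenerates the two experiments' trial lists, runs virtual participants
through them with the competition model, applies the response coding and
latency-trimming rules, and summarizes response tendencies (proportion of
passives per condition) and response latencies (means and standard errors
per target structure x syntactic repetition).

Experiment 1: 30 participants, per list 72 baseline trials plus 24 trials
in each of 4 transitive priming conditions (active/passive prime x full
word repetition or none), with filler trials added so that half of all
pictures elicit transitives.

Experiment 2: a 100-picture training block (90/10 or 10/90
active/passive, drawn from 10 dedicated training verbs) followed by a main
phase of 48 baseline trials plus 24 trials in each of 4 priming conditions
(active/passive x verb repetition or none) and fillers, 480 pictures in
all, half transitive-eliciting; 30 participants per group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lexicon import Lexicon, build_lexicon, spread_residual
from .model import (
    ACTIVE,
    PASSIVE,
    VOICES,
    planning_time,
    run_selection,
)
from .params import ModelParams

__all__ = [
    "EXP1",
    "EXP2_CONTROL",
    "EXP2_EXPERIMENTAL",
    "EXPERIMENTS",
    "TrialSpec",
    "Design",
    "TrialResult",
    "SummaryTable",
    "PatternReport",
    "generate_design",
    "simulate_trial",
    "run_virtual_experiment",
    "code_syntactic_repetition",
    "trim_outliers",
    "summarize",
    "check_patterns",
    "results_to_frame",
]

EXP1 = "exp1"
EXP2_CONTROL = "exp2_control"
EXP2_EXPERIMENTAL = "exp2_experimental"
EXPERIMENTS = (EXP1, EXP2_CONTROL, EXP2_EXPERIMENTAL)

FORCED_ACTIVE = "forced_active"
FORCED_PASSIVE = "forced_passive"
FILLER_INTRANSITIVE = "filler_intransitive"
FILLER_LOCATIVE = "filler_locative"
FREE_TRANSITIVE = "free_transitive"

#: The ten dedicated training verbs of the Experiment-2 pre-session.
TRAINING_VERBS = (
    "pelt", "kiss", "make_up", "punish", "transport",
    "scare", "embrace", "drag", "draw", "strangle",
)
EXP1_VERBS = tuple(f"verb{i:02d}" for i in range(1, 37))  # 36 depicted events
EXP2_MAIN_VERBS = tuple(f"verb{i:02d}" for i in range(1, 32))  # 31 main verbs

# Per-list target-item block patterns.  Each entry is (prime category,
# repetition level); "B" marks a baseline item.  Block patterns repeat to
# exact per-list counts: Exp1 24 blocks x 7 items -> 72 baseline + 4 x 24
# priming; Exp2 24 blocks x 6 items -> 48 baseline + 4 x 24 priming.
# Across the three counterbalanced lists of a triplet the pattern is
# rotated so an item's prime category changes list by list.
_EXP1_BLOCK = (
    ("B", "none"),
    (ACTIVE, "none"),
    (PASSIVE, "none"),
    ("B", "none"),
    (ACTIVE, "full"),
    (PASSIVE, "full"),
    ("B", "none"),
)
_EXP2_BLOCK = (
    ("B", "none"),
    (ACTIVE, "none"),
    (PASSIVE, "none"),
    ("B", "none"),
    (ACTIVE, "verb"),
    (PASSIVE, "verb"),
)
_N_FILLER_TRIALS = 96  # both experiments: brings transitives to half of pictures


@dataclass(frozen=True)
class TrialSpec:
    """One trial: a prime picture followed by a target picture.

    Training trials consist of a single color-coded picture; filler trials
    pair two non-transitive pictures (so every main-phase trial spans two
    pictures).
    """

    trial_index: int
    phase: str  # training | main
    trial_type: str  # baseline | priming | filler | training
    prime_elicitation: str
    target_elicitation: str  # free_transitive | none
    prime_verb: str | None
    target_verb: str | None
    word_repetition: str  # none | verb | full

    @property
    def n_pictures(self) -> int:
        return 1 if self.phase == "training" else 2

    @property
    def condition(self) -> str:
        if self.trial_type == "baseline":
            return "baseline"
        if self.trial_type == "priming":
            prime = ACTIVE if self.prime_elicitation == FORCED_ACTIVE else PASSIVE
            return f"{prime}_{self.word_repetition}"
        return self.trial_type


@dataclass
class Design:
    """Per-participant trial lists for one experiment (or one group)."""

    experiment: str
    participants: int
    seed: int
    verbs: tuple[str, ...]
    per_participant: list[list[TrialSpec]]

    def main_trials(self, participant: int) -> list[TrialSpec]:
        return [t for t in self.per_participant[participant] if t.phase == "main"]

    def pictures_per_list(self, phase: str = "main") -> int:
        counts = {
            sum(t.n_pictures for t in trials if t.phase == phase)
            for trials in self.per_participant
        }
        if len(counts) != 1:
            raise AssertionError("unbalanced lists")
        return counts.pop()

    def n_target_trials(self) -> int:
        return sum(
            1
            for trials in self.per_participant
            for t in trials
            if t.target_elicitation == FREE_TRANSITIVE
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, trials in enumerate(self.per_participant):
            for t in trials:
                rows.append(
                    {
                        "participant": p,
                        "trial_index": t.trial_index,
                        "phase": t.phase,
                        "trial_type": t.trial_type,
                        "condition": t.condition,
                        "prime_elicitation": t.prime_elicitation,
                        "target_elicitation": t.target_elicitation,
                        "prime_verb": t.prime_verb,
                        "target_verb": t.target_verb,
                        "word_repetition": t.word_repetition,
                    }
                )
        return pd.DataFrame(rows)


def _target_items(
    block: Sequence[tuple[str, str]],
    n_blocks: int,
    verbs: Sequence[str],
    list_id: int,
    prime_verb_offset: int,
) -> list[TrialSpec]:
    """Build the free-transitive target trials of one counterbalanced list."""
    items: list[TrialSpec] = []
    size = len(block)
    for i in range(n_blocks * size):
        cat, rep = block[(i + list_id) % size]
        verb = verbs[i % len(verbs)]
        if cat == "B":
            prime = FILLER_INTRANSITIVE if i % 2 == 0 else FILLER_LOCATIVE
            items.append(
                TrialSpec(-1, "main", "baseline", prime, FREE_TRANSITIVE,
                          None, verb, "none")
            )
        else:
            prime_verb = (
                verb if rep != "none" else verbs[(i + prime_verb_offset) % len(verbs)]
            )
            elic = FORCED_ACTIVE if cat == ACTIVE else FORCED_PASSIVE
            items.append(
                TrialSpec(-1, "main", "priming", elic, FREE_TRANSITIVE,
                          prime_verb, verb, rep)
            )
    return items


def _filler_trials(n: int) -> list[TrialSpec]:
    return [
        TrialSpec(
            -1, "main", "filler",
            FILLER_INTRANSITIVE if i % 2 == 0 else FILLER_LOCATIVE,
            "none", None, None, "none",
        )
        for i in range(n)
    ]


def _training_block(group: str, rng: np.random.Generator) -> list[TrialSpec]:
    """100 forced transitive pictures: 10 per training verb, 90/10 voice mix."""
    n_passive = 90 if group == EXP2_EXPERIMENTAL else 10
    elicitations = [FORCED_PASSIVE] * n_passive + [FORCED_ACTIVE] * (100 - n_passive)
    verbs = [v for v in TRAINING_VERBS for _ in range(10)]
    rng.shuffle(elicitations)
    rng.shuffle(verbs)
    return [
        TrialSpec(-1, "training", "training", e, "none", v, None, "none")
        for e, v in zip(elicitations, verbs)
    ]


def generate_design(experiment: str, n_participants: int, seed: int) -> Design:
    """Generate counterbalanced, seeded trial lists for one experiment.

    Participants rotate over a triplet of counterbalanced lists
    (``participant % 3``); main-phase trial order is fully randomized per
    participant, the training block (Experiment 2) precedes the main phase.
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    if n_participants <= 0:
        raise ValueError("n_participants must be > 0")

    if experiment == EXP1:
        verbs: tuple[str, ...] = EXP1_VERBS
        block, n_blocks, offset = _EXP1_BLOCK, 24, 7
    else:
        verbs = EXP2_MAIN_VERBS + TRAINING_VERBS
        block, n_blocks, offset = _EXP2_BLOCK, 24, 5

    per_participant: list[list[TrialSpec]] = []
    for p in range(n_participants):
        rng = np.random.default_rng([seed, p])
        main = _target_items(
            block, n_blocks, verbs[: len(verbs) - 10] if experiment != EXP1 else verbs,
            list_id=p % 3, prime_verb_offset=offset,
        )
        main += _filler_trials(_N_FILLER_TRIALS)
        order = rng.permutation(len(main))
        trials: list[TrialSpec] = []
        if experiment != EXP1:
            trials.extend(_training_block(experiment, rng))
        trials.extend(main[i] for i in order)
        trials = [replace(t, trial_index=i) for i, t in enumerate(trials)]
        per_participant.append(trials)
    return Design(experiment, n_participants, seed, verbs, per_participant)


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------

@dataclass
class TrialResult:
    """One simulated overt production (free target or training picture)."""

    participant: int
    trial_index: int
    phase: str
    condition: str
    prime_structure: str | None
    response: str
    word_repetition: str
    syntactic_repetition: bool | None
    selection_cycles: int
    planning_ms: float
    latency_ms: float
    timed_out: bool
    excluded: bool = False


def _forced_production(
    verb: str, cued: str, lexicon: Lexicon, params: ModelParams,
    rng: np.random.Generator,
):
    """Run a color-coded (forced) production: drive on the cued node only."""
    a_node, p_node = lexicon.pair(verb)
    drive = (
        (params.input_drive, 0.0) if cued == ACTIVE else (0.0, params.input_drive)
    )
    out = run_selection(a_node, p_node, drive, params, rng)
    lexicon.write_back(a_node, p_node)
    lexicon.learn(cued, params)
    spread_residual(lexicon, (verb, cued), params)
    return out


def simulate_trial(
    tspec: TrialSpec,
    lexicon: Lexicon,
    params: ModelParams,
    rng: np.random.Generator,
    prev_structure: str | None = None,
) -> TrialResult | None:
    """Simulate one trial, mutating the lexicon in place.

    Timeline: the prime picture event (forced selection + learning +
    cross-verb spread, for transitive primes), a drive-free settling
    interval, the target picture event (free selection) where present, and
    a final settling interval.  Response latency is the exact additive sum
    ``intercept + ms_per_cycle x selection_cycles + planning_ms``.

    ``prev_structure`` is the structure produced on the *preceding* trial
    and only feeds the practice effect of training-trial planning; for main
    targets the preceding production is this trial's own prime (baseline
    primes are intransitive, hence no practice).
    """
    prime_struct: str | None = None
    prime_out = None
    if tspec.prime_elicitation in (FORCED_ACTIVE, FORCED_PASSIVE):
        prime_struct = ACTIVE if tspec.prime_elicitation == FORCED_ACTIVE else PASSIVE
        prime_out = _forced_production(
            tspec.prime_verb, prime_struct, lexicon, params, rng
        )
    lexicon.settle_all(params.settle_cycles, params, rng)

    if tspec.phase == "training":
        plan = planning_time(prime_struct, prev_structure, "none", params)
        latency = (
            params.latency_intercept_ms
            + params.ms_per_cycle * prime_out.n_cycles
            + plan
        )
        return TrialResult(
            participant=-1, trial_index=tspec.trial_index, phase="training",
            condition="training", prime_structure=prime_struct,
            response=prime_struct, word_repetition="none",
            syntactic_repetition=None, selection_cycles=prime_out.n_cycles,
            planning_ms=plan, latency_ms=latency, timed_out=prime_out.timed_out,
        )

    if tspec.target_elicitation != FREE_TRANSITIVE:
        # filler trial: second picture is another non-transitive event
        lexicon.settle_all(params.settle_cycles, params, rng)
        return None

    a_node, p_node = lexicon.pair(tspec.target_verb)
    out = run_selection(
        a_node, p_node, (params.input_drive, params.input_drive), params, rng
    )
    lexicon.write_back(a_node, p_node)
    response = out.winner
    word_rep = tspec.word_repetition if tspec.trial_type == "priming" else "none"
    plan = planning_time(response, prime_struct, word_rep, params)
    latency = params.latency_intercept_ms + params.ms_per_cycle * out.n_cycles + plan
    synrep = (
        code_syntactic_repetition(prime_struct, response)
        if tspec.trial_type == "priming"
        else None
    )
    lexicon.settle_all(params.settle_cycles, params, rng)
    return TrialResult(
        participant=-1, trial_index=tspec.trial_index, phase="main",
        condition=tspec.condition, prime_structure=prime_struct,
        response=response, word_repetition=word_rep,
        syntactic_repetition=synrep, selection_cycles=out.n_cycles,
        planning_ms=plan, latency_ms=latency, timed_out=out.timed_out,
    )


def run_virtual_experiment(
    design: Design, params: ModelParams, master_seed: int
) -> list[TrialResult]:
    """Run every virtual participant through a design.

    Each participant gets a fresh lexicon at the shipped resting levels and
    an independent RNG stream (``master_seed + participant``), so the run
    is deterministic given (design, params, master_seed).
    """
    results: list[TrialResult] = []
    for p, trials in enumerate(design.per_participant):
        rng = np.random.default_rng(master_seed + p)
        lexicon = build_lexicon(design.verbs, params)
        prev_structure: str | None = None
        for tspec in trials:
            res = simulate_trial(tspec, lexicon, params, rng, prev_structure)
            if res is None:
                prev_structure = None
                continue
            res.participant = p
            results.append(res)
            prev_structure = res.response
    return results


# ---------------------------------------------------------------------------
# Coding, trimming, summarizing
# ---------------------------------------------------------------------------

def code_syntactic_repetition(prime_structure: str, response: str) -> bool:
    """Post-hoc syntactic-repetition coding: prime and response share a structure."""
    if prime_structure not in VOICES:
        raise ValueError(
            "syntactic repetition is defined on priming trials only "
            f"(got prime_structure={prime_structure!r})"
        )
    if response not in VOICES:
        raise ValueError(f"unknown response {response!r}")
    return prime_structure == response


def trim_outliers(results: list[TrialResult]) -> list[TrialResult]:
    """Flag latency outliers: beyond 2 SD from the per-subject, per-condition mean.

    A single pass per (participant x condition) cell of main-phase trials;
    SD uses the n-1 denominator; values strictly outside mean +/- 2 SD are
    marked excluded.  Cells with fewer than two trials exclude nothing.
    The list order is preserved and flags are set in place.
    """
    cells: dict[tuple[int, str], list[TrialResult]] = {}
    for r in results:
        if r.phase != "main":
            continue
        cells.setdefault((r.participant, r.condition), []).append(r)
    for members in cells.values():
        if len(members) < 2:
            continue
        lat = np.array([m.latency_ms for m in members])
        mean = lat.mean()
        sd = lat.std(ddof=1)
        lo, hi = mean - 2.0 * sd, mean + 2.0 * sd
        for m in members:
            m.excluded = bool(m.latency_ms < lo or m.latency_ms > hi)
    return results


def results_to_frame(results: Iterable[TrialResult]) -> pd.DataFrame:
    """Trial log as a tidy frame (one row per overt production)."""
    return pd.DataFrame(
        {
            "participant": r.participant,
            "trial_index": r.trial_index,
            "phase": r.phase,
            "condition": r.condition,
            "prime_structure": r.prime_structure,
            "response": r.response,
            "word_repetition": r.word_repetition,
            "syntactic_repetition": r.syntactic_repetition,
            "selection_cycles": r.selection_cycles,
            "planning_ms": r.planning_ms,
            "latency_ms": r.latency_ms,
            "timed_out": r.timed_out,
            "excluded": r.excluded,
        }
        for r in results
    )


def _expected_conditions(experiment: str) -> list[str]:
    rep = "full" if experiment == EXP1 else "verb"
    return [
        "baseline",
        f"{ACTIVE}_none", f"{ACTIVE}_{rep}",
        f"{PASSIVE}_none", f"{PASSIVE}_{rep}",
    ]


@dataclass
class SummaryTable:
    """Per-condition response tendencies and latency cells for one run."""

    experiment: str
    tendencies: pd.DataFrame
    latencies: pd.DataFrame
    latencies_by_word_repetition: pd.DataFrame

    def passive_rate(self, condition: str) -> float:
        row = self.tendencies.loc[self.tendencies["condition"] == condition]
        if row.empty:
            return float("nan")
        return float(row["p_passive"].iloc[0])

    def baseline_passive_rate(self) -> float:
        return self.passive_rate("baseline")

    def pooled_passive_rate(self, prime: str) -> float:
        """Passive rate pooled over both repetition levels of one prime type."""
        rows = self.tendencies[
            self.tendencies["condition"].str.startswith(f"{prime}_")
        ]
        n = rows["n"].sum()
        return float(rows["n_passive"].sum() / n) if n else float("nan")

    def latency(self, structure: str, syntactic_repetition: bool) -> float:
        rows = self.latencies[
            (self.latencies["target_structure"] == structure)
            & (self.latencies["syntactic_repetition"] == syntactic_repetition)
        ]
        if rows.empty or rows["n"].iloc[0] == 0:
            return float("nan")
        return float(rows["mean_ms"].iloc[0])


def summarize(
    results: list[TrialResult],
    experiment: str,
    by_participant: bool = False,
) -> SummaryTable:
    """Summarize a trial log: tendencies per condition, latencies per cell.

    Tendencies and latencies are computed over non-excluded main-phase
    responses; latency cells cross the target structure with the post-hoc
    syntactic-repetition variable (priming trials only).  Standard errors
    are SD/sqrt(n) over trials, or over participant means when
    ``by_participant`` is set.  Empty cells are reported with ``n = 0`` and
    missing statistics, never as zero.
    """
    if not results:
        raise ValueError("no results to summarize")
    df = results_to_frame(results)
    main = df[(df["phase"] == "main") & (~df["excluded"])]

    tend_rows = []
    for cond in _expected_conditions(experiment):
        sub = main[main["condition"] == cond]
        n = len(sub)
        n_pass = int((sub["response"] == PASSIVE).sum())
        tend_rows.append(
            {
                "condition": cond,
                "n": n,
                "n_passive": n_pass,
                "p_passive": (n_pass / n) if n else float("nan"),
            }
        )
    tendencies = pd.DataFrame(tend_rows)

    prim = main[main["condition"] != "baseline"]

    def _lat_cells(group_cols: list[str]) -> pd.DataFrame:
        rows = []
        combos: Iterable[tuple] = itertools.product(
            VOICES,
            (True, False),
            *(
                [sorted(prim["word_repetition"].unique())]
                if "word_repetition" in group_cols
                else []
            ),
        )
        for combo in combos:
            structure, synrep = combo[0], combo[1]
            sub = prim[
                (prim["response"] == structure)
                & (prim["syntactic_repetition"] == synrep)
            ]
            row = {"target_structure": structure, "syntactic_repetition": synrep}
            if "word_repetition" in group_cols:
                sub = sub[sub["word_repetition"] == combo[2]]
                row["word_repetition"] = combo[2]
            if by_participant:
                means = sub.groupby("participant")["latency_ms"].mean()
                n = len(means)
                mean = means.mean() if n else float("nan")
                se = means.std(ddof=1) / np.sqrt(n) if n > 1 else float("nan")
            else:
                n = len(sub)
                mean = sub["latency_ms"].mean() if n else float("nan")
                se = (
                    sub["latency_ms"].std(ddof=1) / np.sqrt(n)
                    if n > 1
                    else float("nan")
                )
            row.update({"n": n, "mean_ms": mean, "se_ms": se})
            rows.append(row)
        return pd.DataFrame(rows)

    return SummaryTable(
        experiment=experiment,
        tendencies=tendencies,
        latencies=_lat_cells([]),
        latencies_by_word_repetition=_lat_cells(["word_repetition"]),
    )


# ---------------------------------------------------------------------------
# Pattern checks
# ---------------------------------------------------------------------------

@dataclass
class PatternReport:
    """Named qualitative checks against the observed priming signature.

    ``None`` marks a check that could not be evaluated (missing cells or,
    for the group contrast p5, a missing control summary).
    """

    experiment: str
    checks: dict[str, bool | None]
    values: dict[str, float] = field(default_factory=dict)

    def all_true(self, keys: Iterable[str] | None = None) -> bool:
        keys = list(keys) if keys is not None else list(self.checks)
        return all(self.checks.get(k) is True for k in keys)

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "checks": dict(self.checks),
            "values": dict(self.values),
        }


def _strict(a: float, b: float, op: str) -> bool | None:
    if np.isnan(a) or np.isnan(b):
        return None
    return bool(a < b) if op == "<" else bool(a >= b)


def check_patterns(
    summary: SummaryTable,
    experiment: str,
    control_summary: SummaryTable | None = None,
) -> PatternReport:
    """Evaluate the qualitative priming signature on a run summary.

    p1: passive primes raise the passive rate above baseline.
    p2: the passive tendency effect exceeds the active tendency effect
        (inverse preference).
    p3: syntactically repeated actives are produced faster.
    p4: syntactically repeated passives are *not* faster (Exp1 and the
        Exp2 control group) / *are* faster (Exp2 experimental group).
    p5 (Exp2 experimental only): the baseline passive rate exceeds the
        control group's (requires ``control_summary``).
    """
    pb = summary.baseline_passive_rate()
    pp = summary.pooled_passive_rate(PASSIVE)
    pa = summary.pooled_passive_rate(ACTIVE)
    lat_a_rep = summary.latency(ACTIVE, True)
    lat_a_no = summary.latency(ACTIVE, False)
    lat_p_rep = summary.latency(PASSIVE, True)
    lat_p_no = summary.latency(PASSIVE, False)

    checks: dict[str, bool | None] = {}
    values: dict[str, float] = {
        "baseline_passive_rate": pb,
        "passive_prime_passive_rate": pp,
        "active_prime_passive_rate": pa,
        "latency_active_synrep": lat_a_rep,
        "latency_active_nosynrep": lat_a_no,
        "latency_passive_synrep": lat_p_rep,
        "latency_passive_nosynrep": lat_p_no,
    }

    checks["p1"] = None if np.isnan(pp) or np.isnan(pb) else bool(pp > pb)
    if np.isnan(pp) or np.isnan(pb) or np.isnan(pa):
        checks["p2"] = None
    else:
        # active tendency effect = rise in active rate after active primes
        checks["p2"] = bool((pp - pb) > (pb - pa))
    checks["p3"] = _strict(lat_a_rep, lat_a_no, "<")
    if experiment == EXP2_EXPERIMENTAL:
        checks["p4"] = _strict(lat_p_rep, lat_p_no, "<")
    else:
        checks["p4"] = _strict(lat_p_rep, lat_p_no, ">=")
    if experiment == EXP2_EXPERIMENTAL:
        if control_summary is None:
            checks["p5"] = None
        else:
            cb = control_summary.baseline_passive_rate()
            values["control_baseline_passive_rate"] = cb
            checks["p5"] = None if np.isnan(pb) or np.isnan(cb) else bool(pb > cb)
    return PatternReport(experiment=experiment, checks=checks, values=values)
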