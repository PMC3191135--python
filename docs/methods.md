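# Methods

## Model

Grammatical encoding of a transitive event is modeled as two sequential
stages.  The **selection stage** is a noisy two-alternative competition
between an Active-Voice and a Passive-Voice node belonging to the target
verb; the **planning stage** is a deterministic duration for preparing the
selected structure.  Response latency is the exact additive sum of a fixed
intercept (articulation and voice-key delay), the selection time mapped
linearly from cycles to milliseconds, and the planning time.

### Selection dynamics

Per cycle, each node's activation is updated as

    a' = squash( r + d·(a − r) + excitation − inhibition + noise )

Decay acts on the *excursion from the resting level*: the update the
dynamics literature usually writes as multiplicative decay of activation
would pull nodes to zero, whereas a node that has fired is supposed to
return to its (nonzero) resting level.  Decaying the excursion satisfies
both the geometric-decay intuition and the stated asymptote; with zero
input and zero noise the resting level is an exact fixed point.  This
reading is a design choice, not a forced one, and is isolated in
`update_activation` should anyone want to study the alternative.

Other commitments, each made where the verbal model is silent:

- **Squashing** is hard clipping to [0, 1]; it keeps the zero-noise
  dynamics piecewise linear and exactly reproducible by a straight-line
  oracle (tested to 1e−12).
- **Transfer function**: a node below the excitation threshold θ_exc is
  dormant and emits nothing; at or above it, emitted signal is linear,
  `weight × activation`, with a symmetric within-verb inhibitory weight.
- **Noise** is i.i.d. Gaussian per node per cycle, added before squashing,
  for dormant nodes too — noise is what lets passives win occasionally
  from rest.  Pragmatic and conceptual-emphasis influences are subsumed by
  this noise term.
- **Forced (color-coded) productions** are modeled as feedforward drive to
  the cued node only; the race still runs, so the prime's firing leaves
  genuine residual activation.
- **Tie-breaking**: when both nodes cross θ_sel on one cycle the higher
  wins; an exact tie falls to a uniform draw from the trial RNG.  On
  timeout (`max_cycles`, default 500) the higher node wins and the trial is
  flagged, never raised, so harness summaries cannot deadlock.

### Lexicalized network and priming

One node pair per verb.  After any forced production, three things happen
in order: the produced structure's resting level is raised globally by
`learn_increment` (capped at `theta_exc − learn_ceiling_margin`); the
fired node's residual spreads once to the same-voice nodes of all other
verbs with weight `w_cross` (an event, not a per-cycle link, which keeps
the within-trial dynamics two-node and analyzable); then the whole lexicon
settles (`settle_cycles` of drive-free decay).  Settling is applied after
the prime picture *and* after the target picture, so each picture-to-
picture interval is one settling period; filler trials settle twice.
Cross-verb spread is strictly weaker than the same-verb residual whenever
`w_cross < 1`, which yields the lexical-boost ordering (same-verb ≥
different-verb ≥ baseline priming).

Learning applies to forced productions (training trials and primes).  Free
target productions do not move resting levels, but their own residual
activation persists and settles, giving realistic cross-trial carryover.

### Planning stage

Planning duration is a per-structure baseline (`plan_base_*_ms`),
multiplied by `1 − practice_reduction` when the same structure was
produced on the immediately preceding trial (a binary one-trial practice
window, consistent with latency priming being short-lived), and by
`1 − lexical_plan_reduction` when *all* content words repeat.  Verb-only
repetition leaves planning untouched, mirroring the null effect of verb
repetition on latencies in the data being modeled.

## Virtual experiments

**Experiment 1** (30 participants): per list 72 baseline trials (filler
prime, free-choice transitive target), 24 trials in each of four priming
conditions (active/passive prime × full word repetition or none), and 96
filler trials so that exactly half of the 528 pictures elicit transitives
(168 free targets per list; 5040 across 30 participants).

**Experiment 2** (two groups of 30): a 100-trial training block of forced
transitive pictures — 10 verbs × 10 pictures, disjoint from the 31 main
verbs — at 90/10 (control) or 10/90 (experimental) active/passive, then 48
baseline + 24×4 priming (active/passive × verb repetition) + 96 filler
trials: 480 main-phase pictures, half transitive-eliciting, 144 free
targets per list (8640 across 60).  The 96-filler count is reconstructed
from the two published constraints (480 pictures, half transitive); it is
a derivation, not a published number.

Counterbalancing: participants rotate over a triplet of lists.  Exact
per-list condition counts make a strict three-way rotation of every item
impossible (72 baseline vs 48+48 priming slots), so lists are built from
repeating blocks (Exp 1: `B A P B A P B` with repetition levels
alternating; Exp 2: `B A P B A P`) whose assignment to item slots is
rotated by list; per-list counts are exact for every seed (property-tested
over 50 seeds) and an item's prime category changes across the triplet.
Trial order is fully randomized per participant (the published constraints
do not specify spacing rules); the training block always precedes the main
phase.  Identical-sentence repetition trials are not generated: they were
excluded from the original analyses.

Coding and trimming follow the published procedure: responses are coded
active/passive; the post-hoc *syntactic repetition* variable marks
priming-trial responses that match their prime's structure; latencies are
trimmed once per participant × condition cell at mean ± 2 SD (sample SD,
n−1; cells with fewer than two trials are left alone).  Response errors
are not simulated — every virtual response is well-formed — so the
correctness-based exclusions of the original studies are identity
operations here.  Note that a five-value cell can never lose a trial under
this rule: with n = 5 the largest possible standardized deviation is
(n−1)/√n ≈ 1.79 < 2.

Standard errors in latency summaries are SD/√n over trials within a cell;
aggregation over participant means is available as an option.

## Calibration

The only quantitative anchors available are three baseline preference
rates (92% actives in Experiment 1; 10.5% and 18.8% passives in the
Experiment-2 control and experimental groups) and the qualitative pattern
booleans p1–p5.  The calibration module scores candidates by
`Σ((statistic − target)/tolerance)²` averaged over replicate simulations,
with all pattern booleans required true in a majority of replicates
(default 5), and ranks by grid search — the objective is stochastic and
cheap, so reproducible enumeration beats gradient methods here.
Candidates with more than 10% selection timeouts are rejected.

The shipped defaults (`defaults_exp1.yaml`, identical by design to
`defaults_exp2.yaml`: one parameter set covers both experiments, the group
difference emerging entirely from training + learning) place the dynamics
in a specific regime:

- `rest_active = 0.28` sits at the learning ceiling (θ_exc − margin), so
  production experience cannot inflate the already-saturated active bias —
  the model's expression of the ceiling on active preference.
  `rest_passive = 0.17` then sets the baseline passive rate near 9%.
- `w_inhib = 0.5` with `input_drive = 0.04` makes near-tie races stall
  (mutual inhibition exceeds drive until noise separates the nodes) while
  decided races resolve in ~25–30 cycles.  Competition time therefore
  *rises* when priming narrows the gap and *falls* when it widens it.
- `w_cross = 0.6` and `settle_cycles = 35` size the cross-verb boost so
  that a boosted passive still trails the active rest in the
  strong-preference regime (slow fight → no latency benefit for repeated
  passives, patterns p4 for Experiment 1 and the control group) but leads
  it after 90%-passive training has raised `rest_passive` by
  90 × `learn_increment` = 0.036 (fast win → latency facilitation,
  p4 for the experimental group).  `practice_reduction = 0.10` (≈55–60 ms)
  sits between the two regimes' selection-time penalties.
- `ms_per_cycle = 15`, `latency_intercept_ms = 150` and planning baselines
  550/600 ms put simulated latencies in the ~1000–1300 ms range typical of
  voice-key picture description.

With these defaults the three baseline rates land within ±2 percentage
points of their targets and all pattern checks hold, verified across five
seeds at 30 participants/group and three seeds at 60 (the problem sizes
used throughout the tests; the acceptance script uses 30/group, matching
the original samples).

## Known limitations

- Priming *magnitudes* are not calibrated — only baselines and directions.
  The simulated tendency effects of passive primes (and the lexical boost)
  are considerably larger than the human effects, and active primes
  suppress passive responses more strongly than human data suggest, which
  leaves the passive-without-syntactic-repetition latency cell sparsely
  populated at 30 participants.
- The latency dissociation (p4) is a difference of conditional means over
  stochastic cell compositions; at 30 participants/group its margin is
  tens of milliseconds and individual seeds can wobble, which is why the
  calibration was validated across multiple seeds and both sample sizes.
- No response errors, no voice-key artifacts, no timing/lag manipulation,
  no thematic-role (noun) nodes: noun repetition enters only through the
  planning-stage `word_repetition = full` flag.
- Resting levels are structure-level (shared across verbs); verb-specific
  preference biases are not modeled.
- The fitted regression coefficients of the original studies are data
  estimates on human trials and are out of scope; the harness reports
  proportions and cell means instead.
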