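# primevoice

An activation-competition simulator of **syntactic priming** in transitive
sentence production, with a virtual-experiment harness that regenerates two
picture-description experiments and checks whether the model reproduces a
well-known dissociation: priming shows up in **response tendencies for
passives** (the dispreferred structure) but in **response latencies for
actives** (the preferred one) — and a training block that boosts the base
rate of passives makes latency facilitation appear for both structures.

It is aimed at computational psycholinguists who want a runnable,
calibrated instantiation of the residual-activation / competition account
of structural priming, and at methodologists who want a seeded testbed for
tendency-vs-latency analyses (post-hoc syntactic-repetition coding,
per-subject outlier trimming, counterbalanced trial-list generation).

## The model

Each transitive verb owns an Active-Voice node and a Passive-Voice node.
Node activation *a* ∈ [0, 1] evolves in discrete cycles:

    a(t+1) = squash( r + d·(a(t) − r) + excitation − inhibition + ε )

where *r* is the node's resting level (higher for actives, tracking their
corpus frequency), *d* the decay factor (default .95), ε ~ N(0, σ²) the
per-cycle noise, and `squash` clips to [0, 1].  Nodes below the excitation
threshold θ_exc (default .3) are dormant and emit nothing; above it a node
inhibits its within-verb competitor with weight `w_inhib`.  The first node
to reach the selection threshold θ_sel (default .9) *fires*: its structure
is produced.  Competition time falls as the activation gap between the
competitors grows; a near-tie produces a long mutual-inhibition stall.

After a prime is produced, (i) the fired node keeps residual activation
that decays back toward rest, (ii) same-voice nodes of *other* verbs get a
one-shot boost `w_cross × a_fired` (the lexical-boost pathway), and
(iii) the produced structure's resting level is nudged up by a learning
increment (capped below θ_exc) — the route by which a 90%-passive training
block durably shifts the preference bias.

Response latency is additive: `intercept + ms_per_cycle × cycles +
planning`, where planning is a per-structure baseline shortened by
practice (same structure on the preceding trial) and by full lexical
repetition.  Tendencies are decided purely in the selection stage;
latencies mix both stages, which is where the dissociation lives.

## Worked example

Simulate Experiment 1 (30 virtual participants, 72 baseline + 96 priming +
96 filler trials each) with the shipped calibration:

```bash
primevoice summarize --experiment exp1 --participants 30 --seed 1 --out demo
```

which prints the per-condition tendency table

```
condition,n,n_passive,p_passive
baseline,2058,193,0.0938
active_none,692,5,0.0072
active_full,688,1,0.0015
passive_none,684,267,0.3904
passive_full,689,473,0.6865
```

— 9.4% passives at baseline (i.e. ~91% actives), a strong increase after
passive primes, amplified by word repetition, and essentially no passive
responses after active primes — and the latency table

```
target_structure,syntactic_repetition,n,mean_ms,se_ms
active,True,1374,1036.4,2.3
active,False,633,1155.1,4.2
passive,True,740,1258.7,4.8
passive,False,6,1195.5,25.9
```

— syntactically repeated **actives** are ~119 ms faster, while repeated
**passives** are *not* faster (the shortened planning stage is eaten by a
longer competition against the still-dominant active node).
`primevoice patterns ...` renders these checks as booleans (p1–p4, plus p5
for the Experiment-2 group contrast); `primevoice simulate` writes the full
trial log; `primevoice calibrate` grid-searches parameters against
calibration targets.

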