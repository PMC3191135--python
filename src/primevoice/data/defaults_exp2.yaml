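# Shipped default calibration for the training-session experiment; identical
# to the base calibration: a single parameter set reproduces both experiments,
# with the group difference carried entirely by the 100-trial training block
# acting through the learning rule (see docs/methods.md).
decay: 0.95
theta_exc: 0.3
theta_sel: 0.9
rest_active: 0.28
rest_passive: 0.17
w_inhib: 0.5
w_cross: 0.6
noise_sd: 0.02
input_drive: 0.04
settle_cycles: 35
max_cycles: 500
ms_per_cycle: 15.0
latency_intercept_ms: 150.0
plan_base_active_ms: 550.0
plan_base_passive_ms: 600.0
practice_reduction: 0.10
lexical_plan_reduction: 0.02
learn_increment: 0.0004
learn_ceiling_margin: 0.02
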