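# Calibration targets: the printed baseline preference rates plus the
# qualitative priming signature that the shipped defaults must reproduce.
- name: exp1_baseline_actives
  experiment: exp1
  statistic: baseline_active_pct
  target_value: 92.0
  tolerance: 2.0
- name: exp2_control_baseline_passives
  experiment: exp2_control
  statistic: baseline_passive_pct
  target_value: 10.5
  tolerance: 2.0
- name: exp2_experimental_baseline_passives
  experiment: exp2_experimental
  statistic: baseline_passive_pct
  target_value: 18.8
  tolerance: 2.0
- {name: exp1_p1, experiment: exp1, pattern: p1}
- {name: exp1_p2, experiment: exp1, pattern: p2}
- {name: exp1_p3, experiment: exp1, pattern: p3}
- {name: exp1_p4, experiment: exp1, pattern: p4}
- {name: ctrl_p1, experiment: exp2_control, pattern: p1}
- {name: ctrl_p2, experiment: exp2_control, pattern: p2}
- {name: ctrl_p3, experiment: exp2_control, pattern: p3}
- {name: ctrl_p4, experiment: exp2_control, pattern: p4}
- {name: expgrp_p3, experiment: exp2_experimental, pattern: p3}
- {name: expgrp_p4, experiment: exp2_experimental, pattern: p4}
- {name: expgrp_p5, experiment: exp2_experimental, pattern: p5}
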