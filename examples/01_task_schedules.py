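"""Generate the two task schedules and inspect their structure.

The experience task presents four stimuli with Gaussian rewards
(means 35/65 points, SDs 5/20) over 4 blocks x 72 trials; the
description task presents 10 fixed two-option gambles over 4 blocks
x 20 trials.
"""

import peirs_risk as pr
from peirs_risk import task_design as td

sched = pr.make_experience_schedule(seed=1)
print("experience trials:", len(sched))
print(sched.trial_type.value_counts().to_string())
print("ordering violations (forced -> same-stimulus context):",
      td.ordering_violations(sched))
# 288 trials; half are matched-mean context trials where risk attitude
# is expressed; zero violations of the forced-trial ordering rule.

desc, gambles = pr.make_description_schedule(seed=1)
print("\ndescription trials:", len(desc),
      "| gambles:", desc.gamble_id.nunique())
for g in gambles:
    ev_s, ev_r = pr.gamble_expected_values(g)
    print(f"  gamble {g.id:2d} ({g.context:11s})  EV safe {ev_s:6.1f}  "
          f"EV risky {ev_r:6.1f}")
# Gambles 1-8 pit a zero-EV coin flip against risky options spanning
# EV -30..+30; gambles 9/10 are the EV-matched low/high context pairs.
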