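"""How early outcomes boost statistical information at an interim analysis.

The variance-reduction factor V(t) compares the variance of the primary
treatment effect when the correlated early outcomes are used against the
variance from primary-outcome data alone; 1/V is the proportionate gain in
the information fraction, tau = tau0 / V.
"""

import numpy as np

from earlygsd import (
    CorrelationSpec,
    DesignPoint,
    FollowUpSchedule,
    RecruitmentSpec,
    information_fraction,
    time_at_tau0,
)

sched = FollowUpSchedule([1, 2, 4])  # 3/6/12 months in 3-month units
rec = RecruitmentSpec("fixed", 188, 8.0)

print(f"{'alpha':>6}{'V':>8}{'tau0':>8}{'tau':>8}{'info':>8}")
t = time_at_tau0(rec, sched, 0.25)  # first interim: 25% with 12-month data
for alpha in (0.0, 0.25, 0.5, 0.75):
    point = DesignPoint(
        t=t, sched=sched, rec=rec, corr=CorrelationSpec("uniform", alpha), sigma_s=12.0
    )
    s = information_fraction(point)
    print(f"{alpha:>6.2f}{s.V:>8.3f}{s.tau0:>8.3f}{s.tau:>8.3f}{s.info:>8.3f}")

# At the planning correlation alpha = 0.5, V = 0.808: the 3- and 6-month
# outcomes raise the information fraction from 0.25 to 0.309 - about 24%
# more information at no extra cost in time or participants.
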