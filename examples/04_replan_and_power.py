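"""Replanning a real three-analysis trial with closed forms only.

Reconstructs the planning table of a 188-participant shoulder-surgery trial
(interims when 25% and 35% of participants have 12-month data) and computes
the power of the resulting group-sequential design by numerical integration
of the canonical joint distribution - no individual-participant simulation
required.
"""

from earlygsd import replan_start_reacts

for model in ("fixed", "decreasing"):
    res = replan_start_reacts(model)
    print(f"\n{model}-rate recruitment:")
    print(
        res.report[["analysis", "t", "N_1", "N_2", "N_3", "V", "tau", "information"]]
        .round({"t": 2, "N_1": 1, "N_2": 1, "N_3": 1, "V": 3, "tau": 3, "information": 3})
        .to_string(index=False)
    )
    print(f"power at treatment difference 6 (sd 12): {100 * res.power:.1f}%")

# Both recruitment models deliver ~90.6-90.7% power with the same boundary
# schedule - the analytic replan matches the original simulation-based
# design at a fraction of the effort.
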