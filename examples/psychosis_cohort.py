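"""Analyze a period-record cohort table (transition-to-psychosis schema).

The table has one row per assessment period: subject id, family history
(yes/no), period start/end day, transition status (yes only on the final
period) and the HAMD depression score.  If the study's own supplementary
CSV is present at data/real/transition_psychosis.csv it is used; otherwise
a synthetic stand-in cohort with the same schema is generated.
"""

from pathlib import Path

import jointcox as jc

real_path = Path(__file__).resolve().parents[1] / "data" / "real" / \
    "transition_psychosis.csv"
if real_path.exists():
    table = jc.read_real_data(real_path)
    print(f"loaded study data: {real_path}")
else:
    table = jc.synthetic_real_table(seed=20)
    print("study file not found - using the SYNTHETIC stand-in cohort")

d = jc.describe(table)
print(f"\n{d['n_subjects']} subjects ({d['n_family_history']} with family "
      f"history), {d['n_transitions']} transitions")
print(f"HAMD: mean {d['hamd_mean']:.1f}, range {d['hamd_min']:.0f} to "
      f"{d['hamd_max']:.0f}")
print(f"transition times: median {d['transition_time_median']:.0f} days, "
      f"mean {d['transition_time_mean']:.0f} days")

out = jc.analyze_real(table)
print("\nper-method estimates (lambda1 = depression effect, tau = family "
      "history effect):")
print(out.round(4).to_string(index=False))
print("\nthe two Cox rows are attenuated relative to the joint-model rows, "
      "the same pattern the simulation study quantifies.")
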