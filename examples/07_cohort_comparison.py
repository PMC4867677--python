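"""Group-level comparison: age-related P300 latency delay.

Simulates small young and older cohorts through the full pipeline and
tabulates per-measure group means with significance tests, mirroring a
young-vs-older validation analysis.
"""

import pandas as pd

import neurovitals as nv

rows = []
for seed, group in ((13, "young"), (14, "older")):
    for member in nv.generate_cohort(6, group=group, seed=seed):
        _, measures, _ = nv.process_participant(member.recordings)
        for mid, value in nv.measures_to_values(measures).items():
            rows.append(dict(participant=member.participant, group=group,
                             measure_id=mid, value=value))

table = nv.cohort_report(pd.DataFrame(rows))
pd.set_option("display.width", 120)
print(table.round(3).to_string(index=False))
# Expect the P300_latency row to show older > young by roughly 34 ms;
# with n=6 per group the t-test detects this delay most of the time
# (analytic power ~0.84 at the preset effect size).
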