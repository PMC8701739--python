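"""Simulate a small smart-home cohort and inspect its raw event streams.

Generates two normal controls and two early-stage dementia residents for
a week, prints per-channel daily detection counts for one person (the
day-unit summary table) and the cohort profile list.
"""

from adlhome import generate_cohort, summary_report
from adlhome.simulate import CohortConfig

config = CohortConfig(n_normal=2, n_dementia=2, days=7)
profiles, logs = generate_cohort(config, seed=1)

print("cohort profiles (person, group, MMSE, CDR):")
for p in profiles:
    print(f"  {p.person_id}  {p.group:<8}  MMSE {p.mmse:>2}  CDR {p.cdr}")

pid = profiles[0].person_id
events = logs[pid]
print(f"\n{pid}: {len(events)} event rows over 7 days")
print("\nper-channel daily detection counts (first 8 channels):")
print(summary_report(events).iloc[:, :8].to_string())
# Each row is one day; columns are sensor channels (d=door, m=motion,
# p=plug, t=temperature-humidity, v=vibration). Counts are detections or
# state changes summed per day.
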