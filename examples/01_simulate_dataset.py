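"""Generate a study-shaped dual-source dataset and inspect its shape.

Builds the default simulation — 50 health facilities, half in the
intervention arm, 48-76 audited charts each, 28 variables abstracted
from both the paper chart and the EHR — and prints its dimensions and
a ground-truth error census.
"""

from ehrdqa import SimulationConfig, generate_dataset

records, facilities, truth = generate_dataset(SimulationConfig(), seed=1)

n = len(records)
print(f"records:                {n}")
print(f"facilities:             {len(facilities)}")
print(f"records per facility:   {n / len(facilities):.1f}")
print(f"total data items:       {n * 28 * 2}")

n_alert = sum(f.has_vl_alert for f in facilities)
print(f"facilities with the missing-viral-load alert: {n_alert}")

census = (truth.labels.stack().value_counts().drop("", errors="ignore"))
print("\ninjected error census (cells):")
for label, count in census.items():
    print(f"  {label:12s} {count}")

# Each count is the number of dataset cells whose observed text departs
# from the ground truth through that labelled error process; 'lagged'
# marks EHR viral-load entries running one result behind the chart.
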