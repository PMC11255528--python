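"""Date-keyed viral-load alignment on a single record.

Shows why positional comparison misleads when the EHR runs one result
behind the paper chart, and how date alignment recovers the agreement.
"""

import datetime

from ehrdqa import VLEntry, align_vl

D = datetime.date

# paper chart holds three results; the EHR is missing the newest one
paper = [
    VLEntry(value=25.0, date=D(2018, 9, 1), source="paper", position=1),
    VLEntry(value=150.0, date=D(2018, 3, 1), source="paper", position=2),
    VLEntry(value=900.0, date=D(2017, 9, 1), source="paper", position=3),
]
ehr = [
    VLEntry(value=150.0, date=D(2018, 3, 1), source="ehr", position=1),
    VLEntry(value=900.0, date=D(2017, 9, 1), source="ehr", position=2),
]

series = align_vl(paper, ehr)
print("aligned pairs (newest first):")
for pair, match in zip(series.pairs, series.all_viral_loads):
    p = f"{pair.paper.value:g} @ {pair.paper.date}" if pair.paper else "absent"
    e = f"{pair.ehr.value:g} @ {pair.ehr.date}" if pair.ehr else "absent"
    print(f"  paper: {p:18s} | ehr: {e:18s} | match: {match}")

print(f"\nunpaired paper entries: {series.n_unpaired_paper}")
print(f"'at least one viral load' flag: {series.at_least_one}")
# Positionally, 25 vs 150 would look like a disagreement; keyed by date,
# both shared results match and only the newest paper result is missing
# from the EHR.  The at-least-one flag is True because the EHR's most
# recent value (150) matches one of the paper values within 1 copy/mL.
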