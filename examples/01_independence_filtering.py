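"""Collapse raw camera-trap records into independent detection events.

A camera firing repeatedly at a browsing animal produces many records of one
visit.  The 30-minute rule merges records of the same species at the same
site that fall within 30 minutes of the event's first photograph.
"""

from datetime import datetime

from camtrapnet import DetectionRecord, build_matrix, filter_independent

records = [
    DetectionRecord("S001", "sambar", datetime(2022, 6, 1, 6, 0)),
    DetectionRecord("S001", "sambar", datetime(2022, 6, 1, 6, 10)),   # same visit
    DetectionRecord("S001", "sambar", datetime(2022, 6, 1, 6, 40)),   # new visit
    DetectionRecord("S001", "muntjac", datetime(2022, 6, 1, 6, 12)),  # other species
    DetectionRecord("S002", "sambar", datetime(2022, 6, 1, 22, 5)),
]

events = filter_independent(records, window_minutes=30)
print(f"{len(records)} raw records -> {len(events)} independent events")
for e in events:
    print(f"  {e.site_id} {e.species:8s} start {e.event_start:%H:%M} ({e.n_records} records)")

matrix = build_matrix(events)
print("\nsite x species independent-event counts:")
print(matrix.to_frame())
# Each cell counts distinct visits; these counts feed every downstream index.
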