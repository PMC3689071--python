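"""Behavioral metrics: freezing percentage and prepulse inhibition.

Freezing is scored as the portion of the first CS presentation spent
immobile; PPI is the percentage reduction of startle by a prepulse.
"""

from cdfd import (
    FreezingRecord,
    SessionSpec,
    cohort_specs,
    freezing_percentage,
    generate_freezing,
    generate_session,
    generate_startle,
    ppi_percent,
    startle_summary,
)

dataset = generate_session(cohort_specs(1, seed=3), SessionSpec(seed=3))

intervals = generate_freezing(dataset.events, {"A": 0.6, "B": 0.15}, seed=4)
for ctx in ("A", "B"):
    first = dataset.events[dataset.events["context"] == ctx].iloc[0]
    window = (first["cs_onset_s"], first["cs_offset_s"])
    pct = freezing_percentage(FreezingRecord("rat1", intervals, window))
    print(f"freezing to the first CS in Context {ctx}: {pct:.1f}%")

table = generate_startle(15, ss_mean=150.0, ppi_target=40.0, seed=5)
summary = startle_summary(table)
print(f"mean startle alone SS = {summary.ss:.1f}, with prepulse PS = {summary.ps:.1f}")
print(f"PPI = {ppi_percent(summary):.1f}%")
# High freezing in the fearful context and intermediate PPI mirror the
# behavioral readouts the analysis pairs with the unit recordings.
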