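"""Generate a synthetic two-context recording session and write it to CSV.

Builds a small cohort of Poisson units — half of them firing more to the
tone CS in the fearful context (A) — realizes their spike trains over the
full test-day schedule, and saves spikes, events, and the ground truth.
"""

from pathlib import Path

from cdfd import SessionSpec, cohort_specs, generate_session
from cdfd.io import write_events, write_spikes, write_truth

out = Path("example_output")
out.mkdir(exist_ok=True)

units = cohort_specs(
    8, seed=7, modulated_fraction=0.5, transient_gain_A=6.0, sustained_gain_A=2.5
)
dataset = generate_session(units, SessionSpec(seed=7))

write_spikes(dataset.spike_trains, out / "spikes.csv")
write_events(dataset.events, out / "events.csv")
write_truth(dataset.truth, out / "truth.json")

ev = dataset.events
print(f"trials: {len(ev)} ({ev['context'].value_counts().to_dict()})")
print(f"CS duration: {(ev['cs_offset_s'] - ev['cs_onset_s']).iloc[0]:.0f} s")
print(f"first CS onset: {ev['cs_onset_s'].iloc[0]:.0f} s (after pre-tone exposure)")
n = {u: len(t) for u, t in dataset.spike_trains.items()}
print(f"spike counts per unit: {n}")
# 12 trials = 6 per context; units with higher baseline rates carry more
# spikes; ground truth in truth.json names which units were modulated.
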