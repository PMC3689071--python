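"""Quantify context modulation: per-unit paired-bin t-values and the
population direction chi-square, via the full pipeline.

A positive t means the unit fired more to the CS in the fearful context
(A) than in the safe context (B) across the thirty matched 1-s bins.
"""

from cdfd import SessionSpec, cohort_specs, generate_session, run_pipeline

units = cohort_specs(
    24, seed=11, modulated_fraction=0.5, transient_gain_A=4.0, sustained_gain_A=2.0
)
dataset = generate_session(units, SessionSpec(seed=11))
report = run_pipeline(dataset.spike_trains, dataset.events)

cols = ["unit_id", "persistent", "t_value", "t_significant", "t_direction"]
print(report.units[cols].round(2).to_string(index=False))

mod = report.summary["modulation"]
print(f"\nPFUs tested: {mod['n_tested']}, significant positive: "
      f"{mod['n_significant_positive']}, negative: {mod['n_significant_negative']}")
if mod["chi_square"]:
    c = mod["chi_square"]
    print(f"direction chi-square: chi2={c['chi2']:.3f}, p={c['p']:.4f}")
for name, wt in report.summary["window_tests"].items():
    if wt and wt.get("t") is not None:
        print(f"{name}: t({wt['df']}) = {wt['t']:.2f}, p = {wt['p']:.4f}")
# A majority-positive count with a significant chi-square recovers the
# built-in fearful-context bias of the simulated cohort.
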