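# Methods

## Analysis model

Every unit is treated as a point process observed over a two-context
test session. Spikes are aligned to CS onsets (onset at relative time 0)
and counted on half-open bins `[lo, hi)`; a spike exactly on an edge
belongs to the upper bin, and a spike exactly at the analysis window's
end is excluded. Two binning configurations are used, both giving 20
baseline bins:

| purpose    | bin width | window        | baseline    |
|------------|-----------|---------------|-------------|
| transient  | 50 ms     | −1 s … +3 s   | −1 s … 0 s  |
| sustained  | 1 s       | −20 s … +30 s | −20 s … 0 s |

Baseline statistics are the mean and *sample* SD (n−1 divisor) of the 20
baseline bins of the **trial-averaged** profile; each bin of the
trial-averaged profile is then expressed in those SD units. The
symmetric 20-bin structure of the two configurations is what motivates
averaging trials first; pooling all trial × bin baseline counts instead
is available as `pool_baseline_trials`. A baseline with zero variance
(typically a unit that never fires before the CS) makes the Z-profile
undefined; such units are flagged `degenerate` and excluded downstream
with reason `degenerate_baseline` — never dropped silently.

Classification applies two criteria to profiles pooled over all trials
of both contexts (units are classified once, then contexts are
compared; classification restricted to one context is a config option):

* **short-latency**: max of the first 3 post-onset 50-ms bins strictly
  above 3 SD. "Over 3 SDs" is read strictly: a bin at exactly 3.0 does
  not qualify.
* **persistent (PFU)**: at least 2 of the first 10 post-onset 1-s bins
  strictly above 3 SD.

Raising the threshold shrinks the responsive set monotonically (tested
property).

## Context-modulation statistic

Per unit, the thirty 1-s CS bins of the Context-A and Context-B
Z-profiles are paired; with d = z_A − z_B,

    t = mean(d) / (sd(d)/√30),  df = 29,

two-tailed significance at α = 0.05 (critical |t| ≈ 2.045). The raw sum
Σd is reported alongside, since the statistic can equivalently be
described as a scaled sum of the bin differences. Direction is reported
only for significant (or degenerate-but-nonzero) results: positive =
more activity in the fearful context. Zero-variance differences are
handled explicitly: all-zero → t = 0; constant nonzero → direction
reported, t undefined.

The population-level direction test is the Pearson chi-square (df = 1,
no continuity correction) on the 2 × 2 table
`[[n_pos, n − n_pos], [n_neg, n − n_neg]]` over the n analyzable PFUs —
each row contrasting one direction's significant count against the rest
of the same population. With 11 positive and 3 negative of 24 this
yields χ² = 6.454.

Window-mean tests pair per-unit mean Z over a window (0–150 ms for
short-latency units at 50-ms resolution; 0–10 s and the full CS for
PFUs at 1-s resolution) across contexts, with df = n_units − 1.

The habituation analysis splits each context's 6 trials into early/late
3-trial phases; each phase is re-binned and re-normalized **to its own
baseline bins**, the cell value being the mean Z over the response
window (0–150 ms for the 50-ms variant, whole CS for the 1-s variant).
Cells enter a two-within-factor repeated-measures ANOVA (context ×
phase, subject = unit) computed by the standard marginal-mean sum-of-
squares decomposition, each effect tested against its own
subject-interaction error term. Units whose phase baseline is
degenerate (e.g. no baseline spikes in the early or late trials) are
excluded with a note. A split-plot (one between-, one within-factor)
decomposition is provided as plumbing for group × context behavioral
designs. Both ANOVAs are oracle-tested against independent
implementations (statsmodels `AnovaRM`, pingouin `mixed_anova`).

## Behavioral metrics

Freezing arrives as annotated immobility intervals; the score is
100 × |union(intervals) ∩ window| / |window|, with overlapping or
touching annotations merged first, so re-segmenting an annotation
cannot change the score. PPI (%) = 100 × (SS − PS)/SS from mean startle
amplitudes; it requires SS > 0 and is invariant to the load cell's
scale.

## Synthetic data generator

Units are inhomogeneous Poisson processes realized by thinning
(candidates at the rate bound, kept with probability rate/bound), which
makes window counts exactly Poisson with mean = integrated rate; the
test suite checks the realized distribution against an independent
time-rescaling simulator. The rate function is

    r(t) = r₀ · g_T(τ) · g_S(τ)   (τ = time since CS onset)

with g_T = transient gain on [0, 150 ms), g_S decaying linearly from
the sustained gain at onset to 1 at 10 s, context-specific gains, and
multiplicative combination (additive is a config option). The linear
decay is the simplest shape consistent with differential firing
concentrated in the first 10 s of the tone; the two components share
the onset, so a strong sustained response necessarily elevates the
first 150 ms as well — transient/sustained cohorts dissociate cleanly
only when the sustained gain is modest.

Schedule defaults emulate the test day: contexts A then B on one clock
separated by a 1-h gap, 180 s of pre-tone exposure, 6 CS trials of 30 s
per context, offset-to-onset ITIs uniform on [160, 200] s (mean 180 s).
Cohort spontaneous rates are drawn log-uniform over 0.31–34.60 Hz, the
span observed in prelimbic recordings. Simultaneous timestamps are
nudged apart by the 0.1-ms timestamp resolution so trains are strictly
increasing. All randomness flows from one seed through spawned
generator streams: identical specs and seed reproduce the dataset
exactly.

Freezing annotations are generated by tiling each CS window with 1-s
segments frozen independently with a per-context probability (expected
percentage = 100 × p); startle amplitudes are lognormal with a
configured mean PPI level. The generator emulates rate structure and
schedule only — no refractoriness, bursting, waveform/sorting noise,
latency jitter, slow nonstationarity, or correlated noise across units
or between firing and behavior. Passing recovery tests therefore shows
the analysis recovers *rate-coded* context modulation of the assumed
shape, not that it is robust to every feature of cortical data.

## Numerical choices

* Bin-edge membership uses `searchsorted` on the edge grid, so an
  on-edge spike deterministically joins the upper bin.
* Window/bin divisibility is enforced to 1e-9 s.
* Zero-variance difference vectors are detected with a relative
  tolerance of 1e-12 of the data scale (a bit-identical constant
  difference still has a rounding-level SD).
* F statistics with a zero error SS are reported as undefined (NaN in
  memory, null in `summary.json`) with an explanatory note, not as an
  arbitrary large value.
* `summary.json` is written with sorted keys and NaN→null, so repeated
  runs on the same inputs are byte-identical.

## Known limitations

* **The paired-bin t is anticonservative under the null.** Each
  context's 30 CS bins share one baseline mean/SD estimated from only
  20 bins, so baseline estimation error is a common offset across all
  30 bin differences. It inflates |mean(d)| but not the bin-wise SE the
  t divides by: Var(d̄) ≈ 2/30 + 2/20 while the SE estimates 2/30,
  stretching the null t by ≈√2.5 ≈ 1.58. At a nominal two-tailed 5%,
  each direction's false-positive rate is therefore ≈10%, which the
  package's null simulations reproduce (≈10% per side over 500
  unmodulated units). The statistic is implemented as defined because
  it is the field's convention for this analysis; the direction
  chi-square that consumes these flags contrasts the two inflated rates
  against each other, which is why an unmodulated population still
  yields a non-significant chi-square. Interpret per-unit significance
  flags as a ranking device, not calibrated error rates.
* **Recovery power is rate-limited.** With 6 trials per context,
  detection of a modulated unit scales roughly with √(baseline rate);
  below ~4 Hz the PFU criterion and the paired-bin t rarely fire. Under
  the default log-uniform 0.31–34.60-Hz cohort, a 24-unit session with
  half the units modulated (transient gain 4, sustained gain 2) yields
  a majority-positive significant set *and* a significant direction
  chi-square in ≈85% of runs — the residual failures are sessions where
  too few low-rate PFUs survive detection for the chi-square to reach
  its critical value.
* Freezing scoring assumes the immobility intervals are already
  annotated; video analysis is out of scope. Unit identity is assumed
  matched across the two context sessions (required for any paired
  statistic). US-evoked responses, lesions, and biophysical neuron
  models are not modeled.
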