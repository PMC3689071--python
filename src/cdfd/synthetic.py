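"""Synthetic recording sessions with the structure the analysis assumes.

Each unit is an inhomogeneous Poisson process: a constant spontaneous
rate, multiplied (or optionally added to) during CS presentations by a
context-specific response with two components:

* transient — a gain applied for the first 150 ms after CS onset;
* sustained — a gain at onset decaying linearly to 1 at 10 s.

The session schedule mirrors the test-day protocol: 180 s of pre-tone
exposure, then 6 CS-only trials (30-s tone) per context with inter-trial
intervals drawn uniformly from 160-200 s, the two contexts separated by
a long gap on a common clock. Ground-truth unit parameters are returned
alongside the data so recovery tests can close the loop.

Spike trains are realized by thinning: candidates at the rate bound are
kept with probability rate(t)/bound. Counts over any window are then
Poisson with mean equal to the integrated rate, which the test suite
checks against a time-rescaling oracle.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .binning import SpikeTrain
from .errors import ParameterError

__all__ = [
    "SyntheticUnitSpec",
    "SessionSpec",
    "SyntheticDataset",
    "ContextualRate",
    "generate_poisson_train",
    "generate_session",
    "generate_freezing",
    "generate_startle",
    "sample_baseline_rates",
]

TIMESTAMP_RESOLUTION = 1e-4  # s; duplicate spikes are nudged apart by this
TRANSIENT_WINDOW = 0.15  # s after CS onset
SUSTAINED_WINDOW = 10.0  # s; sustained gain decays linearly to 1 here

#: span of spontaneous rates observed in prelimbic recordings (Hz)
RATE_RANGE = (0.31, 34.60)


@dataclass(frozen=True)
class SyntheticUnitSpec:
    """Ground-truth parameters of one simulated unit.

    Gains are dimensionless multipliers on the baseline rate; a gain of 1
    means no response. ``baseline_rate`` of 0 is allowed to exercise the
    zero-baseline exclusion paths downstream.
    """

    unit_id: str
    baseline_rate: float  # spikes/s
    transient_gain_A: float = 1.0
    transient_gain_B: float = 1.0
    sustained_gain_A: float = 1.0
    sustained_gain_B: float = 1.0

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise ParameterError(f"unit {self.unit_id}: baseline_rate must be >= 0")
        for name in ("transient_gain_A", "transient_gain_B",
                     "sustained_gain_A", "sustained_gain_B"):
            if getattr(self, name) < 0:
                raise ParameterError(f"unit {self.unit_id}: {name} must be >= 0")

    def gains(self, context: str) -> tuple[float, float]:
        if context == "A":
            return self.transient_gain_A, self.sustained_gain_A
        if context == "B":
            return self.transient_gain_B, self.sustained_gain_B
        raise ParameterError(f"unknown context {context!r}")


@dataclass(frozen=True)
class SessionSpec:
    """Test-session schedule parameters (defaults = the study protocol)."""

    contexts: tuple[str, ...] = ("A", "B")
    trials_per_context: int = 6
    cs_duration: float = 30.0
    pre_tone_exposure: float = 180.0
    iti_range: tuple[float, float] = (160.0, 200.0)
    seed: int = 0
    intercontext_gap: float = 3600.0  # s between context sessions
    post_session_pad: float = 180.0
    combine: str = "multiplicative"  # or 'additive'

    def __post_init__(self):
        if self.cs_duration <= 0:
            raise ParameterError("cs_duration must be positive")
        if self.trials_per_context < 1:
            raise ParameterError("trials_per_context must be >= 1")
        if self.iti_range[0] > self.iti_range[1] or self.iti_range[0] < 0:
            raise ParameterError("iti_range must satisfy 0 <= min <= max")
        if self.combine not in ("multiplicative", "additive"):
            raise ParameterError("combine must be 'multiplicative' or 'additive'")


@dataclass
class SyntheticDataset:
    spike_trains: dict[str, SpikeTrain]
    events: pd.DataFrame
    truth: dict
    session_span: tuple[float, float] = (0.0, 0.0)
    pre_tone_windows: dict[str, tuple[float, float]] = field(default_factory=dict)


class ContextualRate:
    """Vectorized piecewise rate function for one unit over a schedule."""

    def __init__(self, unit: SyntheticUnitSpec, events: pd.DataFrame, spec: SessionSpec):
        self.unit = unit
        self.spec = spec
        order = np.argsort(events["cs_onset_s"].to_numpy())
        self.onsets = events["cs_onset_s"].to_numpy(dtype=float)[order]
        ctx = events["context"].to_numpy()[order]
        self.tg = np.array([unit.gains(c)[0] for c in ctx])
        self.sg = np.array([unit.gains(c)[1] for c in ctx])

    @property
    def max_rate(self) -> float:
        r = self.unit.baseline_rate
        if r == 0 or self.onsets.size == 0:
            return max(r, 0.0)
        s0 = np.maximum(self.sg, 1.0)  # sustained multiplier peaks at onset
        t0 = np.maximum(self.tg, 1.0)
        if self.spec.combine == "multiplicative":
            peak = np.max(t0 * s0)
        else:
            peak = np.max(1.0 + (t0 - 1.0) + (s0 - 1.0))
        return r * max(peak, 1.0)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        r = np.full(t.shape, self.unit.baseline_rate)
        if self.onsets.size == 0 or self.unit.baseline_rate == 0:
            return r
        idx = np.searchsorted(self.onsets, t, side="right") - 1
        valid = idx >= 0
        rel = np.where(valid, t - self.onsets[np.clip(idx, 0, None)], np.inf)
        in_cs = valid & (rel >= 0) & (rel < self.spec.cs_duration)
        if not np.any(in_cs):
            return r
        i = idx[in_cs]
        rel_cs = rel[in_cs]
        sus = 1.0 + (self.sg[i] - 1.0) * np.clip(1.0 - rel_cs / SUSTAINED_WINDOW, 0.0, 1.0)
        tr = np.where(rel_cs < TRANSIENT_WINDOW, self.tg[i], 1.0)
        if self.spec.combine == "multiplicative":
            mult = tr * sus
        else:
            mult = 1.0 + (tr - 1.0) + (sus - 1.0)
        r[in_cs] = self.unit.baseline_rate * mult
        return r


def _strictly_increasing(times: np.ndarray) -> np.ndarray:
    """Nudge simultaneous timestamps apart by one resolution unit."""
    if times.size < 2:
        return times
    out = times.copy()
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + TIMESTAMP_RESOLUTION
    return out


def generate_poisson_train(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    span: tuple[float, float],
    seed: int | np.random.Generator,
    rate_max: float | None = None,
) -> np.ndarray:
    """Realize an inhomogeneous Poisson process by thinning.

    ``rate_fn`` must be bounded on the span by ``rate_max`` (taken from a
    ``max_rate`` attribute if not given). Negative rates or rates above
    the bound are rejected. Reproducible given the seed.
    """
    t0, t1 = span
    if not t1 > t0:
        raise ParameterError("span must have positive duration")
    if rate_max is None:
        rate_max = getattr(rate_fn, "max_rate", None)
        if rate_max is None:
            raise ParameterError("rate_max required when rate_fn has no max_rate attribute")
    if not np.isfinite(rate_max) or rate_max < 0:
        raise ParameterError("rate bound must be finite and non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rate_max == 0:
        r = np.asarray(rate_fn(np.array([t0])), dtype=float)
        if np.any(r > 0):
            raise ParameterError("rate exceeds its declared bound of 0")
        return np.empty(0)
    n = rng.poisson(rate_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n))
    r = np.asarray(rate_fn(cand), dtype=float)
    if np.any(r < 0):
        raise ParameterError("rate function returned a negative rate")
    if np.any(r > rate_max * (1 + 1e-9)):
        raise ParameterError("rate function exceeds its declared bound")
    keep = rng.uniform(0.0, rate_max, size=n) < r
    return _strictly_increasing(cand[keep])


def generate_session(
    units: list[SyntheticUnitSpec],
    spec: SessionSpec,
) -> SyntheticDataset:
    """Build an event schedule and realize every unit's spike train.

    Per context: ``pre_tone_exposure`` of silence from the tone, then
    ``trials_per_context`` CS presentations with offset-to-onset ITIs
    drawn uniformly from ``iti_range``. Contexts follow each other on one
    clock, separated by ``intercontext_gap``. Identical specs and seed
    yield identical datasets.
    """
    if not units:
        raise ParameterError("generate_session requires at least one unit")
    ids = [u.unit_id for u in units]
    if len(set(ids)) != len(ids):
        raise ParameterError("unit ids must be unique")

    ss = np.random.SeedSequence(spec.seed)
    sched_rng = np.random.default_rng(ss.spawn(1)[0])
    rows = []
    t_cursor = 0.0
    pre_tone_windows: dict[str, tuple[float, float]] = {}
    for ctx in spec.contexts:
        session_start = t_cursor
        onset = session_start + spec.pre_tone_exposure
        pre_tone_windows[ctx] = (session_start, onset)
        for k in range(spec.trials_per_context):
            rows.append(
                dict(
                    session_id=f"test_{ctx}",
                    context=ctx,
                    trial_index=k + 1,
                    cs_onset_s=onset,
                    cs_offset_s=onset + spec.cs_duration,
                    us_onset_s=np.nan,
                )
            )
            iti = sched_rng.uniform(*spec.iti_range)
            onset = onset + spec.cs_duration + iti
        session_end = rows[-1]["cs_offset_s"] + spec.post_session_pad
        t_cursor = session_end + spec.intercontext_gap
    events = pd.DataFrame(rows)
    span = (0.0, float(rows[-1]["cs_offset_s"]) + spec.post_session_pad)

    trains: dict[str, SpikeTrain] = {}
    for u, child in zip(units, ss.spawn(len(units) + 1)[1:]):
        rate = ContextualRate(u, events, spec)
        times = generate_poisson_train(rate, span, np.random.default_rng(child))
        trains[u.unit_id] = SpikeTrain(u.unit_id, times)

    truth = {
        "units": [asdict(u) for u in units],
        "session": asdict(spec),
    }
    return SyntheticDataset(trains, events, truth, span, pre_tone_windows)


def generate_freezing(
    schedule: pd.DataFrame,
    freeze_prob_by_context: dict[str, float],
    seed: int,
    segment: float = 1.0,
) -> list[tuple[float, float]]:
    """Immobility intervals within CS windows, one subject.

    Each CS window is tiled with ``segment``-long pieces, each immobile
    independently with the context's probability; adjacent immobile
    pieces are merged. The expected freezing percentage over a CS window
    equals 100 x probability.
    """
    for ctx, p in freeze_prob_by_context.items():
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"freeze probability for {ctx} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    intervals: list[tuple[float, float]] = []
    for row in schedule.itertuples(index=False):
        p = freeze_prob_by_context.get(str(row.context))
        if p is None or p == 0.0:
            continue
        t0, t1 = float(row.cs_onset_s), float(row.cs_offset_s)
        edges = np.arange(t0, t1 + segment / 2, segment)
        edges[-1] = min(edges[-1], t1)
        frozen = rng.uniform(size=edges.size - 1) < p
        start = None
        for i, fz in enumerate(frozen):
            if fz and start is None:
                start = edges[i]
            if (not fz or i == frozen.size - 1) and start is not None:
                end = edges[i + 1] if fz else edges[i]
                if end > start:
                    intervals.append((float(start), float(end)))
                start = None
    return intervals


def generate_startle(
    n_trials_per_type: int,
    ss_mean: float,
    ppi_target: float,
    cv: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Startle-amplitude trial table with a configured mean PPI level.

    Amplitudes are lognormal with the given coefficient of variation;
    prepulse-startle trials have mean ``ss_mean * (1 - ppi_target/100)``.
    """
    if ss_mean <= 0 or n_trials_per_type < 1:
        raise ParameterError("need positive ss_mean and at least 1 trial per type")
    rng = np.random.default_rng(seed)
    sigma2 = np.log(1 + cv**2)
    rows = []
    for trial_type, mean in (
        ("startle_alone", ss_mean),
        ("prepulse_startle", ss_mean * (1 - ppi_target / 100.0)),
    ):
        mu = np.log(max(mean, 1e-12)) - sigma2 / 2
        amps = rng.lognormal(mu, np.sqrt(sigma2), size=n_trials_per_type)
        rows += [dict(trial_type=trial_type, amplitude=float(a)) for a in amps]
    return pd.DataFrame(rows)


def cohort_specs(
    n_units: int,
    seed: int,
    rate_range: tuple[float, float] = RATE_RANGE,
    modulated_fraction: float = 0.0,
    transient_gain_A: float = 1.0,
    sustained_gain_A: float = 1.0,
    transient_gain_B: float = 1.0,
    sustained_gain_B: float = 1.0,
) -> list[SyntheticUnitSpec]:
    """A cohort of units with log-uniform spontaneous rates.

    The first ``round(n_units * modulated_fraction)`` units carry the
    given context gains; the remainder are unmodulated (all gains 1).
    """
    if not 0.0 <= modulated_fraction <= 1.0:
        raise ParameterError("modulated_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rates = sample_baseline_rates(n_units, rng, rate_range)
    n_mod = int(round(n_units * modulated_fraction))
    width = len(str(max(n_units, 1)))
    specs = []
    for i, r in enumerate(rates):
        if i < n_mod:
            specs.append(SyntheticUnitSpec(
                f"u{i + 1:0{width}d}", float(r),
                transient_gain_A=transient_gain_A, sustained_gain_A=sustained_gain_A,
                transient_gain_B=transient_gain_B, sustained_gain_B=sustained_gain_B,
            ))
        else:
            specs.append(SyntheticUnitSpec(f"u{i + 1:0{width}d}", float(r)))
    return specs


def sample_baseline_rates(
    n: int,
    seed: int | np.random.Generator,
    rate_range: tuple[float, float] = RATE_RANGE,
) -> np.ndarray:
    """Log-uniform spontaneous rates over the observed recording span."""
    lo, hi = rate_range
    if not 0 < lo <= hi:
        raise ParameterError("rate_range must satisfy 0 < lo <= hi")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
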