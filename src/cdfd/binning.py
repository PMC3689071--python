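"""Trial alignment, binning, and baseline Z-score normalization.

Spike trains are aligned to conditioned-stimulus (CS) onsets, counted in
fixed-width bins over a window expressed relative to onset (onset at 0),
and converted to a Z-score profile: the trial-averaged count in each bin,
expressed in standard-deviation units of the pre-CS baseline bins.

Two configurations are conventional for this analysis and both yield 20
baseline bins:

* fine:   50-ms bins, 1-s baseline  (transient, short-latency responses)
* coarse: 1-s bins,  20-s baseline  (sustained responses over the 30-s CS)

All bins are half-open ``[lo, hi)``; a spike exactly at a bin's upper edge
belongs to the next bin, and a spike exactly at the window's end is
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "SpikeTrain",
    "AlignedTrials",
    "BinnedCounts",
    "BaselineStats",
    "ZProfile",
    "align_trials",
    "bin_counts",
    "zscore_profile",
    "spontaneous_rate",
]

#: required columns of an event-schedule table
EVENT_COLUMNS = ("session_id", "context", "trial_index", "cs_onset_s", "cs_offset_s")


@dataclass(frozen=True)
class SpikeTrain:
    """One unit's sorted spike timestamps (seconds) over a session."""

    unit_id: str
    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ParameterError(f"unit {self.unit_id}: times must be 1-D")
        if t.size and np.any(np.diff(t) < 0):
            raise ParameterError(f"unit {self.unit_id}: timestamps not sorted")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size


@dataclass
class AlignedTrials:
    """Per-trial spike times relative to CS onset, with context labels."""

    unit_id: str
    window: tuple[float, float]
    rel_times: list[np.ndarray]
    contexts: list[str]
    trial_index: list[int]

    @property
    def n_trials(self) -> int:
        return len(self.rel_times)


@dataclass
class BinnedCounts:
    """Trials x bins spike-count matrix on a regular grid."""

    bin_width: float
    window: tuple[float, float]
    counts: np.ndarray  # (n_trials, n_bins), non-negative ints
    contexts: list[str] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def edges(self) -> np.ndarray:
        return self.window[0] + self.bin_width * np.arange(self.n_bins + 1)

    def bin_slice(self, lo: float, hi: float) -> slice:
        """Indices of the bins whose span covers ``[lo, hi)``.

        ``lo`` and ``hi`` must fall on the bin grid (within 1e-9 s).
        """
        w = self.bin_width
        i0 = (lo - self.window[0]) / w
        i1 = (hi - self.window[0]) / w
        if abs(i0 - round(i0)) > 1e-9 / w or abs(i1 - round(i1)) > 1e-9 / w:
            raise ParameterError(f"window ({lo}, {hi}) not aligned to {w}-s bin grid")
        i0, i1 = int(round(i0)), int(round(i1))
        if i0 < 0 or i1 > self.n_bins or i0 >= i1:
            raise ParameterError(f"window ({lo}, {hi}) outside binned range {self.window}")
        return slice(i0, i1)


@dataclass
class BaselineStats:
    """Mean and SD (counts/bin) of the baseline bins of a profile."""

    mean: float
    sd: float
    n_bins: int
    degenerate: bool  # sd == 0


@dataclass
class ZProfile:
    """Baseline-normalized trial-averaged profile of one unit.

    ``z[b] = (avg[b] - baseline.mean) / baseline.sd``; when the baseline is
    degenerate (zero SD) the z values are NaN and ``degenerate`` is set —
    downstream stages decide whether to exclude the unit.
    """

    unit_id: str
    bin_width: float
    window: tuple[float, float]
    z: np.ndarray
    avg: np.ndarray  # trial-averaged counts per bin
    baseline: BaselineStats
    baseline_window: tuple[float, float]
    n_trials: int

    @property
    def degenerate(self) -> bool:
        return self.baseline.degenerate

    def bin_slice(self, lo: float, hi: float) -> slice:
        dummy = BinnedCounts(self.bin_width, self.window, np.empty((0, self.z.size), int))
        return dummy.bin_slice(lo, hi)

    def window_values(self, lo: float, hi: float) -> np.ndarray:
        """Z values of the bins covering ``[lo, hi)``."""
        return self.z[self.bin_slice(lo, hi)]

    def window_mean(self, lo: float, hi: float) -> float:
        return float(np.mean(self.window_values(lo, hi)))


def align_trials(
    train: SpikeTrain,
    schedule: pd.DataFrame,
    window: tuple[float, float],
) -> AlignedTrials:
    """Express spike times relative to each trial's CS onset.

    Parameters
    ----------
    train
        Sorted spike timestamps for one unit.
    schedule
        Event table with at least ``cs_onset_s`` and ``context`` columns;
        one row per trial.
    window
        ``(start, end)`` in seconds relative to CS onset; spikes in
        ``[onset+start, onset+end)`` are kept (half-open).
    """
    start, end = window
    if not start < end:
        raise ParameterError(f"window start {start} must precede end {end}")
    t = train.times
    rel_times, contexts, idx = [], [], []
    for row in schedule.itertuples(index=False):
        onset = float(row.cs_onset_s)
        lo = np.searchsorted(t, onset + start, side="left")
        hi = np.searchsorted(t, onset + end, side="left")
        rel_times.append(t[lo:hi] - onset)
        contexts.append(str(row.context))
        idx.append(int(getattr(row, "trial_index", len(idx) + 1)))
    return AlignedTrials(train.unit_id, (start, end), rel_times, contexts, idx)


def bin_counts(
    aligned: AlignedTrials,
    bin_width: float,
    window: tuple[float, float] | None = None,
) -> BinnedCounts:
    """Count aligned spikes on a half-open bin grid.

    The window span must be an integer multiple of ``bin_width`` (to within
    1e-9 s). ``counts[t, b]`` is the number of trial-``t`` spikes in
    ``[start + b*w, start + (b+1)*w)``.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    start, end = window if window is not None else aligned.window
    if window is not None and (start < aligned.window[0] - 1e-12 or end > aligned.window[1] + 1e-12):
        raise ParameterError("binning window exceeds alignment window")
    n_f = (end - start) / bin_width
    if abs(n_f - round(n_f)) > 1e-9 / bin_width:
        raise ParameterError(
            f"window span {end - start} is not an integer multiple of bin width {bin_width}"
        )
    n_bins = int(round(n_f))
    edges = start + bin_width * np.arange(n_bins + 1)
    counts = np.zeros((aligned.n_trials, n_bins), dtype=np.int64)
    for i, rel in enumerate(aligned.rel_times):
        # side='right' puts a spike landing exactly on an edge in the upper bin
        b = np.searchsorted(edges, rel, side="right") - 1
        b = b[(b >= 0) & (b < n_bins)]
        np.add.at(counts[i], b, 1)
    return BinnedCounts(bin_width, (start, end), counts, list(aligned.contexts))


def zscore_profile(
    binned: BinnedCounts,
    baseline_window: tuple[float, float],
    unit_id: str = "",
    pool_trials: bool = False,
) -> ZProfile:
    """Normalize a trial-averaged profile to its pre-CS baseline bins.

    The default computes baseline mean and sample SD (ddof=1) over the
    baseline bins of the *trial-averaged* profile; with ``pool_trials``
    the statistics are instead taken over all trial x baseline-bin counts.
    A zero-SD baseline sets the ``degenerate`` flag and NaN z values
    rather than raising, so callers can apply the exclusion rule.
    """
    lo, hi = baseline_window
    if hi > 0 + 1e-12:
        raise ParameterError("baseline window must precede CS onset (end <= 0)")
    sl = binned.bin_slice(lo, hi)  # raises if not covered / off-grid
    avg = binned.counts.mean(axis=0) if binned.counts.shape[0] else np.zeros(binned.n_bins)
    if pool_trials:
        base_vals = binned.counts[:, sl].ravel().astype(float)
    else:
        base_vals = avg[sl]
    if base_vals.size < 2:
        raise ParameterError("baseline must span at least 2 bins")
    mean = float(base_vals.mean())
    sd = float(base_vals.std(ddof=1))
    degenerate = sd == 0.0
    z = np.full_like(avg, np.nan, dtype=float) if degenerate else (avg - mean) / sd
    stats = BaselineStats(mean, sd, int(sl.stop - sl.start), degenerate)
    return ZProfile(
        unit_id, binned.bin_width, binned.window, z, avg, stats,
        baseline_window, binned.counts.shape[0],
    )


def spontaneous_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Mean firing rate (spikes/s) over an absolute time window.

    Conventionally the pre-tone exposure period (180 s before the first CS).
    """
    t0, t1 = window
    if not t1 > t0:
        raise ParameterError("spontaneous-rate window must have positive duration")
    n = np.searchsorted(train.times, t1, side="left") - np.searchsorted(train.times, t0, side="left")
    return float(n) / (t1 - t0)
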