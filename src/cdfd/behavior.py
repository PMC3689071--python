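"""Behavioral metrics: freezing percentage and prepulse inhibition.

Freezing (immobility except respiration) is the fear index; it arrives
as manually annotated immobility intervals and is scored as the
percentage of an analysis window (conventionally the first CS
presentation of a session) spent immobile. Prepulse inhibition (PPI) is
the percentage reduction of the startle response by a preceding weaker
stimulus: PPI (%) = 100 x (SS - PS) / SS.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError

__all__ = [
    "FreezingRecord",
    "StartleSummary",
    "merge_intervals",
    "freezing_percentage",
    "ppi_percent",
    "startle_summary",
]


@dataclass
class FreezingRecord:
    subject_id: str
    intervals: list[tuple[float, float]]  # (start, end) s of immobility
    analysis_window: tuple[float, float]


@dataclass
class StartleSummary:
    """Mean startle amplitudes (load-cell arbitrary units)."""

    ss: float  # startle-stimulus-alone trials
    ps: float  # prepulse-startle trials


def merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of intervals: sorted, overlapping/touching runs coalesced."""
    for s, e in intervals:
        if not s < e:
            raise ParameterError(f"interval ({s}, {e}) must have start < end")
    merged: list[list[float]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def freezing_percentage(record: FreezingRecord) -> float:
    """Percentage of the analysis window covered by immobility.

    Overlapping annotations are merged first, so the result is the
    measure of the union intersected with the window, in [0, 100].
    """
    w0, w1 = record.analysis_window
    if not w1 > w0:
        raise ParameterError("analysis window must have positive duration")
    covered = 0.0
    for s, e in merge_intervals(record.intervals):
        covered += max(0.0, min(e, w1) - max(s, w0))
    return 100.0 * covered / (w1 - w0)


def ppi_percent(summary: StartleSummary) -> float:
    """PPI (%) = 100 x (SS - PS) / SS; requires SS > 0."""
    if summary.ss <= 0:
        raise ParameterError("PPI undefined: mean startle-alone amplitude must be positive")
    return 100.0 * (summary.ss - summary.ps) / summary.ss


def startle_summary(table: pd.DataFrame) -> StartleSummary:
    """Average amplitudes from a trial table (columns trial_type, amplitude).

    Recognized trial types: ``startle_alone`` and ``prepulse_startle``;
    other rows (prepulse-alone, no-stimulus) are ignored.
    """
    if not {"trial_type", "amplitude"} <= set(table.columns):
        raise ParameterError("startle table needs columns trial_type, amplitude")
    ss_rows = table.loc[table["trial_type"] == "startle_alone", "amplitude"]
    ps_rows = table.loc[table["trial_type"] == "prepulse_startle", "amplitude"]
    if ss_rows.empty or ps_rows.empty:
        raise ParameterError("startle table must contain both trial types")
    return StartleSummary(float(ss_rows.mean()), float(ps_rows.mean()))
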