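"""Responsive-unit classification by baseline Z-score criteria.

Two criteria are applied per unit, both on profiles normalized to 20
pre-CS baseline bins:

* short-latency CS-responsive: at 50-ms resolution (1-s baseline), the
  trial-averaged rate in at least one of the first 3 post-onset bins
  (the 0-150 ms window) exceeds 3 SDs above baseline, strictly.
* persistently firing unit (PFU): at 1-s resolution (20-s baseline),
  2 or more of the first 10 post-onset bins exceed 3 SDs, strictly.

Units whose baseline has zero variance (e.g. no baseline spikes) cannot
be scored against an SD threshold and are excluded with a recorded
reason rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import ZProfile
from .errors import DegenerateBaselineError, ParameterError

__all__ = [
    "UnitClassification",
    "classify_short_latency",
    "classify_persistent",
    "classify_population",
    "EXCLUSION_DEGENERATE",
    "EXCLUSION_MISSING",
]

EXCLUSION_DEGENERATE = "degenerate_baseline"
EXCLUSION_MISSING = "missing_profile"

FINE_BIN = 0.05
COARSE_BIN = 1.0


@dataclass
class UnitClassification:
    unit_id: str
    short_latency: bool
    persistent: bool
    excluded: bool
    exclusion_reason: str | None = None
    baseline_rate: float | None = None

    @property
    def overlap(self) -> bool:
        return self.short_latency and self.persistent


def _check_profile(z: ZProfile, expected_bin: float, op: str) -> None:
    if abs(z.bin_width - expected_bin) > 1e-12:
        raise ParameterError(
            f"{op} expects {expected_bin}-s bins, got {z.bin_width}-s"
        )
    if z.degenerate:
        raise DegenerateBaselineError(
            f"unit {z.unit_id or '?'}: zero-variance baseline; classification refused"
        )


def classify_short_latency(
    z: ZProfile,
    threshold: float = 3.0,
    n_bins: int = 3,
) -> bool:
    """Short-latency criterion on a fine (50-ms) Z-profile.

    True iff any of the first ``n_bins`` post-onset bins (0-150 ms by
    default) is strictly above ``threshold``; a bin exactly at the
    threshold does not qualify.
    """
    _check_profile(z, FINE_BIN, "classify_short_latency")
    vals = z.window_values(0.0, n_bins * z.bin_width)
    return bool(np.max(vals) > threshold)


def classify_persistent(
    z: ZProfile,
    threshold: float = 3.0,
    window_bins: int = 10,
    min_bins: int = 2,
) -> bool:
    """Sustained-activity (PFU) criterion on a coarse (1-s) Z-profile.

    True iff at least ``min_bins`` of the first ``window_bins`` post-onset
    bins are strictly above ``threshold``.
    """
    _check_profile(z, COARSE_BIN, "classify_persistent")
    vals = z.window_values(0.0, window_bins * z.bin_width)
    return bool(np.sum(vals > threshold) >= min_bins)


def classify_population(
    fine_profiles: dict[str, ZProfile],
    coarse_profiles: dict[str, ZProfile],
    baseline_rates: dict[str, float] | None = None,
    threshold: float = 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Classify every unit and tally the population.

    Units missing either profile, or with a degenerate baseline at either
    resolution, are excluded with a reason. Returns a per-unit table and a
    summary with counts and percentages; ``n_total`` always equals
    ``n_analyzed + n_excluded``.
    """
    unit_ids = sorted(set(fine_profiles) | set(coarse_profiles))
    if not unit_ids:
        raise ParameterError("no units to classify")
    rows: list[UnitClassification] = []
    for uid in unit_ids:
        fine = fine_profiles.get(uid)
        coarse = coarse_profiles.get(uid)
        rate = None if baseline_rates is None else baseline_rates.get(uid)
        if fine is None or coarse is None:
            rows.append(UnitClassification(uid, False, False, True, EXCLUSION_MISSING, rate))
            continue
        if fine.degenerate or coarse.degenerate:
            rows.append(UnitClassification(uid, False, False, True, EXCLUSION_DEGENERATE, rate))
            continue
        rows.append(
            UnitClassification(
                uid,
                classify_short_latency(fine, threshold=threshold),
                classify_persistent(coarse, threshold=threshold),
                False,
                None,
                rate,
            )
        )
    table = pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in rows],
            "short_latency": [r.short_latency for r in rows],
            "persistent": [r.persistent for r in rows],
            "overlap": [r.overlap for r in rows],
            "excluded": [r.excluded for r in rows],
            "exclusion_reason": [r.exclusion_reason for r in rows],
            "baseline_rate_hz": [r.baseline_rate for r in rows],
        }
    )
    n_total = len(rows)
    n_excluded = int(table["excluded"].sum())
    n_sl = int(table["short_latency"].sum())
    n_pfu = int(table["persistent"].sum())
    n_overlap = int(table["overlap"].sum())
    summary = {
        "n_total": n_total,
        "n_analyzed": n_total - n_excluded,
        "n_excluded": n_excluded,
        "n_short_latency": n_sl,
        "n_persistent": n_pfu,
        "n_overlap": n_overlap,
        "pct_short_latency": 100.0 * n_sl / n_total,
        "pct_persistent": 100.0 * n_pfu / n_total,
    }
    return table, summary
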