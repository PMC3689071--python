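import numpy as np
import pytest

from cdfd.binning import BaselineStats, ZProfile, align_trials, bin_counts, zscore_profile
from cdfd.synthetic import SessionSpec, cohort_specs, generate_session


def make_zprofile(z, bin_width=1.0, window=None, unit_id="u", degenerate=False):
    """Construct a ZProfile directly from Z values (tests only)."""
    z = np.asarray(z, dtype=float)
    if window is None:
        window = (0.0, bin_width * z.size)
    baseline = BaselineStats(0.0, 0.0 if degenerate else 1.0, 20, degenerate)
    if degenerate:
        z = np.full_like(z, np.nan)
    return ZProfile(unit_id, bin_width, window, z, z.copy(), baseline, (-1.0, 0.0), 6)


def profiles_from(dataset, schedule, bin_width, window, baseline):
    """Z-profiles for every unit of a synthetic dataset over a schedule."""
    out = {}
    for uid, train in dataset.spike_trains.items():
        aligned = align_trials(train, schedule, window)
        out[uid] = zscore_profile(bin_counts(aligned, bin_width), baseline, unit_id=uid)
    return out


@pytest.fixture(scope="session")
def null_session():
    """60 units, equal gains in both contexts (no modulation)."""
    specs = cohort_specs(60, seed=202)
    return generate_session(specs, SessionSpec(seed=202))


@pytest.fixture(scope="session")
def null_session_large():
    """300 unmodulated units for distribution-level null checks."""
    specs = cohort_specs(300, seed=314)
    return generate_session(specs, SessionSpec(seed=314))


@pytest.fixture(scope="session")
def modulated_session():
    """8 units, half with fearful-context transient and sustained gains."""
    specs = cohort_specs(
        8, seed=7, modulated_fraction=0.5, transient_gain_A=6.0, sustained_gain_A=2.5
    )
    return generate_session(specs, SessionSpec(seed=7))
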