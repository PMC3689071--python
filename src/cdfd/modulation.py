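"""Context-modulation statistics.

Per-unit modulation is quantified by a paired t-statistic over the 30
matched 1-s CS bins of a unit's Z-profile in the fearful context (A)
versus the safe context (B): with d[b] = zA[b] - zB[b],

    t = mean(d) / (sd(d) / sqrt(n)),   df = n - 1,

positive t meaning more activity in Context A. The raw sum of the bin
differences is retained alongside for transparency. At the population
level, the tools here provide the pos/neg direction chi-square, paired
window-mean tests across units, bin-wise population averages, and the
two-within-factor repeated-measures ANOVA used for the habituation
(early vs late trials) split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .binning import SpikeTrain, ZProfile, align_trials, bin_counts, zscore_profile
from .errors import ParameterError

__all__ = [
    "ModulationResult",
    "PopulationProfile",
    "AnovaTable",
    "paired_bin_t",
    "proportion_chisq",
    "window_mean_test",
    "population_profile",
    "two_within_anova",
    "mixed_anova",
    "habituation_split",
]


@dataclass
class ModulationResult:
    """Outcome of the paired-bin context-modulation test for one unit."""

    unit_id: str
    t: float  # NaN when degenerate
    df: int
    p: float  # two-tailed; NaN when degenerate
    significant: bool
    direction: str  # 'positive' | 'negative' | 'none'
    raw_sum: float  # sum of z differences over the matched bins
    degenerate: bool = False


@dataclass
class PopulationProfile:
    """Bin-wise mean +/- SE of Z-profiles across units, one context."""

    context: str
    bin_width: float
    window: tuple[float, float]
    mean_z: np.ndarray
    se_z: np.ndarray  # NaN for a single unit
    n_units: int


@dataclass
class AnovaTable:
    """Repeated-measures ANOVA effects; F is NaN when its error SS is 0."""

    effects: pd.DataFrame  # rows: effect; cols: ss, df, ss_error, df_error, F, p
    cell_means: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def effect(self, name: str) -> pd.Series:
        return self.effects.loc[name]


def _zero_variance(d: np.ndarray) -> bool:
    """Treat sub-rounding-error spread as zero variance."""
    scale = max(1.0, float(np.max(np.abs(d))))
    return float(d.std(ddof=1)) <= 1e-12 * scale


def _paired_t(d: np.ndarray) -> tuple[float, int, float]:
    """Textbook paired t on a difference vector; caller handles sd==0."""
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def paired_bin_t(
    zA: np.ndarray,
    zB: np.ndarray,
    alpha: float = 0.05,
    unit_id: str = "",
) -> ModulationResult:
    """Paired t over matched Z-score bins, Context A minus Context B.

    A zero-variance difference vector with nonzero mean is degenerate:
    the direction is still reported but t is undefined and significance
    is not claimed. An all-zero difference yields t = 0.
    """
    zA = np.asarray(zA, dtype=float)
    zB = np.asarray(zB, dtype=float)
    if zA.shape != zB.shape or zA.ndim != 1 or zA.size < 2:
        raise ParameterError("paired_bin_t needs two equal-length 1-D vectors, length >= 2")
    if not (np.all(np.isfinite(zA)) and np.all(np.isfinite(zB))):
        raise ParameterError("paired_bin_t requires finite Z values")
    d = zA - zB
    n = d.size
    raw_sum = float(d.sum())
    if _zero_variance(d):
        if d.mean() == 0.0:
            return ModulationResult(unit_id, 0.0, n - 1, 1.0, False, "none", raw_sum)
        direction = "positive" if d.mean() > 0 else "negative"
        return ModulationResult(
            unit_id, float("nan"), n - 1, float("nan"), False, direction, raw_sum, degenerate=True
        )
    t, df, p = _paired_t(d)
    significant = p < alpha
    direction = ("positive" if t > 0 else "negative") if significant else "none"
    return ModulationResult(unit_id, t, df, p, significant, direction, raw_sum)


def proportion_chisq(n_pos: int, n_neg: int, n_total: int) -> tuple[float, int, float]:
    """Pearson chi-square (df=1, no continuity correction) comparing the
    proportion of significant-positive vs significant-negative units.

    The 2x2 table is ``[[n_pos, n_total - n_pos], [n_neg, n_total - n_neg]]``:
    each row contrasts one direction's significant count against the rest
    of the same population of ``n_total`` units.
    """
    if n_total <= 0:
        raise ParameterError("n_total must be positive")
    if min(n_pos, n_neg) < 0 or n_pos + n_neg > n_total:
        raise ParameterError("counts must satisfy 0 <= n_pos + n_neg <= n_total")
    obs = np.array([[n_pos, n_total - n_pos], [n_neg, n_total - n_neg]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if np.any(col == 0):
        raise ParameterError("chi-square undefined: a table margin is empty")
    expected = row * col / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi2, 1))
    return chi2, 1, p


def window_mean_test(
    profiles_A: dict[str, ZProfile],
    profiles_B: dict[str, ZProfile],
    window: tuple[float, float],
    alpha: float = 0.05,
) -> dict:
    """Paired t across units on per-unit window-mean Z values.

    Each unit contributes its mean Z over ``window`` in each context; the
    unit-wise A-B differences are tested with a paired t (df = n_units-1).
    Requires the same unit ids in both contexts and at least 2 units.
    """
    if set(profiles_A) != set(profiles_B):
        raise ParameterError("window_mean_test requires matched unit ids across contexts")
    units = sorted(profiles_A)
    if len(units) < 2:
        raise ParameterError("window_mean_test requires at least 2 units")
    mA = np.array([profiles_A[u].window_mean(*window) for u in units])
    mB = np.array([profiles_B[u].window_mean(*window) for u in units])
    d = mA - mB
    out = {
        "window_s": list(window),
        "n_units": len(units),
        "mean_A": float(mA.mean()),
        "mean_B": float(mB.mean()),
        "mean_diff": float(d.mean()),
    }
    if _zero_variance(d):
        if d.mean() == 0.0:  # identical profiles across contexts
            out.update(t=0.0, df=len(units) - 1, p=1.0, significant=False, degenerate=False)
        else:
            out.update(t=None, df=len(units) - 1, p=None, significant=False, degenerate=True)
        return out
    t, df, p = _paired_t(d)
    out.update(t=t, df=df, p=p, significant=bool(p < alpha), degenerate=False)
    return out


def population_profile(profiles: dict[str, ZProfile], context: str = "") -> PopulationProfile:
    """Average Z-profiles bin-wise across units (population PSTH)."""
    if not profiles:
        raise ParameterError("population_profile requires at least 1 unit")
    vals = list(profiles.values())
    ref = vals[0]
    for z in vals[1:]:
        if z.window != ref.window or abs(z.bin_width - ref.bin_width) > 1e-12:
            raise ParameterError("population_profile: mismatched bin grids across units")
    mat = np.vstack([z.z for z in vals])
    mean = mat.mean(axis=0)
    if len(vals) > 1:
        se = mat.std(axis=0, ddof=1) / np.sqrt(len(vals))
    else:
        se = np.full(mat.shape[1], np.nan)
    return PopulationProfile(context, ref.bin_width, ref.window, mean, se, len(vals))


# --------------------------------------------------------------------------
# repeated-measures ANOVA (two within-subject factors) and the mixed design
# --------------------------------------------------------------------------

def two_within_anova(
    data: np.ndarray,
    factor_names: tuple[str, str] = ("context", "phase"),
) -> AnovaTable:
    """Two-within-factor repeated-measures ANOVA by full SS decomposition.

    ``data[s, i, j]`` holds subject s's cell mean at level i of the first
    factor and level j of the second. Each effect is tested against its
    own subject-interaction error term (the standard univariate
    within-subject decomposition):

        F_A  = MS_A  / MS_{A x S}
        F_B  = MS_B  / MS_{B x S}
        F_AB = MS_AB / MS_{A x B x S}

    With a zero error SS (e.g. all cells identical) the F is undefined
    and reported as NaN with a note.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ParameterError("two_within_anova expects a (subjects, a, b) array")
    n, a, b = y.shape
    if n < 2 or a < 2 or b < 2:
        raise ParameterError("need >= 2 subjects and >= 2 levels per factor")
    if not np.all(np.isfinite(y)):
        raise ParameterError("two_within_anova requires finite cell values")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))        # per subject
    m_a = y.mean(axis=(0, 2))        # per level of A
    m_b = y.mean(axis=(0, 1))        # per level of B
    m_sa = y.mean(axis=2)            # (n, a)
    m_sb = y.mean(axis=1)            # (n, b)
    m_ab = y.mean(axis=0)            # (a, b)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    rows = []
    notes: list[str] = []
    fa, fb = factor_names
    for name, ss, df, ss_e, df_e in [
        (fa, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (fb, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        (f"{fa}:{fb}", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ]:
        if ss_e > 0:
            F = (ss / df) / (ss_e / df_e)
            p = float(sps.f.sf(F, df, df_e))
        else:
            F, p = float("nan"), float("nan")
            notes.append(f"{name}: zero error SS, F undefined")
        rows.append(dict(effect=name, ss=float(ss), df=df, ss_error=float(ss_e),
                         df_error=df_e, F=float(F), p=p))
    eff = pd.DataFrame(rows).set_index("effect")
    return AnovaTable(eff, notes=notes)


def mixed_anova(
    data: np.ndarray,
    groups: np.ndarray,
    factor_names: tuple[str, str] = ("group", "within"),
) -> AnovaTable:
    """Split-plot ANOVA: one between-subject and one within-subject factor.

    ``data[s, j]`` is subject s's value at within-level j; ``groups[s]``
    assigns each subject to a between-group. Provided as supporting
    plumbing for group x context behavioral designs.
    """
    y = np.asarray(data, dtype=float)
    g = np.asarray(groups)
    if y.ndim != 2 or g.shape != (y.shape[0],):
        raise ParameterError("mixed_anova expects (subjects, within) data and per-subject groups")
    levels = np.unique(g)
    n, k = y.shape
    if levels.size < 2 or k < 2:
        raise ParameterError("need >= 2 groups and >= 2 within levels")
    counts = np.array([(g == lv).sum() for lv in levels])
    if counts.min() < 2:
        raise ParameterError("each group needs >= 2 subjects")

    grand = y.mean()
    m_s = y.mean(axis=1)
    m_g = np.array([y[g == lv].mean() for lv in levels])
    m_w = y.mean(axis=0)
    m_gw = np.vstack([y[g == lv].mean(axis=0) for lv in levels])

    ss_group = k * np.sum(counts * (m_g - grand) ** 2)
    ss_subj_within_g = k * sum(
        np.sum((m_s[g == lv] - m_g[i]) ** 2) for i, lv in enumerate(levels)
    )
    ss_within = n * np.sum((m_w - grand) ** 2)
    ss_gw = sum(
        counts[i] * np.sum((m_gw[i] - m_g[i] - m_w + grand) ** 2)
        for i in range(levels.size)
    )
    ss_total = np.sum((y - grand) ** 2)
    ss_err_within = ss_total - ss_group - ss_subj_within_g - ss_within - ss_gw

    df_g = levels.size - 1
    df_sg = n - levels.size
    df_w = k - 1
    df_gw = df_g * df_w
    df_ew = df_sg * df_w

    rows, notes = [], []
    fg, fw = factor_names
    for name, ss, df, ss_e, df_e in [
        (fg, ss_group, df_g, ss_subj_within_g, df_sg),
        (fw, ss_within, df_w, ss_err_within, df_ew),
        (f"{fg}:{fw}", ss_gw, df_gw, ss_err_within, df_ew),
    ]:
        if ss_e > 0:
            F = (ss / df) / (ss_e / df_e)
            p = float(sps.f.sf(F, df, df_e))
        else:
            F, p = float("nan"), float("nan")
            notes.append(f"{name}: zero error SS, F undefined")
        rows.append(dict(effect=name, ss=float(max(ss, 0.0)), df=df,
                         ss_error=float(max(ss_e, 0.0)), df_error=df_e, F=float(F), p=p))
    eff = pd.DataFrame(rows).set_index("effect")
    return AnovaTable(eff, notes=notes)


# --------------------------------------------------------------------------
# habituation split: early vs late trials, context x phase RM ANOVA
# --------------------------------------------------------------------------

def habituation_split(
    trains: dict[str, SpikeTrain],
    schedule: pd.DataFrame,
    variant: str = "sustained",
    n_phase_trials: int = 3,
    alpha: float = 0.05,
) -> AnovaTable:
    """Split each context's trials into early/late phases and test
    context, phase, and their interaction across units.

    Per unit, context and phase, the trials of that phase are re-binned
    and re-normalized to that phase's own baseline bins, and the mean Z
    over the response window is the cell value. Variants:

    * ``'short_latency'``: 50-ms bins, 1-s baseline, 0-150 ms response
      window. Units with no baseline spikes in the early or late trials
      are excluded (their phase baseline is degenerate).
    * ``'sustained'``: 1-s bins, 20-s baseline, whole-CS (0-30 s) window.

    Units with a degenerate baseline in any cell are excluded; at least
    2 analyzable units are required.
    """
    if variant == "short_latency":
        bw, window, baseline, resp = 0.05, (-1.0, 3.0), (-1.0, 0.0), (0.0, 0.15)
    elif variant == "sustained":
        bw, window, baseline, resp = 1.0, (-20.0, 30.0), (-20.0, 0.0), (0.0, 30.0)
    else:
        raise ParameterError(f"unknown variant {variant!r}")

    contexts = list(dict.fromkeys(schedule["context"]))
    if len(contexts) != 2:
        raise ParameterError("habituation_split requires exactly 2 contexts")

    cells: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for uid in sorted(trains):
        train = trains[uid]
        cell = np.full((2, 2), np.nan)
        ok = True
        for ci, ctx in enumerate(contexts):
            rows = schedule[schedule["context"] == ctx].sort_values("trial_index")
            if len(rows) < 2 * n_phase_trials:
                raise ParameterError(
                    f"context {ctx}: need >= {2 * n_phase_trials} trials for the split"
                )
            for pi, phase_rows in enumerate((rows.iloc[:n_phase_trials],
                                             rows.iloc[-n_phase_trials:])):
                aligned = align_trials(train, phase_rows, window)
                prof = zscore_profile(bin_counts(aligned, bw), baseline, unit_id=uid)
                if prof.degenerate:
                    ok = False
                    break
                cell[ci, pi] = prof.window_mean(*resp)
            if not ok:
                break
        if ok:
            cells[uid] = cell
        else:
            excluded.append(uid)
    if len(cells) < 2:
        raise ParameterError(
            f"habituation_split: fewer than 2 analyzable units ({len(excluded)} excluded)"
        )
    data = np.stack([cells[u] for u in sorted(cells)])
    table = two_within_anova(data, ("context", "phase"))
    cm = pd.DataFrame(
        [
            dict(unit_id=u, context=ctx, phase=ph, mean_z=cells[u][ci, pi])
            for u in sorted(cells)
            for ci, ctx in enumerate(contexts)
            for pi, ph in enumerate(("early", "late"))
        ]
    )
    table.cell_means = cm
    if excluded:
        table.notes.append(f"excluded units (degenerate phase baseline): {excluded}")
    return table
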