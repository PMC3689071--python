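"""End-to-end orchestration: spikes + events in, report out.

The pipeline classifies every unit (short-latency and persistent
criteria on pooled-trial profiles), computes per-unit context-modulation
t-values on per-context 1-s profiles, tallies the direction chi-square
among persistently firing units, runs the paired window-mean tests and
the habituation (early/late) ANOVAs, averages population profiles, and
scores any behavioral annotations provided. Everything is deterministic
given the inputs; no unit is dropped silently.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from .binning import SpikeTrain, ZProfile, align_trials, bin_counts, spontaneous_rate, zscore_profile
from .classification import EXCLUSION_DEGENERATE, classify_population
from .errors import DataFormatError, ParameterError, PipelineError
from .modulation import (
    habituation_split,
    paired_bin_t,
    population_profile,
    proportion_chisq,
    window_mean_test,
)

log = logging.getLogger("cdfd.pipeline")

__all__ = ["PipelineConfig", "Report", "run_pipeline", "write_report", "validate_summary"]


@dataclass
class PipelineConfig:
    """Fixed analysis constants; defaults are the study's conventions."""

    fine_bin: float = 0.05
    fine_window: tuple[float, float] = (-1.0, 3.0)
    fine_baseline: tuple[float, float] = (-1.0, 0.0)
    coarse_bin: float = 1.0
    coarse_window: tuple[float, float] = (-20.0, 30.0)
    coarse_baseline: tuple[float, float] = (-20.0, 0.0)
    sd_threshold: float = 3.0
    alpha: float = 0.05
    short_latency_window: float = 0.15  # s (first 3 fine bins)
    persistent_window: float = 10.0  # s (first 10 coarse bins)
    cs_duration: float = 30.0
    pre_tone_duration: float = 180.0
    pool_baseline_trials: bool = False
    classification_context: str = "pooled"  # or a context label
    run_habituation: bool = True

    def __post_init__(self):
        if self.sd_threshold <= 0:
            raise ParameterError("sd_threshold must be positive")
        for w, bw, name in (
            (self.fine_window, self.fine_bin, "fine"),
            (self.coarse_window, self.coarse_bin, "coarse"),
        ):
            n = (w[1] - w[0]) / bw
            if abs(n - round(n)) > 1e-9:
                raise ParameterError(f"{name} window not divisible by its bin width")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise DataFormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fine_window", "fine_baseline", "coarse_window", "coarse_baseline"):
            if key in known:
                known[key] = tuple(known[key])
        return cls(**known)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


@dataclass
class Report:
    units: pd.DataFrame
    population: pd.DataFrame
    summary: dict
    habituation_cells: dict[str, pd.DataFrame] = field(default_factory=dict)


def _profiles(
    trains: dict[str, SpikeTrain],
    schedule: pd.DataFrame,
    bin_width: float,
    window: tuple[float, float],
    baseline: tuple[float, float],
    pool_trials: bool,
) -> dict[str, ZProfile]:
    out = {}
    for uid in sorted(trains):
        aligned = align_trials(trains[uid], schedule, window)
        out[uid] = zscore_profile(
            bin_counts(aligned, bin_width), baseline, unit_id=uid, pool_trials=pool_trials
        )
    return out


def _anova_to_dict(table) -> dict:
    effects = {}
    for name, row in table.effects.iterrows():
        effects[name] = {
            k: (None if isinstance(v, float) and math.isnan(v) else (float(v) if k not in ("df", "df_error") else int(v)))
            for k, v in row.items()
        }
    return {"effects": effects, "notes": list(table.notes)}


def _nan_to_none(obj):
    if isinstance(obj, dict):
        return {k: _nan_to_none(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_nan_to_none(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(
    trains: dict[str, SpikeTrain],
    events: pd.DataFrame,
    config: PipelineConfig | None = None,
    freezing: pd.DataFrame | None = None,
    startle: pd.DataFrame | None = None,
) -> Report:
    """Run the full analysis; see the module docstring for the stages."""
    cfg = config or PipelineConfig()
    if not trains:
        raise PipelineError("input", None, "no spike trains provided")
    contexts = list(dict.fromkeys(events["context"]))
    paired = len(contexts) == 2

    # -- spontaneous rates from each context's pre-tone exposure period
    pre_tone_rates: dict[str, dict[str, float]] = {}
    for ctx in contexts:
        first = float(events.loc[events["context"] == ctx, "cs_onset_s"].min())
        w = (first - cfg.pre_tone_duration, first)
        pre_tone_rates[ctx] = {uid: spontaneous_rate(trains[uid], w) for uid in sorted(trains)}
    baseline_rates = {
        uid: float(np.mean([pre_tone_rates[c][uid] for c in contexts])) for uid in sorted(trains)
    }

    # -- classification on pooled (or single-context) trials
    if cfg.classification_context == "pooled":
        class_sched = events
    else:
        if cfg.classification_context not in contexts:
            raise PipelineError("classification", None,
                                f"unknown classification context {cfg.classification_context!r}")
        class_sched = events[events["context"] == cfg.classification_context]
    try:
        fine_pooled = _profiles(trains, class_sched, cfg.fine_bin, cfg.fine_window,
                                cfg.fine_baseline, cfg.pool_baseline_trials)
        coarse_pooled = _profiles(trains, class_sched, cfg.coarse_bin, cfg.coarse_window,
                                  cfg.coarse_baseline, cfg.pool_baseline_trials)
    except ParameterError as exc:
        raise PipelineError("binning", None, str(exc)) from exc
    units_table, class_summary = classify_population(
        fine_pooled, coarse_pooled, baseline_rates, threshold=cfg.sd_threshold
    )
    for _, row in units_table[units_table["excluded"]].iterrows():
        log.info("excluded unit %s: %s", row["unit_id"], row["exclusion_reason"])

    # -- per-context profiles for modulation and window tests
    fine_ctx: dict[str, dict[str, ZProfile]] = {}
    coarse_ctx: dict[str, dict[str, ZProfile]] = {}
    for ctx in contexts:
        sched = events[events["context"] == ctx]
        fine_ctx[ctx] = _profiles(trains, sched, cfg.fine_bin, cfg.fine_window,
                                  cfg.fine_baseline, cfg.pool_baseline_trials)
        coarse_ctx[ctx] = _profiles(trains, sched, cfg.coarse_bin, cfg.coarse_window,
                                    cfg.coarse_baseline, cfg.pool_baseline_trials)

    mod_cols = {c: [] for c in ("t_value", "t_df", "t_p", "t_significant", "t_direction",
                                "t_raw_sum", "t_degenerate")}
    modulation_summary: dict = {"n_tested": 0, "n_significant_positive": 0,
                                "n_significant_negative": 0, "chi_square": None, "notes": []}
    if paired:
        cA, cB = contexts
        persistent_ids = set(units_table.loc[units_table["persistent"], "unit_id"])
        n_pos = n_neg = n_tested = 0
        per_unit: dict[str, dict] = {}
        for uid in units_table["unit_id"]:
            pA, pB = coarse_ctx[cA].get(uid), coarse_ctx[cB].get(uid)
            if pA is None or pB is None or pA.degenerate or pB.degenerate:
                per_unit[uid] = dict(t_value=np.nan, t_df=np.nan, t_p=np.nan,
                                     t_significant=False, t_direction="none",
                                     t_raw_sum=np.nan, t_degenerate=True)
                continue
            res = paired_bin_t(
                pA.window_values(0.0, cfg.cs_duration),
                pB.window_values(0.0, cfg.cs_duration),
                alpha=cfg.alpha, unit_id=uid,
            )
            per_unit[uid] = dict(t_value=res.t, t_df=res.df, t_p=res.p,
                                 t_significant=res.significant, t_direction=res.direction,
                                 t_raw_sum=res.raw_sum, t_degenerate=res.degenerate)
            if uid in persistent_ids and not res.degenerate:
                n_tested += 1
                if res.significant and res.direction == "positive":
                    n_pos += 1
                elif res.significant and res.direction == "negative":
                    n_neg += 1
        for uid in units_table["unit_id"]:
            for k in mod_cols:
                mod_cols[k].append(per_unit[uid][k])
        modulation_summary.update(
            n_tested=n_tested, n_significant_positive=n_pos, n_significant_negative=n_neg
        )
        if n_tested:
            try:
                chi2, dfree, p = proportion_chisq(n_pos, n_neg, n_tested)
                modulation_summary["chi_square"] = {
                    "chi2": chi2, "df": dfree, "p": p,
                    "significant": bool(p < cfg.alpha),
                }
            except ParameterError as exc:
                modulation_summary["notes"].append(f"chi-square not computed: {exc}")
        else:
            modulation_summary["notes"].append("no analyzable persistent units")
    else:
        modulation_summary["notes"].append(
            f"paired statistics need exactly 2 contexts, got {len(contexts)}"
        )
        for k in mod_cols:
            mod_cols[k] = [np.nan if k not in ("t_significant", "t_degenerate") else False
                           for _ in range(len(units_table))]
            if k == "t_direction":
                mod_cols[k] = ["none"] * len(units_table)
    for k, v in mod_cols.items():
        units_table[k] = v

    # -- paired window-mean tests across units
    window_tests: dict[str, dict | None] = {}
    if paired:
        cA, cB = contexts

        def _run_window(ids, profs_by_ctx, window, label):
            usable = [u for u in ids
                      if u in profs_by_ctx[cA] and u in profs_by_ctx[cB]
                      and not profs_by_ctx[cA][u].degenerate
                      and not profs_by_ctx[cB][u].degenerate]
            if len(usable) < 2:
                window_tests[label] = None
                return
            window_tests[label] = window_mean_test(
                {u: profs_by_ctx[cA][u] for u in usable},
                {u: profs_by_ctx[cB][u] for u in usable},
                window, alpha=cfg.alpha,
            )

        sl_ids = list(units_table.loc[units_table["short_latency"], "unit_id"])
        pfu_ids = list(units_table.loc[units_table["persistent"], "unit_id"])
        _run_window(sl_ids, fine_ctx, (0.0, cfg.short_latency_window), "short_latency_0_150ms")
        _run_window(pfu_ids, coarse_ctx, (0.0, cfg.persistent_window), "persistent_first_10s")
        _run_window(pfu_ids, coarse_ctx, (0.0, cfg.cs_duration), "persistent_full_cs")

    # -- population profiles (per context, both resolutions)
    pop_rows = []
    for label, profs_by_ctx, bw in (("fine", fine_ctx, cfg.fine_bin),
                                    ("coarse", coarse_ctx, cfg.coarse_bin)):
        for ctx in contexts:
            usable = {u: p for u, p in profs_by_ctx[ctx].items() if not p.degenerate}
            if not usable:
                continue
            pop = population_profile(usable, ctx)
            starts = pop.window[0] + bw * np.arange(pop.mean_z.size)
            for b, t0 in enumerate(starts):
                pop_rows.append(dict(resolution=label, context=ctx,
                                     bin_start_s=round(float(t0), 9),
                                     mean_z=float(pop.mean_z[b]),
                                     se_z=float(pop.se_z[b]), n_units=pop.n_units))
    population = pd.DataFrame(pop_rows)

    # -- habituation split (early vs late trials)
    habituation: dict[str, dict | None] = {}
    hab_cells: dict[str, pd.DataFrame] = {}
    if cfg.run_habituation and paired:
        for variant in ("short_latency", "sustained"):
            try:
                table = habituation_split(trains, events, variant=variant)
                habituation[variant] = _anova_to_dict(table)
                hab_cells[variant] = table.cell_means
            except ParameterError as exc:
                habituation[variant] = None
                log.info("habituation %s skipped: %s", variant, exc)

    # -- spontaneous-rate context comparison
    spont: dict = {
        "per_context_mean_hz": {c: float(np.mean(list(pre_tone_rates[c].values())))
                                for c in contexts}
    }
    if paired and len(trains) >= 2:
        cA, cB = contexts
        rA = np.array([pre_tone_rates[cA][u] for u in sorted(trains)])
        rB = np.array([pre_tone_rates[cB][u] for u in sorted(trains)])
        d = rA - rB
        if d.std(ddof=1) > 0:
            from .modulation import _paired_t

            t, dfree, p = _paired_t(d)
            spont["paired_t"] = {"t": t, "df": dfree, "p": p}

    # -- behavior
    behavior_summary: dict = {}
    if freezing is not None:
        first_cs = {c: events[events["context"] == c].sort_values("trial_index").iloc[0]
                    for c in contexts}
        rows = []
        for sid, grp in freezing.groupby("subject_id", sort=True):
            ivals = [(float(s), float(e)) for s, e in zip(grp["start_s"], grp["end_s"])]
            for ctx in contexts:
                w = (float(first_cs[ctx]["cs_onset_s"]), float(first_cs[ctx]["cs_offset_s"]))
                pct = bhv.freezing_percentage(bhv.FreezingRecord(str(sid), ivals, w))
                rows.append(dict(subject_id=str(sid), context=ctx, freezing_pct=pct))
        ftab = pd.DataFrame(rows)
        behavior_summary["freezing"] = {
            "per_context_mean_pct": {c: float(ftab.loc[ftab["context"] == c, "freezing_pct"].mean())
                                     for c in contexts},
            "n_subjects": int(ftab["subject_id"].nunique()),
        }
    if startle is not None:
        summary = bhv.startle_summary(startle)
        behavior_summary["ppi"] = {"ss": summary.ss, "ps": summary.ps,
                                   "ppi_percent": bhv.ppi_percent(summary)}

    summary = _nan_to_none({
        "contexts": contexts,
        "classification": class_summary,
        "modulation": modulation_summary,
        "window_tests": window_tests,
        "habituation": habituation,
        "spontaneous": spont,
        "behavior": behavior_summary,
        "exclusions": [
            {"unit_id": r["unit_id"], "reason": r["exclusion_reason"]}
            for _, r in units_table[units_table["excluded"]].iterrows()
        ],
        "config": asdict(cfg),
    })
    validate_summary(summary)
    return Report(units_table, population, summary, hab_cells)


_SUMMARY_REQUIRED = {
    "contexts": list,
    "classification": dict,
    "modulation": dict,
    "window_tests": dict,
    "habituation": dict,
    "spontaneous": dict,
    "behavior": dict,
    "exclusions": list,
    "config": dict,
}


def validate_summary(summary: dict) -> None:
    """Structural check of the summary object before serialization."""
    for key, typ in _SUMMARY_REQUIRED.items():
        if key not in summary:
            raise DataFormatError(f"summary missing key {key!r}")
        if not isinstance(summary[key], typ):
            raise DataFormatError(f"summary[{key!r}] must be {typ.__name__}")
    cls = summary["classification"]
    for key in ("n_total", "n_analyzed", "n_excluded", "n_short_latency",
                "n_persistent", "n_overlap"):
        if not isinstance(cls.get(key), int):
            raise DataFormatError(f"classification[{key!r}] must be an int")
    if cls["n_total"] != cls["n_analyzed"] + cls["n_excluded"]:
        raise DataFormatError("classification counts do not add up")


def write_report(report: Report, outdir: str | Path) -> dict[str, Path]:
    """Write units.csv, population.csv and summary.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "units": outdir / "units.csv",
        "population": outdir / "population.csv",
        "summary": outdir / "summary.json",
    }
    report.units.to_csv(paths["units"], index=False)
    report.population.to_csv(paths["population"], index=False)
    paths["summary"].write_text(
        json.dumps(report.summary, indent=2, sort_keys=True, allow_nan=False) + "\n"
    )
    return paths
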