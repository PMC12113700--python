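"""End-to-end study orchestration.

Cohort (simulated or read from disk) -> filtered channels -> behavior-
aligned traces -> per-trace band table -> the three statistical analyses
(intergroup per week, intragroup across weeks, duration-power
correlation) plus the behavior-duration comparison -> CSV report tables
and a run log.

The experimental unit defaults to the rat: the (up to 5) trace values of
a rat x week x structure x behavior cell are aggregated by their mean
before testing, making n the number of rats per group.  The aggregation
rule is a config switch and is stamped into every output table.

Post hoc week-pair tests are emitted only where the Friedman test is
significant, with Holm adjustment applied within each Friedman family
and no correction across the structure x behavior x week grid.
Normality/homoscedasticity diagnostics are computed and logged but never
gate the analysis.
"""

from __future__ import annotations

import itertools
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import BEHAVIORS, GROUPS, STRUCTURES, RecordingSession
from .preprocessing import (
    DEFAULT_MAX_TRACES,
    DEFAULT_TRACE_LEN,
    extract_traces,
    preprocess_channels,
)
from .spectral import DEFAULT_BANDS, band_table, periodogram
from .stats import (
    behavior_duration,
    friedman,
    holm_adjust,
    levene,
    lilliefors,
    mann_whitney_u,
    spearman,
    wilcoxon_signed_rank,
)
from .synthetic import CohortDesign, generate_cohort

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "reduced_config",
    "build_band_table",
    "durations_table",
    "aggregate_cells",
    "run_intergroup",
    "run_intragroup",
    "run_durations",
    "run_correlation",
    "run_all",
]

AGGREGATIONS = ("per-rat-mean", "per-rat-median", "per-trace")


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis parameters; defaults follow the recording protocol."""

    band: tuple[float, float] = (300.0, 500.0)  # band of interest
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    alpha: float = 0.05
    aggregation: str = "per-rat-mean"
    correlation_group: str = "experimental"
    trace_len: float = DEFAULT_TRACE_LEN
    max_traces: int = DEFAULT_MAX_TRACES
    bp_low: float = 300.0
    bp_high: float = 3000.0
    bp_order: int = 4
    notch_base: float | None = 60.0
    notch_q: float = 35.0
    diagnostics: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        if self.correlation_group not in GROUPS:
            raise ValueError(f"correlation_group must be one of {GROUPS}")
        if tuple(self.band) not in {tuple(b) for b in self.bands}:
            raise ValueError(f"band of interest {self.band} must be one of the analysis bands")


def reduced_config(**overrides) -> AnalysisConfig:
    """Desk-scale analysis config matching :func:`~cereb_band_psd.synthetic.reduced_design`:
    bands scaled by 1/5, 1 s traces, no notch."""
    base = dict(
        band=(60.0, 100.0),
        bands=tuple((lo / 5.0, hi / 5.0) for lo, hi in DEFAULT_BANDS),
        trace_len=1.0,
        bp_low=60.0,
        bp_high=600.0,
        notch_base=None,
    )
    base.update(overrides)
    return AnalysisConfig(**base)


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

BAND_COLUMNS = [
    "rat_id",
    "group",
    "week",
    "structure",
    "behavior",
    "window_start",
    "band_low",
    "band_high",
    "auc",
    "normalized_psd",
    "fraction",
]


def build_band_table(
    sessions: Iterable[RecordingSession],
    config: AnalysisConfig,
    behaviors: Sequence[str] = BEHAVIORS,
) -> tuple[pd.DataFrame, dict]:
    """Per-trace x band quantification table for a set of sessions.

    Returns the table and a bookkeeping dict with trace/exclusion counts.
    """
    rows: list[dict] = []
    counts = {"sessions": 0, "traces_ok": 0, "excluded_saturation": 0, "excluded_excursion": 0}
    for session in sessions:
        counts["sessions"] += 1
        channels = preprocess_channels(
            session,
            low=config.bp_low,
            high=config.bp_high,
            order=config.bp_order,
            notch_base=config.notch_base,
            notch_q=config.notch_q,
        )
        for behavior in behaviors:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                traces = extract_traces(
                    session,
                    behavior,
                    trace_len=config.trace_len,
                    max_traces=config.max_traces,
                    channels=channels,
                    include_flagged=True,
                )
            for tr in traces:
                if tr.qc != "ok":
                    counts[tr.qc] += 1
                    continue
                counts["traces_ok"] += 1
                psd = periodogram(tr.samples, tr.fs)
                for bp in band_table(psd, bands=config.bands):
                    rows.append(
                        {
                            "rat_id": tr.rat_id,
                            "group": tr.group,
                            "week": tr.week,
                            "structure": tr.structure,
                            "behavior": tr.behavior,
                            "window_start": tr.start_s,
                            "band_low": bp.band[0],
                            "band_high": bp.band[1],
                            "auc": bp.auc,
                            "normalized_psd": bp.normalized_psd,
                            "fraction": bp.fraction,
                        }
                    )
    df = pd.DataFrame(rows, columns=BAND_COLUMNS)
    return df, counts


def durations_table(sessions: Iterable[RecordingSession], behaviors: Sequence[str] = BEHAVIORS) -> pd.DataFrame:
    """Per rat x week x behavior total duration (s) and episode count."""
    rows = []
    for session in sessions:
        for b in behaviors:
            total, count = behavior_duration(session.episodes, b)
            rows.append(
                {
                    "rat_id": session.rat_id,
                    "group": session.group,
                    "week": session.week,
                    "behavior": b,
                    "duration_s": total,
                    "episode_count": count,
                }
            )
    return pd.DataFrame(rows, columns=["rat_id", "group", "week", "behavior", "duration_s", "episode_count"])


def aggregate_cells(band_df: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Reduce the per-trace band table to one value per experimental-unit
    cell for the band of interest, per the configured aggregation."""
    lo, hi = config.band
    sel = band_df[(band_df["band_low"] == lo) & (band_df["band_high"] == hi)]
    keys = ["group", "rat_id", "week", "structure", "behavior"]
    if config.aggregation == "per-trace":
        out = sel[keys + ["normalized_psd"]].rename(columns={"normalized_psd": "value"}).copy()
    else:
        how = "mean" if config.aggregation == "per-rat-mean" else "median"
        out = (
            sel.groupby(keys, as_index=False)["normalized_psd"].agg(how).rename(columns={"normalized_psd": "value"})
        )
    out["aggregation"] = config.aggregation
    return out


# ---------------------------------------------------------------------------
# Statistical analyses
# ---------------------------------------------------------------------------


def _iqr(v: np.ndarray) -> tuple[float, float]:
    return (float(np.percentile(v, 25)), float(np.percentile(v, 75)))


def run_intergroup(band_df: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Mann-Whitney control-vs-experimental comparison per
    structure x behavior x week, with group medians and IQRs."""
    cells = aggregate_cells(band_df, config)
    rows = []
    weeks = sorted(cells["week"].unique())
    for structure, behavior, week in itertools.product(
        sorted(cells["structure"].unique()), BEHAVIORS, weeks
    ):
        cell = cells[
            (cells["structure"] == structure) & (cells["behavior"] == behavior) & (cells["week"] == week)
        ]
        ctrl = cell.loc[cell["group"] == "control", "value"].to_numpy()
        expe = cell.loc[cell["group"] == "experimental", "value"].to_numpy()
        row = {
            "structure": structure,
            "behavior": behavior,
            "week": week,
            "n_control": ctrl.size,
            "n_experimental": expe.size,
            "aggregation": config.aggregation,
        }
        if ctrl.size == 0 or expe.size == 0:
            row.update(U=np.nan, p=np.nan, method="", significant=False, note="insufficient data")
        else:
            res = mann_whitney_u(ctrl, expe)
            q_c, q_e = _iqr(ctrl), _iqr(expe)
            row.update(
                U=res.statistic,
                p=res.p,
                method=res.method,
                significant=bool(res.p <= config.alpha),
                note="",
                median_control=float(np.median(ctrl)),
                iqr_low_control=q_c[0],
                iqr_high_control=q_c[1],
                median_experimental=float(np.median(expe)),
                iqr_low_experimental=q_e[0],
                iqr_high_experimental=q_e[1],
            )
        rows.append(row)
    return pd.DataFrame(rows)


def run_intragroup(
    band_df: pd.DataFrame, config: AnalysisConfig, group: str = "experimental"
) -> pd.DataFrame:
    """Friedman test across weeks per structure x behavior within one
    group; where significant, all week-pair Wilcoxon post hocs with Holm
    adjustment inside that family."""
    cells = aggregate_cells(band_df, config)
    cells = cells[cells["group"] == group]
    weeks = sorted(cells["week"].unique())
    rows = []
    for structure, behavior in itertools.product(sorted(cells["structure"].unique()), BEHAVIORS):
        cell = cells[(cells["structure"] == structure) & (cells["behavior"] == behavior)]
        pivot = cell.pivot_table(index="rat_id", columns="week", values="value")
        pivot = pivot.reindex(columns=weeks).dropna(axis=0)  # listwise-complete rats
        base = {"structure": structure, "behavior": behavior, "group": group, "aggregation": config.aggregation}
        if len(pivot) < 2 or len(weeks) < 2:
            rows.append(
                {**base, "test": "friedman", "week_pair": "", "statistic": np.nan, "p": np.nan,
                 "p_holm": np.nan, "n": len(pivot), "method": "", "significant": False,
                 "note": "insufficient complete blocks"}
            )
            continue
        res = friedman(pivot.to_numpy())
        fried_sig = bool(res.p <= config.alpha)
        rows.append(
            {**base, "test": "friedman", "week_pair": "", "statistic": res.statistic, "p": res.p,
             "p_holm": np.nan, "n": len(pivot), "method": res.method, "significant": fried_sig, "note": ""}
        )
        if not fried_sig:
            continue
        pairs = list(itertools.combinations(weeks, 2))
        results = [
            wilcoxon_signed_rank(pivot[w1].to_numpy(), pivot[w2].to_numpy()) for w1, w2 in pairs
        ]
        adj = holm_adjust([r.p for r in results])
        for (w1, w2), r, p_h in zip(pairs, results, adj):
            rows.append(
                {**base, "test": "wilcoxon", "week_pair": f"W{w1}-W{w2}", "statistic": r.statistic,
                 "p": r.p, "p_holm": float(p_h), "n": len(pivot), "method": r.method,
                 "significant": bool(p_h <= config.alpha), "note": ""}
            )
    return pd.DataFrame(rows)


def run_durations(sessions, config: AnalysisConfig) -> pd.DataFrame:
    """Mann-Whitney comparison of per-rat total behavior durations per
    behavior x week, with group medians.  Accepts sessions or a
    precomputed durations table."""
    dur = sessions if isinstance(sessions, pd.DataFrame) else durations_table(sessions)
    rows = []
    for behavior, week in itertools.product(BEHAVIORS, sorted(dur["week"].unique())):
        cell = dur[(dur["behavior"] == behavior) & (dur["week"] == week)]
        ctrl = cell.loc[cell["group"] == "control", "duration_s"].to_numpy()
        expe = cell.loc[cell["group"] == "experimental", "duration_s"].to_numpy()
        row = {"behavior": behavior, "week": week, "n_control": ctrl.size, "n_experimental": expe.size}
        if ctrl.size == 0 or expe.size == 0:
            row.update(U=np.nan, p=np.nan, method="", significant=False, note="insufficient data")
        else:
            res = mann_whitney_u(ctrl, expe)
            row.update(
                U=res.statistic, p=res.p, method=res.method,
                significant=bool(res.p <= config.alpha), note="",
                median_control=float(np.median(ctrl)), median_experimental=float(np.median(expe)),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def run_correlation(
    band_df: pd.DataFrame, durations: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Spearman correlation between total behavior duration and
    aggregated normalized PSD per structure x behavior.

    Pairing level (default): one pair per rat x week within the
    configured group, pooled across weeks.
    """
    cells = aggregate_cells(band_df, config)
    if config.aggregation == "per-trace":  # correlation always pairs at rat x week level
        cells = (
            cells.groupby(["group", "rat_id", "week", "structure", "behavior"], as_index=False)["value"].mean()
        )
    cells = cells[cells["group"] == config.correlation_group]
    dur = durations[durations["group"] == config.correlation_group]
    level = f"rat-week within {config.correlation_group}, pooled across weeks"
    rows = []
    for structure, behavior in itertools.product(sorted(cells["structure"].unique()), BEHAVIORS):
        psd_cell = cells[(cells["structure"] == structure) & (cells["behavior"] == behavior)]
        dur_cell = dur[dur["behavior"] == behavior]
        merged = psd_cell.merge(dur_cell, on=["rat_id", "week"], how="inner")
        row = {"structure": structure, "behavior": behavior, "level": level, "n": len(merged)}
        if len(merged) < 3:
            row.update(rho=np.nan, p=np.nan, method="", significant=False, note="fewer than 3 pairs")
        else:
            try:
                res = spearman(merged["duration_s"].to_numpy(), merged["value"].to_numpy(), level=level)
                row.update(rho=res.rho, p=res.p, method=res.method,
                           significant=bool(res.p <= config.alpha), note="")
            except ValueError as exc:
                row.update(rho=np.nan, p=np.nan, method="", significant=False, note=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def _diagnostics(band_df: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Lilliefors/Levene diagnostics per intergroup cell (logged, never gating)."""
    cells = aggregate_cells(band_df, config)
    lillie_n = lillie_reject = levene_n = levene_reject = 0
    for (_, _, _), cell in cells.groupby(["structure", "behavior", "week"]):
        groups = [g["value"].to_numpy() for _, g in cell.groupby("group")]
        for v in groups:
            if v.size >= 4 and np.std(v, ddof=1) > 0:
                lillie_n += 1
                if lilliefors(v, n_mc=2000, seed=config.seed).p <= config.alpha:
                    lillie_reject += 1
        if len(groups) == 2 and all(v.size >= 2 for v in groups):
            try:
                levene_n += 1
                if levene(groups).p <= config.alpha:
                    levene_reject += 1
            except ValueError:
                levene_n -= 1
    return {
        "lilliefors_cells": lillie_n,
        "lilliefors_rejections": lillie_reject,
        "levene_cells": levene_n,
        "levene_rejections": levene_reject,
    }


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisReport:
    """All four report tables plus the run log."""

    intergroup: pd.DataFrame
    intragroup: pd.DataFrame
    durations: pd.DataFrame
    correlation: pd.DataFrame
    log: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("intergroup", "intragroup", "durations", "correlation"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
        (out / "run_log.json").write_text(json.dumps(self.log, indent=2, sort_keys=True) + "\n")


def run_all(
    config: AnalysisConfig,
    design: CohortDesign | None = None,
    sessions: Iterable[RecordingSession] | None = None,
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Run the full study and (optionally) write the report tables.

    Sessions are either supplied directly or simulated from ``design``.
    Deterministic given (config, design): repeated runs produce
    byte-identical tables.
    """
    if sessions is None:
        if design is None:
            raise ValueError("provide either sessions or a cohort design")
        sessions = generate_cohort(design)

    # Stream sessions: quantify and discard, keeping memory flat.
    band_parts, dur_parts = [], []
    counts = {"sessions": 0, "traces_ok": 0, "excluded_saturation": 0, "excluded_excursion": 0}
    for session in sessions:
        part, c = build_band_table([session], config)
        band_parts.append(part)
        dur_parts.append(durations_table([session]))
        for k in counts:
            counts[k] += c.get(k, 0)
    band_df = pd.concat(band_parts, ignore_index=True) if band_parts else pd.DataFrame(columns=BAND_COLUMNS)
    dur_df = pd.concat(dur_parts, ignore_index=True)

    report = AnalysisReport(
        intergroup=run_intergroup(band_df, config),
        intragroup=run_intragroup(band_df, config),
        durations=run_durations(dur_df, config),
        correlation=run_correlation(band_df, dur_df, config),
    )
    report.log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_seed": config.seed,
        "design_seed": getattr(design, "seed", None),
        "aggregation": config.aggregation,
        "alpha": config.alpha,
        "band_of_interest": list(config.band),
        "trace_counts": counts,
    }
    if config.diagnostics and len(band_df):
        report.log["diagnostics"] = _diagnostics(band_df, config)
    if out_dir is not None:
        report.write(out_dir)
    return report
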