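"""Cohort-level orchestration: run all stages, aggregate, compare regions.

Runs the spontaneous, odor-response and respiration-phase analyses over a
set of sessions, builds per-cell and per-pair tables, region summaries
(pair/cell responsiveness, spontaneous medians, phase-locking counts,
population mean phase), interregional Mann-Whitney comparisons and the
full-sample sex comparison.  AON subdivisions are assumed pre-merged in the
region labels; VTT is summarized descriptively and excluded from the
default inferential comparison (DTT vs AON).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AnalysisWindows, Session
from .odor import (
    PSTH,
    classify_cohort,
    compute_psth,
    epoch_trials,
    grand_average_psth,
    per_odor_breakdown,
    responses_to_frame,
    test_pair_significance,
    tuning_profile,
)
from .phase import RespCycleTable, cell_phase_stats, detect_cycles, population_mean_phase
from .spontaneous import spontaneous_table
from .stats import TestResult, mann_whitney_u

logger = logging.getLogger(__name__)


@dataclass
class CohortSummary:
    """All cohort-level outputs; every entry traceable to the cell/pair tables."""

    cells: pd.DataFrame
    pairs: pd.DataFrame
    region_summary: pd.DataFrame
    per_odor: pd.DataFrame
    comparisons: pd.DataFrame
    sex_comparison: pd.DataFrame
    grand_psths: dict = field(default_factory=dict)  # region -> PSTH


def analyze_session(
    session: Session,
    windows: AnalysisWindows = AnalysisWindows(),
    psth_bin_s: float = 0.1,
    psth_span: tuple[float, float] = (-4.0, 8.0),
    phase_bin_deg: float = 6.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-cell and per-pair tables for one session.

    Returns (cells, pairs, psths) where ``psths`` maps (cell_id, odor_id)
    to the pair's peristimulus histogram.  Phase statistics are computed
    over the post-onset window of every trial when a respiration trace is
    present, using cycles detected from the trace.
    """
    cells = spontaneous_table(session, windows)

    cycles: Optional[RespCycleTable] = None
    if session.respiration is not None:
        cycles = detect_cycles(session.respiration)
    phase_windows = [
        (onset, onset + windows.phase_dur)
        for onset in session.events.df["onset_s"].to_numpy()
    ]

    pair_rows = []
    psths: dict = {}
    phase_cols = {
        c: []
        for c in ("theta_deg", "rho", "rayleigh_Z", "rayleigh_p", "phase_significant", "phase_unimodal", "n_phase_spikes")
    }
    selectivity = []
    for rec, train in session.cells:
        counts = epoch_trials(train, session.events, windows)
        for c in counts:
            pair_rows.append(test_pair_significance(c, windows))
            psths[(rec.cell_id, c.odor_id)] = compute_psth(
                train,
                session.events.onsets_for(c.odor_id),
                bin_width_s=psth_bin_s,
                span=psth_span,
            )
        non_vehicle = [c for c in counts if not c.is_vehicle]
        selectivity.append(
            tuning_profile(non_vehicle, windows).selectivity if len(non_vehicle) >= 2 else float("nan")
        )
        if cycles is not None and len(cycles):
            vec, ray, _ = cell_phase_stats(
                train, cycles, phase_windows, bin_deg=phase_bin_deg, alpha=windows.alpha_pair
            )
            phase_cols["theta_deg"].append(vec.theta_deg)
            phase_cols["rho"].append(vec.rho)
            phase_cols["rayleigh_Z"].append(ray.Z)
            phase_cols["rayleigh_p"].append(ray.p)
            phase_cols["phase_significant"].append(ray.significant)
            phase_cols["phase_unimodal"].append(ray.unimodal)
            phase_cols["n_phase_spikes"].append(ray.n)
        else:
            for k in phase_cols:
                phase_cols[k].append(np.nan)

    cells["selectivity"] = selectivity
    for k, v in phase_cols.items():
        cells[k] = v
    cells["session_id"] = session.session_id
    pairs = responses_to_frame(pair_rows)
    pairs["session_id"] = session.session_id
    return cells, pairs, psths


def compare_regions(
    cells: pd.DataFrame,
    pairs: pd.DataFrame,
    region_a: str = "DTT",
    region_b: str = "AON",
) -> pd.DataFrame:
    """Mann-Whitney comparisons of per-cell metrics and per-odorant z-scores.

    Per-cell metrics: spontaneous rate, ISI CV, selectivity.  Per odorant:
    z-scores of all region-A pairs vs region-B pairs (infinite-z sentinels
    excluded from ranks by dropping, with a logged count).
    """
    rows = []

    def _one(metric: str, a: np.ndarray, b: np.ndarray, odor_id: str = "") -> None:
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if a.size == 0 or b.size == 0:
            rows.append(
                {"metric": metric, "odor_id": odor_id, "U": np.nan, "n_a": a.size, "n_b": b.size, "p": np.nan, "skipped": True}
            )
            return
        res = mann_whitney_u(a, b)
        rows.append(
            {"metric": metric, "odor_id": odor_id, "U": res.statistic, "n_a": res.n, "n_b": res.n2, "p": res.p, "skipped": False}
        )

    ca = cells[cells["region"] == region_a]
    cb = cells[cells["region"] == region_b]
    for metric in ("rate_hz", "isi_cv", "selectivity"):
        _one(metric, ca[metric].to_numpy(float), cb[metric].to_numpy(float))

    merged = pairs.merge(cells[["cell_id", "region"]], on="cell_id", how="left")
    odors = sorted(merged.loc[~merged["is_vehicle"], "odor_id"].unique())
    for odor in odors:
        sub = merged[merged["odor_id"] == odor]
        _one(
            "z",
            sub.loc[sub["region"] == region_a, "z"].to_numpy(float),
            sub.loc[sub["region"] == region_b, "z"].to_numpy(float),
            odor_id=odor,
        )
    out = pd.DataFrame(rows)
    out.insert(0, "region_b", region_b)
    out.insert(0, "region_a", region_a)
    return out


def compare_sexes(cells: pd.DataFrame) -> pd.DataFrame:
    """Full-sample Mann-Whitney comparison of spontaneous metrics by sex."""
    rows = []
    f = cells[cells["sex"] == "F"]
    m = cells[cells["sex"] == "M"]
    for metric in ("rate_hz", "isi_cv"):
        a = f[metric].to_numpy(float)
        b = m[metric].to_numpy(float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size == 0 or b.size == 0:
            rows.append({"metric": metric, "U": np.nan, "n_f": a.size, "n_m": b.size, "p": np.nan})
            continue
        res = mann_whitney_u(a, b)
        rows.append({"metric": metric, "U": res.statistic, "n_f": res.n, "n_m": res.n2, "p": res.p})
    return pd.DataFrame(rows)


def run_cohort(
    sessions: Sequence[Session],
    windows: AnalysisWindows = AnalysisWindows(),
    compare: tuple[str, str] = ("DTT", "AON"),
    psth_bin_s: float = 0.1,
    psth_span: tuple[float, float] = (-4.0, 8.0),
) -> CohortSummary:
    """Run every analysis stage over the cohort and aggregate by region."""
    sessions = list(sessions)
    if not sessions:
        raise ValueError("run_cohort requires at least one session")
    all_cells, all_pairs, all_psths = [], [], {}
    for session in sessions:
        cells, pairs, psths = analyze_session(
            session, windows, psth_bin_s=psth_bin_s, psth_span=psth_span
        )
        all_cells.append(cells)
        all_pairs.append(pairs)
        all_psths.update(psths)
    cells = pd.concat(all_cells, ignore_index=True)
    pairs = pd.concat(all_pairs, ignore_index=True)
    if cells.empty:
        raise ValueError("cohort contains no cells")

    region_summary = classify_cohort(pairs, cells)
    per_odor = per_odor_breakdown(pairs, cells)

    extra_rows = []
    grand_psths = {}
    for region in region_summary["region"]:
        rc = cells[cells["region"] == region]
        modulated = rc[
            (rc["phase_significant"] == True) & (rc["phase_unimodal"] == True)  # noqa: E712
        ]
        pop_phase = population_mean_phase(modulated["theta_deg"].to_numpy(float))
        n_phase = int(rc["rayleigh_p"].notna().sum())
        qualifying = pairs.merge(rc[["cell_id"]], on="cell_id")
        strong = qualifying[qualifying["exceeds_sd"] & ~qualifying["is_vehicle"]]
        g = grand_average_psth(
            [
                all_psths[(r.cell_id, r.odor_id)]
                for r in strong.itertuples()
                if (r.cell_id, r.odor_id) in all_psths
            ]
        )
        if g is not None:
            grand_psths[region] = g
        extra_rows.append(
            {
                "region": region,
                "median_rate_hz": float(np.nanmedian(rc["rate_hz"])) if rc["rate_hz"].notna().any() else np.nan,
                "median_isi_cv": float(np.nanmedian(rc["isi_cv"])) if rc["isi_cv"].notna().any() else np.nan,
                "median_selectivity": float(np.nanmedian(rc["selectivity"])) if rc["selectivity"].notna().any() else np.nan,
                "median_selectivity_responsive": _median_selectivity_responsive(rc, pairs),
                "n_cells_with_respiration": n_phase,
                "n_phase_modulated": int(len(modulated)),
                "prop_phase_modulated": len(modulated) / n_phase if n_phase else np.nan,
                "population_mean_phase_deg": pop_phase,
            }
        )
    region_summary = region_summary.merge(pd.DataFrame(extra_rows), on="region")

    comparisons = compare_regions(cells, pairs, *compare)
    sex_comparison = compare_sexes(cells)
    return CohortSummary(
        cells=cells,
        pairs=pairs,
        region_summary=region_summary,
        per_odor=per_odor,
        comparisons=comparisons,
        sex_comparison=sex_comparison,
        grand_psths=grand_psths,
    )


def _median_selectivity_responsive(
    region_cells: pd.DataFrame, pairs: pd.DataFrame
) -> float:
    sig = pairs[pairs["significant"] & ~pairs["is_vehicle"]]
    responsive = region_cells[region_cells["cell_id"].isin(sig["cell_id"])]
    vals = responsive["selectivity"].to_numpy(float)
    vals = vals[np.isfinite(vals)]
    return float(np.median(vals)) if vals.size else float("nan")


def write_summary(summary: CohortSummary, out_dir) -> None:
    """Write all cohort tables as delimited text under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.cells.to_csv(out / "cells.csv", index=False)
    summary.pairs.to_csv(out / "pairs.csv", index=False)
    summary.region_summary.to_csv(out / "region_summary.csv", index=False)
    summary.per_odor.to_csv(out / "per_odor.csv", index=False)
    summary.comparisons.to_csv(out / "comparisons.csv", index=False)
    summary.sex_comparison.to_csv(out / "sex_comparison.csv", index=False)
    for region, psth in summary.grand_psths.items():
        df = pd.DataFrame(
            {
                "bin_center_s": psth.bin_centers_s,
                "rate_hz": psth.rate_hz,
                "sem_hz": psth.sem_hz if psth.sem_hz is not None else np.nan,
            }
        )
        df.to_csv(out / f"grand_psth_{region}.csv", index=False)
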