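"""Per odor-cell-pair response statistics.

Each presentation contributes a pair of spike counts: the 4 s baseline
window immediately before odor onset and the 4 s odor window beginning at
onset.  Responses are summarized per pair as a baseline-normalized z-score,
a paired rank-biserial effect size, and a Wilcoxon signed-rank p-value; per
cell, tuning breadth is summarized by the selectivity index
(maxrate - minrate) / (maxrate + minrate) over mean odor-period rates with
the vehicle omitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import AnalysisWindows, CellRecord, EventTable, SpikeTrain, ValidationError
from .stats import TestResult, wilcoxon_signed_rank

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrialAlignedCounts:
    """Per-trial baseline and odor-window spike counts for one odor-cell pair."""

    cell_id: str
    odor_id: str
    baseline_counts: np.ndarray
    odor_counts: np.ndarray
    is_vehicle: bool = False

    def __post_init__(self) -> None:
        b = np.asarray(self.baseline_counts, dtype=int)
        o = np.asarray(self.odor_counts, dtype=int)
        if b.shape != o.shape or b.ndim != 1:
            raise ValidationError("baseline and odor counts must be 1-D and equal length")
        if b.size < 1:
            raise ValidationError("at least one trial required")
        if (b < 0).any() or (o < 0).any():
            raise ValidationError("negative spike count")
        object.__setattr__(self, "baseline_counts", b)
        object.__setattr__(self, "odor_counts", o)

    @property
    def n_trials(self) -> int:
        return int(self.baseline_counts.size)


@dataclass(frozen=True)
class OdorResponse:
    cell_id: str
    odor_id: str
    is_vehicle: bool
    n_trials: int
    z: float  # NaN undefined; +/-inf when baseline SD = 0 and means differ
    r_rb: float
    p_wilcoxon: float
    mean_baseline_hz: float
    mean_odor_hz: float
    significant: bool
    exceeds_sd: bool
    degenerate: bool = False


@dataclass(frozen=True)
class OdorTuningProfile:
    cell_id: str
    odor_rates_hz: dict  # odor_id -> mean odor-period rate, vehicle omitted
    maxrate: float
    minrate: float
    selectivity: float  # NaN when undefined


@dataclass(frozen=True)
class PSTH:
    """Trial-averaged firing rate around odor onset."""

    bin_edges_s: np.ndarray  # relative to onset, length n_bins + 1
    rate_hz: np.ndarray
    sem_hz: Optional[np.ndarray]
    n_trials: int

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])


def epoch_trials(
    train: SpikeTrain,
    events: EventTable,
    windows: AnalysisWindows = AnalysisWindows(),
) -> list[TrialAlignedCounts]:
    """Baseline/odor spike counts per trial, grouped by odor (vehicle included).

    Trials whose baseline window would extend before the session start are
    dropped with a logged warning.
    """
    out = []
    for odor_id in events.odor_ids:
        sub = events.df[events.df["odor_id"] == odor_id]
        is_vehicle = bool(sub["is_vehicle"].iloc[0])
        base, odor = [], []
        for onset in sub["onset_s"].to_numpy():
            if onset - windows.baseline_dur < 0:
                logger.warning(
                    "dropping trial at %.3fs for cell %s: baseline precedes session start",
                    onset,
                    train.cell_id,
                )
                continue
            base.append(train.count_in(onset - windows.baseline_dur, onset))
            odor.append(train.count_in(onset, onset + windows.odor_dur))
        if base:
            out.append(
                TrialAlignedCounts(
                    cell_id=train.cell_id,
                    odor_id=odor_id,
                    baseline_counts=np.array(base),
                    odor_counts=np.array(odor),
                    is_vehicle=is_vehicle,
                )
            )
    return out


def response_zscore(
    counts: TrialAlignedCounts, windows: AnalysisWindows = AnalysisWindows()
) -> float:
    """Odor-period rate change normalized by the trial-to-trial baseline SD.

    Per-trial rates are counts over the window length; the z-score is
    (mean odor rate - mean baseline rate) / sample SD of baseline rates.
    When the baseline SD is zero the result is 0 for equal means and a
    signed infinity sentinel otherwise; fewer than two trials give NaN.
    """
    if counts.n_trials < 2:
        return float("nan")
    base = counts.baseline_counts / windows.baseline_dur
    odor = counts.odor_counts / windows.odor_dur
    sd = base.std(ddof=1)
    diff = odor.mean() - base.mean()
    if sd == 0:
        if diff == 0:
            return 0.0
        return math.copysign(float("inf"), diff)
    return float(diff / sd)


def rank_biserial_paired(counts: TrialAlignedCounts) -> float:
    """Paired rank-biserial correlation of odor vs baseline counts.

    Signed-rank simple-difference formula: with zero differences discarded
    and ties average-ranked, r = (R+ - R-) / (R+ + R-).  +1 when every
    nonzero difference is positive, -1 when all negative, 0 when all
    differences are zero (degenerate).
    """
    d = counts.odor_counts.astype(float) - counts.baseline_counts.astype(float)
    d = d[d != 0]
    if d.size == 0:
        return 0.0
    ranks = rankdata(np.abs(d))
    r_plus = ranks[d > 0].sum()
    r_minus = ranks[d < 0].sum()
    return float((r_plus - r_minus) / (r_plus + r_minus))


def test_pair_significance(
    counts: TrialAlignedCounts, windows: AnalysisWindows = AnalysisWindows()
) -> OdorResponse:
    """Full per-pair response summary with significance flags."""
    d = counts.odor_counts.astype(float) - counts.baseline_counts.astype(float)
    degenerate = bool((d == 0).all())
    if degenerate:
        test = TestResult(statistic=0.0, p=1.0, n=0, method="degenerate")
    else:
        test = wilcoxon_signed_rank(d)
    z = response_zscore(counts, windows)
    significant = bool(test.p < windows.alpha_pair)
    exceeds = bool(not math.isnan(z) and z >= windows.sd_threshold)
    return OdorResponse(
        cell_id=counts.cell_id,
        odor_id=counts.odor_id,
        is_vehicle=counts.is_vehicle,
        n_trials=counts.n_trials,
        z=z,
        r_rb=rank_biserial_paired(counts),
        p_wilcoxon=test.p,
        mean_baseline_hz=float(counts.baseline_counts.mean() / windows.baseline_dur),
        mean_odor_hz=float(counts.odor_counts.mean() / windows.odor_dur),
        significant=significant,
        exceeds_sd=exceeds,
        degenerate=degenerate,
    )


def selectivity_index(odor_rates: Sequence[float]) -> float:
    """(maxrate - minrate) / (maxrate + minrate) over per-odor mean rates.

    The vehicle must already be omitted from ``odor_rates``.  Undefined
    (NaN) with fewer than two odorants or when all rates are zero.
    """
    rates = np.asarray(odor_rates, dtype=float)
    if rates.size < 2 or np.isnan(rates).any():
        return float("nan")
    mx, mn = rates.max(), rates.min()
    if mx + mn == 0:
        return float("nan")
    return float((mx - mn) / (mx + mn))


def tuning_profile(
    pair_counts: Iterable[TrialAlignedCounts],
    windows: AnalysisWindows = AnalysisWindows(),
) -> OdorTuningProfile:
    """Per-cell tuning profile over mean odor-period rates (vehicle omitted)."""
    rates = {}
    cell_id = None
    for c in pair_counts:
        cell_id = c.cell_id if cell_id is None else cell_id
        if c.cell_id != cell_id:
            raise ValidationError("tuning_profile requires counts from a single cell")
        if not c.is_vehicle:
            rates[c.odor_id] = float(c.odor_counts.mean() / windows.odor_dur)
    if not rates:
        raise ValidationError("no non-vehicle odorants for tuning profile")
    vals = np.array(list(rates.values()))
    return OdorTuningProfile(
        cell_id=cell_id,
        odor_rates_hz=rates,
        maxrate=float(vals.max()),
        minrate=float(vals.min()),
        selectivity=selectivity_index(vals),
    )


def responses_to_frame(responses: Iterable[OdorResponse]) -> pd.DataFrame:
    """Per-pair results table in the delimited dialect's column order."""
    rows = [
        {
            "cell_id": r.cell_id,
            "odor_id": r.odor_id,
            "is_vehicle": r.is_vehicle,
            "n_trials": r.n_trials,
            "z": r.z,
            "r_rb": r.r_rb,
            "p_wilcoxon": r.p_wilcoxon,
            "mean_baseline_hz": r.mean_baseline_hz,
            "mean_odor_hz": r.mean_odor_hz,
            "significant": r.significant,
            "exceeds_sd": r.exceeds_sd,
            "degenerate": r.degenerate,
        }
        for r in responses
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "odor_id",
            "is_vehicle",
            "n_trials",
            "z",
            "r_rb",
            "p_wilcoxon",
            "mean_baseline_hz",
            "mean_odor_hz",
            "significant",
            "exceeds_sd",
            "degenerate",
        ],
    )


def classify_cohort(pairs: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Region-level responsiveness summary from per-pair flags.

    Vehicle pairs are excluded from responsiveness proportions (their test
    results remain in ``pairs``).  Returns one row per region with pair and
    cell counts, significant-pair and strong-response (z >= threshold flag)
    proportions, and the distribution of significant odorant counts among
    responsive cells.
    """
    known = set(cells["cell_id"])
    orphan = set(pairs["cell_id"]) - known
    if orphan:
        raise ValidationError(f"pairs reference unknown cells: {sorted(orphan)}")
    merged = pairs.merge(cells[["cell_id", "region"]], on="cell_id", how="left")
    odor_pairs = merged[~merged["is_vehicle"]]
    rows = []
    for region, grp in odor_pairs.groupby("region", sort=True):
        cell_ids = cells.loc[cells["region"] == region, "cell_id"]
        n_cells = int(cell_ids.nunique())
        sig = grp[grp["significant"]]
        responsive_cells = sig["cell_id"].unique()
        sig_per_cell = sig.groupby("cell_id")["odor_id"].nunique()
        rows.append(
            {
                "region": region,
                "n_cells": n_cells,
                "n_pairs": int(len(grp)),
                "n_significant_pairs": int(len(sig)),
                "prop_significant_pairs": len(sig) / len(grp) if len(grp) else 0.0,
                "n_responsive_cells": int(len(responsive_cells)),
                "prop_responsive_cells": len(responsive_cells) / n_cells
                if n_cells
                else 0.0,
                "n_pairs_exceeds_sd": int(grp["exceeds_sd"].sum()),
                "prop_pairs_exceeds_sd": float(grp["exceeds_sd"].mean())
                if len(grp)
                else 0.0,
                "median_odorants_per_responsive_cell": float(sig_per_cell.median())
                if len(sig_per_cell)
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def per_odor_breakdown(pairs: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Per region x odorant: pair counts, significant counts, median z."""
    merged = pairs.merge(cells[["cell_id", "region"]], on="cell_id", how="left")
    rows = []
    for (region, odor_id), grp in merged.groupby(["region", "odor_id"], sort=True):
        rows.append(
            {
                "region": region,
                "odor_id": odor_id,
                "is_vehicle": bool(grp["is_vehicle"].iloc[0]),
                "n_pairs": int(len(grp)),
                "n_significant": int(grp["significant"].sum()),
                "median_z": float(np.median(grp["z"].replace([np.inf, -np.inf], np.nan).dropna()))
                if grp["z"].replace([np.inf, -np.inf], np.nan).notna().any()
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def compute_psth(
    train: SpikeTrain,
    onsets: Sequence[float],
    bin_width_s: float = 0.1,
    span: tuple[float, float] = (-4.0, 8.0),
) -> PSTH:
    """Trial-averaged firing rate around the given odor onsets.

    Bins of ``bin_width_s`` cover ``span`` (seconds relative to onset).
    The SEM across trials is undefined (None) for a single trial.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValidationError("compute_psth requires at least one trial")
    n_bins = int(round((span[1] - span[0]) / bin_width_s))
    edges = span[0] + bin_width_s * np.arange(n_bins + 1)
    per_trial = np.empty((onsets.size, n_bins))
    for i, onset in enumerate(onsets):
        rel = train.slice(onset + span[0], onset + span[1]) - onset
        counts, _ = np.histogram(rel, bins=edges)
        per_trial[i] = counts / bin_width_s
    rate = per_trial.mean(axis=0)
    sem = (
        per_trial.std(axis=0, ddof=1) / np.sqrt(onsets.size)
        if onsets.size > 1
        else None
    )
    return PSTH(bin_edges_s=edges, rate_hz=rate, sem_hz=sem, n_trials=int(onsets.size))


def grand_average_psth(psths: Sequence[PSTH]) -> Optional[PSTH]:
    """Mean +/- SEM across per-pair PSTHs (e.g. all strong-response pairs).

    Returns None when no pair qualifies.  All inputs must share bin edges.
    """
    psths = list(psths)
    if not psths:
        return None
    edges = psths[0].bin_edges_s
    for p in psths[1:]:
        if not np.array_equal(p.bin_edges_s, edges):
            raise ValidationError("grand_average_psth requires identical bin edges")
    stack = np.vstack([p.rate_hz for p in psths])
    sem = (
        stack.std(axis=0, ddof=1) / np.sqrt(len(psths)) if len(psths) > 1 else None
    )
    return PSTH(
        bin_edges_s=edges,
        rate_hz=stack.mean(axis=0),
        sem_hz=sem,
        n_trials=len(psths),
    )
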