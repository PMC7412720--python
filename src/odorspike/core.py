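"""Session data model for single-unit olfactory recordings.

A session holds sorted spike times for a set of isolated units, an odor
presentation schedule (including the mineral-oil vehicle channel), an
optional uniformly sampled respiration trace, and per-cell metadata
(region, subject, sex).  All times are seconds from session start and all
epochs are half-open intervals ``[start, end)``, so a spike falling exactly
on an odor onset belongs to the odor period.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

REGIONS = ("DTT", "VTT", "AON", "OTHER")
SEXES = ("F", "M", "unknown")

EVENT_COLUMNS = ("odor_id", "is_vehicle", "onset_s", "offset_s")


class ValidationError(ValueError):
    """An invariant of the session data model was violated."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (seconds from session start) for one unit.

    Times must be strictly increasing and nonnegative; duplicates are
    rejected because a sorted single unit cannot fire twice at one instant.
    """

    cell_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1:
            raise ValidationError(f"spike times for {self.cell_id!r} must be 1-D")
        if times.size and not np.all(np.isfinite(times)):
            raise ValidationError(f"non-finite spike time in {self.cell_id!r}")
        if times.size and times[0] < 0:
            raise ValidationError(f"negative spike time in {self.cell_id!r}")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError(
                f"spike times for {self.cell_id!r} must be strictly increasing "
                "(duplicates rejected)"
            )
        object.__setattr__(self, "times", times)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def count_in(self, start: float, end: float) -> int:
        """Number of spikes in the half-open interval [start, end)."""
        lo, hi = np.searchsorted(self.times, [start, end], side="left")
        return int(hi - lo)

    def slice(self, start: float, end: float) -> np.ndarray:
        lo, hi = np.searchsorted(self.times, [start, end], side="left")
        return self.times[lo:hi]


@dataclass(frozen=True)
class EventTable:
    """Odor presentation schedule: one row per trial.

    Columns: ``odor_id``, ``is_vehicle``, ``onset_s``, ``offset_s``.  Rows
    are sorted by onset, intervals must not overlap, and exactly one
    ``odor_id`` is flagged as the vehicle control for the session.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df).reset_index(drop=True)
        missing = set(EVENT_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"event table missing columns {sorted(missing)}")
        df = df.loc[:, list(EVENT_COLUMNS)]
        df["odor_id"] = df["odor_id"].astype(str)
        df["is_vehicle"] = df["is_vehicle"].astype(bool)
        df["onset_s"] = df["onset_s"].astype(float)
        df["offset_s"] = df["offset_s"].astype(float)
        if len(df):
            bad = df.index[df["offset_s"] <= df["onset_s"]]
            if len(bad):
                raise ValidationError(f"event row {bad[0]}: offset_s <= onset_s")
            if not df["onset_s"].is_monotonic_increasing:
                raise ValidationError("event rows must be sorted by onset_s")
            overlap = df["onset_s"].values[1:] < df["offset_s"].values[:-1]
            if overlap.any():
                raise ValidationError(
                    f"event row {int(np.argmax(overlap)) + 1}: intervals overlap"
                )
            veh = df.loc[df["is_vehicle"], "odor_id"].unique()
            if len(veh) != 1:
                raise ValidationError(
                    f"exactly one vehicle odor_id required, found {len(veh)}"
                )
            mixed = df.groupby("odor_id")["is_vehicle"].nunique()
            if (mixed > 1).any():
                raise ValidationError("odor_id with inconsistent is_vehicle flag")
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def odor_ids(self) -> list[str]:
        """All odor identifiers in onset order of first appearance."""
        return list(dict.fromkeys(self.df["odor_id"]))

    @property
    def vehicle_id(self) -> Optional[str]:
        veh = self.df.loc[self.df["is_vehicle"], "odor_id"]
        return None if veh.empty else str(veh.iloc[0])

    def onsets_for(self, odor_id: str) -> np.ndarray:
        return self.df.loc[self.df["odor_id"] == odor_id, "onset_s"].to_numpy()


@dataclass(frozen=True)
class RespirationTrace:
    """Uniformly sampled respiration signal (arbitrary units)."""

    sample_rate: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ValidationError("sample_rate must be > 0")
        values = np.asarray(self.values, dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ValidationError("respiration trace contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sample_rate

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sample_rate


@dataclass(frozen=True)
class CellRecord:
    cell_id: str
    region: str
    subject_id: str
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r} (allowed {REGIONS})")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r} (allowed {SEXES})")


@dataclass(frozen=True)
class Session:
    """One recording session: cells with spike trains, events, respiration."""

    cells: tuple[tuple[CellRecord, SpikeTrain], ...]
    events: EventTable
    duration_s: float
    respiration: Optional[RespirationTrace] = None
    session_id: str = "session"

    def __post_init__(self) -> None:
        cells = tuple(self.cells)
        ids = [rec.cell_id for rec, _ in cells]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate cell_id within session")
        for rec, train in cells:
            if rec.cell_id != train.cell_id:
                raise ValidationError(
                    f"cell record {rec.cell_id!r} paired with train {train.cell_id!r}"
                )
            if train.n_spikes and train.times[-1] >= self.duration_s:
                raise ValidationError(
                    f"spike at {train.times[-1]:g}s >= duration {self.duration_s:g}s "
                    f"for cell {rec.cell_id!r}"
                )
        if len(self.events) and self.events.df["offset_s"].iloc[-1] >= self.duration_s:
            raise ValidationError("event offset beyond session duration")
        object.__setattr__(self, "cells", cells)

    @property
    def cell_ids(self) -> list[str]:
        return [rec.cell_id for rec, _ in self.cells]

    def train(self, cell_id: str) -> SpikeTrain:
        for rec, train in self.cells:
            if rec.cell_id == cell_id:
                return train
        raise KeyError(cell_id)

    def record(self, cell_id: str) -> CellRecord:
        for rec, _ in self.cells:
            if rec.cell_id == cell_id:
                return rec
        raise KeyError(cell_id)


@dataclass(frozen=True)
class AnalysisWindows:
    """Epoching and threshold parameters shared by all analysis stages.

    baseline_dur / odor_dur
        Lengths (s) of the pre-onset baseline and post-onset odor counting
        windows used for every odor-cell pair.
    phase_dur
        Length (s) of the post-onset window pooled across trials for the
        respiratory-phase statistics.
    spont_tail
        Final portion (s) of each interstimulus gap treated as spontaneous
        activity, after odor clearance.
    alpha_pair
        Per-pair significance level for the paired signed-rank test.
    sd_threshold
        z-score cut for the strong-response category used in grand-average
        peristimulus histograms.
    """

    baseline_dur: float = 4.0
    odor_dur: float = 4.0
    phase_dur: float = 8.0
    spont_tail: float = 10.0
    alpha_pair: float = 0.01
    sd_threshold: float = 3.0

    def __post_init__(self) -> None:
        for name in ("baseline_dur", "odor_dur", "phase_dur", "spont_tail"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 < self.alpha_pair < 1:
            raise ValidationError("alpha_pair must lie in (0, 1)")


def interstimulus_tail_windows(
    events: EventTable,
    windows: AnalysisWindows = AnalysisWindows(),
    duration_s: Optional[float] = None,
) -> list[tuple[float, float]]:
    """Final ``spont_tail`` seconds of every inter-event gap.

    For each gap between an event offset and the next event onset the window
    covers the last ``windows.spont_tail`` seconds, by which time delivered
    odor has cleared; gaps shorter than the tail contribute their full
    length.  Segments before the first event and after the last are not
    interstimulus intervals and are excluded.  Intervals are half-open
    ``[start, end)``.
    """
    df = events.df
    out: list[tuple[float, float]] = []
    for off, on in zip(df["offset_s"].values[:-1], df["onset_s"].values[1:]):
        start = max(off, on - windows.spont_tail)
        if on > start:
            out.append((float(start), float(on)))
    return out
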