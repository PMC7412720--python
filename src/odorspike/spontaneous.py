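"""Spontaneous firing metrics over interstimulus tail windows.

The session-wide spontaneous rate of a unit is the reciprocal of its mean
interspike interval (ISI), pooled over the final seconds of every
interstimulus gap; irregularity is summarized by the ISI coefficient of
variation, CV = SD/mean (1 for a Poisson process, 0 for a clock-like
train).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AnalysisWindows, EventTable, Session, SpikeTrain, interstimulus_tail_windows


@dataclass(frozen=True)
class SpontaneousMetrics:
    cell_id: str
    rate_hz: float  # NaN when undefined (n_isis < 1)
    isi_cv: float  # NaN when undefined (n_isis < 2)
    n_isis: int

    @property
    def defined(self) -> bool:
        return self.n_isis >= 2


def pool_spontaneous_isis(
    train: SpikeTrain, windows: Sequence[tuple[float, float]]
) -> np.ndarray:
    """ISIs between consecutive spikes that fall within the same window.

    Intervals spanning a window boundary are excluded, so the pooled sample
    only reflects within-window spacing.  Windows must be disjoint and
    sorted.
    """
    isis = []
    for start, end in windows:
        inside = train.slice(start, end)
        if inside.size >= 2:
            isis.append(np.diff(inside))
    if not isis:
        return np.array([], dtype=float)
    return np.concatenate(isis)


def spontaneous_rate(isis: Sequence[float]) -> float:
    """Firing rate (Hz) as the reciprocal of the mean ISI; NaN if empty."""
    isis = np.asarray(isis, dtype=float)
    if isis.size == 0:
        return float("nan")
    return float(1.0 / isis.mean())


def isi_cv(isis: Sequence[float]) -> float:
    """ISI coefficient of variation, sample (n-1) SD over mean; NaN if n < 2."""
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2:
        return float("nan")
    return float(isis.std(ddof=1) / isis.mean())


def spontaneous_metrics(
    train: SpikeTrain,
    events: EventTable,
    windows: AnalysisWindows = AnalysisWindows(),
) -> SpontaneousMetrics:
    """Pool tail-window ISIs for one unit and summarize rate and CV."""
    tails = interstimulus_tail_windows(events, windows)
    isis = pool_spontaneous_isis(train, tails)
    return SpontaneousMetrics(
        cell_id=train.cell_id,
        rate_hz=spontaneous_rate(isis),
        isi_cv=isi_cv(isis),
        n_isis=int(isis.size),
    )


def spontaneous_table(
    session: Session, windows: AnalysisWindows = AnalysisWindows()
) -> pd.DataFrame:
    """Per-cell spontaneous metrics table (cell_id, region, rate_hz, isi_cv, n_isis)."""
    rows = []
    for rec, train in session.cells:
        m = spontaneous_metrics(train, session.events, windows)
        rows.append(
            {
                "cell_id": rec.cell_id,
                "region": rec.region,
                "subject_id": rec.subject_id,
                "sex": rec.sex,
                "rate_hz": m.rate_hz,
                "isi_cv": m.isi_cv,
                "n_isis": m.n_isis,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "region", "subject_id", "sex", "rate_hz", "isi_cv", "n_isis"],
    )
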