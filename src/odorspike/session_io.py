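"""Readers and writers for the delimited-text session directory format.

A session directory contains comma-delimited UTF-8 tables, each with a
single header row, plus a small YAML manifest::

    session.yaml       duration_s, session_id, resp_sample_rate_hz, resp_t0_s
    spikes.csv         cell_id, time_s
    events.csv         odor_id, is_vehicle, onset_s, offset_s
    cells.csv          cell_id, region, subject_id, sex
    respiration.csv    value                       (optional; one row per sample)

Times are written with 17 significant digits so a write/read round trip is
exact for float64 values.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .core import (
    CellRecord,
    EventTable,
    RespirationTrace,
    Session,
    SpikeTrain,
    ValidationError,
)

_FLOAT_FMT = "%.17g"

REQUIRED_FILES = ("session.yaml", "spikes.csv", "events.csv", "cells.csv")


class SessionLoadError(IOError):
    """A required session file is missing or unreadable."""


def write_session(session: Session, directory: Union[str, Path]) -> None:
    """Write ``session`` to ``directory`` in the delimited dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    manifest = {
        "session_id": session.session_id,
        "duration_s": float(session.duration_s),
    }
    if session.respiration is not None:
        manifest["resp_sample_rate_hz"] = float(session.respiration.sample_rate)
        manifest["resp_t0_s"] = float(session.respiration.t0)
    with open(directory / "session.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    spikes = pd.DataFrame(
        {
            "cell_id": np.concatenate(
                [np.repeat(rec.cell_id, train.n_spikes) for rec, train in session.cells]
            )
            if session.cells
            else np.array([], dtype=str),
            "time_s": np.concatenate([train.times for _, train in session.cells])
            if session.cells
            else np.array([], dtype=float),
        }
    )
    spikes.to_csv(directory / "spikes.csv", index=False, float_format=_FLOAT_FMT)

    session.events.df.to_csv(
        directory / "events.csv", index=False, float_format=_FLOAT_FMT
    )

    cells = pd.DataFrame(
        [
            {
                "cell_id": rec.cell_id,
                "region": rec.region,
                "subject_id": rec.subject_id,
                "sex": rec.sex,
            }
            for rec, _ in session.cells
        ],
        columns=["cell_id", "region", "subject_id", "sex"],
    )
    cells.to_csv(directory / "cells.csv", index=False)

    if session.respiration is not None:
        pd.DataFrame({"value": session.respiration.values}).to_csv(
            directory / "respiration.csv", index=False, float_format=_FLOAT_FMT
        )


def read_session(directory: Union[str, Path]) -> Session:
    """Read a session directory written by :func:`write_session`.

    Raises
    ------
    SessionLoadError
        If a required file is missing.
    ValidationError
        If any data-model invariant fails, naming the offending rule.
    """
    directory = Path(directory)
    for name in REQUIRED_FILES:
        if not (directory / name).is_file():
            raise SessionLoadError(f"missing required session file: {directory / name}")

    with open(directory / "session.yaml", "r", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh) or {}
    if "duration_s" not in manifest:
        raise ValidationError("session.yaml missing duration_s")

    cells_df = pd.read_csv(directory / "cells.csv", dtype=str).fillna("unknown")
    spikes_df = pd.read_csv(
        directory / "spikes.csv",
        dtype={"cell_id": str, "time_s": float},
        float_precision="round_trip",
    )
    events_df = pd.read_csv(directory / "events.csv", float_precision="round_trip")
    events = EventTable(events_df)

    cells = []
    for _, row in cells_df.iterrows():
        rec = CellRecord(
            cell_id=row["cell_id"],
            region=row["region"],
            subject_id=row["subject_id"],
            sex=row.get("sex", "unknown"),
        )
        times = spikes_df.loc[
            spikes_df["cell_id"] == rec.cell_id, "time_s"
        ].to_numpy(dtype=float)
        cells.append((rec, SpikeTrain(rec.cell_id, times)))

    orphans = set(spikes_df["cell_id"]) - set(cells_df["cell_id"])
    if orphans:
        raise ValidationError(f"spikes.csv has unknown cell_id(s): {sorted(orphans)}")

    respiration = None
    resp_path = directory / "respiration.csv"
    if resp_path.is_file():
        if "resp_sample_rate_hz" not in manifest:
            raise ValidationError("respiration.csv present but manifest lacks resp_sample_rate_hz")
        values = pd.read_csv(resp_path, float_precision="round_trip")[
            "value"
        ].to_numpy(dtype=float)
        respiration = RespirationTrace(
            sample_rate=float(manifest["resp_sample_rate_hz"]),
            values=values,
            t0=float(manifest.get("resp_t0_s", 0.0)),
        )

    return Session(
        cells=tuple(cells),
        events=events,
        duration_s=float(manifest["duration_s"]),
        respiration=respiration,
        session_id=str(manifest.get("session_id", directory.name)),
    )


def read_cohort(root: Union[str, Path]) -> list[Session]:
    """Read every session directory directly under ``root`` (sorted by name)."""
    root = Path(root)
    sessions = []
    for entry in sorted(os.listdir(root)):
        path = root / entry
        if path.is_dir() and (path / "session.yaml").is_file():
            sessions.append(read_session(path))
    if not sessions:
        raise SessionLoadError(f"no session directories found under {root}")
    return sessions
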