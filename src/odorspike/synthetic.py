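"""Synthetic sessions with the statistical structure the analyses assume.

A simulated unit fires as an inhomogeneous Poisson process whose intensity
is a product of three factors::

    lambda(t) = baseline_rate
                * exp(kappa * cos(phi(t) - mu)) / I0(kappa)   # respiratory gain
                * odor_gain(t)                                # excitatory transients

The von Mises respiratory gain is normalized by I0(kappa) so its mean over
a cycle is 1 and the off-odor rate equals the baseline rate.  Baseline
rates are log-normal (median ~1.4 Hz), respiration runs near 3 Hz with
gamma-distributed cycle durations, and a minority of cells carry
odor-selective excitatory transients that begin shortly after odor onset
and outlast odor offset.  Spikes are drawn by thinning against the
intensity's upper bound, and all ground truth is retained for
parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import i0

from .core import (
    AnalysisWindows,
    CellRecord,
    EventTable,
    RespirationTrace,
    Session,
    SpikeTrain,
)
from .phase import RespCycleTable
from . import session_io


@dataclass(frozen=True)
class CellGroundTruth:
    """Generative parameters for one simulated unit."""

    cell_id: str
    region: str
    subject_id: str
    sex: str
    baseline_rate_hz: float
    resp_kappa: float
    resp_mu_deg: float
    responsive_odors: tuple[str, ...]
    response_gain: float  # multiplicative, >= 1 (excitatory only)
    response_latency_s: float
    response_duration_s: float

    def __post_init__(self) -> None:
        if self.baseline_rate_hz <= 0:
            raise ValueError("baseline_rate_hz must be > 0")
        if self.resp_kappa < 0:
            raise ValueError("resp_kappa must be >= 0")
        if self.response_gain < 1:
            raise ValueError("response_gain must be >= 1 (excitatory only)")


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults follow the stimulus protocol and cohort structure the analyses
    target: 2 s odor pulses with a 28 s interstimulus interval, 8 trials of
    each of 11 odorants plus a vehicle channel, ~3 Hz respiration with
    variable cycle durations, log-normal spontaneous rates with median
    1.4 Hz, and region-specific fractions of odor-responsive cells.
    """

    n_cells: dict = field(default_factory=lambda: {"DTT": 37, "AON": 37})
    n_odorants: int = 11
    n_trials: int = 8
    odor_dur_s: float = 2.0
    isi_s: float = 28.0
    lead_in_s: float = 30.0
    cells_per_subject: int = 4

    resp_rate_hz: float = 3.0
    resp_cycle_cv: float = 0.15
    resp_sample_rate_hz: float = 100.0
    resp_noise_sd: float = 0.05

    baseline_median_hz: float = 1.4
    baseline_sigma_log: float = 1.0

    frac_modulated: float = 0.6
    kappa_median: float = 0.8
    kappa_sigma_log: float = 0.5
    resp_mu_mean_deg: float = 25.0
    resp_mu_sd_deg: float = 15.0

    fraction_responsive: dict = field(
        default_factory=lambda: {"DTT": 0.30, "AON": 0.11}
    )
    n_responsive_odors_range: tuple = (2, 6)
    gain_median: float = 4.0
    gain_sigma_log: float = 0.4
    response_latency_mean_s: float = 0.4
    response_latency_sd_s: float = 0.15
    response_duration_mean_s: float = 5.0
    response_duration_sd_s: float = 1.0

    seed: int = 0

    @property
    def odor_ids(self) -> list[str]:
        return [f"odor{i + 1:02d}" for i in range(self.n_odorants)]

    @property
    def vehicle_id(self) -> str:
        return "vehicle"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_responsive_odors_range"] = list(self.n_responsive_odors_range)
        return d


def simulate_respiration(
    duration_s: float,
    mean_rate_hz: float = 3.0,
    cycle_cv: float = 0.15,
    sample_rate_hz: float = 100.0,
    noise_sd: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> tuple[RespirationTrace, RespCycleTable]:
    """Simulated piezo-like respiration signal with ground-truth cycles.

    Cycle durations are gamma distributed with the given mean (1/rate) and
    coefficient of variation; each cycle is rendered as one sinusoid period
    plus additive Gaussian noise.  Only cycles fully inside the trace are
    returned.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng() if rng is None else rng
    mean_dur = 1.0 / mean_rate_hz
    n_guess = int(duration_s / mean_dur * 1.3) + 10
    if cycle_cv == 0:
        durs = np.full(n_guess, mean_dur)
    else:
        shape = 1.0 / cycle_cv**2
        durs = rng.gamma(shape, mean_dur / shape, size=n_guess)
    while durs.sum() < duration_s + mean_dur:
        extra = (
            np.full(n_guess, mean_dur)
            if cycle_cv == 0
            else rng.gamma(1.0 / cycle_cv**2, mean_dur * cycle_cv**2, size=n_guess)
        )
        durs = np.concatenate([durs, extra])
    bounds = np.concatenate([[0.0], np.cumsum(durs)])

    n_samples = int(round(duration_s * sample_rate_hz))
    t = np.arange(n_samples) / sample_rate_hz
    idx = np.searchsorted(bounds, t, side="right") - 1
    frac = (t - bounds[idx]) / durs[idx]
    values = np.sin(2 * np.pi * frac)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_samples)

    keep = bounds[1:] <= duration_s
    cycles = RespCycleTable(
        starts_s=bounds[:-1][keep], ends_s=bounds[1:][keep], origin="inspiration-onset"
    )
    trace = RespirationTrace(sample_rate=sample_rate_hz, values=values, t0=0.0)
    return trace, cycles


def make_event_schedule(
    config: SimConfig, rng: np.random.Generator
) -> tuple[EventTable, float]:
    """Pseudorandom block schedule: every stimulus once per block.

    Returns the event table and the session duration (last offset plus one
    full interstimulus interval).
    """
    stimuli = config.odor_ids + [config.vehicle_id]
    rows = []
    t = config.lead_in_s
    step = config.odor_dur_s + config.isi_s
    for _ in range(config.n_trials):
        order = rng.permutation(len(stimuli))
        for j in order:
            rows.append(
                {
                    "odor_id": stimuli[j],
                    "is_vehicle": stimuli[j] == config.vehicle_id,
                    "onset_s": t,
                    "offset_s": t + config.odor_dur_s,
                }
            )
            t += step
    duration = rows[-1]["offset_s"] + config.isi_s
    return EventTable(pd.DataFrame(rows)), float(duration)


def _odor_gain_windows(
    truth: CellGroundTruth, events: EventTable
) -> tuple[np.ndarray, np.ndarray]:
    """Start/end times of the cell's excitatory-transient windows."""
    starts, ends = [], []
    for odor in truth.responsive_odors:
        for onset in events.onsets_for(odor):
            starts.append(onset + truth.response_latency_s)
            ends.append(onset + truth.response_latency_s + truth.response_duration_s)
    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    order = np.argsort(starts)
    return starts[order], ends[order]


def simulate_cell_spikes(
    truth: CellGroundTruth,
    events: EventTable,
    cycles: RespCycleTable,
    duration_s: float,
    rng: Optional[np.random.Generator] = None,
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes by thinning against the intensity bound.

    Candidate spikes are homogeneous Poisson at the intensity's upper bound
    and retained with probability lambda(t)/lambda_max.  Spikes outside any
    ground-truth cycle see unit respiratory gain.
    """
    rng = np.random.default_rng() if rng is None else rng
    kappa = truth.resp_kappa
    vm_norm = i0(kappa)
    vm_max = math.exp(kappa) / vm_norm
    lam_max = truth.baseline_rate_hz * vm_max * truth.response_gain

    n_cand = rng.poisson(lam_max * duration_s)
    t = np.sort(rng.uniform(0.0, duration_s, size=n_cand))

    lam = np.full(t.shape, truth.baseline_rate_hz)
    if kappa > 0 and len(cycles):
        idx = np.searchsorted(cycles.starts_s, t, side="right") - 1
        valid = idx >= 0
        inside = np.zeros(t.size, dtype=bool)
        inside[valid] = t[valid] < cycles.ends_s[idx[valid]]
        phi = (
            2
            * np.pi
            * (t[inside] - cycles.starts_s[idx[inside]])
            / cycles.durations_s[idx[inside]]
        )
        mu = math.radians(truth.resp_mu_deg)
        lam[inside] *= np.exp(kappa * np.cos(phi - mu)) / vm_norm

    if truth.responsive_odors and truth.response_gain > 1:
        starts, ends = _odor_gain_windows(truth, events)
        if starts.size:
            widx = np.searchsorted(starts, t, side="right") - 1
            on = (widx >= 0) & (t < ends[np.clip(widx, 0, None)])
            lam[on] *= truth.response_gain

    accept = rng.uniform(0.0, lam_max, size=t.size) < lam
    times = np.unique(t[accept])
    return SpikeTrain(truth.cell_id, times)


def simulate_cohort(config: SimConfig) -> tuple[list[Session], pd.DataFrame]:
    """Simulate a full cohort of sessions plus the ground-truth table.

    One session per synthetic subject (``cells_per_subject`` cells each,
    regions interleaved so every region appears across subjects); a single
    seed drives deterministic per-subject and per-cell substreams.
    """
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    # interleave regions across the cohort so subjects mix regions
    regions: list[str] = []
    for region in sorted(config.n_cells):
        regions.extend([region] * int(config.n_cells[region]))
    order = master.permutation(len(regions))
    regions = [regions[i] for i in order]
    n_total = len(regions)
    if n_total == 0:
        raise ValueError("config.n_cells is empty")

    # deterministic responsive-cell assignment: exactly round(frac * n) per region
    responsive_ids: set[int] = set()
    for region in sorted(config.n_cells):
        members = [i for i, r in enumerate(regions) if r == region]
        frac = float(config.fraction_responsive.get(region, 0.0))
        n_resp = int(round(frac * len(members)))
        chosen = master.choice(len(members), size=n_resp, replace=False)
        responsive_ids.update(members[int(i)] for i in chosen)

    n_subjects = math.ceil(n_total / config.cells_per_subject)
    sessions: list[Session] = []
    truth_rows: list[dict] = []
    cell_idx = 0
    for s in range(n_subjects):
        subj_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + s]))
        subject_id = f"subj{s + 1:02d}"
        sex = str(subj_rng.choice(["F", "M"]))
        events, duration = make_event_schedule(config, subj_rng)
        trace, cycles = simulate_respiration(
            duration,
            mean_rate_hz=config.resp_rate_hz,
            cycle_cv=config.resp_cycle_cv,
            sample_rate_hz=config.resp_sample_rate_hz,
            noise_sd=config.resp_noise_sd,
            rng=subj_rng,
        )
        cells = []
        n_here = min(config.cells_per_subject, n_total - cell_idx)
        for _ in range(n_here):
            i = cell_idx
            cell_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2_000_000 + i]))
            cell_id = f"cell{i + 1:03d}"
            region = regions[i]
            baseline = config.baseline_median_hz * math.exp(
                config.baseline_sigma_log * cell_rng.normal()
            )
            modulated = cell_rng.uniform() < config.frac_modulated
            kappa = (
                config.kappa_median
                * math.exp(config.kappa_sigma_log * cell_rng.normal())
                if modulated
                else 0.0
            )
            mu = float(
                np.mod(
                    cell_rng.normal(config.resp_mu_mean_deg, config.resp_mu_sd_deg),
                    360.0,
                )
            )
            if i in responsive_ids:
                lo, hi = config.n_responsive_odors_range
                k = int(cell_rng.integers(lo, hi + 1))
                odors = tuple(
                    sorted(
                        cell_rng.choice(config.odor_ids, size=min(k, config.n_odorants), replace=False)
                    )
                )
                gain = max(
                    1.2,
                    config.gain_median
                    * math.exp(config.gain_sigma_log * cell_rng.normal()),
                )
                latency = max(0.1, cell_rng.normal(config.response_latency_mean_s, config.response_latency_sd_s))
                resp_dur = max(1.0, cell_rng.normal(config.response_duration_mean_s, config.response_duration_sd_s))
            else:
                odors, gain, latency, resp_dur = (), 1.0, 0.0, 0.0
            truth = CellGroundTruth(
                cell_id=cell_id,
                region=region,
                subject_id=subject_id,
                sex=sex,
                baseline_rate_hz=baseline,
                resp_kappa=kappa,
                resp_mu_deg=mu,
                responsive_odors=odors,
                response_gain=gain,
                response_latency_s=latency if odors else 0.0,
                response_duration_s=resp_dur if odors else 0.0,
            )
            train = simulate_cell_spikes(truth, events, cycles, duration, cell_rng)
            rec = CellRecord(
                cell_id=cell_id, region=region, subject_id=subject_id, sex=sex
            )
            cells.append((rec, train))
            truth_rows.append(
                {
                    "cell_id": cell_id,
                    "session_id": subject_id,
                    "region": region,
                    "subject_id": subject_id,
                    "sex": sex,
                    "baseline_rate_hz": baseline,
                    "resp_kappa": kappa,
                    "resp_mu_deg": mu,
                    "is_responsive": bool(odors),
                    "n_responsive_odors": len(odors),
                    "responsive_odors": ";".join(odors),
                    "response_gain": gain,
                    "response_latency_s": truth.response_latency_s,
                    "response_duration_s": truth.response_duration_s,
                    "n_spikes": train.n_spikes,
                }
            )
            cell_idx += 1
        sessions.append(
            Session(
                cells=tuple(cells),
                events=events,
                duration_s=duration,
                respiration=trace,
                session_id=subject_id,
            )
        )
    return sessions, pd.DataFrame(truth_rows)


def write_cohort(
    sessions: Sequence[Session],
    truth: pd.DataFrame,
    config: SimConfig,
    root: Path,
) -> None:
    """Write sessions in the delimited dialect plus ground truth and config echo."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for session in sessions:
        session_io.write_session(session, root / session.session_id)
    truth.to_csv(root / "ground_truth.csv", index=False, float_format="%.17g")
    with open(root / "sim_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
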