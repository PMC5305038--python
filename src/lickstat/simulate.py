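"""Synthetic lick-train generator emulating a two-group lickometry study.

Generates clustered lick trains as a renewal-style process: a session is a
sequence of drinking clusters separated by long pauses.  Within-cluster
ILIs are gamma distributed (positive support, low CV); pauses are a shifted
lognormal whose hard minimum exceeds any sensible pause criterion, so the
generator's cluster structure is exactly recoverable by segmentation.
Per-lick volumes are lognormal around the group mean; session consumption
is their sum.  Timestamps are quantised to the recorder resolution
(0.01 s by default), resolving collisions by pushing the later lick up one
resolution step.

Distribution shapes and the default group parameter values are plausible
rat drinking values chosen for the simulator — they are modelling
assumptions, not measured constants.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .microstructure import (
    EVENTS_COLUMNS,
    SESSIONS_COLUMNS,
    SessionRecord,
)

__all__ = [
    "GroupParams",
    "CohortConfig",
    "SessionTruth",
    "simulate_session",
    "simulate_cohort",
    "write_dataset",
    "default_control_params",
    "default_mcao_params",
]

# Lognormal shape parameters for per-lick volume and pause duration.
_VOLUME_SIGMA = 0.25
_PAUSE_SIGMA = 0.4


def _require_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and strictly positive, got {value!r}")


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one experimental group.

    ``pause_min`` is the hard lower bound of the between-cluster pause; it
    must stay above the pause criterion used downstream or generated
    clusters would merge at segmentation time.
    """

    mean_volume_per_lick_ul: float = 5.0
    ili_mean_s: float = 0.14
    ili_cv: float = 0.05
    cluster_size_mean: float = 40.0
    pause_mean_s: float = 6.0
    clusters_per_session_mean: float = 12.0
    session_duration_s: float = 900.0
    pause_min_s: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "mean_volume_per_lick_ul",
            "ili_mean_s",
            "cluster_size_mean",
            "pause_mean_s",
            "session_duration_s",
            "pause_min_s",
        ):
            _require_positive(name, getattr(self, name))
        if not 0 < self.ili_cv < 1:
            raise ValueError(f"ili_cv must lie in (0, 1), got {self.ili_cv!r}")
        if self.cluster_size_mean < 1:
            raise ValueError("cluster_size_mean must be >= 1")
        if not math.isfinite(self.clusters_per_session_mean) or (
            self.clusters_per_session_mean < 0
        ):
            raise ValueError("clusters_per_session_mean must be >= 0")
        if self.pause_mean_s <= self.pause_min_s:
            raise ValueError("pause_mean_s must exceed pause_min_s")


def default_control_params() -> GroupParams:
    return GroupParams()


def default_mcao_params() -> GroupParams:
    """Effect structure: ~20% lower volume per lick, more but smaller
    clusters, identical ILI distribution."""
    return GroupParams(
        mean_volume_per_lick_ul=4.0,
        cluster_size_mean=32.0,
        clusters_per_session_mean=16.0,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study-design configuration: 30 control vs 22 MCAO subjects, 4 daily
    15-min sessions, 0.01 s timestamp resolution."""

    n_control: int = 30
    n_mcao: int = 22
    sessions_per_subject: int = 4
    control_params: GroupParams = field(default_factory=default_control_params)
    mcao_params: GroupParams = field(default_factory=default_mcao_params)
    timestamp_resolution_s: float = 0.01
    master_seed: int = 0
    n_mcao_striatal: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_control", "n_mcao", "sessions_per_subject"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        _require_positive("timestamp_resolution_s", self.timestamp_resolution_s)
        if self.n_mcao_striatal is not None and not (
            0 <= self.n_mcao_striatal <= self.n_mcao
        ):
            raise ValueError("n_mcao_striatal must lie in [0, n_mcao]")

    @property
    def striatal_count(self) -> int:
        """Number of MCAO subjects labelled striatal-only (remainder are
        striatal+cortical).  Defaults to the 13/22 study proportion."""
        if self.n_mcao_striatal is not None:
            return self.n_mcao_striatal
        return round(self.n_mcao * 13 / 22)


@dataclass(frozen=True)
class SessionTruth:
    """Generator-side ground truth for one session (before truncation the
    session is a concatenation of these clusters)."""

    cluster_sizes: tuple[int, ...]
    pauses: tuple[float, ...]

    @property
    def cluster_count(self) -> int:
        return len(self.cluster_sizes)


def _quantise(times: np.ndarray, resolution: float) -> np.ndarray:
    q = np.round(times / resolution) * resolution
    # Collisions after rounding: push the later lick up one step (cascade).
    for i in range(1, q.size):
        if q[i] <= q[i - 1]:
            q[i] = q[i - 1] + resolution
    return np.round(q / resolution) * resolution


def _session_rng(master_seed: int, subject_index: int, session_index: int):
    ss = np.random.SeedSequence(
        entropy=master_seed, spawn_key=(subject_index, session_index)
    )
    return np.random.default_rng(ss)


def simulate_session(
    params: GroupParams,
    seed,
    *,
    subject_id: str = "sim",
    group: str = "control",
    lesion_subtype: str = "none",
    session_index: int = 0,
    timestamp_resolution_s: float = 0.01,
    return_truth: bool = False,
):
    """Simulate one session; deterministic for a fixed seed and parameters.

    ``seed`` may be an int, a SeedSequence, or a Generator.  With
    ``return_truth=True`` also returns the generator's cluster structure
    for segmentation oracles.
    """
    rng = np.random.default_rng(seed)
    n_clusters = int(rng.poisson(params.clusters_per_session_mean))

    ili_shape = 1.0 / params.ili_cv**2
    ili_scale = params.ili_mean_s * params.ili_cv**2
    pause_body_mean = params.pause_mean_s - params.pause_min_s
    pause_mu = math.log(pause_body_mean) - _PAUSE_SIGMA**2 / 2
    vol_mu = math.log(params.mean_volume_per_lick_ul) - _VOLUME_SIGMA**2 / 2

    times_parts: list[np.ndarray] = []
    sizes: list[int] = []
    pauses: list[float] = []
    t = float(params.pause_min_s + rng.lognormal(pause_mu, _PAUSE_SIGMA))
    for _ in range(n_clusters):
        size = 1 + int(rng.poisson(params.cluster_size_mean - 1))
        ilis = rng.gamma(ili_shape, ili_scale, size=size - 1)
        cluster_times = t + np.concatenate(([0.0], np.cumsum(ilis)))
        times_parts.append(cluster_times)
        sizes.append(size)
        pause = float(params.pause_min_s + rng.lognormal(pause_mu, _PAUSE_SIGMA))
        pauses.append(pause)
        t = float(cluster_times[-1] + pause)

    times = np.concatenate(times_parts) if times_parts else np.empty(0)
    keep = times < params.session_duration_s
    times = times[keep]
    times = _quantise(times, timestamp_resolution_s)

    volumes_ul = rng.lognormal(vol_mu, _VOLUME_SIGMA, size=times.size)
    record = SessionRecord(
        subject_id=subject_id,
        group=group,
        lesion_subtype=lesion_subtype,
        session_index=session_index,
        lick_times=times,
        consumption_ml=float(volumes_ul.sum() / 1000.0),
    )
    if return_truth:
        # Truncated truth: clusters with at least one surviving lick.
        surviving = []
        offset = 0
        n_kept = int(keep.sum())
        for size in sizes:
            kept_here = min(max(n_kept - offset, 0), size)
            if kept_here > 0:
                surviving.append(kept_here)
            offset += size
        truth = SessionTruth(cluster_sizes=tuple(surviving), pauses=tuple(pauses))
        return record, truth
    return record


def simulate_cohort(config: CohortConfig) -> list[SessionRecord]:
    """Simulate the full cohort; per-session seeds derive deterministically
    from the master seed and subject/session indices, so the result is
    independent of iteration order."""
    records: list[SessionRecord] = []
    n_striatal = config.striatal_count
    for subject_index in range(config.n_control + config.n_mcao):
        if subject_index < config.n_control:
            group, params = "control", config.control_params
            subtype = "none"
            subject_id = f"C{subject_index + 1:03d}"
        else:
            group, params = "mcao", config.mcao_params
            mcao_rank = subject_index - config.n_control
            subtype = "striatal" if mcao_rank < n_striatal else "striatal_cortical"
            subject_id = f"M{mcao_rank + 1:03d}"
        for session_index in range(config.sessions_per_subject):
            rng = _session_rng(config.master_seed, subject_index, session_index)
            records.append(
                simulate_session(
                    params,
                    rng,
                    subject_id=subject_id,
                    group=group,
                    lesion_subtype=subtype,
                    session_index=session_index,
                    timestamp_resolution_s=config.timestamp_resolution_s,
                )
            )
    return records


def write_dataset(
    records: Sequence[SessionRecord],
    directory,
    timestamp_resolution_s: float = 0.01,
) -> tuple[Path, Path]:
    """Write ``events.csv`` and ``sessions.csv`` for a dataset.

    Timestamps must sit on the resolution grid and remain strictly
    increasing at the written precision; off-grid data are rejected before
    anything is written.
    """
    if not records:
        raise ValueError("write_dataset requires a non-empty dataset")
    for rec in records:
        times = rec.lick_times
        if times.size:
            on_grid = np.abs(
                times / timestamp_resolution_s
                - np.round(times / timestamp_resolution_s)
            )
            if np.any(on_grid > 1e-6):
                raise ValueError(
                    f"timestamps not on the {timestamp_resolution_s} s grid "
                    f"in subject {rec.subject_id} session {rec.session_index}"
                )

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    events_path = directory / "events.csv"
    sessions_path = directory / "sessions.csv"

    decimals = max(0, -int(math.floor(math.log10(timestamp_resolution_s))))
    event_rows = []
    session_rows = []
    for rec in records:
        for t in rec.lick_times:
            event_rows.append(
                (rec.subject_id, rec.group, rec.session_index, f"{t:.{decimals}f}")
            )
        session_rows.append(
            (
                rec.subject_id,
                rec.group,
                rec.lesion_subtype,
                rec.session_index,
                f"{rec.consumption_ml:.6f}",
            )
        )
    pd.DataFrame(event_rows, columns=EVENTS_COLUMNS).to_csv(events_path, index=False)
    pd.DataFrame(session_rows, columns=SESSIONS_COLUMNS).to_csv(
        sessions_path, index=False
    )
    return events_path, sessions_path
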