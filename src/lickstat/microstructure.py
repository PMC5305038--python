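"""Lick-event streams: parsing, cluster segmentation, and microstructure measures.

A drinking *cluster* is a maximal run of licks whose successive inter-lick
intervals (ILIs) are all below a pause criterion; a gap of at least the
criterion starts a new cluster.  Seven per-session measures are computed:
total water consumption, total lick count, lick volume (mL per 1000 licks),
mean licks per cluster, cluster count, mean within-cluster ILI, and ILI
variability (coefficient of variation, %).

Defaults for the pause criterion (0.5 s) and the ILI artifact floor
(0.05 s) follow common lickometry practice and are configurable; both are
analysis assumptions, not measured constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "LESION_SUBTYPES",
    "MEASURES",
    "SessionRecord",
    "Cluster",
    "MicrostructureSummary",
    "read_lick_events",
    "segment_clusters",
    "summarize_session",
    "aggregate_subject",
    "summarize_cohort",
    "write_subject_summaries",
]

GROUPS = ("control", "mcao")
LESION_SUBTYPES = ("none", "striatal", "striatal_cortical")

#: The seven microstructure measures, in reporting order.
MEASURES = (
    "consumption_ml",
    "total_licks",
    "lick_volume_ml_per_1000",
    "licks_per_cluster",
    "cluster_count",
    "ili_mean_s",
    "ili_cv_pct",
)

DEFAULT_PAUSE_CRITERION = 0.5
DEFAULT_ARTIFACT_FLOOR = 0.05


class ValidationError(ValueError):
    """Raised when input data violate the session-record contract."""


@dataclass(frozen=True)
class SessionRecord:
    """One subject-session: ordered lick timestamps plus measured consumption."""

    subject_id: str
    group: str
    session_index: int
    lick_times: np.ndarray
    consumption_ml: float
    lesion_subtype: str = "none"

    def __post_init__(self) -> None:
        times = np.asarray(self.lick_times, dtype=float)
        object.__setattr__(self, "lick_times", times)
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r} for subject {self.subject_id}"
            )
        if self.lesion_subtype not in LESION_SUBTYPES:
            raise ValidationError(
                f"unknown lesion subtype {self.lesion_subtype!r} "
                f"for subject {self.subject_id}"
            )
        if times.size and not np.all(np.diff(times) > 0):
            raise ValidationError(
                f"non-monotone lick timestamps in subject {self.subject_id} "
                f"session {self.session_index}"
            )
        if not np.isfinite(self.consumption_ml) or self.consumption_ml < 0:
            raise ValidationError(
                f"invalid consumption {self.consumption_ml!r} "
                f"for subject {self.subject_id} session {self.session_index}"
            )

    @property
    def n_licks(self) -> int:
        return int(self.lick_times.size)


@dataclass(frozen=True)
class Cluster:
    """A maximal run of licks with all internal ILIs below the pause criterion."""

    start_index: int
    end_index: int
    ilis: np.ndarray

    @property
    def lick_count(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass(frozen=True)
class MicrostructureSummary:
    """The seven per-session (or per-subject) microstructure measures.

    Missing values (e.g. for a session with zero licks) are ``nan``.
    """

    consumption_ml: float
    total_licks: float
    lick_volume_ml_per_1000: float
    licks_per_cluster: float
    cluster_count: float
    ili_mean_s: float
    ili_cv_pct: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MEASURES}


def segment_clusters(
    lick_times: Sequence[float] | np.ndarray, pause_criterion: float
) -> list[Cluster]:
    """Partition strictly increasing lick times into drinking clusters.

    A new cluster starts exactly when an inter-lick interval is >= the
    pause criterion.  Empty input yields an empty list.
    """
    if pause_criterion <= 0:
        raise ValueError("pause_criterion must be positive")
    times = np.asarray(lick_times, dtype=float)
    if times.size == 0:
        return []
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValidationError("lick times must be strictly increasing")

    ilis = np.diff(times)
    # Cluster boundaries fall after each ILI >= criterion.
    breaks = np.flatnonzero(ilis >= pause_criterion)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [times.size - 1]))
    return [
        Cluster(start_index=int(s), end_index=int(e), ilis=ilis[s:e])
        for s, e in zip(starts, ends)
    ]


def _within_cluster_ilis(
    clusters: Sequence[Cluster], artifact_floor: float
) -> np.ndarray:
    if not clusters:
        return np.empty(0)
    ilis = np.concatenate([c.ilis for c in clusters]) if clusters else np.empty(0)
    return ilis[ilis >= artifact_floor]


def summarize_session(
    record: SessionRecord,
    pause_criterion: float = DEFAULT_PAUSE_CRITERION,
    artifact_floor: float = DEFAULT_ARTIFACT_FLOOR,
) -> MicrostructureSummary:
    """Compute the seven microstructure measures for one session.

    ILI statistics use within-cluster ILIs only, after dropping intervals
    below ``artifact_floor`` (spurious double contacts).  ILI variability is
    100 * sample SD / mean.  With zero licks every lick-derived measure is
    ``nan`` and only consumption is reported.
    """
    n = record.n_licks
    if n == 0:
        nan = float("nan")
        return MicrostructureSummary(
            consumption_ml=record.consumption_ml,
            total_licks=0.0,
            lick_volume_ml_per_1000=nan,
            licks_per_cluster=nan,
            cluster_count=0.0,
            ili_mean_s=nan,
            ili_cv_pct=nan,
        )

    clusters = segment_clusters(record.lick_times, pause_criterion)
    ilis = _within_cluster_ilis(clusters, artifact_floor)

    lick_volume = 1000.0 * record.consumption_ml / n
    counts = np.array([c.lick_count for c in clusters], dtype=float)

    if ilis.size == 0:
        ili_mean = float("nan")
        ili_cv = float("nan")
    else:
        ili_mean = float(np.mean(ilis))
        if ilis.size >= 2:
            sd = float(np.std(ilis, ddof=1))
            ili_cv = 100.0 * sd / ili_mean if ili_mean > 0 else float("nan")
        else:
            ili_cv = float("nan")

    return MicrostructureSummary(
        consumption_ml=record.consumption_ml,
        total_licks=float(n),
        lick_volume_ml_per_1000=lick_volume,
        licks_per_cluster=float(np.mean(counts)),
        cluster_count=float(len(clusters)),
        ili_mean_s=ili_mean,
        ili_cv_pct=ili_cv,
    )


def aggregate_subject(
    summaries: Sequence[MicrostructureSummary],
) -> MicrostructureSummary:
    """Average per-session summaries into one per-subject summary.

    Each measure is the unweighted mean across sessions, ignoring missing
    (nan) session values — not a re-pooling of raw licks.
    """
    if not summaries:
        raise ValueError("aggregate_subject requires at least one session summary")
    values = {}
    for m in MEASURES:
        col = np.array([getattr(s, m) for s in summaries], dtype=float)
        finite = col[np.isfinite(col)]
        values[m] = float(np.mean(finite)) if finite.size else float("nan")
    return MicrostructureSummary(**values)


# ---------------------------------------------------------------------------
# I/O: events.csv / sessions.csv dialects
# ---------------------------------------------------------------------------

EVENTS_COLUMNS = ["subject_id", "group", "session_index", "lick_time_s"]
SESSIONS_COLUMNS = [
    "subject_id",
    "group",
    "lesion_subtype",
    "session_index",
    "consumption_ml",
]


def read_lick_events(events_path, sessions_path) -> list[SessionRecord]:
    """Load session records from the events/sessions CSV pair.

    One record is produced per row of ``sessions.csv``; sessions with no
    event rows get empty lick trains.  Event rows may arrive in any order —
    timestamps are sorted within each session; exact duplicates are a
    validation error.
    """
    sessions = pd.read_csv(sessions_path, dtype={"subject_id": str})
    missing = set(SESSIONS_COLUMNS) - set(sessions.columns)
    if missing:
        raise ValidationError(f"sessions file missing columns: {sorted(missing)}")
    events = pd.read_csv(events_path, dtype={"subject_id": str})
    missing = set(EVENTS_COLUMNS) - set(events.columns)
    if missing:
        raise ValidationError(f"events file missing columns: {sorted(missing)}")

    grouped = {
        key: np.sort(sub["lick_time_s"].to_numpy(dtype=float))
        for key, sub in events.groupby(["subject_id", "session_index"], sort=False)
    }

    records = []
    for row in sessions.itertuples(index=False):
        key = (row.subject_id, row.session_index)
        times = grouped.pop(key, np.empty(0))
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError(
                f"duplicate lick timestamps in subject {row.subject_id} "
                f"session {row.session_index}"
            )
        records.append(
            SessionRecord(
                subject_id=row.subject_id,
                group=row.group,
                lesion_subtype=row.lesion_subtype,
                session_index=int(row.session_index),
                lick_times=times,
                consumption_ml=float(row.consumption_ml),
            )
        )
    if grouped:
        orphan = next(iter(grouped))
        raise ValidationError(
            f"event rows for subject {orphan[0]} session {orphan[1]} "
            "have no matching sessions.csv row"
        )
    return records


def summarize_cohort(
    records: Sequence[SessionRecord],
    pause_criterion: float = DEFAULT_PAUSE_CRITERION,
    artifact_floor: float = DEFAULT_ARTIFACT_FLOOR,
) -> pd.DataFrame:
    """Per-subject summary table: metadata columns then the seven measures.

    Sessions are summarised individually, then averaged per subject via
    :func:`aggregate_subject`.
    """
    by_subject: dict[str, list[SessionRecord]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, []).append(rec)

    rows = []
    for subject_id, recs in by_subject.items():
        summaries = [
            summarize_session(r, pause_criterion, artifact_floor) for r in recs
        ]
        agg = aggregate_subject(summaries)
        rows.append(
            {
                "subject_id": subject_id,
                "group": recs[0].group,
                "lesion_subtype": recs[0].lesion_subtype,
                **agg.as_dict(),
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "group", "lesion_subtype", *MEASURES])


def write_subject_summaries(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
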