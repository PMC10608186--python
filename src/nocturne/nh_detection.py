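"""Detection of nocturnal hypoglycemia (NH) episodes.

An NH episode is a maximal run of consecutive readings with interstitial
glucose strictly below 3.9 mmol/L sustained for at least 15 minutes, i.e. at
least three consecutive 5-minute readings, anywhere between midnight and
6 a.m.  Detection always operates on the mmol/L series, never on
standardized values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cgm_io import NocturnalSegment, SLOT_MINUTES

NH_THRESHOLD = 3.9  # mmol/L
MIN_DURATION_MIN = 15.0


@dataclass(frozen=True)
class NHEpisode:
    """A maximal sub-threshold run: start slot, reading count, clock start time."""

    start_index: int
    n_readings: int

    @property
    def start_time_h(self) -> float:
        return self.start_index * SLOT_MINUTES / 60.0

    @property
    def duration_min(self) -> float:
        return self.n_readings * SLOT_MINUTES


@dataclass
class GroupPartition:
    """Kept segments split by NH presence; disjoint and jointly exhaustive."""

    nh_group: list
    non_nh_group: list
    episodes: dict  # (patient_id, night_date) -> list[NHEpisode]


def _values(segment) -> np.ndarray:
    if isinstance(segment, NocturnalSegment):
        return segment.values
    return np.asarray(segment, dtype=float)


def detect_nh_episodes(
    segment,
    threshold: float = NH_THRESHOLD,
    min_duration_min: float = MIN_DURATION_MIN,
) -> list[NHEpisode]:
    """Return all maximal runs of consecutive readings < ``threshold`` lasting
    at least ``min_duration_min``, in time order.

    At the 5-minute cadence the default 15-minute minimum means at least 3
    consecutive readings; a reading exactly at the threshold breaks a run
    (strict inequality).
    """
    values = _values(segment)
    if np.isnan(values).any():
        raise ValueError("NH detection requires a fully imputed segment")
    min_readings = int(np.ceil(min_duration_min / SLOT_MINUTES))
    below = values < threshold
    episodes: list[NHEpisode] = []
    i = 0
    n = len(below)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_readings:
                episodes.append(NHEpisode(start_index=i, n_readings=j - i))
            i = j
        else:
            i += 1
    return episodes


def first_episode_start_time(episodes: list[NHEpisode]) -> float | None:
    """Decimal-hour start of the earliest episode, or None when there is none."""
    if not episodes:
        return None
    return min(episodes, key=lambda e: e.start_index).start_time_h


def partition_by_nh(
    segments: list[NocturnalSegment],
    threshold: float = NH_THRESHOLD,
    min_duration_min: float = MIN_DURATION_MIN,
) -> GroupPartition:
    """Split segments into the NH group (>=1 episode) and the non-NH group."""
    nh, non_nh, episodes = [], [], {}
    for seg in segments:
        eps = detect_nh_episodes(seg, threshold, min_duration_min)
        episodes[(seg.patient_id, seg.night_date)] = eps
        (nh if eps else non_nh).append(seg)
    return GroupPartition(nh_group=nh, non_nh_group=non_nh, episodes=episodes)


def episodes_to_frame(partition: GroupPartition, segments: list[NocturnalSegment]) -> pd.DataFrame:
    """Episode table (one row per episode) for reporting."""
    by_key = {(s.patient_id, s.night_date): s for s in segments}
    rows = []
    for (pid, night), eps in partition.episodes.items():
        seg = by_key[(pid, night)]
        for e in eps:
            window = seg.values[e.start_index : e.start_index + e.n_readings]
            rows.append(
                {
                    "patient_id": pid,
                    "night_date": str(night),
                    "start_index": e.start_index,
                    "start_time_h": e.start_time_h,
                    "n_readings": e.n_readings,
                    "min_glucose": float(np.min(window)),
                    "touches_imputed": bool(
                        seg.imputed_mask[e.start_index : e.start_index + e.n_readings].any()
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "night_date", "start_index", "start_time_h",
            "n_readings", "min_glucose", "touches_imputed",
        ],
    )
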