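"""Reading, nocturnal segmentation, cleaning and standardization of CGM traces.

A recording is a per-patient time series of interstitial glucose sampled at a
nominal 5-minute cadence by a sensor that reports values in the device range
2.2--22.0 mmol/L.  The analysis operates on nocturnal segments: the 72
five-minute slots covering [00:00, 06:00) of one calendar night.  Segments
with a gap of three or more consecutive missing readings, or with more than
10% of the 72 slots missing, are excluded; remaining short gaps are filled by
neighbour averaging and each kept series is standardized to zero mean and
unit (population) variance before clustering.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEVICE_MIN = 2.2
DEVICE_MAX = 22.0
N_SLOTS = 72
SLOT_MINUTES = 5.0

#: Default tolerance (seconds) for snapping a reading to its nearest slot.
CADENCE_TOL_S = 90.0

REQUIRED_COLUMNS = ("patient_id", "timestamp", "glucose_mmol_l")


class OutOfRangePolicy(str, enum.Enum):
    """What to do with glucose values outside the device range."""

    REJECT = "reject"
    CLAMP = "clamp"
    MISSING = "missing"


class SegmentStatus(str, enum.Enum):
    RAW = "RAW"
    IMPUTED = "IMPUTED"
    EXCLUDED = "EXCLUDED"


class ExclusionReason(str, enum.Enum):
    LONG_GAP = "LONG_GAP"
    TOO_MANY_MISSING = "TOO_MANY_MISSING"


@dataclass(frozen=True)
class ExclusionDecision:
    keep: bool
    reason: ExclusionReason | None = None


@dataclass
class CGMRecord:
    """One patient's CGM trace; missing glucose is NaN."""

    patient_id: str
    timestamps: pd.DatetimeIndex
    glucose: np.ndarray

    def __post_init__(self) -> None:
        if len(self.timestamps) != len(self.glucose):
            raise ValueError("timestamps and glucose must have equal length")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")


@dataclass
class NocturnalSegment:
    """One night's glucose series on the fixed 72-slot grid (slot i = i*5 min after 00:00)."""

    patient_id: str
    night_date: object  # datetime.date
    values: np.ndarray  # length 72, mmol/L, NaN = missing
    imputed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    status: SegmentStatus = SegmentStatus.RAW
    exclusion_reason: ExclusionReason | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_SLOTS,):
            raise ValueError(f"segment must have exactly {N_SLOTS} slots")
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros(N_SLOTS, dtype=bool)
        else:
            self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())


@dataclass
class StandardizedSegment:
    """A fully imputed segment rescaled to zero mean and unit population variance."""

    source: NocturnalSegment
    zvalues: np.ndarray

    def __post_init__(self) -> None:
        self.zvalues = np.asarray(self.zvalues, dtype=float)
        if self.zvalues.shape != (N_SLOTS,):
            raise ValueError(f"standardized segment must have {N_SLOTS} values")


def parse_cgm_csv(
    path,
    oor_policy: OutOfRangePolicy | str = OutOfRangePolicy.MISSING,
    device_min: float = DEVICE_MIN,
    device_max: float = DEVICE_MAX,
) -> list[CGMRecord]:
    """Read a CGM export CSV into one :class:`CGMRecord` per patient.

    The file must have columns ``patient_id,timestamp,glucose_mmol_l`` with
    ISO-8601 timestamps.  Zero-coded glucose (the device export convention
    for a dropped reading) becomes missing.  Values outside the device range
    are handled per ``oor_policy``: treated as missing (default), clamped to
    the range, or rejected with an error.
    """
    oor_policy = OutOfRangePolicy(oor_policy)
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"input file is missing columns: {missing_cols}")
    if df.empty:
        return []

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        # +2: 1-based and the header line
        raise ValueError(
            f"unparseable timestamp {df['timestamp'].iloc[bad[0]]!r} at file row {bad[0] + 2}"
        )
    df = df.assign(timestamp=ts)

    dup = df.duplicated(subset=["patient_id", "timestamp"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate reading for patient {row['patient_id']} at {row['timestamp']}"
        )

    glucose = pd.to_numeric(df["glucose_mmol_l"], errors="coerce").to_numpy(dtype=float)
    glucose[glucose == 0.0] = np.nan  # zero-coded missing in device exports
    oor = ~np.isnan(glucose) & ((glucose < device_min) | (glucose > device_max))
    if oor.any():
        if oor_policy is OutOfRangePolicy.REJECT:
            i = int(np.flatnonzero(oor)[0])
            raise ValueError(
                f"glucose {glucose[i]} outside device range "
                f"[{device_min}, {device_max}] at file row {i + 2}"
            )
        if oor_policy is OutOfRangePolicy.CLAMP:
            glucose = np.clip(glucose, device_min, device_max)
        else:
            glucose[oor] = np.nan
    df = df.assign(glucose_mmol_l=glucose)

    records = []
    for pid, sub in df.groupby("patient_id", sort=True):
        sub = sub.sort_values("timestamp")
        records.append(
            CGMRecord(
                patient_id=str(pid),
                timestamps=pd.DatetimeIndex(sub["timestamp"]),
                glucose=sub["glucose_mmol_l"].to_numpy(dtype=float),
            )
        )
    return records


def extract_nocturnal_segments(
    record: CGMRecord, cadence_tol_s: float = CADENCE_TOL_S
) -> list[NocturnalSegment]:
    """Extract one RAW 72-slot segment per calendar night covered by the record.

    Readings in [00:00, 06:00) are snapped to the nearest 5-minute slot
    (ties to the earlier slot); readings farther than ``cadence_tol_s`` from
    every slot centre are dropped.  A night is emitted when at least one
    reading lands on its grid; unfilled slots are missing.  If two readings
    snap to the same slot the one closest to the slot centre wins.
    """
    nights: dict[object, tuple[np.ndarray, np.ndarray]] = {}
    for t, g in zip(record.timestamps, record.glucose):
        minutes = t.hour * 60.0 + t.minute + t.second / 60.0 + t.microsecond / 6e7
        if minutes >= 6 * 60:
            continue
        # nearest slot, ties to the earlier one
        slot = int(np.ceil(minutes / SLOT_MINUTES - 0.5))
        offset_s = abs(minutes - slot * SLOT_MINUTES) * 60.0
        if slot < 0 or slot >= N_SLOTS or offset_s > cadence_tol_s:
            continue
        key = t.date()
        if key not in nights:
            nights[key] = (np.full(N_SLOTS, np.nan), np.full(N_SLOTS, np.inf))
        values, offsets = nights[key]
        if offset_s < offsets[slot]:
            if np.isfinite(offsets[slot]):
                logger.warning(
                    "patient %s night %s: two readings map to slot %d; keeping the closer one",
                    record.patient_id, key, slot,
                )
            values[slot] = g
            offsets[slot] = offset_s
        elif np.isfinite(offsets[slot]):
            logger.warning(
                "patient %s night %s: two readings map to slot %d; keeping the closer one",
                record.patient_id, key, slot,
            )
    return [
        NocturnalSegment(patient_id=record.patient_id, night_date=key, values=vals)
        for key, (vals, _) in sorted(nights.items())
    ]


def apply_exclusion_filter(
    segment: NocturnalSegment,
    gap_run_exclude: int = 3,
    missing_frac_exclude: float = 0.10,
) -> ExclusionDecision:
    """Decide whether a raw segment is usable.

    Excluded if any run of ``gap_run_exclude`` or more consecutive slots is
    missing, or if strictly more than ``missing_frac_exclude`` of the 72
    slots are missing (at 10% that is 8 or more missing slots).
    """
    miss = segment.missing_mask
    run = 0
    for m in miss:
        run = run + 1 if m else 0
        if run >= gap_run_exclude:
            return ExclusionDecision(False, ExclusionReason.LONG_GAP)
    if miss.sum() > missing_frac_exclude * N_SLOTS:
        return ExclusionDecision(False, ExclusionReason.TOO_MANY_MISSING)
    return ExclusionDecision(True)


def impute_gaps(segment: NocturnalSegment) -> NocturnalSegment:
    """Fill missing slots: interior gaps get the mean of the nearest
    non-missing neighbours on each side; leading/trailing gaps copy the
    nearest numeric value.  Returns a new IMPUTED segment; observed values
    are never altered."""
    values = segment.values.copy()
    miss = np.isnan(values)
    if miss.all():
        raise ValueError("cannot impute a fully missing segment")
    if not miss.any():
        return replace(
            segment,
            values=values,
            imputed_mask=np.zeros(N_SLOTS, dtype=bool),
            status=SegmentStatus.IMPUTED,
        )
    obs = np.flatnonzero(~miss)
    for i in np.flatnonzero(miss):
        left = obs[obs < i]
        right = obs[obs > i]
        if left.size and right.size:
            values[i] = 0.5 * (values[left[-1]] + values[right[0]])
        elif right.size:
            values[i] = values[right[0]]
        else:
            values[i] = values[left[-1]]
    return replace(
        segment, values=values, imputed_mask=miss, status=SegmentStatus.IMPUTED
    )


def standardize(segment: NocturnalSegment) -> StandardizedSegment:
    """Rescale a fully imputed segment to zero mean, unit population variance."""
    values = segment.values
    if np.isnan(values).any():
        raise ValueError("segment must be fully imputed before standardization")
    sd = values.std()  # population (divide-by-n) convention -> variance exactly 1
    if sd == 0.0:
        raise ValueError(
            f"constant series (patient {segment.patient_id}, night {segment.night_date}) "
            "cannot be standardized; flag for manual exclusion"
        )
    return StandardizedSegment(source=segment, zvalues=(values - values.mean()) / sd)


# ---------------------------------------------------------------------------
# tabular round-trip

def segments_to_frame(segments: list[NocturnalSegment]) -> pd.DataFrame:
    """Segments table: patient_id, night_date, slot_0..slot_71, status, n_imputed."""
    rows = []
    for s in segments:
        row = {"patient_id": s.patient_id, "night_date": str(s.night_date)}
        row.update({f"slot_{i}": s.values[i] for i in range(N_SLOTS)})
        row["status"] = s.status.value
        row["n_imputed"] = int(s.imputed_mask.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def write_segments_csv(segments: list[NocturnalSegment], path) -> None:
    segments_to_frame(segments).to_csv(path, index=False)


def read_segments_csv(path) -> list[NocturnalSegment]:
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        values = np.array([row[f"slot_{i}"] for i in range(N_SLOTS)], dtype=float)
        seg = NocturnalSegment(
            patient_id=row["patient_id"],
            night_date=pd.Timestamp(row["night_date"]).date(),
            values=values,
            status=SegmentStatus(row["status"]),
        )
        out.append(seg)
    return out


def exclusion_manifest(
    segments: list[NocturnalSegment], decisions: list[ExclusionDecision]
) -> pd.DataFrame:
    """Audit table of every raw segment with its keep/exclude decision."""
    rows = []
    for seg, dec in zip(segments, decisions):
        rows.append(
            {
                "patient_id": seg.patient_id,
                "night_date": str(seg.night_date),
                "n_missing": seg.n_missing,
                "kept": dec.keep,
                "exclusion_reason": dec.reason.value if dec.reason else "",
            }
        )
    return pd.DataFrame(rows)
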