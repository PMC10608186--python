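import datetime

import numpy as np
import pandas as pd
import pytest

from nocturne.cgm_io import N_SLOTS, NocturnalSegment, SegmentStatus

NIGHT = datetime.date(2023, 3, 1)


def make_segment(values, patient_id="p1", night=NIGHT, status=SegmentStatus.RAW):
    """Build a 72-slot segment from a short pattern or full array.

    A short list is placed at the start of a baseline-6.0 night; NaN marks
    missing slots.
    """
    full = np.full(N_SLOTS, 6.0)
    values = np.asarray(values, dtype=float)
    if values.shape == (N_SLOTS,):
        full = values.copy()
    else:
        full[: len(values)] = values
    return NocturnalSegment(patient_id=patient_id, night_date=night, values=full, status=status)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def readings_csv_factory(tmp_path):
    """Write a readings CSV from (patient_id, timestamp, glucose) rows."""

    def write(rows, name="readings.csv"):
        path = tmp_path / name
        pd.DataFrame(rows, columns=["patient_id", "timestamp", "glucose_mmol_l"]).to_csv(
            path, index=False
        )
        return path

    return write


def full_night_rows(patient_id="p1", date="2023-03-01", level=6.5, n=N_SLOTS):
    """One complete night of 5-min readings starting at midnight."""
    base = pd.Timestamp(date)
    return [
        (patient_id, (base + pd.Timedelta(minutes=5 * i)).isoformat(), level)
        for i in range(n)
    ]
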