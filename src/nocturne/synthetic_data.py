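"""Synthetic nocturnal CGM generator.

Emulates the statistical structure of the published nocturnal glucose
patterns so the whole pipeline is exercisable without patient data.  Each
archetype is a piecewise-linear mean trajectory over the night (anchored at
the published initial/final glucose medians, with the shape read from the
qualitative pattern descriptions) plus stationary AR(1) noise, clamped to the
sensor range 2.2--22.0 mmol/L after noise addition (mimicking saturation).
NH archetypes dip below 3.9 mmol/L for at least 15 minutes inside their
published episode window; non-NH archetypes keep a safety margin above the
threshold so intended labels are recovered almost surely.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .cgm_io import (
    DEVICE_MAX,
    DEVICE_MIN,
    N_SLOTS,
    NocturnalSegment,
    SegmentStatus,
)
from .nh_detection import NH_THRESHOLD

SLOT_TIMES_H = np.arange(N_SLOTS) * 5.0 / 60.0

#: label-purity guard: a non-NH mean trajectory must stay this many noise
#: standard deviations above the hypoglycemia threshold
NON_NH_MARGIN_SD = 2.5

DEFAULT_NOISE_SD = 0.6
DEFAULT_AR_COEFF = 0.8

_SYNTHETIC_EPOCH = datetime.date(2023, 1, 1)


@dataclass
class ArchetypeSpec:
    """Generator parameters for one nocturnal glucose pattern."""

    name: str
    group: str  # "NH" | "NON_NH"
    breakpoints: list  # ordered (time_h, level mmol/L) pairs
    noise_sd: float = DEFAULT_NOISE_SD
    ar_coeff: float = DEFAULT_AR_COEFF
    nh_window: tuple | None = None  # (start_h, end_h) of the intended episode

    def __post_init__(self) -> None:
        if self.group not in ("NH", "NON_NH"):
            raise ValueError(f"unknown group {self.group!r}")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")
        times = [t for t, _ in self.breakpoints]
        if sorted(times) != times:
            raise ValueError("breakpoint times must be non-decreasing")
        traj = self.trajectory()
        if self.group == "NH":
            if self.nh_window is None:
                raise ValueError(f"NH archetype {self.name} needs an nh_window")
            lo, hi = self.nh_window
            in_window = (SLOT_TIMES_H >= lo) & (SLOT_TIMES_H < hi)
            below = (traj < NH_THRESHOLD) & in_window
            if _longest_run(below) < 3:
                raise ValueError(
                    f"NH archetype {self.name}: trajectory must stay below "
                    f"{NH_THRESHOLD} mmol/L for >=3 consecutive slots inside nh_window"
                )
        else:
            margin = NH_THRESHOLD + NON_NH_MARGIN_SD * self.noise_sd
            if traj.min() < margin:
                raise ValueError(
                    f"non-NH archetype {self.name}: trajectory dips to "
                    f"{traj.min():.2f} mmol/L, below the purity margin {margin:.2f}"
                )

    def trajectory(self) -> np.ndarray:
        """Mean glucose at the 72 slot times, clamped to the device range."""
        times = np.array([t for t, _ in self.breakpoints], dtype=float)
        levels = np.array([v for _, v in self.breakpoints], dtype=float)
        return np.clip(np.interp(SLOT_TIMES_H, times, levels), DEVICE_MIN, DEVICE_MAX)

    @property
    def anchor_initial(self) -> float:
        """Target mean of slots 0-2 (the 'initial glucose' of a noiseless series)."""
        return float(self.trajectory()[:3].mean())

    @property
    def anchor_final(self) -> float:
        """Target mean of slots 69-71."""
        return float(self.trajectory()[-3:].mean())


@dataclass
class Missingness:
    """Per-segment missingness scenario probabilities (mutually exclusive)."""

    p_single_gap: float = 0.0  # 1-2 missing slots, always imputable
    p_long_gap: float = 0.0  # a run of >=3 missing -> excluded
    p_heavy_missing: float = 0.0  # >=8 scattered missing -> excluded

    def __post_init__(self) -> None:
        probs = (self.p_single_gap, self.p_long_gap, self.p_heavy_missing)
        if any(not 0.0 <= p <= 1.0 for p in probs) or sum(probs) > 1.0 + 1e-12:
            raise ValueError("missingness probabilities must lie in [0,1] and sum to <=1")


@dataclass
class DatasetRecipe:
    archetypes: list
    n_per_archetype: object  # int or {archetype name: int}
    missingness: Missingness = field(default_factory=Missingness)
    seed: int | None = None

    def n_for(self, spec: ArchetypeSpec) -> int:
        if isinstance(self.n_per_archetype, dict):
            n = int(self.n_per_archetype[spec.name])
        else:
            n = int(self.n_per_archetype)
        if n < 1:
            raise ValueError("n_per_archetype must be >= 1")
        return n


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def _ar1_noise(rng: np.random.Generator, n: int, length: int, sd: float, ar: float) -> np.ndarray:
    """Stationary zero-mean AR(1) noise with marginal standard deviation sd."""
    if sd == 0.0:
        return np.zeros((n, length))
    z = rng.standard_normal((n, length))
    e = np.empty((n, length))
    e[:, 0] = sd * z[:, 0]
    s_inn = sd * np.sqrt(1.0 - ar * ar)
    for t in range(1, length):
        e[:, t] = ar * e[:, t - 1] + s_inn * z[:, t]
    return e


def generate_archetype_series(
    spec: ArchetypeSpec, n: int, seed=None, start_date: datetime.date = _SYNTHETIC_EPOCH
) -> list[NocturnalSegment]:
    """Draw ``n`` complete nights from one archetype.

    Each series is the archetype's mean trajectory plus AR(1) noise, clamped
    to the device range.  Segments come back RAW with no missing slots; use
    :func:`inject_missingness` to emulate sensor dropout.
    """
    rng = np.random.default_rng(seed)
    traj = spec.trajectory()
    noise = _ar1_noise(rng, n, N_SLOTS, spec.noise_sd, spec.ar_coeff)
    series = np.clip(traj[None, :] + noise, DEVICE_MIN, DEVICE_MAX)
    return [
        NocturnalSegment(
            patient_id=f"{spec.name}:{i:04d}",
            night_date=start_date,
            values=series[i],
            status=SegmentStatus.RAW,
        )
        for i in range(n)
    ]


def inject_missingness(
    segments: list[NocturnalSegment], missingness: Missingness, seed=None
) -> list[NocturnalSegment]:
    """Knock out slots per the missingness scenario probabilities.

    Scenarios per segment (at most one applies): a 1-2 slot gap that the
    imputation rule can always fill; a run of >=3 consecutive missing slots
    (excluded as a long gap); or >=8 scattered missing slots (excluded as too
    many missing).  Returns new RAW segments; inputs are not modified.
    """
    rng = np.random.default_rng(seed)
    out = []
    p1 = missingness.p_long_gap
    p2 = p1 + missingness.p_heavy_missing
    p3 = p2 + missingness.p_single_gap
    for seg in segments:
        values = seg.values.copy()
        u = rng.uniform()
        if u < p1:
            run = int(rng.integers(3, 7))
            start = int(rng.integers(0, N_SLOTS - run + 1))
            values[start : start + run] = np.nan
        elif u < p2:
            k = int(rng.integers(8, 15))
            idx = rng.choice(N_SLOTS, size=k, replace=False)
            values[idx] = np.nan
        elif u < p3:
            k = int(rng.integers(1, 3))
            idx = rng.choice(N_SLOTS, size=k, replace=False)
            values[idx] = np.nan
        out.append(
            NocturnalSegment(
                patient_id=seg.patient_id,
                night_date=seg.night_date,
                values=values,
                status=SegmentStatus.RAW,
            )
        )
    return out


def generate_study_dataset(recipe: DatasetRecipe):
    """Concatenate archetype outputs with a ground-truth manifest.

    Returns ``(segments, manifest)`` where the manifest records, per segment,
    the generating archetype and whether an NH episode was intended — the
    reference for recovery scoring downstream.
    """
    root = np.random.default_rng(recipe.seed)
    segments: list[NocturnalSegment] = []
    rows = []
    for spec in recipe.archetypes:
        n = recipe.n_for(spec)
        seed = int(root.integers(0, 2**31 - 1))
        for seg in generate_archetype_series(spec, n, seed=seed):
            segments.append(seg)
            rows.append(
                {
                    "patient_id": seg.patient_id,
                    "night_date": str(seg.night_date),
                    "archetype": spec.name,
                    "group": spec.group,
                }
            )
    miss_seed = int(root.integers(0, 2**31 - 1))
    segments = inject_missingness(segments, recipe.missingness, seed=miss_seed)
    return segments, pd.DataFrame(rows)


def segments_to_readings_frame(segments: list[NocturnalSegment]) -> pd.DataFrame:
    """Long-format readings table (patient_id, timestamp, glucose_mmol_l).

    Missing slots are simply absent rows, as in a device export where the
    sensor recorded nothing.
    """
    rows = []
    for seg in segments:
        anchor = pd.Timestamp(seg.night_date)
        for i, v in enumerate(seg.values):
            if np.isnan(v):
                continue
            rows.append(
                {
                    "patient_id": seg.patient_id,
                    "timestamp": (anchor + pd.Timedelta(minutes=5 * i)).isoformat(),
                    "glucose_mmol_l": round(float(v), 4),
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "timestamp", "glucose_mmol_l"])


# ---------------------------------------------------------------------------
# registry

def load_archetypes(path=None) -> list[ArchetypeSpec]:
    """Load archetype specs from a YAML registry (the shipped default one
    covers all 16 published patterns: 10 non-NH and 6 NH)."""
    if path is None:
        text = resources.files("nocturne.data").joinpath("archetypes.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    specs = []
    for entry in raw["archetypes"]:
        specs.append(
            ArchetypeSpec(
                name=entry["name"],
                group=entry["group"],
                breakpoints=[tuple(bp) for bp in entry["breakpoints"]],
                noise_sd=float(entry.get("noise_sd", DEFAULT_NOISE_SD)),
                ar_coeff=float(entry.get("ar_coeff", DEFAULT_AR_COEFF)),
                nh_window=tuple(entry["nh_window"]) if entry.get("nh_window") else None,
            )
        )
    return specs


def default_archetypes(group: str | None = None) -> list[ArchetypeSpec]:
    specs = load_archetypes()
    if group is not None:
        specs = [s for s in specs if s.group == group]
    return specs


def default_recipe(
    n_total: int = 2519,
    missingness: Missingness | None = None,
    seed: int | None = None,
) -> DatasetRecipe:
    """Study-sized recipe: group sizes scaled to the published 2263:256
    non-NH:NH split, spread evenly across the archetypes within each group."""
    specs = default_archetypes()
    n_nh_specs = sum(1 for s in specs if s.group == "NH")
    n_non_specs = len(specs) - n_nh_specs
    n_nh_total = max(n_nh_specs, round(n_total * 256 / 2519))
    n_non_total = max(n_non_specs, n_total - n_nh_total)
    counts = {}
    for i, s in enumerate([s for s in specs if s.group == "NON_NH"]):
        counts[s.name] = n_non_total // n_non_specs + (i < n_non_total % n_non_specs)
    for i, s in enumerate([s for s in specs if s.group == "NH"]):
        counts[s.name] = n_nh_total // n_nh_specs + (i < n_nh_total % n_nh_specs)
    return DatasetRecipe(
        archetypes=specs,
        n_per_archetype=counts,
        missingness=missingness if missingness is not None else Missingness(),
        seed=seed,
    )
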