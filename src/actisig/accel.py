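"""Epoch-level accelerometry processing.

Turns per-subject streams of fixed-length epoch counts into valid-day-filtered
intensity-spectrum features (minutes/day spent in each counts-per-minute
interval) and standard descriptive summaries (SED/LPA/MPA/VPA/MVPA).

Processing order is fixed for reproducibility: clock-window restriction, then
non-wear detection, then day-validity screening, then feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinScheme",
    "EpochStream",
    "WearCriteria",
    "DayValidation",
    "IntensitySpectrum",
    "EvensonSummary",
    "InvalidStreamError",
    "NotAnalyzableError",
    "detect_non_wear",
    "restrict_hours",
    "validate_days",
    "extract_spectrum",
    "evenson_summary",
    "process_stream",
    "read_epoch_csv",
    "read_epoch_dir",
    "write_epoch_csv",
    "spectra_to_frame",
    "write_spectrum_csv",
]

#: Lower edges (cpm) of the default 16-interval intensity scheme.
DEFAULT_BIN_EDGES = (
    0, 100, 250, 500, 1000, 1500, 2000, 2500,
    3000, 3500, 4000, 4500, 5000, 6000, 7000, 8000,
)

#: Evenson lower edges (cpm) for SED / LPA / MPA / VPA.
EVENSON_EDGES = (0, 100, 2296, 4012)
EVENSON_LABELS = ("SED", "LPA", "MPA", "VPA")

MVPA_GUIDELINE_MIN_PER_DAY = 60.0


class InvalidStreamError(ValueError):
    """Raised when an epoch stream violates its structural invariants."""


class NotAnalyzableError(ValueError):
    """Raised when a subject has no valid days and no features can be built."""


def _interval_labels(edges: Sequence[int]) -> tuple[str, ...]:
    labels = [f"{lo}-{hi - 1}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f"{edges[-1]}+")
    return tuple(labels)


@dataclass(frozen=True)
class BinScheme:
    """Contiguous half-open cpm intervals [lo, next_lo), last one unbounded."""

    edges: tuple[int, ...] = DEFAULT_BIN_EDGES
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        edges = tuple(self.edges)
        if len(edges) < 1:
            raise ValueError("scheme needs at least one edge")
        if edges[0] != 0:
            raise ValueError("first interval must start at 0 cpm")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)
        labels = tuple(self.labels) if self.labels else _interval_labels(edges)
        if len(labels) != len(edges):
            raise ValueError("need one label per interval")
        object.__setattr__(self, "labels", labels)

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    @classmethod
    def default(cls) -> "BinScheme":
        return cls()

    @classmethod
    def evenson(cls) -> "BinScheme":
        return cls(edges=EVENSON_EDGES, labels=EVENSON_LABELS)

    def with_first_edge(self, sed_upper: int) -> "BinScheme":
        """Variant scheme whose first interval is [0, sed_upper).

        Later edges below or equal to ``sed_upper`` are dropped so the
        partition stays contiguous (e.g. 250 merges the two lowest intervals).
        """
        if sed_upper <= 0:
            raise ValueError("sed_upper must be positive")
        rest = tuple(e for e in self.edges[1:] if e > sed_upper)
        if not rest:
            raise ValueError("sed_upper must lie below the second edge region")
        return BinScheme(edges=(0, sed_upper) + rest)

    def assign(self, cpm: np.ndarray) -> np.ndarray:
        """Index of the interval containing each cpm value."""
        return np.searchsorted(np.asarray(self.edges), cpm, side="right") - 1


@dataclass
class EpochStream:
    """Timestamped activity counts for one subject at a fixed epoch length."""

    subject_id: str
    times: pd.DatetimeIndex
    counts: np.ndarray
    epoch_length: int = 10

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.counts = np.asarray(self.counts)
        if len(self.times) != len(self.counts):
            raise InvalidStreamError("times and counts length mismatch")
        if np.any(self.counts < 0):
            raise InvalidStreamError("counts must be non-negative")
        if self.epoch_length <= 0:
            raise InvalidStreamError("epoch_length must be positive")
        if len(self.times) > 1:
            deltas = np.diff(self.times.asi8)
            if np.any(deltas <= 0):
                raise InvalidStreamError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def cpm(self) -> np.ndarray:
        """Counts rescaled to counts-per-minute."""
        return self.counts * (60.0 / self.epoch_length)


@dataclass(frozen=True)
class WearCriteria:
    """Wear-time validity rules applied before feature extraction."""

    min_hours_per_day: float = 8.0
    min_days: int = 4
    nonwear_window_minutes: float = 60.0
    day_start_hour: int = 6
    day_end: str = "23:59"

    def __post_init__(self) -> None:
        if self.min_hours_per_day <= 0 or self.min_days <= 0:
            raise ValueError("validity thresholds must be positive")
        if self.nonwear_window_minutes <= 0:
            raise ValueError("nonwear window must be positive")

    @property
    def day_end_seconds(self) -> int:
        h, m = (int(x) for x in self.day_end.split(":"))
        return h * 3600 + m * 60 + 59  # whole final minute is retained


def restrict_hours(stream: EpochStream, criteria: WearCriteria) -> EpochStream:
    """Keep epochs whose start time falls inside the daily clock window."""
    if len(stream) == 0:
        return stream
    tod = (stream.times - stream.times.normalize()).total_seconds().to_numpy()
    keep = (tod >= criteria.day_start_hour * 3600) & (tod <= criteria.day_end_seconds)
    return EpochStream(
        subject_id=stream.subject_id,
        times=stream.times[keep],
        counts=stream.counts[keep],
        epoch_length=stream.epoch_length,
    )


def _contiguous_segments(stream: EpochStream) -> Iterable[slice]:
    """Maximal runs of time-contiguous epochs within a single calendar day."""
    n = len(stream)
    if n == 0:
        return []
    step_ns = stream.epoch_length * 1_000_000_000
    t = stream.times.asi8
    same_day = np.asarray(
        stream.times[1:].normalize() == stream.times[:-1].normalize()
    )
    contiguous = (np.diff(t) == step_ns) & same_day
    breaks = np.flatnonzero(~contiguous) + 1
    starts = np.concatenate(([0], breaks))
    stops = np.concatenate((breaks, [n]))
    return [slice(a, b) for a, b in zip(starts, stops)]


def detect_non_wear(stream: EpochStream, criteria: WearCriteria) -> np.ndarray:
    """Boolean wear mask: False inside zero-count runs of >= the window length.

    Runs are strict zero runs (no interruption tolerance) and never span a
    break in the record or a calendar-day boundary.
    """
    if 60 % stream.epoch_length != 0:
        raise InvalidStreamError("epoch_length must divide 60 s")
    window_epochs = int(round(criteria.nonwear_window_minutes * 60 / stream.epoch_length))
    wear = np.ones(len(stream), dtype=bool)
    zero = stream.counts == 0
    for seg in _contiguous_segments(stream):
        z = zero[seg]
        if not z.any():
            continue
        # boundaries of zero-runs inside this segment
        padded = np.concatenate(([False], z, [False])).astype(np.int8)
        d = np.diff(padded)
        run_starts = np.flatnonzero(d == 1)
        run_stops = np.flatnonzero(d == -1)
        for a, b in zip(run_starts, run_stops):
            if b - a >= window_epochs:
                wear[seg.start + a : seg.start + b] = False
    return wear


@dataclass
class DayValidation:
    """Per-day wear minutes and the subject-level validity verdict."""

    table: pd.DataFrame  # columns: date, wear_minutes, valid
    min_days: int

    @property
    def valid_dates(self) -> list:
        return list(self.table.loc[self.table["valid"], "date"])

    @property
    def n_valid_days(self) -> int:
        return int(self.table["valid"].sum())

    @property
    def subject_valid(self) -> bool:
        return self.n_valid_days >= self.min_days


def validate_days(
    stream: EpochStream, wear_mask: np.ndarray, criteria: WearCriteria
) -> DayValidation:
    """Classify each calendar day by wear minutes; a day needs >= 8 h by default."""
    wear_mask = np.asarray(wear_mask, dtype=bool)
    if len(wear_mask) != len(stream):
        raise InvalidStreamError("wear mask not aligned to stream")
    min_minutes = criteria.min_hours_per_day * 60.0
    if len(stream) == 0:
        table = pd.DataFrame(columns=["date", "wear_minutes", "valid"])
        return DayValidation(table=table, min_days=criteria.min_days)
    dates = stream.times.normalize()
    per_day = (
        pd.Series(wear_mask.astype(float) * stream.epoch_length / 60.0, index=dates)
        .groupby(level=0)
        .sum()
    )
    table = pd.DataFrame(
        {
            "date": per_day.index,
            "wear_minutes": per_day.to_numpy(),
            "valid": per_day.to_numpy() >= min_minutes,
        }
    ).reset_index(drop=True)
    return DayValidation(table=table, min_days=criteria.min_days)


@dataclass
class IntensitySpectrum:
    """Per-subject minutes/day in each cpm interval, averaged over valid days."""

    subject_id: str
    minutes_per_day: np.ndarray
    labels: tuple[str, ...]
    n_valid_days: int
    mean_wear_minutes: float
    overall_cpm: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.minutes_per_day, index=list(self.labels))


def _per_day_bin_minutes(
    stream: EpochStream,
    wear_mask: np.ndarray,
    valid_dates: Sequence,
    scheme: BinScheme,
) -> tuple[np.ndarray, np.ndarray, float]:
    """(n_days x n_bins) minutes matrix, per-day wear minutes, overall cpm."""
    wear_mask = np.asarray(wear_mask, dtype=bool)
    valid_dates = pd.DatetimeIndex(valid_dates)
    if len(valid_dates) == 0:
        raise NotAnalyzableError(f"subject {stream.subject_id!r}: no valid days")
    dates = stream.times.normalize()
    keep = wear_mask & dates.isin(valid_dates)
    cpm = stream.cpm[keep]
    day_codes = pd.Categorical(dates[keep], categories=valid_dates).codes
    bins = scheme.assign(cpm)
    counts2d = np.zeros((len(valid_dates), scheme.n_bins), dtype=np.int64)
    np.add.at(counts2d, (day_codes, bins), 1)
    minutes = counts2d * (stream.epoch_length / 60.0)
    wear_minutes = minutes.sum(axis=1)
    total_counts = float(stream.counts[keep].sum())
    total_wear = float(wear_minutes.sum())
    overall_cpm = total_counts / total_wear if total_wear > 0 else 0.0
    return minutes, wear_minutes, overall_cpm


def extract_spectrum(
    stream: EpochStream,
    wear_mask: np.ndarray,
    valid_dates: Sequence,
    scheme: BinScheme | None = None,
) -> IntensitySpectrum:
    """Build the intensity spectrum from wear epochs on valid days.

    Each wear epoch is rescaled to cpm (counts * 60/epoch_length), assigned to
    exactly one interval, converted to minutes, and averaged (unweighted)
    across valid days.
    """
    scheme = scheme or BinScheme.default()
    minutes, wear_minutes, overall_cpm = _per_day_bin_minutes(
        stream, wear_mask, valid_dates, scheme
    )
    return IntensitySpectrum(
        subject_id=stream.subject_id,
        minutes_per_day=minutes.mean(axis=0),
        labels=scheme.labels,
        n_valid_days=minutes.shape[0],
        mean_wear_minutes=float(wear_minutes.mean()),
        overall_cpm=overall_cpm,
    )


@dataclass
class EvensonSummary:
    """Descriptive SED/LPA/MPA/VPA/MVPA minutes per day and the guideline flag."""

    subject_id: str
    sed: float
    lpa: float
    mpa: float
    vpa: float
    mvpa: float
    meets_guideline: bool
    n_valid_days: int
    mean_wear_minutes: float
    overall_cpm: float


def evenson_summary(
    stream: EpochStream,
    wear_mask: np.ndarray,
    valid_dates: Sequence,
) -> EvensonSummary:
    spec = extract_spectrum(stream, wear_mask, valid_dates, BinScheme.evenson())
    sed, lpa, mpa, vpa = spec.minutes_per_day
    mvpa = mpa + vpa
    return EvensonSummary(
        subject_id=stream.subject_id,
        sed=float(sed),
        lpa=float(lpa),
        mpa=float(mpa),
        vpa=float(vpa),
        mvpa=float(mvpa),
        meets_guideline=bool(mvpa >= MVPA_GUIDELINE_MIN_PER_DAY),
        n_valid_days=spec.n_valid_days,
        mean_wear_minutes=spec.mean_wear_minutes,
        overall_cpm=spec.overall_cpm,
    )


def process_stream(
    stream: EpochStream,
    criteria: WearCriteria | None = None,
    scheme: BinScheme | None = None,
) -> tuple[IntensitySpectrum | None, EvensonSummary | None, DayValidation]:
    """Full per-subject chain: restrict hours, flag non-wear, screen days, extract.

    Returns ``(None, None, validation)`` for subjects failing the valid-day rule.
    """
    criteria = criteria or WearCriteria()
    restricted = restrict_hours(stream, criteria)
    mask = detect_non_wear(restricted, criteria)
    validation = validate_days(restricted, mask, criteria)
    if not validation.subject_valid:
        return None, None, validation
    spectrum = extract_spectrum(restricted, mask, validation.valid_dates, scheme)
    summary = evenson_summary(restricted, mask, validation.valid_dates)
    return spectrum, summary, validation


# ---------------------------------------------------------------------------
# I/O: long epoch CSV (subject_id, timestamp, counts) and per-subject files
# ---------------------------------------------------------------------------

def read_epoch_csv(path: str | Path, epoch_length: int = 10) -> list[EpochStream]:
    """Read a long-format epoch CSV with columns subject_id, timestamp, counts."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    streams = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("timestamp")
        streams.append(
            EpochStream(
                subject_id=str(sid),
                times=pd.DatetimeIndex(grp["timestamp"]),
                counts=grp["counts"].to_numpy(),
                epoch_length=epoch_length,
            )
        )
    return streams


def read_epoch_dir(path: str | Path, epoch_length: int = 10) -> list[EpochStream]:
    """Directory dialect: one ``<subject_id>.csv`` (timestamp, counts) per subject."""
    streams = []
    for f in sorted(Path(path).glob("*.csv")):
        df = pd.read_csv(f, parse_dates=["timestamp"]).sort_values("timestamp")
        streams.append(
            EpochStream(
                subject_id=f.stem,
                times=pd.DatetimeIndex(df["timestamp"]),
                counts=df["counts"].to_numpy(),
                epoch_length=epoch_length,
            )
        )
    return streams


def write_epoch_csv(streams: Iterable[EpochStream], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"subject_id": s.subject_id, "timestamp": s.times, "counts": s.counts}
        )
        for s in streams
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def spectra_to_frame(spectra: Iterable[IntensitySpectrum]) -> pd.DataFrame:
    rows = []
    for s in spectra:
        row: dict = {"subject_id": s.subject_id}
        row.update(dict(zip(s.labels, s.minutes_per_day)))
        row["n_valid_days"] = s.n_valid_days
        row["mean_wear_minutes"] = s.mean_wear_minutes
        row["overall_cpm"] = s.overall_cpm
        rows.append(row)
    return pd.DataFrame(rows)


def write_spectrum_csv(spectra: Iterable[IntensitySpectrum], path: str | Path) -> None:
    spectra_to_frame(spectra).to_csv(path, index=False)
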