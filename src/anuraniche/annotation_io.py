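"""Annotation data model and delimited-text I/O for passive acoustic monitoring.

Field protocols for anuran soundscape surveys annotate each recorded minute
with the species heard, their call rates, the acoustic features of the first
recognizable advertisement call, band sound-pressure levels used as noise
proxies, and a categorical rain index.  This module defines the in-memory
record types (:class:`MinuteRecord` and friends), a survey-design container
(sites, months, daylight/night hour sets), and lossless CSV round-tripping.

The file dialect is UTF-8 comma-delimited text with a mandatory header; one
row per (minute, species) observation.  A silent minute (no anuran detected)
is a row with an empty ``species`` cell and ``call_rate`` 0 — those rows are
retained because acoustic-presence percentages need silent minutes in their
denominators.  Per-call features are serialized into a single cell as a
semicolon-separated list of ``freq:notes:pulses[:duration_ms]`` tuples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CallFeature",
    "SPLProfile",
    "MinuteRecord",
    "SurveyDesign",
    "AnnotationError",
    "read_annotations",
    "write_annotations",
    "split_period",
    "to_frame",
    "from_frame",
    "as_frame",
    "COLUMNS",
]

COLUMNS = [
    "site",
    "date",
    "month",
    "hour",
    "minute_index",
    "species",
    "call_rate",
    "calls",
    "spl_1k",
    "spl_2k",
    "spl_3k",
    "spl_4k",
    "spl_5k",
    "rain_index",
]

_SPL_FIELDS = ("spl_1k", "spl_2k", "spl_3k", "spl_4k", "spl_5k")


class AnnotationError(ValueError):
    """Raised when an annotation file or record violates the data model."""


@dataclass(frozen=True)
class CallFeature:
    """Acoustic features of one advertisement call.

    ``n_pulses == 0`` encodes a tonal (unpulsed) call; ``duration_ms`` is
    optional because most annotation workflows do not measure it per call.
    """

    dominant_freq: float  # Hz
    n_notes: int = 1
    n_pulses: int = 0
    duration_ms: float | None = None

    def __post_init__(self) -> None:
        if not self.dominant_freq > 0:
            raise AnnotationError(f"dominant_freq must be > 0, got {self.dominant_freq}")
        if self.dominant_freq >= 22050:
            raise AnnotationError(f"dominant_freq beyond Nyquist of 44.1 kHz audio: {self.dominant_freq}")
        if self.n_notes < 1:
            raise AnnotationError(f"n_notes must be >= 1, got {self.n_notes}")
        if self.n_pulses < 0:
            raise AnnotationError(f"n_pulses must be >= 0, got {self.n_pulses}")
        if self.duration_ms is not None and not self.duration_ms > 0:
            raise AnnotationError(f"duration_ms must be > 0, got {self.duration_ms}")


@dataclass(frozen=True)
class SPLProfile:
    """Band sound-pressure levels in dB relative to digital full scale.

    Each band is optional (``None`` when not measured).  Values are
    non-positive: 0 dBFS corresponds to a full-scale sine.
    """

    spl_1k: float | None = None
    spl_2k: float | None = None
    spl_3k: float | None = None
    spl_4k: float | None = None
    spl_5k: float | None = None

    def __post_init__(self) -> None:
        for name in _SPL_FIELDS:
            v = getattr(self, name)
            if v is not None and not (-120.0 <= v <= 0.0):
                raise AnnotationError(f"{name}={v} outside [-120, 0] dBFS")

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in _SPL_FIELDS}


@dataclass(frozen=True)
class MinuteRecord:
    """One species' calling activity within one annotated minute.

    ``species`` is empty for a silent minute.  ``call_rate`` counts
    advertisement calls per minute (for species whose call is a long note
    followed by a variable number of clicks, the convention is to count long
    notes).  ``calls`` holds the per-call features actually measured, which
    may be fewer than ``call_rate`` (typically only the first call per minute
    is measured).
    """

    site: str
    date: str  # ISO-8601 YYYY-MM-DD
    hour: int
    minute_index: int
    species: str = ""
    call_rate: int = 0
    calls: tuple[CallFeature, ...] = ()
    spl: SPLProfile = field(default_factory=SPLProfile)
    rain_index: int = 0
    month: str = ""  # YYYY-MM; derived from date when empty

    def __post_init__(self) -> None:
        if not (0 <= self.hour <= 23):
            raise AnnotationError(f"hour={self.hour} outside [0, 23]")
        if not (1 <= self.minute_index <= 5):
            raise AnnotationError(f"minute_index={self.minute_index} outside [1, 5]")
        if self.call_rate < 0:
            raise AnnotationError(f"call_rate={self.call_rate} negative")
        if len(self.calls) > self.call_rate:
            raise AnnotationError(
                f"{len(self.calls)} call features exceed call_rate={self.call_rate}"
            )
        if self.rain_index not in (0, 1, 2):
            raise AnnotationError(f"rain_index={self.rain_index} not in {{0,1,2}}")
        if self.species == "" and self.call_rate != 0:
            raise AnnotationError("empty species with nonzero call_rate")
        if not self.month:
            object.__setattr__(self, "month", self.date[:7])

    @property
    def minute_key(self) -> tuple[str, str, int, int]:
        """Identity of the sampled minute, shared across species rows."""
        return (self.site, self.date, self.hour, self.minute_index)


_DEFAULT_DAYLIGHT = frozenset(range(6, 19))  # 6 a.m.–6 p.m. incl. dawn and dusk
_DEFAULT_NIGHT = frozenset(range(19, 24)) | frozenset(range(0, 6))


@dataclass(frozen=True)
class SurveyDesign:
    """Sites, study months and the daylight/night partition of the day.

    ``sites`` maps site name to altitude (m a.s.l.); ``months`` maps site
    name to its ordered list of study months (``YYYY-MM`` labels) — sites may
    differ (a site with a month of missing data has fewer seasonal classes).
    """

    sites: dict[str, float]
    months: dict[str, tuple[str, ...]]
    daylight_hours: frozenset[int] = _DEFAULT_DAYLIGHT
    night_hours: frozenset[int] = _DEFAULT_NIGHT

    def __post_init__(self) -> None:
        if self.daylight_hours & self.night_hours:
            raise AnnotationError("daylight and night hour sets overlap")
        if self.daylight_hours | self.night_hours != frozenset(range(24)):
            raise AnnotationError("daylight and night hours must partition 0-23")
        for site in self.sites:
            if not self.months.get(site):
                raise AnnotationError(f"site {site!r} has no study months")
        object.__setattr__(
            self, "months", {s: tuple(m) for s, m in self.months.items()}
        )

    def period_hours(self, period: str) -> frozenset[int]:
        if period == "daylight":
            return self.daylight_hours
        if period == "night":
            return self.night_hours
        raise ValueError(f"period must be 'daylight' or 'night', got {period!r}")


def default_design() -> SurveyDesign:
    """Two-site design matching the high-altitude wetland survey layout."""
    sandi = tuple(f"2019-{m:02d}" for m in (9, 10, 11, 12)) + tuple(
        f"2020-{m:02d}" for m in (1, 2, 3)
    )
    malalo = sandi[:-1]  # no usable data in the final month at the lower site
    return SurveyDesign(
        sites={"Sandi": 3188.0, "Malalo": 2648.0},
        months={"Sandi": sandi, "Malalo": malalo},
    )


# ---------------------------------------------------------------------------
# serialization helpers


def _format_float(x: float) -> str:
    return repr(float(x))


def _serialize_calls(calls: Sequence[CallFeature]) -> str:
    parts = []
    for c in calls:
        fields = [_format_float(c.dominant_freq), str(c.n_notes), str(c.n_pulses)]
        if c.duration_ms is not None:
            fields.append(_format_float(c.duration_ms))
        parts.append(":".join(fields))
    return ";".join(parts)


def parse_calls(cell: str) -> tuple[CallFeature, ...]:
    """Parse a serialized ``freq:notes:pulses[:duration]`` feature list."""
    cell = cell.strip()
    if not cell:
        return ()
    out = []
    for part in cell.split(";"):
        bits = part.split(":")
        if len(bits) not in (3, 4):
            raise AnnotationError(f"malformed call feature {part!r}")
        out.append(
            CallFeature(
                dominant_freq=float(bits[0]),
                n_notes=int(bits[1]),
                n_pulses=int(bits[2]),
                duration_ms=float(bits[3]) if len(bits) == 4 else None,
            )
        )
    return tuple(out)


def to_frame(records: Iterable[MinuteRecord]) -> pd.DataFrame:
    """Tabular view of a record list (one row per record), the exact on-disk
    column layout.  SPL bands not measured become NaN."""
    rows = []
    for r in records:
        row = {
            "site": r.site,
            "date": r.date,
            "month": r.month,
            "hour": r.hour,
            "minute_index": r.minute_index,
            "species": r.species,
            "call_rate": r.call_rate,
            "calls": _serialize_calls(r.calls),
            "rain_index": r.rain_index,
        }
        for name, v in r.spl.as_dict().items():
            row[name] = np.nan if v is None else v
        rows.append(row)
    df = pd.DataFrame(rows, columns=COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=COLUMNS)
    return df


def from_frame(df: pd.DataFrame) -> list[MinuteRecord]:
    """Inverse of :func:`to_frame` with row-numbered diagnostics."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"missing required columns: {missing}")
    records: list[MinuteRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            spl_kwargs = {}
            for name in _SPL_FIELDS:
                v = getattr(row, name)
                if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                    spl_kwargs[name] = None
                else:
                    spl_kwargs[name] = float(v)
            species = "" if pd.isna(row.species) else str(row.species)
            month = "" if pd.isna(row.month) else str(row.month)
            records.append(
                MinuteRecord(
                    site=str(row.site),
                    date=str(row.date),
                    month=month,
                    hour=int(row.hour),
                    minute_index=int(row.minute_index),
                    species=species,
                    call_rate=int(row.call_rate),
                    calls=parse_calls("" if pd.isna(row.calls) else str(row.calls)),
                    spl=SPLProfile(**spl_kwargs),
                    rain_index=int(row.rain_index),
                )
            )
        except (AnnotationError, ValueError) as exc:
            errors.append(f"row {i + 2}: {exc}")  # +2: header line + 1-basing
    if errors:
        raise AnnotationError(
            "invalid annotation rows:\n  " + "\n  ".join(errors[:50])
        )
    return records


def as_frame(records: Sequence[MinuteRecord] | pd.DataFrame) -> pd.DataFrame:
    """Accept either a record list or its tabular view; analysis functions
    use this so that a large dataset need only be converted once."""
    if isinstance(records, pd.DataFrame):
        return records
    return to_frame(records)


def read_annotations(path, design: SurveyDesign | None = None) -> list[MinuteRecord]:
    """Read and validate an annotation CSV.

    Every row becomes a validated :class:`MinuteRecord`; rows violating the
    data model are reported together with their file row numbers.  When a
    ``design`` is given, sites must belong to it.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing required columns: {missing}")
    records = from_frame(df)
    if design is not None:
        bad = sorted({r.site for r in records} - set(design.sites))
        if bad:
            raise AnnotationError(f"{path}: sites not in survey design: {bad}")
    return records


def write_annotations(records: Sequence[MinuteRecord], path) -> None:
    """Write records as UTF-8 CSV, losslessly (floats via ``repr``)."""
    to_frame(records).to_csv(path, index=False, encoding="utf-8")


def split_period(
    records: Sequence[MinuteRecord], design: SurveyDesign
) -> tuple[list[MinuteRecord], list[MinuteRecord]]:
    """Partition records into (daylight, night) by hour, order-preserving."""
    day = [r for r in records if r.hour in design.daylight_hours]
    night = [r for r in records if r.hour in design.night_hours]
    return day, night
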