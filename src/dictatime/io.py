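"""Reading RIS timestamp exports and deriving per-region dictation times.

A dictation time is the interval between dictation start and the first
saving of the report, in fractional minutes.  Records whose report was
saved at or before the dictation start are excluded (a zero-length
dictation cannot be a report).  Exams are pooled by canonical anatomical
region through a configurable pattern map, because RIS exports carry
heterogeneous protocol codes.

Timestamps are treated as timezone-naive local times; durations spanning
a daylight-saving change are taken at face value (noted in the load
report).  Durations keep full float precision; rounding happens only at
presentation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_REGIONS",
    "DEFAULT_COLUMNS",
    "DEFAULT_REGION_PATTERNS",
    "TimestampRecord",
    "RegionMap",
    "DurationSample",
    "LoadReport",
    "load_timestamps",
    "compute_dictation_times",
    "pooled_counts",
    "records_to_frame",
    "write_timestamps_csv",
    "write_durations_csv",
    "read_durations_csv",
    "write_load_report",
]

#: Canonical anatomical region labels; unmatched codes fall back to "other".
CANONICAL_REGIONS = (
    "head",
    "chest",
    "abdomen",
    "foot",
    "lumbar_spine",
    "shoulder",
    "wrist",
    "polytrauma",
    "other",
)

#: Logical field -> default CSV column name.
DEFAULT_COLUMNS = {
    "exam_id": "exam_id",
    "region_code": "region_code",
    "dictation_start": "dictation_start",
    "first_save": "first_save",
}

#: Illustrative default protocol-code patterns (institution RIS code lists
#: vary; supply a YAML map for real exports).
DEFAULT_REGION_PATTERNS: dict[str, tuple[str, ...]] = {
    "head": (r"(?i)head", r"(?i)skull", r"(?i)brain", r"(?i)stroke"),
    "chest": (r"(?i)chest", r"(?i)thorax"),
    "abdomen": (r"(?i)abdom",),
    "foot": (r"(?i)foot",),
    "lumbar_spine": (r"(?i)lumbar", r"(?i)l[- ]?spine"),
    "shoulder": (r"(?i)shoulder",),
    "wrist": (r"(?i)wrist",),
    "polytrauma": (r"(?i)polytrauma", r"(?i)whole.?body", r"(?i)\btrauma\b"),
}

# ns -> minutes; both the reader and the synthetic generator divide integer
# nanoseconds by this constant so round trips are bit-exact.
_NS_PER_MIN = 6.0e10


@dataclass(frozen=True)
class TimestampRecord:
    """One RIS export row: exam id, protocol code, and the two timestamps."""

    exam_id: str
    region_code: str
    dictation_start: pd.Timestamp
    first_save: pd.Timestamp

    def __post_init__(self) -> None:
        if not self.exam_id:
            raise ValueError("exam_id must be non-empty")
        if not self.region_code:
            raise ValueError("region_code must be non-empty")
        if pd.isna(self.dictation_start) or pd.isna(self.first_save):
            raise ValueError("timestamps must be parseable (non-NaT)")

    @property
    def duration_minutes(self) -> float:
        """Dictation time in fractional minutes (may be <= 0 for bad rows)."""
        delta = pd.Timestamp(self.first_save) - pd.Timestamp(self.dictation_start)
        return delta.value / _NS_PER_MIN


class RegionMap:
    """Maps raw RIS protocol codes to canonical region labels.

    ``patterns`` maps each canonical label to a sequence of regular
    expressions; the first matching label (in declaration order) wins and
    unmatched codes resolve to ``"other"``.  A pattern may not appear under
    two labels.
    """

    def __init__(self, patterns: Mapping[str, Sequence[str]], fallback: str = "other"):
        seen: dict[str, str] = {}
        compiled: dict[str, list[re.Pattern]] = {}
        for label, pats in patterns.items():
            if label not in CANONICAL_REGIONS or label == fallback:
                raise ValueError(f"unknown canonical region label: {label!r}")
            compiled[label] = []
            for pat in pats:
                if pat in seen:
                    raise ValueError(
                        f"pattern {pat!r} maps to both {seen[pat]!r} and {label!r}"
                    )
                seen[pat] = label
                compiled[label].append(re.compile(pat))
        self._patterns = {k: tuple(v) for k, v in patterns.items()}
        self._compiled = compiled
        self.fallback = fallback

    @classmethod
    def default(cls) -> "RegionMap":
        return cls(DEFAULT_REGION_PATTERNS)

    @classmethod
    def from_yaml(cls, path) -> "RegionMap":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError("region map YAML must be a mapping label -> patterns")
        return cls({k: tuple(v) for k, v in raw.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({k: list(v) for k, v in self._patterns.items()}, fh)

    def resolve(self, code: str) -> str:
        for label, pats in self._compiled.items():
            for pat in pats:
                if pat.search(code):
                    return label
        return self.fallback


@dataclass(frozen=True)
class DurationSample:
    """Per-region vector of valid dictation times (minutes, all > 0)."""

    region: str
    durations: np.ndarray
    n_excluded: int = 0
    exam_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "durations", d)
        if d.size and not np.all(d > 0):
            raise ValueError("durations must all be positive")
        if self.n_excluded < 0:
            raise ValueError("n_excluded must be non-negative")
        if self.exam_ids is not None and len(self.exam_ids) != d.size:
            raise ValueError("exam_ids length must match durations")

    @property
    def n_valid(self) -> int:
        return int(self.durations.size)

    @property
    def n_total(self) -> int:
        return self.n_valid + self.n_excluded


@dataclass
class LoadReport:
    """Counts and messages from one timestamp-export load."""

    path: str
    rows_read: int
    rows_loaded: int
    rows_skipped: int
    messages: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"input: {self.path}",
            f"rows read: {self.rows_read}",
            f"rows loaded: {self.rows_loaded}",
            f"rows skipped (unparseable): {self.rows_skipped}",
            "note: timestamps are timezone-naive local times; durations over a "
            "daylight-saving change are taken at face value",
        ]
        lines.extend(self.messages)
        return "\n".join(lines) + "\n"


def load_timestamps(
    path, format_spec: Mapping[str, str] | None = None
) -> tuple[list[TimestampRecord], LoadReport]:
    """Read a timestamp CSV export into records plus a load report.

    ``format_spec`` overrides the default column names (keys: exam_id,
    region_code, dictation_start, first_save).  Rows with unparseable
    timestamps or empty identifiers are skipped and counted; zero
    parseable rows is fatal.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"timestamp export not found: {p}")
    cols = dict(DEFAULT_COLUMNS)
    cols.update(format_spec or {})
    df = pd.read_csv(p, dtype=str, encoding="utf-8")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"missing declared column(s): {', '.join(missing)}")
    rows_read = int(len(df))

    exam = df[cols["exam_id"]].fillna("").str.strip()
    region = df[cols["region_code"]].fillna("").str.strip()
    start = pd.to_datetime(df[cols["dictation_start"]], errors="coerce", format="mixed")
    save = pd.to_datetime(df[cols["first_save"]], errors="coerce", format="mixed")

    ok = start.notna() & save.notna() & (exam != "") & (region != "")
    rows_loaded = int(ok.sum())
    rows_skipped = rows_read - rows_loaded
    report = LoadReport(str(p), rows_read, rows_loaded, rows_skipped)
    if rows_skipped:
        msg = f"skipped {rows_skipped} row(s) with unparseable timestamps or empty ids"
        report.messages.append(msg)
        logger.warning("%s: %s", p, msg)
    if rows_loaded == 0:
        raise ValueError(f"no parseable rows in {p}")

    records = [
        TimestampRecord(e, r, s, v)
        for e, r, s, v in zip(exam[ok], region[ok], start[ok], save[ok])
    ]
    return records, report


def compute_dictation_times(
    records: Iterable[TimestampRecord], region_map: RegionMap | None = None
) -> dict[str, DurationSample]:
    """Compute dictation times and pool them by canonical region.

    Duration = first_save - dictation_start in fractional minutes.  Records
    with duration <= 0 (saved before or exactly at dictation start) are
    excluded and counted per region.
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    region_map = region_map or RegionMap.default()

    durations: dict[str, list[float]] = {}
    ids: dict[str, list[str]] = {}
    excluded: dict[str, int] = {}
    for rec in records:
        region = region_map.resolve(rec.region_code)
        d = rec.duration_minutes
        if d <= 0.0:
            excluded[region] = excluded.get(region, 0) + 1
            durations.setdefault(region, [])
            ids.setdefault(region, [])
        else:
            durations.setdefault(region, []).append(d)
            ids.setdefault(region, []).append(rec.exam_id)

    n_valid = sum(len(v) for v in durations.values())
    if n_valid == 0:
        counts = {k: v for k, v in sorted(excluded.items())}
        raise ValueError(
            f"all {len(records)} records excluded (non-positive durations per region: {counts})"
        )

    order = {r: i for i, r in enumerate(CANONICAL_REGIONS)}
    out: dict[str, DurationSample] = {}
    for region in sorted(durations, key=lambda r: (order.get(r, len(order)), r)):
        out[region] = DurationSample(
            region=region,
            durations=np.asarray(durations[region], dtype=float),
            n_excluded=excluded.get(region, 0),
            exam_ids=tuple(ids[region]),
        )
    return out


def pooled_counts(samples) -> pd.DataFrame:
    """Per-region (n_total, n_after_exclusion) table with an 'All' row."""
    if isinstance(samples, Mapping):
        samples = list(samples.values())
    else:
        samples = list(samples)
    rows = [
        {"region": s.region, "n_total": s.n_total, "n_after_exclusion": s.n_valid}
        for s in samples
    ]
    rows.append(
        {
            "region": "All",
            "n_total": sum(s.n_total for s in samples),
            "n_after_exclusion": sum(s.n_valid for s in samples),
        }
    )
    return pd.DataFrame(rows, columns=["region", "n_total", "n_after_exclusion"])


def records_to_frame(
    records: Iterable[TimestampRecord], format_spec: Mapping[str, str] | None = None
) -> pd.DataFrame:
    cols = dict(DEFAULT_COLUMNS)
    cols.update(format_spec or {})
    return pd.DataFrame(
        {
            cols["exam_id"]: [r.exam_id for r in records],
            cols["region_code"]: [r.region_code for r in records],
            cols["dictation_start"]: [r.dictation_start.isoformat() for r in records],
            cols["first_save"]: [r.first_save.isoformat() for r in records],
        }
    )


def write_timestamps_csv(
    records: Iterable[TimestampRecord], path, format_spec: Mapping[str, str] | None = None
) -> None:
    records_to_frame(list(records), format_spec).to_csv(path, index=False)


def write_durations_csv(samples, path) -> None:
    """Write per-region durations as (region, exam_id, duration_min)."""
    if isinstance(samples, Mapping):
        samples = list(samples.values())
    frames = []
    for s in samples:
        ids = s.exam_ids if s.exam_ids is not None else [""] * s.n_valid
        frames.append(
            pd.DataFrame(
                {"region": s.region, "exam_id": list(ids), "duration_min": s.durations}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_durations_csv(path) -> dict[str, DurationSample]:
    """Read a (region, exam_id, duration_min) CSV back into samples.

    Exclusion counts are not recoverable from this format and read as 0.
    """
    df = pd.read_csv(path, dtype={"region": str, "exam_id": str})
    if not {"region", "duration_min"}.issubset(df.columns):
        raise ValueError("durations CSV needs columns: region, duration_min")
    out: dict[str, DurationSample] = {}
    for region, grp in df.groupby("region", sort=True):
        ids = None
        if "exam_id" in grp.columns:
            ids = tuple(grp["exam_id"].fillna("").astype(str))
        out[str(region)] = DurationSample(
            region=str(region),
            durations=grp["duration_min"].to_numpy(dtype=float),
            exam_ids=ids,
        )
    return out


def write_load_report(report: LoadReport, path) -> None:
    Path(path).write_text(report.to_text(), encoding="utf-8")
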