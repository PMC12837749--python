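"""Raw camera-trap detection records, independence filtering, and site × species matrices.

A camera trigger produces one or more raw records (photo bursts, videos) of a
species at a site.  Downstream statistics all operate on *independent
detection events*: within each (site, species) group, records falling inside a
30-minute window measured from the event's initial record are merged into one
event, and a record at or beyond the window boundary opens a new event.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DetectionRecord",
    "DetectionEvent",
    "SiteSpeciesMatrix",
    "MalformedRowError",
    "read_detections",
    "filter_independent",
    "build_matrix",
    "write_events_csv",
    "read_events_csv",
]

REQUIRED_COLUMNS = ("site_id", "species", "timestamp")

_WS = re.compile(r"\s+")


def _clean(label: str) -> str:
    return _WS.sub(" ", str(label).strip())


@dataclass(frozen=True)
class DetectionRecord:
    """One raw camera capture: a species seen at a site at minute precision."""

    site_id: str
    species: str
    timestamp: datetime

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be non-empty")
        if not self.species:
            raise ValueError("species must be non-empty")


@dataclass(frozen=True)
class DetectionEvent:
    """An independent detection: ≥ 1 raw records merged under the time window.

    ``event_start`` is the timestamp of the initial record; events of the same
    (site, species) are at least the filtering window apart by event_start.
    """

    site_id: str
    species: str
    event_start: datetime
    n_records: int = 1


class MalformedRowError(ValueError):
    """Raised when detection rows cannot be parsed; carries (line, message) pairs."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:5])
        more = "" if len(errors) <= 5 else f" (+{len(errors) - 5} more)"
        super().__init__(f"{len(errors)} malformed row(s): {lines}{more}")


def read_detections(
    path: str | Path,
    *,
    skip_bad: bool = False,
    dialect: dict | None = None,
) -> list[DetectionRecord]:
    """Read detection records from CSV (columns site_id, species, timestamp).

    Timestamps are ISO 8601 ``YYYY-MM-DD HH:MM`` (seconds tolerated), naive
    local time.  Malformed rows are collected with their file line numbers;
    the read fails with :class:`MalformedRowError` unless ``skip_bad``.
    Extra columns (e.g. ``media_id``) are ignored.
    """
    df = pd.read_csv(path, dtype=str, **(dialect or {}))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"missing required column(s): {', '.join(missing)}")

    records: list[DetectionRecord] = []
    errors: list[tuple[int, str]] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # header is line 1
        site = _clean(getattr(row, "site_id", "") or "")
        species = _clean(getattr(row, "species", "") or "")
        raw_ts = getattr(row, "timestamp", None)
        ts = pd.to_datetime(raw_ts, errors="coerce")
        if not site or not species:
            errors.append((line_no, "empty site_id or species"))
            continue
        if pd.isna(ts):
            errors.append((line_no, f"unparseable timestamp {raw_ts!r}"))
            continue
        records.append(DetectionRecord(site, species, ts.to_pydatetime()))
    if errors and not skip_bad:
        raise MalformedRowError(errors)
    return records


def filter_independent(
    records: Iterable[DetectionRecord],
    window_minutes: float = 30,
) -> list[DetectionEvent]:
    """Collapse raw records into independent detection events.

    Within each (site, species) group, sorted by timestamp, the first record
    opens an event; each subsequent record opens a new event iff it falls at
    or after ``window_minutes`` from the *current event's start* (half-open
    window: exactly 30.0 min later is a new event), otherwise it is merged.

    Species labels are matched after whitespace normalisation and case
    folding; the canonical label of a group is its lexicographically smallest
    observed spelling.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    window = timedelta(minutes=window_minutes)

    groups: dict[tuple[str, str], list[DetectionRecord]] = {}
    labels: dict[tuple[str, str], str] = {}
    for rec in records:
        key = (rec.site_id, rec.species.casefold())
        groups.setdefault(key, []).append(rec)
        prev = labels.get(key)
        if prev is None or rec.species < prev:
            labels[key] = rec.species

    events: list[DetectionEvent] = []
    for key in sorted(groups):
        recs = sorted(groups[key], key=lambda r: r.timestamp)
        start = recs[0].timestamp
        n = 1
        for rec in recs[1:]:
            if rec.timestamp - start >= window:
                events.append(DetectionEvent(key[0], labels[key], start, n))
                start, n = rec.timestamp, 1
            else:
                n += 1
        events.append(DetectionEvent(key[0], labels[key], start, n))
    events.sort(key=lambda e: (e.site_id, e.species.casefold(), e.event_start))
    return events


@dataclass
class SiteSpeciesMatrix:
    """r × S matrix of independent-event counts with a derived presence view."""

    sites: list[str]
    species: list[str]
    counts: np.ndarray  # shape (r, S), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.sites), len(self.species)):
            raise ValueError("counts shape does not match site/species labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate site labels")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")

    @property
    def presence(self) -> np.ndarray:
        """Boolean r × S view: species detected at site."""
        return self.counts > 0

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def event_counts(self) -> pd.Series:
        """Per-species total independent events (n_i)."""
        return pd.Series(self.counts.sum(axis=0), index=self.species, name="n_events")

    def occupancy(self) -> pd.Series:
        """Per-species number of sites with ≥ 1 event."""
        return pd.Series(self.presence.sum(axis=0), index=self.species, name="occupancy")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.sites, name="site_id"), columns=self.species)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SiteSpeciesMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SiteSpeciesMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))


def build_matrix(events: Sequence[DetectionEvent]) -> SiteSpeciesMatrix:
    """Tabulate events into a site × species count matrix (lexicographic order)."""
    if not events:
        raise ValueError("no detection events: supply at least one event to build a matrix")
    sites = sorted({e.site_id for e in events})
    species = sorted({e.species for e in events})
    site_ix = {s: i for i, s in enumerate(sites)}
    sp_ix = {s: i for i, s in enumerate(species)}
    counts = np.zeros((len(sites), len(species)), dtype=np.int64)
    for e in events:
        counts[site_ix[e.site_id], sp_ix[e.species]] += 1
    return SiteSpeciesMatrix(sites, species, counts)


def write_events_csv(events: Sequence[DetectionEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "site_id": [e.site_id for e in events],
            "species": [e.species for e in events],
            "event_start": [e.event_start.strftime("%Y-%m-%d %H:%M") for e in events],
            "n_records": [e.n_records for e in events],
        }
    ).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[DetectionEvent]:
    df = pd.read_csv(path, dtype={"site_id": str, "species": str})
    return [
        DetectionEvent(
            str(r.site_id),
            str(r.species),
            pd.to_datetime(r.event_start).to_pydatetime(),
            int(getattr(r, "n_records", 1)),
        )
        for r in df.itertuples(index=False)
    ]
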