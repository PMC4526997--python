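"""Data model and I/O for participant sensor logs.

A participant contributes three streams: a GPS location trace (nominally one
sample every 5 minutes), a sequence of screen on/off events, and a single
PHQ-9 depressive-symptom score (0-27). All timestamps are UTC epoch seconds;
local time is derived from a fixed per-participant timezone offset in hours
(no DST handling).

File formats are plain CSV:

* location log: header ``timestamp,latitude,longitude``
* screen log:   header ``timestamp,state`` with state in {on, off}
* scores:       header ``participant_id,phq9``

Timestamps may be epoch seconds or ISO-8601 strings. Malformed rows are
dropped and counted via the module logger rather than raising.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: nominal GPS sampling period of the study design, seconds
NOMINAL_SAMPLING_S = 300
SECONDS_PER_DAY = 86_400
#: minimum fraction of the study period a stream must cover to be analyzed
COVERAGE_THRESHOLD = 0.5


class LocationSample(NamedTuple):
    """One GPS fix: epoch seconds, latitude and longitude in degrees."""

    t: float
    lat: float
    lon: float


class ScreenEvent(NamedTuple):
    """One screen state change: epoch seconds and state ('on' or 'off')."""

    t: float
    state: str


@dataclass
class LocationTrace:
    """Time-ordered GPS trace for one participant (column arrays).

    Invariants enforced at construction: strictly increasing timestamps,
    latitudes in [-90, 90], longitudes in [-180, 180], finite times.
    """

    participant_id: str
    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    tz_offset: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if not (len(self.t) == len(self.lat) == len(self.lon)):
            raise ValueError("t, lat, lon must have equal length")
        if len(self.t) and not np.all(np.isfinite(self.t)):
            raise ValueError("timestamps must be finite")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if len(self.lat) and (np.nanmax(np.abs(self.lat)) > 90):
            raise ValueError("latitude out of [-90, 90]")
        if len(self.lon) and (np.nanmax(np.abs(self.lon)) > 180):
            raise ValueError("longitude out of [-180, 180]")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def samples(self) -> list[LocationSample]:
        return [LocationSample(*row) for row in zip(self.t, self.lat, self.lon)]

    def local_seconds_of_day(self) -> np.ndarray:
        """Seconds since local midnight for each sample."""
        return (self.t + self.tz_offset * 3600.0) % SECONDS_PER_DAY


@dataclass
class ParticipantRecord:
    """All streams for one participant; ``phq9`` may be None pre-assignment."""

    participant_id: str
    location: LocationTrace
    screen: list[ScreenEvent] = field(default_factory=list)
    phq9: int | None = None

    def __post_init__(self) -> None:
        if self.phq9 is not None and not (0 <= int(self.phq9) <= 27):
            raise ValueError("phq9 must lie in [0, 27]")


@dataclass
class CoverageReport:
    """Data-sufficiency summary used for the >50% availability filter."""

    participant_id: str
    location_coverage: float
    usage_coverage: float
    eligible_location: bool
    eligible_usage: bool


# ---------------------------------------------------------------------------
# timestamp parsing
# ---------------------------------------------------------------------------

def _parse_timestamps(col: pd.Series) -> np.ndarray:
    """Epoch seconds from a column of epoch numbers or ISO-8601 strings.

    Unparseable entries become NaN.
    """
    numeric = pd.to_numeric(col, errors="coerce")
    out = numeric.to_numpy(dtype=float)
    bad = ~np.isfinite(out)
    if bad.any():
        iso = pd.to_datetime(col[bad], errors="coerce", utc=True)
        ns = iso.to_numpy(dtype="datetime64[ns]").astype("int64")
        # NaT stays NaN; valid datetimes convert to epoch seconds
        out[bad] = np.where(iso.notna().to_numpy(), ns / 1e9, np.nan)
    return out


def _require_columns(df: pd.DataFrame, required: set[str], path) -> pd.DataFrame:
    df = df.rename(columns={c: str(c).strip().lower() for c in df.columns})
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def read_location_log(path, tz_offset: float = 0.0,
                      participant_id: str | None = None) -> LocationTrace:
    """Read a GPS location CSV into a :class:`LocationTrace`.

    Rows with unparseable timestamps or out-of-range coordinates are dropped
    and counted in a log message. Duplicate timestamps collapse to the first
    occurrence; rows are sorted by time.
    """
    path = Path(path)
    df = _require_columns(pd.read_csv(path, dtype=str),
                          {"timestamp", "latitude", "longitude"}, path)
    t = _parse_timestamps(df["timestamp"])
    lat = pd.to_numeric(df["latitude"], errors="coerce").to_numpy(float)
    lon = pd.to_numeric(df["longitude"], errors="coerce").to_numpy(float)
    valid = (np.isfinite(t) & np.isfinite(lat) & np.isfinite(lon)
             & (np.abs(lat) <= 90) & (np.abs(lon) <= 180))
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("%s: rejected %d malformed location rows", path, n_bad)
    t, lat, lon = t[valid], lat[valid], lon[valid]
    if len(t) == 0:
        raise ValueError(f"{path}: no valid location rows")
    order = np.argsort(t, kind="stable")
    t, lat, lon = t[order], lat[order], lon[order]
    keep = np.concatenate([[True], np.diff(t) > 0])  # first of each duplicate t
    return LocationTrace(participant_id or path.stem, t[keep], lat[keep],
                         lon[keep], tz_offset=tz_offset)


def write_location_log(trace: LocationTrace, path) -> None:
    pd.DataFrame({"timestamp": trace.t, "latitude": trace.lat,
                  "longitude": trace.lon}).to_csv(path, index=False)


def read_screen_log(path) -> list[ScreenEvent]:
    """Read a screen on/off event CSV; unrecognized states are rejected."""
    path = Path(path)
    df = _require_columns(pd.read_csv(path, dtype=str), {"timestamp", "state"},
                          path)
    t = _parse_timestamps(df["timestamp"])
    state = df["state"].astype(str).str.strip().str.lower()
    valid = np.isfinite(t) & state.isin(["on", "off"]).to_numpy()
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("%s: rejected %d malformed screen rows", path, n_bad)
    t, state = t[valid], state.to_numpy()[valid]
    if len(t) == 0:
        raise ValueError(f"{path}: no valid screen rows")
    order = np.argsort(t, kind="stable")
    return [ScreenEvent(float(tt), str(ss)) for tt, ss in
            zip(t[order], state[order])]


def write_screen_log(events: Sequence[ScreenEvent], path) -> None:
    pd.DataFrame({"timestamp": [e.t for e in events],
                  "state": [e.state for e in events]}).to_csv(path, index=False)


def read_scores(path) -> pd.Series:
    """PHQ-9 scores keyed by participant id."""
    df = _require_columns(pd.read_csv(path, dtype={"participant_id": str}),
                          {"participant_id", "phq9"}, path)
    s = df.set_index("participant_id")["phq9"].astype(int)
    if ((s < 0) | (s > 27)).any():
        raise ValueError(f"{path}: phq9 scores must lie in [0, 27]")
    return s


def write_scores(scores: pd.Series, path) -> None:
    scores.rename("phq9").rename_axis("participant_id").to_csv(path)


# ---------------------------------------------------------------------------
# data-sufficiency filter
# ---------------------------------------------------------------------------

def assess_coverage(record: ParticipantRecord, study_start: float,
                    study_end: float,
                    bin_s: float = NOMINAL_SAMPLING_S) -> CoverageReport:
    """Fraction of the study period with data, per stream, plus eligibility.

    Location coverage is the fraction of ``bin_s``-second sampling bins of
    the period containing at least one GPS sample; usage coverage is the
    fraction of local calendar days containing at least one screen event.
    Eligibility requires strictly more than half coverage; participants
    whose data "are not available for more than 50% of the time" are
    excluded from the corresponding analysis.
    """
    if study_end <= study_start:
        raise ValueError("study_end must exceed study_start")
    n_bins = math.ceil((study_end - study_start) / bin_s)
    t = record.location.t
    in_period = t[(t >= study_start) & (t < study_end)]
    if len(in_period):
        bins = np.unique(np.floor((in_period - study_start) / bin_s))
        loc_cov = len(bins) / n_bins
    else:
        loc_cov = 0.0

    tz = record.location.tz_offset * 3600.0
    d0 = math.floor((study_start + tz) / SECONDS_PER_DAY)
    d1 = math.floor((study_end - 1 + tz) / SECONDS_PER_DAY)
    n_days = d1 - d0 + 1
    ev = np.array([e.t for e in record.screen], dtype=float)
    ev = ev[(ev >= study_start) & (ev < study_end)]
    if len(ev):
        days = np.unique(np.floor((ev + tz) / SECONDS_PER_DAY))
        usage_cov = len(days) / n_days
    else:
        usage_cov = 0.0

    return CoverageReport(
        participant_id=record.participant_id,
        location_coverage=float(loc_cov),
        usage_coverage=float(usage_cov),
        eligible_location=loc_cov > COVERAGE_THRESHOLD,
        eligible_usage=usage_cov > COVERAGE_THRESHOLD,
    )


# ---------------------------------------------------------------------------
# cohort directory layout + config
# ---------------------------------------------------------------------------

def location_path(directory, participant_id: str) -> Path:
    return Path(directory) / f"{participant_id}_location.csv"


def screen_path(directory, participant_id: str) -> Path:
    return Path(directory) / f"{participant_id}_screen.csv"


def load_cohort(location_dir, screen_dir, scores_file,
                tz_offset: float = 0.0) -> list[ParticipantRecord]:
    """Assemble ParticipantRecords from per-participant CSVs and a score CSV."""
    scores = read_scores(scores_file)
    records = []
    for pid, score in scores.items():
        trace = read_location_log(location_path(location_dir, pid),
                                  tz_offset=tz_offset, participant_id=pid)
        screen = read_screen_log(screen_path(screen_dir, pid))
        records.append(ParticipantRecord(pid, trace, screen, int(score)))
    return records


def write_feature_table(features: pd.DataFrame, path) -> None:
    """Feature CSV, one row per participant; undefined values written as NA."""
    features.rename_axis("participant_id").to_csv(path, na_rep="NA")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant_id", na_values=["NA"],
                       dtype={"participant_id": str})


def load_config(path) -> dict:
    """YAML config with optional sections cohort/baseline/link/preprocess."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
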