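"""The ten behavioral features computed per participant.

Eight location features — location variance, number of clusters, entropy,
normalized entropy, home stay, circadian movement, transition time, total
distance — and two phone-usage features — usage frequency and usage
duration. Undefined values (too little data, degenerate input) are NaN and
serialized as NA.

Conventions fixed here: natural logarithms throughout (the entropy of an
80/20 split is ~0.500, of a 50/50 split ~0.693); occupancy and time
fractions count stationary samples, a proxy for time under near-uniform
sampling; coordinates stay in degrees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

from .io import ParticipantRecord, ScreenEvent, SECONDS_PER_DAY
from .preprocess import (ClusterModel, LabeledTrace, PreprocessConfig,
                         haversine_km, identify_home_cluster, preprocess_trace)
from .io import LocationTrace

log = logging.getLogger(__name__)

FEATURE_NAMES = [
    "location_variance", "entropy", "normalized_entropy", "home_stay",
    "circadian_movement", "transition_time", "total_distance", "n_clusters",
    "usage_frequency", "usage_duration",
]

#: features the study found significantly associated with PHQ-9, with the
#: expected correlation sign (usage signs per the positive-association reading)
SIGNIFICANT_FEATURES = {
    "circadian_movement": -1, "normalized_entropy": -1,
    "location_variance": -1, "home_stay": +1,
    "usage_duration": +1, "usage_frequency": +1,
}


# ---------------------------------------------------------------------------
# location features
# ---------------------------------------------------------------------------

def location_variance(lat: np.ndarray, lon: np.ndarray) -> float:
    """ln of the summed population variances of stationary lat/lon (deg^2).

    NaN for fewer than two samples or zero total variance.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if len(lat) < 2:
        return float("nan")
    total = float(np.var(lat) + np.var(lon))
    if total <= 0.0:
        log.warning("zero coordinate variance; location_variance undefined")
        return float("nan")
    return math.log(total)


def cluster_entropy(p: Sequence[float]) -> float:
    """Shannon entropy -sum p_i ln p_i of the cluster-occupancy distribution."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("p must be a probability distribution")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def normalized_entropy(p: Sequence[float], n_clusters: int | None = None) -> float:
    """Entropy divided by its maximum ln N; defined as 0 for a single cluster.

    Ranges over [0, 1]: 0 when all samples share one cluster, 1 when they
    are spread uniformly over the N clusters.
    """
    p = np.asarray(p, dtype=float)
    n = len(p) if n_clusters is None else int(n_clusters)
    if n < 1:
        raise ValueError("cluster count must be >= 1")
    if n == 1:
        return 0.0
    return cluster_entropy(p) / math.log(n)


def home_stay(model: ClusterModel) -> float:
    """Fraction of stationary samples spent in the home cluster."""
    if model.home_cluster is None:
        raise ValueError("home cluster not identified")
    return float(model.p[model.home_cluster])


@dataclass
class SpectralBand:
    """Lomb-Scargle ordinates inside the circadian period band.

    ``frequencies`` (Hz) are the grid bins with period in the band;
    ``i1``/``i2`` are their first/last indices on the conceptual uniform
    frequency grid of spacing 1/(oversample * span). Ordinates outside the
    band are not evaluated: each Lomb-Scargle ordinate depends only on its
    own frequency.
    """

    frequencies: np.ndarray
    psd: np.ndarray
    i1: int
    i2: int

    @property
    def band_energy(self) -> float:
        """Mean power spectral density over the band bins."""
        return float(self.psd.mean())


PERIOD_BAND_H = (23.5, 24.5)
OVERSAMPLE = 5


def circadian_band(t: np.ndarray, y: np.ndarray,
                   band_h: tuple[float, float] = PERIOD_BAND_H,
                   oversample: int = OVERSAMPLE) -> SpectralBand | None:
    """Lomb-Scargle power of an irregular series in a period band.

    The frequency grid runs from 1/span to the pseudo-Nyquist rate
    1/(2 * median sampling interval) with spacing 1/(oversample * span);
    the band keeps bins whose period lies in ``band_h`` (hours, inclusive),
    expanded to the two nearest bins when the grid is too coarse to place
    two bins inside it. Returns None when the series is shorter than 24 h,
    has < 8 samples, or the band exceeds the resolvable range.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 8:
        return None
    span = t[-1] - t[0]
    if span < 24 * 3600.0:
        return None
    dt_med = float(np.median(np.diff(t)))
    f_nyq = 1.0 / (2.0 * dt_med)
    f_lo = 1.0 / (band_h[1] * 3600.0)
    f_hi = 1.0 / (band_h[0] * 3600.0)
    if f_hi > f_nyq:
        return None
    df = 1.0 / (oversample * span)
    i1 = int(math.ceil(f_lo / df))
    i2 = int(math.floor(f_hi / df))
    if i2 <= i1:  # coarse grid: take the two bins straddling the band
        i1 = max(1, int(math.floor(f_lo / df)))
        i2 = i1 + 1
    freqs = np.arange(i1, i2 + 1) * df
    y_c = y - y.mean()
    if np.var(y_c) == 0.0:  # constant signal: exactly zero power
        psd = np.zeros_like(freqs)
    else:
        psd = lombscargle(t, y_c, 2.0 * np.pi * freqs)
    return SpectralBand(frequencies=freqs, psd=psd, i1=i1, i2=i2)


def circadian_movement(trace: LocationTrace,
                       band_h: tuple[float, float] = PERIOD_BAND_H,
                       oversample: int = OVERSAMPLE) -> float:
    """ln of summed 24 h-band Lomb-Scargle energy of latitude and longitude.

    High values mean the sequence of locations repeats on a circadian
    rhythm (e.g. regular commute times); irregular movement spreads power
    away from the band. NaN when the trace is too short or band energy is
    zero (e.g. a constant trace).
    """
    lat_band = circadian_band(trace.t, trace.lat, band_h, oversample)
    lon_band = circadian_band(trace.t, trace.lon, band_h, oversample)
    if lat_band is None or lon_band is None:
        return float("nan")
    total = lat_band.band_energy + lon_band.band_energy
    if total <= 0.0:
        return float("nan")
    return math.log(total)


def transition_time(labeled: LabeledTrace) -> float:
    """Fraction of labeled samples in the transition state.

    Unknown-state samples are excluded from numerator and denominator.
    """
    n_stat = int(labeled.stationary_mask.sum())
    n_trans = int(labeled.transition_mask.sum())
    if n_stat + n_trans == 0:
        return float("nan")
    return n_trans / (n_stat + n_trans)


def total_distance(trace: LocationTrace,
                   cfg: PreprocessConfig | None = None) -> float:
    """Accumulated haversine distance over consecutive samples, in km.

    Legs spanning a gap longer than ``max_gap_s`` contribute zero (the
    path across an outage is unobserved); their count is logged.
    """
    cfg = cfg or PreprocessConfig()
    if len(trace) < 2:
        return 0.0
    d = haversine_km(trace.lat[:-1], trace.lon[:-1],
                     trace.lat[1:], trace.lon[1:])
    gaps = np.diff(trace.t) > cfg.max_gap_s
    if gaps.any():
        log.debug("total_distance: %d legs over gaps ignored", int(gaps.sum()))
    return float(d[~gaps].sum())


# ---------------------------------------------------------------------------
# phone-usage features
# ---------------------------------------------------------------------------

class ScreenSession(NamedTuple):
    """A participant-initiated interval of phone use."""

    start: float
    end: float

    @property
    def duration_s(self) -> float:
        return self.end - self.start


def usage_sessions(events: Sequence[ScreenEvent],
                   cfg: PreprocessConfig | None = None) -> list[ScreenSession]:
    """Pair on/off events into sessions and drop sub-30 s notification blips.

    Consecutive 'on' events collapse to the first; an 'off' with no open
    session is ignored; a trailing unmatched 'on' is dropped with a
    warning. Sessions shorter than ``min_session_s`` (strictly) are
    removed.
    """
    cfg = cfg or PreprocessConfig()
    sessions: list[ScreenSession] = []
    open_t: float | None = None
    for ev in events:
        if ev.state == "on":
            if open_t is None:
                open_t = ev.t
        elif ev.state == "off":
            if open_t is not None:
                if ev.t > open_t:
                    sessions.append(ScreenSession(open_t, ev.t))
                open_t = None
        else:
            raise ValueError(f"unknown screen state {ev.state!r}")
    if open_t is not None:
        log.warning("unpaired trailing 'on' event at t=%s dropped", open_t)
    return [s for s in sessions if s.duration_s >= cfg.min_session_s]


def count_days(times: Sequence[float], tz_offset: float = 0.0) -> int:
    """Local calendar days from first to last timestamp, inclusive."""
    t = np.asarray(times, dtype=float)
    if len(t) == 0:
        return 0
    local = t + tz_offset * 3600.0
    d0 = math.floor(local.min() / SECONDS_PER_DAY)
    d1 = math.floor(local.max() / SECONDS_PER_DAY)
    return d1 - d0 + 1


def usage_features(sessions: Sequence[ScreenSession],
                   n_days: int) -> tuple[float, float]:
    """(sessions per day, seconds of use per day)."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not sessions:
        return 0.0, 0.0
    total = sum(s.duration_s for s in sessions)
    return len(sessions) / n_days, total / n_days


# ---------------------------------------------------------------------------
# per-participant assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """The ten features for one participant; NaN marks undefined values."""

    participant_id: str
    location_variance: float = float("nan")
    entropy: float = float("nan")
    normalized_entropy: float = float("nan")
    home_stay: float = float("nan")
    circadian_movement: float = float("nan")
    transition_time: float = float("nan")
    total_distance: float = float("nan")
    n_clusters: float = float("nan")
    usage_frequency: float = float("nan")
    usage_duration: float = float("nan")

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def extract_features(record: ParticipantRecord,
                     cfg: PreprocessConfig | None = None,
                     seed: int = 0) -> FeatureVector:
    """Run preprocessing and compute all ten features for one participant.

    Location features degrade to NaN when the trace has no stationary
    samples; usage features are zero when no sessions survive the filter.
    """
    cfg = cfg or PreprocessConfig()
    fv = FeatureVector(participant_id=record.participant_id)
    trace = record.location

    try:
        labeled, model = preprocess_trace(trace, cfg, seed=seed)
    except ValueError:
        labeled, model = None, None
        log.warning("%s: preprocessing failed; location features NA",
                    record.participant_id)

    if labeled is not None and model is not None:
        stat = model.stationary_idx
        fv.location_variance = location_variance(trace.lat[stat],
                                                 trace.lon[stat])
        fv.entropy = cluster_entropy(model.p)
        fv.normalized_entropy = normalized_entropy(model.p, model.k)
        fv.home_stay = home_stay(model)
        fv.transition_time = transition_time(labeled)
        fv.n_clusters = float(model.k)
    fv.circadian_movement = circadian_movement(trace)
    fv.total_distance = total_distance(trace, cfg)

    sessions = usage_sessions(record.screen, cfg)
    times = [e.t for e in record.screen]
    n_days = count_days(times, trace.tz_offset)
    if n_days >= 1:
        fv.usage_frequency, fv.usage_duration = usage_features(sessions, n_days)
    elif not sessions:
        fv.usage_frequency, fv.usage_duration = 0.0, 0.0
    return fv


def feature_table(records: Sequence[ParticipantRecord],
                  cfg: PreprocessConfig | None = None,
                  seed: int = 0) -> pd.DataFrame:
    """Feature matrix: one row per participant, one column per feature."""
    rows = [extract_features(r, cfg, seed=seed).to_dict() for r in records]
    return pd.DataFrame(rows, index=pd.Index(
        [r.participant_id for r in records], name="participant_id"))
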