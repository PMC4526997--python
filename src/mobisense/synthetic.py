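"""Synthetic cohort generator with a latent-severity behavioral link.

No raw sensor data from the original study were ever deposited, so the
pipeline is exercised on simulated participants. Each participant has a
small set of significant places ("anchors") on a local planar patch: a
home anchor plus workplaces/other places, separated by more than twice
the clustering radius so each anchor is recoverable as one cluster. Days
follow a canonical schedule (fixed departure/return times) with
probability ``regularity``, otherwise departure time and anchor order are
shuffled — degrading the 24 h rhythm the circadian-movement feature
measures. Within-anchor positions get GPS jitter, transitions are
constant-speed interpolated runs (> 1 km/h, so the speed labeler sees
genuine transition samples), and samples are dropped at random to a
target coverage. Screen sessions arrive at a daily Poisson rate with
exponential durations (some under 30 s, exercising the session filter).

A cohort draws a latent severity u ~ U(0,1) per participant; behavioral
parameters are ``baseline + slope * u`` and the PHQ-9 score is a monotone
map of u plus Gaussian noise, rounded and clipped to [0, 27]. The default
slopes plant the six associations the analysis should recover: lower
normalized entropy, location variance and circadian movement, and higher
home stay, usage frequency and usage duration, at higher severity.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (LocationTrace, ParticipantRecord, ScreenEvent,
                 location_path, screen_path, write_location_log,
                 write_screen_log, write_scores)

SECONDS_PER_DAY = 86_400
#: epoch anchor for simulated studies (2021-03-01T00:00:00Z)
EPOCH0 = 1_614_556_800.0
KM_PER_DEG = 111.1949  # meridian arc per degree at Earth radius 6371 km
TRAVEL_SPEED_KMH = 25.0
#: anchors must sit further apart than twice the 500 m clustering radius
MIN_ANCHOR_SEP_KM = 1.2
CANONICAL_DEPART_H = 9.0
MAX_AWAY_H = 16.0  # nights are always spent at home


@dataclass
class BehaviorParams:
    """Generative behavioral parameters for one participant.

    n_anchors
        Candidate significant places (>= 1), home included.
    home_stay_frac
        Target fraction of the day spent at the home anchor.
    regularity
        Probability that a day follows the canonical schedule.
    mobility_scale_km
        Radius of the disk (km) on which non-home anchors are placed.
    gps_noise_m
        SD of isotropic GPS jitter around the true position.
    usage_rate_per_day, usage_mean_s
        Poisson rate of screen sessions and their exponential mean
        duration.
    coverage
        Fraction of nominal samples retained (uniform thinning).
    """

    n_anchors: int = 4
    home_stay_frac: float = 0.55
    regularity: float = 0.9
    mobility_scale_km: float = 6.0
    gps_noise_m: float = 15.0
    usage_rate_per_day: float = 15.0
    usage_mean_s: float = 70.0
    coverage: float = 0.85

    def __post_init__(self) -> None:
        if self.n_anchors < 1:
            raise ValueError("n_anchors must be >= 1")
        if not 0.0 <= self.home_stay_frac <= 1.0:
            raise ValueError("home_stay_frac must lie in [0, 1]")
        if not 0.0 <= self.regularity <= 1.0:
            raise ValueError("regularity must lie in [0, 1]")
        if self.mobility_scale_km <= 0:
            raise ValueError("mobility_scale_km must be positive")
        if self.gps_noise_m < 0 or self.usage_rate_per_day < 0:
            raise ValueError("gps_noise_m and usage_rate_per_day must be >= 0")
        if self.usage_mean_s <= 0:
            raise ValueError("usage_mean_s must be positive")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must lie in (0, 1]")


#: default severity slopes: parameter value = baseline + slope * u
DEFAULT_SLOPES: dict[str, float] = {
    "n_anchors": -2.0,
    "home_stay_frac": 0.35,
    "regularity": -0.6,
    "mobility_scale_km": -4.0,
    "usage_rate_per_day": 30.0,
    "usage_mean_s": 110.0,
}


@dataclass
class SeverityLink:
    """Monotone link between latent severity u ~ U(0,1) and the record.

    ``slopes`` shift behavioral parameters linearly in u; the PHQ-9 score
    is round(clip(lo + (hi - lo) * u**score_power + N(0, noise_sd))). The
    default power puts the rounding boundary of the cutoff score 5 (raw
    4.5) at the median latent, so a default cohort splits roughly half
    and half; score_power=1 gives the plain linear 27u map.
    """

    slopes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SLOPES))
    noise_sd: float = 2.0
    score_range: tuple[float, float] = (0.0, 27.0)
    score_power: float = math.log(27.0 / 4.5) / math.log(2.0)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.score_range
        if not (0 <= lo < hi <= 27):
            raise ValueError("score_range must be within [0, 27]")

    def score_for(self, u: float, noise: float = 0.0) -> int:
        lo, hi = self.score_range
        raw = lo + (hi - lo) * u ** self.score_power + noise
        return int(round(min(max(raw, lo), hi)))


def null_link(noise_sd: float = 2.0) -> SeverityLink:
    """A link with all behavioral slopes zero (features carry no signal)."""
    return SeverityLink(slopes={}, noise_sd=noise_sd)


@dataclass
class CohortSpec:
    """Study-design parameters: 2-week observation at 5-minute sampling."""

    n_participants: int = 28
    days: int = 14
    sampling_period_s: float = 300.0
    seed: int = 0
    origin: tuple[float, float] = (41.881, -87.63)
    tz_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.days < 1 or self.sampling_period_s < 1:
            raise ValueError("days >= 1 and sampling_period_s >= 1 required")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


def _place_anchors(rng: np.random.Generator, n_anchors: int,
                   scale_km: float) -> np.ndarray:
    """(n, 2) planar km offsets; home at the origin, pairwise sep > 1.2 km."""
    pts = [np.zeros(2)]
    radius = max(scale_km, MIN_ANCHOR_SEP_KM * 1.3)
    for _ in range(n_anchors - 1):
        for attempt in range(1000):
            r = radius * math.sqrt(rng.uniform(0.1, 1.0))
            theta = rng.uniform(0, 2 * math.pi)
            cand = np.array([r * math.cos(theta), r * math.sin(theta)])
            if all(np.linalg.norm(cand - p) > MIN_ANCHOR_SEP_KM for p in pts):
                pts.append(cand)
                break
        else:
            raise ValueError(
                f"cannot place {n_anchors} anchors with separation "
                f"{MIN_ANCHOR_SEP_KM} km inside a {radius} km disk")
    return np.vstack(pts)


def _day_segments(anchors_km: np.ndarray, order: np.ndarray, depart_h: float,
                  away_h: float) -> list[tuple[float, float, np.ndarray,
                                               np.ndarray]]:
    """Piecewise itinerary (t0_h, t1_h, xy_start, xy_end) over one day."""
    home = anchors_km[0]
    if len(order) == 0 or away_h <= 0:
        return [(0.0, 24.0, home, home)]
    stops = [anchors_km[j] for j in order]
    legs = [home] + stops + [home]
    travel_h = [float(np.linalg.norm(b - a)) / TRAVEL_SPEED_KMH
                for a, b in zip(legs[:-1], legs[1:])]
    stay_h = max(0.0, away_h - sum(travel_h)) / len(stops)
    segs = [(0.0, depart_h, home, home)]
    t = depart_h
    pos = home
    for stop, tr in zip(stops, travel_h[:-1]):
        segs.append((t, t + tr, pos, stop))
        t += tr
        segs.append((t, t + stay_h, stop, stop))
        t += stay_h
        pos = stop
    segs.append((t, t + travel_h[-1], pos, home))
    t += travel_h[-1]
    segs.append((t, 24.0, home, home))
    # overlong itineraries (late departure + long away window) clip at 24 h
    clipped = []
    for t0, t1, p0, p1 in segs:
        t0c, t1c = min(t0, 24.0), min(t1, 24.0)
        if t1c > t0c:
            clipped.append((t0c, t1c, p0, p1))
    return clipped


def generate_participant(params: BehaviorParams, spec: CohortSpec,
                         seed: int,
                         participant_id: str = "p000") -> ParticipantRecord:
    """Simulate one participant's GPS trace and screen events (phq9 unset).

    Deterministic for a fixed seed. Raises when the requested anchors
    cannot be placed with the minimum separation.
    """
    rng = np.random.default_rng(seed)
    anchors_km = _place_anchors(rng, params.n_anchors, params.mobility_scale_km)
    away_h = min((1.0 - params.home_stay_frac) * 24.0, MAX_AWAY_H)
    n_away = params.n_anchors - 1

    # rough travel budget to keep irregular departures inside the day
    if n_away:
        max_travel = 2.0 * params.mobility_scale_km * (n_away + 1) \
            / TRAVEL_SPEED_KMH
        latest_depart = max(7.0, min(21.0, 23.5 - away_h - max_travel))
    period = spec.sampling_period_s
    per_day = int(SECONDS_PER_DAY // period)

    t_all, x_all, y_all = [], [], []
    for day in range(spec.days):
        if n_away == 0 or away_h <= 0:
            segs = _day_segments(anchors_km, np.array([], int), 0.0, 0.0)
        else:
            canonical = rng.uniform() < params.regularity
            if canonical:
                order = np.arange(1, params.n_anchors)
                depart = CANONICAL_DEPART_H
            else:
                order = rng.permutation(np.arange(1, params.n_anchors))
                depart = rng.uniform(6.0, latest_depart)
            segs = _day_segments(anchors_km, order, depart, away_h)
        bounds = np.array([s[1] for s in segs])
        starts = np.array([s[0] for s in segs])
        a = np.vstack([s[2] for s in segs])
        b = np.vstack([s[3] for s in segs])
        th = (np.arange(per_day) * period) / 3600.0  # hours into the day
        seg_i = np.clip(np.searchsorted(bounds, th, side="right"), 0,
                        len(segs) - 1)
        dur = np.maximum(bounds[seg_i] - starts[seg_i], 1e-9)
        frac = np.clip((th - starts[seg_i]) / dur, 0.0, 1.0)
        xy = a[seg_i] + (b[seg_i] - a[seg_i]) * frac[:, None]
        t_all.append(day * SECONDS_PER_DAY + np.arange(per_day) * period)
        x_all.append(xy[:, 0])
        y_all.append(xy[:, 1])

    t = np.concatenate(t_all) + EPOCH0 - spec.tz_offset * 3600.0
    x = np.concatenate(x_all)
    y = np.concatenate(y_all)
    noise_km = params.gps_noise_m / 1000.0
    x = x + rng.normal(0.0, noise_km, len(x))
    y = y + rng.normal(0.0, noise_km, len(y))
    keep = rng.random(len(t)) < params.coverage
    if keep.sum() < 2:
        keep[:2] = True  # degenerate coverage: keep a readable trace
    lat0, lon0 = spec.origin
    lat = lat0 + y[keep] / KM_PER_DEG
    lon = lon0 + x[keep] / (KM_PER_DEG * math.cos(math.radians(lat0)))
    trace = LocationTrace(participant_id, t[keep], lat, lon,
                          tz_offset=spec.tz_offset)

    events: list[ScreenEvent] = []
    for day in range(spec.days):
        k = rng.poisson(params.usage_rate_per_day)
        if k == 0:
            continue
        starts_s = np.sort(rng.uniform(0, SECONDS_PER_DAY, k))
        durs = rng.exponential(params.usage_mean_s, k)
        day0 = day * SECONDS_PER_DAY + EPOCH0 - spec.tz_offset * 3600.0
        for i in range(k):
            s = starts_s[i]
            e = s + durs[i]
            if i + 1 < k:
                e = min(e, starts_s[i + 1] - 1.0)  # no overlapping sessions
            e = min(e, SECONDS_PER_DAY - 1.0)
            if e <= s:
                continue
            events.append(ScreenEvent(day0 + s, "on"))
            events.append(ScreenEvent(day0 + e, "off"))
    return ParticipantRecord(participant_id, trace, events, phq9=None)


def _linked_params(baseline: BehaviorParams, link: SeverityLink,
                   u: float) -> BehaviorParams:
    vals = dataclasses.asdict(baseline)
    for name, slope in link.slopes.items():
        if name not in vals:
            raise KeyError(f"unknown behavioral parameter {name!r}")
        vals[name] = vals[name] + slope * u
    vals["n_anchors"] = max(1, int(round(vals["n_anchors"])))
    vals["home_stay_frac"] = float(np.clip(vals["home_stay_frac"], 0.0, 0.98))
    vals["regularity"] = float(np.clip(vals["regularity"], 0.0, 1.0))
    vals["mobility_scale_km"] = max(0.3, vals["mobility_scale_km"])
    vals["gps_noise_m"] = max(0.0, vals["gps_noise_m"])
    vals["usage_rate_per_day"] = max(0.0, vals["usage_rate_per_day"])
    vals["usage_mean_s"] = max(1.0, vals["usage_mean_s"])
    vals["coverage"] = float(np.clip(vals["coverage"], 0.01, 1.0))
    return BehaviorParams(**vals)


def generate_cohort(spec: CohortSpec, link: SeverityLink | None = None,
                    baseline: BehaviorParams | None = None,
                    return_truth: bool = False):
    """Simulate a cohort of ParticipantRecords with linked PHQ-9 scores.

    Deterministic for a fixed ``spec.seed``. With ``return_truth`` also
    returns a DataFrame of each participant's latent severity and
    generative parameters.
    """
    link = link or SeverityLink()
    baseline = baseline or BehaviorParams()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    us = rng.uniform(0.0, 1.0, n)
    noises = rng.normal(0.0, link.noise_sd, n) if link.noise_sd > 0 \
        else np.zeros(n)
    child_seeds = rng.integers(0, 2**31 - 1, n)
    records, truth_rows = [], []
    for i in range(n):
        pid = f"p{i:03d}"
        params = _linked_params(baseline, link, float(us[i]))
        rec = generate_participant(params, spec, int(child_seeds[i]), pid)
        rec.phq9 = link.score_for(float(us[i]), float(noises[i]))
        records.append(rec)
        truth_rows.append({"participant_id": pid, "u": us[i],
                           "phq9": rec.phq9, **dataclasses.asdict(params)})
    if return_truth:
        return records, pd.DataFrame(truth_rows).set_index("participant_id")
    return records


def write_cohort(records, out_dir, truth: pd.DataFrame | None = None) -> None:
    """Write per-participant CSV logs, a scores CSV and optional truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_location_log(rec.location, location_path(out, rec.participant_id))
        write_screen_log(rec.screen, screen_path(out, rec.participant_id))
    scores = pd.Series({r.participant_id: r.phq9 for r in records})
    write_scores(scores, out / "scores.csv")
    if truth is not None:
        truth.to_csv(out / "ground_truth.csv")
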