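"""GPS preprocessing: movement-state labeling and location clustering.

Two stages precede feature extraction. First, each GPS sample is labeled
*stationary* or *transition* by thresholding its movement speed (time
derivative of position; threshold 1 km/h). Second, the stationary samples
are clustered into significant places with K-means, increasing K from 1
until the farthest point of every cluster lies within a maximum radius
(500 m) of its center. A heuristic then identifies the home cluster as the
place most visited between midnight and 6 a.m. local time among the three
most-visited clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .io import LocationTrace

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

# per-sample movement states
STATIONARY, TRANSITION, UNKNOWN = 0, 1, 2


@dataclass
class PreprocessConfig:
    """Thresholds of the preprocessing stage.

    speed_threshold_kmh
        Boundary between stationary and transition states (strict:
        stationary iff speed < threshold).
    cluster_radius_m
        Maximum allowed distance from any stationary sample to its cluster
        center; K-means K grows until this holds.
    max_gap_s
        Sampling gaps longer than this yield an 'unknown' state (no speed
        estimate across outages) and contribute zero to total distance.
    min_session_s
        Screen sessions shorter than this are discarded as
        notification-driven, not participant-initiated.
    """

    speed_threshold_kmh: float = 1.0
    cluster_radius_m: float = 500.0
    max_gap_s: float = 900.0
    min_session_s: float = 30.0
    k_max: int = 50
    kmeans_restarts: int = 10

    def __post_init__(self) -> None:
        for name in ("speed_threshold_kmh", "cluster_radius_m", "max_gap_s",
                     "min_session_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_max < 1 or self.kmeans_restarts < 1:
            raise ValueError("k_max and kmeans_restarts must be >= 1")

    @classmethod
    def from_dict(cls, d: dict | None) -> "PreprocessConfig":
        return cls(**(d or {}))


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km (Earth radius 6371 km); vectorized."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = (np.sin(dlat / 2.0) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class LabeledTrace:
    """A trace with per-sample speeds (km/h) and movement states."""

    trace: LocationTrace
    speed_kmh: np.ndarray
    state: np.ndarray  # int8: STATIONARY / TRANSITION / UNKNOWN

    @property
    def stationary_mask(self) -> np.ndarray:
        return self.state == STATIONARY

    @property
    def transition_mask(self) -> np.ndarray:
        return self.state == TRANSITION

    @property
    def n_labeled(self) -> int:
        return int((self.state != UNKNOWN).sum())


def estimate_speeds(trace: LocationTrace,
                    cfg: PreprocessConfig | None = None) -> LabeledTrace:
    """Label each sample stationary/transition from its backward-difference speed.

    Speed at sample k is the haversine distance from sample k-1 divided by
    the elapsed time. The first sample inherits the second's speed. Samples
    following a gap longer than ``max_gap_s`` get state 'unknown' (speed
    NaN): a single displacement across an outage says little about movement.
    Traces with fewer than two samples are entirely 'unknown'.
    """
    cfg = cfg or PreprocessConfig()
    n = len(trace)
    speed = np.full(n, np.nan)
    state = np.full(n, UNKNOWN, dtype=np.int8)
    if n < 2:
        return LabeledTrace(trace, speed, state)
    dt = np.diff(trace.t)
    dist = haversine_km(trace.lat[:-1], trace.lon[:-1],
                        trace.lat[1:], trace.lon[1:])
    sp = dist / (dt / 3600.0)
    ok = dt <= cfg.max_gap_s
    speed[1:][ok] = sp[ok]
    speed[0] = speed[1]
    known = np.isfinite(speed)
    state[known & (speed < cfg.speed_threshold_kmh)] = STATIONARY
    state[known & (speed >= cfg.speed_threshold_kmh)] = TRANSITION
    return LabeledTrace(trace, speed, state)


@dataclass
class ClusterModel:
    """Significant places recovered from stationary samples.

    ``assignment`` indexes clusters per *stationary* sample (in trace order
    of the stationary subset, whose trace indices are ``stationary_idx``);
    ``p`` is the occupancy distribution (fraction of stationary samples per
    cluster, summing to 1).
    """

    k: int
    centers: np.ndarray          # (k, 2) mean (lat, lon) per cluster
    assignment: np.ndarray       # (n_stationary,) cluster index
    p: np.ndarray                # (k,) occupancy distribution
    stationary_idx: np.ndarray   # indices into the parent trace
    home_cluster: int | None = None
    home_fallback: bool = False

    def __post_init__(self) -> None:
        if self.k >= 1 and abs(float(self.p.sum()) - 1.0) > 1e-9:
            raise ValueError("occupancy distribution must sum to 1")

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)


def _max_center_distance_m(pts: np.ndarray, centers: np.ndarray,
                           labels: np.ndarray) -> float:
    d_km = haversine_km(pts[:, 0], pts[:, 1],
                        centers[labels, 0], centers[labels, 1])
    return float(np.max(d_km) * 1000.0)


def cluster_stationary(labeled: LabeledTrace,
                       cfg: PreprocessConfig | None = None,
                       seed: int = 0) -> ClusterModel:
    """Adaptive K-means over stationary samples, bounded by a max radius.

    Starting from K=1, K is increased until the farthest sample of every
    cluster lies strictly within ``cluster_radius_m`` of its center
    (haversine on centers taken as coordinate means). The smallest such K
    is returned. Deterministic for a fixed seed (k-means++ with
    ``kmeans_restarts`` restarts).
    """
    cfg = cfg or PreprocessConfig()
    idx = np.flatnonzero(labeled.stationary_mask)
    if len(idx) == 0:
        raise ValueError("no stationary samples to cluster")
    pts = np.column_stack([labeled.trace.lat[idx], labeled.trace.lon[idx]])
    n = len(pts)
    k_cap = min(n, cfg.k_max)
    for k in range(1, k_cap + 1):
        if k == 1:
            centers = pts.mean(axis=0, keepdims=True)
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=cfg.kmeans_restarts,
                        random_state=seed).fit(pts)
            labels = km.labels_.astype(int)
            # centers as coordinate means of the assigned points
            centers = np.vstack([pts[labels == j].mean(axis=0)
                                 for j in range(k)])
        if _max_center_distance_m(pts, centers, labels) < cfg.cluster_radius_m:
            counts = np.bincount(labels, minlength=k)
            return ClusterModel(k=k, centers=centers, assignment=labels,
                                p=counts / counts.sum(), stationary_idx=idx)
    raise RuntimeError(
        f"radius rule unmet at K={k_cap}; raise k_max or cluster_radius_m")


def identify_home_cluster(model: ClusterModel, labeled: LabeledTrace,
                          tz_offset: float | None = None) -> int:
    """Home = most-visited cluster between 12 a.m. and 6 a.m. local time.

    Candidates are restricted to the three most-visited clusters overall.
    Ties break by overall visit count, then lowest index. If no stationary
    sample falls in the night window, falls back to the most-visited
    cluster and sets ``model.home_fallback``. Sets ``model.home_cluster``
    and returns the index.
    """
    tz = labeled.trace.tz_offset if tz_offset is None else tz_offset
    counts = model.counts
    order = np.lexsort((np.arange(model.k), -counts))
    top3 = order[:3]
    local = (labeled.trace.t[model.stationary_idx] + tz * 3600.0) % 86400.0
    night = local < 6 * 3600.0
    night_counts = np.bincount(model.assignment[night], minlength=model.k)
    if night_counts.sum() == 0:
        home = int(order[0])
        model.home_cluster, model.home_fallback = home, True
        log.warning("no stationary samples between 00:00 and 06:00; "
                    "falling back to most-visited cluster %d", home)
        return home
    # maximize night visits, then overall visits, then lowest index
    best = min(top3, key=lambda j: (-night_counts[j], -counts[j], j))
    model.home_cluster, model.home_fallback = int(best), False
    return int(best)


def preprocess_trace(trace: LocationTrace,
                     cfg: PreprocessConfig | None = None,
                     seed: int = 0) -> tuple[LabeledTrace, ClusterModel]:
    """Label speeds, cluster stationary samples, identify the home cluster."""
    cfg = cfg or PreprocessConfig()
    labeled = estimate_speeds(trace, cfg)
    model = cluster_stationary(labeled, cfg, seed=seed)
    identify_home_cluster(model, labeled)
    return labeled, model
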