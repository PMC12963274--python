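"""Indoor/outdoor context inference from GPS fixes and a land-use map.

The chain mirrors smartphone-based context pipelines for free-living
mobility studies:

1. *Stay points*: a sliding-anchor scan over time-sorted fixes emits a stay
   point whenever the carrier remained within a 20 m radius for more than
   2 min. Dwell across a data gap counts only if the flanking fixes are
   within 10 m of each other (the app stops reporting when stationary).
2. *Stay regions*: stay-point centroids are clustered with HDBSCAN in a
   local metric projection; noise points become singleton regions.
3. *Land use*: a region centroid inside a "building" polygon gets a high
   indoor probability (default 0.9); inside outdoor land use (urban, park,
   forest) a low one (0.1); outside every polygon 0.5 — the no-evidence
   value.
4. *Bout labels*: each walking bout gets the time-weighted mean indoor
   probability over its interval (stay-region occupancy -> region
   probability; moving GPS -> outdoor probability; no evidence -> 0.5).
   Bouts whose evidence coverage is below 50% of their duration are labeled
   ``unknown`` and excluded from context-stratified outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from sklearn.cluster import HDBSCAN

from .bouts import WalkingBout
from .config import ContextConfig
from .geo import haversine_m, latlon_to_xy

__all__ = [
    "StayPoint",
    "StayRegion",
    "detect_stay_points",
    "cluster_stay_points",
    "assign_landuse",
    "label_bout_context",
    "infer_participant_context",
]


class GpsValidationError(ValueError):
    """Raised for unsorted fixes or invalid map geometry."""


@dataclass
class StayPoint:
    lat: float
    lon: float
    arrival_s: float
    departure_s: float

    @property
    def dwell_s(self) -> float:
        return self.departure_s - self.arrival_s


@dataclass
class StayRegion:
    region_id: int
    stay_points: list[StayPoint]
    lat: float
    lon: float
    landuse: str = "none"
    p_indoor: float = 0.5
    occupancy: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# stay-point detection


def _effective_dwell(times, dists_between, cfg: ContextConfig) -> float:
    """Dwell credited over consecutive member fixes.

    Short inter-fix intervals always count; long ones (> gap_max_s) count
    only when the flanking fixes are within gap_radius_m (the 10 m rule for
    suspended sampling).
    """
    dt = np.diff(times)
    ok = (dt <= cfg.gap_max_s) | (dists_between <= cfg.gap_radius_m)
    return float(dt[ok].sum())


def detect_stay_points(fixes: pd.DataFrame, cfg: ContextConfig) -> list[StayPoint]:
    """Sliding-window stay-point scan over one participant's fixes.

    Starting at fix i, the window extends while each next fix stays within
    ``stay_radius_m`` of the running window centroid (the window is a
    spatial cluster around its own centroid, which is robust to receiver
    jitter). If the credited dwell — consecutive-fix intervals, counting a
    long data gap only when its flanking fixes are within ``gap_radius_m``
    — exceeds ``stay_dwell_s``, the centroid is emitted as a stay point and
    the scan restarts at the first fix outside the window.
    """
    cfg.validate()
    n = len(fixes)
    if n == 0:
        return []
    t = fixes["timestamp_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise GpsValidationError("GPS fixes must be strictly increasing in time")
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    x, y = latlon_to_xy(lat, lon, float(lat[0]), float(lon[0]))

    stay_points: list[StayPoint] = []
    i = 0
    while i < n - 1:
        cx, cy = x[i], y[i]
        j = i + 1
        while j < n:
            if np.hypot(x[j] - cx, y[j] - cy) > cfg.stay_radius_m:
                break
            m = j - i + 1
            cx += (x[j] - cx) / m
            cy += (y[j] - cy) / m
            j += 1
        # window is [i, j) — every accepted fix within radius of the
        # running centroid at acceptance time
        if j - i >= 2:
            seg_d = haversine_m(lat[i:j - 1], lon[i:j - 1], lat[i + 1:j], lon[i + 1:j])
            dwell = _effective_dwell(t[i:j], seg_d, cfg)
        else:
            dwell = 0.0
        if dwell > cfg.stay_dwell_s:
            stay_points.append(
                StayPoint(
                    lat=float(lat[i:j].mean()),
                    lon=float(lon[i:j].mean()),
                    arrival_s=float(t[i]),
                    departure_s=float(t[j - 1]),
                )
            )
            i = j
        else:
            i += 1
    return stay_points


# ---------------------------------------------------------------------------
# clustering into regions


def cluster_stay_points(
    stay_points: list[StayPoint], cfg: ContextConfig
) -> list[StayRegion]:
    """Cluster stay-point centroids into stay regions with HDBSCAN.

    Clustering runs in a local equirectangular projection (meters) with
    ``cluster_epsilon_m`` as the cluster-selection epsilon. Noise points
    become singleton regions so every stay point belongs to exactly one
    region. Region occupancy is the union of member dwell intervals.
    """
    cfg.validate()
    if not stay_points:
        return []
    lat = np.array([p.lat for p in stay_points])
    lon = np.array([p.lon for p in stay_points])
    ref_lat, ref_lon = float(lat.mean()), float(lon.mean())
    x, y = latlon_to_xy(lat, lon, ref_lat, ref_lon)
    pts = np.column_stack([x, y])
    n = len(stay_points)
    if n < 2:
        labels = np.array([-1])
    else:
        labels = HDBSCAN(
            min_cluster_size=max(2, cfg.cluster_min_size),
            allow_single_cluster=True,
            copy=True,
        ).fit_predict(pts)
    # epsilon consolidation: the density hierarchy over-fragments tiny
    # samples, so points within cluster_epsilon_m (or sharing an HDBSCAN
    # label) are unioned — single linkage at epsilon, matching the
    # epsilon-equivalent cluster-selection convention
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    eps2 = cfg.cluster_epsilon_m**2
    for i in range(n):
        for j in range(i + 1, n):
            if d2[i, j] <= eps2 or (labels[i] == labels[j] and labels[i] != -1):
                union(i, j)
    groups_by_root: dict[int, list[int]] = {}
    for i in range(n):
        groups_by_root.setdefault(find(i), []).append(i)
    regions: list[StayRegion] = []
    next_id = 0
    for g in sorted(groups_by_root.values()):
        members = [stay_points[i] for i in g]
        occ = sorted((p.arrival_s, p.departure_s) for p in members)
        merged: list[tuple[float, float]] = []
        for a, b in occ:
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        regions.append(
            StayRegion(
                region_id=next_id,
                stay_points=members,
                lat=float(np.mean([p.lat for p in members])),
                lon=float(np.mean([p.lon for p in members])),
                occupancy=merged,
            )
        )
        next_id += 1
    return regions


# ---------------------------------------------------------------------------
# land use


def _containing_landuse(lat: float, lon: float, landuse_map: dict) -> str:
    """Land-use label at a point: buildings first, then the smallest
    containing outdoor polygon; boundary counts as inside."""
    pt = Point(lon, lat)
    best_label, best_area = "none", np.inf
    for feat in landuse_map.get("features", []):
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise GpsValidationError("invalid polygon in land-use map")
        if not geom.covers(pt):
            continue
        label = feat.get("properties", {}).get("landuse", "none")
        if label == "building":
            return "building"
        if geom.area < best_area:
            best_label, best_area = label, geom.area
    return best_label


def assign_landuse(
    region: StayRegion, landuse_map: dict, cfg: ContextConfig
) -> StayRegion:
    """Set the region's land-use label and indoor probability.

    building -> ``p_indoor_building``; park/forest/urban -> the low outdoor
    probability; no containing polygon -> 0.5 (no evidence).
    """
    cfg.validate()
    label = _containing_landuse(region.lat, region.lon, landuse_map)
    region.landuse = label
    if label == "building":
        region.p_indoor = cfg.p_indoor_building
    elif label in ("urban", "park", "forest"):
        region.p_indoor = cfg.p_indoor_outdoor_landuse
    else:
        region.p_indoor = 0.5
    return region


# ---------------------------------------------------------------------------
# bout labeling


def _interval_intersection(a0, a1, b0, b1) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def label_bout_context(
    bout: WalkingBout,
    fixes: pd.DataFrame,
    regions: list[StayRegion],
    cfg: ContextConfig,
) -> WalkingBout:
    """Label one bout indoor/outdoor/unknown by time-weighted evidence.

    The bout interval is partitioned into: time inside a stay-region
    occupancy (weight = that region's p_indoor), remaining time covered by
    moving GPS (weight = outdoor land-use probability), and time with no
    evidence (weight 0.5). If the evidence fraction is below
    ``min_bout_gps_coverage`` the bout is ``unknown`` regardless of the mean.
    """
    cfg.validate()
    t0, t1 = bout.start_s, bout.end_s
    total = max(t1 - t0, 1e-9)

    # stay-region occupancy within the bout (regions never overlap in time
    # for a single trace; clip to be safe)
    events: list[tuple[float, float, float]] = []  # (start, end, p)
    for region in regions:
        for a, b in region.occupancy:
            ov = _interval_intersection(t0, t1, a, b)
            if ov > 0:
                events.append((max(t0, a), min(t1, b), region.p_indoor))
    events.sort()
    stay_time = 0.0
    weighted = 0.0
    covered: list[tuple[float, float]] = []
    cursor = t0
    for a, b, p in events:
        a = max(a, cursor)
        if b <= a:
            continue
        stay_time += b - a
        weighted += (b - a) * p
        covered.append((a, b))
        cursor = b

    # moving-GPS coverage outside stay occupancy: each fix is evidence for
    # +/- half the nominal fix spacing around it
    times = fixes["timestamp_s"].to_numpy(dtype=float) if len(fixes) else np.array([])
    moving_time = 0.0
    if times.size:
        half = cfg.gps_cover_max_gap_s / 2.0
        inside = (times >= t0 - half) & (times <= t1 + half)
        ts = times[inside]
        # union of fix neighbourhoods, clipped to the bout
        fix_cover: list[tuple[float, float]] = []
        for ft in ts:
            a, b = max(t0, ft - half), min(t1, ft + half)
            if b <= a:
                continue
            if fix_cover and a <= fix_cover[-1][1]:
                fix_cover[-1] = (fix_cover[-1][0], max(fix_cover[-1][1], b))
            else:
                fix_cover.append((a, b))
        for a, b in fix_cover:
            seg = b - a
            for ca, cb in covered:
                seg -= _interval_intersection(a, b, ca, cb)
            if seg > 0:
                moving_time += seg
                weighted += seg * cfg.p_indoor_outdoor_landuse
    evidence = stay_time + moving_time
    weighted += (total - evidence) * 0.5
    p = weighted / total
    coverage = evidence / total
    bout.p_indoor = float(p)
    bout.evidence_coverage = float(min(1.0, coverage))
    if coverage < cfg.min_bout_gps_coverage or abs(p - cfg.indoor_threshold) < 1e-12:
        bout.context = "unknown"
    elif p > cfg.indoor_threshold:
        bout.context = "indoor"
    else:
        bout.context = "outdoor"
    return bout


def infer_participant_context(
    bouts: list[WalkingBout],
    fixes: pd.DataFrame,
    landuse_map: dict,
    cfg: ContextConfig,
) -> tuple[list[WalkingBout], list[StayRegion]]:
    """Full chain for one participant: stay points -> regions -> labels."""
    cfg.validate()
    fixes = fixes.sort_values("timestamp_s").reset_index(drop=True)
    stay_points = detect_stay_points(fixes, cfg)
    regions = cluster_stay_points(stay_points, cfg)
    for region in regions:
        assign_landuse(region, landuse_map, cfg)
    for bout in bouts:
        label_bout_context(bout, fixes, regions, cfg)
    return bouts, regions
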