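"""Synthetic gait cohort generator with known ground truth.

Emulates the data structure of a free-living wearable + smartphone study of
people with Parkinson's (PwP) and older-adult controls:

* stride-level gait events per participant-day, organised into walking bouts
  (within-bout inter-stride gaps < 3 s, between-bout gaps > 3 s), with stride
  speed drawn from a participant-specific K*-component Gaussian mixture
  truncated to a physiological range;
* GPS fixes — jittered around a planted home location during indoor bouts,
  along constant-velocity paths during outdoor bouts, and absent for a
  configurable fraction of bouts (emulating suspended sampling);
* a land-use polygon map with a "building" footprint around each planted stay
  location and urban/park surroundings;
* clinical covariates whose association with the planted mode count K* is a
  proportional-odds model with configurable per-SD log-odds.

Every quantity the downstream pipeline estimates (bout boundaries, context,
mode count, clinical association) is planted here and recorded in
:class:`GroundTruth`, so recovery can be asserted exactly.

One stride is one full gait cycle (two steps); downstream step counts are
2 x stride counts throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CohortSpec, ConfigurationError
from .geo import xy_to_latlon

__all__ = [
    "GroundTruth",
    "ParticipantTruth",
    "CohortData",
    "generate_cohort",
    "generate_clinical_covariates",
    "generate_participant_strides",
    "generate_gps_trace",
    "generate_landuse_map",
]

# population parameters for clinical covariates (PwP unless noted);
# centres/spreads chosen to bracket published cohort medians and IQRs
_CLINICAL_POP = {
    "age_pwp": (64.0, 9.0),
    "age_control": (70.0, 5.0),
    "p_male_pwp": 0.62,
    "p_male_control": 0.47,
    "height_m": (1.70, 0.08),
    "mass_kg": (75.0, 10.0),
    "ledd_mg": (550.0, 280.0),
    "updrs3": (22.0, 12.0),
    "updrs2": (10.0, 5.0),
    "fogq": (5.0, 4.0),
    "pd_duration_y": (4.5, 2.5),
    "llfdi": (133.0, 14.0),
    "n_meds": (3.0, 1.5),
}


@dataclass
class ParticipantTruth:
    participant_id: str
    cohort: str  # "pwp" | "control"
    k: int
    means: np.ndarray  # ascending, m/s
    sds: np.ndarray
    weights: np.ndarray  # sum to 1
    indoor_decrement: float  # m/s subtracted from indoor mode means
    home_lat: float
    home_lon: float

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "cohort": self.cohort,
            "k": int(self.k),
            "means": [float(m) for m in self.means],
            "sds": [float(s) for s in self.sds],
            "weights": [float(w) for w in self.weights],
            "indoor_decrement": float(self.indoor_decrement),
            "home_lat": float(self.home_lat),
            "home_lon": float(self.home_lon),
        }


@dataclass
class GroundTruth:
    """Planted truth for a synthetic cohort.

    ``bouts`` has one row per planted bout: participant_id, day, bout_index,
    start_s, end_s, n_strides, context ("indoor"|"outdoor"), has_gps.
    """

    participants: dict[str, ParticipantTruth] = field(default_factory=dict)
    bouts: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "participants": {p: t.to_dict() for p, t in self.participants.items()},
            "bouts": self.bouts.to_dict(orient="list"),
        }


@dataclass
class CohortData:
    strides: pd.DataFrame
    gps: pd.DataFrame
    landuse: dict  # GeoJSON-style FeatureCollection
    clinical: pd.DataFrame
    truth: GroundTruth


def _rng(spec: CohortSpec, *stream) -> np.random.Generator:
    """Independent, reproducible stream per (seed, purpose, participant)."""
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed) % (2**31), *stream]))


def _participant_ids(spec: CohortSpec) -> list[tuple[str, str]]:
    ids = [(f"PWP{i + 1:03d}", "pwp") for i in range(spec.n_pwp)]
    ids += [(f"CTL{i + 1:03d}", "control") for i in range(spec.n_control)]
    return ids


# ---------------------------------------------------------------------------
# clinical covariates and planted mode counts


def _ordinal_thresholds(n_levels: int) -> np.ndarray:
    """Cumulative-logit thresholds giving equal marginal category mass."""
    cum = np.arange(1, n_levels) / n_levels
    return np.log(cum / (1.0 - cum))


def _draw_k(rng, eta: float, k_min: int, k_max: int) -> int:
    levels = np.arange(k_min, k_max + 1)
    if len(levels) == 1:
        return int(levels[0])
    theta = _ordinal_thresholds(len(levels))
    cum = 1.0 / (1.0 + np.exp(-(theta - eta)))  # P(K <= level_j)
    u = rng.uniform()
    idx = int(np.searchsorted(cum, u))
    return int(levels[idx])


def generate_clinical_covariates(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Clinical table and per-participant mixture truth.

    For PwP the planted mode count K* follows a proportional-odds model whose
    linear predictor is ``clinical_mode_logodds`` per standard deviation of
    LEDD plus the same per SD of MDS-UPDRS III (higher medication load and
    motor severity push toward more modes). Controls draw K* from the same
    thresholds at zero linear predictor and carry no PD-specific fields.
    """
    spec.validate()
    truth = GroundTruth()
    rows = []
    for p_index, (pid, cohort) in enumerate(_participant_ids(spec)):
        rng = _rng(spec, 1, p_index)
        pop = _CLINICAL_POP
        if cohort == "pwp":
            age = rng.normal(*pop["age_pwp"])
            sex = "M" if rng.uniform() < pop["p_male_pwp"] else "F"
            z_ledd = rng.normal()
            z_updrs3 = rng.normal()
            ledd = max(50.0, pop["ledd_mg"][0] + pop["ledd_mg"][1] * z_ledd)
            updrs3 = max(0.0, pop["updrs3"][0] + pop["updrs3"][1] * z_updrs3)
            row = {
                "participant_id": pid,
                "cohort": cohort,
                "age_y": age,
                "sex": sex,
                "height_m": rng.normal(*pop["height_m"]),
                "mass_kg": rng.normal(*pop["mass_kg"]),
                "ledd_mg": ledd,
                "updrs3": updrs3,
                "updrs2": max(0.0, rng.normal(*pop["updrs2"])),
                "fogq": max(0.0, rng.normal(*pop["fogq"])),
                "pd_duration_y": max(0.25, rng.normal(*pop["pd_duration_y"])),
                "llfdi": rng.normal(*pop["llfdi"]),
                "n_meds": max(1, round(rng.normal(*pop["n_meds"]))),
            }
            eta = spec.clinical_mode_logodds * (z_ledd + z_updrs3)
        else:
            row = {
                "participant_id": pid,
                "cohort": cohort,
                "age_y": rng.normal(*pop["age_control"]),
                "sex": "M" if rng.uniform() < pop["p_male_control"] else "F",
                "height_m": rng.normal(*pop["height_m"]),
                "mass_kg": rng.normal(*pop["mass_kg"]),
                "ledd_mg": np.nan,
                "updrs3": np.nan,
                "updrs2": np.nan,
                "fogq": np.nan,
                "pd_duration_y": np.nan,
                "llfdi": np.nan,
                "n_meds": np.nan,
            }
            eta = 0.0
        rows.append(row)

        k = _draw_k(rng, eta, spec.mode_count_min, spec.mode_count_max)
        centre = rng.normal(spec.base_speed_mean, spec.base_speed_sd)
        means = centre + spec.mode_spacing * (np.arange(k) - (k - 1) / 2.0)
        raw_w = rng.dirichlet(np.full(k, spec.weight_concentration))
        weights = (raw_w + 0.15) / (1.0 + 0.15 * k)  # floor small modes
        decrement = (
            spec.indoor_speed_decrement_pwp
            if cohort == "pwp"
            else spec.indoor_speed_decrement_control
        )
        home_x = p_index * spec.participant_spacing_m + rng.uniform(-50, 50)
        home_y = rng.uniform(-50, 50)
        home_lat, home_lon = xy_to_latlon(
            home_x, home_y, spec.reference_lat, spec.reference_lon
        )
        truth.participants[pid] = ParticipantTruth(
            participant_id=pid,
            cohort=cohort,
            k=k,
            means=means,
            sds=np.full(k, spec.mode_sd),
            weights=weights,
            indoor_decrement=decrement,
            home_lat=float(home_lat),
            home_lon=float(home_lon),
        )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# strides


def _sample_truncated_mixture(rng, means, sds, weights, n, lo, hi):
    """n draws from the mixture, component-wise rejection into (lo, hi)."""
    comp = rng.choice(len(means), size=n, p=weights)
    x = rng.normal(means[comp], sds[comp])
    bad = (x <= lo) | (x >= hi)
    while bad.any():
        x[bad] = rng.normal(means[comp[bad]], sds[comp[bad]])
        bad = (x <= lo) | (x >= hi)
    return x


def generate_participant_strides(
    spec: CohortSpec, participant_id: str, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stride table and planted-bout table for one participant.

    Bouts are laid out sequentially within each day: bout count per day is
    negative-binomial (mean ``bouts_per_day_mean``), strides-per-bout is
    lognormal floored at 3, within-bout strides are contiguous (gap 0 s) and
    between-bout gaps are > 3 s by construction. Indoor bouts have every mode
    mean reduced by the cohort's indoor decrement before truncated sampling.
    """
    spec.validate()
    if participant_id not in truth.participants:
        raise ConfigurationError(f"unknown participant {participant_id!r}")
    pt = truth.participants[participant_id]
    p_index = list(truth.participants).index(participant_id)
    rng = _rng(spec, 2, p_index)
    lo, hi = spec.speed_truncation
    disp = spec.bouts_per_day_dispersion
    p_nb = disp / (disp + spec.bouts_per_day_mean)

    stride_rows = []
    bout_rows = []
    prev_indoor: bool | None = None
    for day in range(spec.n_days):
        day_start = day * 86400.0
        day_end = day_start + 86400.0
        n_bouts = max(1, int(rng.negative_binomial(disp, p_nb)))
        t = day_start + 6 * 3600.0
        for b in range(n_bouts):
            indoor = rng.uniform() < spec.indoor_fraction_bouts
            # between-bout gap strictly > 3 s by construction; a context
            # switch carries a longer dwell floor (leaving/arriving home)
            floor = (
                spec.transition_gap_floor_s
                if prev_indoor is not None and indoor != prev_indoor
                else 3.5
            )
            t += floor + rng.exponential(max(1.0, spec.inter_bout_gap_mean_s - 3.5))
            n_str = max(
                3,
                int(round(rng.lognormal(spec.strides_per_bout_logmean,
                                        spec.strides_per_bout_logsd))),
            )
            durations = rng.uniform(
                spec.stride_duration_min_s, spec.stride_duration_max_s, n_str
            )
            if t + durations.sum() > day_end - 600.0:
                break
            prev_indoor = indoor
            means = pt.means - (pt.indoor_decrement if indoor else 0.0)
            speeds = _sample_truncated_mixture(
                rng, means, pt.sds, pt.weights, n_str, lo, hi
            )
            starts = t + np.concatenate(([0.0], np.cumsum(durations[:-1])))
            stride_rows.append(
                pd.DataFrame(
                    {
                        "participant_id": participant_id,
                        "day": day,
                        "stride_start_s": starts,
                        "stride_duration_s": durations,
                        "stride_length_m": speeds * durations,
                    }
                )
            )
            end = float(starts[-1] + durations[-1])
            bout_rows.append(
                {
                    "participant_id": participant_id,
                    "day": day,
                    "bout_index": len(bout_rows),
                    "start_s": float(t),
                    "end_s": end,
                    "n_strides": n_str,
                    "context": "indoor" if indoor else "outdoor",
                    "has_gps": bool(rng.uniform() >= spec.gps_missing_bout_fraction),
                }
            )
            t = end
    strides = (
        pd.concat(stride_rows, ignore_index=True)
        if stride_rows
        else pd.DataFrame(
            columns=[
                "participant_id", "day", "stride_start_s",
                "stride_duration_s", "stride_length_m",
            ]
        )
    )
    return strides, pd.DataFrame(bout_rows)


# ---------------------------------------------------------------------------
# GPS


def generate_gps_trace(
    spec: CohortSpec, participant_id: str, truth: GroundTruth
) -> pd.DataFrame:
    """GPS fixes for one participant given their planted bout timeline.

    Indoor bouts emit fixes jittered around the home stay centroid, padded by
    ``gps_pad_s`` on each side (clipped so pads never overlap a neighbouring
    bout) so the stay-point dwell rule can trigger. Outdoor bouts emit fixes
    along a constant-velocity path starting a few hundred meters from home.
    Bouts flagged ``has_gps=False`` emit nothing.
    """
    pt = truth.participants[participant_id]
    p_index = list(truth.participants).index(participant_id)
    rng = _rng(spec, 3, p_index)
    bouts = truth.bouts[truth.bouts["participant_id"] == participant_id]
    bouts = bouts.sort_values("start_s").reset_index(drop=True)
    interval = spec.gps_fix_interval_s
    rows = []
    last_t = -np.inf
    for i, bout in bouts.iterrows():
        if not bout["has_gps"]:
            continue
        # pads are clipped against outdoor neighbours only: home fixes during
        # a neighbouring indoor bout are truthful evidence, but would wrongly
        # suggest "indoor" during an outdoor bout
        prev_end = (
            bouts.loc[i - 1, "end_s"]
            if i > 0 and bouts.loc[i - 1, "context"] == "outdoor"
            else -np.inf
        )
        next_start = (
            bouts.loc[i + 1, "start_s"]
            if i + 1 < len(bouts) and bouts.loc[i + 1, "context"] == "outdoor"
            else np.inf
        )
        if bout["context"] == "indoor":
            t0 = max(bout["start_s"] - spec.gps_pad_s, prev_end + 1.0)
            t1 = min(bout["end_s"] + spec.gps_pad_s, next_start - 1.0)
            times = np.arange(t0, t1 + 1e-9, interval)
            times = times[times > last_t + 0.5]
            if times.size == 0:
                continue
            x = rng.normal(0.0, spec.gps_jitter_sd_m, times.size)
            y = rng.normal(0.0, spec.gps_jitter_sd_m, times.size)
            lat, lon = xy_to_latlon(x, y, pt.home_lat, pt.home_lon)
        else:
            times = np.arange(bout["start_s"], bout["end_s"] + 1e-9, interval)
            times = times[times > last_t + 0.5]
            if times.size == 0:
                continue
            theta0 = rng.uniform(0, 2 * np.pi)
            r0 = rng.uniform(250.0, 500.0)
            heading = rng.uniform(0, 2 * np.pi)
            dt = times - times[0]
            x = r0 * np.cos(theta0) + spec.outdoor_speed_mps * dt * np.cos(heading)
            y = r0 * np.sin(theta0) + spec.outdoor_speed_mps * dt * np.sin(heading)
            lat, lon = xy_to_latlon(x, y, pt.home_lat, pt.home_lon)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": participant_id,
                    "timestamp_s": times,
                    "lat": lat,
                    "lon": lon,
                    "accuracy_m": rng.uniform(5.0, 15.0, times.size),
                }
            )
        )
        last_t = times[-1]
    if not rows:
        return pd.DataFrame(
            columns=["participant_id", "timestamp_s", "lat", "lon", "accuracy_m"]
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# land-use map


def _square(lat: float, lon: float, half_m: float) -> list:
    """GeoJSON ring (lon, lat) of a square of half-width half_m centred here."""
    corners_xy = [(-half_m, -half_m), (half_m, -half_m), (half_m, half_m),
                  (-half_m, half_m), (-half_m, -half_m)]
    ring = []
    for x, y in corners_xy:
        la, lo = xy_to_latlon(x, y, lat, lon)
        ring.append([float(lo), float(la)])
    return [ring]


def generate_landuse_map(truth: GroundTruth, building_half_m: float = 10.0) -> dict:
    """GeoJSON-style FeatureCollection over the planted stay locations.

    One 20 m "building" square per planted home centroid, one "park" polygon
    away from all homes, and an "urban" background rectangle covering the
    whole cohort extent. Downstream assignment checks buildings first and
    then the smallest containing outdoor polygon, so feature order is not
    load-bearing.
    """
    features = []
    lats = [t.home_lat for t in truth.participants.values()]
    lons = [t.home_lon for t in truth.participants.values()]
    for t in truth.participants.values():
        features.append(
            {
                "type": "Feature",
                "properties": {"landuse": "building",
                               "participant_id": t.participant_id},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": _square(t.home_lat, t.home_lon, building_half_m),
                },
            }
        )
    if lats:
        ref_lat, ref_lon = lats[0], lons[0]
        park_lat, park_lon = xy_to_latlon(0.0, 3000.0, ref_lat, ref_lon)
        features.append(
            {
                "type": "Feature",
                "properties": {"landuse": "park"},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": _square(float(park_lat), float(park_lon), 150.0),
                },
            }
        )
        # urban background: bounding box of all homes inflated by 10 km
        mid_lat = float(np.mean(lats))
        mid_lon = float(np.mean(lons))
        span = 10_000.0 + max(
            1.0,
            max(abs(x) for x in
                [0.0] + [(lo - mid_lon) * 111_000 for lo in lons]
                + [(la - mid_lat) * 111_000 for la in lats]),
        )
        features.append(
            {
                "type": "Feature",
                "properties": {"landuse": "urban"},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": _square(mid_lat, mid_lon, span),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


# ---------------------------------------------------------------------------
# driver


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Generate a full synthetic cohort (strides, GPS, map, clinical, truth)."""
    spec.validate()
    clinical, truth = generate_clinical_covariates(spec)
    stride_frames = []
    bout_frames = []
    for pid in truth.participants:
        s, b = generate_participant_strides(spec, pid, truth)
        stride_frames.append(s)
        bout_frames.append(b)
    truth.bouts = pd.concat(bout_frames, ignore_index=True)
    gps_frames = [generate_gps_trace(spec, pid, truth) for pid in truth.participants]
    gps = pd.concat(gps_frames, ignore_index=True)
    strides = pd.concat(stride_frames, ignore_index=True)
    landuse = generate_landuse_map(truth)
    return CohortData(
        strides=strides, gps=gps, landuse=landuse, clinical=clinical, truth=truth
    )
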