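"""Configuration objects for every pipeline stage.

Each stage owns a small dataclass whose defaults encode the consensus
real-world gait conventions this package implements: the 3-s bout break,
the 0.2–3.0 s / >0.15 m stride validity window, the 20 m / 2 min stay-point
rule with its 10 m data-gap extension, the 0.5 indoor-probability decision
threshold, the 1–9 mode search with BIC selection, and the fixed resampling
targets 2,500 / 5,000 / 7,500 / 10,000 strides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


class ConfigurationError(ValueError):
    """Raised when a stage configuration violates its invariants."""


# ---------------------------------------------------------------------------
# synthetic cohort


@dataclass
class CohortSpec:
    """Parameters of a synthetic gait cohort with known ground truth.

    The generator plants, per participant, a true number of walking-speed
    modes K* (a Gaussian mixture over stride speed), a home stay location,
    per-bout indoor/outdoor context, and clinical covariates whose link to
    K* is a proportional-odds model with ``clinical_mode_logodds`` per-SD
    log-odds on standardized LEDD and MDS-UPDRS III.
    """

    n_pwp: int = 10
    n_control: int = 10
    n_days: int = 7
    seed: int = 0
    indoor_fraction_bouts: float = 0.8
    indoor_speed_decrement_control: float = 0.08  # m/s
    indoor_speed_decrement_pwp: float = 0.0  # m/s
    mode_count_min: int = 2
    mode_count_max: int = 4
    clinical_mode_logodds: float = 0.3

    # bout/timing structure
    bouts_per_day_mean: float = 200.0
    bouts_per_day_dispersion: float = 10.0  # negative-binomial size parameter
    strides_per_bout_logmean: float = 2.2  # lognormal, rounded, floored at 3
    strides_per_bout_logsd: float = 0.75
    inter_bout_gap_mean_s: float = 120.0  # exponential, shifted past 3 s
    stride_duration_min_s: float = 0.9
    stride_duration_max_s: float = 1.4
    speed_truncation: tuple[float, float] = (0.05, 3.0)

    # speed mixture geometry
    base_speed_mean: float = 0.9  # m/s, cohort-level centre of mode grid
    base_speed_sd: float = 0.05  # between-participant SD of the grid centre
    mode_spacing: float = 0.25  # m/s between adjacent planted modes
    mode_sd: float = 0.05  # m/s within-mode SD (>= 4 sigma separation)
    weight_concentration: float = 5.0  # Dirichlet concentration for mode weights

    # GPS emission
    gps_fix_interval_s: float = 15.0
    gps_jitter_sd_m: float = 3.0
    gps_missing_bout_fraction: float = 0.15
    gps_pad_s: float = 90.0  # indoor dwell emitted before/after each bout
    outdoor_speed_mps: float = 1.4
    transition_gap_floor_s: float = 150.0  # min gap at indoor/outdoor switches
    reference_lat: float = 52.0
    reference_lon: float = 0.0
    participant_spacing_m: float = 5000.0

    def validate(self) -> "CohortSpec":
        if self.n_pwp < 1 or self.n_control < 1:
            raise ConfigurationError("n_pwp and n_control must be >= 1")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        for name in ("indoor_fraction_bouts", "gps_missing_bout_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 1 <= self.mode_count_min <= self.mode_count_max:
            raise ConfigurationError("need 1 <= mode_count_min <= mode_count_max")
        lo, hi = self.speed_truncation
        if not 0 < lo < hi:
            raise ConfigurationError("speed_truncation must satisfy 0 < lo < hi")
        if self.stride_duration_min_s <= 0 or (
            self.stride_duration_max_s < self.stride_duration_min_s
        ):
            raise ConfigurationError("invalid stride duration range")
        return self


# ---------------------------------------------------------------------------
# bout segmentation


@dataclass(frozen=True)
class DurationClass:
    """Labeled half-open duration interval (lo, hi]; hi may be inf."""

    label: str
    lo_s: float
    hi_s: float = float("inf")

    def contains(self, duration_s: float) -> bool:
        return self.lo_s < duration_s <= self.hi_s


DEFAULT_DURATION_CLASSES = (
    DurationClass(">10 s", 10.0),
    DurationClass("10–30 s", 10.0, 30.0),
    DurationClass(">30 s", 30.0),
    DurationClass(">60 s", 60.0),
)

#: duration classes over which gait (not activity) outcomes are estimated
GAIT_CLASS_LABELS = (">10 s", "10–30 s", ">30 s")


@dataclass
class BoutConfig:
    break_threshold_s: float = 3.0
    min_stride_duration_s: float = 0.2
    max_stride_duration_s: float = 3.0
    min_stride_length_m: float = 0.15
    min_strides_per_bout: int = 3
    duration_classes: tuple[DurationClass, ...] = DEFAULT_DURATION_CLASSES

    def validate(self) -> "BoutConfig":
        if not 0 < self.min_stride_duration_s < self.max_stride_duration_s:
            raise ConfigurationError("need 0 < min < max stride duration")
        if not self.duration_classes:
            raise ConfigurationError("duration_classes must be non-empty")
        if self.min_strides_per_bout < 1:
            raise ConfigurationError("min_strides_per_bout must be >= 1")
        return self


# ---------------------------------------------------------------------------
# context inference


@dataclass
class ContextConfig:
    stay_radius_m: float = 20.0
    stay_dwell_s: float = 120.0
    gap_radius_m: float = 10.0
    gap_max_s: float = 60.0  # fix gaps longer than this need the 10 m rule
    indoor_threshold: float = 0.5
    p_indoor_building: float = 0.9
    p_indoor_outdoor_landuse: float = 0.1
    min_bout_gps_coverage: float = 0.5
    cluster_min_size: int = 2
    cluster_epsilon_m: float = 25.0
    gps_cover_max_gap_s: float = 30.0  # fix spacing still counted as coverage

    def validate(self) -> "ContextConfig":
        if self.stay_radius_m <= 0 or self.gap_radius_m <= 0:
            raise ConfigurationError("radii must be > 0")
        if self.stay_dwell_s <= 0:
            raise ConfigurationError("stay_dwell_s must be > 0")
        if not 0.0 < self.indoor_threshold < 1.0:
            raise ConfigurationError("indoor_threshold must be in (0, 1)")
        for name in ("p_indoor_building", "p_indoor_outdoor_landuse",
                     "min_bout_gps_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        return self


# ---------------------------------------------------------------------------
# speed modes


@dataclass
class ModesConfig:
    k_min: int = 1
    k_max: int = 9
    variance_families: tuple[str, ...] = ("equal", "varying")
    n_init: int = 10
    burn_in_iter: int = 25  # iterations per restart before picking the best
    max_iter: int = 500
    rel_tol: float = 1e-8
    variance_floor_factor: float = 1e-4  # times the sample variance
    resample_targets: tuple[int, ...] = (2500, 5000, 7500, 10000)
    seed: int = 0

    def validate(self) -> "ModesConfig":
        if not 1 <= self.k_min <= self.k_max:
            raise ConfigurationError("need 1 <= k_min <= k_max")
        if self.rel_tol <= 0:
            raise ConfigurationError("rel_tol must be > 0")
        if any(f not in ("equal", "varying") for f in self.variance_families):
            raise ConfigurationError("variance families must be equal|varying")
        if self.n_init < 1 or self.max_iter < 1:
            raise ConfigurationError("n_init and max_iter must be >= 1")
        return self


# ---------------------------------------------------------------------------
# statistics


@dataclass
class StatsConfig:
    alpha_report: float = 0.05
    elimination_threshold: float = 0.05
    standardize: bool = True
    fisher_mc_draws: int = 100_000
    seed: int = 0

    def validate(self) -> "StatsConfig":
        for name in ("alpha_report", "elimination_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if self.fisher_mc_draws < 1:
            raise ConfigurationError("fisher_mc_draws must be >= 1")
        return self


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """End-to-end run: either simulate a cohort or read input files."""

    out_dir: str = "gaitcontext_out"
    seed: int = 0
    log_level: str = "INFO"

    cohort: Optional[CohortSpec] = None  # simulation mode
    strides_csv: Optional[str] = None  # file mode
    gps_csv: Optional[str] = None
    map_geojson: Optional[str] = None
    clinical_csv: Optional[str] = None

    bouts: BoutConfig = field(default_factory=BoutConfig)
    context: ContextConfig = field(default_factory=ContextConfig)
    modes: ModesConfig = field(default_factory=ModesConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    min_days: int = 3
    run_modes: bool = True
    run_stats: bool = True

    def validate(self) -> "RunConfig":
        sim = self.cohort is not None
        files = self.strides_csv is not None
        if sim == files:
            raise ConfigurationError(
                "provide exactly one of a simulation spec (cohort) or input "
                "file paths (strides_csv, ...)"
            )
        if files and self.gps_csv is None:
            raise ConfigurationError("file mode requires gps_csv")
        if files and self.map_geojson is None:
            raise ConfigurationError("file mode requires map_geojson")
        if sim:
            self.cohort.validate()
        self.bouts.validate()
        self.context.validate()
        self.modes.validate()
        self.stats.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)
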