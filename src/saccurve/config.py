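"""Configuration objects and their YAML round-trip.

Every default that the experiment's write-up pins down (geometry, detection
window and threshold, inclusion radii, latency caps, timing windows,
bootstrap count) lives here, so a sensitivity analysis is a config edit.
Values the write-up does not report (trial-level latency spread, gaze noise,
landing scatter) are assumptions documented in docs/methods.md.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import yaml


@dataclass
class ApparatusConfig:
    """Screen geometry and recording parameters."""

    viewing_distance_cm: float = 76.5
    target_eccentricity_deg: float = 15.0
    distractor_offset_deg: float = 7.5     # corners at (+-7.5, +-7.5)
    sampling_rate_hz: float = 1000.0
    fixation_radius_deg: float = 3.5

    def __post_init__(self) -> None:
        for name in ("viewing_distance_cm", "target_eccentricity_deg",
                     "distractor_offset_deg", "fixation_radius_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sampling_rate_hz < 250:
            raise ValueError("sampling_rate_hz must be >= 250")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def distractor_positions(self) -> Tuple[Tuple[float, float], ...]:
        """The four corners of a square centered on the screen center."""
        d = self.distractor_offset_deg
        return ((d, d), (-d, d), (-d, -d), (d, -d))


@dataclass
class DetectionParams:
    """Velocity-threshold saccade detection parameters.

    Threshold = median(smoothed speed) + k * SD, where SD is by default the
    robust (MAD-based) spread of the smoothed speed; the plain standard
    deviation is available with ``robust=False``.  ``floor_deg_s`` bounds the
    threshold from below so that noiseless recordings (zero spread) do not
    trigger on arbitrarily slow drift.
    """

    window: int = 20               # samples in the moving average
    k: float = 3.0                 # threshold multiplier, SD units
    min_duration_ms: float = 20.0  # minimal above-threshold run
    robust: bool = True
    floor_deg_s: float = 20.0
    merge_gap_ms: float = 10.0     # sub-threshold gaps shorter than this merge

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.k <= 0 or self.min_duration_ms <= 0:
            raise ValueError("k and min_duration_ms must be positive")


@dataclass
class SelectionCriteria:
    """Trial inclusion filters and distractor-timing windows."""

    fixation_radius_deg: float = 3.5
    landing_radius_deg: float = 3.5
    max_latency_first_ms: float = 400.0
    max_latency_second_ms: float = 700.0
    pre_window_ms: float = 150.0    # distractor offset within this before 1st onset
    inter_gap_ms: float = 100.0     # distractor offset at least this before 2nd onset
    fixation_hold_ms: float = 200.0

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if val <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class AnalysisParams:
    """Trajectory normalization and inference parameters."""

    n_bins: int = 50           # monotonic-resampling bins along the saccade axis
    margin: float = 0.05       # chord fraction excluded at each end of the median
    n_boot: int = 10000
    min_baseline_trials: int = 5
    seed: int = 0


#: Exp. 1 mean saccade latencies (ms) by distractor modality; trial-level SDs
#: are generator assumptions (see docs/methods.md).
DEFAULT_LATENCY_MEANS: Dict[str, Tuple[float, float]] = {
    "visual": (172.02, 497.28),
    "auditory": (160.50, 462.92),
    "audiovisual": (163.88, 473.86),
    "none": (179.44, 480.99),
}

#: Exp. 1 condition-wise normalized curvature angles (deg, negative = away
#: from the distractor) used as the default injected effects.
DEFAULT_EFFECT_MAP: Dict[Tuple[str, str], float] = {
    ("visual", "inter_saccadic"): -2.65,
    ("auditory", "inter_saccadic"): -0.52,
    ("audiovisual", "inter_saccadic"): -3.34,
    ("visual", "pre_saccadic_inter"): -0.76,
    ("auditory", "pre_saccadic_inter"): -0.58,
    ("audiovisual", "pre_saccadic_inter"): -1.05,
    ("visual", "pre_saccadic_intra"): -1.38,
    ("auditory", "pre_saccadic_intra"): 0.24,
    ("audiovisual", "pre_saccadic_intra"): -1.15,
}


@dataclass
class LatencyModel:
    """Truncated-Gaussian latency sampler parameters (per modality)."""

    means: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LATENCY_MEANS))
    sd_first_ms: float = 30.0
    sd_second_ms: float = 60.0
    min_first_ms: float = 80.0
    min_second_gap_ms: float = 60.0   # 2nd onset at least this after 1st offset
    cap_first_ms: float = 400.0       # online abort caps
    cap_second_ms: float = 700.0


@dataclass
class SaccadeKinematics:
    """Duration as an affine function of amplitude (main-sequence-like)."""

    slope_ms_per_deg: float = 2.2
    intercept_ms: float = 21.0

    def duration_ms(self, amplitude_deg: float) -> float:
        return self.intercept_ms + self.slope_ms_per_deg * amplitude_deg


@dataclass
class ArtifactRates:
    blink: float = 0.0
    fixation_break: float = 0.0
    landing_error: float = 0.0


@dataclass
class SimulationConfig:
    """Design of a synthetic double-step saccade experiment."""

    n_participants: int = 8
    trials_per_cell: int = 150
    distractor_onset_range_ms: Tuple[float, float] = (-100.0, 300.0)
    distractor_duration_ms: float = 50.0
    modalities: Tuple[str, ...] = ("visual", "auditory", "audiovisual")
    effect_map: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MAP))
    latency: LatencyModel = field(default_factory=LatencyModel)
    kinematics: SaccadeKinematics = field(default_factory=SaccadeKinematics)
    idiosyncrasy_sd_deg: float = 1.0
    trial_curvature_sd_deg: float = 1.0
    noise_sd_deg: float = 0.0
    landing_sd_deg: float = 0.5
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.trials_per_cell <= 0:
            raise ValueError("participant and trial counts must be positive")
        lo, hi = self.distractor_onset_range_ms
        if not lo < hi:
            raise ValueError("distractor_onset_range_ms must be increasing")
        if self.distractor_duration_ms <= 0:
            raise ValueError("distractor_duration_ms must be positive")


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs."""

    apparatus: ApparatusConfig = field(default_factory=ApparatusConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: Optional[str] = None


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        # tuple keys (effect map) become 'modality|interval' strings
        return {("|".join(k) if isinstance(k, tuple) else k): _to_plain(v)
                for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def config_to_dict(cfg: PipelineConfig) -> dict:
    return _to_plain(cfg)


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def _tuplify(x):
    return tuple(x) if isinstance(x, list) else x


def config_from_dict(d: dict) -> PipelineConfig:
    sim = d.get("simulation", {})
    effect_map = {tuple(k.split("|")): v
                  for k, v in sim.get("effect_map", _to_plain(DEFAULT_EFFECT_MAP)).items()}
    latency = sim.get("latency", {})
    lat = LatencyModel(
        means={k: tuple(v) for k, v in latency.get(
            "means", _to_plain(DEFAULT_LATENCY_MEANS)).items()},
        **{k: latency[k] for k in latency if k != "means"})
    kin = SaccadeKinematics(**sim.get("kinematics", {}))
    arts = ArtifactRates(**sim.get("artifact_rates", {}))
    sim_kwargs = {k: _tuplify(v) for k, v in sim.items()
                  if k not in ("effect_map", "latency", "kinematics", "artifact_rates")}
    simulation = SimulationConfig(effect_map=effect_map, latency=lat,
                                  kinematics=kin, artifact_rates=arts, **sim_kwargs)
    return PipelineConfig(
        apparatus=ApparatusConfig(**d.get("apparatus", {})),
        detection=DetectionParams(**d.get("detection", {})),
        selection=SelectionCriteria(**d.get("selection", {})),
        analysis=AnalysisParams(**d.get("analysis", {})),
        simulation=simulation,
        out_dir=d.get("out_dir"),
    )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})
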