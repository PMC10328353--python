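"""Configuration objects for simulation, classification and the pipeline.

All configuration is plain dataclasses with eager validation: an invalid
field raises :class:`ConfigurationError` naming the offending field, so a
bad YAML file fails at load time rather than mid-pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

__all__ = [
    "ConfigurationError",
    "SimConfig",
    "ThresholdConfig",
    "PipelineConfig",
]


class ConfigurationError(ValueError):
    """An invalid configuration value; the message names the field."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{name}: {msg}")


def _check_prob(value: float, name: str) -> None:
    _check(0.0 <= value <= 1.0, name, f"probability must be in [0, 1], got {value}")


def _check_interval(lo_hi, name: str) -> None:
    _check(
        len(lo_hi) == 2 and lo_hi[0] <= lo_hi[1],
        name,
        f"must be a (low, high) interval with low <= high, got {lo_hi}",
    )


@dataclass
class SimConfig:
    """Parameters of the synthetic study generator.

    Defaults emulate the study design: a cohort of young warmblood riding
    horses trotted in hand on a straight line over three visits, with an
    inertial-sensor-style head/pelvis vertical displacement record per
    trial and a rider questionnaire per visit.

    Amplitudes and asymmetries are in millimetres of vertical displacement;
    durations in seconds; ``sample_rate`` in Hz.
    """

    n_horses: int = 65
    n_visits: int = 3
    strides_per_trial: int = 40
    stride_duration_mean: float = 0.72  # typical straight-line trot
    stride_duration_sd: float = 0.04
    sample_rate: float = 200.0
    head_amplitude: float = 45.0  # half-range of head vertical oscillation
    pelvis_amplitude: float = 30.0
    extremum_noise_sd: float = 2.0  # per-extremum Gaussian noise, mm
    outlier_prob: float = 0.02  # per-stride chance of a displaced head extremum
    outlier_magnitude: float = 60.0
    asym_range_head: tuple = (-15.0, 15.0)  # latent HDmin/HDmax range, mm
    asym_range_pelvis: tuple = (-8.0, 8.0)
    laterality_prob_range: tuple = (0.2, 0.8)  # per-horse P(right protracted)
    questionnaire_link_slope: float = 0.0  # logit units per mm; 0 = null linkage
    missingness_prob: float = 0.15  # "no perception/did not answer" rate
    surface_probs: dict = field(default_factory=lambda: {"soft": 0.5, "hard": 0.5})
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_horses >= 1, "n_horses", "must be >= 1")
        _check(self.n_visits >= 1, "n_visits", "must be >= 1")
        _check(self.strides_per_trial >= 2, "strides_per_trial",
               "at least two strides needed for an SD")
        _check(self.stride_duration_mean > 0, "stride_duration_mean", "must be > 0")
        _check(self.stride_duration_sd >= 0, "stride_duration_sd", "must be >= 0")
        _check(self.sample_rate > 0, "sample_rate", "must be > 0")
        _check(self.head_amplitude > 0, "head_amplitude", "must be > 0")
        _check(self.pelvis_amplitude > 0, "pelvis_amplitude", "must be > 0")
        _check(self.extremum_noise_sd >= 0, "extremum_noise_sd", "must be >= 0")
        _check_prob(self.outlier_prob, "outlier_prob")
        _check(self.outlier_magnitude >= 0, "outlier_magnitude", "must be >= 0")
        _check_interval(self.asym_range_head, "asym_range_head")
        _check_interval(self.asym_range_pelvis, "asym_range_pelvis")
        _check_interval(self.laterality_prob_range, "laterality_prob_range")
        _check_prob(self.laterality_prob_range[0], "laterality_prob_range")
        _check_prob(self.laterality_prob_range[1], "laterality_prob_range")
        _check_prob(self.missingness_prob, "missingness_prob")
        _check(
            set(self.surface_probs) == {"soft", "hard"},
            "surface_probs", f"keys must be {{soft, hard}}, got {set(self.surface_probs)}",
        )
        total = sum(self.surface_probs.values())
        _check(abs(total - 1.0) < 1e-9, "surface_probs", f"must sum to 1, got {total}")
        for k, v in self.surface_probs.items():
            _check_prob(v, f"surface_probs[{k}]")
        _check(int(self.seed) == self.seed, "seed", "must be an integer")


@dataclass
class ThresholdConfig:
    """Clinical classification thresholds and filtering constants.

    ``head_threshold`` (6 mm) and ``pelvis_threshold`` (3 mm) are the
    manufacturer-recommended limits above which a trial-mean parameter is
    considered asymmetric, provided its stride-to-stride SD does not exceed
    ``sd_ratio_max`` (100%) of the mean.  ``outlier_sd_factor`` is the
    iterative outlier-removal cut (three-or-more SDs).  ``head_tas_weight``
    down-weights head terms in the total asymmetry score so that both body
    ends contribute on the pelvic threshold scale.
    """

    head_threshold: float = 6.0
    pelvis_threshold: float = 3.0
    sd_ratio_max: float = 1.0
    outlier_sd_factor: float = 3.0
    head_tas_weight: float = 0.5

    def __post_init__(self) -> None:
        for name in ("head_threshold", "pelvis_threshold", "sd_ratio_max",
                     "outlier_sd_factor", "head_tas_weight"):
            _check(getattr(self, name) > 0, name, "must be > 0")

    def threshold_for(self, parameter: str) -> float:
        if parameter.startswith("hd"):
            return self.head_threshold
        if parameter.startswith("pd"):
            return self.pelvis_threshold
        raise ConfigurationError(f"parameter: unknown asymmetry parameter {parameter!r}")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (simulate -> extract -> report)."""

    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    alpha: float = 0.05
    target_n: int = 15  # valid preference-test observations aimed for per horse
    pt_attempts: int = 18
    pt_valid_prob: float = 0.9
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        _check(0.0 < self.alpha < 1.0, "alpha", "must be in (0, 1)")
        _check(self.target_n >= 1, "target_n", "must be >= 1")
        _check(self.pt_attempts >= 1, "pt_attempts", "must be >= 1")
        _check_prob(self.pt_valid_prob, "pt_valid_prob")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config: top level must be a mapping")
        sim = SimConfig(**{**raw.get("sim", {})})
        thr = ThresholdConfig(**{**raw.get("thresholds", {})})
        rest = {k: v for k, v in raw.items() if k not in ("sim", "thresholds")}
        try:
            return cls(sim=sim, thresholds=thr, **rest)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
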