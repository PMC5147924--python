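"""Configuration objects for the simulation and analysis pipeline.

All tunable quantities live in small frozen dataclasses so that a run is
fully described by one :class:`RunConfig`, which can be round-tripped
through YAML.  Units are stated per field; accelerations are handled in
g internally and reported in mg at epoch level, energy expenditure is in
J·min⁻¹·kg⁻¹ throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

SECONDS_PER_DAY = 86400


@dataclass(frozen=True)
class TruthCoefficients:
    """Quadratic wrist-metric → PAEE mapping used as simulation ground truth.

    PAEE = alpha + beta1 * m + beta2 * m**2, with m the wrist metric in mg.
    With ``beta2 < 0`` the curve peaks at ``-beta1 / (2 * beta2)`` mg; the
    defaults place that peak at 1369 mg (HPFVM) and 983 mg (ENMO), and are
    anchored so that a metric value of 46 mg (HPFVM) / 31 mg (ENMO) maps to
    36.4 J·min⁻¹·kg⁻¹.
    """

    alpha: float = 0.0
    beta1_hpfvm: float = 0.8048264
    beta2_hpfvm: float = -2.939469e-04
    beta1_enmo: float = 1.1930054
    beta2_enmo: float = -6.068186e-04

    def paee_from_hpfvm(self, m):
        return self.alpha + self.beta1_hpfvm * m + self.beta2_hpfvm * m**2

    def paee_from_enmo(self, m):
        return self.alpha + self.beta1_enmo * m + self.beta2_enmo * m**2

    @property
    def hpfvm_vertex(self) -> float:
        return -self.beta1_hpfvm / (2.0 * self.beta2_hpfvm)

    @property
    def enmo_vertex(self) -> float:
        return -self.beta1_enmo / (2.0 * self.beta2_enmo)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic dual-sensor cohort generator.

    The defaults emulate a free-living UK adult cohort wearing a wrist
    accelerometer and a combined heart-rate + trunk-acceleration sensor
    for six days, with epoch-level marginals matching the published
    summary statistics of that population (mean PAEE ≈ 36 J·min⁻¹·kg⁻¹,
    wrist ENMO ≈ 32 mg, HPFVM ≈ 48 mg, trunk acceleration ≈ 0.12 m·s⁻²).
    """

    n_participants: int = 1695
    days: int = 6
    epoch_length: int = 300  # seconds; must divide 86400
    seed: int = 0

    # cohort composition (means/SDs by sex: male, female)
    male_fraction: float = 0.48
    age_mean: tuple[float, float] = (49.68, 50.07)
    age_sd: tuple[float, float] = (7.29, 7.00)
    height_mean: tuple[float, float] = (1.78, 1.63)
    height_sd: tuple[float, float] = (0.06, 0.06)
    bmi_mean: tuple[float, float] = (26.98, 26.05)
    bmi_residual_sd: float = 4.3
    bmi_paee_slope: float = -0.08  # kg·m⁻² per J·min⁻¹·kg⁻¹ of person-mean PAEE

    # latent activity-intensity process (J·min⁻¹·kg⁻¹)
    intensity_mean: tuple[float, float] = (36.7, 36.7)  # male, female
    person_sd_log: float = 0.27  # between-person lognormal sigma of intensity
    within_sd_log: float = 0.8  # within-person lognormal sigma per epoch
    ar1: float = 0.0  # optional AR(1) of within-person log innovations
    sleep_start_hour: float = 23.0
    sleep_end_hour: float = 7.0
    sleep_weight: float = 0.04  # sleep-block intensity multiplier
    diurnal_amplitude: float = 0.35  # midday bump on waking intensity

    # wrist→PAEE ground-truth mapping
    truth: TruthCoefficients = field(default_factory=TruthCoefficients)

    # criterion (combined-sensing) error model, multiplicative so that
    # criterion PAEE stays non-negative and E[criterion | wrist] is exactly
    # the truth curve: criterion = intensity * u_person * v_epoch with
    # lognormal mean-one factors.
    criterion_noise_sd_log: float = 0.42  # epoch-level lognormal sigma
    person_offset_sd_log: float = 0.287  # person calibration factor sigma
    sex_calibration_factor: tuple[float, float] = (1.05, 0.9538)  # male, female

    # wrist metric observation error (defaults are exact observation)
    wrist_noise_sd_mg: float = 0.0
    wrist_person_offset_sd_mg: float = 0.0

    # trunk acceleration: trunk = (t0 + t1*hpfvm) * u_person * v_epoch, m·s⁻²
    trunk_intercept: float = 0.026  # m·s⁻²
    trunk_slope: float = 0.002  # m·s⁻² per mg HPFVM
    trunk_person_sd_log: float = 0.2
    trunk_noise_sd_log: float = 0.4

    # non-wear episode injection (per sensor)
    nonwear_rate: float = 0.15  # episodes per day
    nonwear_duration_hours: tuple[float, float] = (1.5, 4.0)  # uniform range

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be at least 2")
        if self.days < 1:
            raise ValueError("days must be at least 1")
        if self.epoch_length <= 0 or SECONDS_PER_DAY % self.epoch_length:
            raise ValueError("epoch_length must be a positive divisor of 86400")
        for name in ("person_sd_log", "within_sd_log", "criterion_noise_sd_log",
                     "person_offset_sd_log", "wrist_noise_sd_mg",
                     "wrist_person_offset_sd_mg", "trunk_person_sd_log",
                     "trunk_noise_sd_log", "nonwear_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError("ar1 must lie in (-1, 1)")
        if not 0.0 < self.male_fraction < 1.0:
            raise ValueError("male_fraction must lie in (0, 1)")

    @property
    def epochs_per_day(self) -> int:
        return SECONDS_PER_DAY // self.epoch_length

    @property
    def epochs_per_participant(self) -> int:
        return self.days * self.epochs_per_day


@dataclass(frozen=True)
class FilterConfig:
    """Butterworth filter settings for raw wrist signal processing."""

    lowpass_cutoff: float = 20.0  # Hz, sensor-noise removal
    highpass_cutoff: float = 0.2  # Hz, gravity removal for HPFVM
    filter_order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.highpass_cutoff < self.lowpass_cutoff:
            raise ValueError("need 0 < highpass_cutoff < lowpass_cutoff")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


@dataclass(frozen=True)
class NonwearConfig:
    """Non-wear detection rules for the two sensors.

    Wrist: per-axis standard deviation below ``wrist_sd_threshold`` in every
    ``sd_window`` block of a run lasting at least ``wrist_min_duration``.
    Combined sensor: zero trunk movement for strictly longer than
    ``combined_zero_movement_min`` with invalid heart rate throughout.
    """

    wrist_sd_threshold: float = 13.0  # mg
    wrist_min_duration: float = 3600.0  # seconds ("longer than 1 hour")
    combined_zero_movement_min: float = 5400.0  # seconds (">90 min")
    hr_invalid_required: bool = True
    sd_window: float = 60.0  # seconds

    def __post_init__(self) -> None:
        if self.wrist_sd_threshold <= 0 or self.sd_window <= 0:
            raise ValueError("thresholds and windows must be positive")
        for dur in (self.wrist_min_duration, self.combined_zero_movement_min):
            if dur <= 0 or (dur / self.sd_window) % 1:
                raise ValueError("durations must be positive multiples of sd_window")


@dataclass(frozen=True)
class SplitConfig:
    """Person-level train/test split settings."""

    train_fraction: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction <= 1.0:
            raise ValueError("train_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration of a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    nonwear: NonwearConfig = field(default_factory=NonwearConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    output_dir: str = "results/run"
    log_level: str = "INFO"


def _to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _build(cls, data: dict[str, Any]):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.type in (
                "GeneratorConfig", "FilterConfig", "NonwearConfig",
                "SplitConfig", "TruthCoefficients"):
            sub = {"GeneratorConfig": GeneratorConfig, "FilterConfig": FilterConfig,
                   "NonwearConfig": NonwearConfig, "SplitConfig": SplitConfig,
                   "TruthCoefficients": TruthCoefficients}[f.type if isinstance(f.type, str) else f.type.__name__]
            kwargs[f.name] = _build(sub, val)
        elif isinstance(val, list):
            kwargs[f.name] = tuple(val)
        else:
            kwargs[f.name] = val
    return cls(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a RunConfig to a YAML file."""
    Path(path).write_text(yaml.safe_dump(_to_dict(config), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML file; missing keys keep their defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build(RunConfig, data)
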