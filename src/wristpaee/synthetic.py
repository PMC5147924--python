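"""Synthetic dual-sensor cohort generator.

No public accession exists for free-living cohorts wearing a wrist
accelerometer and a combined heart-rate + trunk-acceleration sensor
simultaneously, so this module simulates one with known ground truth:

* a cohort of adults with realistic sex, age, height, weight and BMI
  marginals, where BMI is inversely related to habitual PAEE;
* a latent epoch-level activity-intensity process per participant
  (diurnal profile with a nightly sleep block, lognormal within-person
  variation, lognormal between-person heterogeneity);
* wrist ENMO/HPFVM obtained by inverting a known quadratic
  wrist-metric → PAEE curve, so the curvilinear relationship the models
  estimate is present by construction and recoverable;
* a criterion PAEE signal equal to latent intensity times mean-one
  lognormal person-level (calibration) and epoch-level (measurement)
  error factors, keeping the criterion non-negative and its conditional
  mean on the wrist metric exactly on the truth curve;
* injected non-wear episodes per sensor with exact ground truth.

Raw 60 Hz triaxial bouts (stationary / sinusoidal / mixed) are generated
separately for testing the signal-processing and non-wear surfaces; raw
waveforms are never simulated for whole cohorts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import GeneratorConfig
from .signals import RawTriaxialSignal

BASE_DATE = pd.Timestamp("2016-01-04")  # arbitrary Monday anchoring the grid

PUBLIC_COHORT_COLUMNS = ["participant_id", "sex", "age", "height_m", "weight_kg", "bmi"]

EPOCH_COLUMNS = ["participant_id", "epoch_start", "enmo_mg", "hpfvm_mg",
                 "trunk_acc_ms2", "paee_jminkg", "hr_valid",
                 "wear_wrist", "wear_combined"]

# canonical device orientations for mixed bouts (unit vectors)
_ORIENTATIONS = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
    [1, 1, 1], [-1, 1, -1], [1, -1, 0],
], dtype=float)
_ORIENTATIONS /= np.linalg.norm(_ORIENTATIONS, axis=1, keepdims=True)


def _rng(config: GeneratorConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def invert_quadratic(paee, beta1: float, beta2: float, alpha: float = 0.0):
    """Solve alpha + beta1*m + beta2*m**2 = paee for the branch below the
    vertex (beta2 < 0). Input must not exceed the curve's maximum."""
    paee = np.asarray(paee, dtype=float)
    disc = beta1 * beta1 + 4.0 * beta2 * (paee - alpha)
    return (-beta1 + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * beta2)


def _intensity_cap(config: GeneratorConfig) -> float:
    t = config.truth
    peak_h = t.paee_from_hpfvm(t.hpfvm_vertex)
    peak_e = t.paee_from_enmo(t.enmo_vertex)
    return 0.999 * min(peak_h, peak_e)


def expected_paee(config: GeneratorConfig) -> float:
    """Population mean criterion PAEE implied by the configuration."""
    m = config.male_fraction
    return (m * config.intensity_mean[0] * config.sex_calibration_factor[0]
            + (1 - m) * config.intensity_mean[1] * config.sex_calibration_factor[1])


def _cohort_with_latents(config: GeneratorConfig) -> pd.DataFrame:
    """Cohort covariates plus the hidden person-level simulation factors."""
    n = config.n_participants
    rng = _rng(config, 0)
    n_male = int(round(config.male_fraction * n))
    sex_idx = rng.permutation(np.r_[np.zeros(n_male, int), np.ones(n - n_male, int)])

    def by_sex(pair):
        return np.asarray(pair)[sex_idx]

    age = np.clip(rng.normal(by_sex(config.age_mean), by_sex(config.age_sd)), 18.0, 90.0)
    height = np.clip(rng.normal(by_sex(config.height_mean), by_sex(config.height_sd)),
                     1.25, 2.15)

    s_b = config.person_sd_log
    mu = by_sex(config.intensity_mean) * np.exp(rng.normal(-s_b**2 / 2, s_b, n))
    s_u = config.person_offset_sd_log
    calib = by_sex(config.sex_calibration_factor) * np.exp(
        rng.normal(-s_u**2 / 2, s_u, n))
    s_t = config.trunk_person_sd_log
    trunk_factor = np.exp(rng.normal(-s_t**2 / 2, s_t, n))
    wrist_offset = rng.normal(0.0, config.wrist_person_offset_sd_mg, n) \
        if config.wrist_person_offset_sd_mg > 0 else np.zeros(n)

    habitual_paee = mu * calib  # expected long-run mean criterion PAEE
    bmi = np.clip(
        by_sex(config.bmi_mean)
        + config.bmi_paee_slope * (habitual_paee - expected_paee(config))
        + rng.normal(0.0, config.bmi_residual_sd, n),
        16.0, 55.0)
    weight = bmi * height**2

    return pd.DataFrame({
        "participant_id": [f"P{i + 1:05d}" for i in range(n)],
        "sex": np.where(sex_idx == 0, "male", "female"),
        "age": age, "height_m": height, "weight_kg": weight, "bmi": bmi,
        "mu_intensity": mu, "calib_factor": calib,
        "trunk_factor": trunk_factor, "wrist_offset_mg": wrist_offset,
    })


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the participant table (one row per participant).

    Columns: participant_id, sex, age (y), height_m, weight_kg,
    bmi (kg·m⁻², equal to weight/height² by construction).
    """
    return _cohort_with_latents(config)[PUBLIC_COHORT_COLUMNS].copy()


def diurnal_weights(config: GeneratorConfig) -> np.ndarray:
    """Multiplicative intensity profile over one day of epochs, mean one.

    A nightly sleep block at ``sleep_weight`` and a sinusoidal midday
    bump over waking hours.
    """
    hours = np.arange(config.epochs_per_day) * config.epoch_length / 3600.0
    start, end = config.sleep_start_hour, config.sleep_end_hour
    if start > end:  # block wraps midnight
        asleep = (hours >= start) | (hours < end)
    else:
        asleep = (hours >= start) & (hours < end)
    wake_hours = hours[~asleep]
    span = wake_hours.max() - wake_hours.min() + config.epoch_length / 3600.0
    phase = (wake_hours - wake_hours.min()) / span
    bump = 1.0 + config.diurnal_amplitude * np.sin(np.pi * phase)
    w = np.empty_like(hours)
    w[asleep] = config.sleep_weight
    w[~asleep] = bump
    return w / w.mean()


def _nonwear_mask(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    """Boolean per-epoch mask of injected non-wear for one sensor."""
    n_e = config.epochs_per_participant
    mask = np.zeros(n_e, dtype=bool)
    n_episodes = rng.poisson(config.nonwear_rate * config.days)
    total_s = n_e * config.epoch_length
    lo, hi = config.nonwear_duration_hours
    for _ in range(n_episodes):
        dur_s = rng.uniform(lo, hi) * 3600.0
        start_s = rng.uniform(0.0, max(total_s - dur_s, 0.0))
        i0 = int(start_s // config.epoch_length)
        i1 = int(np.ceil((start_s + dur_s) / config.epoch_length))
        mask[i0:min(i1, n_e)] = True
    return mask


def generate_epoch_series(participant: pd.Series, config: GeneratorConfig
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one participant's epoch-level dual-sensor record.

    Returns ``(epochs, latent)``: the observed record (ENMO/HPFVM in mg,
    trunk acceleration in m·s⁻², criterion PAEE in J·min⁻¹·kg⁻¹, wear
    flags) and the parallel ground-truth layer.
    """
    if "mu_intensity" not in participant.index:
        full = _cohort_with_latents(config)
        participant = full[full["participant_id"] == participant["participant_id"]].iloc[0]
    idx = int(str(participant["participant_id"])[1:]) - 1
    rng = _rng(config, 1, idx)
    n_e = config.epochs_per_participant
    t = config.truth

    # latent intensity: diurnal profile x lognormal within-person variation
    w = np.tile(diurnal_weights(config), config.days)
    z = rng.standard_normal(n_e)
    phi = config.ar1
    if phi:
        z = sps.lfilter([np.sqrt(1 - phi**2)], [1.0, -phi], z)
        z[0] /= np.sqrt(1 - phi**2)  # stationary start
    s_w = config.within_sd_log
    intensity = participant["mu_intensity"] * w * np.exp(s_w * z - s_w**2 / 2)
    intensity = np.clip(intensity, 0.0, _intensity_cap(config))

    hpfvm_true = invert_quadratic(intensity, t.beta1_hpfvm, t.beta2_hpfvm, t.alpha)
    enmo_true = invert_quadratic(intensity, t.beta1_enmo, t.beta2_enmo, t.alpha)
    trunk_true = config.trunk_intercept + config.trunk_slope * hpfvm_true

    # observed wrist metrics (exact by default; optional measurement error)
    def observe(truth_mg: np.ndarray) -> np.ndarray:
        out = truth_mg + participant["wrist_offset_mg"]
        if config.wrist_noise_sd_mg > 0:
            out = out + rng.normal(0.0, config.wrist_noise_sd_mg, n_e)
        return np.maximum(out, 0.0)

    enmo_obs = observe(enmo_true)
    hpfvm_obs = observe(hpfvm_true)

    # criterion PAEE and trunk acceleration with multiplicative errors
    s_v = config.criterion_noise_sd_log
    v_epoch = np.exp(rng.normal(-s_v**2 / 2, s_v, n_e)) if s_v > 0 else np.ones(n_e)
    paee = intensity * participant["calib_factor"] * v_epoch
    s_t = config.trunk_noise_sd_log
    v_trunk = np.exp(rng.normal(-s_t**2 / 2, s_t, n_e)) if s_t > 0 else np.ones(n_e)
    trunk_obs = trunk_true * participant["trunk_factor"] * v_trunk

    # injected non-wear episodes, one mask per sensor
    worn_wrist = ~_nonwear_mask(_rng(config, 2, idx), config)
    worn_combined = ~_nonwear_mask(_rng(config, 3, idx), config)
    enmo_obs = np.where(worn_wrist, enmo_obs, 0.0)
    hpfvm_obs = np.where(worn_wrist, hpfvm_obs, 0.0)
    trunk_obs = np.where(worn_combined, trunk_obs, 0.0)
    paee = np.where(worn_combined, paee, np.nan)

    starts = BASE_DATE + pd.to_timedelta(
        np.arange(n_e) * config.epoch_length, unit="s")
    epochs = pd.DataFrame({
        "participant_id": participant["participant_id"],
        "epoch_start": starts,
        "enmo_mg": enmo_obs, "hpfvm_mg": hpfvm_obs,
        "trunk_acc_ms2": trunk_obs, "paee_jminkg": paee,
        "hr_valid": worn_combined,
        "wear_wrist": worn_wrist, "wear_combined": worn_combined,
    })
    latent = pd.DataFrame({
        "participant_id": participant["participant_id"],
        "epoch_start": starts,
        "true_intensity": intensity,
        "wrist_enmo_true": enmo_true, "wrist_hpfvm_true": hpfvm_true,
        "trunk_acc_true": trunk_true,
        "worn_wrist": worn_wrist, "worn_combined": worn_combined,
    })
    return epochs, latent


def generate_dataset(config: GeneratorConfig, with_latent: bool = False):
    """Simulate the whole cohort: (cohort, epochs[, latent]) DataFrames."""
    full = _cohort_with_latents(config)
    epoch_frames, latent_frames = [], []
    for _, row in full.iterrows():
        epochs, latent = generate_epoch_series(row, config)
        epoch_frames.append(epochs)
        if with_latent:
            latent_frames.append(latent)
    cohort = full[PUBLIC_COHORT_COLUMNS].copy()
    epochs = pd.concat(epoch_frames, ignore_index=True)
    if with_latent:
        return cohort, epochs, pd.concat(latent_frames, ignore_index=True)
    return cohort, epochs


def linear_truth(config: GeneratorConfig, metric: str,
                 n_participants: int = 3000, seed: int = 987654321
                 ) -> tuple[float, float]:
    """Population least-squares projection of the truth curve on {1, m}.

    The generator's truth is quadratic, so a linear prediction model has
    no generative coefficients; its natural target is the best linear
    approximation over the simulated epoch population, which this
    estimates by a large one-day Monte Carlo of the latent process only
    (no observation noise enters: the projection is of E[PAEE | m] = f(m)).
    Returns (alpha, beta1).
    """
    import dataclasses
    probe = dataclasses.replace(config, n_participants=n_participants, days=1,
                                seed=seed, nonwear_rate=0.0)
    t = config.truth
    full = _cohort_with_latents(probe)
    rng = _rng(probe, 10)
    w = np.tile(diurnal_weights(probe), probe.days)
    n_e = probe.epochs_per_participant
    s_w = probe.within_sd_log
    mu = full["mu_intensity"].to_numpy()[:, None]
    z = rng.standard_normal((n_participants, n_e))
    intensity = mu * w[None, :] * np.exp(s_w * z - s_w**2 / 2)
    intensity = np.clip(intensity, 0.0, _intensity_cap(probe)).ravel()
    if metric == "hpfvm":
        m = invert_quadratic(intensity, t.beta1_hpfvm, t.beta2_hpfvm, t.alpha)
    elif metric == "enmo":
        m = invert_quadratic(intensity, t.beta1_enmo, t.beta2_enmo, t.alpha)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    beta1 = float(np.cov(m, intensity)[0, 1] / np.var(m))
    alpha = float(intensity.mean() - beta1 * m.mean())
    return alpha, beta1


def generate_raw_bout(kind: str, duration: float = 60.0, sample_rate: float = 60.0,
                      amplitude: float = 0.1, frequency: float = 1.0,
                      orientation=(0.0, 0.0, 1.0), noise_sd: float = 0.0,
                      offset=(0.0, 0.0, 0.0), gain=(1.0, 1.0, 1.0),
                      seed: int = 0) -> RawTriaxialSignal:
    """Generate a short raw triaxial bout in g.

    Kinds
    -----
    stationary:
        Gravity along ``orientation``; vector magnitude 1 g before
        offset/gain distortion.
    sinusoidal:
        ``orientation * (1 + amplitude * sin(2*pi*frequency*t))`` —
        movement superposed on gravity along the same axis.
    mixed:
        Alternating stationary holds cycling through distinct
        orientations, separated by sinusoidal movement bursts; suitable
        as an auto-calibration fixture.

    The observed signal is ``true * gain + offset`` per axis, plus white
    noise of ``noise_sd`` g.
    """
    if duration <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample_rate must be positive")
    if kind in ("sinusoidal", "mixed") and sample_rate <= 2.0 * frequency:
        raise ValueError(
            f"sample_rate {sample_rate} Hz cannot represent {frequency} Hz (aliased)")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    tt = np.arange(n) / sample_rate
    ori = np.asarray(orientation, dtype=float)
    ori = ori / np.linalg.norm(ori)

    if kind == "stationary":
        true = np.tile(ori, (n, 1))
    elif kind == "sinusoidal":
        vm = 1.0 + amplitude * np.sin(2.0 * np.pi * frequency * tt)
        true = vm[:, None] * ori[None, :]
    elif kind == "mixed":
        hold = int(round(30.0 * sample_rate))  # 30 s stationary holds
        burst = int(round(10.0 * sample_rate))  # 10 s movement bursts
        true = np.empty((n, 3))
        i, k = 0, 0
        while i < n:
            o = _ORIENTATIONS[k % len(_ORIENTATIONS)]
            j = min(i + hold, n)
            true[i:j] = o
            i = j
            if i < n:
                j = min(i + burst, n)
                seg_t = tt[i:j]
                vm = 1.0 + amplitude * np.sin(2.0 * np.pi * frequency * seg_t)
                true[i:j] = vm[:, None] * o[None, :]
                i = j
            k += 1
    else:
        raise ValueError(f"unknown bout kind {kind!r}")

    if noise_sd > 0:
        true = true + rng.normal(0.0, noise_sd, size=true.shape)
    observed = true * np.asarray(gain, dtype=float) + np.asarray(offset, dtype=float)
    return RawTriaxialSignal(observed, sample_rate, BASE_DATE)


def generate_wrist_nonwear_fixture(duration: float = 6 * 3600.0,
                                   sample_rate: float = 20.0,
                                   episodes=((2 * 3600.0, 1.5 * 3600.0),),
                                   noise_sd: float = 0.002,
                                   seed: int = 0):
    """An active raw signal with injected stationary non-wear episodes.

    ``episodes`` is a sequence of (start_s, duration_s). The active
    portion is sinusoidal movement (amplitude 0.2 g, ~1.3 Hz) with
    per-axis noise far above the non-wear SD threshold; episodes are
    stationary with ``noise_sd`` below it. Returns (signal, episodes).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    tt = np.arange(n) / sample_rate
    ori = np.array([0.0, 0.0, 1.0])
    vm = 1.0 + 0.2 * np.sin(2.0 * np.pi * 1.3 * tt)
    data = vm[:, None] * ori[None, :] + rng.normal(0.0, 0.05, (n, 3))
    for start_s, dur_s in episodes:
        i0, i1 = int(start_s * sample_rate), int((start_s + dur_s) * sample_rate)
        seg = slice(max(i0, 0), min(i1, n))
        m = seg.stop - seg.start
        data[seg] = ori[None, :] + rng.normal(0.0, noise_sd, (m, 3))
    return RawTriaxialSignal(data, sample_rate, BASE_DATE), list(episodes)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def write_epochs_csv(epochs: pd.DataFrame, path) -> None:
    out = epochs.copy()
    out["epoch_start"] = pd.to_datetime(out["epoch_start"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
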