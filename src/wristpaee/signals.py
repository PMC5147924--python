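"""Raw wrist-acceleration signal processing.

Turns a calibrated triaxial signal sampled at tens of Hz into the two
epoch-level movement metrics used for energy-expenditure prediction:

* **ENMO** (Euclidean Norm Minus One): vector magnitude minus 1 g,
  truncated to zero per sample.
* **HPFVM** (High-Pass Filtered Vector Magnitude): vector magnitude
  passed through a 0.2 Hz high-pass filter (gravity treated as a
  low-frequency component), rectified.

Both metrics are averaged over fixed 5-minute epochs and reported in mg.
A 20 Hz low-pass filter removes sensor noise above the physiological
range before metric derivation, and a simplified auto-calibration
estimates per-axis offset and gain from stationary periods so that
stationary vector magnitude equals 1 g.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal as sps

from .config import SECONDS_PER_DAY, FilterConfig

logger = logging.getLogger(__name__)

G_TO_MG = 1000.0


class CalibrationInfeasibleError(RuntimeError):
    """Raised when too few distinct stationary orientations are available."""


@dataclass
class RawTriaxialSignal:
    """A triaxial acceleration recording in units of g.

    Parameters
    ----------
    data:
        Array of shape (n_samples, 3) holding X, Y, Z in g.
    sample_rate:
        Sampling frequency in Hz.
    start_time:
        Timestamp of the first sample.
    """

    data: np.ndarray
    sample_rate: float
    start_time: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2016-01-04"))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError("data must have shape (n_samples, 3)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal contains non-finite samples")
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from the start."""
        return np.arange(self.n_samples) / self.sample_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times,
                             "x_g": self.data[:, 0],
                             "y_g": self.data[:, 1],
                             "z_g": self.data[:, 2]})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sample_rate: float,
                   start_time="2016-01-04") -> "RawTriaxialSignal":
        return cls(frame[["x_g", "y_g", "z_g"]].to_numpy(), sample_rate, start_time)


@dataclass(frozen=True)
class CalibrationParams:
    """Per-axis offset/gain correcting a raw signal to local gravity.

    Calibrated = (raw - offset) / gain, so that stationary vector
    magnitude is 1 g.
    """

    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)  # g
    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_stationary_points: int = 0
    post_calibration_error: float = 0.0  # RMS deviation of stationary VM from 1 g

    def __post_init__(self) -> None:
        if any(not 0.5 < g_ < 1.5 for g_ in self.gain):
            raise ValueError("gains must lie in (0.5, 1.5)")
        if self.post_calibration_error < 0:
            raise ValueError("post_calibration_error must be >= 0")


def vector_magnitude(samples: np.ndarray) -> np.ndarray:
    """Euclidean norm sqrt(X^2 + Y^2 + Z^2) per sample, in g."""
    samples = np.asarray(samples, dtype=float)
    return np.sqrt(np.sum(samples**2, axis=-1))


def enmo_series(vm: np.ndarray) -> np.ndarray:
    """ENMO per sample: max(VM - 1 g, 0)."""
    return np.maximum(np.asarray(vm, dtype=float) - 1.0, 0.0)


def _sos(cutoff: float, sample_rate: float, order: int, btype: str) -> np.ndarray:
    nyq = sample_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"{btype} cutoff {cutoff} Hz must lie in (0, Nyquist={nyq} Hz)")
    return sps.butter(order, cutoff / nyq, btype=btype, output="sos")


def _min_length(sos: np.ndarray) -> int:
    # sosfiltfilt default padlen; inputs must be strictly longer
    return 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                           (sos[:, 5] == 0).sum()))


def lowpass_filter(sig: RawTriaxialSignal,
                   config: FilterConfig = FilterConfig()) -> RawTriaxialSignal:
    """Zero-phase Butterworth low-pass of each axis (sensor-noise removal)."""
    sos = _sos(config.lowpass_cutoff, sig.sample_rate, config.filter_order, "lowpass")
    if sig.n_samples <= _min_length(sos):
        raise ValueError("signal shorter than filter warm-up length")
    filtered = sps.sosfiltfilt(sos, sig.data, axis=0)
    return RawTriaxialSignal(filtered, sig.sample_rate, sig.start_time)


def hpfvm_series(vm: np.ndarray, sample_rate: float,
                 config: FilterConfig = FilterConfig()) -> np.ndarray:
    """HPFVM per sample: |high-pass(VM)| with a zero-phase Butterworth filter.

    The high-passed signal is signed; it is rectified (absolute value)
    before epoch averaging so the result is a non-negative intensity
    metric comparable to ENMO.
    """
    vm = np.asarray(vm, dtype=float)
    sos = _sos(config.highpass_cutoff, sample_rate, config.filter_order, "highpass")
    if vm.shape[0] <= _min_length(sos):
        raise ValueError("VM series shorter than filter warm-up length")
    return np.abs(sps.sosfiltfilt(sos, vm))


def butterworth_gain(freq: float, cutoff: float, order: int, btype: str) -> float:
    """Analytic magnitude response of the zero-phase (forward-backward)
    Butterworth filter at ``freq``; used as an independent oracle."""
    ratio = (freq / cutoff) if btype == "lowpass" else (cutoff / freq)
    single_pass = 1.0 / np.sqrt(1.0 + ratio ** (2 * order))
    return single_pass**2  # applied twice


def digital_filter_gain(freq: float, sample_rate: float, cutoff: float,
                        order: int, btype: str) -> float:
    """Frequency-domain magnitude of the designed zero-phase digital filter
    at ``freq`` (|H|² of the Butterworth section, applied forward-backward).
    Near Nyquist this differs from the analog prototype because of bilinear
    warping; it is the exact oracle for the implemented filter."""
    sos = _sos(cutoff, sample_rate, order, btype)
    _, h = sps.sosfreqz(sos, worN=[freq / (sample_rate / 2.0) * np.pi])
    return float(np.abs(h[0]) ** 2)


def find_stationary_windows(sig: RawTriaxialSignal, sd_threshold_g: float = 0.013,
                            window_s: float = 10.0) -> np.ndarray:
    """Mean (X, Y, Z) of each non-overlapping window whose per-axis SD is
    below ``sd_threshold_g`` on every axis. Returns array (n_windows, 3)."""
    n_win = int(round(window_s * sig.sample_rate))
    n = sig.n_samples // n_win
    if n == 0:
        return np.empty((0, 3))
    blocks = sig.data[:n * n_win].reshape(n, n_win, 3)
    sds = blocks.std(axis=1)
    keep = np.all(sds < sd_threshold_g, axis=1)
    return blocks[keep].mean(axis=1)


def _count_orientations(points: np.ndarray, min_angle_deg: float = 15.0) -> int:
    """Greedy count of directions pairwise separated by at least min_angle."""
    if len(points) == 0:
        return 0
    units = points / np.linalg.norm(points, axis=1, keepdims=True)
    cos_min = np.cos(np.deg2rad(min_angle_deg))
    chosen: list[np.ndarray] = []
    for u in units:
        # distinct if the angle to every already-chosen direction exceeds threshold
        if all(float(u @ c) < cos_min for c in chosen):
            chosen.append(u)
    return len(chosen)


def autocalibrate(sig: RawTriaxialSignal, stationary_sd_threshold: float = 0.013,
                  min_orientations: int = 6, window_s: float = 10.0) -> CalibrationParams:
    """Estimate per-axis offset and gain from stationary periods.

    Stationary windows should have vector magnitude exactly 1 g; offset
    and gain are chosen by least squares to bring them there. Requires
    stationary windows spanning at least ``min_orientations`` distinct
    orientations, otherwise the problem is underdetermined and a
    :class:`CalibrationInfeasibleError` is raised.
    """
    points = find_stationary_windows(sig, stationary_sd_threshold, window_s)
    if _count_orientations(points) < min_orientations:
        raise CalibrationInfeasibleError(
            f"found {_count_orientations(points)} distinct stationary orientations, "
            f"need {min_orientations}")

    def residuals(theta: np.ndarray) -> np.ndarray:
        off, gain = theta[:3], theta[3:]
        return vector_magnitude((points - off) / gain) - 1.0

    pre_error = float(np.sqrt(np.mean(residuals(np.array([0, 0, 0, 1, 1, 1.0]))**2)))
    res = optimize.least_squares(
        residuals, x0=np.array([0, 0, 0, 1, 1, 1.0]),
        bounds=([-0.5] * 3 + [0.51] * 3, [0.5] * 3 + [1.49] * 3))
    post_error = float(np.sqrt(np.mean(res.fun**2)))
    if post_error >= pre_error:
        logger.warning("auto-calibration did not improve fit; returning identity")
        return CalibrationParams(n_stationary_points=len(points),
                                 post_calibration_error=pre_error)
    return CalibrationParams(offset=tuple(res.x[:3]), gain=tuple(res.x[3:]),
                             n_stationary_points=len(points),
                             post_calibration_error=post_error)


def apply_calibration(sig: RawTriaxialSignal,
                      params: CalibrationParams) -> RawTriaxialSignal:
    """Apply offset/gain correction: calibrated = (raw - offset) / gain."""
    corrected = (sig.data - np.asarray(params.offset)) / np.asarray(params.gain)
    return RawTriaxialSignal(corrected, sig.sample_rate, sig.start_time)


def summarise_epochs(values: np.ndarray, sample_rate: float,
                     epoch_length: int = 300,
                     start_time="2016-01-04",
                     wear: np.ndarray | None = None) -> pd.DataFrame:
    """Average a per-sample series (in g) over a fixed epoch grid.

    The grid is anchored at the first sample, with half-open intervals
    [t, t + epoch_length). An epoch is valid only when fully covered by
    samples and, if a ``wear`` mask is given, when every sample in it is
    wear time. Means are reported in mg.

    Returns a DataFrame with columns epoch_start, mean_mg, n_samples, valid.
    """
    if epoch_length <= 0 or SECONDS_PER_DAY % epoch_length:
        raise ValueError("epoch_length must be a positive divisor of 86400")
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n == 0:
        return pd.DataFrame(columns=["epoch_start", "mean_mg", "n_samples", "valid"])
    per_epoch = int(round(epoch_length * sample_rate))
    n_epochs = int(np.ceil(n / per_epoch))
    start_time = pd.Timestamp(start_time)
    starts = start_time + pd.to_timedelta(np.arange(n_epochs) * epoch_length, unit="s")
    idx = np.arange(n) // per_epoch
    sums = np.bincount(idx, weights=values, minlength=n_epochs)
    counts = np.bincount(idx, minlength=n_epochs)
    means = np.divide(sums, counts, out=np.full(n_epochs, np.nan), where=counts > 0)
    valid = counts == per_epoch
    if wear is not None:
        wear = np.asarray(wear, dtype=bool)
        worn_counts = np.bincount(idx, weights=wear.astype(float), minlength=n_epochs)
        valid &= worn_counts == counts
    out = pd.DataFrame({"epoch_start": starts, "mean_mg": means * G_TO_MG,
                        "n_samples": counts, "valid": valid})
    out.loc[~out["valid"], "mean_mg"] = np.nan
    return out


def process_raw_signal(sig: RawTriaxialSignal,
                       filters: FilterConfig = FilterConfig(),
                       epoch_length: int = 300,
                       calibrate: bool = True,
                       wear: np.ndarray | None = None) -> pd.DataFrame:
    """Full raw-signal path: calibrate, low-pass, derive ENMO and HPFVM,
    summarise to epochs.

    Returns a DataFrame with epoch_start, enmo_mg, hpfvm_mg, valid.
    """
    if calibrate:
        try:
            params = autocalibrate(sig)
            sig = apply_calibration(sig, params)
        except CalibrationInfeasibleError:
            logger.warning("calibration infeasible; proceeding with identity")
    sig = lowpass_filter(sig, filters)
    vm = vector_magnitude(sig.data)
    enmo = enmo_series(vm)
    hpfvm = hpfvm_series(vm, sig.sample_rate, filters)
    e = summarise_epochs(enmo, sig.sample_rate, epoch_length, sig.start_time, wear)
    h = summarise_epochs(hpfvm, sig.sample_rate, epoch_length, sig.start_time, wear)
    return pd.DataFrame({"epoch_start": e["epoch_start"],
                         "enmo_mg": e["mean_mg"], "hpfvm_mg": h["mean_mg"],
                         "valid": e["valid"] & h["valid"]})
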