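"""Non-wear detection and exclusion.

Two rules, one per sensor:

* **Wrist accelerometer** — non-wear is any period where the standard
  deviation of acceleration in each of the three axes stays below
  13 mg for at least one hour. The SD is computed in consecutive
  non-overlapping 60 s blocks; a run of qualifying blocks forms a
  candidate period, so boundary error is bounded by the block length.
* **Combined sensor** — non-wear is a contiguous run of exactly zero
  trunk movement lasting strictly longer than 90 minutes with
  non-physiological (invalid) heart rate throughout. Zero movement with
  valid heart rate is sleep, not non-wear.

Detected non-wear epochs are excluded from all downstream analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import NonwearConfig
from .signals import RawTriaxialSignal

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WearSegment:
    """A maximal run of constant wear status for one sensor."""

    start: pd.Timestamp
    end: pd.Timestamp
    worn: bool
    sensor: str  # "wrist" or "combined"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must be after start")


def _runs(flags: np.ndarray):
    """Yield (start_index, stop_index, value) for maximal constant runs."""
    if len(flags) == 0:
        return
    change = np.flatnonzero(np.diff(flags.astype(np.int8))) + 1
    bounds = np.r_[0, change, len(flags)]
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        yield int(i0), int(i1), bool(flags[i0])


def _segments_from_blocks(nonwear_blocks: np.ndarray, block_s: float,
                          start_time: pd.Timestamp, sensor: str) -> list[WearSegment]:
    segs = []
    for i0, i1, nw in _runs(nonwear_blocks):
        segs.append(WearSegment(
            start=start_time + pd.Timedelta(seconds=i0 * block_s),
            end=start_time + pd.Timedelta(seconds=i1 * block_s),
            worn=not nw, sensor=sensor))
    return segs


def detect_wrist_nonwear(sig: RawTriaxialSignal,
                         config: NonwearConfig = NonwearConfig()) -> list[WearSegment]:
    """Flag wrist non-wear from sustained low per-axis variance.

    Returns wear/non-wear segments partitioning the record (trailing
    samples not filling a whole SD window are folded into the last block).
    """
    if sig.duration < config.sd_window:
        raise ValueError("signal shorter than one SD window")
    n_win = int(round(config.sd_window * sig.sample_rate))
    n_blocks = sig.n_samples // n_win
    blocks = sig.data[:n_blocks * n_win].reshape(n_blocks, n_win, 3)
    sds_mg = blocks.std(axis=1) * 1000.0
    low = np.all(sds_mg < config.wrist_sd_threshold, axis=1)

    min_blocks = int(round(config.wrist_min_duration / config.sd_window))
    nonwear = np.zeros(n_blocks, dtype=bool)
    for i0, i1, val in _runs(low):
        if val and (i1 - i0) >= min_blocks:
            nonwear[i0:i1] = True
    return _segments_from_blocks(nonwear, config.sd_window, sig.start_time, "wrist")


def detect_combined_nonwear(trunk: pd.Series | np.ndarray,
                            hr_valid: pd.Series | np.ndarray,
                            epoch_start: pd.Series | np.ndarray,
                            epoch_length: float = 300.0,
                            config: NonwearConfig = NonwearConfig()) -> list[WearSegment]:
    """Flag combined-sensor non-wear from an epoch-level record.

    ``trunk`` is epoch trunk acceleration (zero movement means exactly 0
    after device quantisation), ``hr_valid`` the per-epoch heart-rate
    validity flag, both aligned on ``epoch_start``.
    """
    trunk = np.asarray(trunk, dtype=float)
    hr_valid = np.asarray(hr_valid, dtype=bool)
    starts = pd.to_datetime(pd.Series(np.asarray(epoch_start))).reset_index(drop=True)
    if not (len(trunk) == len(hr_valid) == len(starts)):
        raise ValueError("trunk, hr_valid and epoch_start must be equally long")
    if len(starts) > 1:
        step = (starts.iloc[1] - starts.iloc[0]).total_seconds()
        diffs = starts.diff().dropna().dt.total_seconds()
        if step != epoch_length or not np.allclose(diffs, epoch_length):
            raise ValueError("epoch series not aligned to the epoch grid")

    candidate = trunk == 0.0
    if config.hr_invalid_required:
        candidate &= ~hr_valid
    nonwear = np.zeros(len(trunk), dtype=bool)
    for i0, i1, val in _runs(candidate):
        # "extended (>90 min)": strictly longer than the threshold
        if val and (i1 - i0) * epoch_length > config.combined_zero_movement_min:
            nonwear[i0:i1] = True
    return _segments_from_blocks(nonwear, epoch_length, starts.iloc[0], "combined")


def segments_to_frame(segments: list[WearSegment]) -> pd.DataFrame:
    return pd.DataFrame([{"sensor": s.sensor, "start": s.start, "end": s.end,
                          "worn": s.worn} for s in segments])


def flag_epochs(epochs: pd.DataFrame, segments: list[WearSegment],
                epoch_length: float = 300.0) -> pd.DataFrame:
    """Set wear_wrist / wear_combined flags from detected segments.

    An epoch is non-wear for a sensor if any part of it overlaps a
    non-worn segment of that sensor.
    """
    out = epochs.copy()
    starts = pd.to_datetime(out["epoch_start"])
    ends = starts + pd.Timedelta(seconds=epoch_length)
    for sensor, col in (("wrist", "wear_wrist"), ("combined", "wear_combined")):
        if col not in out.columns:
            out[col] = True
        for seg in segments:
            if seg.sensor != sensor or seg.worn:
                continue
            overlap = (starts < seg.end) & (ends > seg.start)
            out.loc[overlap, col] = False
    return out


def apply_exclusions(epochs: pd.DataFrame,
                     segments: list[WearSegment] | None = None,
                     epoch_length: float = 300.0) -> pd.DataFrame:
    """Drop epochs not fully worn on both sensors.

    If ``segments`` is given the wear flags are first refreshed from
    them; otherwise the existing wear_wrist / wear_combined columns are
    used as-is.
    """
    out = flag_epochs(epochs, segments, epoch_length) if segments else epochs
    keep = out["wear_wrist"].astype(bool) & out["wear_combined"].astype(bool)
    if not keep.any():
        logger.warning("all %d epochs flagged as non-wear", len(out))
    return out.loc[keep].reset_index(drop=True)


def wrist_nonwear_epoch_proxy(epochs: pd.DataFrame,
                              config: NonwearConfig = NonwearConfig(),
                              epoch_length: float = 300.0) -> pd.Series:
    """Epoch-level stand-in for the raw-signal wrist rule.

    When only epoch summaries are available (as for the simulated
    cohort), a run of epochs with exactly zero wrist movement on both
    metrics lasting at least the wrist minimum duration is flagged
    non-wear. Returns a boolean Series, True = worn.
    """
    zero = (epochs["enmo_mg"].to_numpy() == 0.0) & \
           (epochs["hpfvm_mg"].to_numpy() == 0.0)
    worn = np.ones(len(epochs), dtype=bool)
    min_epochs = int(np.ceil(config.wrist_min_duration / epoch_length))
    offset = 0
    for _, grp in epochs.groupby("participant_id", sort=False):
        z = zero[offset:offset + len(grp)]
        for i0, i1, val in _runs(z):
            if val and (i1 - i0) >= min_epochs:
                worn[offset + i0:offset + i1] = False
        offset += len(grp)
    return pd.Series(worn, index=epochs.index, name="wear_wrist")
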