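"""Position-to-velocity preprocessing and saccade-based trial exclusion.

Positions are low-pass filtered with a zero-phase (forward-backward)
second-order Butterworth at 20 Hz, differentiated to velocity, and trials
with a saccade inside the open-loop window (-100 to 250 ms from motion
onset) are excluded.  The two-pass filter has unit DC gain, no phase delay,
and an effective magnitude response equal to the squared single-pass
response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .synthdata import TrialTraceSet

__all__ = [
    "VelocityTraceSet",
    "SaccadeEvent",
    "lowpass_filter",
    "butter_lowpass",
    "differentiate",
    "central_difference",
    "detect_saccades",
    "exclude_trials",
    "preprocess_session",
]


@dataclass
class VelocityTraceSet:
    """Velocity traces for a session, on the same time base as the source."""

    time_ms: np.ndarray  # (T,)
    velocity: np.ndarray  # (n, T, 2) deg/s
    meta: pd.DataFrame
    sample_rate_hz: float = 1000.0

    @property
    def n_trials(self) -> int:
        return self.velocity.shape[0]

    @property
    def speed(self) -> np.ndarray:
        """Radial speed sqrt(vh^2 + vv^2), shape (n, T)."""
        return np.hypot(self.velocity[..., 0], self.velocity[..., 1])

    def subset(self, mask: np.ndarray) -> "VelocityTraceSet":
        mask = np.asarray(mask)
        return VelocityTraceSet(
            time_ms=self.time_ms,
            velocity=self.velocity[mask],
            meta=self.meta.loc[mask].reset_index(drop=True),
            sample_rate_hz=self.sample_rate_hz,
        )


@dataclass(frozen=True)
class SaccadeEvent:
    trial_index: int
    onset_ms: float
    offset_ms: float
    peak_speed_deg_s: float

    def __post_init__(self) -> None:
        if not self.onset_ms < self.offset_ms:
            raise ValueError("saccade onset must precede offset")


def butter_lowpass(
    x: np.ndarray, cutoff_hz: float = 20.0, fs_hz: float = 1000.0,
    order: int = 2, axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass along ``axis``."""
    if cutoff_hz >= fs_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=fs_hz)
    startup = 3 * max(len(a), len(b))  # filtfilt edge-padding length
    if x.shape[axis] < 3 * startup:
        raise ValueError(
            f"trace length {x.shape[axis]} too short for filter startup ({startup})"
        )
    return signal.filtfilt(b, a, x, axis=axis)


def lowpass_filter(
    traces: TrialTraceSet, cutoff_hz: float = 20.0, order: int = 2
) -> TrialTraceSet:
    """Low-pass the position traces of a session (zero-phase, DC gain 1)."""
    filt = butter_lowpass(
        traces.position, cutoff_hz=cutoff_hz, fs_hz=traces.sample_rate_hz,
        order=order, axis=1,
    )
    return TrialTraceSet(
        time_ms=traces.time_ms, position=filt, meta=traces.meta,
        sample_rate_hz=traces.sample_rate_hz,
    )


def central_difference(x: np.ndarray, dt_s: float, axis: int = -1) -> np.ndarray:
    """Central-difference derivative (one-sided at the endpoints)."""
    return np.gradient(x, dt_s, axis=axis)


def differentiate(traces: TrialTraceSet) -> VelocityTraceSet:
    """Differentiate position to velocity in deg/s."""
    dt = np.diff(traces.time_ms)
    if dt.size == 0 or not np.allclose(dt, dt[0]):
        raise ValueError("time base must be uniform")
    vel = central_difference(traces.position, dt_s=dt[0] / 1000.0, axis=1)
    return VelocityTraceSet(
        time_ms=traces.time_ms, velocity=vel, meta=traces.meta,
        sample_rate_hz=traces.sample_rate_hz,
    )


def detect_saccades(
    velocities: VelocityTraceSet,
    speed_thresh: float = 30.0,
    min_dur_ms: float = 5.0,
    baseline_ms: float = 50.0,
) -> list[list[SaccadeEvent]]:
    """Detect saccades as residual-speed excursions above a running median.

    The smooth-pursuit baseline is a running median of radial speed
    (``baseline_ms`` window); samples exceeding it by ``speed_thresh`` deg/s
    for at least ``min_dur_ms`` form one event.  Returns one (possibly
    empty) event list per trial.
    """
    dt_ms = 1000.0 / velocities.sample_rate_hz
    win = max(int(round(baseline_ms / dt_ms)) | 1, 3)  # odd window
    speed = velocities.speed
    baseline = ndimage.median_filter(speed, size=(1, win), mode="nearest")
    above = (speed - baseline) > speed_thresh
    min_len = max(int(round(min_dur_ms / dt_ms)), 1)

    t = velocities.time_ms
    events: list[list[SaccadeEvent]] = []
    for i in range(velocities.n_trials):
        row = above[i]
        trial_events: list[SaccadeEvent] = []
        if row.any():
            lab, n_lab = ndimage.label(row)
            for k in range(1, n_lab + 1):
                idx = np.flatnonzero(lab == k)
                if idx.size >= min_len:
                    trial_events.append(
                        SaccadeEvent(
                            trial_index=int(velocities.meta["trial_index"].iloc[i]),
                            onset_ms=float(t[idx[0]]),
                            offset_ms=float(t[idx[-1]]),
                            peak_speed_deg_s=float(speed[i, idx].max()),
                        )
                    )
        events.append(trial_events)
    return events


def exclude_trials(
    traces: TrialTraceSet,
    events: list[list[SaccadeEvent]],
    window: tuple[float, float] = (-100.0, 250.0),
) -> tuple[TrialTraceSet, pd.DataFrame]:
    """Drop trials with a saccade overlapping the open-loop window.

    The window is a closed interval in ms relative to motion onset; a trial
    is removed iff any event overlaps it.  Returns the kept set and an
    exclusion log (trial_index, reason, event onset/offset).
    """
    lo, hi = window
    keep = np.ones(traces.n_trials, dtype=bool)
    log_rows = []
    for i, trial_events in enumerate(events):
        for ev in trial_events:
            if ev.onset_ms <= hi and ev.offset_ms >= lo:
                keep[i] = False
                log_rows.append(
                    dict(
                        trial_index=int(traces.meta["trial_index"].iloc[i]),
                        reason="saccade_in_open_loop_window",
                        onset_ms=ev.onset_ms,
                        offset_ms=ev.offset_ms,
                    )
                )
                break
    log = pd.DataFrame(log_rows, columns=["trial_index", "reason", "onset_ms", "offset_ms"])
    return traces.subset(keep), log


def preprocess_session(
    traces: TrialTraceSet,
    cutoff_hz: float = 20.0,
    speed_thresh: float = 30.0,
    window: tuple[float, float] = (-100.0, 250.0),
) -> tuple[VelocityTraceSet, pd.DataFrame]:
    """Filter, differentiate, and exclude saccade-contaminated trials.

    Returns the velocity set of kept trials and the exclusion log.
    """
    filtered = lowpass_filter(traces, cutoff_hz=cutoff_hz)
    vel = differentiate(filtered)
    events = detect_saccades(vel, speed_thresh=speed_thresh)
    kept_traces, log = exclude_trials(filtered, events, window=window)
    keep_idx = kept_traces.meta["trial_index"].to_numpy()
    mask = np.isin(vel.meta["trial_index"].to_numpy(), keep_idx)
    return vel.subset(mask), log
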