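"""Open-field trajectory kinematics and episode statistics.

Marker-position tracks (default 30 samples/s, arena-centered coordinates in
mm, counter-clockwise positive) are turned into windowed linear speed,
cumulative rotation (about the arena center or of the heading vector),
field-on/field-off episode statistics with fold changes and t-tests,
behavioral onset/offset latencies, freezing-of-gait intervals, and
turn-direction summaries across trials.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Trajectory",
    "KinematicsSeries",
    "EpisodeStats",
    "BehaviorEvent",
    "FrozenInterval",
    "TurnSummary",
    "linear_speed",
    "angular_kinematics",
    "episode_stats",
    "detect_behavior_latency",
    "detect_freezing",
    "turn_direction_summary",
]


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped planar marker positions in the arena frame.

    x, y in mm with the origin at the arena center, y up, CCW positive;
    all points must lie within 1.1× the arena radius.
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena_center: tuple[float, float] = (0.0, 0.0)
    arena_radius: float = 50.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        for name, arr in (("time", t), ("x", x), ("y", y)):
            object.__setattr__(self, name, arr)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1 or t.size < 2:
            raise ValueError("time, x, y must be matched 1-D arrays (n >= 2)")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
            raise ValueError("time grid must be uniform")
        r = np.hypot(x - self.arena_center[0], y - self.arena_center[1])
        if np.any(r > 1.1 * self.arena_radius):
            bad = np.flatnonzero(r > 1.1 * self.arena_radius)
            raise ValueError(
                f"{bad.size} points outside 1.1x arena radius "
                f"(first at index {bad[0]})"
            )

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class KinematicsSeries:
    """Derived kinematics on the trajectory's time grid.

    ``cumulative_angle`` is in revolutions (CCW positive, starting at 0);
    ``angular_rate`` in rev/min; ``linear_speed`` in mm/s.
    """

    time: np.ndarray
    linear_speed: np.ndarray
    heading: np.ndarray
    cumulative_angle: np.ndarray
    angular_rate: np.ndarray
    heading_defined: np.ndarray


@dataclass(frozen=True)
class EpisodeStats:
    """Field-on vs field-off summary of a kinematic quantity."""

    mean_on: float
    mean_off: float
    sd_on: float
    sd_off: float
    sem_on: float
    sem_off: float
    ci95_on: tuple[float, float]
    ci95_off: tuple[float, float]
    fold_change: float
    p_value: float
    t_statistic: float
    n_on: int
    n_off: int


@dataclass(frozen=True)
class BehaviorEvent:
    """Onset/offset latencies of a detected behavioral response; None marks
    a censored (never-crossed) side."""

    onset_latency: float | None
    offset_latency: float | None
    detection_threshold: float


@dataclass(frozen=True)
class FrozenInterval:
    start: float
    stop: float

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass(frozen=True)
class TurnSummary:
    """Per-trial turn directions and the fraction contralateral to the
    injected hemisphere."""

    n_ccw: int
    n_cw: int
    n_contralateral: int
    n_trials: int
    reversal_flags: list[bool]
    excluded_trials: list[int]

    @property
    def contralateral_fraction(self) -> float:
        return self.n_contralateral / self.n_trials


def _moving_average(values: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (window truncated at the
    record boundaries rather than padded)."""
    if n <= 1:
        return values.copy()
    kernel = np.ones(n)
    summed = np.convolve(values, kernel, mode="same")
    norm = np.convolve(np.ones_like(values), kernel, mode="same")
    return summed / norm


def linear_speed(traj: Trajectory, window: float = 0.5) -> np.ndarray:
    """Windowed linear speed in mm/s.

    Frame-to-frame displacement magnitudes divided by the frame interval,
    then averaged in a centered window (default 500 ms). The window must
    cover at least 2 frame intervals.
    """
    fs = traj.sample_rate
    n_win = int(round(window * fs))
    if n_win < 2:
        raise ValueError("window must span at least 2 sample intervals")
    dt = 1.0 / fs
    step = np.hypot(np.diff(traj.x), np.diff(traj.y)) / dt
    inst = np.concatenate([[step[0]], step])  # speed at sample i from step i-1→i
    return _moving_average(inst, n_win)


def angular_kinematics(
    traj: Trajectory,
    mode: str = "heading",
    window: float = 0.5,
    speed_floor: float = 1.0,
) -> KinematicsSeries:
    """Cumulative rotation and angular rate of a trajectory.

    Two references are supported:

    - ``about_center``: the unwrapped polar angle of the marker about the
      arena center — revolutions around the arena (running along the
      periphery).
    - ``heading``: the unwrapped direction of the velocity vector — captures
      rotation around the body axis even for small circles far off-center.

    CCW is positive in both. Below ``speed_floor`` (mm/s) the heading is
    undefined and held at its last defined value (flagged in
    ``heading_defined``). Angle increments take the shortest arc per frame.
    Returns cumulative angle in revolutions (starting at 0) and a windowed
    angular rate in rev/min.
    """
    fs = traj.sample_rate
    speed = linear_speed(traj, window=window)
    dx = np.gradient(traj.x)
    dy = np.gradient(traj.y)
    heading_raw = np.arctan2(dy, dx)
    defined = speed > speed_floor

    if mode == "about_center":
        cx, cy = traj.arena_center
        rx, ry = traj.x - cx, traj.y - cy
        if np.all(np.hypot(rx, ry) < 1e-9):
            raise ValueError("trajectory identically at the arena center")
        angle = np.unwrap(np.arctan2(ry, rx))
    elif mode == "heading":
        # hold heading through low-speed stretches before unwrapping, so
        # tracking jitter at rest does not wind the angle
        held = heading_raw.copy()
        last = held[0]
        for i in range(held.size):
            if defined[i]:
                last = held[i]
            else:
                held[i] = last
        angle = np.unwrap(held)
    else:
        raise ValueError("mode must be 'about_center' or 'heading'")

    cumulative = (angle - angle[0]) / (2.0 * math.pi)
    n_win = max(2, int(round(window * fs)))
    rate_inst = np.gradient(cumulative, traj.time) * 60.0  # rev/min
    rate = _moving_average(rate_inst, n_win)
    return KinematicsSeries(
        time=traj.time,
        linear_speed=speed,
        heading=heading_raw,
        cumulative_angle=cumulative,
        angular_rate=rate,
        heading_defined=defined,
    )


def _ci95(mean: float, sem: float, n: int) -> tuple[float, float]:
    if n < 2 or sem == 0.0:
        return (mean, mean)
    half = stats.t.ppf(0.975, n - 1) * sem
    return (mean - half, mean + half)


def episode_stats(
    time: np.ndarray,
    values: np.ndarray,
    field_windows: list[tuple[float, float]],
) -> EpisodeStats:
    """Field-on vs field-off statistics of a kinematic series.

    Samples inside any field window form the 'on' condition; the rest are
    'off'. Reports per-condition mean, sd, sem and t-based 95% CI, the
    unpaired two-sample t-test, and the on/off fold change.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if not field_windows:
        raise ValueError("need at least one field window")
    on_mask = np.zeros(time.shape, dtype=bool)
    for lo, hi in field_windows:
        on_mask |= (time >= lo) & (time < hi)
    if not on_mask.any() or on_mask.all():
        raise ValueError("both on and off periods must be non-empty")
    on = values[on_mask]
    off = values[~on_mask]

    sd_on = float(np.std(on, ddof=1)) if on.size > 1 else 0.0
    sd_off = float(np.std(off, ddof=1)) if off.size > 1 else 0.0
    if sd_on == 0.0 and sd_off == 0.0:
        warnings.warn("zero variance in both conditions; p-value degenerate",
                      stacklevel=2)
        t_stat, p = float("inf") if np.mean(on) != np.mean(off) else 0.0, float("nan")
    else:
        t_stat, p = stats.ttest_ind(on, off, equal_var=False)
        t_stat, p = float(t_stat), float(p)
    mean_on, mean_off = float(np.mean(on)), float(np.mean(off))
    sem_on = sd_on / math.sqrt(on.size) if on.size else float("nan")
    sem_off = sd_off / math.sqrt(off.size) if off.size else float("nan")
    fold = mean_on / mean_off if mean_off > 0 else float("nan")
    return EpisodeStats(
        mean_on=mean_on,
        mean_off=mean_off,
        sd_on=sd_on,
        sd_off=sd_off,
        sem_on=sem_on,
        sem_off=sem_off,
        ci95_on=_ci95(mean_on, sem_on, on.size),
        ci95_off=_ci95(mean_off, sem_off, off.size),
        fold_change=fold,
        p_value=p,
        t_statistic=t_stat,
        n_on=int(on.size),
        n_off=int(off.size),
    )


def detect_behavior_latency(
    time: np.ndarray,
    speed: np.ndarray,
    field_window: tuple[float, float],
    baseline: tuple[float, float],
    k: float = 2.0,
    hold: float = 2.0,
) -> BehaviorEvent:
    """Onset/offset latency of a speed response to the field.

    The detection threshold is baseline_mean + k·baseline_sd. Onset is the
    first time after field start at which the speed stays above threshold
    for at least ``hold`` seconds; offset is the first time after field end
    at which it stays below equally long. Either side is censored (None)
    when the condition is never met.
    """
    time = np.asarray(time, dtype=float)
    speed = np.asarray(speed, dtype=float)
    t_on, t_off = field_window
    mean_b, sd_b = baseline
    threshold = mean_b + k * sd_b
    dt = float(time[1] - time[0])
    n_hold = max(1, int(round(hold / dt)))

    def first_sustained(mask: np.ndarray, start_idx: int) -> int | None:
        run = 0
        for i in range(start_idx, mask.size):
            run = run + 1 if mask[i] else 0
            if run >= n_hold:
                return i - n_hold + 1
        return None

    i_on = int(np.searchsorted(time, t_on))
    i_off = int(np.searchsorted(time, t_off))
    above = speed > threshold
    onset_idx = first_sustained(above, i_on)
    onset = float(time[onset_idx] - t_on) if onset_idx is not None else None
    offset_idx = first_sustained(~above, i_off)
    offset = float(time[offset_idx] - t_off) if offset_idx is not None else None
    return BehaviorEvent(
        onset_latency=onset, offset_latency=offset, detection_threshold=threshold
    )


def detect_freezing(
    traj: Trajectory,
    reference_noise_floor: float,
    noise_sd: float = 0.11,
    window: float = 3.0,
) -> tuple[list[FrozenInterval], np.ndarray]:
    """Freezing-of-gait intervals from a marker trajectory.

    The absolute linear speed is averaged over ``window`` seconds (default
    3 s, matching the slow-motion analysis of paw tracks); samples where it
    does not exceed the tracking noise floor of a fixed marker
    (``reference_noise_floor`` + 2·``noise_sd``) are classified frozen.
    Returns the frozen intervals and the smoothed speed series.
    """
    if reference_noise_floor <= 0:
        raise ValueError("reference_noise_floor must be > 0")
    speed = linear_speed(traj, window=max(window, 2.0 / traj.sample_rate))
    smoothed = _moving_average(np.abs(speed), int(round(window * traj.sample_rate)))
    frozen = smoothed <= reference_noise_floor + 2.0 * noise_sd
    intervals: list[FrozenInterval] = []
    start = None
    for i, f in enumerate(frozen):
        if f and start is None:
            start = traj.time[i]
        elif not f and start is not None:
            intervals.append(FrozenInterval(float(start), float(traj.time[i])))
            start = None
    if start is not None:
        intervals.append(FrozenInterval(float(start), float(traj.time[-1])))
    return intervals, smoothed


def turn_direction_summary(
    trials: list[np.ndarray],
    injected_side: list[str],
    times: list[np.ndarray] | None = None,
    rate_window: float = 5.0,
) -> TurnSummary:
    """Summarize turn directions across trials of cumulative-angle series.

    Each trial is a cumulative-angle series in revolutions (CCW positive).
    The net sign gives the turn direction; a trial injected in the left
    hemisphere is contralateral when it turns clockwise (negative), and vice
    versa. A reversal flag is set when the windowed angular rate changes
    sign after motion onset (|angle| first exceeding 5% of its net span).
    Trials with zero net angle are excluded with a warning.
    """
    if len(trials) != len(injected_side):
        raise ValueError("need one injected_side per trial")
    n_ccw = n_cw = n_contra = 0
    reversal_flags: list[bool] = []
    excluded: list[int] = []
    n_kept = 0
    for idx, (angle, side) in enumerate(zip(trials, injected_side)):
        angle = np.asarray(angle, dtype=float)
        net = angle[-1] - angle[0]
        if net == 0.0:
            warnings.warn(f"trial {idx} has zero net angle; excluded", stacklevel=2)
            excluded.append(idx)
            continue
        n_kept += 1
        sign = 1 if net > 0 else -1
        if sign > 0:
            n_ccw += 1
        else:
            n_cw += 1
        if side not in ("left", "right"):
            raise ValueError("injected_side entries must be 'left' or 'right'")
        contralateral = (side == "left" and sign < 0) or (
            side == "right" and sign > 0
        )
        n_contra += int(contralateral)

        # reversal: windowed rate changes sign after motion onset
        if times is not None:
            t = np.asarray(times[idx], dtype=float)
        else:
            t = np.arange(angle.size, dtype=float)
        onset_level = 0.05 * abs(net)
        moving = np.abs(angle - angle[0]) > onset_level
        start = int(np.argmax(moving)) if moving.any() else 0
        dt = t[1] - t[0]
        n_win = max(1, int(round(rate_window / dt)))
        rate = _moving_average(np.gradient(angle, t), n_win)
        after = rate[start:]
        significant = after[np.abs(after) > 0.05 * np.max(np.abs(rate))]
        reversal_flags.append(
            bool(significant.size and (significant.max() > 0 > significant.min()))
        )
    if n_kept == 0:
        raise ValueError("no usable trials (all zero net angle)")
    return TurnSummary(
        n_ccw=n_ccw,
        n_cw=n_cw,
        n_contralateral=n_contra,
        n_trials=n_kept,
        reversal_flags=reversal_flags,
        excluded_trials=excluded,
    )
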