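"""Seeded synthetic-data generators for every pipeline input.

Each generator emulates the statistical structure of one experimental data
stream — GCaMP6f calcium traces at 10 Hz with ~5% ΔF/F transients,
exponential photobleaching and Gaussian camera noise; DyLight 550
thermometry traces obeying the −2.2 %/°C calibration; calorimetric
heating-rate observations; open-field marker trajectories at 30 Hz in a
50-mm-radius arena (peripheral running, body-axis rotation, freezing of
gait, baseline exploration); and Poisson first-spike latencies — and
returns the generating ground truth alongside, so every analysis stage can
be tested end-to-end without any recorded data.

All randomness flows through a single integer seed; identical parameters
and seed give identical output.
"""

from __future__ import annotations

import math

import numpy as np

from .calcium import SpikeTemplate, SpikeTrain, LatencySet, default_template
from .kinematics import Trajectory
from .physics import HeatingObservation
from .thermometry import FluorescenceTrace, ThermoCalibration

__all__ = [
    "SCENARIOS",
    "gen_gcamp_trace",
    "gen_thermometry_trace",
    "gen_heating_observations",
    "gen_trajectory",
    "gen_scenario_trajectory",
    "gen_latencies",
]

#: Named behavioral scenario presets with the measured condition means:
#: motor-cortex stimulation (fast peripheral running vs slow exploration),
#: striatal stimulation (body-axis rotation, 22 mm head circles), and
#: deep-striatum freezing of gait.
SCENARIOS: dict[str, dict] = {
    "motor-cortex": {
        "off_mode": "explore",
        "on_mode": "peripheral_run",
        "off_params": {"mean_speed": 5.3},
        "on_params": {"speed": 83.8, "radius": 45.0},
        "duration": 180.0,
        "field_windows": [(60.0, 120.0)],
    },
    "striatum": {
        "off_mode": "explore",
        "on_mode": "body_rotation",
        "off_params": {"mean_speed": 5.3},
        "on_params": {"radius": 22.0, "rev_per_min": 4.7, "center": (15.0, 0.0)},
        "duration": 180.0,
        "field_windows": [(60.0, 120.0)],
    },
    "fog": {
        "off_mode": "explore",
        "on_mode": "fog",
        "off_params": {"mean_speed": 17.7},
        "on_params": {"speed_floor": 1.04},
        "duration": 180.0,
        "field_windows": [(60.0, 120.0)],
    },
}


def gen_gcamp_trace(
    spike_times: np.ndarray,
    duration: float,
    template: SpikeTemplate | None = None,
    noise_sigma: float = 0.5,
    bleach_tau: float | None = None,
    fs: float = 10.0,
    baseline: float = 1000.0,
    dark_noise: float = 100.0,
    seed: int = 0,
) -> tuple[FluorescenceTrace, SpikeTrain]:
    """Synthesize a raw GCaMP6f ROI trace with known spikes.

    The clean signal is baseline·exp(−t/bleach_tau)·(1 + Σᵢ template(t−tᵢ)/100);
    the camera adds a constant dark offset and Gaussian noise of
    ``noise_sigma`` percent of baseline. Returns the raw trace together with
    the generating spike train.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    if spike_times.size and (spike_times[0] < 0 or spike_times[-1] > duration):
        raise ValueError("spike_times must lie within [0, duration]")
    if template is None:
        template = default_template()
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    transients = np.zeros(n)
    tw = template.waveform
    for t_i in spike_times:
        rel = (t - t_i) * template.sample_rate
        k = np.round(rel).astype(int)
        ok = (k >= 0) & (k < tw.size)
        transients[ok] += tw[k[ok]]

    bleach = np.exp(-t / bleach_tau) if bleach_tau else np.ones(n)
    clean = baseline * bleach * (1.0 + transients / 100.0)
    noisy = clean + dark_noise + rng.normal(0.0, noise_sigma / 100.0 * baseline, n)
    trace = FluorescenceTrace(time=t, intensity=noisy, dark_noise=dark_noise)
    train = SpikeTrain(event_times=spike_times, duration=duration)
    return trace, train


def gen_thermometry_trace(
    temperature_profile: np.ndarray,
    calibration: ThermoCalibration = ThermoCalibration(),
    noise_sigma: float = 0.0,
    fs: float = 10.0,
    baseline: float = 1000.0,
    dark_noise: float = 0.0,
    seed: int = 0,
) -> FluorescenceTrace:
    """Synthesize a thermometer-dye intensity trace from a ΔT profile.

    intensity(t) = baseline·(1 + slope·ΔT(t)/100) + dark + noise; with the
    default −2.2 %/°C calibration a +2 °C plateau dips the intensity 4.4%.
    """
    profile = np.asarray(temperature_profile, dtype=float)
    rng = np.random.default_rng(seed)
    t = np.arange(profile.size) / fs
    intensity = baseline * (1.0 + calibration.slope * profile / 100.0)
    intensity = intensity + dark_noise
    if noise_sigma > 0:
        intensity = intensity + rng.normal(
            0.0, noise_sigma / 100.0 * baseline, profile.size
        )
    return FluorescenceTrace(time=t, intensity=intensity, dark_noise=dark_noise)


def gen_heating_observations(
    context: str = "suspension",
    true_slope: float = 5.8e-4,
    densities: np.ndarray | None = None,
    noise_sigma: float = 1e-5,
    intercept: float = 0.0,
    seed: int = 0,
) -> list[HeatingObservation]:
    """Synthesize calorimetric heating-rate observations on a known line.

    rate = slope·density + intercept + Gaussian noise, clipped at zero. The
    default slope is the measured suspension value 5.8e-4 °C·µm³/s;
    densities default to 20 points spaning the measured 0.1–0.5 °C/s range.
    """
    rng = np.random.default_rng(seed)
    if densities is None:
        densities = np.linspace(170.0, 900.0, 20)
    densities = np.asarray(densities, dtype=float)
    rates = true_slope * densities + intercept
    rates = rates + rng.normal(0.0, noise_sigma, densities.size)
    rates = np.clip(rates, 0.0, None)
    return [
        HeatingObservation(density=float(d), rate=float(r), context=context)
        for d, r in zip(densities, rates)
    ]


def _explore_track(
    n: int,
    fs: float,
    rng: np.random.Generator,
    mean_speed: float = 5.3,
    speed_cv: float = 0.1,
    heading_diffusion: float = 0.5,
    arena_radius: float = 50.0,
    start: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Bounded correlated random walk: near-constant step length with a
    slowly diffusing heading, steered back inside 85% of the arena radius."""
    xy = np.empty((n, 2))
    xy[0] = start
    theta = rng.uniform(0.0, 2.0 * math.pi)
    dt = 1.0 / fs
    for i in range(1, n):
        theta += rng.normal(0.0, heading_diffusion * math.sqrt(dt))
        v = mean_speed * max(0.0, 1.0 + speed_cv * rng.normal())
        step = np.array([math.cos(theta), math.sin(theta)]) * v * dt
        nxt = xy[i - 1] + step
        if np.hypot(*nxt) > 0.85 * arena_radius:
            # steer toward the center instead of crossing the wall
            theta = math.atan2(-xy[i - 1][1], -xy[i - 1][0]) + rng.normal(0.0, 0.3)
            step = np.array([math.cos(theta), math.sin(theta)]) * v * dt
            nxt = xy[i - 1] + step
        xy[i] = nxt
    return xy


def _circle_track(
    n: int,
    fs: float,
    rng: np.random.Generator,
    radius: float,
    rev_per_min: float,
    center: tuple[float, float] = (0.0, 0.0),
    jitter: float = 0.0,
    ccw: bool = True,
    phase: float = 0.0,
) -> np.ndarray:
    omega = (1.0 if ccw else -1.0) * rev_per_min * 2.0 * math.pi / 60.0
    t = np.arange(n) / fs
    ang = phase + omega * t
    xy = np.stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)], axis=1
    )
    if jitter > 0:
        xy = xy + rng.normal(0.0, jitter, xy.shape)
    return xy


def _fog_track(
    n: int,
    fs: float,
    rng: np.random.Generator,
    speed_floor: float = 0.52,
    center: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Stationary point plus positional jitter calibrated so the mean
    frame-to-frame speed equals ``speed_floor`` (the apparent speed of a
    fixed marker under tracking noise)."""
    # independent Gaussian jitter: |Δp| is Rayleigh with mean σ√2·√(π/2)
    sigma = speed_floor / (fs * math.sqrt(math.pi)) if speed_floor > 0 else 0.0
    xy = np.tile(np.asarray(center, dtype=float), (n, 1))
    if sigma > 0:
        xy = xy + rng.normal(0.0, sigma, xy.shape)
    return xy


def gen_trajectory(
    mode: str,
    duration: float,
    fs: float = 30.0,
    seed: int = 0,
    arena_radius: float = 50.0,
    **params,
) -> Trajectory:
    """Synthesize a marker trajectory in one of four behavioral modes.

    - ``peripheral_run``: circular path near the wall at a set linear speed
      (``speed``, mm/s) or angular rate (``rev_per_min``), with positional
      jitter — fast arena circling evoked by motor-cortex stimulation.
    - ``body_rotation``: a small circle (default 22 mm radius) about a
      settable off-center point — rotation around the body axis evoked by
      striatal stimulation.
    - ``fog``: stationary point with jitter calibrated to a target apparent
      speed (``speed_floor``) — freezing of gait.
    - ``explore``: bounded correlated random walk at a set mean speed
      (default 5.3 mm/s) — baseline exploration.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs)) + 1
    if mode == "peripheral_run":
        radius = params.pop("radius", 0.9 * arena_radius)
        if radius > arena_radius:
            raise ValueError("requested radius exceeds the arena radius")
        if "rev_per_min" in params:
            rev = params.pop("rev_per_min")
        else:
            speed = params.pop("speed", 83.8)
            rev = speed / (2.0 * math.pi * radius) * 60.0
        xy = _circle_track(
            n, fs, rng, radius=radius, rev_per_min=rev,
            jitter=params.pop("jitter", 0.0),
            ccw=params.pop("ccw", True), phase=params.pop("phase", 0.0),
        )
    elif mode == "body_rotation":
        radius = params.pop("radius", 22.0)
        center = params.pop("center", (15.0, 0.0))
        if radius + math.hypot(*center) > arena_radius:
            raise ValueError("rotation circle extends beyond the arena")
        xy = _circle_track(
            n, fs, rng, radius=radius,
            rev_per_min=params.pop("rev_per_min", 4.7), center=center,
            jitter=params.pop("jitter", 0.0),
            ccw=params.pop("ccw", True), phase=params.pop("phase", 0.0),
        )
    elif mode == "fog":
        xy = _fog_track(
            n, fs, rng,
            speed_floor=params.pop("speed_floor", 0.52),
            center=params.pop("center", (0.0, 0.0)),
        )
    elif mode == "explore":
        xy = _explore_track(
            n, fs, rng,
            mean_speed=params.pop("mean_speed", 5.3),
            speed_cv=params.pop("speed_cv", 0.1),
            heading_diffusion=params.pop("heading_diffusion", 0.5),
            arena_radius=arena_radius,
            start=params.pop("start", (0.0, 0.0)),
        )
    else:
        raise ValueError(f"unknown trajectory mode {mode!r}")
    if params:
        raise TypeError(f"unused parameters for mode {mode!r}: {sorted(params)}")
    t = np.arange(n) / fs
    return Trajectory(time=t, x=xy[:, 0], y=xy[:, 1], arena_radius=arena_radius)


def gen_scenario_trajectory(
    scenario: str, seed: int = 0, fs: float = 30.0
) -> tuple[Trajectory, list[tuple[float, float]]]:
    """Full-session trajectory for a named scenario preset.

    Concatenates off-mode and on-mode segments around the preset's field
    windows (the segments join continuously in position). Returns the
    trajectory and the field windows.
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}"
        )
    cfg = SCENARIOS[scenario]
    rng = np.random.default_rng(seed)
    duration = cfg["duration"]
    windows = cfg["field_windows"]
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    on_mask = np.zeros(n, dtype=bool)
    for lo, hi in windows:
        on_mask |= (t >= lo) & (t < hi)

    # build each contiguous segment in its own mode, chaining start points
    xy = np.empty((n, 2))
    seg_start = 0
    pos = (0.0, 0.0)
    while seg_start < n:
        seg_on = on_mask[seg_start]
        seg_end = seg_start
        while seg_end < n and on_mask[seg_end] == seg_on:
            seg_end += 1
        m = seg_end - seg_start
        seg_seed = int(rng.integers(0, 2**31 - 1))
        mode = cfg["on_mode"] if seg_on else cfg["off_mode"]
        prm = dict(cfg["on_params"] if seg_on else cfg["off_params"])
        seg_duration = (m - 1) / fs if m > 1 else 1.0 / fs
        if mode == "explore":
            prm["start"] = pos
        elif mode in ("peripheral_run", "body_rotation"):
            # start the circle at the phase closest to the current position
            center = prm.get("center", (0.0, 0.0))
            prm["phase"] = math.atan2(pos[1] - center[1], pos[0] - center[0])
        elif mode == "fog":
            prm["center"] = pos
        traj = gen_trajectory(mode, seg_duration, fs=fs, seed=seg_seed, **prm)
        xy[seg_start:seg_end, 0] = traj.x[:m]
        xy[seg_start:seg_end, 1] = traj.y[:m]
        pos = (float(xy[seg_end - 1, 0]), float(xy[seg_end - 1, 1]))
        seg_start = seg_end
    return Trajectory(time=t, x=xy[:, 0], y=xy[:, 1]), list(windows)


def gen_latencies(
    lambda_s: float, n: int, seed: int = 0
) -> LatencySet:
    """Draw first-spike latencies: integer bins from a Poisson law with mean
    ``lambda_s`` plus uniform within-bin jitter."""
    rng = np.random.default_rng(seed)
    if n < 0:
        raise ValueError("n must be >= 0")
    k = rng.poisson(lambda_s, size=n).astype(float)
    return LatencySet(latencies=k + rng.uniform(0.0, 1.0, size=n))
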