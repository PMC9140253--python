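"""Jerk-limited (S-curve) point-to-point motion profiles.

The concussive stimulus in the assay is a single earth-vertical stroke of a
linear motor: the capsule holding the larvae is accelerated gently and then
brought to rest by an abrupt deceleration.  The stroke is specified the way
industrial motion controllers specify it — by a set of kinematic limits
(maximal velocity, acceleration, deceleration and jerk) plus start and end
positions — and realised as a seven-phase jerk-limited S-curve:

    1. jerk  +j   (acceleration ramps 0 -> +a)
    2. jerk   0   (constant acceleration +a)
    3. jerk  -j   (acceleration ramps +a -> 0; velocity reaches its peak)
    4. jerk   0   (constant-velocity cruise)
    5. jerk  -j   (deceleration ramps 0 -> -d)
    6. jerk   0   (constant deceleration -d)
    7. jerk  +j   (deceleration ramps -d -> 0; comes to rest at the target)

Acceleration and deceleration magnitudes are limited independently (the
braking phase is far harder than the launch), both sharing the jerk limit.
When the commanded travel is too short for every limit to be attained the
phases collapse in a fixed order: the cruise shrinks to zero first, then the
peak velocity is reduced below its limit, and finally the acceleration
phases become triangular (peak acceleration below its limit).

Profiles are evaluated from the closed-form piecewise polynomials of each
phase on a uniform time grid, so the kinematic invariants (derivative
relations between position, velocity, acceleration and jerk) hold to
machine precision rather than to an integrator's tolerance.

Units follow the motor controller's convention: positions in mm, velocity
in m/s, acceleration in m/s^2, jerk in m/s^3, time in s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

#: standard gravity, m/s^2
G_0 = 9.80665

__all__ = [
    "MotionLimits",
    "MotionProfile",
    "ProfileMetrics",
    "InfeasibleLimitsError",
    "generate_profile",
    "profile_metrics",
    "to_g",
    "trapezoid_duration",
    "write_oscilloscope_readout",
    "read_oscilloscope_readout",
]


class InfeasibleLimitsError(ValueError):
    """Raised when a kinematic limit set cannot produce a valid motion."""


@dataclass(frozen=True)
class MotionLimits:
    """Kinematic limit set for a point-to-point stroke.

    Parameters
    ----------
    start_position, end_position:
        Commanded endpoints in mm, signed relative to the home position.
    v_max:
        Velocity limit, m/s.
    a_max:
        Acceleration limit for the launch phase, m/s^2.
    d_max:
        Deceleration limit for the braking phase, m/s^2.
    j_max:
        Jerk limit shared by all ramps, m/s^3.  ``math.inf`` yields the
        classical trapezoidal velocity profile.
    dt:
        Sampling interval of the output grid, s.
    """

    start_position: float
    end_position: float
    v_max: float
    a_max: float
    d_max: float
    j_max: float
    dt: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("v_max", "a_max", "d_max", "j_max", "dt"):
            value = getattr(self, name)
            if not value > 0 or math.isnan(value):
                raise InfeasibleLimitsError(f"{name} must be positive, got {value!r}")
        if self.dt == math.inf:
            raise InfeasibleLimitsError("dt must be finite")
        for name in ("start_position", "end_position"):
            if not math.isfinite(getattr(self, name)):
                raise InfeasibleLimitsError(f"{name} must be finite")

    @property
    def travel_length_mm(self) -> float:
        return abs(self.end_position - self.start_position)


@dataclass(frozen=True)
class MotionProfile:
    """Sampled trajectory on a uniform time grid (last sample may be partial)."""

    time: np.ndarray          # s
    position: np.ndarray      # mm, absolute
    velocity: np.ndarray      # m/s
    acceleration: np.ndarray  # m/s^2
    jerk: np.ndarray          # m/s^3

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("position", "velocity", "acceleration", "jerk"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array length mismatch: {name} has "
                                 f"{len(getattr(self, name))} samples, time has {n}")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class ProfileMetrics:
    """Oscilloscope-style scalar summary of a sampled profile."""

    duration_ms: float
    travel_length_mm: float
    peak_velocity: float        # m/s
    peak_acceleration: float    # m/s^2, launch direction
    peak_deceleration: float    # m/s^2, magnitude
    peak_deceleration_g: float  # in units of standard gravity


def to_g(acceleration: float) -> float:
    """Convert an acceleration in m/s^2 to multiples of standard gravity."""
    if not math.isfinite(acceleration):
        raise ValueError("acceleration must be finite")
    return acceleration / G_0


def trapezoid_duration(length_m: float, v: float, a: float, d: float) -> float:
    """Closed-form duration of the infinite-jerk (trapezoidal) profile.

    Valid when the travel is long enough for the velocity limit to be
    reached: T = L/v + v/(2a) + v/(2d).
    """
    return length_m / v + v / (2 * a) + v / (2 * d)


# ---------------------------------------------------------------------------
# phase solving


def _ramp(v: float, a_lim: float, j: float) -> tuple[float, float, float]:
    """Times of one jerk-bounded velocity ramp 0 -> v.

    Returns ``(t_j, t_const, a_peak)``: jerk-phase time, constant-
    acceleration time and attained peak acceleration.  The ramp is
    trapezoidal in acceleration when v >= a_lim^2/j, else triangular.
    """
    if math.isinf(j):
        return 0.0, v / a_lim, a_lim
    if v >= a_lim * a_lim / j:
        return a_lim / j, v / a_lim - a_lim / j, a_lim
    t_j = math.sqrt(v / j)
    return t_j, 0.0, j * t_j


def _ramp_distance(v: float, a_lim: float, j: float) -> float:
    # velocity is antisymmetric about the ramp midpoint: mean speed v/2
    t_j, t_c, _ = _ramp(v, a_lim, j)
    return v * (2 * t_j + t_c) / 2


def _solve_phases(L: float, lim: MotionLimits) -> list[tuple[float, float]]:
    """Return the (duration, jerk) list for travel ``L`` metres (> 0)."""
    v_max, a, d, j = lim.v_max, lim.a_max, lim.d_max, lim.j_max

    def overshoot(v: float) -> float:
        return _ramp_distance(v, a, j) + _ramp_distance(v, d, j) - L

    if overshoot(v_max) <= 0:
        v_peak = v_max
        t_cruise = -overshoot(v_max) / v_max
    else:
        # short travel: no cruise, peak velocity below its limit
        v_peak = brentq(overshoot, 1e-12 * v_max, v_max, xtol=1e-15, rtol=1e-14)
        t_cruise = 0.0

    tj_a, tc_a, _ = _ramp(v_peak, a, j)
    tj_d, tc_d, _ = _ramp(v_peak, d, j)
    phases = [
        ("jerk-up (launch)", tj_a, j),
        ("constant-acceleration", tc_a, 0.0),
        ("jerk-down (launch)", tj_a, -j),
        ("constant-velocity cruise", t_cruise, 0.0),
        ("jerk-down (braking)", tj_d, -j),
        ("constant-deceleration", tc_d, 0.0),
        ("jerk-up (braking)", tj_d, j),
    ]
    active = [(name, t, jk) for name, t, jk in phases if t > 0.0]
    for name, t, _ in active:
        if t < lim.dt:
            raise InfeasibleLimitsError(
                f"sampling interval dt={lim.dt} s exceeds the "
                f"{name} phase duration ({t:.6g} s); reduce dt"
            )
    return [(t, jk) for _, t, jk in active]


def generate_profile(limits: MotionLimits) -> MotionProfile:
    """Generate the jerk-limited S-curve profile for a kinematic limit set.

    Phase durations are solved so that every applicable limit is attained
    whenever the travel length permits; shorter travels collapse phases in
    the documented order (cruise, then peak velocity, then triangular
    acceleration ramps).  A zero-length travel yields a degenerate single-
    sample profile at rest.
    """
    travel_m = (limits.end_position - limits.start_position) / 1000.0
    if travel_m == 0.0:
        z = np.zeros(1)
        return MotionProfile(
            time=z.copy(),
            position=np.full(1, float(limits.start_position)),
            velocity=z.copy(), acceleration=z.copy(), jerk=z.copy(),
        )
    sign = 1.0 if travel_m > 0 else -1.0
    phases = _solve_phases(abs(travel_m), limits)

    durations = np.array([t for t, _ in phases])
    jerks = np.array([jk for _, jk in phases])
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    total = starts[-1]

    # propagate (x, v, a) analytically to each phase boundary
    x0 = np.empty(len(phases)); v0 = np.empty(len(phases)); a0 = np.empty(len(phases))
    x, v, a = 0.0, 0.0, 0.0
    for i, (t, jk) in enumerate(phases):
        x0[i], v0[i], a0[i] = x, v, a
        x += v * t + a * t * t / 2 + jk * t ** 3 / 6
        v += a * t + jk * t * t / 2
        a += jk * t
    # by construction the final state is at rest exactly at the target;
    # clamp residual round-off
    x = abs(travel_m)

    grid = np.arange(0.0, total, limits.dt)
    if total - grid[-1] > 1e-12:
        grid = np.append(grid, total)
    else:
        grid[-1] = total

    idx = np.minimum(np.searchsorted(starts, grid, side="right") - 1, len(phases) - 1)
    tau = grid - starts[idx]
    jk = jerks[idx]
    acc = a0[idx] + jk * tau
    vel = v0[idx] + a0[idx] * tau + jk * tau ** 2 / 2
    pos = x0[idx] + v0[idx] * tau + a0[idx] * tau ** 2 / 2 + jk * tau ** 3 / 6
    # pin the endpoints to exact rest
    vel[0] = vel[-1] = 0.0
    acc[0] = acc[-1] = 0.0
    pos[-1] = x

    return MotionProfile(
        time=grid,
        position=limits.start_position + sign * pos * 1000.0,
        velocity=sign * vel,
        acceleration=sign * acc,
        jerk=sign * jk.astype(float),
    )


def profile_metrics(profile: MotionProfile) -> ProfileMetrics:
    """Scalar kinematic summary (duration, travel, peak values) of a profile."""
    if len(profile) == 0:
        raise ValueError("empty profile")
    direction = math.copysign(1.0, profile.position[-1] - profile.position[0]) \
        if profile.position[-1] != profile.position[0] else 1.0
    a_dir = direction * profile.acceleration
    peak_dec = float(max(0.0, -a_dir.min()))
    return ProfileMetrics(
        duration_ms=float((profile.time[-1] - profile.time[0]) * 1000.0),
        travel_length_mm=float(abs(profile.position[-1] - profile.position[0])),
        peak_velocity=float(np.abs(profile.velocity).max()),
        peak_acceleration=float(max(0.0, a_dir.max())),
        peak_deceleration=peak_dec,
        peak_deceleration_g=to_g(peak_dec),
    )


# ---------------------------------------------------------------------------
# oscilloscope-style readout

_READOUT_COLUMNS = ["time_ms", "position_mm", "velocity_m_s",
                    "acceleration_m_s2", "jerk_m_s3"]


def write_oscilloscope_readout(profile: MotionProfile, destination) -> None:
    """Write a profile as the comma-delimited oscilloscope readout.

    One row per sample; columns ``time_ms, position_mm, velocity_m_s,
    acceleration_m_s2, jerk_m_s3``; floats with 6 significant digits.
    """
    frame = pd.DataFrame({
        "time_ms": profile.time * 1000.0,
        "position_mm": profile.position,
        "velocity_m_s": profile.velocity,
        "acceleration_m_s2": profile.acceleration,
        "jerk_m_s3": profile.jerk,
    })
    frame.to_csv(destination, index=False, float_format="%.6g")


def read_oscilloscope_readout(source) -> MotionProfile:
    """Read a readout written by :func:`write_oscilloscope_readout`."""
    frame = pd.read_csv(source)
    missing = [c for c in _READOUT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"readout is missing columns: {missing}")
    return MotionProfile(
        time=frame["time_ms"].to_numpy() / 1000.0,
        position=frame["position_mm"].to_numpy(),
        velocity=frame["velocity_m_s"].to_numpy(),
        acceleration=frame["acceleration_m_s2"].to_numpy(),
        jerk=frame["jerk_m_s3"].to_numpy(),
    )
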