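"""Target temperature-time profiles and scan protocol constants.

Temperature targets are expressed as elevations ΔT (°C) above a uniform body
temperature.  A regulation profile is a piecewise-linear curve alternating
ramps (capped at 15 °C/min, slow enough that the temporal Kalman filter does
not lag) and plateaus; outside the heating window the target is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAMMA_PROTON_HZ_PER_T",
    "MAX_RAMP_RATE_C_PER_MIN",
    "ScanProtocol",
    "PlateauSpec",
    "TargetProfile",
    "build_profile",
]

#: CODATA proton gyromagnetic ratio, Hz/T.
GAMMA_PROTON_HZ_PER_T = 42.577478518e6

#: Fastest allowed target ramp, °C/min.
MAX_RAMP_RATE_C_PER_MIN = 15.0


@dataclass(frozen=True)
class ScanProtocol:
    """Dynamic MR thermometry acquisition constants.

    Defaults reproduce a single-shot EPI protocol on a 1.5 T scanner:
    8 slices per second, TE 21 ms, 1.4×1.4×3 mm voxels, PRF coefficient
    −0.0094 ppm/°C.
    """

    field_strength: float = 1.5            # T
    echo_time: float = 0.021               # s
    frame_interval: float = 1.0            # s
    prf_coefficient: float = -0.0094e-6    # (dimensionless) per °C
    gyromagnetic_ratio: float = GAMMA_PROTON_HZ_PER_T  # Hz/T
    voxel_size: tuple[float, float, float] = (1.4, 1.4, 3.0)  # mm
    n_slices: int = 8

    def __post_init__(self) -> None:
        if self.field_strength <= 0:
            raise ValueError("field_strength must be positive")
        if self.echo_time <= 0:
            raise ValueError("echo_time must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.prf_coefficient >= 0:
            raise ValueError("prf_coefficient must be negative (water PRF)")
        if any(d <= 0 for d in self.voxel_size):
            raise ValueError("voxel dimensions must be positive")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


@dataclass(frozen=True)
class PlateauSpec:
    """Compact description of a staircase heating profile.

    ``levels[i]`` is held for ``durations[i]`` seconds; consecutive levels are
    joined by linear ramps at ``ramp_rate`` °C/min (the first ramp starts
    from 0).
    """

    levels: tuple[float, ...]
    durations: tuple[float, ...]
    ramp_rate: float = MAX_RAMP_RATE_C_PER_MIN  # °C/min

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(float(v) for v in self.levels))
        object.__setattr__(self, "durations", tuple(float(v) for v in self.durations))
        if len(self.levels) != len(self.durations):
            raise ValueError("levels and durations must have equal length")
        if any(d <= 0 for d in self.durations):
            raise ValueError("plateau durations must be positive")
        if not (0 < self.ramp_rate <= MAX_RAMP_RATE_C_PER_MIN):
            raise ValueError(
                f"ramp_rate must be in (0, {MAX_RAMP_RATE_C_PER_MIN}] °C/min"
            )


@dataclass(frozen=True)
class TargetProfile:
    """Piecewise-linear target elevation ΔT(t).

    ``breakpoints`` is an ordered sequence of (time s, ΔT °C); the target is
    interpolated linearly between breakpoints and is 0 before the first and
    after the last one.  ``body_temperature`` is only needed to convert to
    absolute temperature for thermal-dose accounting.
    """

    breakpoints: tuple[tuple[float, float], ...]
    body_temperature: float = 37.0
    _times: np.ndarray = field(init=False, repr=False, compare=False)
    _temps: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pts = tuple((float(t), float(v)) for t, v in self.breakpoints)
        object.__setattr__(self, "breakpoints", pts)
        times = np.array([t for t, _ in pts])
        temps = np.array([v for _, v in pts])
        if len(pts):
            if np.any(np.diff(times) <= 0):
                raise ValueError("breakpoint times must be strictly increasing")
            if temps[0] != 0.0:
                raise ValueError("profile must start at ΔT = 0")
            slopes = np.diff(temps) / np.diff(times) * 60.0
            if np.any(np.abs(slopes) > MAX_RAMP_RATE_C_PER_MIN + 1e-9):
                raise ValueError(
                    f"profile slope exceeds {MAX_RAMP_RATE_C_PER_MIN} °C/min"
                )
        object.__setattr__(self, "_times", times)
        object.__setattr__(self, "_temps", temps)

    @property
    def end_time(self) -> float:
        """Time of the last breakpoint (heating stop), 0 for an empty profile."""
        return float(self._times[-1]) if len(self._times) else 0.0

    def __call__(self, t):
        return eval_target(self, t)

    def slope(self, t: float) -> float:
        """Analytic target slope ∂T_t/∂t (°C/s) on the segment containing t.

        Uses the right-continuous segment [t_i, t_{i+1}); 0 outside the
        profile support.
        """
        times, temps = self._times, self._temps
        if len(times) < 2 or t < times[0] or t >= times[-1]:
            return 0.0
        i = int(np.searchsorted(times, t, side="right") - 1)
        return float((temps[i + 1] - temps[i]) / (times[i + 1] - times[i]))


def eval_target(profile: TargetProfile, t):
    """Evaluate the target elevation ΔT(t) in °C.

    Accepts a scalar or array of times (s, all ≥ 0); linear interpolation
    between breakpoints, 0 outside their span.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    times, temps = profile._times, profile._temps
    if len(times) == 0:
        out = np.zeros_like(t_arr)
    else:
        out = np.interp(t_arr, times, temps, left=0.0, right=0.0)
        # np.interp clamps to the edge values; enforce 0 outside the support
        out = np.where((t_arr < times[0]) | (t_arr > times[-1]), 0.0, out)
    return out if out.ndim else float(out)


def build_profile(
    spec: PlateauSpec,
    body_temperature: float = 37.0,
    start_time: float = 0.0,
) -> TargetProfile:
    """Expand a plateau staircase into an explicit piecewise-linear profile.

    Each plateau is preceded by a linear ramp at ``spec.ramp_rate`` from the
    previous level (starting level 0 at ``start_time``).  The profile ends
    when the last plateau ends; afterwards the target is 0 (free cooling).
    """
    if not spec.levels:
        return TargetProfile((), body_temperature=body_temperature)
    rate_per_s = spec.ramp_rate / 60.0
    t = float(start_time)
    level = 0.0
    pts: list[tuple[float, float]] = [(t, 0.0)]
    for target_level, duration in zip(spec.levels, spec.durations):
        ramp = abs(target_level - level) / rate_per_s
        if ramp > 0:
            t += ramp
            pts.append((t, target_level))
        t += duration
        pts.append((t, target_level))
        level = target_level
    return TargetProfile(tuple(pts), body_temperature=body_temperature)
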