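"""Test-shot calibration of the tissue thermal parameters.

A brief low-power emission (gel preset 3 W / 20 s, in-vivo preset 2 W / 30 s,
110 s recorded) locates the hotspot, defines the 3×3×3 control ROI, and
yields the two controller inputs:

* absorption α from a nonlinear fit of the hottest-voxel temperature curve to
  the logarithmic point-source heating/cooling model;
* diffusivity D from the growth of the in-plane Gaussian width of the cooling
  hotspot, σ²(t) increasing linearly with slope 2D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .bhte import TemperatureFrame, hotspot_curve_model

__all__ = [
    "CalibrationError",
    "ControlROI",
    "AbsorptionFit",
    "DiffusionFit",
    "locate_hotspot_roi",
    "fit_absorption",
    "fit_diffusion",
    "calibrate_from_frames",
]

ROI_HALF = 1  # 3×3×3 block

GEL_SHOT = dict(power=3.0, on_duration=20.0)
IN_VIVO_SHOT = dict(power=2.0, on_duration=30.0)
SHOT_RECORD_DURATION = 110.0


class CalibrationError(RuntimeError):
    """Raised when the test shot cannot yield usable thermal parameters."""


@dataclass
class ControlROI:
    """3×3×3 voxel control region centred on the test-shot hotspot.

    Clipped at grid borders (at least 8 voxels survive); ``valid`` flags are
    refreshed dynamically during regulation.
    """

    center: tuple[int, int, int]
    indices: np.ndarray          # (n, 3) member voxel indices
    valid: np.ndarray            # (n,) bool
    grid_shape: tuple[int, int, int]

    @classmethod
    def centered(cls, center, grid_shape) -> "ControlROI":
        center = tuple(int(c) for c in center)
        if any(not (0 <= c < n) for c, n in zip(center, grid_shape)):
            raise ValueError("ROI center outside the grid")
        ranges = []
        clipped = False
        for c, n in zip(center, grid_shape):
            lo, hi = c - ROI_HALF, c + ROI_HALF + 1
            if lo < 0 or hi > n:
                clipped = True
            ranges.append(np.arange(max(lo, 0), min(hi, n)))
        if clipped:
            warnings.warn("control ROI clipped at grid border", stacklevel=2)
        grid = np.meshgrid(*ranges, indexing="ij")
        indices = np.stack([g.ravel() for g in grid], axis=1)
        return cls(center, indices, np.ones(len(indices), dtype=bool), tuple(grid_shape))

    def linear_indices(self) -> np.ndarray:
        return np.ravel_multi_index(self.indices.T, self.grid_shape)


def _frame_stack(frames) -> tuple[np.ndarray, np.ndarray]:
    """(x, y, z, t) stack and times from TemperatureFrames or raw arrays."""
    if isinstance(frames, np.ndarray) and frames.ndim == 4:
        return frames, np.arange(frames.shape[3], dtype=float)
    stack = np.stack([np.asarray(f.delta_t) for f in frames], axis=-1)
    times = np.array([f.time for f in frames], dtype=float)
    return stack, times


def locate_hotspot_roi(frames, baseline_std: float = 0.0) -> ControlROI:
    """Centre the control ROI on the hottest voxel over the whole shot.

    Requires the peak elevation to exceed 3× the baseline temperature STD;
    ties resolve to the lowest linear voxel index.
    """
    stack, _ = _frame_stack(frames)
    peak = stack.max(axis=3)
    if peak.max() <= 3.0 * baseline_std:
        raise CalibrationError(
            f"test shot too weak: peak {peak.max():.3g} °C <= "
            f"3 x baseline STD ({baseline_std:.3g} °C)"
        )
    center = np.unravel_index(int(np.argmax(peak)), peak.shape)
    return ControlROI.centered(center, peak.shape)


@dataclass
class AbsorptionFit:
    """Result of the hottest-voxel logarithmic curve fit."""

    alpha: float          # °C s⁻¹ W⁻¹
    tau: float            # s, characteristic diffusion time
    t_on: float
    t_off: float
    power: float
    residual_rms: float   # °C


def fit_absorption(
    times: np.ndarray,
    temps: np.ndarray,
    power: float,
    t_on: float,
    t_off: float,
    tau_starts: tuple[float, ...] = (1.0, 5.0, 20.0, 60.0),
) -> AbsorptionFit:
    """Nonlinear least squares for (α, τ) with P, t_on, t_off fixed and known.

    Multi-start over τ; bounds α ∈ (0, 10], τ ∈ [0.1, 300] s.  The best
    residual wins; failure of every start (or a degenerate all-zero curve)
    raises :class:`CalibrationError`.
    """
    times = np.asarray(times, dtype=float)
    temps = np.asarray(temps, dtype=float)
    if power <= 0:
        raise ValueError("power must be positive")
    if times.shape != temps.shape:
        raise ValueError("times and temps must match")
    if np.all(temps == 0) or not np.any(np.isfinite(temps)):
        raise CalibrationError("hottest-voxel curve is degenerate (all zero)")

    def residual(p):
        return hotspot_curve_model(times, p[0], power, p[1], t_on, t_off) - temps

    alpha0 = max(temps.max() / max(power * (t_off - t_on), 1e-9), 1e-3)
    best = None
    for tau0 in tau_starts:
        try:
            sol = least_squares(
                residual, x0=[alpha0, tau0],
                bounds=([1e-6, 0.1], [10.0, 300.0]),
            )
        except Exception:
            continue
        if not sol.success or not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise CalibrationError("absorption fit failed to converge from all starts")
    rms = float(np.sqrt(np.mean(residual(best.x) ** 2)))
    return AbsorptionFit(
        alpha=float(best.x[0]), tau=float(best.x[1]),
        t_on=t_on, t_off=t_off, power=power, residual_rms=rms,
    )


@dataclass
class DiffusionFit:
    """Result of the cooling-phase Gaussian width-growth fit."""

    diffusion: float       # D = slope/2, mm² s⁻¹
    slope: float           # dσ²/dt, mm²/s
    times: np.ndarray      # s, frames used
    sigmas: np.ndarray     # mm, fitted widths per frame
    amplitudes: np.ndarray # °C, fitted peak amplitudes per frame
    r_squared: float
    method: str


def _fit_gaussian_2d(plane: np.ndarray, dx: float, dy: float,
                     center_xy: tuple[int, int], window_radius: int):
    """Isotropic 2D Gaussian (free amplitude and centre, zero offset) on a window."""
    nx, ny = plane.shape
    i0, i1 = max(center_xy[0] - window_radius, 0), min(center_xy[0] + window_radius + 1, nx)
    j0, j1 = max(center_xy[1] - window_radius, 0), min(center_xy[1] + window_radius + 1, ny)
    sub = plane[i0:i1, j0:j1]
    x = np.arange(i0, i1)[:, None] * dx
    y = np.arange(j0, j1)[None, :] * dy
    amp0 = float(sub.max())
    if amp0 <= 0:
        raise CalibrationError("no positive signal in Gaussian-fit window")
    pk = np.unravel_index(int(np.argmax(sub)), sub.shape)
    cx0, cy0 = float(x[pk[0], 0]), float(y[0, pk[1]])
    # second-moment width seed over the window
    w = np.clip(sub, 0, None)
    tot = w.sum()
    sig0 = float(
        np.sqrt(
            ((w * ((x - cx0) ** 2 + (y - cy0) ** 2)).sum() / max(tot, 1e-12)) / 2.0
        )
    )
    sig0 = min(max(sig0, 0.5 * min(dx, dy)), window_radius * max(dx, dy))

    def residual(p):
        a, cx, cy, s = p
        return (a * np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * s**2)))).ravel() - sub.ravel()

    sol = least_squares(
        residual, x0=[amp0, cx0, cy0, sig0],
        bounds=([0.0, x.min(), y.min(), 0.1 * min(dx, dy)],
                [np.inf, x.max(), y.max(), 10 * window_radius * max(dx, dy)]),
    )
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise CalibrationError("2D Gaussian fit diverged")
    return float(sol.x[0]), float(sol.x[3])


def fit_diffusion(
    frames,
    times: np.ndarray | None = None,
    slice_index: int | None = None,
    center: tuple[int, int] | None = None,
    voxel_size: tuple[float, float, float] = (1.4, 1.4, 3.0),
    window_radius: int = 15,
    method: str = "sigma_squared",
) -> DiffusionFit:
    """Estimate D from the in-plane spread of the cooling hotspot.

    Per cooling frame, an isotropic 2D Gaussian is fitted on the hottest
    slice; the default estimator then regresses σ² on time (slope 2D, the
    dimensionally exact form).  ``method="sigma"`` instead fits σ(t) with a
    line of slope s and converts via D = s·σ̄ (the local tangent of
    σ = √(2Dt)), kept for comparison with width-versus-time plots.
    """
    stack, t_auto = _frame_stack(frames)
    t = np.asarray(times, dtype=float) if times is not None else t_auto
    if stack.shape[3] < 3:
        raise CalibrationError("need >= 3 cooling frames for the diffusion fit")
    if method not in ("sigma_squared", "sigma"):
        raise ValueError("method must be 'sigma_squared' or 'sigma'")
    if slice_index is None or center is None:
        pk = np.unravel_index(int(np.argmax(stack[..., 0])), stack.shape[:3])
        slice_index = pk[2] if slice_index is None else slice_index
        center = pk[:2] if center is None else center
    dx, dy, _ = voxel_size
    sigmas, amps, used_t = [], [], []
    failures = 0
    for k in range(stack.shape[3]):
        try:
            a, s = _fit_gaussian_2d(stack[:, :, slice_index, k], dx, dy,
                                    center, window_radius)
        except CalibrationError:
            failures += 1
            continue
        amps.append(a)
        sigmas.append(s)
        used_t.append(t[k])
    if failures > 0.3 * stack.shape[3] or len(sigmas) < 3:
        raise CalibrationError(
            f"Gaussian fit diverged on {failures}/{stack.shape[3]} cooling frames"
        )
    used_t = np.asarray(used_t)
    sigmas = np.asarray(sigmas)
    if method == "sigma_squared":
        yv = sigmas**2
        slope, intercept = np.polyfit(used_t, yv, 1)
        diffusion = slope / 2.0
    else:
        yv = sigmas
        s_lin, intercept = np.polyfit(used_t, yv, 1)
        slope = 2.0 * s_lin * float(np.mean(sigmas))  # dσ²/dt = 2σ·dσ/dt
        diffusion = s_lin * float(np.mean(sigmas))
    fit_y = np.polyval([slope, intercept] if method == "sigma_squared"
                       else [s_lin, intercept], used_t)
    ss_res = float(np.sum((yv - fit_y) ** 2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DiffusionFit(
        diffusion=float(max(diffusion, 0.0)), slope=float(slope),
        times=used_t, sigmas=sigmas, amplitudes=np.asarray(amps),
        r_squared=r2, method=method,
    )


def calibrate_from_frames(
    frames,
    power: float,
    t_on: float,
    t_off: float,
    voxel_size: tuple[float, float, float] = (1.4, 1.4, 3.0),
    baseline_std: float = 0.0,
    cooling_start_offset: float = 5.0,
    window_radius: int = 15,
) -> dict:
    """Full test-shot analysis: ROI, α fit and D fit from one frame series.

    ``frames`` is the recorded ΔT series (filtered in the full pipeline);
    the diffusion fit uses frames later than ``t_off + cooling_start_offset``.
    Returns a dict with keys ``roi``, ``absorption``, ``diffusion``.
    """
    stack, times = _frame_stack(frames)
    roi = locate_hotspot_roi(frames, baseline_std=baseline_std)
    cx, cy, cz = roi.center
    curve = stack[cx, cy, cz, :]
    absorption = fit_absorption(times, curve, power, t_on, t_off)
    cooling = times > t_off + cooling_start_offset
    if cooling.sum() < 3:
        raise CalibrationError("fewer than 3 cooling frames recorded")
    diffusion = fit_diffusion(
        stack[..., cooling], times=times[cooling], slice_index=cz,
        center=(cx, cy), voxel_size=voxel_size, window_radius=window_radius,
    )
    return {"roi": roi, "absorption": absorption, "diffusion": diffusion}
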