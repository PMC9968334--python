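"""PID + bioheat power computation.

Each frame the controller tracks the hottest valid voxel of the 3×3×3
control ROI and solves the model-inverting PID law

    P = (1/α) [ ∂T_t/∂t − D·∇²T_m + q·ξ + (q²/4)·∫ξ dτ ],   ξ = T_t − T_m,

whose closed-loop error equation has the critically damped double root −q/2
(response time t_r = 2/q).  The Laplacian at the control voxel is a 7-point
finite-difference stencil, temporally smoothed with binomial weights
[1, 4, 6, 4, 1] — by symmetry the smoothed value estimates the Laplacian two
frames back, an accepted group delay at the 1 s cadence.

Actuator saturation (0 to the 27 W diode limit) freezes the error integral
(anti-windup); without this the clamp destabilizes ramps.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .bhte import ThermoParams
from .calibration import ControlROI

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "refresh_roi_validity",
    "select_control_voxel",
    "point_laplacian",
    "smoothed_laplacian",
    "compute_power",
]

LAPLACIAN_WEIGHTS = (1, 4, 6, 4, 1)
ROI_STD_LIMIT_C = 1.0


@dataclass(frozen=True)
class ControllerConfig:
    """Gains, calibration and actuator limits of the power controller."""

    params: ThermoParams
    q: float = 0.25                 # s⁻¹
    max_power: float = 27.0         # W
    laplacian_weights: tuple[int, ...] = LAPLACIAN_WEIGHTS
    frame_interval: float = 1.0     # s
    std_limit: float = ROI_STD_LIMIT_C  # °C, ROI validity threshold

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError("q must be positive")
        if self.max_power <= 0:
            raise ValueError("max_power must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if len(self.laplacian_weights) == 0 or any(
            w < 0 for w in self.laplacian_weights
        ):
            raise ValueError("laplacian_weights must be non-negative")

    @property
    def response_time(self) -> float:
        """Controller response time t_r = 2/q (s)."""
        return 2.0 / self.q


@dataclass
class ControllerState:
    """Mutable per-session controller memory."""

    integral: float = 0.0                        # ∫ξ dτ, °C·s
    lap_history: deque = field(default_factory=lambda: deque(maxlen=5))
    control_voxel: tuple[int, int, int] | None = None
    last_power: float = 0.0
    last_raw_power: float = 0.0
    saturated: bool = False


def refresh_roi_validity(
    roi: ControlROI,
    snr_mask: np.ndarray,
    running_std: np.ndarray,
    std_limit: float = ROI_STD_LIMIT_C,
) -> ControlROI:
    """Re-flag ROI voxels: valid iff high SNR and quiet residuals.

    ``running_std`` holds, per ROI member, the trailing-window standard
    deviation of the Kalman innovations — a heating-insensitive noise
    estimate, so a voxel that is genuinely heating is not discarded.
    Returns the ROI with updated ``valid``; the caller must hold power (and
    raise an alarm) if nothing survives.
    """
    idx = roi.indices
    snr_ok = snr_mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    std = np.asarray(running_std, dtype=float)
    if std.shape != (len(idx),):
        raise ValueError("running_std must have one entry per ROI voxel")
    roi.valid = snr_ok & (std <= std_limit)
    return roi


def select_control_voxel(filtered: np.ndarray, roi: ControlROI) -> tuple[int, int, int]:
    """Hottest valid ROI voxel of the filtered map; ties → lowest linear index."""
    if not roi.valid.any():
        raise ValueError("no valid voxel in the control ROI")
    idx = roi.indices[roi.valid]
    vals = filtered[idx[:, 0], idx[:, 1], idx[:, 2]]
    # roi.indices are generated in C order, so argmax already prefers the
    # lowest linear index on ties
    return tuple(int(c) for c in idx[int(np.argmax(vals))])


def point_laplacian(
    field: np.ndarray,
    voxel: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    valid_mask: np.ndarray | None = None,
) -> float:
    """7-point anisotropic Laplacian at one voxel (°C/mm²).

    A neighbour that is off-grid or flagged invalid is replaced by its
    mirror across the centre (even extension); if both neighbours along an
    axis are unusable that axis contributes nothing.
    """
    total = 0.0
    center = float(field[voxel])

    def sample(offset_axis, step):
        idx = list(voxel)
        idx[offset_axis] += step
        if not (0 <= idx[offset_axis] < field.shape[offset_axis]):
            return None
        idx = tuple(idx)
        if valid_mask is not None and not valid_mask[idx]:
            return None
        v = field[idx]
        return float(v) if np.isfinite(v) else None

    for axis, h in enumerate(voxel_size):
        plus = sample(axis, +1)
        minus = sample(axis, -1)
        if plus is None and minus is None:
            continue
        if plus is None:
            plus = minus
        elif minus is None:
            minus = plus
        total += (plus + minus - 2.0 * center) / (h * h)
    return total


def smoothed_laplacian(
    state: ControllerState,
    field: np.ndarray,
    voxel: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    weights: tuple[int, ...] = LAPLACIAN_WEIGHTS,
    valid_mask: np.ndarray | None = None,
) -> float:
    """Push this frame's Laplacian into the history and return the smoothed value.

    The binomial weighting over the last five frames centres the estimate on
    frame t−2; during warm-up the weight vector is truncated to the available
    history and renormalized.
    """
    state.lap_history.append(point_laplacian(field, voxel, voxel_size, valid_mask))
    hist = np.asarray(state.lap_history, dtype=float)
    w = np.asarray(weights, dtype=float)[-len(hist):]
    return float(np.dot(w, hist) / w.sum())


def compute_power(
    state: ControllerState,
    target: float,
    target_slope: float,
    measured: float,
    laplacian: float,
    config: ControllerConfig,
) -> tuple[float, ControllerState]:
    """One PID/model power update; returns (applied power W, state).

    The raw demand is clamped to [0, max_power]; the integral only advances
    by ξ·Δt on unclamped frames (anti-windup) and the saturation flag records
    clamping.
    """
    alpha = config.params.absorption
    if alpha <= 0:
        raise ValueError("calibrated absorption must be positive")
    q = config.q
    xi = target - measured
    p_raw = (
        target_slope
        - config.params.diffusion * laplacian
        + q * xi
        + (q * q / 4.0) * state.integral
    ) / alpha
    power = float(np.clip(p_raw, 0.0, config.max_power))
    state.saturated = not (0.0 <= p_raw <= config.max_power)
    if not state.saturated:
        state.integral += xi * config.frame_interval
    state.last_power = power
    state.last_raw_power = float(p_raw)
    return power, state
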