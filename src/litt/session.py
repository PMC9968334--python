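"""Closed-loop regulation sessions and efficiency metrics.

Runs the full loop at the 1 s frame cadence: bioheat advance with the last
applied power → synthetic complex frame → thermometry (reference, drift
correction, Kalman) → controller power update, with a one-frame actuation
latency (power computed from frame t heats during [t, t+Δt)).

The session timeline is: 10 reference dynamics, 20 further baseline dynamics
(measurement-noise estimation and drift-window warm-up), then regulation
along the target profile.  Efficiency is scored as the paper's field does:
mean difference and RMSE of (target − maximal filtered ROI temperature) over
the heating period (target > 0), per ramp/plateau segment and in total, plus
the temperature STD of a designated non-heated voxel.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bhte import LaserSource, PhantomModel, ThermoParams, bhte_step, source_profile
from .calibration import ControlROI
from .controller import (
    ControllerConfig,
    ControllerState,
    compute_power,
    refresh_roi_validity,
    select_control_voxel,
    smoothed_laplacian,
)
from .mrisynth import (
    N_REFERENCE_FRAMES,
    CorruptionModel,
    FrameSynthesizer,
    ellipsoid_template,
    noise_sigma_for_temperature_std,
)
from .profiles import PlateauSpec, ScanProtocol, TargetProfile, build_profile
from .thermometry import (
    BASELINE_WINDOW,
    DoseMap,
    DriftCorrector,
    KalmanConfig,
    accumulate_cem43,
    build_reference,
    compute_snr_mask,
    init_kalman,
    kalman_update,
    reconstruct_temperature,
)

__all__ = [
    "SessionConfig",
    "SessionRecord",
    "RegulationMetrics",
    "make_scenario",
    "run_closed_loop",
    "compute_metrics",
    "GEL_SCENARIO",
    "IN_VIVO_THREE_PLATEAU",
    "IN_VIVO_SINGLE_PLATEAU",
]

#: Mild scanner-like field drift, rad: constant, in-plane gradients, per frame.
DEFAULT_DRIFT = ((0.01, 2.0e-4, -1.5e-4, 5.0e-4),)
#: Abort threshold for a runaway simulation, °C above body temperature.
DIVERGENCE_LIMIT_C = 60.0

# study-condition presets: (α °C s⁻¹ W⁻¹, D mm² s⁻¹, baseline STD °C,
# plateau levels °C, durations s, body temperature °C)
GEL_SCENARIO = dict(
    alpha=0.35, diffusion=0.23, baseline_std=0.27,
    levels=(5.0, 10.0, 15.0), durations=(100.0, 100.0, 100.0),
    body_temperature=14.0,
)
IN_VIVO_THREE_PLATEAU = dict(
    alpha=0.65, diffusion=0.18, baseline_std=0.47,
    levels=(5.0, 10.0, 15.0), durations=(300.0, 300.0, 300.0),
    body_temperature=38.6,
)
IN_VIVO_SINGLE_PLATEAU = dict(
    alpha=0.65, diffusion=0.18, baseline_std=0.69,
    levels=(30.0,), durations=(700.0,),
    body_temperature=38.6,
)


@dataclass
class SessionConfig:
    """Everything a closed-loop run needs, fully constructed."""

    protocol: ScanProtocol
    phantom: PhantomModel
    source: LaserSource
    profile: TargetProfile
    corruption: CorruptionModel
    controller: ControllerConfig
    kalman: KalmanConfig
    magnitude_template: np.ndarray
    roi_center: tuple[int, int, int]
    baseline_voxel: tuple[int, int, int]
    baseline_frames: int = 30
    cooling_frames: int = 0

    def __post_init__(self) -> None:
        if self.baseline_frames < N_REFERENCE_FRAMES + BASELINE_WINDOW:
            raise ValueError(
                f"baseline needs >= {N_REFERENCE_FRAMES + BASELINE_WINDOW} frames"
            )

    @property
    def n_frames(self) -> int:
        dt = self.protocol.frame_interval
        return int(np.ceil(self.profile.end_time / dt)) + 1 + self.cooling_frames


@dataclass
class SessionRecord:
    """Full closed-loop trace: one row per frame plus the final dose map."""

    frames: pd.DataFrame
    dose: DoseMap
    profile: TargetProfile
    calibration: ThermoParams
    seed: int
    alarms: list = field(default_factory=list)
    final_temperature: np.ndarray | None = None  # last filtered ΔT map, °C


@dataclass
class RegulationMetrics:
    """Tracking-efficiency summary in the units the study conditions use."""

    segments: pd.DataFrame       # label, kind, start, end, n, mean_difference, rmse
    mean_difference: float       # °C, total heating period
    rmse: float                  # °C, total heating period
    baseline_std: float          # °C, non-heated voxel over the whole record


def make_scenario(
    *,
    alpha: float,
    diffusion: float,
    baseline_std: float,
    levels,
    durations,
    body_temperature: float,
    seed: int = 0,
    grid: tuple[int, int, int] = (112, 112, 8),
    voxel: tuple[float, float, float] = (1.4, 1.4, 3.0),
    baseline_frames: int = 30,
    cooling_frames: int = 0,
    q: float = 0.25,
    max_power: float = 27.0,
    drift=DEFAULT_DRIFT,
    controller_params: ThermoParams | None = None,
    template_magnitude: float = 100.0,
) -> SessionConfig:
    """Build a closed-loop configuration from study-condition parameters.

    The laser tip sits at the central voxel with the fiber along the slice
    axis; the baseline (non-heated) monitor voxel is placed > 30 mm from the
    tip in-plane.  ``controller_params`` defaults to the true (α, D) — the
    matched-calibration condition; pass a different pair to study model
    mismatch.
    """
    protocol = ScanProtocol(voxel_size=tuple(voxel), n_slices=grid[2])
    params = ThermoParams(absorption=alpha, diffusion=diffusion)
    phantom = PhantomModel(
        shape=tuple(grid), voxel_size=tuple(voxel), params=params,
        boundary="insulated_z",
    )
    tip_idx = tuple(n // 2 for n in grid)
    tip = tuple(i * d for i, d in zip(tip_idx, voxel))
    source = LaserSource(tip_position=tip, max_power=max_power)
    template = ellipsoid_template(tuple(grid), tuple(voxel), magnitude=template_magnitude)
    sigma = noise_sigma_for_temperature_std(baseline_std, template_magnitude, protocol)
    corruption = CorruptionModel(
        complex_noise_sigma=sigma, drift_coefficients=drift, seed=int(seed)
    )
    dt = protocol.frame_interval
    profile = build_profile(
        PlateauSpec(tuple(levels), tuple(durations)),
        body_temperature=body_temperature,
        start_time=baseline_frames * dt,
    )
    controller = ControllerConfig(
        params=controller_params or params,
        q=q, max_power=max_power, frame_interval=dt,
    )
    # the non-heated monitor voxel sits well outside the heat halo (the 2D
    # spread of a long regulated heating reaches tens of mm) but inside tissue
    offset_vox = int(np.ceil(min(50.0, (grid[0] // 2 - 6) * voxel[0]) / voxel[0]))
    baseline_voxel = (
        min(tip_idx[0] + offset_vox, grid[0] - 2), tip_idx[1], tip_idx[2]
    )
    return SessionConfig(
        protocol=protocol, phantom=phantom, source=source, profile=profile,
        corruption=corruption, controller=controller, kalman=KalmanConfig(transition_dt=dt),
        magnitude_template=template, roi_center=tip_idx,
        baseline_voxel=baseline_voxel, baseline_frames=baseline_frames,
        cooling_frames=cooling_frames,
    )


def with_seed(config: SessionConfig, seed: int) -> SessionConfig:
    """Copy of the configuration with a fresh noise seed."""
    return replace(config, corruption=replace(config.corruption, seed=int(seed)))


def run_closed_loop(config: SessionConfig) -> SessionRecord:
    """Execute the full simulator ↔ thermometry ↔ controller loop.

    Returns the per-frame trace, final dose map and any alarms.  Aborts with
    a diagnostic if the simulated elevation exceeds the divergence limit.
    """
    protocol = config.protocol
    dt = protocol.frame_interval
    n_frames = config.n_frames
    grid = config.phantom.shape
    factor_grid = source_profile(config.phantom, config.source)
    synth = FrameSynthesizer(config.magnitude_template, config.corruption, protocol)
    drift = DriftCorrector(protocol, grid)
    roi = ControlROI.centered(config.roi_center, grid)
    roi_lin = (roi.indices[:, 0], roi.indices[:, 1], roi.indices[:, 2])
    ctrl = ControllerState()
    dose = DoseMap.zeros(grid)

    ref_buffer: list[np.ndarray] = []
    init_buffer: list[np.ndarray] = []
    mag_window: deque = deque(maxlen=BASELINE_WINDOW)
    innov_window: deque = deque(maxlen=BASELINE_WINDOW)
    reference = None
    kalman_state = None
    alarms: list = []
    rows: list[dict] = []

    true_field = config.phantom.new_field()
    applied_power = 0.0
    n_ref = N_REFERENCE_FRAMES
    init_end = n_ref + BASELINE_WINDOW  # first frame with the filter running

    for k in range(n_frames):
        t = k * dt
        if k > 0:
            true_field = bhte_step(
                true_field, applied_power, dt, config.phantom, config.source,
                factor_grid,
            )
        if true_field.max() > DIVERGENCE_LIMIT_C:
            raise RuntimeError(
                f"simulation diverged: ΔT reached {true_field.max():.1f} °C at "
                f"frame {k} (power {applied_power:.2f} W)"
            )
        img = synth.synthesize(k, true_field)
        mag_window.append(np.abs(img))

        target = float(config.profile(t))
        slope = config.profile.slope(t)
        row = dict(
            frame=k, time=t, target=target, target_slope=slope,
            true_max=float(true_field.max()), applied_power=np.nan,
            raw_power=np.nan, measured_max=np.nan, measured_mean=np.nan,
            xi=np.nan, integral=np.nan, laplacian=np.nan,
            control_voxel=-1, n_valid=0, saturated=False, alarm=False,
            baseline_raw=np.nan, baseline_filtered=np.nan,
        )

        if k < n_ref:
            ref_buffer.append(img)
            if k == n_ref - 1:
                reference = build_reference(np.stack(ref_buffer, axis=-1))
                ref_buffer.clear()
            row["applied_power"] = applied_power = 0.0
            rows.append(row)
            continue

        dt_raw = reconstruct_temperature(img, reference, protocol)
        snr_mask = compute_snr_mask(np.stack(mag_window, axis=-1))
        phase_diff = dt_raw * synth.factor  # wrapped phase difference, rad
        corrected_pd, _ = drift.update(k, phase_diff, dt_raw, snr_mask)
        dt_corr = corrected_pd / synth.factor
        row["baseline_raw"] = float(dt_corr[config.baseline_voxel])

        if k < init_end:
            init_buffer.append(dt_corr)
            if k == init_end - 1:
                kalman_state = init_kalman(
                    np.stack(init_buffer, axis=-1), config.kalman
                )
                init_buffer.clear()
            row["applied_power"] = applied_power = 0.0
            rows.append(row)
            continue

        kalman_update(kalman_state, dt_corr, config.kalman)
        filtered = kalman_state.temperature
        innov_window.append(kalman_state.innovation[roi_lin])
        accumulate_cem43(dose, filtered, config.profile.body_temperature, dt)
        row["baseline_filtered"] = float(filtered[config.baseline_voxel])

        if len(innov_window) >= 2:
            running_std = np.nanstd(np.stack(innov_window, axis=0), axis=0, ddof=1)
        else:
            running_std = np.zeros(len(roi.indices))
        roi = refresh_roi_validity(roi, snr_mask, running_std,
                                   config.controller.std_limit)
        row["n_valid"] = int(roi.valid.sum())
        if target == 0.0 and slope == 0.0:
            # laser armed only while the target profile is active
            if roi.valid.any():
                cv = select_control_voxel(filtered, roi)
                row["measured_max"] = float(filtered[cv])
                row["control_voxel"] = int(np.ravel_multi_index(cv, grid))
            row["applied_power"] = applied_power = 0.0
            rows.append(row)
            continue
        if not roi.valid.any():
            alarms.append((k, "all control-ROI voxels invalid; power held at 0"))
            row["alarm"] = True
            row["applied_power"] = applied_power = 0.0
            rows.append(row)
            continue

        cv = select_control_voxel(filtered, roi)
        ctrl.control_voxel = cv
        lap = smoothed_laplacian(
            ctrl, filtered, cv, protocol.voxel_size,
            config.controller.laplacian_weights, snr_mask,
        )
        measured = float(filtered[cv])
        vidx = roi.indices[roi.valid]
        row["measured_mean"] = float(
            filtered[vidx[:, 0], vidx[:, 1], vidx[:, 2]].mean()
        )
        power, ctrl = compute_power(ctrl, target, slope, measured, lap,
                                    config.controller)
        row.update(
            measured_max=measured, xi=target - measured, integral=ctrl.integral,
            laplacian=lap, raw_power=ctrl.last_raw_power, applied_power=power,
            control_voxel=int(np.ravel_multi_index(cv, grid)),
            saturated=ctrl.saturated,
        )
        applied_power = power
        rows.append(row)

    df = pd.DataFrame(rows)
    return SessionRecord(
        frames=df, dose=dose, profile=config.profile,
        calibration=config.controller.params, seed=config.corruption.seed,
        alarms=alarms,
        final_temperature=(
            kalman_state.temperature.copy() if kalman_state is not None else None
        ),
    )


def _segment_label(v0: float, v1: float) -> tuple[str, str]:
    def fmt(v):
        return f"{v:g}"

    if v0 == v1:
        return fmt(v0), "plateau"
    return f"{fmt(v0)} → {fmt(v1)}", "ramp"


def compute_metrics(record: SessionRecord,
                    profile: TargetProfile | None = None) -> RegulationMetrics:
    """Mean difference and RMSE of target − measured max, per segment and total.

    Only heating-period frames (target > 0) are scored; alarm frames carry no
    measurement and are skipped.  The baseline STD comes from the raw
    (drift-corrected, unfiltered) temperature of the designated non-heated
    voxel over the whole record.
    """
    profile = profile or record.profile
    df = record.frames
    heat = df[(df["target"] > 0) & np.isfinite(df["measured_max"])]
    if heat.empty:
        raise ValueError("record contains no heating frames")
    err = heat["target"] - heat["measured_max"]

    seg_rows = []
    bp = profile.breakpoints
    for (t0, v0), (t1, v1) in zip(bp[:-1], bp[1:]):
        label, kind = _segment_label(v0, v1)
        sel = err[(heat["time"] > t0) & (heat["time"] <= t1)]
        if sel.empty:
            continue
        seg_rows.append(
            dict(
                label=label, kind=kind, start=t0, end=t1, n=len(sel),
                mean_difference=float(sel.mean()),
                rmse=float(np.sqrt(np.mean(sel**2))),
            )
        )
    total_mean = float(err.mean())
    total_rmse = float(np.sqrt(np.mean(err**2)))
    assert total_rmse >= abs(total_mean) - 1e-12
    baseline = df["baseline_raw"].to_numpy()
    baseline = baseline[np.isfinite(baseline)]
    return RegulationMetrics(
        segments=pd.DataFrame(seg_rows),
        mean_difference=total_mean,
        rmse=total_rmse,
        baseline_std=float(np.std(baseline, ddof=1)) if baseline.size > 1 else 0.0,
    )
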