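"""Real-time PRF thermometry pipeline.

Per dynamic frame the pipeline runs: phase-difference temperature
reconstruction against a 10-frame complex reference → sliding-window
spatio-temporal drift correction → per-voxel 2-state Kalman filtering →
SNR masking and CEM43 thermal-dose accumulation.  The Kalman-filtered field
is what the power controller consumes; raw values are kept alongside.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .bhte import TemperatureFrame  # re-export: frames are produced by the twin
from .mrisynth import N_REFERENCE_FRAMES, ComplexSeries, prf_phase_factor, wrap_phase
from .profiles import ScanProtocol

__all__ = [
    "TemperatureFrame",
    "KalmanConfig",
    "KalmanState",
    "DoseMap",
    "DriftCorrector",
    "build_reference",
    "reconstruct_temperature",
    "compute_snr_mask",
    "init_kalman",
    "kalman_update",
    "accumulate_cem43",
]

#: SNR exclusion: fraction of the maximum windowed-mean magnitude.
SNR_THRESHOLD_FRACTION = 0.05
#: Frames in the SNR / drift sliding windows and the Kalman noise baseline.
BASELINE_WINDOW = 20
#: Temperature gate (°C) restricting the drift-fit population.
DRIFT_GATE_C = (-5.0, 5.0)
#: Variance floor (°C²) so noiseless data cannot zero the Kalman gain.
MEASUREMENT_VARIANCE_FLOOR = 1e-4
#: Lethal thermal dose, equivalent minutes at 43 °C.
CEM43_LETHAL_MINUTES = 240.0


def build_reference(series) -> np.ndarray:
    """Reference phase: per-voxel phase of the complex mean of frames 0–9."""
    data = series.data if isinstance(series, ComplexSeries) else np.asarray(series)
    if data.ndim != 4 or data.shape[3] < N_REFERENCE_FRAMES:
        raise ValueError(f"need >= {N_REFERENCE_FRAMES} frames to build a reference")
    return np.angle(data[..., :N_REFERENCE_FRAMES].mean(axis=3))


def reconstruct_temperature(
    frame: np.ndarray, reference_phase: np.ndarray, protocol: ScanProtocol
) -> np.ndarray:
    """ΔT (°C) from one complex frame: wrapped phase difference over the PRF factor."""
    frame = np.asarray(frame)
    phase = np.angle(frame) if np.iscomplexobj(frame) else frame
    if phase.shape != reference_phase.shape:
        raise ValueError("frame and reference shapes differ")
    return wrap_phase(phase - reference_phase) / prf_phase_factor(protocol)


def compute_snr_mask(
    magnitude_window: np.ndarray, fraction: float = SNR_THRESHOLD_FRACTION
) -> np.ndarray:
    """Voxels whose windowed-mean magnitude reaches ``fraction`` of the maximum.

    ``magnitude_window`` is either a (x, y, z, n) stack of consecutive
    magnitude frames or an already-averaged 3D mean.
    """
    m = np.asarray(magnitude_window, dtype=float)
    mean = m.mean(axis=3) if m.ndim == 4 else m
    return mean >= fraction * mean.max()


class DriftCorrector:
    """Sliding-window first-order spatio-temporal phase-drift estimator.

    Per slice, fits drift(x, y, k) = a0 + a1·x + a2·y + a3·k (rad; x, y in
    mm, k the frame index) by least squares over the trailing ``window``
    frames, restricted to voxels that pass the SNR mask and whose
    uncorrected temperature lies inside the gate — so a genuine hotspot
    cannot bias the fit.  The fitted drift at the current frame is
    subtracted from the phase difference before temperature conversion.
    """

    def __init__(
        self,
        protocol: ScanProtocol,
        grid_shape: tuple[int, int, int],
        window: int = BASELINE_WINDOW,
        gate: tuple[float, float] = DRIFT_GATE_C,
        min_voxels: int = 50,
    ) -> None:
        if gate[0] >= gate[1]:
            raise ValueError("gate lower bound must be below upper bound")
        self.protocol = protocol
        self.window = window
        self.gate = gate
        self.min_voxels = min_voxels
        nx, ny, nz = grid_shape
        dx, dy, _ = protocol.voxel_size
        self._x = np.arange(nx)[:, None] * dx  # (nx, 1) mm
        self._y = np.arange(ny)[None, :] * dy  # (1, ny) mm
        self.n_slices = nz
        self._moments: deque = deque()  # per frame: (A (nz,4,4), b (nz,4), n (nz,))
        self.coefficients = np.zeros((nz, 4))

    def _frame_moments(self, phase_diff, eligible, k):
        nz = self.n_slices
        A = np.zeros((nz, 4, 4))
        b = np.zeros((nz, 4))
        counts = np.zeros(nz)
        for s in range(nz):
            m = eligible[:, :, s]
            n = int(m.sum())
            counts[s] = n
            if n == 0:
                continue
            x = np.broadcast_to(self._x, m.shape)[m]
            y = np.broadcast_to(self._y, m.shape)[m]
            u = np.stack([np.ones_like(x), x, y, np.full_like(x, float(k))])
            A[s] = u @ u.T
            b[s] = u @ phase_diff[:, :, s][m]
        return A, b, counts

    def update(
        self,
        frame_index: int,
        phase_diff: np.ndarray,
        delta_t_uncorrected: np.ndarray,
        snr_mask: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Ingest one frame; return (corrected phase difference, coefficients)."""
        lo, hi = self.gate
        eligible = (
            snr_mask
            & np.isfinite(delta_t_uncorrected)
            & (delta_t_uncorrected > lo)
            & (delta_t_uncorrected < hi)
        )
        self._moments.append(self._frame_moments(phase_diff, eligible, frame_index))
        if len(self._moments) > self.window:
            self._moments.popleft()
        A = sum(m[0] for m in self._moments)
        b = sum(m[1] for m in self._moments)
        counts = sum(m[2] for m in self._moments)
        coeffs = self.coefficients.copy()
        for s in range(self.n_slices):
            if counts[s] < self.min_voxels:
                warnings.warn(
                    f"drift fit: slice {s} has {int(counts[s])} eligible voxels "
                    f"(< {self.min_voxels}); keeping previous coefficients",
                    stacklevel=2,
                )
                continue
            # ridge-free solve; lstsq handles the rank-deficient single-frame case
            coeffs[s] = np.linalg.lstsq(A[s], b[s], rcond=None)[0]
        self.coefficients = coeffs
        a = coeffs.T[:, None, None, :]  # (4, 1, 1, nz)
        drift_now = (
            a[0]
            + a[1] * self._x[:, :, None]
            + a[2] * self._y[:, :, None]
            + a[3] * float(frame_index)
        )
        return phase_diff - drift_now, coeffs


@dataclass(frozen=True)
class KalmanConfig:
    """Settings of the per-voxel temperature/rate Kalman filter."""

    process_noise_variance: float = 0.001  # °C²
    transition_dt: float = 1.0             # s
    process_model: str = "isotropic"       # or "white_acceleration"

    def __post_init__(self) -> None:
        if self.process_noise_variance <= 0:
            raise ValueError("process_noise_variance must be positive")
        if self.transition_dt <= 0:
            raise ValueError("transition_dt must be positive")
        if self.process_model not in ("isotropic", "white_acceleration"):
            raise ValueError("unknown process model")

    def process_covariance(self) -> np.ndarray:
        q, dt = self.process_noise_variance, self.transition_dt
        if self.process_model == "isotropic":
            return q * np.eye(2)
        return q * np.array([[dt**4 / 4, dt**3 / 2], [dt**3 / 2, dt**2]])


@dataclass
class KalmanState:
    """Vectorized filter state over the voxel grid.

    The constant-velocity transition [[1, Δt], [0, 1]] propagates temperature
    and its rate; the 2×2 covariance is stored as (p11, p12, p22) arrays.
    """

    temperature: np.ndarray
    rate: np.ndarray
    p11: np.ndarray
    p12: np.ndarray
    p22: np.ndarray
    measurement_variance: np.ndarray
    innovation: np.ndarray = field(default=None)  # last residual, NaN where skipped
    skipped: np.ndarray = field(default=None)


def init_kalman(
    baseline: np.ndarray, config: KalmanConfig,
    variance_floor: float = MEASUREMENT_VARIANCE_FLOOR,
) -> KalmanState:
    """Initialize from the first 20 temperature dynamics.

    The per-voxel measurement noise variance is the sample variance of the
    voxel's baseline temperature series (floored); the state starts at the
    baseline mean with zero rate.
    """
    baseline = np.asarray(baseline, dtype=float)
    if baseline.ndim != 4 or baseline.shape[3] < 2:
        raise ValueError("baseline must be a (x, y, z, n>=2) temperature stack")
    var = np.maximum(baseline.var(axis=3, ddof=1), variance_floor)
    mean = baseline.mean(axis=3)
    dt = config.transition_dt
    return KalmanState(
        temperature=mean,
        rate=np.zeros_like(mean),
        p11=var.copy(),
        p12=np.zeros_like(mean),
        p22=var / dt**2,
        measurement_variance=var,
        innovation=np.zeros_like(mean),
        skipped=np.zeros(mean.shape, dtype=bool),
    )


def kalman_update(
    state: KalmanState, measurement: np.ndarray, config: KalmanConfig
) -> KalmanState:
    """One predict/update cycle over all voxels (in place; state returned).

    Only the temperature component is observed.  Voxels with a non-finite
    measurement get the prediction only and are flagged in ``state.skipped``.
    """
    z = np.asarray(measurement, dtype=float)
    dt = config.transition_dt
    Q = config.process_covariance()
    # predict
    t_pred = state.temperature + dt * state.rate
    r_pred = state.rate
    p11 = state.p11 + 2 * dt * state.p12 + dt**2 * state.p22 + Q[0, 0]
    p12 = state.p12 + dt * state.p22 + Q[0, 1]
    p22 = state.p22 + Q[1, 1]
    # update (observation H = [1, 0])
    ok = np.isfinite(z)
    innov = np.where(ok, z - t_pred, 0.0)
    S = p11 + state.measurement_variance
    k1 = np.where(ok, p11 / S, 0.0)
    k2 = np.where(ok, p12 / S, 0.0)
    state.temperature = t_pred + k1 * innov
    state.rate = r_pred + k2 * innov
    state.p11 = (1.0 - k1) * p11
    state.p12 = (1.0 - k1) * p12
    state.p22 = p22 - k2 * p12
    state.innovation = np.where(ok, innov, np.nan)
    state.skipped = ~ok
    return state


@dataclass
class DoseMap:
    """Cumulative equivalent minutes at 43 °C, with the lethal threshold mask."""

    cem43: np.ndarray
    lethal_threshold: float = CEM43_LETHAL_MINUTES

    @classmethod
    def zeros(cls, shape) -> "DoseMap":
        return cls(np.zeros(shape, dtype=float))

    @property
    def lethal_mask(self) -> np.ndarray:
        return self.cem43 >= self.lethal_threshold


def accumulate_cem43(
    dose: DoseMap, delta_t: np.ndarray, body_temperature: float, dt: float
) -> DoseMap:
    """Advance the thermal dose by ``dt`` seconds of the given elevation field.

    Sapareto–Dean accumulation: cem43 += R^(43 − T) · dt/60 with
    R = 0.5 for T ≥ 43 °C and R = 0.25 below.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t_abs = body_temperature + np.asarray(delta_t, dtype=float)
    r = np.where(t_abs >= 43.0, 0.5, 0.25)
    dose.cem43 += r ** (43.0 - t_abs) * (dt / 60.0)
    return dose
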