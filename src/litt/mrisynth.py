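"""Synthetic dynamic MR image generation with PRF temperature encoding.

Turns simulated temperature-elevation frames into complex multi-slice image
dynamics: per voxel the phase advances by the PRF factor (rad/°C) times ΔT,
a slow per-slice spatio-temporal phase drift is added, and independent
complex Gaussian noise corrupts each frame.  Reconstructing these images with
the thermometry pipeline closes the loop without a scanner.

A single post-coil-combination magnitude/phase channel is modelled; phases
are stored wrapped to (−π, π].  In the protocol regime used here (1.5 T,
TE 21 ms) a 30 °C elevation shifts the phase by ≈ −2.4 rad, far from a 2π
wrap, so no unwrapping stage exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bhte import TemperatureFrame
from .profiles import ScanProtocol

__all__ = [
    "ComplexSeries",
    "CorruptionModel",
    "FrameSynthesizer",
    "prf_phase_factor",
    "synthesize_series",
    "noise_sigma_for_temperature_std",
    "ellipsoid_template",
]

#: Number of initial dynamics averaged into the reference phase image.
N_REFERENCE_FRAMES = 10


def prf_phase_factor(protocol: ScanProtocol) -> float:
    """Phase change per °C (rad/°C): 2π·γ·B0·κ·TE; negative for water."""
    return (
        2.0
        * np.pi
        * protocol.gyromagnetic_ratio
        * protocol.field_strength
        * protocol.prf_coefficient
        * protocol.echo_time
    )


def wrap_phase(phi):
    """Wrap angles to (−π, π]."""
    return np.pi - np.mod(np.pi - np.asarray(phi), 2.0 * np.pi)


@dataclass(frozen=True)
class CorruptionModel:
    """Noise and drift applied to the synthetic complex dynamics.

    ``drift_coefficients`` holds one (a0 rad, a1 rad/mm, a2 rad/mm,
    a3 rad/frame) tuple per slice: a first-order polynomial in in-plane
    position and frame index, mirroring the form the drift corrector removes.
    A single tuple is broadcast to every slice.

    ``magnitude_loss_per_C`` (fraction per °C, default 0) linearly attenuates
    the magnitude with temperature elevation, a crude stand-in for the
    T1/T2*-driven signal loss of hot tissue; useful to exercise the
    SNR-exclusion logic.
    """

    complex_noise_sigma: float = 0.0
    drift_coefficients: tuple = ()
    seed: int = 0
    magnitude_loss_per_C: float = 0.0

    def __post_init__(self) -> None:
        if self.complex_noise_sigma < 0:
            raise ValueError("complex_noise_sigma must be non-negative")
        if self.magnitude_loss_per_C < 0:
            raise ValueError("magnitude_loss_per_C must be non-negative")
        dc = np.atleast_2d(np.asarray(self.drift_coefficients, dtype=float))
        if dc.size and dc.shape[1] != 4:
            raise ValueError("drift coefficients must be (a0, a1, a2, a3) per slice")
        object.__setattr__(
            self, "drift_coefficients", tuple(map(tuple, dc)) if dc.size else ()
        )

    def drift_table(self, n_slices: int) -> np.ndarray:
        if not self.drift_coefficients:
            return np.zeros((n_slices, 4))
        dc = np.asarray(self.drift_coefficients, dtype=float)
        if dc.shape[0] == 1:
            dc = np.repeat(dc, n_slices, axis=0)
        if dc.shape[0] != n_slices:
            raise ValueError("drift coefficient rows must match slice count")
        return dc


@dataclass
class ComplexSeries:
    """Complex-valued dynamic series (x, y, z, frame) with acquisition times."""

    data: np.ndarray
    times: np.ndarray
    protocol: ScanProtocol

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, frame)")
        if self.data.shape[3] != self.times.size:
            raise ValueError("frame count and times length differ")
        if self.data.shape[3] < 2 * N_REFERENCE_FRAMES:
            raise ValueError(
                f"pipeline needs >= {2 * N_REFERENCE_FRAMES} baseline dynamics"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def magnitude(self, k: int) -> np.ndarray:
        return np.abs(self.data[..., k])

    def phase(self, k: int) -> np.ndarray:
        return np.angle(self.data[..., k])


class FrameSynthesizer:
    """Streaming synthesizer: one complex frame per simulated temperature map.

    Keeps its own random generator so a closed-loop session consuming frames
    one at a time produces bit-identical output to batch synthesis with the
    same seed.
    """

    def __init__(
        self,
        magnitude_template: np.ndarray,
        corruption: CorruptionModel,
        protocol: ScanProtocol,
        baseline_phase: float | np.ndarray = 0.0,
    ) -> None:
        self.template = np.asarray(magnitude_template, dtype=float)
        if self.template.ndim != 3:
            raise ValueError("magnitude template must be 3D")
        if np.any(self.template < 0):
            raise ValueError("magnitude must be non-negative")
        self.corruption = corruption
        self.protocol = protocol
        self.baseline_phase = baseline_phase
        self.rng = np.random.default_rng(corruption.seed)
        self.factor = prf_phase_factor(protocol)
        nx, ny, nz = self.template.shape
        dx, dy, _ = protocol.voxel_size
        drift = corruption.drift_table(nz)
        x = np.arange(nx)[:, None, None] * dx
        y = np.arange(ny)[None, :, None] * dy
        a = drift.T[:, None, None, :]  # (4, 1, 1, nz)
        self._drift_static = a[0] + a[1] * x + a[2] * y  # rad, (nx, ny, nz)
        self._drift_per_frame = np.broadcast_to(a[3], (nx, ny, nz))

    def synthesize(self, frame_index: int, delta_t: np.ndarray) -> np.ndarray:
        delta_t = np.asarray(delta_t, dtype=float)
        if delta_t.shape != self.template.shape:
            raise ValueError("temperature field does not match template grid")
        phase = (
            self.baseline_phase
            + self.factor * delta_t
            + self._drift_static
            + self._drift_per_frame * frame_index
        )
        magnitude = self.template
        loss = self.corruption.magnitude_loss_per_C
        if loss > 0:
            magnitude = magnitude * np.clip(1.0 - loss * delta_t, 0.0, None)
        img = magnitude * np.exp(1j * wrap_phase(phase))
        sigma = self.corruption.complex_noise_sigma
        if sigma > 0:
            noise = self.rng.standard_normal(img.shape + (2,))
            img = img + sigma * (noise[..., 0] + 1j * noise[..., 1])
        return img


def synthesize_series(
    temps: list[TemperatureFrame],
    magnitude_template: np.ndarray,
    corruption: CorruptionModel,
    protocol: ScanProtocol,
    baseline_phase: float | np.ndarray = 0.0,
) -> ComplexSeries:
    """Batch-synthesize a full dynamic series from temperature frames."""
    synth = FrameSynthesizer(magnitude_template, corruption, protocol, baseline_phase)
    data = np.stack(
        [synth.synthesize(f.frame_index, f.delta_t) for f in temps], axis=-1
    )
    times = np.array([f.time for f in temps])
    return ComplexSeries(data, times, protocol)


def noise_sigma_for_temperature_std(
    target_std: float,
    template_magnitude: float,
    protocol: ScanProtocol,
    n_reference: int = N_REFERENCE_FRAMES,
) -> float:
    """Complex noise sigma producing a given single-voxel temperature STD.

    Small-noise propagation: each phase image has STD σ/m, so the
    temperature time series of a voxel fluctuates with

        std(ΔT) = (σ/m) / |prf_phase_factor|.

    The noise of the ``n_reference``-frame complex reference enters every
    frame of a voxel identically — a static (σ/m)·√(1/n_reference) offset,
    not temporal noise — so it does not contribute to the temporal STD this
    function targets (the stability measure read off a non-heated voxel).
    """
    if target_std < 0:
        raise ValueError("target_std must be non-negative")
    if target_std == 0:
        return 0.0
    if template_magnitude <= 0:
        raise ValueError("template magnitude must be positive")
    del n_reference  # reference noise is static per voxel; see docstring
    factor = abs(prf_phase_factor(protocol))
    return target_std * factor * template_magnitude


def ellipsoid_template(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    magnitude: float = 100.0,
    semiaxis_fraction: float = 0.95,
    void_center_xy: tuple[float, float] | None = None,
    void_radius_mm: float = 0.0,
) -> np.ndarray:
    """Uniform elliptic-cylinder phantom magnitude, optional catheter void.

    Every slice of the stack contains the same in-plane ellipse filling
    ``semiaxis_fraction`` of each half-extent; outside it the signal is 0
    (air).  A low-signal cylinder along z emulates the probe void visible on
    magnitude images.
    """
    nx, ny, nz = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x = (np.arange(nx)[:, None, None] - cx) / (semiaxis_fraction * (nx - 1) / 2.0)
    y = (np.arange(ny)[None, :, None] - cy) / (semiaxis_fraction * (ny - 1) / 2.0)
    template = np.where(
        np.broadcast_to(x**2 + y**2, shape) <= 1.0, float(magnitude), 0.0
    )
    if void_center_xy is not None and void_radius_mm > 0:
        dx, dy, _ = voxel_size
        xm = np.arange(nx)[:, None, None] * dx - void_center_xy[0]
        ym = np.arange(ny)[None, :, None] * dy - void_center_xy[1]
        template = np.where(
            xm**2 + ym**2 <= void_radius_mm**2, 0.02 * magnitude, template
        )
    return template
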