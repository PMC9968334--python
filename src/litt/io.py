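"""NIfTI / JSON persistence for dynamic series, temperature maps and traces.

Complex dynamics are stored as paired magnitude + phase 4D NIfTI volumes
with a JSON sidecar (times, protocol, corruption settings); temperature and
dose fields as plain NIfTI with voxel size in the affine.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .mrisynth import ComplexSeries, CorruptionModel
from .profiles import ScanProtocol
from .thermometry import DoseMap

__all__ = [
    "save_complex_series",
    "load_complex_series",
    "save_temperature_series",
    "load_temperature_series",
    "save_dose",
    "save_sidecar",
    "load_sidecar",
]


def _affine(voxel_size) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def save_sidecar(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def load_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())


def save_complex_series(series: ComplexSeries, stem,
                        corruption: CorruptionModel | None = None) -> None:
    """Write <stem>_mag.nii.gz, <stem>_phase.nii.gz and <stem>.json."""
    stem = Path(stem)
    aff = _affine(series.protocol.voxel_size)
    nib.save(nib.Nifti1Image(np.abs(series.data).astype(np.float32), aff),
             str(stem) + "_mag.nii.gz")
    nib.save(nib.Nifti1Image(np.angle(series.data).astype(np.float32), aff),
             str(stem) + "_phase.nii.gz")
    payload = {
        "times_s": series.times,
        "protocol": asdict(series.protocol),
    }
    if corruption is not None:
        payload["corruption"] = {
            "complex_noise_sigma": corruption.complex_noise_sigma,
            "drift_coefficients": corruption.drift_coefficients,
            "seed": corruption.seed,
        }
    save_sidecar(str(stem) + ".json", payload)


def load_complex_series(stem) -> ComplexSeries:
    stem = Path(stem)
    mag = np.asarray(nib.load(str(stem) + "_mag.nii.gz").dataobj, dtype=float)
    phase = np.asarray(nib.load(str(stem) + "_phase.nii.gz").dataobj, dtype=float)
    meta = load_sidecar(str(stem) + ".json")
    proto = dict(meta["protocol"])
    proto["voxel_size"] = tuple(proto["voxel_size"])
    protocol = ScanProtocol(**proto)
    return ComplexSeries(mag * np.exp(1j * phase), np.asarray(meta["times_s"]),
                         protocol)


def save_temperature_series(stack: np.ndarray, times, voxel_size, stem,
                            power_trace=None) -> None:
    """4D ΔT NIfTI (°C) plus a JSON sidecar with frame times and powers."""
    stem = Path(stem)
    nib.save(
        nib.Nifti1Image(np.asarray(stack, dtype=np.float32), _affine(voxel_size)),
        str(stem) + "_temp.nii.gz",
    )
    payload = {"times_s": np.asarray(times)}
    if power_trace is not None:
        payload["power_W"] = np.asarray(power_trace)
    save_sidecar(str(stem) + ".json", payload)


def load_temperature_series(stem) -> tuple[np.ndarray, np.ndarray, dict]:
    stem = Path(stem)
    img = nib.load(str(stem) + "_temp.nii.gz")
    meta = load_sidecar(str(stem) + ".json")
    return (np.asarray(img.dataobj, dtype=float),
            np.asarray(meta["times_s"], dtype=float), meta)


def save_dose(dose: DoseMap, voxel_size, path) -> None:
    nib.save(
        nib.Nifti1Image(dose.cem43.astype(np.float32), _affine(voxel_size)),
        str(path),
    )
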