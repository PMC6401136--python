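"""TIFF / JSON-sidecar / CSV file formats.

Holograms are stored as 16-bit grayscale TIFF with a JSON sidecar
(wavelength nm, pixel pitch µm, geometry flag, provenance metadata);
phase and optical-thickness maps as 32-bit float TIFF with a sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .reconstruct import OpticalThicknessMap, OpticsMeta, PhaseMap
from .simulate import Hologram

__all__ = [
    "save_hologram",
    "load_hologram",
    "save_phase_map",
    "load_phase_map",
    "save_ot_map",
    "load_ot_map",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_hologram(holo: Hologram, path: str | Path) -> Path:
    path = Path(path)
    data = np.clip(np.round(holo.intensity), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = {
        "wavelength_nm": holo.wavelength_nm,
        "dx_um": holo.dx_um,
        "dy_um": holo.dy_um,
        "geometry": holo.geometry,
        **{k: v for k, v in holo.meta.items()},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    return path


def load_hologram(path: str | Path) -> Hologram:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return Hologram(
        intensity=data,
        wavelength_nm=float(meta.get("wavelength_nm", 632.8)),
        dx_um=float(meta.get("dx_um", 0.1)),
        dy_um=float(meta.get("dy_um", 0.1)),
        geometry=meta.get("geometry", "reflection"),
        meta={k: v for k, v in meta.items()
              if k not in ("wavelength_nm", "dx_um", "dy_um", "geometry")},
    )


def save_phase_map(pm: PhaseMap, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, pm.values.astype(np.float32))
    _sidecar(path).write_text(json.dumps({
        "kind": "phase", "units": "rad",
        "wrapped": pm.wrapped,
        "background_corrected": pm.background_corrected,
        "wavelength_nm": pm.meta.wavelength_nm,
        "dx_um": pm.meta.dx_um, "dy_um": pm.meta.dy_um,
        "geometry": pm.meta.geometry,
    }, indent=2, sort_keys=True))
    return path


def load_phase_map(path: str | Path) -> PhaseMap:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return PhaseMap(
        values=tifffile.imread(path).astype(float),
        wrapped=bool(meta.get("wrapped", False)),
        background_corrected=bool(meta.get("background_corrected", False)),
        meta=OpticsMeta(
            wavelength_nm=float(meta.get("wavelength_nm", 632.8)),
            dx_um=float(meta.get("dx_um", 0.1)),
            dy_um=float(meta.get("dy_um", 0.1)),
            geometry=meta.get("geometry", "reflection"),
        ),
    )


def save_ot_map(ot: OpticalThicknessMap, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, ot.values.astype(np.float32))
    _sidecar(path).write_text(json.dumps({
        "kind": "optical_thickness", "units": ot.units,
        "dx_um": ot.dx_um, "dy_um": ot.dy_um,
    }, indent=2, sort_keys=True))
    return path


def load_ot_map(path: str | Path) -> OpticalThicknessMap:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return OpticalThicknessMap(
        values=tifffile.imread(path).astype(float),
        units=meta.get("units", "nm"),
        dx_um=float(meta.get("dx_um", 0.1)),
        dy_um=float(meta.get("dy_um", 0.1)),
    )
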