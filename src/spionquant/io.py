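"""Reading and writing of volumes, masks, SAXS curves and tables.

Tomograms and masks travel as multi-page TIFF with the voxel size recorded
in ImageJ-style metadata (``spacing``, unit nm), so files round-trip
through FIJI. SAXS curves are two-column whitespace/CSV text (q in nm^-1,
intensity, optional third column sigma).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .types import BinaryParticle, SAXSCurve, VoxelVolume

__all__ = [
    "save_tomogram",
    "load_tomogram",
    "save_mask",
    "load_mask",
    "read_saxs_curve",
    "write_saxs_curve",
    "write_json",
]


def save_tomogram(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume as ImageJ-compatible multi-page TIFF (voxel size in
    the metadata, nm)."""
    vx = volume.voxel_size
    tifffile.imwrite(
        str(path), volume.data.astype(np.float32), imagej=True,
        resolution=(1.0 / vx, 1.0 / vx),
        metadata={"spacing": vx, "unit": "nm", "axes": "ZYX"})


def _voxel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    meta = tif.imagej_metadata or {}
    if "spacing" in meta:
        return float(meta["spacing"])
    page = tif.pages[0]
    if "XResolution" in page.tags:
        num, den = page.tags["XResolution"].value
        if num:
            return float(den) / float(num)
    return None


def load_tomogram(path: str | Path, voxel_size: float | None = None) -> VoxelVolume:
    """Read a TIFF stack; voxel size from metadata unless given explicitly."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        vx = voxel_size if voxel_size is not None else _voxel_size_from_tiff(tif)
    if vx is None:
        raise ValueError(f"{path}: no voxel size in TIFF metadata; pass voxel_size explicitly")
    if data.ndim == 2:
        data = data[None]
    return VoxelVolume(data=data, voxel_size=float(vx))


def save_mask(particle: BinaryParticle, path: str | Path) -> None:
    vx = particle.voxel_size
    tifffile.imwrite(
        str(path), particle.mask.astype(np.uint8), imagej=True,
        resolution=(1.0 / vx, 1.0 / vx),
        metadata={"spacing": vx, "unit": "nm", "axes": "ZYX"})


def load_mask(path: str | Path, voxel_size: float | None = None,
              source_id: int = 0) -> BinaryParticle:
    vol = load_tomogram(path, voxel_size=voxel_size)
    return BinaryParticle(mask=vol.data > 0, voxel_size=vol.voxel_size, source_id=source_id)


def read_saxs_curve(path: str | Path, wavelength: float = 0.1524) -> SAXSCurve:
    """Read a two- or three-column text curve (q nm^-1, I[, sigma])."""
    raw = np.loadtxt(str(path), comments=("#", "%"), delimiter=None)
    if raw.ndim == 1:
        raw = raw[None, :]
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns (q, intensity)")
    return SAXSCurve(q=raw[:, 0], intensity=raw[:, 1], wavelength=wavelength)


def write_saxs_curve(curve: SAXSCurve, path: str | Path) -> None:
    np.savetxt(str(path), np.column_stack([curve.q, curve.intensity]),
               header="q_nm^-1 intensity", fmt="%.8g")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
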