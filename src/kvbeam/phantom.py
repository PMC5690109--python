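"""Voxelized phantoms and HU-to-material mapping.

Coordinate convention (fixed package-wide): the X-ray source sits at the
origin, +z points into the phantom, x is the inline (anode-cathode) axis and
y the crossline axis; positions are in cm.  The phantom surface plane is at
z = SSD.  Voxel indexing is 0-based; ``origin`` is the world position of the
*center* of voxel (0, 0, 0).

The native volume format is a pair of raw little-endian arrays (material id
uint8, density float32, C-order with z fastest-varying) plus a JSON sidecar
header carrying dims, spacing, origin and the material id table.  DICOM
import belongs at the interface boundary (an adapter can build a HU volume
with pydicom and feed it to :func:`apply_hu_mapping`); it is deliberately not
a core dependency.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import physdata

__all__ = ["VoxelPhantom", "HuMapping", "build_water_phantom",
           "apply_hu_mapping", "read_volume", "write_volume"]


@dataclass
class VoxelPhantom:
    """Material/density grid with spacing and origin.

    ``material`` holds uint8 indices into ``material_names``;
    ``density`` is g/cm^3 per voxel.  Arrays have shape (nx, ny, nz).
    """

    material: np.ndarray
    density: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    material_names: tuple[str, ...] = ("water",)

    def __post_init__(self):
        if self.material.shape != self.density.shape or self.material.ndim != 3:
            raise ValueError("material/density must be matching 3-D arrays")
        if min(self.material.shape) < 1:
            raise ValueError("dims must be >= 1")
        if min(self.spacing) <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.material.max(initial=0) >= len(self.material_names):
            raise ValueError("voxel references unknown material index")
        for name in self.material_names:
            physdata.get_table(name)  # every voxel must map to known data

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.material.shape

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size per axis, cm (= dims x spacing)."""
        return tuple(n * d for n, d in zip(self.dims, self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def bounds(self):
        """((xmin, xmax), (ymin, ymax), (zmin, zmax)) of the voxel box, cm."""
        lo = [o - 0.5 * d for o, d in zip(self.origin, self.spacing)]
        hi = [l + e for l, e in zip(lo, self.extent)]
        return tuple(zip(lo, hi))

    def voxel_index(self, point) -> tuple[int, int, int]:
        (x0, _), (y0, _), (z0, _) = self.bounds()
        idx = tuple(int(np.floor((p - l) / d)) for p, l, d in
                    zip(point, (x0, y0, z0), self.spacing))
        if any(i < 0 or i >= n for i, n in zip(idx, self.dims)):
            raise ValueError(f"point {point} outside phantom")
        return idx


@dataclass(frozen=True)
class HuMapping:
    """Ordered HU intervals -> (material id, density or (rho_lo, rho_hi) ramp).

    Intervals are [lo, hi) except the last, which is closed; they must be
    contiguous and non-overlapping.
    """

    intervals: tuple[tuple[float, float, str, object], ...]

    def __post_init__(self):
        prev_hi = None
        for lo, hi, mat, rho in self.intervals:
            if hi <= lo:
                raise ValueError(f"empty HU interval [{lo}, {hi})")
            if prev_hi is not None and lo != prev_hi:
                raise ValueError("HU intervals must be contiguous")
            physdata.get_table(mat)
            prev_hi = hi

    @classmethod
    def air_water_default(cls) -> "HuMapping":
        """Two-bin mapping: HU < -300 air, otherwise water, density ramped
        linearly with HU (water 1.0 at HU 0)."""
        return cls(((-1100.0, -300.0, "air", 1.2048e-3),
                    (-300.0, 2000.0, "water", (0.7, 3.0))))


def build_water_phantom(dims=(103, 103, 108),
                        voxel_size=(0.4, 0.4, 0.3),
                        ssd: float = 15.0) -> VoxelPhantom:
    """Homogeneous water phantom, surface centered on the beam axis at z=SSD.

    The default grid downsamples the transverse axes to 0.4 cm voxels for
    desk-scale point-of-interest tallies; ``dims=(512, 512, 108)``,
    ``voxel_size=(0.081, 0.081, 0.30)`` reconstructs the full-resolution
    28.3 million voxel grid.
    """
    if min(dims) < 1 or min(voxel_size) <= 0:
        raise ValueError("dims must be >= 1 and voxel sizes positive")
    nx, ny, nz = dims
    dx, dy, dz = voxel_size
    mat = np.zeros(dims, dtype=np.uint8)
    rho = np.ones(dims, dtype=np.float32)
    # voxel (0,0,0) center: x/y centered on beam axis, first z layer at surface
    origin = (-(nx - 1) / 2 * dx, -(ny - 1) / 2 * dy, ssd + dz / 2)
    return VoxelPhantom(mat, rho, (dx, dy, dz), origin, ("water",))


def apply_hu_mapping(hu_volume: np.ndarray, mapping: HuMapping,
                     spacing=(0.1, 0.1, 0.1), origin=(0.0, 0.0, 0.0)
                     ) -> VoxelPhantom:
    """Voxelwise material and density assignment from a HU volume."""
    hu = np.asarray(hu_volume, dtype=float)
    if hu.ndim != 3:
        raise ValueError("hu_volume must be 3-D")
    names = []
    mat = np.full(hu.shape, 255, dtype=np.uint8)
    rho = np.zeros(hu.shape, dtype=np.float32)
    for lo, hi, name, density in mapping.intervals:
        if name not in names:
            names.append(name)
        mid = names.index(name)
        last = (lo, hi) == (mapping.intervals[-1][0], mapping.intervals[-1][1])
        sel = (hu >= lo) & ((hu <= hi) if last else (hu < hi))
        mat[sel] = mid
        if isinstance(density, tuple):
            r_lo, r_hi = density
            rho[sel] = r_lo + (hu[sel] - lo) / (hi - lo) * (r_hi - r_lo)
        else:
            rho[sel] = density
    uncovered = np.argwhere(mat == 255)
    if len(uncovered):
        i, j, k = uncovered[0]
        raise ValueError(
            f"HU value {hu[i, j, k]} at voxel ({i}, {j}, {k}) not covered "
            "by mapping")
    return VoxelPhantom(mat, rho, tuple(spacing), tuple(origin), tuple(names))


# --- raw + sidecar I/O -------------------------------------------------------

def write_volume(phantom: VoxelPhantom, path) -> None:
    """Write ``<stem>.json`` sidecar plus ``<stem>.mat.raw`` / ``.rho.raw``."""
    stem = Path(path).with_suffix("")
    header = {
        "format": "kvbeam-voxel-volume",
        "dims": list(phantom.dims),
        "spacing_cm": list(phantom.spacing),
        "origin_cm": list(phantom.origin),
        "materials": list(phantom.material_names),
        "dtypes": {"material": "uint8", "density": "<f4"},
        "order": "C (z fastest)",
    }
    stem.with_suffix(".json").write_text(json.dumps(header, indent=1))
    phantom.material.astype(np.uint8).tofile(stem.with_suffix(".mat.raw"))
    phantom.density.astype("<f4").tofile(stem.with_suffix(".rho.raw"))


def read_volume(path) -> VoxelPhantom:
    """Inverse of :func:`write_volume`; bit-exact round trip."""
    stem = Path(path).with_suffix("")
    try:
        header = json.loads(stem.with_suffix(".json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed or missing header {stem}.json: {exc}")
    dims = tuple(header["dims"])
    n = int(np.prod(dims))
    mat_raw = stem.with_suffix(".mat.raw").read_bytes()
    rho_raw = stem.with_suffix(".rho.raw").read_bytes()
    if len(mat_raw) != n:
        raise ValueError(
            f"{stem}.mat.raw: expected {n} bytes, found {len(mat_raw)}")
    if len(rho_raw) != 4 * n:
        raise ValueError(
            f"{stem}.rho.raw: expected {4 * n} bytes, found {len(rho_raw)}")
    mat = np.frombuffer(mat_raw, dtype=np.uint8).reshape(dims).copy()
    rho = np.frombuffer(rho_raw, dtype="<f4").reshape(dims).copy()
    return VoxelPhantom(mat, rho, tuple(header["spacing_cm"]),
                        tuple(header["origin_cm"]),
                        tuple(header["materials"]))
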