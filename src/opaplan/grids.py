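"""Volumetric rasters and named structure masks.

Axis convention (fixed throughout the package):

* axis 0 (x): patient left -> right
* axis 1 (y): posterior -> anterior
* axis 2 (z): inferior -> superior

``spacing`` and ``origin`` are in millimetres; ``origin`` is the physical
coordinate of the *center* of voxel ``(0, 0, 0)``.  Dose values are in Gy,
mask values are boolean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

from .errors import GeometryError

# canonical structure names
BODY = "BODY"
LUNG_L = "LUNG_L"
LUNG_R = "LUNG_R"
LUNG_WHOLE = "LUNG_WHOLE"
PTV = "PTV"
HEART = "HEART"
CORD = "CORD"

STRUCTURE_NAMES = (BODY, LUNG_L, LUNG_R, LUNG_WHOLE, PTV, HEART, CORD)


@dataclass
class VolumeGrid:
    """A scalar field sampled on a regular 3D lattice.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz)``; Gy for dose, anything scalar
        otherwise.
    spacing_mm
        Voxel pitch along (x, y, z), strictly positive.
    origin_mm
        Physical coordinate of the center of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GeometryError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or len(self.origin_mm) != 3:
            raise GeometryError("spacing_mm and origin_mm must be length-3")
        if any(s <= 0 for s in self.spacing_mm):
            raise GeometryError(f"spacing must be > 0, got {self.spacing_mm}")
        if any(n < 1 for n in self.values.shape):
            raise GeometryError(f"shape components must be >= 1, got {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.spacing_mm[axis]

    def like(self, values: np.ndarray) -> "VolumeGrid":
        """A new grid on the same lattice with different values."""
        return replace(self, values=values)

    def same_lattice(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass
class StructureSet:
    """Named binary masks sharing one lattice.

    Required masks: BODY, PTV, LUNG_WHOLE.  LUNG_L/LUNG_R, HEART and CORD
    are optional (phantom variants may omit them).  Invariants enforced:
    every mask lies inside BODY (the PTV may overlap lung masks -- a
    mediastinal target abuts lung), and LUNG_WHOLE is the union of LUNG_L
    and LUNG_R when both are present.
    """

    grid: VolumeGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            self.masks[name] = m
            if m.shape != self.grid.shape:
                raise GeometryError(f"mask {name!r} shape {m.shape} != grid {self.grid.shape}")
        for required in (BODY, PTV, LUNG_WHOLE):
            if required not in self.masks:
                raise GeometryError(f"required mask {required!r} missing")
        body = self.masks[BODY]
        for name, m in self.masks.items():
            if name != BODY and np.any(m & ~body):
                raise GeometryError(f"mask {name!r} extends outside BODY")
        if LUNG_L in self.masks and LUNG_R in self.masks:
            union = self.masks[LUNG_L] | self.masks[LUNG_R]
            if not np.array_equal(union, self.masks[LUNG_WHOLE]):
                raise GeometryError("LUNG_WHOLE != LUNG_L | LUNG_R")

    def mask(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> Iterator[str]:
        return iter(self.masks)

    def volume_cm3(self, name: str) -> float:
        return float(np.count_nonzero(self.masks[name])) * self.grid.voxel_volume_cm3

    def translated(self, shift_mm: tuple[float, float, float]) -> "StructureSet":
        """Same masks on a lattice whose origin is shifted (for invariance tests)."""
        new_origin = tuple(o + s for o, s in zip(self.grid.origin_mm, shift_mm))
        return StructureSet(
            grid=VolumeGrid(self.grid.values, self.grid.spacing_mm, new_origin),
            masks=dict(self.masks),
        )


def mask_extent_mm(mask: np.ndarray, grid: VolumeGrid, axis: int) -> float:
    """Physical extent of a mask along an axis.

    Measured center-to-center between the extreme occupied voxels, plus one
    voxel pitch so a single-voxel mask has extent equal to the pitch.
    """
    idx = np.flatnonzero(mask.any(axis=tuple(a for a in range(3) if a != axis)))
    if idx.size == 0:
        return 0.0
    return float((idx[-1] - idx[0] + 1) * grid.spacing_mm[axis])
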