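"""Digital thorax phantoms and geometric measurement.

Two phantom families are provided:

* :func:`build_thorax_phantom` -- an anthropomorphic-ish thorax: elliptic
  body cylinder, two lateral ellipsoidal lungs, a central mediastinal PTV
  (elliptic cylinder of width E and length Lt), an ellipsoidal heart and a
  cylindrical spinal cord.  Deliberately built from analytic solids so
  every measured quantity has a closed-form oracle.
* :func:`build_idealized_cylinder_phantom` -- the circular-cylinder
  geometry underlying the partial-arc lung-volume model: circular body,
  central cylindrical PTV, and lung tissue filling the annulus between the
  beam corridor and the skin.  Used to compare voxel-level unirradiated
  lung volume against the closed-form restricted-volume expression.

All phantom dimensions are centimetres; grids are stored in millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import grids
from .errors import GeometryError, MeasurementError
from .grids import StructureSet, VolumeGrid, mask_extent_mm

log = logging.getLogger(__name__)


@dataclass
class GeometryInputs:
    """The six scalars the arc-angle solver consumes.

    T: transverse thorax diameter (cm); E: PTV width (cm); Lt: PTV axial
    length (cm); V_W: whole-lung volume (cm^3); V_OW: lung volume outside
    the cranio-caudal field slab (cm^3); expected_v5: target fraction of
    lung receiving >= 5 Gy (0..1).
    """

    T: float
    E: float
    Lt: float
    V_W: float
    V_OW: float
    expected_v5: float = 0.55

    def __post_init__(self) -> None:
        if not (self.T > self.E):
            raise GeometryError(f"need T > E, got T={self.T}, E={self.E}")
        if min(self.T, self.E, self.Lt) <= 0:
            raise GeometryError("all lengths must be > 0")
        if not (0.0 <= self.V_OW <= self.V_W):
            raise GeometryError(f"need 0 <= V_OW <= V_W, got {self.V_OW} vs {self.V_W}")
        if self.V_W <= 0:
            raise GeometryError("whole-lung volume must be > 0")
        if not (0.0 < self.expected_v5 < 1.0):
            raise GeometryError(f"expected_v5 must be in (0, 1), got {self.expected_v5}")


@dataclass
class PhantomSpec:
    """Parameters of the analytic thorax phantom (all lengths cm).

    The body is an elliptic cylinder spanning the whole grid in z (a
    constant axial cross-section keeps parallel-beam entry depths
    z-independent).  ``jitter_sigma_cm`` adds a small seeded Gaussian
    perturbation to structure centers, emulating patient-to-patient
    placement variability while staying deterministic for a fixed seed.
    """

    body_semiaxis_x_cm: float = 15.0
    body_semiaxis_y_cm: float = 10.0
    lung_offset_x_cm: float = 8.0
    lung_semiaxes_cm: tuple[float, float, float] = (5.5, 7.5, 13.0)
    ptv_width_cm: float = 6.0        # E, left-right
    ptv_depth_cm: float = 6.0        # anterior-posterior
    ptv_length_cm: float = 16.0      # Lt, cranio-caudal
    heart_center_cm: tuple[float, float, float] = (2.0, 3.0, -5.0)
    heart_semiaxes_cm: tuple[float, float, float] = (4.0, 3.5, 4.5)
    cord_center_y_cm: float = -7.0
    cord_radius_cm: float = 0.6
    voxel_spacing_mm: float = 3.0
    z_margin_cm: float = 2.0
    jitter_sigma_cm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ptv_width_cm >= 2 * self.body_semiaxis_x_cm:
            raise GeometryError("PTV wider than the body")
        if self.ptv_depth_cm >= 2 * self.body_semiaxis_y_cm:
            raise GeometryError("PTV deeper than the body")
        if min(self.ptv_width_cm, self.ptv_depth_cm, self.ptv_length_cm) <= 0:
            raise GeometryError("PTV dimensions must be positive")
        if self.voxel_spacing_mm <= 0:
            raise GeometryError("voxel spacing must be positive")
        if any(a < 0 for a in self.lung_semiaxes_cm):
            raise GeometryError("lung semi-axes must be non-negative")

    @property
    def grid_z_extent_cm(self) -> float:
        return max(self.ptv_length_cm, 2 * self.lung_semiaxes_cm[2]) + 2 * self.z_margin_cm


def _build_grid(extent_x_cm: float, extent_y_cm: float, extent_z_cm: float,
                spacing_mm: float) -> VolumeGrid:
    sp = spacing_mm
    n = [max(1, int(np.ceil(e * 10.0 / sp))) for e in (extent_x_cm, extent_y_cm, extent_z_cm)]
    origin = tuple(-(ni - 1) / 2.0 * sp for ni in n)
    return VolumeGrid(np.zeros(tuple(n), dtype=np.uint8), (sp, sp, sp), origin)


def build_thorax_phantom(spec: PhantomSpec) -> StructureSet:
    """Rasterize the analytic thorax described by ``spec``.

    Deterministic for a fixed seed; with ``jitter_sigma_cm == 0`` the
    structures sit exactly at their nominal centers.
    """
    grid = _build_grid(2 * spec.body_semiaxis_x_cm + 2.0,
                       2 * spec.body_semiaxis_y_cm + 2.0,
                       spec.grid_z_extent_cm,
                       spec.voxel_spacing_mm)
    x = grid.axis_coords_mm(0) / 10.0  # cm
    y = grid.axis_coords_mm(1) / 10.0
    z = grid.axis_coords_mm(2) / 10.0
    X, Y = np.meshgrid(x, y, indexing="ij")

    rng = np.random.default_rng(spec.seed)
    def jitter() -> np.ndarray:
        if spec.jitter_sigma_cm <= 0:
            return np.zeros(3)
        return rng.normal(0.0, spec.jitter_sigma_cm, size=3)

    body2d = (X / spec.body_semiaxis_x_cm) ** 2 + (Y / spec.body_semiaxis_y_cm) ** 2 <= 1.0
    body = np.broadcast_to(body2d[:, :, None], grid.shape).copy()

    jp = jitter()
    ptv2d = (((X - jp[0]) / (spec.ptv_width_cm / 2)) ** 2
             + ((Y - jp[1]) / (spec.ptv_depth_cm / 2)) ** 2) <= 1.0
    zptv = np.abs(z - jp[2]) <= spec.ptv_length_cm / 2
    ptv = ptv2d[:, :, None] & zptv[None, None, :] & body

    la, lb, lc = spec.lung_semiaxes_cm
    lungs = {}
    for name, sgn in ((grids.LUNG_R, -1), (grids.LUNG_L, +1)):
        # patient right = -x under the left->right axis convention
        if la <= 0 or lb <= 0 or lc <= 0:
            lungs[name] = np.zeros(grid.shape, dtype=bool)
            continue
        jl = jitter()
        q2d = (((X - sgn * spec.lung_offset_x_cm - jl[0]) / la) ** 2
               + ((Y - jl[1]) / lb) ** 2)
        lungs[name] = (q2d[:, :, None] + ((z[None, None, :] - jl[2]) / lc) ** 2) <= 1.0
        lungs[name] &= body

    jh = jitter()
    hc = np.asarray(spec.heart_center_cm) + jh
    ha, hb, hcz = spec.heart_semiaxes_cm
    heart = ((((X - hc[0]) / ha) ** 2 + ((Y - hc[1]) / hb) ** 2)[:, :, None]
             + ((z[None, None, :] - hc[2]) / hcz) ** 2) <= 1.0
    heart &= body & ~ptv

    cord2d = X ** 2 + (Y - spec.cord_center_y_cm) ** 2 <= spec.cord_radius_cm ** 2
    cord = np.broadcast_to(cord2d[:, :, None], grid.shape) & body

    masks = {
        grids.BODY: body,
        grids.PTV: ptv,
        grids.LUNG_L: lungs[grids.LUNG_L] & ~ptv,
        grids.LUNG_R: lungs[grids.LUNG_R] & ~ptv,
        grids.HEART: heart,
        grids.CORD: cord,
    }
    masks[grids.LUNG_WHOLE] = masks[grids.LUNG_L] | masks[grids.LUNG_R]
    return StructureSet(grid=grid, masks=masks)


def build_idealized_cylinder_phantom(
    T_cm: float = 30.0,
    E_cm: float = 6.0,
    Lt_cm: float = 16.0,
    field_margin_cm: float = 2.0,
    lung_cap_cm: float = 0.0,
    voxel_spacing_mm: float = 3.0,
) -> StructureSet:
    """Circular-cylinder phantom realizing the restricted-volume model.

    Body: disc of diameter ``T_cm`` (elliptic cylinder with equal axes).
    PTV: central cylinder of diameter ``E_cm``, length ``Lt_cm``.
    Lung: the annulus between the beam-corridor half-width
    ``E/2 + field_margin_cm`` and the skin, spanning the cranio-caudal
    field slab ``Lt + 2*field_margin_cm`` exactly, plus optional caps of
    ``lung_cap_cm`` per side beyond the slab (these contribute V_OW and
    receive no dose by construction).
    """
    if E_cm + 2 * field_margin_cm >= T_cm:
        raise GeometryError("beam corridor as wide as the body: no lateral lung annulus")
    w = E_cm / 2 + field_margin_cm
    B = T_cm / 2
    slab_half = Lt_cm / 2 + field_margin_cm
    grid = _build_grid(T_cm + 2.0, T_cm + 2.0,
                       2 * (slab_half + lung_cap_cm) + 2.0, voxel_spacing_mm)
    x = grid.axis_coords_mm(0) / 10.0
    y = grid.axis_coords_mm(1) / 10.0
    z = grid.axis_coords_mm(2) / 10.0
    X, Y = np.meshgrid(x, y, indexing="ij")
    r2 = X ** 2 + Y ** 2

    body2d = r2 <= B ** 2
    body = np.broadcast_to(body2d[:, :, None], grid.shape).copy()
    ptv = ((r2 <= (E_cm / 2) ** 2)[:, :, None]
           & (np.abs(z) <= Lt_cm / 2)[None, None, :])
    lung2d = (r2 > w ** 2) & body2d
    lung = lung2d[:, :, None] & (np.abs(z) <= slab_half + lung_cap_cm)[None, None, :]
    masks = {
        grids.BODY: body,
        grids.PTV: ptv,
        grids.LUNG_L: lung & (X > 0)[:, :, None],
        grids.LUNG_R: lung & (X <= 0)[:, :, None],
    }
    masks[grids.LUNG_WHOLE] = masks[grids.LUNG_L] | masks[grids.LUNG_R]
    return StructureSet(grid=grid, masks=masks)


def measure_geometry(
    structs: StructureSet,
    field_margin_cm: float = 2.0,
    expected_v5: float = 0.55,
    extent_mode: str = "centroid_plane",
) -> GeometryInputs:
    """Measure the solver's inputs from structure masks.

    E is the maximal left-right PTV extent on the axial slice through the
    PTV centroid; Lt the superior-inferior extent on the coronal plane
    through the centroid; T the left-right BODY extent on the same axial
    slice.  V_W is the voxelized whole-lung volume and V_OW the lung
    volume outside the axial slab ``[PTV_inf - margin, PTV_sup + margin]``
    (margin per side; the default 2 cm yields the customary 4 cm total
    added to Lt).  Extents are center-to-center plus one voxel pitch.

    ``extent_mode='bbox'`` switches E/Lt/T to global bounding-box extents,
    a more robust choice for concave targets.
    """
    ptv = structs.mask(grids.PTV)
    if not ptv.any():
        raise MeasurementError("PTV mask is empty")
    lung = structs.mask(grids.LUNG_WHOLE)
    body = structs.mask(grids.BODY)
    grid = structs.grid
    if extent_mode not in ("centroid_plane", "bbox"):
        raise ValueError(f"unknown extent_mode {extent_mode!r}")

    ii, jj, kk = np.nonzero(ptv)
    ci, cj, ck = (int(round(v.mean())) for v in (ii, jj, kk))
    if extent_mode == "centroid_plane":
        E_mm = mask_extent_mm(ptv[:, :, ck][:, :, None], grid, 0)
        T_mm = mask_extent_mm(body[:, :, ck][:, :, None], grid, 0)
        Lt_mm = mask_extent_mm(ptv[:, cj, :][:, None, :], grid, 2)
    else:
        E_mm = mask_extent_mm(ptv, grid, 0)
        T_mm = mask_extent_mm(body, grid, 0)
        Lt_mm = mask_extent_mm(ptv, grid, 2)

    voxvol = grid.voxel_volume_cm3
    V_W = float(np.count_nonzero(lung)) * voxvol

    z = grid.axis_coords_mm(2) / 10.0  # cm
    dz_cm = grid.spacing_mm[2] / 10.0
    ptv_z = z[kk]
    lo = ptv_z.min() - dz_cm / 2 - field_margin_cm
    hi = ptv_z.max() + dz_cm / 2 + field_margin_cm
    out_slab = (z < lo) | (z > hi)
    V_OW = float(np.count_nonzero(lung & out_slab[None, None, :])) * voxvol

    geom = GeometryInputs(T=T_mm / 10.0, E=E_mm / 10.0, Lt=Lt_mm / 10.0,
                          V_W=V_W, V_OW=V_OW, expected_v5=expected_v5)
    log.info("measured geometry: T=%.2f E=%.2f Lt=%.2f V_W=%.1f V_OW=%.1f",
             geom.T, geom.E, geom.Lt, geom.V_W, geom.V_OW)
    return geom
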