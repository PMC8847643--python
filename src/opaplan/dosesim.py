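"""Forward arc-dose simulator.

A deliberately simple, fully documented dose model that makes arc-angle
choices testable end-to-end:

* parallel (non-divergent) beams, one per control point, entering along
  the gantry direction (0 deg = anterior);
* beam's-eye-view aperture = the 2D projection of the PTV onto the plane
  perpendicular to the beam, dilated by a circular margin;
* primary dose only, attenuated exponentially with depth in the
  homogeneous unit-density body, ``exp(-mu * depth_cm)``;
* the accumulated field is globally scaled so a normalization statistic
  on the PTV (mean dose or D95) equals the prescription.

Parallel beams keep the never-irradiated ("restricted") lateral region
exactly cylindrical, matching the angle-solver's geometric model; there
is no scatter, so that region receives exactly zero dose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import grids
from .errors import DomainError, GeometryError, MeasurementError
from .grids import StructureSet, VolumeGrid
from .vba import ArcPlan

log = logging.getLogger(__name__)


@dataclass
class BeamModel:
    """Tunable parameters of the toy beam.

    mu_per_cm: linear attenuation coefficient (megavoltage order).
    aperture_margin_cm: circular dilation of the PTV projection; equals
    the field margin used by the restricted-radius formula (2 cm).
    control_point_spacing_deg: gantry sampling of each arc.
    normalization: 'PTV_MEAN' scales mean PTV dose to the prescription;
    'PTV_D95' scales the dose covering 95% of the PTV instead.
    """

    mu_per_cm: float = 0.05
    aperture_margin_cm: float = 2.0
    control_point_spacing_deg: float = 4.0
    normalization: str = "PTV_MEAN"

    def __post_init__(self) -> None:
        if self.mu_per_cm <= 0:
            raise DomainError("mu must be > 0")
        if self.aperture_margin_cm < 0:
            raise DomainError("aperture margin must be >= 0")
        if self.control_point_spacing_deg <= 0:
            raise DomainError("control-point spacing must be > 0")
        if self.normalization not in ("PTV_MEAN", "PTV_D95"):
            raise DomainError(f"unknown normalization {self.normalization!r}")


@dataclass
class PlanSpec:
    """Prescription: total dose and fractionation."""

    total_dose_gy: float = 45.0
    fractions: int = 25

    def __post_init__(self) -> None:
        if self.total_dose_gy <= 0 or self.fractions < 1:
            raise DomainError("prescription must be positive")

    @property
    def dose_per_fraction_gy(self) -> float:
        return self.total_dose_gy / self.fractions


def control_points(plan: ArcPlan, spacing: float | None = None) -> np.ndarray:
    """All control-point gantry angles of a plan, in delivery order.

    Per arc: angles from start towards stop at the given spacing in the
    arc's rotation sense, with both endpoints included (a short final
    step lands exactly on the stop angle).
    """
    sp = plan.gantry_spacing if spacing is None else spacing
    return np.concatenate([arc.angles(sp) for arc in plan.arcs])


def _require(structs: StructureSet) -> tuple[np.ndarray, np.ndarray]:
    body = structs.mask(grids.BODY)
    ptv = structs.mask(grids.PTV)
    if not body.any():
        raise GeometryError("BODY mask is empty")
    if not ptv.any():
        raise MeasurementError("PTV mask is empty")
    return body, ptv


class _BeamGeometry:
    """Per-phantom precomputation shared by all control points."""

    def __init__(self, structs: StructureSet, beam: BeamModel):
        grid = structs.grid
        self.grid = grid
        self.body, self.ptv = _require(structs)
        x_cm = grid.axis_coords_mm(0) / 10.0
        y_cm = grid.axis_coords_mm(1) / 10.0
        self.z_cm = grid.axis_coords_mm(2) / 10.0
        self.X, self.Y = np.meshgrid(x_cm, y_cm, indexing="ij")
        self.nz = grid.shape[2]
        # lateral bin grid for the (u, z) aperture plane
        self.du = min(grid.spacing_mm[:2]) / 10.0
        umax = float(np.hypot(np.abs(x_cm).max(), np.abs(y_cm).max())) + self.du
        self.nu = 2 * int(np.ceil(umax / self.du)) + 1
        self.u0 = -(self.nu - 1) / 2.0 * self.du
        pi, pj, self.pk = np.nonzero(self.ptv)
        self.px, self.py = x_cm[pi], y_cm[pj]
        # z-uniform body cross-section enables a 2D entry-depth fast path
        body2d = self.body.any(axis=2)
        if not np.array_equal(self.body, np.broadcast_to(body2d[:, :, None], self.body.shape)):
            raise GeometryError(
                "simulator requires a z-uniform BODY (constant axial cross-section)"
            )
        self.body2d = body2d
        self.margin = beam.aperture_margin_cm
        self.mu = beam.mu_per_cm

    def _ubin(self, u: np.ndarray) -> np.ndarray:
        return np.clip(np.round((u - self.u0) / self.du).astype(np.intp), 0, self.nu - 1)

    def aperture_and_attenuation(self, gantry_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(aperture[u, z], attenuation2d[x, y], ubin2d[x, y]) for one angle."""
        g = np.deg2rad(gantry_deg)
        c, s = np.cos(g), np.sin(g)
        U = self.X * c - self.Y * s        # lateral coordinate, beam's eye view
        W = self.X * s + self.Y * c        # towards the source
        ub = self._ubin(U)
        # aperture: PTV projection on (u, z), dilated by a circular margin
        occ = np.zeros((self.nu, self.nz), dtype=bool)
        occ[self._ubin(self.px * c - self.py * s), self.pk] = True
        dist = ndimage.distance_transform_edt(
            ~occ, sampling=(self.du, self.grid.spacing_mm[2] / 10.0)
        )
        aperture = dist <= self.margin
        # entry depth per ray column (convex z-uniform body: single interval)
        entry = np.full(self.nu, -np.inf)
        np.maximum.at(entry, ub[self.body2d], W[self.body2d])
        depth = entry[ub] - W
        att = np.where(self.body2d, np.exp(-self.mu * np.clip(depth, 0.0, None)), 0.0)
        return aperture, att, ub


def _unique_angles(plan: ArcPlan, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Unique gantry angles with trapezoidal quadrature weights.

    Each control point represents half the angular interval on either
    side of it within its arc, so an irregular final step (the remainder
    landing on the arc's stop angle) is weighted by the arc length it
    stands for, not as a full extra beam.
    """
    all_angles: list[np.ndarray] = []
    all_weights: list[np.ndarray] = []
    for arc in plan.arcs:
        a = arc.angles(spacing)
        offs = (a - arc.start) % 360.0 if arc.direction == "CW" else (arc.start - a) % 360.0
        offs[0] = 0.0
        w = np.empty_like(offs)
        if len(offs) == 1:
            w[:] = arc.span
        else:
            gaps = np.diff(offs)
            w[0] = gaps[0] / 2.0
            w[-1] = gaps[-1] / 2.0
            w[1:-1] = (gaps[:-1] + gaps[1:]) / 2.0
        all_angles.append(np.round(a, 6) % 360.0)
        all_weights.append(w)
    angles = np.concatenate(all_angles)
    weights = np.concatenate(all_weights)
    uniq, inverse = np.unique(angles, return_inverse=True)
    agg = np.zeros(uniq.size)
    np.add.at(agg, inverse, weights)
    return uniq, agg


def simulate_dose(
    structs: StructureSet,
    plan: ArcPlan,
    beam: BeamModel | None = None,
    rx: PlanSpec | None = None,
) -> VolumeGrid:
    """Accumulate dose over a plan's control points and normalize.

    Returns a dose grid in Gy on the structure set's lattice.  The result
    is deterministic; control points at coincident gantry angles (the CW
    and CCW passes of the same sector) are weighted, not recomputed.
    """
    beam = beam or BeamModel()
    rx = rx or PlanSpec()
    geo = _BeamGeometry(structs, beam)
    angles, weights = _unique_angles(plan, beam.control_point_spacing_deg)
    dose = np.zeros(structs.grid.shape)
    for g, wgt in zip(angles, weights):
        aperture, att, ub = geo.aperture_and_attenuation(g)
        dose += (wgt * att)[:, :, None] * aperture[ub, :]
    ptv_dose = dose[geo.ptv]
    if beam.normalization == "PTV_MEAN":
        stat = float(ptv_dose.mean())
    else:  # PTV_D95: dose exceeded by 95% of the target
        stat = float(np.percentile(ptv_dose, 5.0))
    if stat <= 0:
        raise GeometryError("plan delivers no dose to the PTV; cannot normalize")
    dose *= rx.total_dose_gy / stat
    log.info("simulated %s plan: %d unique gantry angles, %.1f deg total weight",
             plan.plan_type, len(angles), float(weights.sum()))
    return structs.grid.like(dose)


def simulate_fixed_beams(
    structs: StructureSet,
    gantry_angles_deg: np.ndarray | list[float],
    beam: BeamModel | None = None,
) -> VolumeGrid:
    """Unnormalized dose from an explicit list of beam angles.

    A lower-level entry point (single-beam studies, custom samplings);
    :func:`simulate_dose` is the plan-level interface.
    """
    beam = beam or BeamModel()
    geo = _BeamGeometry(structs, beam)
    dose = np.zeros(structs.grid.shape)
    for g in np.atleast_1d(np.asarray(gantry_angles_deg, dtype=float)):
        aperture, att, ub = geo.aperture_and_attenuation(g % 360.0)
        dose += att[:, :, None] * aperture[ub, :]
    return structs.grid.like(dose)


def geometric_unirradiated_fraction(
    structs: StructureSet,
    plan: ArcPlan,
    beam: BeamModel | None = None,
) -> float:
    """Fraction of lung voxels traversed by no control-point aperture.

    The voxel-level brute-force counterpart of the solver's restricted
    volume divided by V_W.
    """
    beam = beam or BeamModel()
    lung = structs.mask(grids.LUNG_WHOLE)
    if not lung.any():
        raise MeasurementError("LUNG_WHOLE mask is empty")
    geo = _BeamGeometry(structs, beam)
    angles, _ = _unique_angles(plan, beam.control_point_spacing_deg)
    irradiated = np.zeros(structs.grid.shape, dtype=bool)
    for g in angles:
        aperture, _, ub = geo.aperture_and_attenuation(g)
        irradiated |= aperture[ub, :] & geo.body2d[:, :, None]
    n_lung = np.count_nonzero(lung)
    return float(np.count_nonzero(lung & ~irradiated)) / n_lung
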