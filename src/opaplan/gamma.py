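"""Gamma-index comparison of two dose distributions.

For each reference point p above the low-dose cutoff,

    gamma(p) = min over r' of sqrt(|r' - p|^2 / DTA^2
                                   + (D_e(r') - D_r(p))^2 / dD^2)

where D_e is the evaluated distribution interpolated continuously,
DTA the distance-to-agreement criterion and dD the dose criterion as a
percentage of the *global* reference maximum.  A point passes when
gamma <= 1; the passing rate is the percentage of included reference
points that pass.

The search is n-dimensional (singleton axes are squeezed, so planar 2D
fields stored as (nx, ny, 1) grids work unchanged), samples candidate
displacements on a sphere of radius ``search_radius_multiple * DTA`` at
a step of ``DTA / subsample``, and uses linear interpolation of the
evaluated grid.  Displacements are visited in order of increasing
radius with an active-set shrink: once a point's running minimum cannot
be improved by any farther displacement it is retired, which makes the
identical-distribution case O(1) displacements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import DomainError, GeometryError
from .grids import VolumeGrid


@dataclass
class GammaSpec:
    """Criteria and numerical knobs of the gamma comparison."""

    dose_criterion_pct: float = 3.0
    dta_mm: float = 3.0
    pass_threshold_pct: float = 95.0
    low_dose_cutoff_pct: float = 10.0
    search_radius_multiple: float = 3.0
    subsample: int = 10  # displacement samples per DTA

    def __post_init__(self) -> None:
        for name in ("dose_criterion_pct", "dta_mm", "pass_threshold_pct",
                     "low_dose_cutoff_pct", "search_radius_multiple"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        if self.subsample < 1:
            raise DomainError("subsample must be >= 1")


@dataclass
class GammaResult:
    pass_rate_pct: float
    passed: bool               # pass_rate >= pass_threshold
    gamma: np.ndarray          # per included reference point (capped at the search radius)
    n_points: int


def _squeeze_axes(grid: VolumeGrid) -> tuple[np.ndarray, list[np.ndarray]]:
    values = np.asarray(grid.values, dtype=float)
    axes = [grid.axis_coords_mm(a) for a in range(3)]
    keep = [a for a in range(3) if values.shape[a] > 1]
    if not keep:
        keep = [0]
    squeezed = values.reshape([values.shape[a] for a in keep])
    return squeezed, [axes[a] for a in keep]


def _displacements(spec: GammaSpec, ndim: int) -> tuple[np.ndarray, np.ndarray]:
    """Candidate displacement vectors (mm) sorted by radius."""
    step = spec.dta_mm / spec.subsample
    radius = spec.search_radius_multiple * spec.dta_mm
    n = int(np.floor(radius / step))
    axis = np.arange(-n, n + 1) * step
    mesh = np.meshgrid(*([axis] * ndim), indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    r2 = np.sum(pts ** 2, axis=1)
    keep = r2 <= radius ** 2 + 1e-12
    pts, r2 = pts[keep], r2[keep]
    order = np.argsort(r2, kind="stable")
    return pts[order], r2[order]


def gamma_passing_rate(
    reference: VolumeGrid,
    evaluated: VolumeGrid,
    spec: GammaSpec | None = None,
) -> GammaResult:
    """Global-normalization gamma passing rate of ``evaluated`` vs ``reference``."""
    spec = spec or GammaSpec()
    ref_vals, ref_axes = _squeeze_axes(reference)
    ev_vals, ev_axes = _squeeze_axes(evaluated)
    if ref_vals.ndim != ev_vals.ndim:
        raise GeometryError("reference and evaluated grids differ in dimensionality")
    if not (np.all(np.isfinite(ref_vals)) and np.all(np.isfinite(ev_vals))):
        raise DomainError("dose grids must be finite")
    # geometric overlap of bounding boxes
    for ra, ea in zip(ref_axes, ev_axes):
        if ra[0] > ea[-1] or ea[0] > ra[-1]:
            raise GeometryError("reference and evaluated grids do not overlap")

    ref_max = float(ref_vals.max())
    if ref_max <= 0:
        raise DomainError("reference distribution has no positive dose")
    dose_norm = spec.dose_criterion_pct / 100.0 * ref_max
    cutoff = spec.low_dose_cutoff_pct / 100.0 * ref_max

    include = ref_vals >= cutoff
    if not include.any():
        raise DomainError("all reference points fall below the low-dose cutoff")
    idx = np.nonzero(include)
    pts = np.stack([ax[i] for ax, i in zip(ref_axes, idx)], axis=1)
    ref_d = ref_vals[include]

    interp = RegularGridInterpolator(
        ev_axes, ev_vals, method="linear", bounds_error=False, fill_value=np.nan
    )
    disp, disp_r2 = _displacements(spec, ref_vals.ndim)
    dta2 = spec.dta_mm ** 2

    n = pts.shape[0]
    gamma2 = np.full(n, np.inf)
    active = np.arange(n)
    batch = 64
    for b0 in range(0, disp.shape[0], batch):
        if active.size == 0:
            break
        d_b = disp[b0:b0 + batch]
        r2_b = disp_r2[b0:b0 + batch] / dta2
        if r2_b[0] >= gamma2[active].max():
            break
        coords = pts[active][:, None, :] + d_b[None, :, :]
        vals = interp(coords.reshape(-1, pts.shape[1])).reshape(active.size, d_b.shape[0])
        vals = np.where(np.isnan(vals), np.inf, vals)  # outside the evaluated grid
        dd2 = ((vals - ref_d[active][:, None]) / dose_norm) ** 2
        cand = np.min(r2_b[None, :] + dd2, axis=1)
        np.minimum.at(gamma2, active, cand)
        # a point stays active while a farther displacement could improve it
        active = active[gamma2[active] > r2_b[-1]]

    gamma = np.sqrt(gamma2)
    rate = 100.0 * float(np.count_nonzero(gamma <= 1.0)) / n
    return GammaResult(
        pass_rate_pct=rate,
        passed=rate >= spec.pass_threshold_pct,
        gamma=gamma,
        n_points=n,
    )
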