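"""Independent oracles used by the test suite.

These deliberately re-derive quantities by brute force (root bracketing,
exhaustive search, direct voxel counting) so they share no code path with
the implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import brentq

import opaplan as op


def bisect_theta(geom: op.GeometryInputs, margin_total: float = 4.0) -> float:
    """Numeric root of the restricted-volume balance equation in theta."""
    R = (geom.T - geom.E - margin_total) / 2.0

    def f(theta: float) -> float:
        restricted = (np.pi * R * R * (360.0 - theta) / 360.0
                      * (geom.Lt + margin_total)) + geom.V_OW
        return restricted - geom.V_W * (1.0 - geom.expected_v5)

    return brentq(f, 0.0, 360.0, xtol=1e-12, rtol=1e-15)


def brute_force_vx(dose: np.ndarray, mask: np.ndarray, level_gy: float) -> float:
    """V_x by direct voxel counting."""
    d = dose[mask]
    return 100.0 * np.count_nonzero(d >= level_gy) / d.size


def brute_force_gamma_rate(
    reference: op.VolumeGrid,
    evaluated: op.VolumeGrid,
    spec: op.GammaSpec,
    upsample: int = 10,
) -> float:
    """Exhaustive-search gamma passing rate.

    Resamples the evaluated distribution onto a lattice ``upsample`` times
    finer, then for every reference point above the cutoff scans *all*
    fine-lattice points inside a window of one DTA (sufficient to decide
    gamma <= 1) without any early exit or active-set logic.
    """
    ref = np.asarray(reference.values, dtype=float)
    keep = [a for a in range(3) if ref.shape[a] > 1]
    ref = ref.reshape([ref.shape[a] for a in keep])
    ref_axes = [reference.axis_coords_mm(a) for a in keep]
    ev = np.asarray(evaluated.values, dtype=float)
    ev = ev.reshape([ev.shape[a] for a in keep])
    ev_axes = [evaluated.axis_coords_mm(a) for a in keep]

    fine_axes = [np.linspace(ax[0], ax[-1], (len(ax) - 1) * upsample + 1)
                 for ax in ev_axes]
    interp = RegularGridInterpolator(ev_axes, ev, method="linear")
    mesh = np.meshgrid(*fine_axes, indexing="ij")
    fine_vals = interp(np.stack([m.ravel() for m in mesh], axis=1)).reshape(mesh[0].shape)

    ref_max = ref.max()
    norm = spec.dose_criterion_pct / 100.0 * ref_max
    cutoff = spec.low_dose_cutoff_pct / 100.0 * ref_max
    idx = np.nonzero(ref >= cutoff)
    pts = np.stack([ax[i] for ax, i in zip(ref_axes, idx)], axis=1)
    vals = ref[idx]

    n_pass = 0
    for p, d in zip(pts, vals):
        # exhaustive scan of the fine lattice inside a one-DTA box
        sl, local_axes = [], []
        for ax, c in zip(fine_axes, p):
            lo = np.searchsorted(ax, c - spec.dta_mm, side="left")
            hi = np.searchsorted(ax, c + spec.dta_mm, side="right")
            sl.append(slice(lo, hi))
            local_axes.append(ax[lo:hi] - c)
        window = fine_vals[tuple(sl)]
        if window.size == 0:
            continue
        r2 = sum(np.square(a)[(...,) + (None,) * (len(local_axes) - 1 - i)]
                 for i, a in enumerate(local_axes))
        g2 = r2 / spec.dta_mm ** 2 + ((window - d) / norm) ** 2
        g2 = g2[r2 <= spec.dta_mm ** 2]
        if g2.size and g2.min() <= 1.0:
            n_pass += 1
    return 100.0 * n_pass / len(vals)


def ellipsoid_cap_volume(a: float, b: float, c: float, z0: float) -> float:
    """Volume of the ellipsoid region with |z-center| > z0 (both caps)."""
    if z0 >= c:
        return 0.0
    single = np.pi * a * b * (2.0 * c / 3.0 - z0 + z0 ** 3 / (3.0 * c * c))
    return 2.0 * single
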