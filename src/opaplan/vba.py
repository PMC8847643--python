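"""The volume-based arc-angle algorithm and arc sequencing.

The algorithm turns thorax/target geometry into a personalized total
gantry span theta_A for lung-sparing VMAT of a mediastinal target:

1. The lateral "restricted" lung region on one side has radius
   ``R = (T - E - m) / 2`` where T is the transverse thorax diameter, E
   the target width and m the total lateral field margin (default 4 cm,
   i.e. 2 cm per side).
2. The unirradiated lung volume is modeled as a partial cylinder of
   radius R and length ``Lt + m`` spanning the angular complement of the
   arc, plus the out-of-field lung V_OW.  Requiring it to equal
   ``V_W * (1 - expected_V5)`` and solving for the angle gives

   ``theta_A = 360 * (1 - (V_W*(1-expected_V5) - V_OW) / (pi R^2 (Lt+m)))``

   The classic formulation uses the factor 0.45, recovered here with the
   default expected_V5 = 0.55.

Gantry angles use the IEC-style convention: 0 deg = beam entering
anteriorly, reported in [0, 360).  The sequencer splits theta_A into six
deliverable partial arcs (three clockwise, three counterclockwise) that
never traverse the 180/-180 meridian mid-arc, because C-arm linacs such
as the Elekta Versa HD cannot rotate through it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InfeasibleGeometryError, MachineLimitError
from .phantom import GeometryInputs


class Feasibility(str, enum.Enum):
    OK = "OK"
    NEEDS_FULL_ARC = "NEEDS_FULL_ARC"  # implied theta_A >= 360
    INFEASIBLE = "INFEASIBLE"          # implied theta_A <= 0


def normalize_gantry_angle(angle: float) -> float:
    """Map an angle to [0, 360); congruent mod 360 and idempotent."""
    if not math.isfinite(angle):
        raise DomainError(f"gantry angle must be finite, got {angle}")
    r = float(angle) % 360.0
    return 0.0 if r >= 360.0 else r  # tiny negatives wrap to 360.0 in float


def restricted_radius(T: float, E: float, margin_total: float = 4.0) -> float:
    """Radius (cm) of one side's restricted lung region: (T - E - m) / 2."""
    if T <= E + margin_total:
        raise InfeasibleGeometryError(
            f"T={T} <= E+margin={E + margin_total}: no lateral restricted region exists"
        )
    return (T - E - margin_total) / 2.0


@dataclass
class OpaResult:
    """Solver output: radius, angle, feasibility class, implied lung V5."""

    R: float
    theta_a: float
    feasible: Feasibility
    achieved_geometric_v5: float

    def __post_init__(self) -> None:
        if self.R < 0:
            raise DomainError("restricted radius must be >= 0")
        if self.feasible is Feasibility.OK and not (0.0 < self.theta_a < 360.0):
            raise DomainError("feasible solutions require 0 < theta_a < 360")


def solve_opa_angle(geom: GeometryInputs, margin_total: float = 4.0) -> OpaResult:
    """Closed-form personalized arc angle from the six geometry scalars.

    Solves ``pi R^2 ((360 - theta)/360) (Lt + m) + V_OW
    = V_W (1 - expected_v5)`` for theta.  When the sparing goal is met
    with no angular restriction (right side <= V_OW) the case is
    classified NEEDS_FULL_ARC with theta clamped to 360; when even a
    vanishing arc cannot spare enough lung the case is INFEASIBLE with
    theta clamped to 0.  ``achieved_geometric_v5`` reports the lung V5
    implied by the clamped angle under the same cylinder model.
    """
    R = restricted_radius(geom.T, geom.E, margin_total)
    denom = math.pi * R * R * (geom.Lt + margin_total)
    required = geom.V_W * (1.0 - geom.expected_v5) - geom.V_OW

    def implied_v5(theta: float) -> float:
        restricted = denom * (360.0 - theta) / 360.0 + geom.V_OW
        return 1.0 - min(restricted, geom.V_W) / geom.V_W

    if required <= 0.0:
        return OpaResult(R, 360.0, Feasibility.NEEDS_FULL_ARC, implied_v5(360.0))
    if denom <= 0.0 or required >= denom:
        return OpaResult(R, 0.0, Feasibility.INFEASIBLE, implied_v5(0.0))
    theta = 360.0 * (1.0 - required / denom)
    return OpaResult(R, theta, Feasibility.OK, geom.expected_v5)


@dataclass
class Arc:
    """One gantry arc; angles in degrees, stored normalized to [0, 360)."""

    start: float
    stop: float
    direction: str  # "CW" or "CCW"
    collimator_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in ("CW", "CCW"):
            raise DomainError(f"direction must be CW or CCW, got {self.direction!r}")
        self.start = normalize_gantry_angle(self.start)
        self.stop = normalize_gantry_angle(self.stop)
        if self.start == self.stop:
            raise DomainError("arc start and stop coincide")
        if self._crosses_meridian():
            raise MachineLimitError(
                f"arc {self.start} -> {self.stop} ({self.direction}) traverses 180 deg mid-arc"
            )

    @property
    def span(self) -> float:
        """Angular measure traversed, in (0, 360)."""
        d = (self.stop - self.start) % 360.0
        return d if self.direction == "CW" else (360.0 - d) % 360.0

    def _crosses_meridian(self) -> bool:
        # offset from 180 along the traversal; interior crossing only
        if self.direction == "CW":
            off = (180.0 - self.start) % 360.0
        else:
            off = (self.start - 180.0) % 360.0
        eps = 1e-9  # endpoints may sit exactly on the meridian
        return eps < off < self.span - eps

    def angles(self, spacing: float) -> np.ndarray:
        """Control-point angles from start to stop, endpoints included."""
        if spacing <= 0:
            raise DomainError("spacing must be positive")
        n = int(self.span // spacing)
        offs = np.arange(n + 1) * spacing
        if offs[-1] < self.span:
            offs = np.append(offs, self.span)
        raw = self.start + offs if self.direction == "CW" else self.start - offs
        return raw % 360.0


@dataclass
class ArcPlan:
    """An ordered, deliverable set of arcs.

    FA plans hold exactly two full (359 deg) arcs; OPA plans exactly six
    partial arcs.  ``max_seconds_per_arc`` is carried for provenance only
    (delivery-time prediction is out of scope).
    """

    arcs: list[Arc]
    plan_type: str  # "FA" or "OPA"
    gantry_spacing: float = 4.0
    max_seconds_per_arc: float | None = None

    def __post_init__(self) -> None:
        if self.plan_type not in ("FA", "OPA"):
            raise DomainError(f"plan_type must be FA or OPA, got {self.plan_type!r}")
        expected = 2 if self.plan_type == "FA" else 6
        if len(self.arcs) != expected:
            raise DomainError(
                f"{self.plan_type} plans need exactly {expected} arcs, got {len(self.arcs)}"
            )

    def coverage(self, direction: str) -> float:
        """Total angular measure covered by arcs of one rotation sense."""
        return float(sum(a.span for a in self.arcs if a.direction == direction))


def sequence_full_arcs(collimator_offset: float = 5.0) -> ArcPlan:
    """The two-full-arc baseline: CW 180 -> 179, then CCW 179 -> 180.

    Each arc spans 359 deg; the collimator of the second arc is rotated by
    ``collimator_offset`` to reduce tongue-and-groove overlap.
    """
    arcs = [
        Arc(180.0, 179.0, "CW", 0.0),
        Arc(179.0, 180.0, "CCW", collimator_offset),
    ]
    return ArcPlan(arcs=arcs, plan_type="FA", max_seconds_per_arc=120.0)


def sequence_opa_arcs(
    theta_a: float,
    collimator_offset: float = 5.0,
    sentinel_gap: float = 1.0,
) -> ArcPlan:
    """Split theta_A into the six deliverable partial arcs.

    CW: [180 -> 180 + q], [-q -> q], [180 - q -> 180 - gap];
    CCW: the same three sectors reversed; q = theta_A / 4.  The 1-degree
    sentinel gap short of 180 keeps every arc clear of the machine's
    rotation limit.  Per rotation sense the covered measure is
    theta_A - sentinel_gap: the anterior sector (-q, q) plus the posterior
    sector (180 - q, 180 + q) minus the sentinel.
    """
    if not (0.0 < theta_a < 360.0):
        raise DomainError(f"theta_a must be in (0, 360), got {theta_a}")
    if theta_a <= 4.0 * sentinel_gap:
        raise DomainError(
            f"theta_a={theta_a} too small for a {sentinel_gap} deg sentinel gap"
        )
    q = theta_a / 4.0
    cw = [(180.0, 180.0 + q), (-q, q), (180.0 - q, 180.0 - sentinel_gap)]
    ccw = [(180.0 - sentinel_gap, 180.0 - q), (q, -q), (180.0 + q, 180.0)]
    arcs = [Arc(a, b, "CW", 0.0) for a, b in cw]
    arcs += [Arc(a, b, "CCW", collimator_offset) for a, b in ccw]
    return ArcPlan(arcs=arcs, plan_type="OPA", max_seconds_per_arc=40.0)
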