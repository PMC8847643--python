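"""Plan-quality metrics: DVH, V_x / D_x, HI, CI and OAR constraint checks.

Conventions
-----------
* Cumulative DVH: the value at dose d is the percentage of the
  structure's volume receiving at least d Gy, so the curve starts at
  100% and is non-increasing.
* V_x (percent) and D_x (Gy) are read off the cumulative curve with
  linear interpolation between bin edges.
* HI = D5 / D95 (1 is perfectly homogeneous; up to 1.40 acceptable).
* CI = reference-isodose volume / target volume (1 is perfectly
  conformal; 0.9-2 acceptable, 2-2.5 tolerable), with the reference
  isodose at 100% of the prescription.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import grids
from .errors import DomainError, MeasurementError, MissingMetricError
from .grids import StructureSet, VolumeGrid

DEFAULT_BIN_WIDTH_GY = 0.05


@dataclass
class DVHCurve:
    """Cumulative dose-volume curve of one structure."""

    structure: str
    dose_edges_gy: np.ndarray        # uniform, ascending, starts at 0
    volume_pct: np.ndarray           # non-increasing, volume_pct[0] == 100
    volume_cm3: float

    def __post_init__(self) -> None:
        self.dose_edges_gy = np.asarray(self.dose_edges_gy, dtype=float)
        self.volume_pct = np.asarray(self.volume_pct, dtype=float)
        if self.dose_edges_gy.shape != self.volume_pct.shape:
            raise DomainError("DVH edges and values must have equal length")
        if np.any(np.diff(self.volume_pct) > 1e-9):
            raise DomainError("cumulative DVH must be non-increasing")
        if np.any((self.volume_pct < -1e-9) | (self.volume_pct > 100 + 1e-9)):
            raise DomainError("DVH values must lie in [0, 100]")


def compute_dvh(
    dose: VolumeGrid,
    mask: np.ndarray,
    structure: str = "",
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
) -> DVHCurve:
    """Cumulative DVH of ``dose`` over ``mask``.

    Bin edges run from 0 to just past the maximum structure dose in
    uniform steps.  Volume-weighting is uniform because the lattice is
    regular (each voxel carries the same volume).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MeasurementError(f"empty structure mask {structure!r}: cannot compute DVH")
    if bin_width_gy <= 0:
        raise DomainError("bin width must be > 0")
    d = np.asarray(dose.values)[mask].ravel()
    if np.any(d < 0):
        raise DomainError("dose must be non-negative")
    n_bins = int(np.ceil(d.max() / bin_width_gy)) + 1
    edges = np.arange(n_bins + 1) * bin_width_gy
    # % of voxels with dose >= edge
    d_sorted = np.sort(d)
    at_least = d.size - np.searchsorted(d_sorted, edges, side="left")
    pct = 100.0 * at_least / d.size
    return DVHCurve(
        structure=structure,
        dose_edges_gy=edges,
        volume_pct=pct,
        volume_cm3=d.size * dose.voxel_volume_cm3,
    )


def V_at_dose(dvh: DVHCurve, x_gy: float) -> float:
    """Percent of the structure receiving at least ``x_gy`` (V_0 = 100)."""
    if x_gy < 0:
        raise DomainError("dose level must be >= 0")
    return float(np.interp(x_gy, dvh.dose_edges_gy, dvh.volume_pct, right=0.0))


def D_at_volume(dvh: DVHCurve, v_pct: float) -> float:
    """Minimum dose received by the hottest ``v_pct`` of the structure.

    The largest dose at which coverage is still at least ``v_pct``,
    linearly interpolated into the next bin; D_100 is the minimum
    structure dose (to within one bin).
    """
    if not (0.0 < v_pct <= 100.0):
        raise DomainError("volume level must be in (0, 100]")
    pct, edges = dvh.volume_pct, dvh.dose_edges_gy
    idx = int(np.nonzero(pct >= v_pct)[0][-1])  # pct[0] == 100 guarantees a hit
    if idx == len(pct) - 1 or pct[idx] == v_pct:
        return float(edges[idx])
    # interpolate within the bin where coverage crosses v_pct
    frac = (pct[idx] - v_pct) / (pct[idx] - pct[idx + 1])
    return float(edges[idx] + frac * (edges[idx + 1] - edges[idx]))


@dataclass
class HIResult:
    value: float
    acceptable: bool  # within [1.00, 1.40]


def homogeneity_index(dvh: DVHCurve) -> HIResult:
    """HI = D5 / D95, with the customary acceptability band [1.00, 1.40]."""
    d95 = D_at_volume(dvh, 95.0)
    bin_width = float(dvh.dose_edges_gy[1] - dvh.dose_edges_gy[0]) \
        if len(dvh.dose_edges_gy) > 1 else 0.0
    if d95 <= bin_width:  # indistinguishable from zero at this binning
        raise DomainError("D95 = 0: homogeneity index undefined")
    hi = D_at_volume(dvh, 5.0) / d95
    return HIResult(value=hi, acceptable=1.0 <= hi <= 1.40)


@dataclass
class CIResult:
    value: float
    acceptable: bool  # within [0.9, 2]
    tolerable: bool   # within (2, 2.5]


def conformity_index(
    dose: VolumeGrid, ptv_mask: np.ndarray, reference_dose_gy: float = 45.0
) -> CIResult:
    """CI = volume of the reference isodose / target volume."""
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    if not ptv_mask.any():
        raise MeasurementError("empty PTV mask: cannot compute CI")
    if reference_dose_gy <= 0:
        raise DomainError("reference dose must be > 0")
    v_ri = np.count_nonzero(np.asarray(dose.values) >= reference_dose_gy)
    ci = float(v_ri / np.count_nonzero(ptv_mask))
    return CIResult(value=ci,
                    acceptable=0.9 <= ci <= 2.0,
                    tolerable=2.0 < ci <= 2.5)


# ---------------------------------------------------------------------------
# constraint table


@dataclass
class Constraint:
    structure: str
    metric: str       # e.g. "max_dose_gy", "mean_dose_gy", "V20_pct"
    comparator: str   # "<" or "<="
    limit: float

    def __post_init__(self) -> None:
        if self.comparator not in ("<", "<="):
            raise DomainError(f"comparator must be < or <=, got {self.comparator!r}")
        if self.limit <= 0:
            raise DomainError("constraint limits must be positive")

    def check(self, value: float) -> bool:
        return value < self.limit if self.comparator == "<" else value <= self.limit


@dataclass
class ConstraintTable:
    rows: list[Constraint]


def default_constraint_table() -> ConstraintTable:
    """The clinical OAR limits used for mediastinal 45 Gy planning.

    Spinal cord maximum < 45 Gy; mean heart dose < 34 Gy and heart V40
    < 50%; mean lung dose < 20 Gy; lung V20/V15/V10/V5 at most
    20/30/50/55% -- each lung metric applied to the whole, right and
    left lung.
    """
    rows = [Constraint(grids.CORD, "max_dose_gy", "<", 45.0),
            Constraint(grids.HEART, "mean_dose_gy", "<", 34.0),
            Constraint(grids.HEART, "V40_pct", "<", 50.0)]
    for lung in (grids.LUNG_WHOLE, grids.LUNG_R, grids.LUNG_L):
        rows.append(Constraint(lung, "mean_dose_gy", "<", 20.0))
        for metric, limit in (("V20_pct", 20.0), ("V15_pct", 30.0),
                              ("V10_pct", 50.0), ("V5_pct", 55.0)):
            rows.append(Constraint(lung, metric, "<=", limit))
    return ConstraintTable(rows=rows)


@dataclass
class ConstraintVerdict:
    structure: str
    metric: str
    value: float
    comparator: str
    limit: float
    passed: bool


def evaluate_constraints(
    metrics: Mapping[str, Mapping[str, float]],
    table: ConstraintTable | None = None,
) -> list[ConstraintVerdict]:
    """One verdict per table row; a missing metric raises, never passes."""
    table = table or default_constraint_table()
    verdicts = []
    for row in table.rows:
        try:
            value = float(metrics[row.structure][row.metric])
        except KeyError:
            raise MissingMetricError(
                f"metric {row.metric!r} for structure {row.structure!r} not supplied"
            ) from None
        verdicts.append(ConstraintVerdict(
            structure=row.structure, metric=row.metric, value=value,
            comparator=row.comparator, limit=row.limit,
            passed=row.check(value),
        ))
    return verdicts


def all_pass(verdicts: Sequence[ConstraintVerdict]) -> bool:
    return all(v.passed for v in verdicts)


# ---------------------------------------------------------------------------
# per-structure metric extraction and the plan report


V_LEVELS_GY = (5.0, 10.0, 15.0, 20.0, 30.0, 40.0)


def structure_metrics(
    dose: VolumeGrid,
    structs: StructureSet,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
) -> dict[str, dict[str, float]]:
    """Mean/max, V_x, D5/D95 for every non-empty structure mask."""
    out: dict[str, dict[str, float]] = {}
    for name in structs.names():
        mask = structs.mask(name)
        if not mask.any():
            continue
        dvh = compute_dvh(dose, mask, structure=name, bin_width_gy=bin_width_gy)
        vals = np.asarray(dose.values)[mask]
        m: dict[str, float] = {
            "mean_dose_gy": float(vals.mean()),
            "max_dose_gy": float(vals.max()),
            "volume_cm3": dvh.volume_cm3,
            "D5_gy": D_at_volume(dvh, 5.0),
            "D95_gy": D_at_volume(dvh, 95.0),
        }
        for lvl in V_LEVELS_GY:
            m[f"V{lvl:g}_pct"] = V_at_dose(dvh, lvl)
        out[name] = m
    return out


@dataclass
class PlanReport:
    """Everything reported per plan: structure metrics, HI, CI, verdicts."""

    plan_type: str
    structures: dict[str, dict[str, float]]
    hi: HIResult
    ci: CIResult
    constraints: list[ConstraintVerdict] = field(default_factory=list)
    gamma_pass_pct: float | None = None

    @property
    def constraints_pass(self) -> bool:
        return all_pass(self.constraints)

    def to_dict(self) -> dict:
        return {
            "plan_type": self.plan_type,
            "structures": self.structures,
            "hi": {"value": self.hi.value, "acceptable": self.hi.acceptable},
            "ci": {"value": self.ci.value, "acceptable": self.ci.acceptable,
                   "tolerable": self.ci.tolerable},
            "constraints": [vars(v) for v in self.constraints],
            "constraints_pass": self.constraints_pass,
            "gamma_pass_pct": self.gamma_pass_pct,
        }


def plan_report(
    dose: VolumeGrid,
    structs: StructureSet,
    plan_type: str,
    prescription_gy: float = 45.0,
    table: ConstraintTable | None = None,
) -> PlanReport:
    """Assemble the full evaluation of one simulated plan."""
    mets = structure_metrics(dose, structs)
    ptv_dvh = compute_dvh(dose, structs.mask(grids.PTV), structure=grids.PTV)
    table = table or default_constraint_table()
    rows = [r for r in table.rows if r.structure in mets]
    verdicts = evaluate_constraints(mets, ConstraintTable(rows=rows)) if rows else []
    return PlanReport(
        plan_type=plan_type,
        structures=mets,
        hi=homogeneity_index(ptv_dvh),
        ci=conformity_index(dose, structs.mask(grids.PTV), prescription_gy),
        constraints=verdicts,
    )


def report_table(reports: Sequence[PlanReport]) -> str:
    """Human-readable side-by-side comparison of plan reports."""
    names = sorted({n for r in reports for n in r.structures})
    lines = ["{:<28}".format("Parameter") + "".join(f"{r.plan_type:>12}" for r in reports)]
    lines.append("-" * len(lines[0]))
    lines.append("{:<28}".format("PTV HI")
                 + "".join(f"{r.hi.value:>12.3f}" for r in reports))
    lines.append("{:<28}".format("PTV CI")
                 + "".join(f"{r.ci.value:>12.3f}" for r in reports))
    for name in names:
        keys = sorted({k for r in reports for k in r.structures.get(name, {})})
        for k in keys:
            row = f"{name} {k}"
            vals = "".join(
                f"{r.structures.get(name, {}).get(k, float('nan')):>12.2f}"
                for r in reports
            )
            lines.append(f"{row:<28}" + vals)
    return "\n".join(lines)
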