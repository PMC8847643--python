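"""End-to-end run: phantom -> geometry -> arc angle -> plans -> dose -> report.

The pipeline compares the two-full-arc baseline (FA) against the
personalized partial-arc plan (OPA) on the same phantom and reports both
plans' metrics plus the lung-V5 difference.  Given a fixed seed every
artifact, including the serialized report, is byte-identical between
runs (no timestamps; the provenance header carries a hash of the
configuration instead).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, grids
from .dosesim import BeamModel, PlanSpec, geometric_unirradiated_fraction, simulate_dose
from .errors import InfeasibleGeometryError
from .gamma import GammaSpec
from .io import write_dvh_csv, write_plan, write_raster
from .metrics import PlanReport, compute_dvh, plan_report, report_table
from .phantom import GeometryInputs, PhantomSpec, build_thorax_phantom, measure_geometry
from .vba import (Feasibility, OpaResult, sequence_full_arcs, sequence_opa_arcs,
                  solve_opa_angle)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a reproducible comparison run needs."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    expected_v5: float = 0.55
    field_margin_cm: float = 2.0
    prescription: PlanSpec = field(default_factory=PlanSpec)
    beam: BeamModel = field(default_factory=BeamModel)
    gamma: GammaSpec = field(default_factory=GammaSpec)
    collimator_offset_deg: float = 5.0
    sentinel_gap_deg: float = 1.0
    extent_mode: str = "centroid_plane"
    write_dose: bool = False
    outdir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("phantom", PhantomSpec), ("prescription", PlanSpec),
                         ("beam", BeamModel), ("gamma", GammaSpec)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "phantom" in d and isinstance(d["phantom"], PhantomSpec):
            p = d["phantom"]
            p.lung_semiaxes_cm = tuple(p.lung_semiaxes_cm)
            p.heart_center_cm = tuple(p.heart_center_cm)
            p.heart_semiaxes_cm = tuple(p.heart_semiaxes_cm)
        return cls(**d)

    def config_hash(self) -> str:
        """Digest of the scientific configuration (output location and
        logging verbosity excluded, so relocated reruns hash identically)."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


@dataclass
class PipelineResult:
    config_hash: str
    geometry: GeometryInputs
    opa: OpaResult
    reports: dict[str, PlanReport]       # keys "FA", "OPA"
    unirradiated_fraction: dict[str, float]
    comparison: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "provenance": {"package": "opaplan", "version": __version__,
                           "config_hash": self.config_hash},
            "geometry": dataclasses.asdict(self.geometry),
            "opa_solution": {
                "R_cm": self.opa.R,
                "theta_a_deg": self.opa.theta_a,
                "feasible": self.opa.feasible.value,
                "achieved_geometric_v5": self.opa.achieved_geometric_v5,
            },
            "reports": {k: r.to_dict() for k, r in self.reports.items()},
            "unirradiated_lung_fraction": self.unirradiated_fraction,
            "comparison": self.comparison,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise
        log.info("stage %-12s %.2f s", name, time.perf_counter() - t0)
        return out
    return wrap


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full comparison; optionally write artifacts to disk.

    A NEEDS_FULL_ARC classification falls back to the FA baseline for the
    "OPA" plan (no restriction is warranted); an INFEASIBLE geometry
    raises :class:`InfeasibleGeometryError`.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    structs = _stage("phantom")(build_thorax_phantom, config.phantom)
    geom = _stage("measure")(
        measure_geometry, structs, config.field_margin_cm,
        config.expected_v5, config.extent_mode,
    )
    opa = _stage("solve")(solve_opa_angle, geom, 2.0 * config.field_margin_cm)
    if opa.feasible is Feasibility.INFEASIBLE:
        raise InfeasibleGeometryError(
            f"no positive arc angle meets expected V5={config.expected_v5}"
        )

    fa_plan = sequence_full_arcs(config.collimator_offset_deg)
    if opa.feasible is Feasibility.NEEDS_FULL_ARC:
        opa_plan = sequence_full_arcs(config.collimator_offset_deg)
    else:
        opa_plan = sequence_opa_arcs(opa.theta_a, config.collimator_offset_deg,
                                     config.sentinel_gap_deg)

    reports: dict[str, PlanReport] = {}
    doses = {}
    unirr = {}
    for label, plan in (("FA", fa_plan), ("OPA", opa_plan)):
        dose = _stage(f"simulate-{label}")(
            simulate_dose, structs, plan, config.beam, config.prescription
        )
        doses[label] = dose
        unirr[label] = geometric_unirradiated_fraction(structs, plan, config.beam)
        reports[label] = _stage(f"metrics-{label}")(
            plan_report, dose, structs, label, config.prescription.total_dose_gy
        )

    v5_fa = reports["FA"].structures[grids.LUNG_WHOLE]["V5_pct"]
    v5_opa = reports["OPA"].structures[grids.LUNG_WHOLE]["V5_pct"]
    result = PipelineResult(
        config_hash=config.config_hash(),
        geometry=geom,
        opa=opa,
        reports=reports,
        unirradiated_fraction=unirr,
        comparison={
            "lung_v5_fa_pct": v5_fa,
            "lung_v5_opa_pct": v5_opa,
            "delta_lung_v5_pp": v5_opa - v5_fa,
        },
    )

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_plan(fa_plan, outdir / "plan_FA.json")
        write_plan(opa_plan, outdir / "plan_OPA.json")
        (outdir / "report.json").write_text(result.to_json())
        (outdir / "comparison.txt").write_text(
            report_table([reports["FA"], reports["OPA"]]) + "\n"
        )
        save_config(config, outdir / "config.yaml")
        for label, dose in doses.items():
            for name in structs.names():
                if structs.mask(name).any():
                    dvh = compute_dvh(dose, structs.mask(name), structure=name)
                    write_dvh_csv(dvh, outdir / f"dvh_{label}_{name}.csv")
            if config.write_dose:
                write_raster(dose, outdir / f"dose_{label}", name=f"dose_{label}")
        log.info("artifacts written to %s", outdir)
    return result
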