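"""File formats: volume rasters, structure sets, plan JSON, DVH CSV.

Rasters are written as NIfTI (via nibabel) with a plain-text YAML
sidecar (``<name>.meta.yaml``) recording shape, spacing, origin and the
axis convention.  The sidecar is authoritative for geometry; on read it
is cross-checked against the NIfTI affine and any inconsistency is a
hard error rather than a silent reinterpretation.

Arc plans serialize to JSON with angles rounded to 0.1 degree (the
precision at which gantry angles are customarily reported); in-memory
angles stay exact floats.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import RasterFormatError
from .grids import StructureSet, VolumeGrid
from .metrics import DVHCurve
from .vba import Arc, ArcPlan

AXES_DOC = "x: left->right, y: posterior->anterior, z: inferior->superior"
_SIDECAR_KEYS = ("shape", "spacing_mm", "origin_mm", "axes")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name.removesuffix(".nii") + ".meta.yaml")


def write_raster(grid: VolumeGrid, path: str | Path, name: str = "") -> Path:
    """Write a grid as ``<path>.nii`` (if no suffix) plus a YAML sidecar."""
    path = Path(path)
    if path.suffix != ".nii":
        path = path.with_suffix(".nii")
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(grid.spacing_mm) + [1.0])
    affine[:3, 3] = grid.origin_mm
    values = grid.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    nib.save(nib.Nifti1Image(values, affine), str(path))
    meta = {
        "name": name or path.stem,
        "shape": [int(n) for n in grid.shape],
        "spacing_mm": [float(s) for s in grid.spacing_mm],
        "origin_mm": [float(o) for o in grid.origin_mm],
        "axes": AXES_DOC,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_raster(path: str | Path) -> VolumeGrid:
    """Read a raster written by :func:`write_raster`; geometry is validated."""
    path = Path(path)
    if path.suffix != ".nii":
        path = path.with_suffix(".nii")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise RasterFormatError(f"sidecar {sidecar} missing")
    text = sidecar.read_text()
    try:
        meta = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        offset = getattr(mark, "index", "?") if mark is not None else "?"
        raise RasterFormatError(f"malformed sidecar {sidecar} at byte {offset}: {exc}") from exc
    if not isinstance(meta, dict):
        raise RasterFormatError(f"sidecar {sidecar} is not a mapping")
    for key in _SIDECAR_KEYS:
        if key not in meta:
            raise RasterFormatError(f"sidecar {sidecar} missing required field {key!r}")
    img = nib.load(str(path))
    values = np.asarray(img.dataobj)
    if list(values.shape) != list(meta["shape"]):
        raise RasterFormatError(
            f"{path}: data shape {values.shape} != sidecar shape {meta['shape']}"
            " (partial or truncated read rejected)"
        )
    spacing = tuple(float(s) for s in meta["spacing_mm"])
    origin = tuple(float(o) for o in meta["origin_mm"])
    affine_spacing = img.affine[:3, :3].diagonal()
    if not np.allclose(affine_spacing, spacing, atol=1e-4):
        raise RasterFormatError(f"{path}: NIfTI affine spacing disagrees with sidecar")
    return VolumeGrid(values, spacing, origin)


def write_structure_set(structs: StructureSet, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mask in structs.masks.items():
        write_raster(structs.grid.like(mask), directory / name, name=name)
    (directory / "structures.yaml").write_text(
        yaml.safe_dump({"masks": sorted(structs.masks), "axes": AXES_DOC})
    )
    return directory


def read_structure_set(directory: str | Path) -> StructureSet:
    directory = Path(directory)
    index = directory / "structures.yaml"
    if not index.exists():
        raise RasterFormatError(f"{index} missing")
    names = yaml.safe_load(index.read_text())["masks"]
    masks = {}
    grid = None
    for name in names:
        g = read_raster(directory / name)
        masks[name] = np.asarray(g.values, dtype=bool)
        grid = g
    assert grid is not None
    return StructureSet(grid=grid.like(np.zeros(grid.shape, dtype=np.uint8)), masks=masks)


# ---------------------------------------------------------------------------
# arc plans


def plan_to_dict(plan: ArcPlan) -> dict:
    return {
        "plan_type": plan.plan_type,
        "gantry_spacing_deg": plan.gantry_spacing,
        "max_seconds_per_arc": plan.max_seconds_per_arc,
        "arcs": [
            {
                "start_deg": round(a.start, 1),
                "stop_deg": round(a.stop, 1),
                "direction": a.direction,
                "collimator_offset_deg": round(a.collimator_offset, 1),
            }
            for a in plan.arcs
        ],
    }


def plan_from_dict(d: dict) -> ArcPlan:
    arcs = [
        Arc(a["start_deg"], a["stop_deg"], a["direction"], a["collimator_offset_deg"])
        for a in d["arcs"]
    ]
    return ArcPlan(
        arcs=arcs,
        plan_type=d["plan_type"],
        gantry_spacing=d.get("gantry_spacing_deg", 4.0),
        max_seconds_per_arc=d.get("max_seconds_per_arc"),
    )


def write_plan(plan: ArcPlan, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(plan_to_dict(plan), indent=2, sort_keys=True) + "\n")
    return path


def read_plan(path: str | Path) -> ArcPlan:
    return plan_from_dict(json.loads(Path(path).read_text()))


def plan_table(plan: ArcPlan) -> str:
    """Human-readable arc listing."""
    lines = [f"{plan.plan_type} plan ({len(plan.arcs)} arcs)",
             f"{'arc':>4} {'start':>8} {'stop':>8} {'dir':>5} {'span':>8} {'collim':>7}"]
    for i, a in enumerate(plan.arcs, 1):
        lines.append(
            f"{i:>4} {a.start:>8.1f} {a.stop:>8.1f} {a.direction:>5} "
            f"{a.span:>8.1f} {a.collimator_offset:>7.1f}"
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# DVH CSV


def write_dvh_csv(dvh: DVHCurve, path: str | Path) -> Path:
    """Columns dose_gy, volume_pct; structure and volume in a comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# structure={dvh.structure} volume_cm3={dvh.volume_cm3!r}\n")
        pd.DataFrame(
            {"dose_gy": dvh.dose_edges_gy, "volume_pct": dvh.volume_pct}
        ).to_csv(fh, index=False)
    return path


def read_dvh_csv(path: str | Path) -> DVHCurve:
    path = Path(path)
    header = path.read_text().splitlines()[0]
    if not header.startswith("# structure="):
        raise RasterFormatError(f"{path}: missing DVH header comment")
    fields = dict(part.split("=", 1) for part in header[2:].split(" "))
    df = pd.read_csv(path, comment="#")
    return DVHCurve(
        structure=fields["structure"],
        dose_edges_gy=df["dose_gy"].to_numpy(),
        volume_pct=df["volume_pct"].to_numpy(),
        volume_cm3=float(fields["volume_cm3"]),
    )
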