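"""File formats, run configuration and the end-to-end pipeline.

Meshes are exchanged as legacy ASCII VTK unstructured grids (hexahedra or
tetrahedra) with CELL_DATA arrays such as ``region_label`` (int) and
``fibre`` (3-vector); lead traces as CSV with a ``time_ms`` column; run
configuration as YAML with a small validated schema.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import HexMesh, RegionLabelField, FibreField
from .forward import LeadTraces

_VTK_CELL_HEX = 12
_VTK_CELL_TET = 10


def write_field_vtk(
    path: str | Path,
    nodes: np.ndarray,
    cells: np.ndarray,
    cell_fields: dict[str, np.ndarray] | None = None,
    point_fields: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write a legacy ASCII VTK unstructured grid (hexahedra or tetrahedra).

    Scalar fields are written as SCALARS, 3-component fields as VECTORS.
    Field lengths must match the entity counts; empty field names are
    rejected.
    """
    path = Path(path)
    nodes = np.asarray(nodes, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    npts, ncell = len(nodes), len(cells)
    nverts = cells.shape[1]
    if nverts == 8:
        ctype = _VTK_CELL_HEX
    elif nverts == 4:
        ctype = _VTK_CELL_TET
    else:
        raise ValueError(f"unsupported cell arity {nverts}")

    def check(fields, count, kind):
        for name, arr in (fields or {}).items():
            if not name or not name.strip():
                raise ValueError("empty field name")
            if len(arr) != count:
                raise ValueError(
                    f"{kind} field {name!r} has length {len(arr)}, expected {count}"
                )

    check(cell_fields, ncell, "cell")
    check(point_fields, npts, "point")

    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\natriasim field export\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {npts} double\n")
        np.savetxt(f, nodes, fmt="%.10g")
        f.write(f"CELLS {ncell} {ncell * (nverts + 1)}\n")
        np.savetxt(f, np.column_stack([np.full(ncell, nverts), cells]), fmt="%d")
        f.write(f"CELL_TYPES {ncell}\n")
        np.savetxt(f, np.full(ncell, ctype), fmt="%d")

        def dump(fields, count, header):
            if not fields:
                return
            f.write(f"{header} {count}\n")
            for name, arr in fields.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, arr, fmt="%.10g")
                elif np.issubdtype(arr.dtype, np.integer):
                    f.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%d")
                else:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr.astype(float), fmt="%.10g")

        dump(cell_fields, ncell, "CELL_DATA")
        dump(point_fields, npts, "POINT_DATA")
    return path


def read_field_vtk(path: str | Path):
    """Read back a legacy ASCII VTK unstructured grid written by this module.

    Returns (nodes, cells, cell_fields, point_fields).
    """
    tokens = Path(path).read_text().split("\n")
    i = 0
    nodes = cells = None
    cell_fields: dict[str, np.ndarray] = {}
    point_fields: dict[str, np.ndarray] = {}
    target = None
    while i < len(tokens):
        line = tokens[i].strip()
        parts = line.split()
        if not parts:
            i += 1
            continue
        key = parts[0]
        if key == "POINTS":
            n = int(parts[1])
            data = " ".join(tokens[i + 1: i + 1 + n]).split()
            nodes = np.array(data, dtype=float).reshape(n, 3)
            i += n + 1
        elif key == "CELLS":
            n = int(parts[1])
            rows = [tokens[i + 1 + j].split() for j in range(n)]
            cells = np.array([r[1:] for r in rows], dtype=np.int64)
            i += n + 1
        elif key == "CELL_TYPES":
            i += int(parts[1]) + 1
        elif key == "CELL_DATA":
            target = cell_fields
            count = int(parts[1])
            i += 1
        elif key == "POINT_DATA":
            target = point_fields
            count = int(parts[1])
            i += 1
        elif key == "SCALARS":
            name, dtype = parts[1], parts[2]
            data = " ".join(tokens[i + 2: i + 2 + count]).split()
            target[name] = np.array(
                data, dtype=np.int64 if dtype == "int" else float)
            i += count + 2
        elif key == "VECTORS":
            name = parts[1]
            data = " ".join(tokens[i + 1: i + 1 + count]).split()
            target[name] = np.array(data, dtype=float).reshape(count, 3)
            i += count + 1
        else:
            i += 1
    return nodes, cells, cell_fields, point_fields


def write_mesh_vtk(path, mesh: HexMesh, labels: RegionLabelField | None = None,
                   fibres: FibreField | None = None, **extra_cell_fields):
    """Convenience wrapper: mesh + region_label + fibre CELL_DATA arrays."""
    cell_fields = dict(extra_cell_fields)
    if labels is not None:
        cell_fields["region_label"] = labels.indices
    if fibres is not None:
        cell_fields["fibre"] = fibres.vectors
    return write_field_vtk(path, mesh.nodes, mesh.elements,
                           cell_fields=cell_fields)


def write_traces_csv(path: str | Path, traces: LeadTraces) -> Path:
    """Lead traces as CSV: time_ms column plus one column per lead."""
    if len(set(traces.names)) != len(traces.names):
        dupes = sorted({n for n in traces.names if traces.names.count(n) > 1})
        raise ValueError(f"duplicate lead names: {dupes}")
    df = pd.DataFrame(traces.values, columns=traces.names)
    df.insert(0, "time_ms", traces.times)
    df.to_csv(path, index=False, float_format="%.10g")
    return Path(path)


def read_traces_csv(path: str | Path) -> LeadTraces:
    df = pd.read_csv(path)
    names = [c for c in df.columns if c != "time_ms"]
    return LeadTraces(times=df["time_ms"].to_numpy(), names=names,
                      values=df[names].to_numpy())


def write_trace_csv(path: str | Path, trace) -> Path:
    """Single-cell trace as CSV (time_ms, Vm_mV, Na_mM, K_mM, Ca_mM)."""
    cols = {"time_ms": trace.time, "Vm_mV": trace.vm}
    if trace.concentrations is not None:
        cols["Na_mM"] = trace.concentrations[:, 0]
        cols["K_mM"] = trace.concentrations[:, 1]
        cols["Ca_mM"] = trace.concentrations[:, 2]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
    return Path(path)


# --------------------------------------------------------------------------
# Run configuration and pipeline
# --------------------------------------------------------------------------

_SCHEMA = {
    "geometry": dict,
    "protocol": dict,
    "tissue": dict,
    "forward": dict,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    geometry: dict
    protocol: dict = field(default_factory=dict)
    tissue: dict = field(default_factory=dict)
    forward: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "geometry" not in raw:
            raise ValueError("config missing required section: geometry")
        for key, typ in _SCHEMA.items():
            if key in raw and not isinstance(raw[key], typ):
                raise ValueError(f"config section {key!r} must be a mapping")
        return cls(geometry=raw["geometry"],
                   protocol=raw.get("protocol", {}),
                   tissue=raw.get("tissue", {}),
                   forward=raw.get("forward", {}),
                   seed=int(raw.get("seed", 0)))

    def to_dict(self) -> dict:
        return {"geometry": self.geometry, "protocol": self.protocol,
                "tissue": self.tissue, "forward": self.forward,
                "seed": self.seed}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Geometry -> monodomain -> forward -> analysis, with a manifest.

    The manifest records the package version, the config hash, per-stage
    wall times and the artifact list; identical configs give byte-identical
    stage outputs (all stages are deterministic).
    """
    from . import __version__
    from .analysis import compute_brms_map, compute_lat_map
    from .calibration import measure_cv, simulate_slab_cv, SlabConfig
    from .cell import make_regional_cell
    from .forward import compute_pseudo_ecg, standard_lead_positions
    from .geometry import (AtriaConfig, assign_fibres, build_idealized_atria,
                           build_slab, uniform_labels,
                           DEFAULT_PRINCIPAL_VECTORS)
    from .monodomain import (ConductivityField, Stimulus, StimulusSet,
                             run_monodomain)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config_hash": config.digest(),
                      "stages": {}, "artifacts": [], "status": "running"}
    t_all = time.time()

    def stage(name):
        manifest["stages"][name] = {"wall_s": None}
        return time.time()

    try:
        # --- geometry ---
        t0 = stage("geometry")
        kind = config.geometry.get("kind", "slab")
        if kind == "slab":
            mesh = build_slab(
                config.geometry.get("nx", 50), config.geometry.get("ny", 50),
                config.geometry.get("nz", 3),
                config.geometry.get("spacing_um", 300.0))
            labels = uniform_labels(mesh)
            fibres = assign_fibres(
                mesh, labels, {"TISSUE": np.array([0.0, -1.0, 0.0])})
        elif kind == "atria":
            mesh, labels, fibres = build_idealized_atria(AtriaConfig(
                **config.geometry.get("atria", {})))
        else:
            raise ValueError(f"unknown geometry kind {kind!r}")
        write_mesh_vtk(out / "mesh.vtk", mesh, labels, fibres)
        manifest["artifacts"].append("mesh.vtk")
        manifest["stages"]["geometry"]["wall_s"] = time.time() - t0

        # --- monodomain ---
        t0 = stage("monodomain")
        tissue = config.tissue
        sigma_l = tissue.get("sigma_l", 3.74)
        ratio = tissue.get("anisotropy_ratio", 0.35)
        cond = ConductivityField.uniform(mesh, sigma_l, ratio, fibres)
        cell_map = {name: make_regional_cell(tissue.get("cell_map", {}).get(
            name, tissue.get("default_cell", "RA/PM")))
            for name in labels.names}
        proto = config.protocol
        h = (mesh.spacing_um or 300.0) * 1e-4
        if proto.get("site", "face") == "face":
            nodes = np.nonzero(mesh.nodes[:, 0] < mesh.nodes[:, 0].min()
                               + 2.5 * h)[0]
        else:
            nodes = np.asarray(proto["nodes"], dtype=np.int64)
        stims = StimulusSet([Stimulus(
            nodes=nodes, start=proto.get("start", 0.0),
            duration=proto.get("duration", 2.0),
            amplitude=proto.get("amplitude", 52.0),
            period=proto.get("bcl", 1000.0), count=proto.get("n_beats", 1))])
        vm = run_monodomain(mesh, labels, cond, cell_map, stims,
                            duration=proto.get("sim_ms", 40.0),
                            dt=proto.get("dt", 0.02),
                            output_dt=proto.get("output_dt", 1.0))
        manifest["stages"]["monodomain"]["wall_s"] = time.time() - t0

        # --- forward + analysis ---
        t0 = stage("forward")
        center = mesh.nodes.mean(axis=0)
        leads = standard_lead_positions(center)
        traces = compute_pseudo_ecg(vm, leads,
                                    gamma=config.forward.get("gamma", 1.0))
        write_traces_csv(out / "leads.csv", traces)
        manifest["artifacts"].append("leads.csv")
        manifest["stages"]["forward"]["wall_s"] = time.time() - t0

        t0 = stage("analysis")
        lat = compute_lat_map(vm)
        brms = compute_brms_map(traces.values)
        if kind == "slab":
            L = mesh.nodes[:, 0].max()
            mid = mesh.nodes.mean(axis=0)
            pa, pb = mid.copy(), mid.copy()
            pa[0], pb[0] = 0.3 * L, 0.7 * L
            manifest["achieved_cv_cm_s"] = measure_cv(vm, pa, pb)
        np.savetxt(out / "lat_ms.txt", lat.times)
        np.savetxt(out / "brms_mV.txt", brms.values)
        manifest["artifacts"] += ["lat_ms.txt", "brms_mV.txt"]
        manifest["stages"]["analysis"]["wall_s"] = time.time() - t0
        manifest["status"] = "complete"
    except Exception as exc:  # noqa: BLE001 - stage name is part of the report
        failed = [k for k, v in manifest["stages"].items()
                  if v["wall_s"] is None]
        manifest["status"] = "failed"
        manifest["error"] = f"stage {failed[-1] if failed else '?'}: {exc}"
        raise
    finally:
        manifest["total_wall_s"] = time.time() - t_all
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
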