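"""Configuration handling, file formats and run manifests.

CSV dialect: comma separated, header row, UTF-8, '.' decimal, units
encoded in the column names.  Geometry exports as ASCII STL, meshes as
Gmsh MSH 2.2 and VTK XML (VTU); field snapshot series get a PVD
collection file.  Every pipeline run can write a manifest recording the
configuration snapshot, package version, mesh identity, seeds and output
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import Mesh, ShrimpGeometrySpec
from .properties import ComponentPropertyTable, SorptionIsotherm
from .solver import ConstantMaterial, DryingCurve, SimulationConfig

__all__ = [
    "load_config",
    "save_config",
    "load_property_table",
    "save_property_table",
    "load_geometry_spec",
    "save_geometry_spec",
    "write_curve_csv",
    "read_curve_csv",
    "write_results_json",
    "write_vtu",
    "write_pvd",
    "write_stl",
    "write_msh",
    "read_msh",
    "RunManifest",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _cfg_to_dict(cfg: SimulationConfig) -> dict:
    d = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, SorptionIsotherm):
            v = {"A": v.A, "B": v.B, "C": v.C,
                 "air_temperature_label": v.air_temperature_label,
                 "nesting": v.nesting}
        elif isinstance(v, ConstantMaterial):
            v = dataclasses.asdict(v)
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, tuple):
            v = list(v)
        d[f.name] = v
    return d


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_cfg_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if isinstance(raw.get("isotherm"), dict):
        raw["isotherm"] = SorptionIsotherm(**raw["isotherm"])
    if isinstance(raw.get("material"), dict):
        raw["material"] = ConstantMaterial(**raw["material"])
    for key in ("T_air", "RH"):
        if isinstance(raw.get(key), list):
            raw[key] = tuple(np.asarray(x, dtype=float) for x in raw[key])
    if isinstance(raw.get("snapshot_times"), list):
        raw["snapshot_times"] = tuple(raw["snapshot_times"])
    return SimulationConfig(**raw)


def save_property_table(table: ComponentPropertyTable, path: str | Path) -> None:
    doc = {f"{comp}.{prop}": list(coeffs)
           for (comp, prop), coeffs in table.coefficients.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_property_table(path: str | Path) -> ComponentPropertyTable:
    """Component property polynomials from a YAML mapping of
    "<component>.<property>" to [a0, a1, a2] coefficient lists."""
    raw = yaml.safe_load(Path(path).read_text())
    coeffs = {}
    for key, vals in raw.items():
        comp, prop = key.split(".", 1)
        coeffs[(comp, prop)] = tuple(float(v) for v in vals)
    return ComponentPropertyTable(coefficients=coeffs)


def save_geometry_spec(spec: ShrimpGeometrySpec, path: str | Path) -> None:
    d = dataclasses.asdict(spec)
    for key in ("first_segment_semi_axes", "taper_profile",
                "spine_control_points"):
        d[key] = [list(x) if isinstance(x, tuple) else x for x in d[key]]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_geometry_spec(path: str | Path) -> ShrimpGeometrySpec:
    """Swept-ellipse geometry parameters from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(ShrimpGeometrySpec)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
    for key in ("first_segment_semi_axes", "taper_profile",
                "spine_control_points"):
        if key in raw:
            raw[key] = tuple(tuple(x) if isinstance(x, list) else x
                             for x in raw[key])
    return ShrimpGeometrySpec(**raw)


# ---------------------------------------------------------------------------
# Curves and results
# ---------------------------------------------------------------------------

def write_curve_csv(curve: DryingCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False, float_format="%.9g")


def read_curve_csv(path: str | Path) -> DryingCurve:
    return DryingCurve.from_frame(pd.read_csv(path))


def write_results_json(results: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(results, indent=2, default=default))


# ---------------------------------------------------------------------------
# Mesh / field formats
# ---------------------------------------------------------------------------

def write_vtu(mesh: Mesh, path: str | Path, point_data: dict | None = None) -> None:
    """Minimal ASCII VTK XML unstructured-grid writer (tet meshes)."""
    n, m = mesh.n_nodes, mesh.n_elements
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        "\n".join(" ".join(f"{x:.9g}" for x in row) for row in mesh.nodes),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        "\n".join(" ".join(str(i) for i in tet) for tet in mesh.tets),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(4 * (i + 1)) for i in range(m)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join("10" for _ in range(m)),  # VTK_TETRA
        "</DataArray>",
        "</Cells>",
    ]
    if point_data:
        lines.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            lines += [
                f'<DataArray type="Float64" Name="{name}" format="ascii">',
                " ".join(f"{v:.9g}" for v in arr),
                "</DataArray>",
            ]
        lines.append("</PointData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def write_pvd(vtu_files: list[tuple[float, str]], path: str | Path) -> None:
    """ParaView collection file mapping times to VTU snapshot files."""
    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="Collection" version="0.1">', "<Collection>"]
    for t, f in vtu_files:
        lines.append(f'<DataSet timestep="{t:.9g}" file="{f}"/>')
    lines += ["</Collection>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def write_stl(mesh: Mesh, path: str | Path, name: str = "surface") -> None:
    """ASCII STL of the mesh boundary surface."""
    tris = mesh.nodes[mesh.boundary_tris]
    normals = mesh.boundary_area_vectors()
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.where(norms > 0, norms, 1.0)
    out = [f"solid {name}"]
    for tri, nrm in zip(tris, normals):
        out.append(f"facet normal {nrm[0]:.9g} {nrm[1]:.9g} {nrm[2]:.9g}")
        out.append("  outer loop")
        for v in tri:
            out.append(f"    vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
        out.append("  endloop")
        out.append("endfacet")
    out.append(f"endsolid {name}")
    Path(path).write_text("\n".join(out))


def write_msh(mesh: Mesh, path: str | Path) -> None:
    """Gmsh MSH 2.2 ASCII writer (tetrahedra + boundary triangles)."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes",
             str(mesh.n_nodes)]
    for i, p in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    lines += ["$EndNodes", "$Elements",
              str(mesh.n_elements + len(mesh.boundary_tris))]
    eid = 1
    for tri in mesh.boundary_tris:
        lines.append(f"{eid} 2 2 1 1 " + " ".join(str(v + 1) for v in tri))
        eid += 1
    for tet in mesh.tets:
        lines.append(f"{eid} 4 2 2 2 " + " ".join(str(v + 1) for v in tet))
        eid += 1
    lines.append("$EndElements")
    Path(path).write_text("\n".join(lines))


def read_msh(path: str | Path, char_size: float = float("nan"),
             probe_point=None) -> Mesh:
    """Read a MSH 2.2 ASCII file written by :func:`write_msh`."""
    text = Path(path).read_text().splitlines()
    it = iter(text)
    nodes, tets, tris = [], [], []
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append([float(x) for x in parts[1:4]])
        elif line.strip() == "$Elements":
            m = int(next(it))
            for _ in range(m):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                conn = [int(v) - 1 for v in parts[3 + ntags:]]
                if etype == 2:
                    tris.append(conn)
                elif etype == 4:
                    tets.append(conn)
    nodes = np.asarray(nodes)
    tets = np.asarray(tets, dtype=int)
    tris = np.asarray(tris, dtype=int)
    if probe_point is None:
        probe_point = nodes.mean(axis=0)
    return Mesh(nodes=nodes, tets=tets, boundary_tris=tris,
                probe_point=np.asarray(probe_point, dtype=float),
                char_size=char_size)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    command: str
    config: dict = field(default_factory=dict)
    package_version: str = ""
    mesh: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # filename -> sha256

    def add_output(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs[p.name] = _sha256(p)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def for_run(cls, command: str, cfg: SimulationConfig | None = None,
                mesh: Mesh | None = None, seeds: dict | None = None
                ) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config=_cfg_to_dict(cfg) if cfg is not None else {},
            package_version=__version__,
            mesh={"n_elements": mesh.n_elements, "n_nodes": mesh.n_nodes,
                  "max_size_m": mesh.char_size} if mesh is not None else {},
            seeds=seeds or {},
        )
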