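"""Cohort I/O: VTK legacy unstructured grids, plain-array containers, CSV.

Two mesh dialects are supported:

* VTK legacy ASCII ``UNSTRUCTURED_GRID`` with hexahedron cells (type 12),
  per-cell ``density`` scalars and a per-point ``surface`` mask — readable by
  ParaView and friends;
* a single-file NumPy container (``.npz``) with named arrays ``nodes``,
  ``elements``, ``surface_node_ids`` and ``density``.

File connectivity is written/read 0-based (the VTK convention).  The
anthropometric table is a CSV with header
``subject_id,stature_cm,bmi,age_years``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mesh import (
    AnthropometricRecord,
    CorrespondenceError,
    DensityField,
    FemurSample,
    HexMesh,
)

__all__ = [
    "write_vtk",
    "read_vtk",
    "write_npz",
    "read_npz",
    "read_anthro_table",
    "write_anthro_table",
    "load_cohort",
    "save_cohort",
]

ANTHRO_COLUMNS = ["subject_id", "stature_cm", "bmi", "age_years"]


def write_vtk(path: str | Path, mesh: HexMesh, density: DensityField | None = None,
              title: str = "parafemur femur mesh") -> None:
    """Write a VTK legacy ASCII unstructured grid of hexahedra."""
    path = Path(path)
    n, m = mesh.n_nodes, mesh.n_elements
    surface_mask = np.zeros(n, dtype=np.int64)
    surface_mask[mesh.surface_node_ids] = 1
    with path.open("w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.17g")
        f.write(f"CELLS {m} {m * 9}\n")
        cells = np.column_stack([np.full(m, 8, dtype=np.int64), mesh.elements])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {m}\n")
        np.savetxt(f, np.full(m, 12, dtype=np.int64), fmt="%d")
        f.write(f"POINT_DATA {n}\n")
        f.write("SCALARS surface int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, surface_mask, fmt="%d")
        if density is not None:
            f.write(f"CELL_DATA {m}\n")
            f.write(f"SCALARS density_{density.basis} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, density.values, fmt="%.17g")


def _tokens(path: Path) -> list[str]:
    with path.open() as f:
        lines = f.readlines()
    # Strip the two header lines and blank lines; keep everything tokenized.
    toks: list[str] = []
    for line in lines[2:]:
        toks.extend(line.split())
    return toks


def read_vtk(path: str | Path) -> tuple[HexMesh, DensityField | None]:
    """Read a hexahedral mesh (plus optional density field) written by
    :func:`write_vtk` or an equivalent legacy ASCII VTK file."""
    path = Path(path)
    toks = _tokens(path)
    it = iter(range(len(toks)))
    i = 0

    def expect(keyword: str) -> int:
        nonlocal i
        while i < len(toks) and toks[i].upper() != keyword:
            i += 1
        if i >= len(toks):
            raise ValueError(f"{path}: missing {keyword} section")
        return i

    expect("DATASET")
    if toks[i + 1].upper() != "UNSTRUCTURED_GRID":
        raise ValueError(f"{path}: not an unstructured grid")
    expect("POINTS")
    n = int(toks[i + 1])
    start = i + 3
    nodes = np.array(toks[start:start + 3 * n], dtype=np.float64).reshape(n, 3)
    i = start + 3 * n
    expect("CELLS")
    m = int(toks[i + 1])
    start = i + 3
    raw = np.array(toks[start:start + 9 * m], dtype=np.int64).reshape(m, 9)
    if not np.all(raw[:, 0] == 8):
        raise ValueError(f"{path}: non-hexahedral cell found")
    elements = raw[:, 1:]
    i = start + 9 * m
    expect("CELL_TYPES")
    start = i + 2
    types = np.array(toks[start:start + m], dtype=np.int64)
    if not np.all(types == 12):
        raise ValueError(f"{path}: cell types other than hexahedron (12) present")
    i = start + m

    surface_ids: np.ndarray | None = None
    density: DensityField | None = None
    basis = "apparent"
    while i < len(toks):
        tok = toks[i].upper()
        if tok == "POINT_DATA":
            j = i
            while j < len(toks) and toks[j].upper() != "SCALARS":
                j += 1
            name = toks[j + 1]
            j += 4  # SCALARS name type [ncomp] LOOKUP_TABLE default
            if toks[j].upper() == "LOOKUP_TABLE":
                j += 2
            else:
                j += 1
            if name == "surface":
                mask = np.array(toks[j:j + n], dtype=np.float64)
                surface_ids = np.nonzero(mask > 0.5)[0]
            i = j + n
        elif tok == "CELL_DATA":
            j = i
            while j < len(toks) and toks[j].upper() != "SCALARS":
                j += 1
            name = toks[j + 1]
            j += 4
            if toks[j].upper() == "LOOKUP_TABLE":
                j += 2
            else:
                j += 1
            values = np.array(toks[j:j + m], dtype=np.float64)
            if name.startswith("density"):
                if name.endswith("_ash"):
                    basis = "ash"
                density = DensityField(values=values, basis=basis)
            i = j + m
        else:
            i += 1

    if surface_ids is None or surface_ids.size == 0:
        raise ValueError(f"{path}: no 'surface' point mask found")
    mesh = HexMesh(nodes=nodes, elements=elements, surface_node_ids=surface_ids)
    return mesh, density


def write_npz(path: str | Path, mesh: HexMesh, density: DensityField | None = None) -> None:
    arrays = dict(nodes=mesh.nodes, elements=mesh.elements,
                  surface_node_ids=mesh.surface_node_ids)
    if density is not None:
        arrays["density"] = density.values
        arrays["density_basis"] = np.array(density.basis)
    np.savez(path, **arrays)


def read_npz(path: str | Path) -> tuple[HexMesh, DensityField | None]:
    with np.load(path, allow_pickle=False) as data:
        mesh = HexMesh(nodes=data["nodes"], elements=data["elements"],
                       surface_node_ids=data["surface_node_ids"])
        density = None
        if "density" in data:
            basis = str(data["density_basis"]) if "density_basis" in data else "apparent"
            density = DensityField(values=data["density"], basis=basis)
    return mesh, density


def read_anthro_table(path: str | Path) -> dict[str, AnthropometricRecord]:
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in ANTHRO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"anthropometric table missing columns: {missing}")
    records: dict[str, AnthropometricRecord] = {}
    for row in df.itertuples(index=False):
        rec = AnthropometricRecord(subject_id=str(row.subject_id), stature=float(row.stature_cm),
                                   bmi=float(row.bmi), age=float(row.age_years))
        records[rec.subject_id] = rec
    return records


def write_anthro_table(path: str | Path, records: Iterable[AnthropometricRecord]) -> None:
    df = pd.DataFrame(
        [(r.subject_id, r.stature, r.bmi, r.age) for r in records],
        columns=ANTHRO_COLUMNS,
    )
    df.to_csv(path, index=False)


def _read_mesh_any(path: Path) -> tuple[HexMesh, DensityField | None]:
    if path.suffix == ".npz":
        return read_npz(path)
    return read_vtk(path)


def load_cohort(mesh_sources: Sequence[str | Path], anthro_table: str | Path) -> list[FemurSample]:
    """Load a corresponded cohort and verify it.

    Each mesh file's stem is its ``subject_id`` and must match a row of the
    anthropometric CSV.  All meshes must share a topology hash; the first
    mesh sets the reference and any deviating subject is named in the
    raised :class:`CorrespondenceError`.  Anthropometrics outside plausible
    human ranges trigger a warning, not an error.
    """
    records = read_anthro_table(anthro_table)
    samples: list[FemurSample] = []
    reference_hash: str | None = None
    for source in mesh_sources:
        path = Path(source)
        subject_id = path.stem
        if subject_id not in records:
            raise KeyError(f"no anthropometric row for subject {subject_id!r}")
        mesh, density = _read_mesh_any(path)
        if density is None:
            raise ValueError(f"{path}: no density field found")
        if reference_hash is None:
            reference_hash = mesh.topology_hash
        elif mesh.topology_hash != reference_hash:
            raise CorrespondenceError(
                f"subject {subject_id!r} breaks mesh correspondence "
                f"(topology hash differs from the first mesh)"
            )
        rec = records[subject_id]
        for msg in rec.plausibility_warnings():
            warnings.warn(msg, UserWarning, stacklevel=2)
        samples.append(FemurSample(anthro=rec, mesh=mesh, density=density))
    return samples


def write_landmarks(path: str | Path, landmarks, shell_element_ids) -> None:
    """JSON landmark/shell index sets accompanying a cohort directory."""
    import json

    data = {name: np.asarray(getattr(landmarks, name)).tolist()
            for name in ("head", "neck", "proximal_shaft", "mid_shaft", "distal",
                         "anterior_midshaft_surface")}
    data["surface_shell_element_ids"] = np.asarray(shell_element_ids).tolist()
    Path(path).write_text(json.dumps(data))


def read_landmarks(path: str | Path):
    """Returns (AxisLandmarks, shell_element_ids)."""
    import json

    from .morphometrics import AxisLandmarks

    data = json.loads(Path(path).read_text())
    shell = np.asarray(data.pop("surface_shell_element_ids"), dtype=np.int64)
    landmarks = AxisLandmarks(**{k: np.asarray(v, dtype=np.int64) for k, v in data.items()})
    return landmarks, shell


def save_cohort(directory: str | Path, samples: Sequence[FemurSample],
                fmt: str = "vtk") -> list[Path]:
    """Write one mesh file per sample plus ``anthro.csv``; returns mesh paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample in samples:
        suffix = ".vtk" if fmt == "vtk" else ".npz"
        path = directory / f"{sample.anthro.subject_id}{suffix}"
        if fmt == "vtk":
            write_vtk(path, sample.mesh, sample.density)
        else:
            write_npz(path, sample.mesh, sample.density)
        paths.append(path)
    write_anthro_table(directory / "anthro.csv", [s.anthro for s in samples])
    return paths
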