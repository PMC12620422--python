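"""Corresponded hexahedral femur meshes and rigid (Procrustes) alignment.

A cohort is a list of :class:`FemurSample` objects sharing one hexahedral
connectivity (node ``i`` is anatomically homologous across subjects).  Shapes
are compared only after removing pose, which is done here with rigid-body
Procrustes transformations: rotation + translation, never scaling or
reflection.  The optimum is computed over the outer-surface nodes and applied
to all nodes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "HexMesh",
    "DensityField",
    "AnthropometricRecord",
    "FemurSample",
    "RigidTransform",
    "CorrespondenceError",
    "AlignmentError",
    "procrustes_align",
    "align_cohort",
]


class CorrespondenceError(ValueError):
    """Raised when meshes that must share a topology do not."""


class AlignmentError(ValueError):
    """Raised when a rigid alignment problem is degenerate."""


def _topology_hash(elements: np.ndarray, surface_node_ids: np.ndarray, n_nodes: int) -> str:
    h = hashlib.sha1()
    h.update(np.int64(n_nodes).tobytes())
    h.update(np.ascontiguousarray(elements, dtype=np.int64).tobytes())
    h.update(np.ascontiguousarray(np.sort(surface_node_ids), dtype=np.int64).tobytes())
    return h.hexdigest()


@dataclass(frozen=True)
class HexMesh:
    """A hexahedral mesh: ``nodes`` (n, 3) in mm, ``elements`` (m, 8) 0-based.

    ``surface_node_ids`` index the outer-surface nodes used by Procrustes
    alignment.  ``topology_hash`` digests the connectivity so correspondence
    across a cohort can be checked cheaply; it is derived, never supplied.
    """

    nodes: np.ndarray
    elements: np.ndarray
    surface_node_ids: np.ndarray
    topology_hash: str = field(init=False)

    def __post_init__(self) -> None:
        nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        surf = np.ascontiguousarray(self.surface_node_ids, dtype=np.int64)
        if nodes.ndim != 2 or nodes.shape[1] != 3:
            raise ValueError(f"nodes must be (n, 3), got {nodes.shape}")
        if elements.ndim != 2 or elements.shape[1] != 8:
            raise ValueError(f"elements must be (m, 8) hexahedra, got {elements.shape}")
        n = nodes.shape[0]
        if elements.size and (elements.min() < 0 or elements.max() >= n):
            raise CorrespondenceError("element connectivity references nodes outside [0, n)")
        if surf.size == 0:
            raise ValueError("surface_node_ids must be non-empty")
        if surf.min() < 0 or surf.max() >= n:
            raise ValueError("surface_node_ids outside [0, n)")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "elements", elements)
        object.__setattr__(self, "surface_node_ids", surf)
        object.__setattr__(self, "topology_hash", _topology_hash(elements, surf, n))

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def surface_nodes(self) -> np.ndarray:
        return self.nodes[self.surface_node_ids]

    def with_nodes(self, nodes: np.ndarray) -> "HexMesh":
        """Same topology, new coordinates."""
        return HexMesh(nodes=nodes, elements=self.elements, surface_node_ids=self.surface_node_ids)


@dataclass(frozen=True)
class DensityField:
    """Per-element density in g/cm^3; ``basis`` records the convention
    ('apparent' or 'ash') the values carry — bookkeeping only."""

    values: np.ndarray
    basis: str = "apparent"

    def __post_init__(self) -> None:
        values = np.ascontiguousarray(self.values, dtype=np.float64)
        if values.ndim != 1:
            raise ValueError("density values must be 1-D (one per element)")
        if np.any(values < 0):
            raise ValueError("densities must be >= 0")
        if self.basis not in ("apparent", "ash"):
            raise ValueError(f"unknown density basis {self.basis!r}")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.shape[0]


_PLAUSIBLE = {"stature": (100.0, 220.0), "bmi": (10.0, 60.0), "age": (18.0, 110.0)}


@dataclass(frozen=True)
class AnthropometricRecord:
    """One subject's predictors: stature (cm), BMI (kg/m^2), age (years)."""

    subject_id: str
    stature: float
    bmi: float
    age: float

    def __post_init__(self) -> None:
        for name in ("stature", "bmi", "age"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    def plausibility_warnings(self) -> list[str]:
        out = []
        for name, (lo, hi) in _PLAUSIBLE.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                out.append(f"{self.subject_id}: {name}={v} outside plausible range [{lo}, {hi}]")
        return out

    def as_vector(self) -> np.ndarray:
        return np.array([self.stature, self.bmi, self.age], dtype=np.float64)


@dataclass(frozen=True)
class FemurSample:
    """One subject: corresponded mesh + element density field + anthropometrics."""

    anthro: AnthropometricRecord
    mesh: HexMesh
    density: DensityField

    def __post_init__(self) -> None:
        if len(self.density) != self.mesh.n_elements:
            raise CorrespondenceError(
                f"{self.anthro.subject_id}: density length {len(self.density)} "
                f"!= element count {self.mesh.n_elements}"
            )


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ x + t with R proper orthogonal (no scaling, no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.ascontiguousarray(self.rotation, dtype=np.float64)
        t = np.ascontiguousarray(self.translation, dtype=np.float64)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be (3,3), translation (3,)")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self.compose(other)).apply(x) == self.apply(other.apply(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


def _kabsch(moving: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform taking ``moving`` onto ``target``.

    Closed form via the SVD of the cross-covariance, with the usual
    determinant guard that flips the smallest singular direction so the
    result is a proper rotation rather than a reflection.
    """
    mc = moving.mean(axis=0)
    tc = target.mean(axis=0)
    A = moving - mc
    B = target - tc
    H = A.T @ B
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return RigidTransform(R, t)


def procrustes_align(moving: HexMesh, reference: HexMesh) -> tuple[RigidTransform, HexMesh]:
    """Rigidly align ``moving`` to ``reference``.

    The optimal rotation/translation minimises the mean squared distance
    between corresponding *surface* nodes and is applied to *all* nodes.

    Raises
    ------
    CorrespondenceError
        if the two meshes do not share a topology.
    AlignmentError
        if the surface node cloud is degenerate (fewer than 3 nodes, or
        collinear/coincident).
    """
    if moving.topology_hash != reference.topology_hash:
        raise CorrespondenceError("moving and reference meshes differ in topology")
    src = moving.surface_nodes
    dst = reference.surface_nodes
    if src.shape[0] < 3:
        raise AlignmentError("need at least 3 surface nodes")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise AlignmentError("surface nodes are collinear or coincident")
    transform = _kabsch(src, dst)
    aligned = moving.with_nodes(transform.apply(moving.nodes))
    return transform, aligned


def mean_surface_distance(a: HexMesh, b: HexMesh) -> float:
    """Mean Euclidean distance between corresponding surface nodes."""
    return float(np.linalg.norm(a.surface_nodes - b.surface_nodes, axis=1).mean())


def align_cohort(samples: Sequence[FemurSample], reference_index: int = 0) -> list[FemurSample]:
    """Align every sample to the cohort member at ``reference_index``.

    Geometry only: density fields are untouched; the reference sample is
    returned unchanged.
    """
    n = len(samples)
    if not -n <= reference_index < n:
        raise IndexError(f"reference_index {reference_index} out of range for cohort of {n}")
    reference = samples[reference_index]
    out: list[FemurSample] = []
    for i, sample in enumerate(samples):
        if sample is reference:
            out.append(sample)
            continue
        try:
            _, aligned = procrustes_align(sample.mesh, reference.mesh)
        except (CorrespondenceError, AlignmentError) as exc:
            raise type(exc)(f"subject {sample.anthro.subject_id}: {exc}") from exc
        out.append(replace(sample, mesh=aligned))
    return out
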