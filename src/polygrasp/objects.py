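"""Polycube stimulus objects.

The stimulus objects are solids built from face-connected unit cubes on an
integer lattice, each cube made of one of two materials (beech wood or
brass).  With a cube side of 2.5 cm and the default densities this
reproduces the reference masses of the light (all wood, ~97 g) stimulus
objects.  The module derives everything downstream stages need from the
cell list: total mass, center of mass, the exposed surface (faces not
shared between two cubes) and contact-point samples with outward normals.

Coordinate convention: right-handed, z up, gravity along -z, y pointing
from the participant toward the object.  Objects sit on the table plane
z = 0; the only admissible pose is a rotation about the vertical axis
(the objects are presented on a turntable) plus a translation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CubeCell",
    "Pose",
    "ContactPoint",
    "RigidObject",
    "ConnectivityError",
    "ValidationError",
    "ConfigurationError",
    "build_object",
    "object_mass",
    "center_of_mass",
    "exposed_faces",
    "sample_contacts",
    "read_object_json",
    "write_object_json",
    "DEFAULT_DENSITIES",
    "MATERIALS",
]

MATERIALS = ("wood", "brass")

#: Default material densities in g/cm^3.  Beech wood at 0.62 g/cm^3 gives a
#: 10-cube object of 2.5-cm cubes a mass of 96.875 g (~97 g); brass density
#: is the conventional 8.5 g/cm^3.  Both are configurable per object.
DEFAULT_DENSITIES: dict[str, float] = {"wood": 0.62, "brass": 8.5}

# Face directions, fixed order used for face ids and normals.
_FACE_DIRS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (-1, 0, 0),
    (0, 1, 0),
    (0, -1, 0),
    (0, 0, 1),
    (0, 0, -1),
)


class ValidationError(ValueError):
    """Raised for malformed object specifications (e.g. duplicate cells)."""


class ConnectivityError(ValidationError):
    """Raised when the cell set is not one face-connected component."""


class ConfigurationError(ValueError):
    """Raised when required configuration (e.g. a density) is missing."""


@dataclass(frozen=True)
class CubeCell:
    """One cube of the polycube, at an integer lattice position."""

    lattice_pos: tuple[int, int, int]
    material: str

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ValidationError(
                f"unknown material {self.material!r}; expected one of {MATERIALS}"
            )
        if len(self.lattice_pos) != 3 or not all(
            int(c) == c for c in self.lattice_pos
        ):
            raise ValidationError(f"lattice_pos must be an integer 3-vector, got {self.lattice_pos}")


@dataclass(frozen=True)
class Pose:
    """Rigid placement: rotation about the vertical (z) axis + translation in cm."""

    yaw_deg: float = 0.0
    translation_cm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def rotation_matrix(self) -> np.ndarray:
        a = np.deg2rad(self.yaw_deg)
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (…,3) from object frame to world frame."""
        r = self.rotation_matrix()
        return np.asarray(points) @ r.T + np.asarray(self.translation_cm)

    def apply_direction(self, vecs: np.ndarray) -> np.ndarray:
        return np.asarray(vecs) @ self.rotation_matrix().T


@dataclass(frozen=True)
class ContactPoint:
    """A candidate digit placement on an exposed cube face (world frame)."""

    position: tuple[float, float, float]
    normal: tuple[float, float, float]
    face_id: tuple[int, int, int, int]  # (i, j, k, face-direction index)

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.normal, dtype=float)


@dataclass
class RigidObject:
    """A polycube solid with per-cube materials and a table-top pose."""

    cells: list[CubeCell]
    side_cm: float = 2.5
    densities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    pose: Pose = field(default_factory=Pose)
    name: str = "object"

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValidationError("object must contain at least one cell")
        positions = [c.lattice_pos for c in self.cells]
        if len(set(positions)) != len(positions):
            raise ValidationError("duplicate lattice positions in cell list")
        _check_connected(positions)
        if self.side_cm <= 0:
            raise ValidationError("side_cm must be positive")

    # --- derived geometry -------------------------------------------------

    @property
    def cell_masses_g(self) -> np.ndarray:
        vol = self.side_cm**3
        try:
            return np.array([vol * self.densities[c.material] for c in self.cells])
        except KeyError as exc:
            raise ConfigurationError(f"no density configured for material {exc.args[0]!r}") from exc

    @property
    def mass_g(self) -> float:
        return float(self.cell_masses_g.sum())

    def cell_centroids_world(self) -> np.ndarray:
        local = (np.array([c.lattice_pos for c in self.cells], dtype=float) + 0.5) * self.side_cm
        return self.pose.apply(local)

    @property
    def com_cm(self) -> np.ndarray:
        m = self.cell_masses_g
        return (m[:, None] * self.cell_centroids_world()).sum(axis=0) / m.sum()

    def exposed_faces(self) -> list[tuple[int, int, int, int]]:
        return exposed_faces(self)

    def sample_contacts(self, per_face_grid: int = 1) -> list[ContactPoint]:
        return sample_contacts(self, per_face_grid)


def _check_connected(positions: Sequence[tuple[int, int, int]]) -> None:
    cellset = set(positions)
    seen = {positions[0]}
    stack = [positions[0]]
    while stack:
        p = stack.pop()
        for d in _FACE_DIRS:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if q in cellset and q not in seen:
                seen.add(q)
                stack.append(q)
    if len(seen) != len(cellset):
        raise ConnectivityError(
            f"cells are not face-connected: reached {len(seen)} of {len(cellset)}"
        )


def build_object(
    cells: Iterable[tuple[int, int, int]] | Iterable[CubeCell],
    materials: str | Sequence[str] | None = None,
    side_cm: float = 2.5,
    densities: Mapping[str, float] | None = None,
    pose: Pose | None = None,
    name: str = "object",
) -> RigidObject:
    """Construct a validated :class:`RigidObject`.

    ``cells`` may be CubeCell instances or bare lattice positions; in the
    latter case ``materials`` gives either one material for all cells or a
    per-cell sequence.
    """
    cells = list(cells)
    if cells and isinstance(cells[0], CubeCell):
        cube_cells = list(cells)  # type: ignore[arg-type]
    else:
        if materials is None:
            materials = "wood"
        if isinstance(materials, str):
            materials = [materials] * len(cells)
        if len(materials) != len(cells):
            raise ValidationError("materials must match number of cells")
        cube_cells = [
            CubeCell(tuple(int(v) for v in pos), mat)  # type: ignore[arg-type]
            for pos, mat in zip(cells, materials)
        ]
    return RigidObject(
        cells=cube_cells,
        side_cm=side_cm,
        densities=dict(densities) if densities is not None else dict(DEFAULT_DENSITIES),
        pose=pose or Pose(),
        name=name,
    )


def object_mass(obj: RigidObject) -> float:
    """Total mass in grams: sum of side^3 * density over cells (pose-invariant)."""
    return obj.mass_g


def center_of_mass(obj: RigidObject) -> np.ndarray:
    """Mass-weighted mean of cube centroids, in world cm."""
    return obj.com_cm


def exposed_faces(obj: RigidObject) -> list[tuple[int, int, int, int]]:
    """Faces not shared between two cells, as (i, j, k, dir-index), sorted."""
    cellset = {c.lattice_pos for c in obj.cells}
    faces = []
    for c in obj.cells:
        i, j, k = c.lattice_pos
        for di, d in enumerate(_FACE_DIRS):
            if (i + d[0], j + d[1], k + d[2]) not in cellset:
                faces.append((i, j, k, di))
    faces.sort()
    return faces


def sample_contacts(obj: RigidObject, per_face_grid: int = 1) -> list[ContactPoint]:
    """Sample ``per_face_grid``² contact points per exposed face.

    Points form a regular grid on each face (face center for grid 1);
    normals are the outward face normals mapped through the pose.  Ordering
    is deterministic: sorted by face id, then row-major grid index.
    """
    if per_face_grid < 1:
        raise ValidationError("per_face_grid must be >= 1")
    s = obj.side_cm
    g = per_face_grid
    # Fractional in-face offsets, centered within g x g sub-squares.
    ticks = (np.arange(g) + 0.5) / g
    contacts: list[ContactPoint] = []
    for face in exposed_faces(obj):
        i, j, k, di = face
        d = np.array(_FACE_DIRS[di], dtype=float)
        origin = np.array([i, j, k], dtype=float) * s
        # Face plane: the face center is cell center + (s/2) * d.
        center = origin + 0.5 * s + 0.5 * s * d
        # Two in-plane axes spanning the face.
        axis = np.flatnonzero(d)[0]
        u = np.zeros(3)
        v = np.zeros(3)
        u[(axis + 1) % 3] = 1.0
        v[(axis + 2) % 3] = 1.0
        for a in ticks:
            for b in ticks:
                local = center + (a - 0.5) * s * u + (b - 0.5) * s * v
                world = obj.pose.apply(local)
                normal = obj.pose.apply_direction(d)
                contacts.append(
                    ContactPoint(
                        position=tuple(float(x) for x in world),
                        normal=tuple(float(x) for x in normal),
                        face_id=face,
                    )
                )
    return contacts


# --- JSON interchange -----------------------------------------------------


def read_object_json(path: str | Path) -> RigidObject:
    """Read an object spec: name, side_cm, cells (pos + material), optional pose."""
    with open(path) as fh:
        spec = json.load(fh)
    return object_from_dict(spec)


def object_from_dict(spec: Mapping) -> RigidObject:
    cells = [
        CubeCell(tuple(int(v) for v in c["pos"]), c["material"]) for c in spec["cells"]
    ]
    pose_spec = spec.get("pose") or {}
    pose = Pose(
        yaw_deg=float(pose_spec.get("yaw_deg", 0.0)),
        translation_cm=tuple(pose_spec.get("translation_cm", (0.0, 0.0, 0.0))),
    )
    return RigidObject(
        cells=cells,
        side_cm=float(spec.get("side_cm", 2.5)),
        densities={str(k): float(v) for k, v in spec.get("densities", DEFAULT_DENSITIES).items()},
        pose=pose,
        name=str(spec.get("name", "object")),
    )


def object_to_dict(obj: RigidObject) -> dict:
    return {
        "name": obj.name,
        "side_cm": obj.side_cm,
        "cells": [
            {"pos": list(c.lattice_pos), "material": c.material} for c in obj.cells
        ],
        "densities": dict(obj.densities),
        "pose": {
            "yaw_deg": obj.pose.yaw_deg,
            "translation_cm": list(obj.pose.translation_cm),
        },
        "mass_g": obj.mass_g,
        "com_cm": [float(x) for x in obj.com_cm],
    }


def write_object_json(obj: RigidObject, path: str | Path) -> None:
    """Write the object spec plus derived mass and center of mass."""
    with open(path, "w") as fh:
        json.dump(object_to_dict(obj), fh, indent=2)
        fh.write("\n")
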