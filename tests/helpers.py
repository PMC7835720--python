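"""Shared helpers for constructing grasps and random polycubes in tests."""

import numpy as np

from polygrasp.objects import ContactPoint, sample_contacts
from polygrasp.grasp import Grasp


def contact(pos, normal, face_id=(0, 0, 0, 0)):
    return ContactPoint(position=tuple(pos), normal=tuple(normal), face_id=face_id)


def opposite_face_grasp(obj, axis=0):
    """Grasp through the centers of the two outermost faces along an axis."""
    contacts = sample_contacts(obj, 1)
    lo = min(contacts, key=lambda c: c.position[axis])
    hi = max(contacts, key=lambda c: c.position[axis])
    return Grasp(thumb=lo, index=hi)


def random_polycube_cells(rng, n_cells):
    """Random face-connected polycube grown by a lattice walk."""
    cells = {(0, 0, 0)}
    dirs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while len(cells) < n_cells:
        base = list(cells)[rng.integers(len(cells))]
        d = dirs[rng.integers(6)]
        cells.add((base[0] + d[0], base[1] + d[1], base[2] + d[2]))
    zmin = min(c[2] for c in cells)
    return [(i, j, k - zmin) for i, j, k in cells]
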