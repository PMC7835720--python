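"""Two-digit grasp enumeration and optimality scoring.

A grasp is an unordered pair of contact points (thumb and index) on the
object's exposed surface.  Grasps must satisfy force closure — the line
connecting the contacts must lie within both friction cones, so the digits
can oppose each other — and are then scored under four optimality
criteria:

``aperture``
    Hinge penalty (cm) on grip aperture above the precision-grip limit
    (default 2.5 cm): humans abandon two-digit grips for wider objects.
``nga``
    Misalignment (rad) of the thumb–index axis with the natural grasp
    axis, the comfortable orientation of a precision grip.
``torque``
    Magnitude (N·m) of the gravitational moment of the object's weight
    about the grasp axis; grasping far from the center of mass forces the
    object to rotate in the grip.
``visibility``
    Fraction of the object's surface occluded from the viewpoint by a
    simple hand volume placed over the grasp.

Raw costs are min–max normalized within each object's candidate set so
criteria on very different scales become comparable, and combined as a
weighted sum.  All costs are symmetric under swapping thumb and index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .objects import ContactPoint, RigidObject, sample_contacts

__all__ = [
    "CRITERIA",
    "Grasp",
    "HandModel",
    "ModelConfig",
    "GraspScore",
    "DegenerateGraspError",
    "combinatorial_budget",
    "force_closure",
    "aperture",
    "aperture_cost",
    "nga_cost",
    "torque_magnitude",
    "visibility_cost",
    "score_grasp",
    "enumerate_grasps",
    "normalize_costs",
]

#: Criterion order used in every cost 4-vector.
CRITERIA = ("aperture", "nga", "torque", "visibility")


class DegenerateGraspError(ValueError):
    """Raised for grasps with coincident contacts / zero-length grasp axis."""


@dataclass(frozen=True)
class Grasp:
    """A thumb + index contact pair.  All costs are digit-swap symmetric."""

    thumb: ContactPoint
    index: ContactPoint

    def __post_init__(self) -> None:
        if self.thumb.face_id == self.index.face_id:
            raise DegenerateGraspError("thumb and index on the same face")

    @property
    def axis(self) -> np.ndarray:
        """Unit vector along the thumb–index line (direction arbitrary)."""
        d = self.index.pos - self.thumb.pos
        n = np.linalg.norm(d)
        if n == 0:
            raise DegenerateGraspError("coincident contact positions")
        return d / n

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.thumb.pos + self.index.pos)


@dataclass(frozen=True)
class HandModel:
    """Rectangular occluder spanning the contacts, extruded toward the viewer.

    Deliberately crude: only the ordering of grasps by occluded fraction is
    treated as meaningful downstream.
    """

    depth_cm: float = 10.0
    width_cm: float = 3.0


def _default_nga_dir() -> tuple[float, float, float]:
    # Horizontal, 45 deg between the frontal (y) and lateral (x) axes.
    s = 1.0 / np.sqrt(2.0)
    return (s, s, 0.0)


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of the grasp-optimality model.

    ``viewpoint_cm`` defaults to an eye position 34 cm on the participant's
    side of the object and 30 cm above the table.
    """

    aperture_threshold_cm: float = 2.5
    friction_mu: float = 0.5
    nga_dir: tuple[float, float, float] = field(default_factory=_default_nga_dir)
    gravity_ms2: float = 9.81
    viewpoint_cm: tuple[float, float, float] = (0.0, -34.0, 30.0)
    weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    hand: HandModel = field(default_factory=HandModel)
    per_face_grid: int = 1

    def __post_init__(self) -> None:
        if self.aperture_threshold_cm <= 0:
            raise ValueError("aperture_threshold_cm must be positive")
        if self.friction_mu <= 0:
            raise ValueError("friction_mu must be positive")
        if not np.isclose(np.linalg.norm(self.nga_dir), 1.0):
            raise ValueError("nga_dir must be a unit vector")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4,) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be a nonnegative 4-vector summing to 1")


@dataclass
class GraspScore:
    """Per-grasp constraint flag, raw criterion costs and normalized costs."""

    force_closure: bool
    aperture_cm: float
    torque_Nm: float
    nga_angle_rad: float
    occluded_fraction: float
    raw_costs: np.ndarray | None = None  # 4-vector, CRITERIA order
    normalized_costs: np.ndarray | None = None
    combined_cost: float | None = None


def combinatorial_budget(
    surface_area_cm2: float, patch_area_cm2: float
) -> tuple[int, int]:
    """Candidate-location and ordered-digit-pair counts for a surface.

    Coarsely sampling ``surface_area_cm2`` in fingertip-sized patches of
    ``patch_area_cm2`` yields ``n_locations`` candidate contact sites and
    ``n_locations**2`` ordered thumb/index configurations — the size of the
    search space a two-digit grasp planner faces.
    """
    if surface_area_cm2 <= 0 or patch_area_cm2 <= 0:
        raise ValueError("areas must be positive")
    n_locations = int(round(surface_area_cm2 / patch_area_cm2))
    return n_locations, n_locations**2


def force_closure(grasp: Grasp, mu: float = 0.5) -> bool:
    """Two-contact friction-cone test.

    True iff the line between the contacts lies inside both friction cones:
    the angle between each contact normal and the direction toward its own
    side of the connecting line is at most atan(mu).  Contacts pushing on
    the same side of the object (normals not opposed) fail and cannot lift
    the object.
    """
    d = grasp.thumb.pos - grasp.index.pos  # index -> thumb
    dist = np.linalg.norm(d)
    if dist == 0:
        raise DegenerateGraspError("coincident contact positions")
    d = d / dist
    cone = np.arctan(mu)
    ang_t = np.arccos(np.clip(np.dot(grasp.thumb.n, d), -1.0, 1.0))
    ang_i = np.arccos(np.clip(np.dot(grasp.index.n, -d), -1.0, 1.0))
    return bool(ang_t <= cone + 1e-12 and ang_i <= cone + 1e-12)


def aperture(grasp: Grasp) -> float:
    """Grip aperture: Euclidean distance between the contacts, cm."""
    return float(np.linalg.norm(grasp.thumb.pos - grasp.index.pos))


def aperture_cost(aperture_cm: float, a0: float = 2.5) -> float:
    """Hinge penalty: cm of aperture in excess of the precision-grip limit a0."""
    if a0 <= 0:
        raise ValueError("a0 must be positive")
    return max(0.0, float(aperture_cm) - float(a0))


def nga_cost(grasp: Grasp, nga_dir: Sequence[float]) -> float:
    """Acute angle (rad) between the undirected grasp axis and the NGA."""
    nga = np.asarray(nga_dir, dtype=float)
    if not np.isclose(np.linalg.norm(nga), 1.0):
        raise ValueError("nga_dir must be a unit vector")
    cosang = abs(float(np.dot(grasp.axis, nga)))
    return float(np.arccos(np.clip(cosang, 0.0, 1.0)))


def torque_magnitude(grasp: Grasp, obj: RigidObject, g: float = 9.81) -> float:
    """Gravity moment of the object's weight about the grasp axis, N·m.

    The weight m·g acts at the center of mass along -z; the returned value
    is the component of its moment about the line through the two contacts:
    |((COM - p) × m g ĝ) · â|.  Zero iff the COM lies in the vertical plane
    containing the contact line.
    """
    a_hat = grasp.axis  # raises on degenerate grasps
    p_m = grasp.thumb.pos * 0.01  # cm -> m
    com_m = obj.com_cm * 0.01
    f = obj.mass_g * 1e-3 * g * np.array([0.0, 0.0, -1.0])  # weight, N
    moment = np.cross(com_m - p_m, f)
    return float(abs(np.dot(moment, a_hat)))


def _ray_hits_obb(
    start: np.ndarray,
    end: np.ndarray,
    center: np.ndarray,
    axes: np.ndarray,
    half_sizes: np.ndarray,
    eps: float = 1e-9,
) -> bool:
    """Does the open segment start→end intersect the oriented box?

    ``axes`` is a 3×3 matrix of orthonormal rows; slab test in box frame.
    """
    s = axes @ (start - center)
    e = axes @ (end - center)
    d = e - s
    t0, t1 = 0.0, 1.0
    for k in range(3):
        h = half_sizes[k]
        if abs(d[k]) < eps:
            if abs(s[k]) > h:
                return False
            continue
        ta = (-h - s[k]) / d[k]
        tb = (h - s[k]) / d[k]
        if ta > tb:
            ta, tb = tb, ta
        t0 = max(t0, ta)
        t1 = min(t1, tb)
        if t0 > t1:
            return False
    # Ignore grazing contact exactly at the start point (the surface sample
    # itself often lies on the slab boundary).
    return t1 > eps


def hand_occluder_box(
    grasp: Grasp, viewpoint: np.ndarray, hand: HandModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Oriented box (center, axis rows, half sizes) of the hand volume.

    The box spans the two contacts along the grasp axis and is extruded
    from the contact line toward the viewer by ``hand.depth_cm``.  Returns
    None for an empty (zero depth or width) hand volume.
    """
    if hand.depth_cm <= 0 or hand.width_cm <= 0:
        return None
    u = grasp.axis
    mid = grasp.midpoint
    to_view = np.asarray(viewpoint, dtype=float) - mid
    to_view = to_view - np.dot(to_view, u) * u
    nv = np.linalg.norm(to_view)
    if nv < 1e-9:  # viewer along the grasp axis: extrude upward instead
        to_view = np.array([0.0, 0.0, 1.0]) - u[2] * u
        nv = np.linalg.norm(to_view)
    v = to_view / nv
    w = np.cross(u, v)
    center = mid + 0.5 * hand.depth_cm * v
    axes = np.vstack([u, v, w])
    half = np.array(
        [0.5 * aperture(grasp), 0.5 * hand.depth_cm, 0.5 * hand.width_cm]
    )
    return center, axes, half


def visibility_cost(
    grasp: Grasp,
    obj: RigidObject,
    viewpoint: Sequence[float],
    hand: HandModel | None = None,
    surface_points: np.ndarray | None = None,
) -> float:
    """Fraction of surface sample points hidden from the viewpoint by the hand.

    The hand is modelled as a rectangular slab spanning the two contacts,
    extruded toward the viewer; a surface point counts as occluded when the
    segment from the point to the viewpoint crosses that slab.
    """
    hand = hand or HandModel()
    vp = np.asarray(viewpoint, dtype=float)
    if surface_points is None:
        surface_points = np.array([c.pos for c in sample_contacts(obj, 1)])
    lo = surface_points.min(axis=0) - 1e-9
    hi = surface_points.max(axis=0) + 1e-9
    if bool(np.all(vp >= lo) and np.all(vp <= hi)):
        # conservative check on the bounding box only
        raise ValueError("viewpoint lies inside the object's bounding box")
    box = hand_occluder_box(grasp, vp, hand)
    if box is None:
        return 0.0
    center, axes, half = box
    hits = sum(
        _ray_hits_obb(p, vp, center, axes, half) for p in surface_points
    )
    return hits / len(surface_points)


def score_grasp(
    grasp: Grasp,
    obj: RigidObject,
    config: ModelConfig,
    surface_points: np.ndarray | None = None,
) -> GraspScore:
    """Compute the constraint flag and all four raw criterion costs."""
    ap = aperture(grasp)
    score = GraspScore(
        force_closure=force_closure(grasp, config.friction_mu),
        aperture_cm=ap,
        torque_Nm=torque_magnitude(grasp, obj, config.gravity_ms2),
        nga_angle_rad=nga_cost(grasp, config.nga_dir),
        occluded_fraction=visibility_cost(
            grasp, obj, config.viewpoint_cm, config.hand, surface_points
        ),
    )
    score.raw_costs = np.array(
        [
            aperture_cost(ap, config.aperture_threshold_cm),
            score.nga_angle_rad,
            score.torque_Nm,
            score.occluded_fraction,
        ]
    )
    return score


def enumerate_grasps(
    obj: RigidObject,
    contacts: Sequence[ContactPoint] | None = None,
    config: ModelConfig | None = None,
) -> list[tuple[Grasp, GraspScore]]:
    """All force-closure-valid unordered contact pairs, fully scored.

    Thumb/index assignment does not change any cost, so enumeration is over
    unordered pairs in deterministic (contact-order) sequence.  Normalized
    costs are filled in across the returned candidate set.
    """
    config = config or ModelConfig()
    if contacts is None:
        contacts = sample_contacts(obj, config.per_face_grid)
    surface_points = (
        np.array([c.pos for c in contacts]) if contacts else None
    )
    out: list[tuple[Grasp, GraspScore]] = []
    for i in range(len(contacts)):
        for j in range(i + 1, len(contacts)):
            if contacts[i].face_id == contacts[j].face_id:
                continue
            if np.allclose(contacts[i].pos, contacts[j].pos):
                continue
            grasp = Grasp(thumb=contacts[i], index=contacts[j])
            if not force_closure(grasp, config.friction_mu):
                continue
            out.append((grasp, score_grasp(grasp, obj, config, surface_points)))
    normalize_costs([s for _, s in out], config.weights)
    return out


def normalize_costs(
    scores: Sequence[GraspScore],
    weights: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> Sequence[GraspScore]:
    """Min–max normalize raw costs per criterion over a candidate set.

    Within the set, the best grasp on a criterion gets normalized cost 0 and
    the worst 1; a criterion constant across the set normalizes to 0 for
    all.  ``combined_cost`` is the weighted sum of normalized costs.
    """
    if not scores:
        return scores
    raw = np.array([s.raw_costs for s in scores], dtype=float)
    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    norm = np.where(span > 0, (raw - lo) / safe, 0.0)
    w = np.asarray(weights, dtype=float)
    for s, row in zip(scores, norm):
        s.normalized_costs = row
        s.combined_cost = float(row @ w)
    return scores
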