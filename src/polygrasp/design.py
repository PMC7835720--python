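"""Criterion-isolating grasp-pair selection.

For each stimulus object we pick one near-optimal and one sub-optimal
grasp that differ as much as possible on a single target optimality
criterion while the remaining three criteria stay approximately constant
within the pair (|Δ| ≤ ε in normalized units) — so a participant judging
the pair is probed on that one criterion.  Residual off-target differences
are counterbalanced across the objects of a criterion block, which the
counterbalance report quantifies.

Optimality differences are expressed as Δ = normalized cost of the
sub-optimal grasp minus normalized cost of the near-optimal grasp, so
positive Δ means the near-optimal grasp is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .grasp import CRITERIA, Grasp, GraspScore, ModelConfig, enumerate_grasps
from .objects import RigidObject

__all__ = [
    "DesignError",
    "GraspPair",
    "DesignSpec",
    "select_pair",
    "design_experiment",
    "counterbalance_report",
    "assign_sticker_colors",
    "design_to_frame",
]


class DesignError(ValueError):
    """Raised when no valid criterion-isolating pair/design exists."""


@dataclass
class GraspPair:
    """A (near-optimal, sub-optimal) grasp pair isolating one criterion."""

    object_id: str
    criterion: str
    near_optimal: Grasp
    sub_optimal: Grasp
    near_score: GraspScore
    sub_score: GraspScore
    delta: np.ndarray  # optimality differences (near - sub), normalized units
    relaxed: bool = False  # True when the off-target tolerance was relaxed
    near_index: int = -1
    sub_index: int = -1

    @property
    def target_delta(self) -> float:
        return float(self.delta[CRITERIA.index(self.criterion)])


@dataclass
class DesignSpec:
    """Experiment design: objects, pairs per criterion, isolation tolerance."""

    objects: list[RigidObject]
    per_criterion_count: int = 4
    epsilon: float = 0.2
    counterbalance: bool = True
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        if self.per_criterion_count < 1:
            raise DesignError("per_criterion_count must be >= 1")
        if self.epsilon < 0:
            raise DesignError("epsilon must be >= 0")


def select_pair(
    obj_id: str,
    criterion: str,
    candidates: Sequence[tuple[Grasp, GraspScore]],
    epsilon: float = 0.2,
) -> GraspPair:
    """Exhaustively search candidate pairs for the best criterion isolator.

    Among ordered pairs (near, sub) whose off-target |Δ| are all ≤ epsilon,
    return the one maximizing the target-criterion Δ.  If no pair satisfies
    the tolerance, fall back to the pair minimizing the worst off-target
    |Δ| within the top decile of target Δs, flagged ``relaxed``.
    """
    if criterion not in CRITERIA:
        raise DesignError(f"unknown criterion {criterion!r}")
    if len(candidates) < 2:
        raise DesignError("need at least 2 scored candidates")
    ci = CRITERIA.index(criterion)
    norm = np.array([s.normalized_costs for _, s in candidates], dtype=float)
    # delta[a, b, :] = optimality(near=a) - optimality(sub=b) = cost[b] - cost[a]
    delta = norm[None, :, :] - norm[:, None, :]
    target = delta[:, :, ci]
    off = np.abs(np.delete(delta, ci, axis=2)).max(axis=2)
    positive = target > 0
    if not positive.any():
        raise DesignError("no candidate pair with positive target delta")
    feasible = positive & (off <= epsilon)
    if feasible.any():
        masked = np.where(feasible, target, -np.inf)
        a, b = np.unravel_index(int(np.argmax(masked)), masked.shape)
        relaxed = False
    else:
        # top decile of positive target deltas, then minimize worst off-target
        vals = target[positive]
        cutoff = np.quantile(vals, 0.9)
        pool = positive & (target >= cutoff)
        masked = np.where(pool, off, np.inf)
        a, b = np.unravel_index(int(np.argmin(masked)), masked.shape)
        relaxed = True
    return GraspPair(
        object_id=obj_id,
        criterion=criterion,
        near_optimal=candidates[a][0],
        sub_optimal=candidates[b][0],
        near_score=candidates[a][1],
        sub_score=candidates[b][1],
        delta=delta[a, b].copy(),
        relaxed=relaxed,
        near_index=int(a),
        sub_index=int(b),
    )


def design_experiment(spec: DesignSpec) -> tuple[list[GraspPair], np.ndarray]:
    """Select one pair per object, criteria assigned in blocks.

    The first ``per_criterion_count`` objects probe the first criterion,
    the next block the second, and so on.  Returns the pairs and the
    4 x n_objects matrix of per-criterion optimality differences (each
    column one pair's Δ vector).
    """
    needed = spec.per_criterion_count * len(CRITERIA)
    if len(spec.objects) < needed:
        raise DesignError(
            f"need {needed} objects ({spec.per_criterion_count} per criterion), "
            f"got {len(spec.objects)}"
        )
    pairs: list[GraspPair] = []
    for idx, obj in enumerate(spec.objects[:needed]):
        criterion = CRITERIA[idx // spec.per_criterion_count]
        candidates = enumerate_grasps(obj, config=spec.model)
        pairs.append(select_pair(obj.name, criterion, candidates, spec.epsilon))
    matrix = np.column_stack([p.delta for p in pairs])
    return pairs, matrix


def counterbalance_report(pairs: Sequence[GraspPair]) -> pd.DataFrame:
    """Signed sums of off-target deltas within each criterion block.

    Rows are criterion blocks, columns the four criteria; entry (block, j)
    is the sum over the block's objects of Δ_j.  Off-target sums near zero
    indicate residual differences counterbalance across objects.
    """
    if not pairs:
        raise DesignError("no pairs to report on")
    blocks = sorted({p.criterion for p in pairs}, key=CRITERIA.index)
    rows = {}
    for block in blocks:
        total = np.zeros(len(CRITERIA))
        for p in pairs:
            if p.criterion == block:
                total += p.delta
        rows[block] = total
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CRITERIA))


def assign_sticker_colors(
    pairs: Sequence[GraspPair], seed: int
) -> list[dict[str, str]]:
    """Randomly map the near/sub roles of each pair to blue/green markers."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in pairs:
        near_blue = bool(rng.integers(2))
        out.append(
            {"near_optimal": "blue", "sub_optimal": "green"}
            if near_blue
            else {"near_optimal": "green", "sub_optimal": "blue"}
        )
    return out


def design_to_frame(pairs: Sequence[GraspPair]) -> pd.DataFrame:
    """Tabular design output: one row per pair with its Δ vector and flag."""
    rows = []
    for p in pairs:
        row = {
            "object": p.object_id,
            "criterion": p.criterion,
            "near_grasp_id": p.near_index,
            "sub_grasp_id": p.sub_index,
            "relaxed": p.relaxed,
        }
        for j, name in enumerate(CRITERIA):
            row[f"delta_{name}"] = float(p.delta[j])
        rows.append(row)
    return pd.DataFrame(rows)
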