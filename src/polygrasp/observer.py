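"""Parametric 2AFC observer and trial-table simulation.

The experiment asks, for each object, which of two marked grasps is
better; responses are scored correct when the model-optimal (near-optimal)
grasp is chosen.  The observer here is deliberately minimal scaffolding
for the data's structure, not a claim about human mechanism: the
probability of a correct judgment is a logistic function of the pair's
optimality difference Δ,

    P(correct) = λ/2 + (1 − λ) · 1 / (1 + exp(−k·Δ)),

with a session-specific sensitivity k ≥ 0 (vision, video, grasping) and a
lapse rate λ.  k = 0 yields chance (50%) performance; larger k yields
higher accuracy.  The observer is memoryless across trials — matching the
absence of within-session learning in the judgments being emulated — with
an optional linear sensitivity drift for power analyses.

Each participant draws from an independent RNG stream derived from the
master seed, so enlarging the cohort never perturbs existing participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .design import GraspPair

__all__ = [
    "SESSIONS",
    "ObserverModel",
    "TrialRecord",
    "ObserverFit",
    "p_correct",
    "simulate_experiment",
    "records_to_frame",
    "frame_to_records",
    "fit_observer",
    "pair_deltas",
]

SESSIONS = ("vision", "video", "grasping")

TRIAL_COLUMNS = [
    "participant",
    "session",
    "object",
    "criterion",
    "trial",
    "order",
    "chose_near_optimal",
]


@dataclass(frozen=True)
class ObserverModel:
    """Session-wise sensitivity to the optimality difference, plus lapses."""

    sensitivity_k: Mapping[str, float] = field(
        default_factory=lambda: {"vision": 0.0, "video": 3.0, "grasping": 3.0}
    )
    lapse: float = 0.0
    seed: int = 0
    drift_per_trial: float = 0.0  # optional k increment per trial index

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")
        for s, k in self.sensitivity_k.items():
            if not np.isfinite(k) or k < 0:
                raise ValueError(f"sensitivity for session {s!r} must be finite and >= 0")


@dataclass(frozen=True)
class TrialRecord:
    """One simulated judgment of which grasp of a pair is better."""

    participant_id: int
    session: str
    object_id: str
    criterion: str
    trial_index: int
    presentation_order: str  # "near_first" | "near_second"
    chose_near_optimal: bool


def p_correct(delta: float | np.ndarray, k: float, lapse: float = 0.0) -> np.ndarray:
    """Probability of choosing the near-optimal grasp of a pair."""
    if not 0.0 <= lapse <= 0.5:
        raise ValueError("lapse must lie in [0, 0.5]")
    if k < 0:
        raise ValueError("k must be >= 0")
    return lapse / 2.0 + (1.0 - lapse) * expit(k * np.asarray(delta, dtype=float))


def pair_deltas(
    design: Sequence[GraspPair] | Sequence[tuple], delta_mode: str = "target"
) -> list[tuple[str, str, float]]:
    """Extract (object_id, criterion, Δ) triples from a design.

    ``delta_mode`` selects the Δ the observer sees: the target-criterion
    normalized difference (default) or the combined-cost difference.
    """
    out = []
    for item in design:
        if isinstance(item, GraspPair):
            if delta_mode == "target":
                d = item.target_delta
            elif delta_mode == "combined":
                d = float(item.sub_score.combined_cost - item.near_score.combined_cost)
            else:
                raise ValueError(f"unknown delta_mode {delta_mode!r}")
            out.append((item.object_id, item.criterion, d))
        else:
            obj_id, criterion, d = item
            out.append((str(obj_id), str(criterion), float(d)))
    return out


def _participant_rng(seed: int, participant_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, participant_id)))


def simulate_experiment(
    design: Sequence[GraspPair] | Sequence[tuple],
    observer: ObserverModel,
    n_participants: int = 21,
    sessions: Iterable[str] = SESSIONS,
    delta_mode: str = "target",
) -> list[TrialRecord]:
    """Simulate one cohort: per participant x session x pair, one judgment.

    Object order and presentation order are randomized per participant from
    the master seed; results are fully reproducible given the seed.
    """
    info = pair_deltas(design, delta_mode)
    if not info:
        raise ValueError("design is empty")
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    sessions = list(sessions)
    unknown = set(sessions) - set(SESSIONS)
    if unknown:
        raise ValueError(f"unknown sessions: {sorted(unknown)}")
    deltas = np.array([d for _, _, d in info])
    records: list[TrialRecord] = []
    for pid in range(n_participants):
        rng = _participant_rng(observer.seed, pid)
        for session in sessions:
            k = observer.sensitivity_k.get(session, 0.0)
            order = rng.permutation(len(info))
            near_first = rng.integers(2, size=len(info)).astype(bool)
            trial_k = k + observer.drift_per_trial * np.arange(len(info))
            p = np.array(
                [
                    p_correct(deltas[order[t]], trial_k[t], observer.lapse)
                    for t in range(len(info))
                ]
            )
            correct = rng.random(len(info)) < p
            for t, pair_idx in enumerate(order):
                obj_id, criterion, _ = info[pair_idx]
                records.append(
                    TrialRecord(
                        participant_id=pid,
                        session=session,
                        object_id=obj_id,
                        criterion=criterion,
                        trial_index=t,
                        presentation_order="near_first" if near_first[t] else "near_second",
                        chose_near_optimal=bool(correct[t]),
                    )
                )
    return records


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial table in the interchange schema consumed by the analysis stage."""
    return pd.DataFrame(
        {
            "participant": [r.participant_id for r in records],
            "session": [r.session for r in records],
            "object": [r.object_id for r in records],
            "criterion": [r.criterion for r in records],
            "trial": [r.trial_index for r in records],
            "order": [r.presentation_order for r in records],
            "chose_near_optimal": [int(r.chose_near_optimal) for r in records],
        },
        columns=TRIAL_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(
            participant_id=int(row.participant),
            session=str(row.session),
            object_id=str(row.object),
            criterion=str(row.criterion),
            trial_index=int(row.trial),
            presentation_order=str(row.order),
            chose_near_optimal=bool(row.chose_near_optimal),
        )
        for row in frame.itertuples(index=False)
    ]


@dataclass(frozen=True)
class ObserverFit:
    """Maximum-likelihood sensitivity estimate for one session."""

    k: float
    log_likelihood: float
    at_boundary: bool


def fit_observer(
    records: Sequence[TrialRecord] | pd.DataFrame,
    deltas: Mapping[str, float],
    lapse: float = 0.0,
    k_max: float = 100.0,
) -> dict[str, ObserverFit]:
    """Fit the session sensitivities k by maximum likelihood (lapse fixed).

    ``deltas`` maps object id to the pair's Δ.  Uses bounded 1-D search per
    session; an estimate pinned at 0 or ``k_max`` (e.g. from all-constant
    responses) is flagged ``at_boundary``.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    fits: dict[str, ObserverFit] = {}
    for session, grp in frame.groupby("session"):
        d = grp["object"].map(deltas).to_numpy(dtype=float)
        if np.isnan(d).any():
            missing = sorted(set(grp["object"][grp["object"].map(deltas).isna()]))
            raise KeyError(f"no delta provided for objects {missing}")
        y = grp["chose_near_optimal"].to_numpy(dtype=float)

        def nll(k: float) -> float:
            p = np.clip(p_correct(d, k, lapse), 1e-12, 1 - 1e-12)
            return -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

        res = minimize_scalar(nll, bounds=(0.0, k_max), method="bounded")
        k_hat = float(res.x)
        boundary = k_hat < 1e-3 or k_hat > k_max - 1e-3
        fits[str(session)] = ObserverFit(
            k=k_hat, log_likelihood=-float(res.fun), at_boundary=boundary
        )
    return fits
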