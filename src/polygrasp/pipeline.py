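"""End-to-end pipeline: objects → grasp scoring → design → simulation → stats.

Ties the stages together under one seeded configuration and writes a
reproducible artifact bundle (design CSV, trial CSV, analysis report JSON,
figures).  Every output embeds a hash of the resolved configuration so a
bundle can be traced back to the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .design import DesignSpec, GraspPair, design_experiment, design_to_frame
from .grasp import HandModel, ModelConfig
from .objects import RigidObject, build_object, object_from_dict, object_to_dict
from .observer import ObserverModel, records_to_frame, simulate_experiment
from . import stats as st

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "generate_fixtures",
    "run_pipeline",
    "load_config",
]

log = logging.getLogger("polygrasp")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# --- demo object set ------------------------------------------------------

# Four 10-cube shapes: an L, a T, a planar zigzag and a 3D staircase.  The
# original stimulus shapes are not machine-readable, so these are plausible
# stand-ins with the same cube count and connectivity properties.
_SHAPES: dict[str, list[tuple[int, int, int]]] = {
    "ell": [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0), (5, 0, 0),
            (6, 0, 0), (6, 0, 1), (6, 0, 2), (6, 0, 3)],
    "tee": [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0), (5, 0, 0),
            (6, 0, 0), (3, 0, 1), (3, 0, 2), (3, 0, 3)],
    "zig": [(0, 0, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0), (2, 2, 0), (3, 2, 0),
            (4, 2, 0), (4, 3, 0), (4, 4, 0), (4, 4, 1)],
    "stair": [(0, 0, 0), (1, 0, 0), (1, 0, 1), (2, 0, 1), (2, 0, 2), (3, 0, 2),
              (3, 0, 3), (3, 1, 3), (3, 2, 3), (3, 2, 2)],
}

# Four material configurations per shape: all wood (light, ~97 g) and three
# half-brass layouts (heavy, ~712 g at the default densities) differing in
# mass distribution.
_MATERIAL_CONFIGS: dict[str, list[str]] = {
    "wood": ["wood"] * 10,
    "brass_head": ["brass"] * 5 + ["wood"] * 5,
    "brass_tail": ["wood"] * 5 + ["brass"] * 5,
    "brass_mixed": ["brass" if i % 2 == 0 else "wood" for i in range(10)],
}


def generate_fixtures(seed: int = 0) -> list[RigidObject]:
    """Demo stimulus set: 16 objects (4 shapes × 4 material configurations).

    Each object is a validated, face-connected 10-cube polycube; the seed
    randomizes only the turntable orientation of each object.
    """
    rng = np.random.default_rng(seed)
    objects = []
    from .objects import Pose

    for shape_name, cells in _SHAPES.items():
        for mat_name, materials in _MATERIAL_CONFIGS.items():
            yaw = float(rng.uniform(0.0, 360.0))
            objects.append(
                build_object(
                    cells,
                    materials,
                    pose=Pose(yaw_deg=yaw),
                    name=f"{shape_name}-{mat_name}",
                )
            )
    return objects


# --- configuration --------------------------------------------------------


@dataclass
class PipelineConfig:
    """Resolved configuration of one end-to-end run."""

    seed: int = 0
    objects_path: str | None = None  # None -> generated demo set
    model: ModelConfig = field(default_factory=ModelConfig)
    per_criterion_count: int = 4
    epsilon: float = 0.2
    sensitivity_k: dict[str, float] = field(
        default_factory=lambda: {"vision": 0.0, "video": 3.0, "grasping": 3.0}
    )
    lapse: float = 0.0
    n_participants: int = 21
    sessions: tuple[str, ...] = ("vision", "video", "grasping")
    bootstrap_reps: int = 10000
    alpha: float = 0.05
    rope: tuple[float, float] = (-0.4, 0.4)
    run_bayes: bool = True
    out_dir: str = "out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"]["nga_dir"] = list(self.model.nga_dir)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where outputs land does not affect their content
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML or JSON pipeline configuration file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model_raw = raw.pop("model", {})
    hand_raw = model_raw.pop("hand", {})
    model_kwargs = dict(model_raw)
    if "nga_dir" in model_kwargs:
        model_kwargs["nga_dir"] = tuple(model_kwargs["nga_dir"])
    if "viewpoint_cm" in model_kwargs:
        model_kwargs["viewpoint_cm"] = tuple(model_kwargs["viewpoint_cm"])
    if "weights" in model_kwargs:
        model_kwargs["weights"] = tuple(model_kwargs["weights"])
    model = ModelConfig(hand=HandModel(**hand_raw), **model_kwargs)
    if "sessions" in raw:
        raw["sessions"] = tuple(raw["sessions"])
    if "rope" in raw:
        raw["rope"] = tuple(raw["rope"])
    return PipelineConfig(model=model, **raw)


# --- stages ---------------------------------------------------------------


def _load_objects(config: PipelineConfig) -> list[RigidObject]:
    if config.objects_path is None:
        return generate_fixtures(config.seed)
    path = Path(config.objects_path)
    try:
        with open(path) as fh:
            specs = json.load(fh)
        return [object_from_dict(s) for s in specs]
    except (OSError, KeyError, ValueError) as exc:
        raise PipelineError("build-objects", str(exc)) from exc


def _write_csv(frame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, index=False)


def _test_result_dict(res: st.TestResult) -> dict:
    return {
        "t": res.t,
        "df": res.df,
        "p": res.p,
        "mean_diff": res.mean_diff,
        "ci": list(res.ci) if res.ci else None,
        "hdi95": list(res.hdi95) if res.hdi95 else None,
        "effect_size": res.effect_size,
        "rope_fraction": res.rope_fraction,
    }


def analyze_trials(trials, config: PipelineConfig) -> dict:
    """Full analysis report for a trial table: per-session tests and contrasts."""
    pc = st.percent_correct(trials)
    sessions = [s for s in config.sessions if s in set(pc["session"])]
    report: dict = {"sessions": {}, "contrasts": {}}
    values = {s: st.session_values(pc, s) for s in sessions}
    for s in sessions:
        v = values[s]
        res = st.one_sample_t(v, st.CHANCE)
        res.ci = st.bootstrap_ci(v, reps=config.bootstrap_reps, seed=config.seed)
        if config.run_bayes:
            bay = st.bayes_estimate(v, st.CHANCE, rope=config.rope, seed=config.seed)
            res.hdi95 = bay.hdi95
            res.rope_fraction = bay.rope_fraction
        report["sessions"][s] = {
            "mean_percent_correct": float(v.mean()),
            **_test_result_dict(res),
        }
    for i in range(len(sessions)):
        for j in range(i + 1, len(sessions)):
            a, b = sessions[j], sessions[i]  # later session minus earlier
            res = st.paired_t(values[a], values[b])
            if config.run_bayes:
                bay = st.bayes_estimate_paired(
                    values[a], values[b], rope=config.rope, seed=config.seed
                )
                res.hdi95 = bay.hdi95
                res.rope_fraction = bay.rope_fraction
            report["contrasts"][f"{a}_vs_{b}"] = _test_result_dict(res)
    report["learning_trend"] = {
        s: _test_result_dict(r) for s, r in st.learning_trend(trials).items()
    }
    if {"vision", "grasping"} <= set(sessions):
        report["replication_subset"] = st.select_replication_subset(
            trials, alpha=config.alpha, seed=config.seed
        )
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle to ``config.out_dir``.

    Returns a manifest dict with output paths and the config hash.  The run
    is deterministic given the configuration (including its seed).
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, force=False)
    log.info("pipeline start: config hash %s", chash)

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)

    stage("build-objects")
    objects_path = out / "objects.json"
    try:
        objects = _load_objects(config)
        with open(objects_path, "w") as fh:
            json.dump(
                {"config_hash": chash, "objects": [object_to_dict(o) for o in objects]},
                fh,
                indent=2,
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("build-objects", str(exc)) from exc

    stage("design-stimuli")
    try:
        spec = DesignSpec(
            objects=objects,
            per_criterion_count=config.per_criterion_count,
            epsilon=config.epsilon,
            model=config.model,
        )
        pairs, delta_matrix = design_experiment(spec)
    except Exception as exc:
        raise PipelineError("design-stimuli", str(exc)) from exc
    design_path = out / "design.csv"
    _write_csv(design_to_frame(pairs), design_path, chash)

    stage("simulate")
    try:
        observer = ObserverModel(
            sensitivity_k=dict(config.sensitivity_k),
            lapse=config.lapse,
            seed=config.seed,
        )
        records = simulate_experiment(
            pairs, observer, config.n_participants, config.sessions
        )
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    trials = records_to_frame(records)
    trials_path = out / "trials.csv"
    _write_csv(trials, trials_path, chash)

    stage("analyze")
    try:
        report = analyze_trials(trials, config)
    except Exception as exc:
        raise PipelineError("analyze", str(exc)) from exc
    report_meta = {
        "config_hash": chash,
        "version": __version__,
        "config": config.to_dict(),
        "delta_matrix": delta_matrix.tolist(),
        "report": report,
    }
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report_meta, fh, indent=2)
        fh.write("\n")

    fig_path = out / "session_means.png"
    st.plot_session_means(
        trials, str(fig_path), reps=min(config.bootstrap_reps, 2000), seed=config.seed
    )

    log.info("pipeline done in %.1fs", time.time() - t0)
    return {
        "config_hash": chash,
        "objects": str(objects_path),
        "design": str(design_path),
        "trials": str(trials_path),
        "report": str(report_path),
        "figure": str(fig_path),
        "n_pairs": len(pairs),
    }
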