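"""Decision-making layer: intention-to-command mapping, the delivery state
machine, and an end-to-end drinking-task simulation on synthetic data.

A task needs exactly two decoded commands: the cup choice (deliver) and
``back`` (return).  Between them the vision stack segments and locates the
requested object and the frame graph maps it into the robot frame; robot
motion itself is simulated as an instantaneous waypoint traversal with a
configurable fixed duration.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np

from . import blda, decoder, vision
from .preprocess import preprocess_session
from .synth import SessionTiming, SyntheticSessionSpec, synthesize_recording
from .vision import FrameGraph, RigidTransform, SceneObject, SceneSpec

__all__ = ["Command", "SystemState", "map_decision", "transition", "run_e2e"]

logger = logging.getLogger(__name__)


class Command(enum.Enum):
    CUP1 = "cup1"
    CUP2 = "cup2"
    CUP3 = "cup3"
    BACK = "back"

    @property
    def object_id(self) -> int | None:
        """1-based object index for deliver commands, None for ``back``."""
        return None if self is Command.BACK else int(self.value[-1])


def map_decision(decision: int) -> Command:
    """Bijection decoded key -> command: keys 1..3 deliver cup 1..3, key 4
    sends the held object back."""
    mapping = {1: Command.CUP1, 2: Command.CUP2, 3: Command.CUP3, 4: Command.BACK}
    try:
        return mapping[decision]
    except KeyError:
        raise ValueError(f"decoded key {decision} outside the 4-key speller") from None


@dataclass(frozen=True)
class LogEvent:
    t: float                        # simulated seconds since session start
    kind: str                       # decode | transition | rejected | ...
    detail: str
    position: tuple[float, float, float] | None = None
    frame: str = ""


@dataclass
class SystemState:
    mode: str = "idle"              # idle | delivering | holding | returning
    held_object: int | None = None
    clock: float = 0.0
    log: list[LogEvent] = field(default_factory=list)

    def record(self, kind: str, detail: str,
               position: np.ndarray | None = None, frame: str = "") -> None:
        pos = tuple(float(v) for v in position) if position is not None else None
        self.log.append(LogEvent(self.clock, kind, detail, pos, frame))


def transition(
    state: SystemState,
    command: Command,
    world: dict,
    motion_s: float = 10.0,
) -> bool:
    """Apply a command; returns True if accepted, False if rejected (the
    reason is logged either way).

    ``world`` maps object ids to robot-frame positions and may carry a
    ``"mouth"`` position.  Deliver is valid only from ``idle`` with the
    object located; ``back`` only from ``holding``.
    """
    if command is Command.BACK:
        if state.mode != "holding":
            state.record("rejected", f"back invalid in mode {state.mode}")
            return False
        state.mode = "returning"
        state.record("transition", f"returning object {state.held_object}")
        state.clock += motion_s
        state.mode = "idle"
        state.record("transition", f"object {state.held_object} returned; idle")
        state.held_object = None
        return True

    obj = command.object_id
    if state.mode != "idle":
        state.record("rejected", f"{command.value} invalid in mode {state.mode}")
        return False
    if obj not in world:
        state.record("rejected", f"{command.value}: object {obj} not located")
        return False
    state.mode = "delivering"
    state.record("transition", f"delivering object {obj}",
                 np.asarray(world[obj]), "robot")
    state.clock += motion_s
    state.mode = "holding"
    state.held_object = obj
    mouth = world.get("mouth")
    state.record("transition", f"holding object {obj} at mouth",
                 np.asarray(mouth) if mouth is not None else None, "robot")
    return True


# ---------------------------------------------------------------------------
# End-to-end simulation
# ---------------------------------------------------------------------------

def _default_scene(seed: int) -> SceneSpec:
    return SceneSpec(
        objects=(
            SceneObject("cylinder", (-0.30, 0.0), height=0.12, radius=0.075),
            SceneObject("cylinder", (0.0, 0.10), height=0.15, radius=0.07),
            SceneObject("box", (0.30, -0.05), height=0.13, size=(0.12, 0.12)),
        ),
        seed=seed,
    )


def _default_frames() -> FrameGraph:
    # camera tilted/offset above the board; board offset from the robot base
    c = np.cos(np.pi)
    s = np.sin(np.pi)
    r_kc = np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])   # board -> camera
    return FrameGraph([
        RigidTransform(r_kc, np.array([0.1, -0.05, 1.0]), "board", "camera"),
        RigidTransform(np.eye(3), np.array([0.45, 0.2, 0.0]), "board", "robot"),
    ])


def run_e2e(config: dict | None = None, seed: int = 0) -> dict:
    """Simulate a batch of drinking tasks end to end.

    ``config`` keys (all optional): ``tasks`` (list of cup ids 1..3 or an
    int count), ``eeg`` (SyntheticSessionSpec overrides for the test EEG;
    ``train_*`` prefixed keys shape the training session), ``theta0``,
    ``scene`` (a SceneSpec), ``frames`` (a FrameGraph), ``mouth`` (robot
    frame 3-vector), ``motion_s``.
    """
    config = dict(config or {})
    rng = np.random.default_rng(seed)
    timing = config.get("timing", SessionTiming())
    eeg_cfg = dict(config.get("eeg", {}))
    train_cfg = {
        "n_trials": eeg_cfg.pop("train_trials", 40),
        "rounds_per_trial": eeg_cfg.pop("train_rounds", timing.rounds_per_trial_training),
    }
    test_rounds = eeg_cfg.pop("test_rounds", timing.m_max)
    theta0 = config.get("theta0", 0.5)
    motion_s = config.get("motion_s", 10.0)

    tasks = config.get("tasks", 10)
    if isinstance(tasks, int):
        tasks = [int(rng.integers(1, 4)) for _ in range(tasks)]

    # -- train the decoder on its own synthetic session --------------------
    train_spec = SyntheticSessionSpec(
        seed=int(rng.integers(2**31)), **train_cfg, **eeg_cfg
    )
    train_rec = synthesize_recording(train_spec, timing)
    feats = preprocess_session(train_rec, timing)
    X, t = blda.build_training_set(feats)
    model = blda.fit(X, t)

    # -- perceive the scene once (objects are static) ----------------------
    scene = config.get("scene", _default_scene(seed))
    cloud, _ = vision.synth_scene(scene)
    nrm = vision.normals(cloud)
    plane_set = vision.extract_planes(cloud, nrm)
    located: dict = {}
    fail_stage = None
    if not plane_set.planes:
        fail_stage = "plane-extraction"
    else:
        hulls = vision.object_hulls(plane_set, cloud)
        objset = vision.segment_objects(cloud, plane_set, hulls)
        frames = config.get("frames", _default_frames())
        cam_to_robot = frames.transform("camera", "robot")
        centroids = [vision.locate(idx, cloud) for idx in objset.objects]
        # deliver command i refers to the i-th object left to right (board x)
        order = np.argsort([cam_to_robot.apply(c)[0] for c in centroids])
        for obj_id, k in enumerate(order, start=1):
            located[obj_id] = cam_to_robot.apply(centroids[k])
        located["mouth"] = np.asarray(config.get("mouth", (0.0, -0.4, 0.4)))

    # -- run the tasks ------------------------------------------------------
    state = SystemState()
    task_reports = []
    for task_idx, cup in enumerate(tasks):
        intended = [cup, 4]                      # choose the cup, then back
        test_spec = SyntheticSessionSpec(
            n_trials=2, rounds_per_trial=test_rounds,
            seed=int(rng.integers(2**31)), **eeg_cfg,
        )
        rec = synthesize_recording(test_spec, timing, targets=intended)
        report = decoder.simulate_online(rec, model, theta0, timing)

        decisions = [r.decision for r in report.trials]
        rounds = [r.M for r in report.trials]
        decode_s = sum(r.selection_s for r in report.trials)
        state.clock += report.trials[0].selection_s

        task_fail = fail_stage
        commands = [map_decision(d) for d in decisions]
        state.record("decode", f"task {task_idx}: decoded {commands[0].value}")
        ok1 = transition(state, commands[0], located, motion_s=motion_s)
        if task_fail is None and not ok1:
            task_fail = "delivery"
        state.clock += report.trials[1].selection_s
        state.record("decode", f"task {task_idx}: decoded {commands[1].value}")
        ok2 = transition(state, commands[1], located, motion_s=motion_s)
        if task_fail is None and not ok2:
            task_fail = "return"
        if task_fail is None and decisions != intended:
            task_fail = "decode"
        if state.mode != "idle":
            # recover so the next task starts clean
            if state.mode == "holding":
                transition(state, Command.BACK, located, motion_s=motion_s)
        task_reports.append({
            "task": task_idx,
            "cup": cup,
            "intended": intended,
            "decisions": decisions,
            "rounds": rounds,
            "decode_s": decode_s,
            "success": task_fail is None,
            "fail_stage": task_fail,
        })

    n_ok = sum(r["success"] for r in task_reports)
    return {
        "tasks": task_reports,
        "n_tasks": len(task_reports),
        "accuracy": n_ok / len(task_reports) if task_reports else float("nan"),
        "n_decodes": 2 * len(task_reports),
        "mean_rounds": float(np.mean([m for r in task_reports for m in r["rounds"]]))
        if task_reports else float("nan"),
        "objects_located": {k: v.tolist() for k, v in located.items()
                            if isinstance(k, int)},
        "log": state.log,
        "theta0": theta0,
    }
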