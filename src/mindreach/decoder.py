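"""Self-adaptive online decoding: score normalization, the theta0 stopping
rule, offline simulation, threshold selection and information transfer rate.

Each round contributes one feature vector per key; per-key features are
averaged over the rounds seen so far, scored by the discriminant's
predictive mean, and the scores are normalized to the simplex.  The trial
stops as soon as at least ``m_min`` rounds are in and the best normalized
score reaches ``theta0``, or is forced at ``m_max`` rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .blda import BldaModel, augment_bias
from .preprocess import DEFAULT_BAND, DEFAULT_DECIMATION, preprocess_session
from .synth import EegRecording, SessionTiming

__all__ = [
    "DecodeState",
    "TrialResult",
    "SimulationReport",
    "ThresholdCurve",
    "normalize_scores",
    "step",
    "simulate_online",
    "itr_bits_per_min",
    "wolpaw_bits",
    "select_threshold",
]

logger = logging.getLogger(__name__)


def normalize_scores(mu: np.ndarray) -> np.ndarray:
    """Shifted-sum normalization onto [0, 1]:

        S_i = (mu_i - min mu) / sum_j (mu_j - min mu)

    All-equal scores map to the uniform 1/K.  The result sums to one and is
    invariant to adding a constant to every score.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.size < 2:
        raise ValueError("need at least two scores")
    if not np.all(np.isfinite(mu)):
        raise ValueError(f"non-finite scores: {mu}")
    shifted = mu - mu.min()
    total = shifted.sum()
    if total == 0.0:
        return np.full(mu.size, 1.0 / mu.size)
    return shifted / total


@dataclass
class DecodeState:
    """Accumulator of one trial's rounds."""

    n_keys: int
    M: int = 0
    sum_features: dict[int, np.ndarray] = field(default_factory=dict)
    scores_raw: np.ndarray | None = None
    scores_norm: np.ndarray | None = None
    decision: int | None = None

    @property
    def decided(self) -> bool:
        return self.decision is not None


def _argmax_lowest_key(scores: np.ndarray) -> int:
    """1-based argmax; ties broken by the lowest key id (and logged)."""
    best = np.flatnonzero(scores == scores.max())
    if best.size > 1:
        logger.info("score tie between keys %s; picking key %d",
                    (best + 1).tolist(), best[0] + 1)
    return int(best[0]) + 1


def step(
    state: DecodeState,
    round_features: dict[int, np.ndarray],
    model: BldaModel,
    theta0: float,
    timing: SessionTiming,
) -> DecodeState:
    """Consume one round (a feature vector per key) and maybe decide.

    Mutates and returns ``state``.  Features arrive *without* the bias
    coordinate; it is appended at scoring time.
    """
    if set(round_features) != set(range(1, state.n_keys + 1)):
        raise ValueError(
            f"round features for keys {sorted(round_features)}; expected 1..{state.n_keys}"
        )
    if state.decided:
        raise ValueError("trial already decided; reset the state")

    state.M += 1
    for key, x in round_features.items():
        x = np.asarray(x, dtype=float)
        if key in state.sum_features:
            if x.size != state.sum_features[key].size:
                raise ValueError("feature length changed mid-trial")
            state.sum_features[key] = state.sum_features[key] + x
        else:
            state.sum_features[key] = x.copy()

    mu = np.array([
        model.predict_mean(augment_bias(state.sum_features[k] / state.M))
        for k in range(1, state.n_keys + 1)
    ])
    state.scores_raw = mu
    state.scores_norm = normalize_scores(mu)

    if state.M >= timing.m_min and state.scores_norm.max() >= theta0:
        state.decision = _argmax_lowest_key(state.scores_norm)
    elif state.M >= timing.m_max:
        state.decision = _argmax_lowest_key(state.scores_norm)
    return state


@dataclass(frozen=True)
class TrialResult:
    trial_index: int
    target: int
    decision: int
    M: int
    selection_s: float


@dataclass(frozen=True)
class SimulationReport:
    trials: list[TrialResult]
    accuracy: float
    mean_M: float
    mean_selection_s: float
    theta0: float

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _features_by_trial_round(
    recording: EegRecording,
    timing: SessionTiming,
    band: tuple[float, float],
    step_: int,
) -> dict[int, dict[int, dict[int, np.ndarray]]]:
    """trial -> round -> key -> feature vector (bias not yet appended)."""
    out: dict[int, dict[int, dict[int, np.ndarray]]] = {}
    for f in preprocess_session(recording, timing, band=band, step=step_):
        out.setdefault(f.trial_index, {}).setdefault(f.round_index, {})[f.key_id] = f.x
    return out


def simulate_online(
    recording: EegRecording,
    model: BldaModel,
    theta0: float,
    timing: SessionTiming,
    band: tuple[float, float] = DEFAULT_BAND,
    decimation: int = DEFAULT_DECIMATION,
) -> SimulationReport:
    """Replay a recorded session through the adaptive loop.

    Selection time per trial is ``M * t_round`` (flash time only; pauses
    between trials are not charged to the selection).
    """
    table = _features_by_trial_round(recording, timing, band, decimation)
    results: list[TrialResult] = []
    for trial in sorted(table):
        state = DecodeState(n_keys=timing.n_keys)
        for rnd in sorted(table[trial]):
            step(state, table[trial][rnd], model, theta0, timing)
            if state.decided:
                break
        if not state.decided:
            # fewer recorded rounds than m_max: force the decision
            state.decision = _argmax_lowest_key(state.scores_norm)
        results.append(
            TrialResult(
                trial_index=trial,
                target=int(recording.targets[trial]),
                decision=state.decision,
                M=state.M,
                selection_s=state.M * timing.t_round,
            )
        )
    accuracy = float(np.mean([r.decision == r.target for r in results]))
    mean_m = float(np.mean([r.M for r in results]))
    return SimulationReport(
        trials=results,
        accuracy=accuracy,
        mean_M=mean_m,
        mean_selection_s=mean_m * timing.t_round,
        theta0=theta0,
    )


def wolpaw_bits(K: int, p: float) -> float:
    """Bits per selection: log2 K + p log2 p + (1-p) log2((1-p)/(K-1))."""
    if K < 2:
        raise ValueError(f"need K >= 2 symbols, got {K}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"accuracy must lie in [0, 1], got {p}")
    bits = np.log2(K)
    if p > 0.0:
        bits += p * np.log2(p)
    if p < 1.0:
        bits += (1.0 - p) * np.log2((1.0 - p) / (K - 1))
    return float(max(bits, 0.0))


def itr_bits_per_min(K: int, p: float, t_selection: float) -> float:
    """Information transfer rate in bits/min for one selection of K symbols
    at accuracy ``p`` taking ``t_selection`` seconds."""
    if t_selection <= 0:
        raise ValueError(f"selection time must be positive, got {t_selection}")
    return 60.0 * wolpaw_bits(K, p) / t_selection


@dataclass(frozen=True)
class ThresholdCurve:
    grid: np.ndarray
    accuracy: np.ndarray
    itr: np.ndarray
    mean_M: np.ndarray
    chosen: float


def default_theta_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 0.9501, 0.05), 2)


def select_threshold(
    recording: EegRecording,
    model: BldaModel,
    timing: SessionTiming,
    grid: np.ndarray | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    decimation: int = DEFAULT_DECIMATION,
) -> ThresholdCurve:
    """Sweep theta0 over ``grid`` on held-out data; pick the smallest theta0
    whose accuracy first reaches the maximum over the grid."""
    grid = default_theta_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty theta0 grid")
    if np.any(np.diff(grid) < 0):
        raise ValueError("theta0 grid must be sorted ascending")
    acc, itr, mm = [], [], []
    for theta0 in grid:
        rep = simulate_online(recording, model, float(theta0), timing,
                              band=band, decimation=decimation)
        acc.append(rep.accuracy)
        itr.append(itr_bits_per_min(timing.n_keys, rep.accuracy, rep.mean_selection_s))
        mm.append(rep.mean_M)
    acc = np.array(acc)
    chosen = float(grid[int(np.argmax(acc))])   # argmax returns the first max
    return ThresholdCurve(
        grid=grid, accuracy=acc, itr=np.array(itr), mean_M=np.array(mm), chosen=chosen
    )
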