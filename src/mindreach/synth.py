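"""Session timing, flash scheduling, synthetic P300 EEG and recording I/O.

A *round* is one flash of every speller key; a *trial* is the selection of a
single key (``M`` rounds); a *session* is ``N`` trials.  The synthetic
generator emulates a 4-key oddball paradigm: every key flashes once per
round in random order, and only flashes of the attended (target) key carry
an event-related positive deflection on top of the background noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_CHANNELS",
    "PARIETO_OCCIPITAL",
    "SessionTiming",
    "SyntheticSessionSpec",
    "FlashEvent",
    "EegRecording",
    "make_flash_schedule",
    "p300_template",
    "default_topography",
    "synthesize_recording",
    "write_recording",
    "read_recording",
]

#: 30-channel scalp montage (10-20 labels), biased toward parieto-occipital
#: sites where the decoded deflection is strongest.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "FZ", "F4", "F8",
    "FT7", "FC3", "FCZ", "FC4", "FT8",
    "T7", "C3", "CZ", "C4", "T8",
    "TP7", "CP3", "CPZ", "CP4", "TP8",
    "P7", "P3", "PZ", "P4", "P8",
    "O1", "OZ", "O2",
)

#: Channels that receive full weight in the default response topography.
PARIETO_OCCIPITAL: frozenset[str] = frozenset(
    {"P7", "P3", "PZ", "P4", "P8", "O1", "OZ", "O2", "CP3", "CPZ", "CP4"}
)


class ConfigurationError(ValueError):
    """Raised when timing or generator parameters violate their invariants."""


@dataclass(frozen=True)
class SessionTiming:
    """Timing constants of one speller session.

    Defaults follow the hardware-free reference configuration: 4 keys,
    1.2 s rounds, 200 ms inter-stimulus interval, 100 ms stimulus,
    600 ms analysis epochs at 250 Hz, adaptive round bounds 3..8.
    """

    fs: float = 250.0
    n_keys: int = 4
    t_round: float = 1.2
    isi: float = 0.2
    stimulus: float = 0.1
    t_epoch: float = 0.6
    rounds_per_trial_training: int = 10
    m_min: int = 3
    m_max: int = 8

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        if self.n_keys < 2:
            raise ConfigurationError(f"need at least 2 keys, got {self.n_keys}")
        if self.isi * self.n_keys > self.t_round + 1e-12:
            raise ConfigurationError(
                f"isi*n_keys = {self.isi * self.n_keys:g} exceeds t_round = {self.t_round:g}"
            )
        if not (self.stimulus <= self.isi <= self.t_epoch <= self.t_round):
            raise ConfigurationError(
                "require stimulus <= isi <= t_epoch <= t_round, got "
                f"{self.stimulus:g}, {self.isi:g}, {self.t_epoch:g}, {self.t_round:g}"
            )
        if self.m_min > self.m_max:
            raise ConfigurationError(f"m_min {self.m_min} > m_max {self.m_max}")

    @property
    def epoch_samples(self) -> int:
        """Samples per analysis epoch (150 at 250 Hz / 600 ms)."""
        return int(round(self.t_epoch * self.fs))

    @property
    def round_samples(self) -> int:
        return int(round(self.t_round * self.fs))

    @property
    def isi_samples(self) -> int:
        return int(round(self.isi * self.fs))


@dataclass(frozen=True)
class SyntheticSessionSpec:
    """Parameters of the synthetic oddball EEG generator."""

    n_trials: int = 40
    rounds_per_trial: int = 10
    p300_amplitude: float = 5.0           # microvolt peak of the target bump
    p300_latency: float = 0.3             # s after flash onset
    latency_jitter_sd: float = 0.0        # s
    noise_sd: float = 2.0                 # microvolt
    noise_model: str = "ar1"              # white | ar1 | pink
    channel_topography: np.ndarray | None = None
    inter_trial_gap: float = 1.0          # s of silence between trials
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.rounds_per_trial < 1:
            raise ConfigurationError("n_trials and rounds_per_trial must be >= 1")
        if self.p300_amplitude < 0 or self.noise_sd < 0 or self.latency_jitter_sd < 0:
            raise ConfigurationError("amplitudes and standard deviations must be >= 0")
        if self.noise_model not in ("white", "ar1", "pink"):
            raise ConfigurationError(f"unknown noise_model {self.noise_model!r}")
        if self.channel_topography is not None:
            topo = np.asarray(self.channel_topography, dtype=float)
            if not np.all(np.isfinite(topo)):
                raise ConfigurationError("channel topography must be finite")
            object.__setattr__(self, "channel_topography", topo)


@dataclass(frozen=True)
class FlashEvent:
    """One key flash: sample index of onset plus schedule provenance."""

    onset_sample: int
    key_id: int           # 1-based key id
    round_index: int      # 0-based within the trial
    trial_index: int      # 0-based within the session


@dataclass
class EegRecording:
    """Continuous multichannel recording with flash-event annotations."""

    data: np.ndarray                      # channels x samples, microvolt
    fs: float
    channel_names: tuple[str, ...]
    events: list[FlashEvent]
    targets: np.ndarray                   # per-trial intended key id, 1-based

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        self.targets = np.asarray(self.targets, dtype=int)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return len(self.targets)

    def validate_events(self, timing: SessionTiming) -> None:
        """Check schedule invariants: per-(trial, round) key multiset and
        epoch windows contained in the data."""
        n_epoch = timing.epoch_samples
        seen: dict[tuple[int, int], list[int]] = {}
        last = -1
        for ev in self.events:
            if ev.onset_sample <= last:
                raise ValueError("event onsets must be strictly increasing")
            last = ev.onset_sample
            if ev.onset_sample + n_epoch > self.n_samples:
                raise ValueError(
                    f"epoch of event at sample {ev.onset_sample} "
                    f"(trial {ev.trial_index}, key {ev.key_id}) overruns the data"
                )
            seen.setdefault((ev.trial_index, ev.round_index), []).append(ev.key_id)
        for (trial, rnd), keys in seen.items():
            if sorted(keys) != list(range(1, timing.n_keys + 1)):
                raise ValueError(
                    f"trial {trial} round {rnd} keys {sorted(keys)} are not a "
                    f"permutation of 1..{timing.n_keys}"
                )


def make_flash_schedule(
    timing: SessionTiming,
    n_trials: int,
    rounds: int,
    seed: int | np.random.Generator = 0,
    inter_trial_gap: float = 1.0,
    lead_in: float = 1.0,
) -> list[FlashEvent]:
    """Random flash schedule: every key once per round, rounds back to back.

    Round ``r`` of a trial starts ``r * t_round`` seconds into the trial;
    flashes within a round are ``isi`` seconds apart in a fresh random key
    order.  Trials are separated by ``inter_trial_gap`` seconds of silence.
    """
    if n_trials < 1 or rounds < 1:
        raise ConfigurationError("n_trials and rounds must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events: list[FlashEvent] = []
    trial_span = rounds * timing.t_round
    for trial in range(n_trials):
        t0 = lead_in + trial * (trial_span + inter_trial_gap)
        for rnd in range(rounds):
            order = rng.permutation(timing.n_keys) + 1
            for pos, key in enumerate(order):
                onset = t0 + rnd * timing.t_round + pos * timing.isi
                events.append(
                    FlashEvent(
                        onset_sample=int(round(onset * timing.fs)),
                        key_id=int(key),
                        round_index=rnd,
                        trial_index=trial,
                    )
                )
    return events


def p300_template(timing: SessionTiming, latency: float, amplitude: float) -> np.ndarray:
    """Positive half-cosine bump of 200 ms width peaking at ``latency``.

    Returned as one epoch worth of samples (zero outside the bump).
    """
    t = np.arange(timing.epoch_samples) / timing.fs
    width = 0.2
    tpl = np.where(
        np.abs(t - latency) <= width / 2.0,
        amplitude * np.cos(np.pi * (t - latency) / width),
        0.0,
    )
    return tpl


def default_topography(channel_names: Sequence[str]) -> np.ndarray:
    """Weight 1.0 on parieto-occipital channels, 0.3 elsewhere."""
    return np.array(
        [1.0 if name in PARIETO_OCCIPITAL else 0.3 for name in channel_names]
    )


def _noise(
    rng: np.random.Generator, model: str, sd: float, shape: tuple[int, int]
) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(shape)
    if model == "white":
        return rng.normal(0.0, sd, shape)
    if model == "ar1":
        # AR(1) with coefficient .95 plus an equal-power white floor,
        # rescaled so the marginal sd is the requested one.
        phi = 0.95
        w = rng.normal(0.0, 1.0, shape)
        from scipy.signal import lfilter

        ar = lfilter([1.0], [1.0, -phi], w, axis=1)
        mix = ar / np.sqrt(1.0 / (1.0 - phi**2)) + rng.normal(0.0, 1.0, shape)
        return mix * (sd / np.sqrt(2.0))
    if model == "pink":
        n = shape[1]
        spec = np.fft.rfft(rng.normal(0.0, 1.0, shape), axis=1)
        freqs = np.fft.rfftfreq(n, d=1.0)
        scale = np.ones_like(freqs)
        scale[1:] = 1.0 / np.sqrt(freqs[1:])
        pink = np.fft.irfft(spec * scale, n=n, axis=1)
        pink /= pink.std(axis=1, keepdims=True)
        return pink * sd
    raise ConfigurationError(f"unknown noise model {model!r}")


def synthesize_recording(
    spec: SyntheticSessionSpec,
    timing: SessionTiming = SessionTiming(),
    channel_names: Sequence[str] = DEFAULT_CHANNELS,
    targets: Sequence[int] | None = None,
) -> EegRecording:
    """Render a full synthetic session.

    Target-flash epochs carry the topography-weighted template on top of the
    background noise; non-target flashes add nothing.  Fully reproducible
    from ``spec.seed``.  Per-trial target keys are drawn uniformly unless
    ``targets`` supplies them.
    """
    rng = np.random.default_rng(spec.seed)
    events = make_flash_schedule(
        timing,
        spec.n_trials,
        spec.rounds_per_trial,
        seed=rng,
        inter_trial_gap=spec.inter_trial_gap,
    )
    if targets is None:
        targets = rng.integers(1, timing.n_keys + 1, size=spec.n_trials)
    else:
        targets = np.asarray(targets, dtype=int)
        if targets.shape != (spec.n_trials,):
            raise ConfigurationError(
                f"expected {spec.n_trials} targets, got shape {targets.shape}"
            )
        if targets.min() < 1 or targets.max() > timing.n_keys:
            raise ConfigurationError("targets must be key ids in 1..n_keys")

    trial_span = spec.rounds_per_trial * timing.t_round + spec.inter_trial_gap
    total_s = 1.0 + spec.n_trials * trial_span + 1.0
    n_samples = int(round(total_s * timing.fs))
    n_channels = len(channel_names)

    data = _noise(rng, spec.noise_model, spec.noise_sd, (n_channels, n_samples))

    topo = spec.channel_topography
    if topo is None:
        topo = default_topography(channel_names)
    topo = np.asarray(topo, dtype=float)
    if topo.shape != (n_channels,):
        raise ConfigurationError(
            f"topography length {topo.shape} does not match {n_channels} channels"
        )

    for ev in events:
        if ev.key_id != targets[ev.trial_index]:
            continue
        latency = spec.p300_latency
        if spec.latency_jitter_sd > 0:
            latency += rng.normal(0.0, spec.latency_jitter_sd)
        tpl = p300_template(timing, latency, spec.p300_amplitude)
        sl = slice(ev.onset_sample, ev.onset_sample + tpl.size)
        data[:, sl] += topo[:, None] * tpl[None, :]

    rec = EegRecording(
        data=data,
        fs=timing.fs,
        channel_names=tuple(channel_names),
        events=events,
        targets=targets,
    )
    rec.validate_events(timing)
    return rec


# ---------------------------------------------------------------------------
# File I/O: delimited signal matrix + TSV event sidecar (diff-able, text only)
# ---------------------------------------------------------------------------

def _paths(base: str | Path) -> tuple[Path, Path]:
    base = Path(base)
    if base.suffix == ".tsv":
        base = base.with_suffix("")
    return base.with_suffix(".data.tsv"), base.with_suffix(".events.tsv")


def write_recording(rec: EegRecording, base: str | Path) -> tuple[Path, Path]:
    """Write ``<base>.data.tsv`` (header ``# fs=..``, channel-name row, one
    row per channel) and ``<base>.events.tsv``.  Floats are written with
    17 significant digits so the round trip is bit-exact."""
    data_path, event_path = _paths(base)
    data_path.parent.mkdir(parents=True, exist_ok=True)
    with open(data_path, "w") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write("\t".join(rec.channel_names) + "\n")
        np.savetxt(fh, rec.data, fmt="%.17g", delimiter="\t")
    with open(event_path, "w") as fh:
        fh.write("onset_sample\tkey_id\tround\ttrial\tis_target\n")
        for ev in rec.events:
            is_t = int(ev.key_id == rec.targets[ev.trial_index])
            fh.write(
                f"{ev.onset_sample}\t{ev.key_id}\t{ev.round_index}\t{ev.trial_index}\t{is_t}\n"
            )
    return data_path, event_path


class RecordingParseError(ValueError):
    """Raised when a recording file fails to parse; names the offender."""


def read_recording(base: str | Path) -> EegRecording:
    data_path, event_path = _paths(base)
    if not data_path.exists():
        raise RecordingParseError(f"missing signal file {data_path}")
    if not event_path.exists():
        raise RecordingParseError(f"missing event sidecar {event_path}")

    with open(data_path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs="):
            raise RecordingParseError(f"{data_path}:1: expected '# fs=' header")
        fs = float(header[len("# fs="):])
        channel_names = tuple(fh.readline().strip().split("\t"))
        try:
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise RecordingParseError(f"{data_path}: bad signal matrix: {exc}") from exc
    if data.shape[0] != len(channel_names):
        raise RecordingParseError(
            f"{data_path}: {data.shape[0]} signal rows but {len(channel_names)} channel names"
        )

    events: list[FlashEvent] = []
    target_of: dict[int, int] = {}
    with open(event_path) as fh:
        head = fh.readline().strip().split("\t")
        expected = ["onset_sample", "key_id", "round", "trial", "is_target"]
        if head != expected:
            raise RecordingParseError(f"{event_path}:1: expected columns {expected}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise RecordingParseError(
                    f"{event_path}:{lineno}: expected 5 fields, got {len(parts)}"
                )
            try:
                onset, key, rnd, trial, is_t = (int(p) for p in parts)
            except ValueError as exc:
                raise RecordingParseError(
                    f"{event_path}:{lineno}: non-integer field: {exc}"
                ) from exc
            events.append(FlashEvent(onset, key, rnd, trial))
            if is_t:
                prev = target_of.get(trial)
                if prev is not None and prev != key:
                    raise RecordingParseError(
                        f"{event_path}:{lineno}: trial {trial} has conflicting targets"
                    )
                target_of[trial] = key

    n_trials = max((ev.trial_index for ev in events), default=-1) + 1
    missing = [t for t in range(n_trials) if t not in target_of]
    if missing:
        raise RecordingParseError(
            f"{event_path}: trials {missing} have no target-flagged event"
        )
    targets = np.array([target_of[t] for t in range(n_trials)], dtype=int)
    return EegRecording(
        data=data, fs=fs, channel_names=channel_names, events=events, targets=targets
    )
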