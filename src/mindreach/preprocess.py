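"""Bandpass filtering, epoch extraction, decimation and feature assembly.

The online pipeline is: 0.1-20 Hz causal bandpass -> 600 ms epochs at flash
onsets -> keep every 6th sample -> concatenate channels (channel-major) into
one feature vector of P = n_channels * n_kept entries.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfilt

from .synth import ConfigurationError, EegRecording, SessionTiming

__all__ = [
    "Epoch",
    "FeatureVector",
    "bandpass",
    "extract_epochs",
    "decimate",
    "featurize",
    "average_rounds",
    "preprocess_session",
]

DEFAULT_BAND = (0.1, 20.0)
DEFAULT_DECIMATION = 6


@dataclass(frozen=True)
class Epoch:
    """One post-onset analysis window (channels x samples)."""

    data: np.ndarray
    key_id: int
    round_index: int
    trial_index: int
    is_target: bool | None = None

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class FeatureVector:
    """Flattened epoch with schedule provenance."""

    x: np.ndarray
    key_id: int
    round_index: int
    trial_index: int
    is_target: bool | None = None


def bandpass(
    recording: EegRecording,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
) -> EegRecording:
    """Causal Butterworth bandpass applied per channel (forward only, as an
    online loop would).  Second-order sections keep the near-unit-circle
    0.1 Hz poles numerically clean."""
    nyq = recording.fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ConfigurationError(
            f"band ({low:g}, {high:g}) Hz invalid for Nyquist {nyq:g} Hz"
        )
    sos = butter(order, [low, high], btype="band", fs=recording.fs, output="sos")
    filtered = sosfilt(sos, recording.data, axis=1)
    return dataclasses.replace(
        recording,
        data=filtered,
        events=list(recording.events),
        targets=recording.targets.copy(),
    )


def extract_epochs(recording: EegRecording, timing: SessionTiming) -> list[Epoch]:
    """One epoch per flash event, ``t_epoch`` from its onset.

    Epochs may overlap (the ISI is shorter than the epoch).  Targets from
    the recording, when present, populate the ``is_target`` flag.
    """
    n = timing.epoch_samples
    epochs: list[Epoch] = []
    for ev in recording.events:
        stop = ev.onset_sample + n
        if stop > recording.n_samples:
            raise ValueError(
                f"epoch of event at sample {ev.onset_sample} (trial "
                f"{ev.trial_index}, round {ev.round_index}, key {ev.key_id}) "
                f"overruns the recording ({recording.n_samples} samples)"
            )
        is_target = None
        if recording.targets.size > ev.trial_index:
            is_target = bool(ev.key_id == recording.targets[ev.trial_index])
        epochs.append(
            Epoch(
                data=recording.data[:, ev.onset_sample:stop].copy(),
                key_id=ev.key_id,
                round_index=ev.round_index,
                trial_index=ev.trial_index,
                is_target=is_target,
            )
        )
    return epochs


def decimate(epoch: Epoch, step: int = DEFAULT_DECIMATION) -> Epoch:
    """Keep samples 0, step, 2*step, ... of each channel.

    Plain subsampling, no extra anti-alias filter: the 0.1-20 Hz bandpass
    already limits content below the decimated Nyquist (~20.8 Hz at 250/6).
    """
    if step < 1:
        raise ConfigurationError(f"decimation step must be >= 1, got {step}")
    return dataclasses.replace(epoch, data=epoch.data[:, ::step])


def featurize(epoch: Epoch) -> FeatureVector:
    """Channel-major concatenation of a (decimated) epoch."""
    return FeatureVector(
        x=epoch.data.reshape(-1).copy(),
        key_id=epoch.key_id,
        round_index=epoch.round_index,
        trial_index=epoch.trial_index,
        is_target=epoch.is_target,
    )


def average_rounds(features: list[FeatureVector]) -> FeatureVector:
    """Elementwise mean of one key's feature vectors over rounds 1..M."""
    if not features:
        raise ValueError("cannot average an empty feature list")
    lengths = {f.x.size for f in features}
    if len(lengths) != 1:
        raise ValueError(f"feature lengths differ: {sorted(lengths)}")
    mean = np.mean([f.x for f in features], axis=0)
    last = features[-1]
    return dataclasses.replace(last, x=mean)


def preprocess_session(
    recording: EegRecording,
    timing: SessionTiming,
    band: tuple[float, float] = DEFAULT_BAND,
    step: int = DEFAULT_DECIMATION,
) -> list[FeatureVector]:
    """Full offline pass: filter, epoch, decimate, featurize every flash."""
    filtered = bandpass(recording, band[0], band[1])
    return [
        featurize(decimate(ep, step)) for ep in extract_epochs(filtered, timing)
    ]
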