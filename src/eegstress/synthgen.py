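"""Synthetic DEAP-shaped EEG generator with a planted stress effect.

Each trial is a sum of five band-limited oscillatory components (delta,
theta, alpha, beta, gamma) whose amplitudes depend on the trial's class:
stressed trials carry elevated beta/gamma power and suppressed alpha power,
the classic frontal correlate of mental stress.  White Gaussian noise and
occasional single-sample spike artifacts are added so the de-noising stage
has something measurable to remove.  Self-assessment labels follow the
valence-arousal convention: stressed trials draw low valence, unstressed
trials high valence, and arousal is uninformative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .deap_io import (
    Recording,
    default_channel_names,
    write_labels_csv,
    write_participant,
    write_participant_mat,
)
from .errors import ConfigurationError

#: Nominal band edges in Hz used by the generator.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

# Component RMS amplitudes (arbitrary µV-like units).  Stressed trials:
# beta/gamma elevated, alpha suppressed; slow bands identical across classes.
DEFAULT_STRESSED_POWERS: dict[str, float] = {
    "delta": 18.0, "theta": 14.0, "alpha": 10.0, "beta": 16.0, "gamma": 8.0,
}
DEFAULT_UNSTRESSED_POWERS: dict[str, float] = {
    "delta": 18.0, "theta": 14.0, "alpha": 20.0, "beta": 7.0, "gamma": 3.0,
}

#: Amplitude of an isolated spike artifact, well above any band component.
SPIKE_AMPLITUDE = 150.0


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults reproduce the DEAP dimensions
    (32 participants x 40 trials x 40 channels x 8064 samples at 128 Hz)."""

    n_participants: int = 32
    n_trials: int = 40
    n_channels: int = 40
    n_samples: int = 8064
    sampling_rate: float = 128.0
    band_powers_stressed: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRESSED_POWERS)
    )
    band_powers_unstressed: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UNSTRESSED_POWERS)
    )
    noise_sd: float = 4.0
    artifact_rate: float = 0.5  # expected spikes per channel per trial
    stressed_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_participants", "n_trials", "n_channels", "n_samples"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 <= self.stressed_fraction <= 1.0:
            raise ConfigurationError("stressed_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.artifact_rate < 0:
            raise ConfigurationError(
                "noise_sd and artifact_rate must be non-negative"
            )
        top = max(hi for _, hi in BAND_EDGES.values())
        if self.sampling_rate <= 2.0 * top:
            raise ConfigurationError(
                f"sampling_rate must exceed twice the top band frequency "
                f"({2 * top:g} Hz)"
            )
        for powers in (self.band_powers_stressed, self.band_powers_unstressed):
            missing = set(BAND_EDGES) - set(powers)
            if missing:
                raise ConfigurationError(
                    f"band power map missing bands: {sorted(missing)}"
                )


def _stressed_mask(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministically-rounded stressed/unstressed trial assignment."""
    n_stressed = int(round(config.stressed_fraction * config.n_trials))
    mask = np.zeros(config.n_trials, dtype=bool)
    mask[rng.permutation(config.n_trials)[:n_stressed]] = True
    return mask


def _trial_signal(
    config: SynthConfig, stressed: bool, rng: np.random.Generator
) -> np.ndarray:
    """One trial of shape (n_channels, n_samples)."""
    powers = (
        config.band_powers_stressed
        if stressed
        else config.band_powers_unstressed
    )
    t = np.arange(config.n_samples) / config.sampling_rate
    x = rng.normal(0.0, config.noise_sd, (config.n_channels, config.n_samples))
    for band, (lo, hi) in BAND_EDGES.items():
        amp = powers[band]
        freq = rng.uniform(lo, hi, (config.n_channels, 1))
        phase = rng.uniform(0.0, 2.0 * np.pi, (config.n_channels, 1))
        jitter = rng.uniform(0.8, 1.2, (config.n_channels, 1))
        # RMS of a sinusoid is amp/sqrt(2); scale so component RMS == amp
        x += amp * jitter * np.sqrt(2.0) * np.sin(
            2.0 * np.pi * freq * t + phase
        )
    n_spikes = rng.poisson(config.artifact_rate, config.n_channels)
    for ch, k in enumerate(n_spikes):
        if k:
            pos = rng.integers(0, config.n_samples, k)
            sign = rng.choice((-1.0, 1.0), k)
            x[ch, pos] += sign * SPIKE_AMPLITUDE
    return x.astype(np.float32)


def _participant(
    config: SynthConfig, participant_id: str, seed_seq: np.random.SeedSequence
) -> Recording:
    rng = np.random.default_rng(seed_seq)
    stressed = _stressed_mask(config, rng)
    data = np.empty(
        (config.n_trials, config.n_channels, config.n_samples),
        dtype=np.float32,
    )
    labels = np.empty((config.n_trials, 4))
    for trial in range(config.n_trials):
        data[trial] = _trial_signal(config, stressed[trial], rng)
        if stressed[trial]:
            valence = rng.uniform(1.0, 4.5)
        else:
            valence = rng.uniform(5.5, 9.0)
        labels[trial] = (valence, *rng.uniform(1.0, 9.0, 3))
    return Recording(
        participant_id=participant_id,
        data=data,
        labels=labels,
        sampling_rate=config.sampling_rate,
        channel_names=default_channel_names(config.n_channels),
    )


def iter_recordings(config: SynthConfig | None = None) -> Iterator[Recording]:
    """Yield one synthetic :class:`Recording` per participant.

    Each participant draws from an independent child stream of
    ``config.seed``, so streaming and materializing give identical output,
    and identical seeds give bitwise-identical datasets.
    """
    config = config or SynthConfig()
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    for i, child in enumerate(children):
        yield _participant(config, f"s{i + 1:02d}", child)


def generate_dataset(config: SynthConfig | None = None) -> list[Recording]:
    """Materialize the whole synthetic dataset (one Recording per
    participant).  For DEAP-scale configs prefer :func:`iter_recordings`,
    which streams participants instead of holding ~6 GB in memory."""
    return list(iter_recordings(config))


def write_dataset(
    config: SynthConfig | None = None,
    out_dir: str | Path = ".",
    container: str = "npz",
) -> list[Path]:
    """Write the synthetic dataset to disk in the layout ``deap_io`` reads.

    ``container`` selects ``"npz"`` (compressed numeric container, with a
    CSV label sidecar) or ``"mat"`` (MATLAB-style matrix container).
    """
    if container not in ("npz", "mat"):
        raise ConfigurationError(f"unknown container {container!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in iter_recordings(config):
        if container == "npz":
            path = write_participant(rec, out_dir / f"{rec.participant_id}.npz")
            write_labels_csv(rec, out_dir / f"{rec.participant_id}_labels.csv")
        else:
            path = write_participant_mat(
                rec, out_dir / f"{rec.participant_id}.mat"
            )
        paths.append(path)
    return paths
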