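"""Per-band feature extraction and feature-matrix assembly.

Fifteen features per sub-band: ten time-domain statistics (variance,
standard deviation, minimum, maximum, mean, RMS, skewness, kurtosis,
median, histogram mode) and five frequency-domain quantities (energy,
log-energy entropy, Shannon entropy, mean power spectral density, absolute
power).  With five sub-bands this gives the 75-column multidomain feature
matrix, one row per (participant, trial, channel), with a binary stress
label derived from the trial's valence rating.

Conventions: variance/std use the N-1 denominator; skewness and kurtosis
are standardized central moments (kurtosis plain, Gaussian -> 3), defined
as 0 when the signal is constant; the entropies act on the squared samples
normalized to sum 1 with the 0*log(0) := 0 convention; the mode is the
midpoint of the most populated bin of a 64-bin fixed-width histogram.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .deap_io import Recording
from .errors import ConsistencyError, DomainError
from .label import to_stress_label
from .wavelet import (
    WaveletConfig,
    decompose,
    denoise_decomposition,
    extract_subbands,
)

TIME_FEATURES: tuple[str, ...] = (
    "variance", "std", "min", "max", "mean", "rms",
    "skewness", "kurtosis", "median", "mode",
)
FREQ_FEATURES: tuple[str, ...] = (
    "energy", "log_energy_entropy", "shannon_entropy", "psd",
    "absolute_power",
)
FEATURE_NAMES: tuple[str, ...] = TIME_FEATURES + FREQ_FEATURES

KEY_COLUMNS: tuple[str, ...] = ("participant", "trial", "channel", "label")

MODE_BINS = 64


def _histogram_mode(x: np.ndarray, bins: int = MODE_BINS) -> np.ndarray:
    """Midpoint of the most populated fixed-width bin, along the last axis."""
    x2 = x.reshape(-1, x.shape[-1])
    n_rows = x2.shape[0]
    lo = x2.min(axis=1)
    hi = x2.max(axis=1)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    idx = ((x2 - lo[:, None]) / safe[:, None] * bins).astype(np.intp)
    np.clip(idx, 0, bins - 1, out=idx)  # right edge falls in the last bin
    idx += (np.arange(n_rows) * bins)[:, None]
    counts = np.bincount(idx.ravel(), minlength=n_rows * bins)
    j = counts.reshape(n_rows, bins).argmax(axis=1)  # ties -> lowest bin
    out = np.where(span > 0, lo + (j + 0.5) * span / bins, lo)
    return out.reshape(x.shape[:-1])


def compute_features(band_signal: np.ndarray) -> dict[str, np.ndarray]:
    """The 15 features of one band signal, computed along the last axis.

    Accepts a 1-D signal (returns scalars) or a stack of signals.
    """
    x = np.asarray(band_signal, dtype=float)
    n = x.shape[-1]
    if n < 2:
        raise DomainError("need at least 2 samples (variance undefined)")

    mu = x.mean(axis=-1)
    xc = x - mu[..., None]
    xc2 = xc * xc
    m2 = xc2.mean(axis=-1)
    m3 = (xc2 * xc).mean(axis=-1)
    m4 = (xc2 * xc2).mean(axis=-1)
    nonconst = m2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        skewness = np.where(nonconst, m3 / np.where(nonconst, m2, 1) ** 1.5, 0.0)
        kurtosis = np.where(nonconst, m4 / np.where(nonconst, m2, 1) ** 2, 0.0)

    sq = x**2
    energy = sq.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = sq / np.where(energy > 0, energy, 1.0)[..., None]
    pos = p > 0
    logp = np.where(pos, np.log(np.where(pos, p, 1.0)), 0.0)
    shannon = np.where(energy > 0, -(p * logp).sum(axis=-1), 0.0)
    log_energy = np.where(energy > 0, logp.sum(axis=-1), 0.0)

    # one-sided periodogram |DFT|^2 / N, summarized by its mean
    psd = (np.abs(np.fft.rfft(x, axis=-1)) ** 2 / n).mean(axis=-1)

    return {
        "variance": x.var(axis=-1, ddof=1),
        "std": x.std(axis=-1, ddof=1),
        "min": x.min(axis=-1),
        "max": x.max(axis=-1),
        "mean": mu,
        "rms": np.sqrt(np.mean(sq, axis=-1)),
        "skewness": skewness,
        "kurtosis": kurtosis,
        "median": np.median(x, axis=-1),
        "mode": _histogram_mode(x),
        "energy": energy,
        "log_energy_entropy": log_energy,
        "shannon_entropy": shannon,
        "psd": psd,
        "absolute_power": energy / n,
    }


def feature_column_names(band_map_order: Iterable[str]) -> list[str]:
    """Band-major column names, feature order fixed within each band."""
    return [
        f"{band}_{feat}" for band in band_map_order for feat in FEATURE_NAMES
    ]


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """All non-key columns of a feature matrix."""
    return [c for c in matrix.columns if c not in KEY_COLUMNS]


def build_feature_matrix(
    recordings: Iterable[Recording],
    wavelet_config: WaveletConfig | None = None,
    label_threshold: float = 5.0,
    denoise: bool = True,
    trials: int | None = None,
) -> pd.DataFrame:
    """Assemble the multidomain feature matrix from recordings.

    One row per (participant, trial, channel); columns are the per-band
    features after de-noising and sub-band extraction, plus the key columns
    and the binary stress label.  ``trials`` restricts each recording to
    its first ``trials`` trials.  Recordings may be a generator; they are
    consumed one at a time so full DEAP-scale datasets can be streamed.
    """
    cfg = wavelet_config or WaveletConfig()
    bands = list(cfg.band_map)
    columns = feature_column_names(bands)

    frames: list[pd.DataFrame] = []
    sampling_rate: float | None = None
    channel_names: tuple[str, ...] | None = None
    for rec in recordings:
        if sampling_rate is None:
            sampling_rate, channel_names = rec.sampling_rate, rec.channel_names
        elif (
            rec.sampling_rate != sampling_rate
            or rec.channel_names != channel_names
        ):
            raise ConsistencyError(
                "recordings disagree on sampling rate or channel set"
            )
        n_trials = rec.n_trials if trials is None else min(trials, rec.n_trials)
        blocks = np.empty((n_trials * rec.n_channels, len(columns)))
        labels = np.empty(n_trials * rec.n_channels, dtype=int)
        for t in range(n_trials):
            decomp = decompose(rec.data[t].astype(float), cfg)
            if denoise:
                decomp = denoise_decomposition(decomp)
            subbands = extract_subbands(decomp)
            per_band = {b: compute_features(subbands[b]) for b in bands}
            row = np.column_stack(
                [per_band[b][f] for b in bands for f in FEATURE_NAMES]
            )
            sl = slice(t * rec.n_channels, (t + 1) * rec.n_channels)
            blocks[sl] = row
            labels[sl] = to_stress_label(
                rec.labels[t, 0], rec.labels[t, 1], threshold=label_threshold
            )
        frame = pd.DataFrame(blocks, columns=columns)
        frame.insert(0, "participant", rec.participant_id)
        frame.insert(
            1, "trial", np.repeat(np.arange(n_trials), rec.n_channels)
        )
        frame.insert(2, "channel", list(rec.channel_names) * n_trials)
        frame.insert(3, "label", labels)
        frames.append(frame)
    if not frames:
        raise ConsistencyError("no recordings supplied")
    return pd.concat(frames, ignore_index=True)
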