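"""Discrete wavelet transform de-noising and sub-band extraction.

The de-noising chain is the classic wavelet shrinkage recipe: multilevel
DWT with a Daubechies-8 mother wavelet (8 levels by default), the universal
threshold ``sqrt(2 ln n)`` applied to each detail level with soft
thresholding, and inverse reconstruction.  Sub-band signals (delta..gamma)
are reconstructed from individual coefficient sets of the same
decomposition.

Two band maps are shipped.  ``TABLE_BAND_MAP`` assigns CD5=gamma,
CD6=alpha, CD7=beta, CD8=theta, CA8=delta with the nominal Hz ranges often
quoted alongside it; at a 128 Hz sampling rate those level assignments are
not physically consistent with the quoted ranges (every mapped coefficient
set then covers only 0-4 Hz).  ``RATE128_BAND_MAP`` is the
sampling-rate-consistent alternative for 128 Hz data, built on the same
8-level transform: D1=gamma (32-64 Hz), D2=beta (16-32), D3=alpha (8-16),
D4=theta (4-8), and the union of D5..D8 and A8 as delta (0-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt

from .errors import ConfigurationError, DomainError, StateError

# band -> (coefficient keys, nominal Hz range); keys are "D<k>" or "A<L>"
BandMap = dict[str, tuple[tuple[str, ...], tuple[float, float]]]

TABLE_BAND_MAP: BandMap = {
    "gamma": (("D5",), (30.0, 60.0)),
    "alpha": (("D6",), (15.0, 30.0)),
    "beta": (("D7",), (8.0, 15.0)),
    "theta": (("D8",), (4.0, 8.0)),
    "delta": (("A8",), (0.0, 4.0)),
}

RATE128_BAND_MAP: BandMap = {
    "gamma": (("D1",), (32.0, 64.0)),
    "beta": (("D2",), (16.0, 32.0)),
    "alpha": (("D3",), (8.0, 16.0)),
    "theta": (("D4",), (4.0, 8.0)),
    "delta": (("D5", "D6", "D7", "D8", "A8"), (0.0, 4.0)),
}

#: Signal extension mode at the boundaries (deterministic, low edge
#: artifacts for EEG-length windows).
BOUNDARY_MODE = "symmetric"


@dataclass
class WaveletConfig:
    wavelet_name: str = "db8"
    levels: int = 8
    threshold_mode: str = "literal"  # or "sigma_scaled"
    band_map: BandMap = field(default_factory=lambda: dict(TABLE_BAND_MAP))

    def validate(self, n_samples: int | None = None) -> None:
        if self.levels < 1:
            raise ConfigurationError("levels must be >= 1")
        if self.threshold_mode not in ("literal", "sigma_scaled"):
            raise ConfigurationError(
                f"unknown threshold_mode {self.threshold_mode!r}"
            )
        if n_samples is not None:
            max_level = pywt.dwt_max_level(
                n_samples, pywt.Wavelet(self.wavelet_name).dec_len
            )
            if self.levels > max_level:
                raise ConfigurationError(
                    f"{self.levels}-level decomposition too deep for "
                    f"{n_samples} samples with {self.wavelet_name} "
                    f"(max {max_level})"
                )


@dataclass
class WaveletDecomposition:
    """Approximation CA_L plus detail sequences CD1..CD_L for one or more
    signals (decomposition runs along the last axis)."""

    approximation: np.ndarray
    details: list[np.ndarray]  # index 0 is CD1 (finest)
    config: WaveletConfig
    original_length: int

    @property
    def levels(self) -> int:
        return len(self.details)


def decompose(
    signal: np.ndarray, config: WaveletConfig | None = None
) -> WaveletDecomposition:
    """Multilevel DWT along the last axis of ``signal``."""
    config = config or WaveletConfig()
    signal = np.asarray(signal, dtype=float)
    config.validate(signal.shape[-1])
    coeffs = pywt.wavedec(
        signal,
        config.wavelet_name,
        mode=BOUNDARY_MODE,
        level=config.levels,
        axis=-1,
    )
    # pywt returns [cA_L, cD_L, ..., cD1]; store details finest-first
    return WaveletDecomposition(
        approximation=coeffs[0],
        details=coeffs[:0:-1],
        config=config,
        original_length=signal.shape[-1],
    )


def universal_threshold(n: float) -> float:
    """Universal shrinkage threshold ``sqrt(2 ln n)`` for ``n`` samples."""
    if n < 1:
        raise DomainError(f"sample count must be >= 1, got {n}")
    return float(np.sqrt(2.0 * np.log(n)))


def soft_threshold(
    decomp: WaveletDecomposition, t: float | np.ndarray
) -> WaveletDecomposition:
    """Shrink every detail coefficient by ``t``:
    ``x -> sign(x) * max(|x| - t, 0)``.  Approximation untouched."""
    if np.any(np.asarray(t) < 0):
        raise DomainError("threshold must be non-negative")
    details = [np.sign(d) * np.maximum(np.abs(d) - t, 0.0) for d in decomp.details]
    return replace(decomp, details=details)


def _noise_sigma(finest_detail: np.ndarray) -> np.ndarray:
    """Robust noise scale from the finest detail band: MAD / 0.6745."""
    return np.median(np.abs(finest_detail), axis=-1, keepdims=True) / 0.6745


def denoise_decomposition(decomp: WaveletDecomposition) -> WaveletDecomposition:
    """Per-level universal-threshold soft shrinkage of the details.

    Each level's threshold uses that level's own coefficient count.  In
    ``literal`` mode the threshold is exactly ``sqrt(2 ln n)``; in
    ``sigma_scaled`` mode it is multiplied by a median-absolute-deviation
    noise estimate of the finest detail band (per signal).
    """
    sigma = (
        _noise_sigma(decomp.details[0])
        if decomp.config.threshold_mode == "sigma_scaled"
        else 1.0
    )
    details = []
    for d in decomp.details:
        t = sigma * universal_threshold(d.shape[-1])
        details.append(np.sign(d) * np.maximum(np.abs(d) - t, 0.0))
    return replace(decomp, details=details)


def _coeff_list(decomp: WaveletDecomposition) -> list[np.ndarray]:
    return [decomp.approximation] + decomp.details[::-1]


def reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Inverse multilevel DWT, trimmed to the original signal length."""
    try:
        out = pywt.waverec(
            _coeff_list(decomp),
            decomp.config.wavelet_name,
            mode=BOUNDARY_MODE,
            axis=-1,
        )
    except ValueError as exc:
        raise StateError(f"inconsistent coefficient structure: {exc}") from exc
    return out[..., : decomp.original_length]


def denoise(
    signal: np.ndarray, config: WaveletConfig | None = None
) -> np.ndarray:
    """Decompose, soft-threshold the details, reconstruct."""
    return reconstruct(denoise_decomposition(decompose(signal, config)))


def _resolve_key(decomp: WaveletDecomposition, key: str) -> np.ndarray:
    kind, num = key[0].upper(), int(key[1:])
    if kind == "D":
        if not 1 <= num <= decomp.levels:
            raise ConfigurationError(
                f"band map references D{num} but decomposition has "
                f"{decomp.levels} levels"
            )
        return decomp.details[num - 1]
    if kind == "A":
        if num != decomp.levels:
            raise ConfigurationError(
                f"band map references A{num} but the approximation is "
                f"A{decomp.levels}"
            )
        return decomp.approximation
    raise ConfigurationError(f"unknown coefficient key {key!r}")


def extract_subbands(decomp: WaveletDecomposition) -> dict[str, np.ndarray]:
    """Reconstruct one time-domain signal per band of the config's band map.

    Each band keeps only its own coefficient set(s); all other coefficients
    are zeroed before inverse transformation.  By linearity of the inverse
    DWT the bands sum to the full reconstruction when the map covers every
    coefficient set exactly once.
    """
    bands: dict[str, np.ndarray] = {}
    for band, (keys, _hz) in decomp.config.band_map.items():
        if isinstance(keys, str):  # tolerate single-key shorthand
            keys = (keys,)
        keep = {k.upper() for k in keys}
        for k in keep:
            _resolve_key(decomp, k)  # validates
        approx = (
            decomp.approximation
            if f"A{decomp.levels}" in keep
            else np.zeros_like(decomp.approximation)
        )
        details = [
            d if f"D{i + 1}" in keep else np.zeros_like(d)
            for i, d in enumerate(decomp.details)
        ]
        bands[band] = reconstruct(
            replace(decomp, approximation=approx, details=details)
        )
    return bands
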