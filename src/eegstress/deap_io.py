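"""Reading and writing DEAP-style per-participant recordings.

A per-participant file holds a 3-D EEG array of shape
``trials x channels x samples`` and a per-trial self-assessment label array
(valence, arousal, dominance, liking, each on a 1-9 scale).  Both the
MATLAB-style ``.mat`` container used by the public DEAP distribution and
this package's own compressed ``.npz`` container are supported.  Channel
selection works by 10-20 electrode name against the canonical DEAP channel
ordering, so index-only files remain addressable by name.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import scipy.io

from .errors import ChannelLookupError, FormatError

#: Canonical 32-channel EEG ordering of the preprocessed DEAP distribution.
DEAP_EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: Peripheral (non-EEG) channels appended after the 32 EEG channels.
DEAP_PERIPHERAL_CHANNELS: tuple[str, ...] = (
    "hEOG", "vEOG", "zEMG", "tEMG", "GSR", "Respiration",
    "Plethysmograph", "Temperature",
)

#: The ten frontal channels used for stress analysis.
FRONTAL_CHANNELS: tuple[str, ...] = (
    "FC1", "FC2", "FC5", "FC6", "F3", "F4", "F7", "F8", "FP1", "FP2",
)

LABEL_NAMES: tuple[str, ...] = ("valence", "arousal", "dominance", "liking")


def default_channel_names(n_channels: int) -> tuple[str, ...]:
    """Standard DEAP channel names for the first ``n_channels`` channels.

    Channels beyond the 40 named DEAP channels get synthetic ``EXG{i}``
    names so arbitrary channel counts remain addressable.
    """
    names = DEAP_EEG_CHANNELS + DEAP_PERIPHERAL_CHANNELS
    if n_channels <= len(names):
        return names[:n_channels]
    extra = tuple(f"EXG{i}" for i in range(len(names) + 1, n_channels + 1))
    return names + extra


@dataclass(eq=False)
class Recording:
    """One participant's EEG session.

    data
        Array of shape ``(n_trials, n_channels, n_samples)``, trials-major.
    labels
        Array of shape ``(n_trials, 4)`` with per-trial
        (valence, arousal, dominance, liking) ratings on the 1-9 scale.
    """

    participant_id: str
    data: np.ndarray
    labels: np.ndarray
    sampling_rate: float = 128.0
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(
                f"data must be 3-D (trials x channels x samples), "
                f"got {self.data.ndim}-D"
            )
        if not self.channel_names:
            self.channel_names = default_channel_names(self.data.shape[1])
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        if self.labels.shape != (self.data.shape[0], 4):
            raise FormatError(
                f"labels must have shape ({self.data.shape[0]}, 4), "
                f"got {self.labels.shape}"
            )
        if self.labels.size and (
            self.labels.min() < 1.0 or self.labels.max() > 9.0
        ):
            raise FormatError("label values must lie in [1, 9]")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def equals(self, other: "Recording") -> bool:
        """Exact equality of content (for stored precision)."""
        return (
            self.participant_id == other.participant_id
            and self.sampling_rate == other.sampling_rate
            and self.channel_names == other.channel_names
            and np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
        )


def _normalize_labels(labels: np.ndarray, n_trials: int) -> np.ndarray:
    """Accept labels stored either trials x 4 or 4 x trials."""
    labels = np.asarray(labels)
    if labels.ndim != 2 or 4 not in labels.shape:
        raise FormatError(
            f"label array must be 2-D with a length-4 axis, got shape "
            f"{labels.shape}"
        )
    if labels.shape == (n_trials, 4):
        return labels
    if labels.shape == (4, n_trials):
        return labels.T
    raise FormatError(
        f"label array shape {labels.shape} does not match {n_trials} trials"
    )


def _find_arrays(container: dict) -> tuple[np.ndarray, np.ndarray]:
    keys = {k.lower(): k for k in container if not k.startswith("__")}
    if "data" not in keys:
        raise FormatError("file is missing a 'data' array")
    if "labels" not in keys:
        raise FormatError("file is missing a 'labels' array")
    return np.asarray(container[keys["data"]]), np.asarray(
        container[keys["labels"]]
    )


def read_participant(path: str | Path) -> Recording:
    """Read one participant's DEAP-style file (``.mat`` or ``.npz``).

    The label array is accepted in either ``4 x trials`` or ``trials x 4``
    orientation and normalized to per-trial rows.
    """
    path = Path(path)
    if path.suffix.lower() == ".mat":
        container = scipy.io.loadmat(path)
        sampling_rate = float(
            np.ravel(container.get("sampling_rate", 128.0))[0]
        )
        channel_names: tuple[str, ...] = ()
        participant_id = path.stem
    elif path.suffix.lower() == ".npz":
        with np.load(path, allow_pickle=False) as npz:
            container = {k: npz[k] for k in npz.files}
        sampling_rate = float(container.pop("sampling_rate", 128.0))
        raw_names = container.pop("channel_names", None)
        channel_names = (
            tuple(str(c) for c in raw_names) if raw_names is not None else ()
        )
        pid = container.pop("participant_id", None)
        participant_id = str(pid) if pid is not None else path.stem
    else:
        raise FormatError(f"unsupported container suffix: {path.suffix!r}")

    data, labels = _find_arrays(container)
    if data.ndim != 3:
        raise FormatError(f"data array must be 3-D, got {data.ndim}-D")
    labels = _normalize_labels(labels, data.shape[0])
    return Recording(
        participant_id=participant_id,
        data=data,
        labels=labels,
        sampling_rate=sampling_rate,
        channel_names=channel_names,
    )


def write_participant(rec: Recording, path: str | Path) -> Path:
    """Write a recording to the package's compressed ``.npz`` container."""
    path = Path(path)
    np.savez_compressed(
        path,
        data=rec.data,
        labels=rec.labels,
        sampling_rate=np.float64(rec.sampling_rate),
        channel_names=np.array(rec.channel_names),
        participant_id=np.str_(rec.participant_id),
    )
    # np.savez appends .npz when absent
    return path if path.suffix == ".npz" else path.with_suffix(
        path.suffix + ".npz"
    )


def write_participant_mat(rec: Recording, path: str | Path) -> Path:
    """Write a recording as a MATLAB-style ``.mat`` matrix container."""
    path = Path(path)
    scipy.io.savemat(
        path,
        {
            "data": rec.data,
            "labels": rec.labels,
            "sampling_rate": rec.sampling_rate,
        },
    )
    return path


def write_labels_csv(rec: Recording, path: str | Path) -> Path:
    """Write the per-trial self-assessment labels as a CSV sidecar."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("trial",) + LABEL_NAMES)
        for t, row in enumerate(rec.labels):
            writer.writerow([t] + [f"{v:.6g}" for v in row])
    return path


def select_channels(
    rec: Recording, names: tuple[str, ...] | list[str] | None = None
) -> Recording:
    """Restrict a recording to the requested channels, in requested order.

    ``names`` defaults to the ten frontal channels
    (FC1, FC2, FC5, FC6, F3, F4, F7, F8, FP1, FP2).  Lookup is
    case-insensitive (the 10-20 names appear in mixed capitalization in the
    wild).  Trials and samples are never reordered.
    """
    if names is None:
        names = FRONTAL_CHANNELS
    lookup = {c.lower(): i for i, c in enumerate(rec.channel_names)}
    indices = []
    for name in names:
        idx = lookup.get(name.lower())
        if idx is None:
            raise ChannelLookupError(
                f"unknown channel {name!r}; available: "
                f"{', '.join(rec.channel_names)}"
            )
        indices.append(idx)
    return replace(
        rec,
        data=rec.data[:, indices, :],
        channel_names=tuple(rec.channel_names[i] for i in indices),
    )
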