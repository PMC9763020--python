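"""ADASYN oversampling of the minority class.

Adaptive synthetic sampling generates minority-class points by linear
interpolation between minority neighbors, allocating more synthetic points
to minority samples whose neighborhoods are dominated by the majority
class (the hard-to-learn border regions).  With balance level beta = 1 the
classes end up equal up to rounding slack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .errors import BalanceError, ConfigurationError
from .features import feature_columns


@dataclass(frozen=True)
class BalanceConfig:
    k_neighbors: int = 5
    beta: float = 1.0  # fraction of the class gap to close
    seed: int = 0

    def validate(self) -> None:
        if self.k_neighbors < 1:
            raise ConfigurationError("k_neighbors must be >= 1")
        if not 0.0 < self.beta <= 1.0:
            raise ConfigurationError("beta must lie in (0, 1]")


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing exactly to ``total``, proportional to quotas."""
    base = np.floor(quotas).astype(int)
    rem = total - int(base.sum())
    if rem > 0:
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:rem]] += 1
    return base


def adasyn_balance(
    matrix: pd.DataFrame, config: BalanceConfig | None = None
) -> pd.DataFrame:
    """Append density-adaptive synthetic minority rows to a feature matrix.

    The number of synthetic points is ``round((majority - minority) * beta)``,
    distributed over minority points proportionally to the fraction of
    majority samples among each point's k nearest neighbors (in the
    standardized feature space).  Each synthetic point is
    ``x_i + u * (x_z - x_i)`` with ``u ~ U[0, 1]`` and ``x_z`` a random one
    of x_i's k nearest *minority* neighbors, so it lies on the segment
    between two original minority points.  Original rows are never modified.
    Synthetic rows carry ``participant = trial = -1`` and
    ``channel = "synthetic"``.
    """
    cfg = config or BalanceConfig()
    cfg.validate()
    y = matrix["label"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise BalanceError(f"need exactly 2 classes, got {classes.size}")
    minority_class = classes[np.argmin(counts)]
    majority_class = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_maj == n_min:
        return matrix.copy()
    if n_min <= cfg.k_neighbors:
        raise BalanceError(
            f"minority class has {n_min} samples; needs more than "
            f"k_neighbors = {cfg.k_neighbors}"
        )
    total = int(round((n_maj - n_min) * cfg.beta))
    if total == 0:
        return matrix.copy()

    cols = feature_columns(matrix)
    X = matrix[cols].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    idx_min = np.flatnonzero(y == minority_class)
    k = cfg.k_neighbors
    # ratio of majority samples among each minority point's k neighbors
    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(Z)
    _, nbrs = nn_all.kneighbors(Z[idx_min])
    nbrs = nbrs[:, 1:]  # drop self
    r = (y[nbrs] == majority_class).mean(axis=1)
    if r.sum() == 0.0:
        warnings.warn(
            "no minority point has majority neighbors; nothing to synthesize",
            stacklevel=2,
        )
        return matrix.copy()
    counts_i = _largest_remainder(r / r.sum() * total, total)

    nn_min = NearestNeighbors(n_neighbors=k + 1).fit(Z[idx_min])
    _, min_nbrs = nn_min.kneighbors(Z[idx_min])
    min_nbrs = min_nbrs[:, 1:]

    rng = np.random.default_rng(cfg.seed)
    synth = np.empty((total, len(cols)))
    pos = 0
    for i, g in enumerate(counts_i):
        if g == 0:
            continue
        xi = X[idx_min[i]]
        picks = rng.integers(0, k, g)
        u = rng.uniform(0.0, 1.0, g)
        for j in range(g):
            xz = X[idx_min[min_nbrs[i, picks[j]]]]
            synth[pos] = xi + u[j] * (xz - xi)
            pos += 1

    synth_df = pd.DataFrame(synth, columns=cols)
    synth_df.insert(0, "participant", -1)
    synth_df.insert(1, "trial", -1)
    synth_df.insert(2, "channel", "synthetic")
    synth_df.insert(3, "label", minority_class)
    synth_df = synth_df[list(matrix.columns)]
    return pd.concat([matrix, synth_df], ignore_index=True)
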