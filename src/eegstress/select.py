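"""Pearson-correlation feature ranking and forward selection.

Features are ranked by the absolute Pearson correlation between each
feature column and the binary stress label.  Ranking is pooled at the
feature-name level by default: the 15 feature names are scored by their
mean |C| across the five sub-bands, and keeping the top 10 names in every
band reduces the 75-column matrix to 50 columns.  Forward selection then
walks the ranking, adding one feature at a time and stopping as soon as
the evaluator's accuracy fails to improve (patience 1) or the cap of 10
features is reached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, DomainError, StateError
from .features import KEY_COLUMNS, feature_columns


@dataclass
class SelectionResult:
    correlations: dict[str, float]
    ranking: list[str]
    selected: list[str] = field(default_factory=list)
    history: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "correlations": self.correlations,
                    "ranking": self.ranking,
                    "selected": self.selected,
                    "history": self.history,
                },
                indent=2,
            )
        )
        return path


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient C of two equal-length series.

    C = sum((x_i - xbar)(y_i - ybar)) /
        sqrt(sum((x_i - xbar)^2) * sum((y_i - ybar)^2))
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D and of equal length")
    if x.size < 2:
        raise DomainError("need at least 2 samples")
    dx = x - x.mean()
    dy = y - y.mean()
    ssx = float(dx @ dx)
    ssy = float(dy @ dy)
    if ssx == 0.0 or ssy == 0.0:
        raise DegenerateInputError("constant input: correlation undefined")
    return float(dx @ dy) / np.sqrt(ssx * ssy)


def _band_feature(column: str) -> str:
    """Strip the leading band prefix from a 'band_feature' column name."""
    return column.split("_", 1)[1] if "_" in column else column


def rank_features(
    matrix: pd.DataFrame, pool_bands: bool = True
) -> SelectionResult:
    """Rank feature columns by |C| against the binary label, descending.

    With ``pool_bands`` the per-column |C| values are averaged across bands
    for each feature name and the ranking is over the 15 names; otherwise
    the ranking is over raw columns.  Ties break by column order (stable
    sort).  Constant columns cannot correlate and score 0.
    """
    labels = matrix["label"].to_numpy(dtype=float)
    if np.unique(labels).size < 2:
        raise DegenerateInputError("labels contain a single class")
    scores: dict[str, float] = {}
    counts: dict[str, int] = {}
    for col in feature_columns(matrix):
        try:
            c = abs(pearson_correlation(matrix[col].to_numpy(float), labels))
        except DegenerateInputError:
            c = 0.0
        key = _band_feature(col) if pool_bands else col
        scores[key] = scores.get(key, 0.0) + c
        counts[key] = counts.get(key, 0) + 1
    correlations = {k: scores[k] / counts[k] for k in scores}
    order = sorted(
        correlations, key=lambda k: -correlations[k]
    )  # dict preserves first-seen column order; sort is stable
    return SelectionResult(correlations=correlations, ranking=order)


def forward_select(
    result: SelectionResult,
    evaluator: Callable[[list[str]], float],
    max_features: int = 10,
) -> SelectionResult:
    """Expand the feature set along the ranking until accuracy stalls.

    ``evaluator`` maps a feature-name subset to a scalar accuracy.  The
    first feature is always kept; each further feature is kept only if it
    strictly improves the accuracy, and the search stops at the first
    non-improvement (patience 1) or at ``max_features``.
    """
    if not result.ranking:
        raise StateError("ranking is empty; run rank_features first")
    selected: list[str] = []
    history: list[float] = []
    best = -np.inf
    for name in result.ranking[:max_features]:
        acc = float(evaluator(selected + [name]))
        history.append(acc)
        if acc > best:
            selected = selected + [name]
            best = acc
        else:
            break
    return replace(result, selected=selected, history=history)


def apply_selection(
    matrix: pd.DataFrame, selected: Sequence[str], pool_bands: bool = True
) -> pd.DataFrame:
    """Keep the key columns plus the selected features.

    With ``pool_bands`` the selected entries are feature names kept in
    every band (10 names x 5 bands -> 50 columns); otherwise they are raw
    column names.
    """
    chosen = set(selected)
    keep = [
        c
        for c in matrix.columns
        if c in KEY_COLUMNS
        or (_band_feature(c) if pool_bands else c) in chosen
    ]
    return matrix[keep]


def make_cv_evaluator(
    matrix: pd.DataFrame,
    net_config=None,
    k: int = 5,
    pool_bands: bool = True,
):
    """Default forward-selection evaluator: stratified k-fold CV accuracy
    of the pipeline's neural-network classifier on the candidate columns,
    with a short training budget and a fixed seed."""
    from .classify import NetConfig, kfold_cv

    cfg = net_config or NetConfig(hidden_units=8, epochs=60, seed=0)
    y = matrix["label"].to_numpy(dtype=int)

    def evaluator(names: list[str]) -> float:
        sub = apply_selection(matrix, names, pool_bands=pool_bands)
        X = sub[feature_columns(sub)].to_numpy(dtype=float)
        return kfold_cv(X, y, k=k, config=cfg).mean["accuracy"]

    return evaluator
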