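"""Binary stress labeling from valence-arousal self-assessment ratings.

Following the circumplex (valence-arousal) reading of the 1-9 rating
scale, a trial is labeled stressed (1) when its valence falls on the
negative side of the scale midpoint and unstressed (0) otherwise.  Both
arousal branches of the rule produce the same label, so arousal is
accepted but non-determining; the boundary value (valence exactly at the
threshold) is assigned to the stressed side.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError


def to_stress_label(
    valence: float | np.ndarray,
    arousal: float | np.ndarray | None = None,
    threshold: float = 5.0,
) -> int | np.ndarray:
    """Map valence (and non-determining arousal) to a binary stress label.

    Returns 1 (stressed) when ``valence <= threshold``, else 0.  Scalar
    input gives a scalar int; array input gives an int array.
    """
    v = np.asarray(valence, dtype=float)
    if np.any(v < 1.0) or np.any(v > 9.0):
        raise DomainError("valence must lie on the 1-9 scale")
    if arousal is not None:
        a = np.asarray(arousal, dtype=float)
        if np.any(a < 1.0) or np.any(a > 9.0):
            raise DomainError("arousal must lie on the 1-9 scale")
    label = (v <= threshold).astype(int)
    return int(label) if np.isscalar(valence) or v.ndim == 0 else label
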