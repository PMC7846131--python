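"""Monotone least-squares projection used by the density estimator."""

from __future__ import annotations

import numpy as np
from sklearn.isotonic import isotonic_regression


def pav_nonincreasing(y: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Best non-increasing approximation of ``y`` in (weighted) least squares.

    Pool-adjacent-violators; an already non-increasing sequence is returned
    unchanged and the projection is idempotent.
    """
    y = np.asarray(y, dtype=float)
    return isotonic_regression(y, sample_weight=weights, increasing=False)
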