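"""Shared numerical tolerances.

The zero-delta tolerance is shared between the per-stage explainers and the
chain propagation so that a coordinate treated as "unchanged" by a stage
explainer (zero attribution row) is also treated as a zero denominator by the
Hadamard division — the two conventions must cancel consistently or chained
efficiency breaks.
"""

from __future__ import annotations

import numpy as np

# |delta| <= ZERO_TOL * max(1, |a_e|, |a_b|)  =>  treat the delta as zero.
ZERO_TOL: float = 1e-9

# Probability clipping for log-loss transforms; keeps loss deltas finite so
# the chain division never sees an infinity.
LOG_LOSS_EPS: float = 1e-12

# Default relative tolerance for efficiency (summation-to-delta) checks.
EFFICIENCY_TOL: float = 1e-6


def near_zero_delta(a_e: np.ndarray, a_b: np.ndarray, tol: float = ZERO_TOL) -> np.ndarray:
    """Boolean mask of coordinates whose explicand/baseline delta is ~zero.

    Relative to the magnitude of the two operands, with an absolute floor of
    1, because exact-zero comparisons are fragile after float chains.
    """
    a_e = np.asarray(a_e, dtype=float)
    a_b = np.asarray(a_b, dtype=float)
    scale = np.maximum(1.0, np.maximum(np.abs(a_e), np.abs(a_b)))
    return np.abs(a_e - a_b) <= tol * scale
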