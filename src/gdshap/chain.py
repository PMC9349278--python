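"""Chained propagation of per-stage attributions through a series of models.

For a single explicand/baseline pair the recursion is

    ψ^k = φ̂(h_k, ·, ·)                       (final stage, scalar output)
    ψ^i = φ̂(h_i, ·, ·) · (ψ^{i+1} ⊘ Δf_i)    for i = k−1, …, 1

where ``Δf_i = f_i(x^e) − f_i(x^b)`` is the vector of intermediate output
deltas, ``⊘`` is Hadamard division with the zero-denominator-maps-to-zero
convention, and each φ̂ is evaluated at the *propagated* intermediate pair
``(f_{i−1}(x^e), f_{i−1}(x^b))``.  Every intermediate ψ^i sums to
``f_k(x^e) − f_k(x^b)``: per-stage column efficiency survives the chain.

The production attribution averages ψ^1 over a distribution of baselines —
never the chain evaluated at an averaged baseline, which is a different
(and biased) estimator.

The propagation is deliberately factored into per-stage *messages* (an
attribution matrix plus the stage's intermediate output pair) and a pure
combiner, so that the stages of a pipeline can live in separate processes —
or separate institutions — that exchange only these arrays and still
reproduce the in-process result bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._config import ZERO_TOL, near_zero_delta
from .models import SeriesModel
from .stages import stage_attribution

__all__ = [
    "ChainResult",
    "AttributionResult",
    "hadamard_div",
    "stage_message",
    "combine_messages",
    "propagate",
    "explain",
    "explain_batch",
]


def hadamard_div(
    a: np.ndarray,
    b: np.ndarray,
    zero_mask: np.ndarray | None = None,
    zero_tol: float = ZERO_TOL,
) -> np.ndarray:
    """Elementwise a/b with the convention a_i/0 := 0.

    ``zero_mask`` marks denominators to treat as zero; by default
    ``|b_i| <= zero_tol``.
    """
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise ValueError("hadamard_div: operands must have equal length")
    if zero_mask is None:
        zero_mask = np.abs(b) <= zero_tol
    out = np.zeros_like(a)
    live = ~zero_mask
    out[live] = a[live] / b[live]
    return out


@dataclass
class ChainResult:
    """Single-baseline chain output.

    ``psi[i]`` is the attribution to the inputs of stage i+1 (0-indexed);
    ``psi[0]`` is the attribution in the raw feature space.
    """

    psi: list[np.ndarray]
    out_e: list[np.ndarray]
    out_b: list[np.ndarray]

    @property
    def phi(self) -> np.ndarray:
        return self.psi[0]

    @property
    def deltas(self) -> list[np.ndarray]:
        return [e - b for e, b in zip(self.out_e, self.out_b)]


@dataclass
class AttributionResult:
    """Baseline-averaged attribution for one explicand."""

    phi: np.ndarray
    n_baselines: int
    per_baseline: list[ChainResult] | None = None


def stage_message(stage, z_e: np.ndarray, z_b: np.ndarray, zero_tol: float = ZERO_TOL) -> dict:
    """Everything downstream needs from one stage: matrix + output pair.

    This is the full payload a model owner must disclose per explicand —
    the stage itself never leaves the process.
    """
    attr = stage_attribution(stage, z_e, z_b, zero_tol)
    return {
        "matrix": attr.matrix,
        "out_e": np.asarray(stage(attr.z_e), dtype=float).reshape(-1),
        "out_b": np.asarray(stage(attr.z_b), dtype=float).reshape(-1),
    }


def combine_messages(messages: list[dict], zero_tol: float = ZERO_TOL) -> ChainResult:
    """Run the backward recursion over per-stage messages."""
    if not messages:
        raise ValueError("no stage messages to combine")
    if messages[-1]["out_e"].shape[0] != 1:
        raise ValueError(
            f"chain explanation requires a scalar final output, got width "
            f"{messages[-1]['out_e'].shape[0]}"
        )
    k = len(messages)
    psi: list[np.ndarray] = [None] * k  # type: ignore[list-item]
    psi[k - 1] = messages[k - 1]["matrix"][:, 0].copy()
    for i in range(k - 2, -1, -1):
        out_e, out_b = messages[i]["out_e"], messages[i]["out_b"]
        ratio = hadamard_div(
            psi[i + 1],
            out_e - out_b,
            zero_mask=near_zero_delta(out_e, out_b, zero_tol),
            zero_tol=zero_tol,
        )
        psi[i] = messages[i]["matrix"] @ ratio
    return ChainResult(
        psi=psi,
        out_e=[m["out_e"] for m in messages],
        out_b=[m["out_b"] for m in messages],
    )


def propagate(
    series: SeriesModel,
    x_e: np.ndarray,
    x_b: np.ndarray,
    zero_tol: float = ZERO_TOL,
) -> ChainResult:
    """Single-baseline chained attribution through a series of models."""
    if series.n_outputs != 1:
        raise ValueError(
            f"chain explanation requires a scalar final output, got width {series.n_outputs}"
        )
    x_e = np.asarray(x_e, dtype=float).reshape(-1)
    x_b = np.asarray(x_b, dtype=float).reshape(-1)
    messages = []
    z_e, z_b = x_e, x_b
    for stage in series.stages:
        msg = stage_message(stage, z_e, z_b, zero_tol)
        messages.append(msg)
        z_e, z_b = msg["out_e"], msg["out_b"]
    return combine_messages(messages, zero_tol)


def _baseline_rows(baselines) -> np.ndarray:
    rows = getattr(baselines, "rows", baselines)
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[0] == 0:
        raise ValueError("baseline set is empty")
    return rows


def explain(
    series: SeriesModel,
    x_e: np.ndarray,
    baselines,
    retain_intermediate: bool = False,
    zero_tol: float = ZERO_TOL,
) -> AttributionResult:
    """Baseline-averaged attribution: the mean over per-baseline chains.

    Deterministic given the baseline row order.  The sum of ``phi`` equals
    ``f_k(x^e) − mean_b f_k(x^b)`` up to the chain's zero-delta tolerance.
    """
    rows = _baseline_rows(baselines)
    chains = [propagate(series, x_e, x_b, zero_tol) for x_b in rows]
    phi = np.mean([c.phi for c in chains], axis=0)
    return AttributionResult(
        phi=phi,
        n_baselines=rows.shape[0],
        per_baseline=chains if retain_intermediate else None,
    )


def explain_batch(
    series: SeriesModel,
    X_e: np.ndarray,
    baselines,
    n_baselines: int | None = None,
    seed: int | None = None,
    zero_tol: float = ZERO_TOL,
) -> np.ndarray:
    """Attribution matrix: one row of ``phi`` per explicand.

    With ``n_baselines`` set, a seeded subsample of the baseline rows
    (without replacement when possible) is drawn once and shared by all
    explicands, so a fixed seed reproduces the matrix exactly.
    """
    from .baselines import subsample  # local import: baselines is a leaf module

    X_e = np.atleast_2d(np.asarray(X_e, dtype=float))
    rows = _baseline_rows(baselines)
    if n_baselines is not None and n_baselines != rows.shape[0]:
        rows = subsample(rows, n_baselines, seed=seed).rows
    return np.vstack([explain(series, x_e, rows, zero_tol=zero_tol).phi for x_e in X_e])
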