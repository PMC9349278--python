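"""Per-stage attribution matrices.

Each explainer maps a stage ``h : R^m -> R^o`` and an input pair
``(z^e, z^b)`` to a matrix ``φ̂(h, z^e, z^b)`` of shape (m, o) whose q-th
column sums to ``h(z^e)_q − h(z^b)_q`` (per-column summation-to-delta) and
whose p-th row is zero whenever ``z^e_p = z^b_p``.

Linear and tree stages are explained exactly (single-baseline interventional
Shapley values); dense-network stages use rescale multipliers chained
through the layers; output transforms are elementwise and therefore trivially
exact.  The zero-delta convention is shared with the chain module: a
nonlinearity whose pre-activation delta is ~zero contributes nothing
downstream, rather than falling back to a derivative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._config import ZERO_TOL, near_zero_delta
from .models import (
    ACTIVATIONS,
    DenseNetStage,
    LinearStage,
    TransformStage,
    Tree,
    TreeEnsembleStage,
)
from .shapley import _subset_weighted_phi

__all__ = [
    "StageAttribution",
    "linear_attr",
    "tree_attr",
    "dense_attr",
    "transform_attr",
    "stage_attribution",
]

# enumeration guard for per-tree relevant-feature subsets
_TREE_ENUM_CAP = 18


@dataclass
class StageAttribution:
    """Attribution matrix of shape (m, o) for one stage and input pair."""

    matrix: np.ndarray
    stage: object
    z_e: np.ndarray
    z_b: np.ndarray

    def column_residuals(self) -> np.ndarray:
        """|column sums − output deltas|, one per output coordinate."""
        out_e = np.asarray(self.stage(self.z_e), dtype=float).reshape(-1)
        out_b = np.asarray(self.stage(self.z_b), dtype=float).reshape(-1)
        return np.abs(self.matrix.sum(axis=0) - (out_e - out_b))


def _pair(z_e, z_b, m: int) -> tuple[np.ndarray, np.ndarray]:
    z_e = np.asarray(z_e, dtype=float).reshape(-1)
    z_b = np.asarray(z_b, dtype=float).reshape(-1)
    if z_e.shape[0] != m or z_b.shape[0] != m:
        raise ValueError(f"input pair length {z_e.shape[0]}/{z_b.shape[0]} != stage width {m}")
    return z_e, z_b


def linear_attr(stage: LinearStage, z_e, z_b) -> StageAttribution:
    """Exact attribution for an affine stage: entry [p, q] = W[q, p]·Δz_p.

    The intercept cancels in the delta and contributes nothing.
    """
    z_e, z_b = _pair(z_e, z_b, stage.n_inputs)
    matrix = stage.weights.T * (z_e - z_b)[:, None]
    return StageAttribution(matrix, stage, z_e, z_b)


def _tree_relevant_features(tree: Tree, z_e: np.ndarray, z_b: np.ndarray, zero_tol: float) -> list[int]:
    """Features whose splice value can change the leaf reached.

    Walks the tree following both children only at nodes whose feature
    differs between explicand and baseline; all other splits route
    identically for every spliced sample and are irrelevant to the lift.
    """
    differs = ~near_zero_delta(z_e, z_b, zero_tol)
    rel: list[int] = []
    seen: set[int] = set()
    stack = [0]
    while stack:
        i = stack.pop()
        f = int(tree.feature[i])
        if f < 0:
            continue
        if differs[f]:
            if f not in seen:
                seen.add(f)
                rel.append(f)
            stack.extend((int(tree.left[i]), int(tree.right[i])))
        else:
            child = tree.left[i] if z_e[f] <= tree.threshold[i] else tree.right[i]
            stack.append(int(child))
    return sorted(rel)


def tree_attr(stage: TreeEnsembleStage, z_e, z_b, zero_tol: float = ZERO_TOL) -> StageAttribution:
    """Exact single-baseline interventional Shapley values for a tree ensemble.

    Shapley linearity in the game makes the ensemble attribution the sum of
    per-tree attributions.  Within one tree, only the features on the union
    of reachable explicand/baseline paths are live players; the Shapley
    values over that (small) set are computed by subset enumeration and all
    other features are dummies with exactly zero credit.
    """
    z_e, z_b = _pair(z_e, z_b, stage.n_inputs)
    phi = np.zeros(stage.n_inputs)
    for t_idx, tree in enumerate(stage.trees):
        rel = _tree_relevant_features(tree, z_e, z_b, zero_tol)
        if not rel:
            continue
        if len(rel) > _TREE_ENUM_CAP:
            raise ValueError(
                f"tree {t_idx}: {len(rel)} live features exceeds the enumeration cap "
                f"({_TREE_ENUM_CAP}); reduce tree depth"
            )

        def value(mask: int) -> float:
            chi = z_b.copy()
            for bit, f in enumerate(rel):
                if mask >> bit & 1:
                    chi[f] = z_e[f]
            return tree.predict_one(chi)

        phi[rel] += _subset_weighted_phi(value, len(rel))
    return StageAttribution(phi[:, None], stage, z_e, z_b)


_ACT_DERIVS = {
    "relu": lambda a: (a > 0).astype(float),
    "sigmoid": lambda a: (s := ACTIVATIONS["sigmoid"](a)) * (1.0 - s),
    "tanh": lambda a: 1.0 - np.tanh(a) ** 2,
    "identity": lambda a: np.ones_like(a),
    "square": lambda a: 2.0 * a,
}


def dense_attr(
    stage: DenseNetStage,
    z_e,
    z_b,
    zero_tol: float = ZERO_TOL,
    gradient_fallback: bool = False,
) -> StageAttribution:
    """Rescale-rule attribution for a dense network.

    Multipliers are chained layerwise: affine layers contribute their weight
    matrices, elementwise layers contribute diagonal ratios
    ``Δσ_q / Δa_q`` (set to 0 where the pre-activation delta is ~zero, so an
    unchanged hidden unit contributes exactly nothing downstream).  The
    attribution matrix is ``diag(Δz) · multiplier`` and satisfies per-column
    summation-to-delta because each diagonal ratio converts the incoming
    linear delta into the exact nonlinear output delta.

    ``gradient_fallback`` replaces the zero multiplier at ~zero-delta units
    with the activation's derivative at the explicand pre-activation
    (classic backprop behavior).  It is off by default and excluded from the
    efficiency and zero-row guarantees.
    """
    z_e, z_b = _pair(z_e, z_b, stage.n_inputs)
    mult = np.eye(stage.n_inputs)
    a_e, a_b = z_e, z_b
    for layer in stage.layers:
        if layer[0] == "affine":
            _, W, b = layer
            mult = mult @ W.T
            a_e = W @ a_e + b
            a_b = W @ a_b + b
        else:
            act = ACTIVATIONS[layer[1]]
            s_e, s_b = act(a_e), act(a_b)
            delta_a = a_e - a_b
            if gradient_fallback:
                ratio = _ACT_DERIVS[layer[1]](a_e)
            else:
                ratio = np.zeros_like(delta_a)
            live = ~near_zero_delta(a_e, a_b, zero_tol)
            ratio[live] = (s_e[live] - s_b[live]) / delta_a[live]
            mult = mult * ratio[None, :]
            a_e, a_b = s_e, s_b
    matrix = (z_e - z_b)[:, None] * mult
    return StageAttribution(matrix, stage, z_e, z_b)


def transform_attr(stage: TransformStage, z_e, z_b) -> StageAttribution:
    """Diagonal attribution for an elementwise output transform."""
    z_e, z_b = _pair(z_e, z_b, stage.n_inputs)
    matrix = np.diag(stage.scalar_map(z_e) - stage.scalar_map(z_b))
    return StageAttribution(matrix, stage, z_e, z_b)


def stage_attribution(stage, z_e, z_b, zero_tol: float = ZERO_TOL) -> StageAttribution:
    """Dispatch to the explainer matching the stage kind."""
    if isinstance(stage, LinearStage):
        return linear_attr(stage, z_e, z_b)
    if isinstance(stage, TreeEnsembleStage):
        return tree_attr(stage, z_e, z_b, zero_tol)
    if isinstance(stage, DenseNetStage):
        return dense_attr(stage, z_e, z_b, zero_tol)
    if isinstance(stage, TransformStage):
        return transform_attr(stage, z_e, z_b)
    raise TypeError(f"no stage explainer for {type(stage).__name__}")
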