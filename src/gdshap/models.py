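"""Typed model stages and series-of-models compositions.

A *series of models* is a composition ``f_k = h_k ∘ … ∘ h_1`` of typed stages
``h_i : R^{m_i} -> R^{o_i}`` with the dimension contract ``m_{i+1} = o_i``.
Four stage kinds are supported:

- :class:`LinearStage` — affine map ``z -> W z + b``;
- :class:`TreeEnsembleStage` — sum of binary regression trees;
- :class:`DenseNetStage` — alternating affine and elementwise-nonlinearity
  layers (a multilayer perceptron);
- :class:`TransformStage` — elementwise scalar output transform (sigmoid,
  negation, log-loss against a fixed binary label).

Stages evaluate on single samples (1-D) or row-matrices (2-D) and serialize
to a versioned JSON schema (see :func:`save_series` / :func:`load_series`,
documented in ``docs/model_schema.md``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ._config import LOG_LOSS_EPS

SCHEMA_VERSION = 1

__all__ = [
    "SchemaError",
    "LinearStage",
    "Tree",
    "TreeEnsembleStage",
    "DenseNetStage",
    "TransformStage",
    "SeriesModel",
    "forward",
    "load_series",
    "save_series",
    "series_from_dict",
    "series_to_dict",
    "ACTIVATIONS",
    "TRANSFORMS",
]


class SchemaError(ValueError):
    """Raised when a model JSON document violates the schema.

    Carries the JSON path of the offending element in the message.
    """


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable in both tails
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "relu": lambda x: np.maximum(x, 0.0),
    "sigmoid": _sigmoid,
    "tanh": np.tanh,
    "identity": lambda x: np.asarray(x, dtype=float),
    "square": lambda x: np.square(x),
}


def _as_batch(z: np.ndarray, m: int, who: str) -> tuple[np.ndarray, bool]:
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    if single:
        z = z[None, :]
    if z.ndim != 2 or z.shape[1] != m:
        raise ValueError(
            f"{who}: expected input width {m}, got array of shape {z.shape}"
        )
    return z, single


@dataclass
class LinearStage:
    """Affine stage ``z -> W z + b`` with ``W`` of shape (o, m)."""

    weights: np.ndarray
    intercept: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        o, m = self.weights.shape
        if self.intercept is None:
            self.intercept = np.zeros(o)
        self.intercept = np.asarray(self.intercept, dtype=float).reshape(-1)
        if self.intercept.shape[0] != o:
            raise ValueError(
                f"linear stage: intercept length {self.intercept.shape[0]} "
                f"does not match output width {o}"
            )

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[0]

    def __call__(self, z: np.ndarray) -> np.ndarray:
        zb, single = _as_batch(z, self.n_inputs, "linear stage")
        out = zb @ self.weights.T + self.intercept
        return out[0] if single else out

    def to_dict(self) -> dict:
        return {
            "kind": "linear",
            "weights": self.weights.tolist(),
            "intercept": self.intercept.tolist(),
        }


@dataclass
class Tree:
    """A binary regression tree stored as flat parallel node arrays.

    ``feature[i] < 0`` marks node ``i`` as a leaf with value ``value[i]``;
    internal nodes route a sample left iff ``x[feature] <= threshold``
    (ties go left).
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.feature = np.asarray(self.feature, dtype=int)
        self.threshold = np.asarray(self.threshold, dtype=float)
        self.left = np.asarray(self.left, dtype=int)
        self.right = np.asarray(self.right, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        n = self.feature.shape[0]
        for name in ("threshold", "left", "right", "value"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"tree: node array '{name}' length != {n}")

    @property
    def n_nodes(self) -> int:
        return self.feature.shape[0]

    def validate(self, m: int) -> None:
        """Check node wiring: feature indices < m, every path reaches a leaf."""
        for i in range(self.n_nodes):
            if self.feature[i] < 0:
                continue
            if self.feature[i] >= m:
                raise ValueError(
                    f"tree node {i}: feature index {self.feature[i]} >= input width {m}"
                )
            for child in (self.left[i], self.right[i]):
                if child < 0 or child >= self.n_nodes:
                    raise ValueError(f"tree node {i}: child index {child} out of range")
        # every path terminates: walk from root with a visit bound
        stack, seen = [0], 0
        while stack:
            i = stack.pop()
            seen += 1
            if seen > 2 * self.n_nodes:
                raise ValueError("tree: cycle detected (path does not terminate)")
            if self.feature[i] >= 0:
                stack.extend((int(self.left[i]), int(self.right[i])))

    def predict_one(self, x: np.ndarray) -> float:
        i = 0
        while self.feature[i] >= 0:
            i = int(self.left[i]) if x[self.feature[i]] <= self.threshold[i] else int(self.right[i])
        return float(self.value[i])

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": [None if f < 0 else t for f, t in zip(self.feature, self.threshold)],
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": [v if f < 0 else None for f, v in zip(self.feature, self.value)],
        }


@dataclass
class TreeEnsembleStage:
    """Sum-of-trees stage with a single scalar output."""

    trees: list[Tree]
    n_features: int

    def __post_init__(self) -> None:
        for t_idx, tree in enumerate(self.trees):
            try:
                tree.validate(self.n_features)
            except ValueError as exc:
                raise ValueError(f"tree {t_idx}: {exc}") from exc

    @property
    def n_inputs(self) -> int:
        return self.n_features

    @property
    def n_outputs(self) -> int:
        return 1

    def __call__(self, z: np.ndarray) -> np.ndarray:
        zb, single = _as_batch(z, self.n_inputs, "tree ensemble stage")
        out = np.zeros((zb.shape[0], 1))
        for tree in self.trees:
            out[:, 0] += [tree.predict_one(row) for row in zb]
        return out[0] if single else out

    def to_dict(self) -> dict:
        return {
            "kind": "tree_ensemble",
            "n_features": self.n_features,
            "trees": [t.to_dict() for t in self.trees],
        }


@dataclass
class DenseNetStage:
    """Dense network: alternating affine and elementwise activation layers.

    ``layers`` items are either ``("affine", W, b)`` with ``W`` of shape
    (out, in), or ``("activation", name)`` with ``name`` in
    :data:`ACTIVATIONS`.  Consecutive affine widths must chain.
    """

    layers: list[tuple]

    def __post_init__(self) -> None:
        width = None
        norm: list[tuple] = []
        for idx, layer in enumerate(self.layers):
            if layer[0] == "affine":
                _, W, b = layer
                W = np.atleast_2d(np.asarray(W, dtype=float))
                b = np.zeros(W.shape[0]) if b is None else np.asarray(b, dtype=float).reshape(-1)
                if b.shape[0] != W.shape[0]:
                    raise ValueError(f"dense layer {idx}: bias length != output width")
                if width is not None and W.shape[1] != width:
                    raise ValueError(
                        f"dense layer {idx}: input width {W.shape[1]} != previous output {width}"
                    )
                width = W.shape[0]
                norm.append(("affine", W, b))
            elif layer[0] == "activation":
                name = layer[1]
                if name not in ACTIVATIONS:
                    raise ValueError(
                        f"dense layer {idx}: unsupported activation '{name}' "
                        f"(supported: {sorted(ACTIVATIONS)})"
                    )
                norm.append(("activation", name))
            else:
                raise ValueError(f"dense layer {idx}: unknown layer type '{layer[0]}'")
        if not norm or norm[0][0] != "affine":
            raise ValueError("dense stage: first layer must be affine")
        self.layers = norm

    @property
    def n_inputs(self) -> int:
        return self.layers[0][1].shape[1]

    @property
    def n_outputs(self) -> int:
        for layer in reversed(self.layers):
            if layer[0] == "affine":
                return layer[1].shape[0]
        raise AssertionError("unreachable: validated dense stage has an affine layer")

    def pre_post_activations(self, z: np.ndarray) -> list[np.ndarray]:
        """All intermediate layer outputs (after each layer), batch-first."""
        zb, single = _as_batch(z, self.n_inputs, "dense stage")
        outs = []
        a = zb
        for layer in self.layers:
            if layer[0] == "affine":
                a = a @ layer[1].T + layer[2]
            else:
                a = ACTIVATIONS[layer[1]](a)
            outs.append(a[0] if single else a)
        return outs

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return self.pre_post_activations(z)[-1]

    def collapsed_affine(self) -> LinearStage:
        """Collapse an identity-activation net to its equivalent affine map."""
        W = np.eye(self.n_inputs)
        b = np.zeros(self.n_inputs)
        for layer in self.layers:
            if layer[0] == "affine":
                W = layer[1] @ W
                b = layer[1] @ b + layer[2]
            elif layer[1] != "identity":
                raise ValueError("collapse requires identity activations only")
        return LinearStage(W, b)

    def to_dict(self) -> dict:
        out = []
        for layer in self.layers:
            if layer[0] == "affine":
                out.append({"type": "affine", "weights": layer[1].tolist(), "bias": layer[2].tolist()})
            else:
                out.append({"type": "activation", "name": layer[1]})
        return {"kind": "dense", "layers": out}


_TRANSFORM_KINDS = ("sigmoid", "log_odds_to_prob", "log_loss", "negate")


@dataclass
class TransformStage:
    """Elementwise scalar transform of a stage's output (m = o).

    ``sigmoid`` and ``log_odds_to_prob`` both map log-odds to probabilities;
    ``log_loss`` maps a probability to the cross-entropy against a fixed
    binary ``label`` (probabilities clipped away from {0, 1}); ``negate``
    flips sign.
    """

    kind: str
    n_features: int = 1
    label: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _TRANSFORM_KINDS:
            raise ValueError(
                f"unknown transform '{self.kind}' (supported: {_TRANSFORM_KINDS})"
            )
        if self.kind == "log_loss":
            if self.label not in (0, 1):
                raise ValueError("log_loss transform requires a binary label (0 or 1)")

    @property
    def n_inputs(self) -> int:
        return self.n_features

    @property
    def n_outputs(self) -> int:
        return self.n_features

    def scalar_map(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.kind in ("sigmoid", "log_odds_to_prob"):
            return _sigmoid(z)
        if self.kind == "negate":
            return -z
        p = np.clip(z, LOG_LOSS_EPS, 1.0 - LOG_LOSS_EPS)
        if self.label == 1:
            return -np.log(p)
        return -np.log(1.0 - p)

    def __call__(self, z: np.ndarray) -> np.ndarray:
        zb, single = _as_batch(z, self.n_inputs, "transform stage")
        out = self.scalar_map(zb)
        return out[0] if single else out

    def to_dict(self) -> dict:
        d = {"kind": "transform", "transform": self.kind, "n_features": self.n_features}
        if self.label is not None:
            d["label"] = int(self.label)
        return d


Stage = LinearStage | TreeEnsembleStage | DenseNetStage | TransformStage


@dataclass
class SeriesModel:
    """Ordered composition of stages with chained dimensions."""

    stages: list

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("series must contain at least one stage")
        for i in range(1, len(self.stages)):
            o_prev = self.stages[i - 1].n_outputs
            m_next = self.stages[i].n_inputs
            if o_prev != m_next:
                raise ValueError(
                    f"stage {i}: input width {m_next} does not match "
                    f"stage {i - 1} output width {o_prev}"
                )

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def n_inputs(self) -> int:
        return self.stages[0].n_inputs

    @property
    def n_outputs(self) -> int:
        return self.stages[-1].n_outputs

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        """Intermediate outputs ``[f_1(x), …, f_k(x)]``."""
        outs = []
        a = np.asarray(x, dtype=float)
        for stage in self.stages:
            a = stage(a)
            outs.append(a)
        return outs

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[-1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Final scalar outputs for a row-matrix of samples."""
        out = self(np.atleast_2d(np.asarray(X, dtype=float)))
        return out[:, 0] if out.ndim == 2 and out.shape[1] == 1 else out


def forward(series: SeriesModel, x: np.ndarray) -> list[np.ndarray]:
    """Functional alias for :meth:`SeriesModel.forward`."""
    return series.forward(x)


# ---------------------------------------------------------------------------
# JSON (de)serialization


def series_to_dict(series: SeriesModel) -> dict:
    return {"version": SCHEMA_VERSION, "stages": [s.to_dict() for s in series.stages]}


def _require(d: dict, key: str, path: str):
    if key not in d:
        raise SchemaError(f"{path}: missing required field '{key}'")
    return d[key]


def _stage_from_dict(d: dict, path: str):
    kind = _require(d, "kind", path)
    try:
        if kind == "linear":
            return LinearStage(
                np.asarray(_require(d, "weights", path), dtype=float),
                np.asarray(d.get("intercept"), dtype=float) if d.get("intercept") is not None else None,
            )
        if kind == "tree_ensemble":
            trees = []
            for t_idx, td in enumerate(_require(d, "trees", path)):
                tpath = f"{path}.trees[{t_idx}]"
                feature = _require(td, "feature", tpath)
                thr = [0.0 if t is None else t for t in _require(td, "threshold", tpath)]
                val = [0.0 if v is None else v for v in _require(td, "value", tpath)]
                trees.append(
                    Tree(feature, thr, _require(td, "left", tpath), _require(td, "right", tpath), val)
                )
            return TreeEnsembleStage(trees, int(_require(d, "n_features", path)))
        if kind == "dense":
            layers = []
            for l_idx, ld in enumerate(_require(d, "layers", path)):
                lpath = f"{path}.layers[{l_idx}]"
                ltype = _require(ld, "type", lpath)
                if ltype == "affine":
                    layers.append(("affine", _require(ld, "weights", lpath), ld.get("bias")))
                elif ltype == "activation":
                    layers.append(("activation", _require(ld, "name", lpath)))
                else:
                    raise SchemaError(f"{lpath}: unknown layer type '{ltype}'")
            return DenseNetStage(layers)
        if kind == "transform":
            return TransformStage(
                _require(d, "transform", path),
                int(_require(d, "n_features", path)),
                d.get("label"),
            )
    except SchemaError:
        raise
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    raise SchemaError(
        f"{path}: unknown stage kind '{kind}' "
        "(supported: linear, tree_ensemble, dense, transform)"
    )


def series_from_dict(doc: dict) -> SeriesModel:
    if "version" not in doc:
        raise SchemaError("$: missing required field 'version'")
    if doc["version"] != SCHEMA_VERSION:
        raise SchemaError(f"$.version: unsupported schema version {doc['version']}")
    stages = [
        _stage_from_dict(sd, f"$.stages[{i}]") for i, sd in enumerate(_require(doc, "stages", "$"))
    ]
    try:
        return SeriesModel(stages)
    except ValueError as exc:
        raise SchemaError(f"$.stages: {exc}") from exc


def save_series(series: SeriesModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(series_to_dict(series), indent=1))


def load_series(path: str | Path) -> SeriesModel:
    with open(path) as fh:
        return series_from_dict(json.load(fh))
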