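"""Seeded synthetic fixtures: data with controlled structure and model series.

Everything every other module needs for testing is generated here from a
(seed, spec) pair, bit-reproducibly: block-correlated Gaussian features with
planted coefficients and dummy features, random stages of each kind, and
three canned pipeline templates —

- ``stacked_scores``: feature banks compressed to opaque scores by a first
  linear stage (with passthrough features carried by identity rows), combined
  by a downstream network — the consumer-score / stacked-generalization
  pattern;
- ``extractor_to_tree``: a dense feature extractor feeding a tree ensemble;
- ``model_plus_loss``: a logistic risk model whose chain is extended by
  probability and log-loss transforms, plus explicands with a planted
  covariate shift (one feature re-scaled for a fraction of rows, as when a
  measurement changes units upstream of a deployed model).

The generators are first-class, tested code: dummy features are never read
by generated models, labels come from a logistic link on the planted
coefficients, and regeneration from the same spec is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .models import (
    DenseNetStage,
    LinearStage,
    SeriesModel,
    TransformStage,
    Tree,
    TreeEnsembleStage,
)

__all__ = [
    "FixtureSpec",
    "gen_tabular",
    "apply_covariate_shift",
    "gen_random_stage",
    "gen_series",
    "fit_logistic",
    "TEMPLATES",
]

TEMPLATES = ("stacked_scores", "extractor_to_tree", "model_plus_loss")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic tabular data set.

    Features are standard Gaussians grouped into correlated blocks
    (pairwise correlation ``rho`` within a block); ``coefficients`` drive a
    logistic link for the binary labels; ``dummy`` features get coefficient
    zero and are excluded from every generated model's input set.
    """

    n: int = 2000
    m: int = 8
    seed: int = 0
    rho: float = 0.5
    block_size: int = 2
    coefficients: tuple | None = None  # defaults to alternating-sign 1/sqrt(m) scale
    dummy: tuple = ()
    shift_feature: int = 0
    shift_multiplier: float = 2.2
    shift_fraction: float = 0.5

    def resolved_coefficients(self) -> np.ndarray:
        if self.coefficients is not None:
            beta = np.asarray(self.coefficients, dtype=float)
            if beta.shape[0] != self.m:
                raise ValueError("coefficients length != m")
        else:
            signs = np.where(np.arange(self.m) % 2 == 0, 1.0, -1.0)
            beta = signs * np.linspace(1.5, 0.5, self.m)
        beta = beta.copy()
        beta[list(self.dummy)] = 0.0
        return beta

    def active_features(self) -> list[int]:
        return [i for i in range(self.m) if i not in set(self.dummy)]


def _block_cov(m: int, block_size: int, rho: float) -> np.ndarray:
    cov = np.eye(m)
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        cov[start:stop, start:stop] = rho
        np.fill_diagonal(cov[start:stop, start:stop], 1.0)
    return cov


def gen_tabular(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and binary labels from the spec's logistic link."""
    rng = np.random.default_rng(spec.seed)
    cov = _block_cov(spec.m, spec.block_size, spec.rho)
    L = np.linalg.cholesky(cov)
    X = rng.standard_normal((spec.n, spec.m)) @ L.T
    # dummy features are independent draws: uncorrelated with everything
    for j in spec.dummy:
        X[:, j] = rng.standard_normal(spec.n)
    logits = X @ spec.resolved_coefficients()
    p = 1.0 / (1.0 + np.exp(-logits))
    y = (rng.uniform(size=spec.n) < p).astype(int)
    return X, y


def apply_covariate_shift(X: np.ndarray, spec: FixtureSpec, seed: int | None = None) -> np.ndarray:
    """Rescale one feature for a seeded fraction of rows (unit-change shift)."""
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    X = np.array(X, dtype=float, copy=True)
    n = X.shape[0]
    hit = rng.uniform(size=n) < spec.shift_fraction
    X[hit, spec.shift_feature] *= spec.shift_multiplier
    return X


def _random_tree(rng: np.random.Generator, features: list[int], depth: int, lo: float, hi: float) -> Tree:
    feature, threshold, left, right, value = [], [], [], [], []

    def build(d: int) -> int:
        idx = len(feature)
        if d == 0:
            feature.append(-1)
            threshold.append(0.0)
            left.append(-1)
            right.append(-1)
            value.append(float(rng.standard_normal()))
            return idx
        feature.append(int(rng.choice(features)))
        threshold.append(float(rng.uniform(lo, hi)))
        left.append(-1)
        right.append(-1)
        value.append(0.0)
        left[idx] = build(d - 1)
        right[idx] = build(d - 1)
        return idx

    build(depth)
    return Tree(feature, threshold, left, right, value)


def gen_random_stage(
    kind: str,
    n_inputs: int,
    seed: int = 0,
    n_outputs: int = 1,
    depth: int = 3,
    n_trees: int = 3,
    hidden: tuple = (8,),
    activation: str = "relu",
    features: list[int] | None = None,
    data_range: tuple = (-2.5, 2.5),
    transform: str = "sigmoid",
    label: int | None = None,
):
    """A random stage of the requested kind, deterministic under the seed."""
    rng = np.random.default_rng(seed)
    if kind == "linear":
        W = rng.standard_normal((n_outputs, n_inputs)) / np.sqrt(n_inputs)
        b = 0.1 * rng.standard_normal(n_outputs)
        return LinearStage(W, b)
    if kind == "tree":
        allowed = list(range(n_inputs)) if features is None else list(features)
        lo, hi = data_range
        trees = [_random_tree(rng, allowed, depth, lo, hi) for _ in range(n_trees)]
        return TreeEnsembleStage(trees, n_inputs)
    if kind == "dense":
        layers: list[tuple] = []
        widths = [n_inputs, *hidden, n_outputs]
        for a, b_ in zip(widths[:-1], widths[1:]):
            W = rng.standard_normal((b_, a)) / np.sqrt(a)
            bias = 0.1 * rng.standard_normal(b_)
            layers.append(("affine", W, bias))
            layers.append(("activation", activation))
        layers.pop()  # no nonlinearity after the output layer
        return DenseNetStage(layers)
    if kind == "transform":
        return TransformStage(transform, n_features=n_inputs, label=label)
    raise ValueError(f"unknown stage kind '{kind}'")


def fit_logistic(
    X: np.ndarray, y: np.ndarray, n_steps: int = 200, lr: float = 0.5
) -> tuple[np.ndarray, float]:
    """Few-step full-batch gradient descent on the logistic loss.

    Deliberately simple and deterministic — fixtures need a sensible fitted
    model, not a tuned one.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    n, m = X.shape
    beta = np.zeros(m)
    b0 = 0.0
    for _ in range(n_steps):
        p = 1.0 / (1.0 + np.exp(-(X @ beta + b0)))
        g = (p - y) / n
        beta -= lr * (X.T @ g)
        b0 -= lr * float(g.sum())
    return beta, b0


def gen_series(template: str, seed: int = 0, spec: FixtureSpec | None = None) -> dict:
    """A canned pipeline plus matching data.

    Returns a dict with at least ``series`` (the composition), ``X`` and
    ``y``; templates add template-specific extras (see below).  Everything
    is reconstructible from (template, seed).
    """
    if template not in TEMPLATES:
        raise ValueError(f"unknown template '{template}' (choose from {TEMPLATES})")
    rng = np.random.default_rng(seed)

    if template == "stacked_scores":
        # banks of proprietary features compressed to two scores, three
        # passthrough features carried by identity rows
        spec = spec or FixtureSpec(n=1500, m=9, seed=seed, block_size=3)
        X, y = gen_tabular(spec)
        banks = ([0, 1, 2], [3, 4, 5])
        passthrough = [6, 7, 8]
        W1 = np.zeros((2 + len(passthrough), spec.m))
        for row, bank in enumerate(banks):
            W1[row, bank] = rng.standard_normal(len(bank))
        for row, j in enumerate(passthrough, start=2):
            W1[row, j] = 1.0
        stage1 = LinearStage(W1)
        stage2 = gen_random_stage(
            "dense", n_inputs=W1.shape[0], seed=seed + 1, hidden=(6,), activation="tanh"
        )
        series = SeriesModel([stage1, stage2])
        return {
            "series": series,
            "X": X,
            "y": y,
            "spec": spec,
            "banks": banks,
            "passthrough": passthrough,
        }

    if template == "extractor_to_tree":
        spec = spec or FixtureSpec(n=1500, m=6, seed=seed)
        X, y = gen_tabular(spec)
        d = 4
        extractor = gen_random_stage("dense", n_inputs=spec.m, seed=seed + 1, n_outputs=d, hidden=(8,))
        Z = np.atleast_2d(extractor(X))
        lo, hi = float(np.quantile(Z, 0.1)), float(np.quantile(Z, 0.9))
        head = gen_random_stage(
            "tree", n_inputs=d, seed=seed + 2, depth=3, n_trees=4, data_range=(lo, hi)
        )
        series = SeriesModel([extractor, head])
        return {"series": series, "X": X, "y": y, "spec": spec}

    # model_plus_loss: fitted logistic risk model, its probability chain,
    # and per-label loss chains over shifted explicands
    spec = spec or FixtureSpec(n=2000, m=8, seed=seed, shift_feature=0)
    X, y = gen_tabular(spec)
    beta, b0 = fit_logistic(X, y)
    linear = LinearStage(beta[None, :], [b0])
    prob = TransformStage("log_odds_to_prob", n_features=1)
    series = SeriesModel([linear])  # log-odds output chain
    loss_series = {
        lab: SeriesModel([linear, prob, TransformStage("log_loss", n_features=1, label=lab)])
        for lab in (0, 1)
    }
    X_shift = apply_covariate_shift(X, spec)
    return {
        "series": series,
        "prob_series": SeriesModel([linear, prob]),
        "loss_series": loss_series,
        "X": X,
        "y": y,
        "X_shift": X_shift,
        "spec": spec,
        "beta": beta,
        "intercept": b0,
    }
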