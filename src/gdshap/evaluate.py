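"""Ablation-test evaluation of feature attributions.

The ablation test masks each explicand's features one at a time — in the
order the attributions rank them — by overwriting them with an imputation
row's values, and traces the mean model output as a function of the number
of ablated features.  Masking the most *positive* features first should
drag the mean output down fast (lower curves = attributions that better
describe the model); masking the most negative first should push it up.
Each sample is ranked independently, so the curve summarizes many local
ablations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import SeriesModel

__all__ = ["AblationCurve", "ablate", "summarize"]

_DIRECTIONS = ("positive", "negative", "absolute", "random")


@dataclass
class AblationCurve:
    direction: str
    impute_row: np.ndarray
    values: np.ndarray  # mean model output at k = 0 … k_max
    metric: str = "output"

    @property
    def k(self) -> np.ndarray:
        return np.arange(self.values.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "mean_output": self.values})


def _predict(model, X: np.ndarray) -> np.ndarray:
    if isinstance(model, SeriesModel):
        return model.predict(X)
    out = np.asarray(model(X), dtype=float)
    return out[:, 0] if out.ndim == 2 and out.shape[1] == 1 else out.reshape(-1)


def _orders(phi: np.ndarray, direction: str, rng: np.random.Generator | None) -> list[np.ndarray]:
    """Per-sample ablation order: the eligible features, most salient first.

    Stable sort on (key, index) so ties break by feature index.  In the
    positive (negative) direction only features with positive (negative)
    attributions are eligible — ablating sign-mixed features has no clear
    expected effect on the output.
    """
    n, m = phi.shape
    orders = []
    for i in range(n):
        row = phi[i]
        if direction == "positive":
            eligible = np.flatnonzero(row > 0)
            key = -row[eligible]
        elif direction == "negative":
            eligible = np.flatnonzero(row < 0)
            key = row[eligible]
        elif direction == "absolute":
            eligible = np.arange(m)
            key = -np.abs(row)
        elif direction == "random":
            orders.append(rng.permutation(m))
            continue
        else:
            raise ValueError(f"unknown direction '{direction}' (choose from {_DIRECTIONS})")
        orders.append(eligible[np.argsort(key, kind="stable")])
    return orders


def ablate(
    model,
    X_e: np.ndarray,
    phi: np.ndarray,
    impute_row: np.ndarray,
    direction: str = "positive",
    k_max: int | None = None,
    seed: int | None = None,
    metric: str = "output",
    keep_top_k: bool = False,
) -> AblationCurve:
    """Mean model output as features are progressively masked.

    At step k the top-k ranked features of each sample (per its own
    attribution row) are replaced by ``impute_row``; the curve flattens once
    a sample's eligible features are exhausted.  ``seed`` drives the
    ``random`` direction only.

    ``keep_top_k`` inverts the indicator: the top-k ranked features are
    *kept* and everything else is masked (the complementary audit variant).
    """
    X_e = np.atleast_2d(np.asarray(X_e, dtype=float))
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    impute_row = np.asarray(impute_row, dtype=float).reshape(-1)
    n, m = X_e.shape
    if phi.shape != X_e.shape:
        raise ValueError(f"attribution shape {phi.shape} != explicand shape {X_e.shape}")
    if impute_row.shape[0] != m:
        raise ValueError("imputation row width mismatch")
    if k_max is None:
        k_max = m
    rng = np.random.default_rng(seed) if direction == "random" else None
    orders = _orders(phi, direction, rng)

    values = np.empty(k_max + 1)
    for k in range(k_max + 1):
        X_mod = X_e.copy()
        for i, order in enumerate(orders):
            top = order[: min(k, order.shape[0])]
            if keep_top_k:
                mask = np.ones(m, dtype=bool)
                mask[top] = False
                X_mod[i, mask] = impute_row[mask]
            else:
                X_mod[i, top] = impute_row[top]
        values[k] = float(_predict(model, X_mod).mean())
    return AblationCurve(direction=direction, impute_row=impute_row, values=values, metric=metric)


def summarize(phi: np.ndarray, feature_names: list[str] | None = None) -> pd.DataFrame:
    """Per-feature mean |φ| with a deterministic importance ranking.

    Ties in mean |φ| rank by feature index; scaling all attributions by a
    positive constant leaves the ranking unchanged.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    mean_abs = np.abs(phi).mean(axis=0)
    m = phi.shape[1]
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(m)]
    order = np.argsort(-mean_abs, kind="stable")
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    return pd.DataFrame(
        {"feature": feature_names, "mean_abs_attribution": mean_abs, "rank": rank}
    )
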