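"""Exact Shapley machinery for interventional (baseline) lifts.

The single-baseline lift extends a model ``f : R^m -> R`` to feature subsets
by splicing: ``v(S) = f(χ^S)`` where ``χ^S`` takes the explicand's values on
``S`` and the baseline's elsewhere.  Everything in this module is exact —
the subset-weighted oracle evaluates all ``2^m`` splices and is intended for
small ``m`` only (fixtures, cross-checks), never as the production
attribution path.

Also implemented here is the K-partition approximation that unifies the
rescale rule (K = 1) and the sign-split two-partition variant with the exact
Shapley values (K = m, singleton cells) for stages of the form ``h = f ∘ g``
with ``g`` affine to a scalar.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from ._config import EFFICIENCY_TOL, ZERO_TOL, near_zero_delta

__all__ = [
    "SingleBaselineLift",
    "ShapleyVector",
    "Partition",
    "lift_value",
    "exact_shapley",
    "permutation_shapley",
    "exact_shapley_distribution",
    "k_partition_shapley",
    "check_efficiency",
    "ORACLE_CAP",
]

ORACLE_CAP = 12


def _scalar(y) -> float:
    """Coerce a model output to a float; models may return shape-(1,) arrays."""
    arr = np.asarray(y, dtype=float)
    if arr.size != 1:
        raise ValueError(f"expected scalar model output, got shape {arr.shape}")
    return float(arr.reshape(()))


@dataclass
class SingleBaselineLift:
    """Set function ``v(S) = f(χ^S)`` for one explicand/baseline pair."""

    model: Callable[[np.ndarray], float]
    x_e: np.ndarray
    x_b: np.ndarray

    def __post_init__(self) -> None:
        self.x_e = np.asarray(self.x_e, dtype=float).reshape(-1)
        self.x_b = np.asarray(self.x_b, dtype=float).reshape(-1)
        if self.x_e.shape != self.x_b.shape:
            raise ValueError("explicand and baseline must have equal length")

    @property
    def m(self) -> int:
        return self.x_e.shape[0]

    def splice(self, S: Iterable[int]) -> np.ndarray:
        chi = self.x_b.copy()
        idx = list(S)
        chi[idx] = self.x_e[idx]
        return chi

    def value(self, S: Iterable[int]) -> float:
        return _scalar(self.model(self.splice(S)))

    def value_of_mask(self, mask: int) -> float:
        return self.value(i for i in range(self.m) if mask >> i & 1)


def lift_value(lift: SingleBaselineLift, S: Iterable[int]) -> float:
    """Value of the spliced sample with explicand features on ``S``."""
    return lift.value(S)


@dataclass
class ShapleyVector:
    phi: np.ndarray
    method: str
    lift: SingleBaselineLift | None = None

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float).reshape(-1)


def _subset_weighted_phi(value_of_mask: Callable[[int], float], m: int) -> np.ndarray:
    """Exact Shapley values of an m-player game from its 2^m subset values.

    Marginal contributions are combined with the weights
    |S|! (m − |S| − 1)! / m!, which is the closed form of the average over
    player orderings.
    """
    vals = np.array([value_of_mask(mask) for mask in range(1 << m)])
    fact = [math.factorial(i) for i in range(m + 1)]
    w = np.array([fact[s] * fact[m - s - 1] / fact[m] for s in range(m)])
    phi = np.zeros(m)
    for mask in range(1 << m):
        s = bin(mask).count("1")
        for i in range(m):
            if not mask >> i & 1:
                phi[i] += w[s] * (vals[mask | (1 << i)] - vals[mask])
    return phi


def exact_shapley(lift: SingleBaselineLift, cap: int = ORACLE_CAP) -> ShapleyVector:
    """Exact Shapley values of a single-baseline lift (subset-weighted form).

    Evaluates all 2^m spliced samples.  Refuses m beyond ``cap``: this is
    the oracle, not the production attribution path.
    """
    if lift.m > cap:
        raise ValueError(
            f"exact enumeration refused for m={lift.m} > cap={cap}; "
            "use the chained explainers for production attributions"
        )
    return ShapleyVector(_subset_weighted_phi(lift.value_of_mask, lift.m), "oracle", lift)


def permutation_shapley(lift: SingleBaselineLift, cap: int = 8) -> ShapleyVector:
    """Shapley values by direct average over all m! player orderings.

    Redundant with :func:`exact_shapley` by design — an independently coded
    form of the same definition, kept for cross-checks at small m.
    """
    m = lift.m
    if m > cap:
        raise ValueError(f"permutation enumeration refused for m={m} > cap={cap}")
    vals = np.array([lift.value_of_mask(mask) for mask in range(1 << m)])
    phi = np.zeros(m)
    n_perm = 0
    for perm in itertools.permutations(range(m)):
        n_perm += 1
        mask = 0
        for i in perm:
            phi[i] += vals[mask | (1 << i)] - vals[mask]
            mask |= 1 << i
    return ShapleyVector(phi / n_perm, "oracle_permutation", lift)


def exact_shapley_distribution(
    model: Callable[[np.ndarray], float],
    x_e: np.ndarray,
    D: np.ndarray,
    cap: int = ORACLE_CAP,
    check: bool = True,
) -> ShapleyVector:
    """Exact Shapley values against a baseline distribution.

    Computed two ways — as the unweighted mean of per-baseline exact Shapley
    values, and as exact Shapley values of the distribution lift
    ``v(S) = mean_b f(χ^S_b)`` — and asserted equal (they coincide because
    the Shapley value is linear in the game).  Returns the mean form.
    """
    D = np.atleast_2d(np.asarray(D, dtype=float))
    if D.shape[0] == 0:
        raise ValueError("baseline distribution is empty")
    x_e = np.asarray(x_e, dtype=float).reshape(-1)
    lifts = [SingleBaselineLift(model, x_e, xb) for xb in D]
    per_baseline = np.stack([exact_shapley(lift, cap=cap).phi for lift in lifts])
    phi_mean = per_baseline.mean(axis=0)
    if check:
        m = x_e.shape[0]
        if m > cap:
            raise ValueError(f"exact enumeration refused for m={m} > cap={cap}")

        def dist_value(mask: int) -> float:
            return float(np.mean([lift.value_of_mask(mask) for lift in lifts]))

        phi_dist = _subset_weighted_phi(dist_value, m)
        if not np.allclose(phi_mean, phi_dist, rtol=1e-8, atol=1e-10):
            raise AssertionError(
                "per-baseline mean and distribution-lift Shapley values disagree: "
                f"{phi_mean} vs {phi_dist}"
            )
    return ShapleyVector(phi_mean, "oracle_distribution")


@dataclass
class Partition:
    """K disjoint feature sets covering {0..m-1}."""

    groups: list[list[int]]
    m: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for g_idx, g in enumerate(self.groups):
            if len(g) == 0:
                raise ValueError(f"partition cell {g_idx} is empty")
            for i in g:
                if i < 0 or i >= self.m:
                    raise ValueError(f"partition cell {g_idx}: index {i} out of range")
                if i in seen:
                    raise ValueError(f"partition cells overlap at feature {i}")
                seen.add(i)
        if seen != set(range(self.m)):
            raise ValueError("partition does not cover all features")

    @property
    def K(self) -> int:
        return len(self.groups)

    @classmethod
    def singletons(cls, m: int) -> "Partition":
        return cls([[i] for i in range(m)], m)


def k_partition_shapley(
    beta: np.ndarray,
    intercept: float,
    f: Callable[[float], float],
    x_e: np.ndarray,
    x_b: np.ndarray,
    partition: Partition,
    zero_tol: float = ZERO_TOL,
) -> ShapleyVector:
    """K-partition approximate Shapley values for ``h = f ∘ g``, g affine.

    The K partition cells play a coalition game over the single-baseline
    lift of ``h``; their exact Shapley values are computed by enumeration
    and then propagated linearly within each cell, in proportion to the
    linear contribution deltas ``β_i (x^e_i − x^b_i)``.  K = 1 recovers the
    rescale rule; singleton cells recover the exact Shapley values of ``h``.

    When a cell's total linear delta is ~zero, its credit is split uniformly
    over the cell's changed features (with a warning), or assigned nowhere
    when the cell contains no changed feature.
    """
    x_e = np.asarray(x_e, dtype=float).reshape(-1)
    x_b = np.asarray(x_b, dtype=float).reshape(-1)
    beta = np.asarray(beta, dtype=float).reshape(-1)
    m = x_e.shape[0]
    K = partition.K

    def group_value(mask: int) -> float:
        chi = x_b.copy()
        for j in range(K):
            if mask >> j & 1:
                idx = partition.groups[j]
                chi[idx] = x_e[idx]
        return float(f(float(beta @ chi + intercept)))

    phi_group = _subset_weighted_phi(group_value, K)

    phi = np.zeros(m)
    changed = ~near_zero_delta(x_e, x_b, zero_tol)
    for j, cell in enumerate(partition.groups):
        idx = np.asarray(cell, dtype=int)
        d = beta[idx] * (x_e[idx] - x_b[idx])
        total = d.sum()
        scale = max(1.0, float(np.abs(d).max(initial=0.0)))
        if abs(total) > zero_tol * scale:
            phi[idx] = phi_group[j] * d / total
        else:
            live = idx[changed[idx]]
            if live.size:
                warnings.warn(
                    f"partition cell {j}: zero linear delta; splitting credit "
                    f"uniformly over {live.size} changed feature(s)",
                    stacklevel=2,
                )
                phi[live] = phi_group[j] / live.size
            # else: the cell is a dummy player, credit stays 0
    return ShapleyVector(phi, "k_partition")


def check_efficiency(
    phi: np.ndarray,
    model: Callable[[np.ndarray], float],
    x_e: np.ndarray,
    baseline: np.ndarray,
    tol: float = EFFICIENCY_TOL,
) -> tuple[bool, float]:
    """Summation-to-delta check.

    ``baseline`` may be a single row (target ``f(x^b)``) or a matrix of
    baseline rows (target ``mean_b f(x^b)``).  Returns (passed, residual)
    where the residual is compared against ``tol * max(1, |f(x^e)|)``.
    """
    phi = np.asarray(phi, dtype=float).reshape(-1)
    f_e = _scalar(model(np.asarray(x_e, dtype=float)))
    B = np.atleast_2d(np.asarray(baseline, dtype=float))
    target = float(np.mean([_scalar(model(row)) for row in B]))
    residual = abs(phi.sum() - (f_e - target))
    return residual <= tol * max(1.0, abs(f_e)), residual
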