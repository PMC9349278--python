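"""Group-level attribution with mass-conserving renormalization.

Feature attributions are aggregated to named groups (gene sets, feature
categories, …) by summing members.  Groups may overlap and need not cover
all features; features in no group form a residual group.  Because overlap
counts shared features more than once, the raw group sums are rescaled by a
single factor so that groups plus residual conserve the total attribution
mass Σ_i φ_i — the grouped explanation then satisfies the same
summation-to-delta identity as the feature-level one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["GroupSpec", "GroupAttribution", "group_attr", "read_gmt"]

RESIDUAL_NAME = "_residual"

# denominators below this (relative to the attribution scale) skip rescaling
_FACTOR_TOL = 1e-12


@dataclass
class GroupSpec:
    """Named, possibly overlapping feature-index groups over m features."""

    groups: dict[str, list[int]]
    m: int
    residual: list[int] = field(init=False)

    def __post_init__(self) -> None:
        covered: set[int] = set()
        norm: dict[str, list[int]] = {}
        for name, members in self.groups.items():
            idx = sorted(set(int(i) for i in members))
            for i in idx:
                if i < 0 or i >= self.m:
                    raise ValueError(f"group '{name}': feature index {i} out of range [0, {self.m})")
            norm[name] = idx
            covered.update(idx)
        self.groups = norm
        self.residual = sorted(set(range(self.m)) - covered)


@dataclass
class GroupAttribution:
    values: dict[str, float]
    residual: float
    factor: float

    @property
    def total(self) -> float:
        return sum(self.values.values()) + self.residual


def group_attr(phi: np.ndarray, spec: GroupSpec, residual_fixed: bool = False) -> GroupAttribution:
    """Aggregate feature attributions to groups, conserving total mass.

    Raw group values are member sums; the residual group collects features
    outside every named group.  All raw values are then multiplied by the
    single factor ``Σ_i φ_i / (Σ_j raw_j + raw_residual)`` so the grouped
    total equals the feature-level total.  With ``residual_fixed`` the
    residual keeps its raw value and only the named groups are rescaled.
    A ~zero denominator leaves values unscaled with a warning.
    """
    phi = np.asarray(phi, dtype=float).reshape(-1)
    if phi.shape[0] != spec.m:
        raise ValueError(f"attribution length {phi.shape[0]} != spec width {spec.m}")
    if not np.all(np.isfinite(phi)):
        raise ValueError("attributions must be finite")
    raw = {name: float(phi[idx].sum()) for name, idx in spec.groups.items()}
    raw_residual = float(phi[spec.residual].sum())
    total = float(phi.sum())
    scale = max(1.0, abs(total))

    if residual_fixed:
        denom = sum(raw.values())
        numer = total - raw_residual
    else:
        denom = sum(raw.values()) + raw_residual
        numer = total
    if abs(denom) <= _FACTOR_TOL * scale:
        warnings.warn(
            "group attribution: ~zero total raw group mass; skipping renormalization",
            stacklevel=2,
        )
        factor = 1.0
    else:
        factor = numer / denom
    values = {name: v * factor for name, v in raw.items()}
    residual = raw_residual if residual_fixed else raw_residual * factor
    return GroupAttribution(values=values, residual=residual, factor=factor)


def read_gmt(path: str | Path, feature_index: dict[str, int]) -> GroupSpec:
    """Read gene sets in GMT format against a feature-name → index map.

    Each line is ``name<TAB>description<TAB>member1<TAB>member2…``.  Members
    absent from ``feature_index`` are dropped (count logged); sets that are
    empty after filtering are dropped with a warning.
    """
    groups: dict[str, list[int]] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected name, description and at least "
                    f"one member (tab-separated), got {len(parts)} field(s)"
                )
            name, members = parts[0], set(parts[2:])
            known = sorted(feature_index[g] for g in members if g in feature_index)
            n_dropped += len(members) - len(known)
            if not known:
                warnings.warn(f"gene set '{name}' has no known members; dropped", stacklevel=2)
                continue
            groups[name] = known
    if n_dropped:
        logger.info("read_gmt: dropped %d member(s) absent from the feature map", n_dropped)
    return GroupSpec(groups, m=len(feature_index))
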