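"""Total-mortality arithmetic on the integer percent grid.

Total mortality of benthic fauna is the direct mortality from substrate
extraction plus the indirect mortality of the fauna that survived it:

    total = direct + indirect * (1 - direct)

with mortalities expressed as proportions.  All distributional versions of
this combination are computed by numerical approximation on the integer
percent grid 0..100 (1% accuracy) and mapped back to the five ordinal
mortality classes used by the network variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bn_core import CPT, VariableSpec

__all__ = [
    "MortalityClassScheme",
    "DEFAULT_SCHEME",
    "GRID_SIZE",
    "class_to_grid",
    "grid_to_class",
    "combine_mortality",
    "direct_mortality_from_intensity",
    "build_total_mortality_cpt",
]

#: number of integer percent grid points (0..100 inclusive)
GRID_SIZE = 101

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class MortalityClassScheme:
    """Ordered, disjoint integer percent intervals covering 0..100."""

    bounds: tuple[tuple[int, int], ...] = ((0, 10), (11, 30), (31, 60), (61, 80), (81, 100))

    def __post_init__(self) -> None:
        prev_hi = -1
        for lo, hi in self.bounds:
            if lo != prev_hi + 1 or hi < lo:
                raise ValueError(f"intervals must be ordered, disjoint and gapless: {self.bounds}")
            prev_hi = hi
        if self.bounds[0][0] != 0 or self.bounds[-1][1] != 100:
            raise ValueError("intervals must cover 0..100")

    @property
    def n_classes(self) -> int:
        return len(self.bounds)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"{lo}-{hi}%" for lo, hi in self.bounds)

    @property
    def widths(self) -> tuple[int, ...]:
        """Number of integer grid points inside each interval."""
        return tuple(hi - lo + 1 for lo, hi in self.bounds)

    @property
    def midpoints(self) -> tuple[float, ...]:
        return tuple((lo + hi) / 2 for lo, hi in self.bounds)

    def class_of(self, percent: int) -> int:
        if not 0 <= percent <= 100:
            raise ValueError(f"grid value outside 0-100: {percent}")
        for k, (lo, hi) in enumerate(self.bounds):
            if lo <= percent <= hi:
                return k
        raise AssertionError("unreachable: scheme covers 0..100")


DEFAULT_SCHEME = MortalityClassScheme()


def _check_dist(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"{name} must be a 1-d probability vector")
    if (p < 0).any():
        raise ValueError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"{name} does not sum to 1 (sum={p.sum()!r})")
    return p


def class_to_grid(class_dist: Sequence[float], scheme: MortalityClassScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Spread each class mass uniformly over the integer percents of its interval."""
    p = _check_dist(np.asarray(class_dist, dtype=float), "class distribution")
    if p.size != scheme.n_classes:
        raise ValueError(f"expected {scheme.n_classes} class masses, got {p.size}")
    grid = np.zeros(GRID_SIZE)
    for mass, (lo, hi) in zip(p, scheme.bounds):
        grid[lo : hi + 1] += mass / (hi - lo + 1)
    return grid


def grid_to_class(grid_dist: Sequence[float], scheme: MortalityClassScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Assign each grid point's mass to its containing class interval."""
    g = _check_dist(np.asarray(grid_dist, dtype=float), "grid distribution")
    if g.size != GRID_SIZE:
        raise ValueError(f"grid distribution must have {GRID_SIZE} points, got {g.size}")
    out = np.zeros(scheme.n_classes)
    for k, (lo, hi) in enumerate(scheme.bounds):
        out[k] = g[lo : hi + 1].sum()
    return out


def combine_mortality(direct: Sequence[float], indirect: Sequence[float]) -> np.ndarray:
    """Distribution of total mortality from independent direct and indirect grids.

    For every grid pair (d, i) the total is ``d + i * (100 - d) / 100``,
    rounded half-up to the nearest integer percent; the pair's joint mass
    ``p(d) * p(i)`` accumulates there.
    """
    pd_ = _check_dist(np.asarray(direct, dtype=float), "direct")
    pi_ = _check_dist(np.asarray(indirect, dtype=float), "indirect")
    if pd_.size != GRID_SIZE or pi_.size != GRID_SIZE:
        raise ValueError(f"grid distributions must have {GRID_SIZE} points")
    d = np.arange(GRID_SIZE, dtype=float)[:, None]
    i = np.arange(GRID_SIZE, dtype=float)[None, :]
    total = d + i * (100.0 - d) / 100.0
    idx = np.floor(total + 0.5).astype(int)  # round half-up
    joint = pd_[:, None] * pi_[None, :]
    out = np.zeros(GRID_SIZE)
    np.add.at(out, idx, joint)
    s = out.sum()
    if abs(s - 1.0) > _SUM_TOL:
        raise AssertionError(f"mass not conserved in combination: {s!r}")
    return out


def direct_mortality_from_intensity(intensity: int, dispersion: int = 0) -> np.ndarray:
    """Grid distribution of direct mortality for a mining-intensity state.

    Direct mortality is taken as directly proportionate to the mined share:
    a point mass at `intensity` percent by default.  ``dispersion`` widens it
    to a uniform over ``intensity +- dispersion`` integer percents (mean
    preserved; the widened support must stay inside 0..100).
    """
    if intensity not in (50, 75, 100):
        raise ValueError(f"unknown mining intensity state: {intensity!r} (expected 50, 75 or 100)")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    lo, hi = intensity - dispersion, intensity + dispersion
    if lo < 0 or hi > 100:
        raise ValueError(f"dispersion {dispersion} pushes support outside 0-100 for intensity {intensity}")
    grid = np.zeros(GRID_SIZE)
    grid[lo : hi + 1] = 1.0 / (hi - lo + 1)
    return grid


def build_total_mortality_cpt(
    child: str,
    direct_parent: VariableSpec,
    indirect_parent: VariableSpec,
    scheme: MortalityClassScheme = DEFAULT_SCHEME,
) -> CPT:
    """Deterministic CPT for a total-mortality node over the 5-class scheme.

    Each of the 25 (direct class, indirect class) rows is computed by
    expanding both classes to the 1% grid, combining, and collapsing back to
    classes.
    """
    labels = scheme.labels
    for spec in (direct_parent, indirect_parent):
        if tuple(spec.states) != labels:
            raise ValueError(
                f"parent {spec.name!r} states {spec.states} are not the mortality class scheme {labels}"
            )
    k = scheme.n_classes
    table = np.zeros((k, k, k))
    eye = np.eye(k)
    for di in range(k):
        d_grid = class_to_grid(eye[di], scheme)
        for ii in range(k):
            i_grid = class_to_grid(eye[ii], scheme)
            table[di, ii] = grid_to_class(combine_mortality(d_grid, i_grid), scheme)
    return CPT(child=child, parents=(direct_parent.name, indirect_parent.name), table=table)
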