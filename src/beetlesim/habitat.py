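"""Spatial forest: a square lattice of 5 m x 5 m tree patches.

Every patch holds exactly one tree carrying a *primary attractiveness*
(PA) value on an abstract 0-9 scale.  PA = 0 marks a non-host; PA is
inverse to the tree's resistance against mass attack.  Three habitat
types are supported:

``resistant``
    PA drawn uniformly from {0, 1, 2, 3} for every tree.
``susceptible``
    PA drawn uniformly from {6, 7, 8, 9}.
``scattered``
    A resistant matrix in which a fraction ``p`` (percent) of trees is
    replaced by highly attractive trees of a fixed PA (default 8).

The dispersal source sits on the central patch; habitats are isotropic
around it.  Distances are measured between patch centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RESISTANT = "resistant"
SCATTERED = "scattered"
SUSCEPTIBLE = "susceptible"
HABITAT_TYPES = (RESISTANT, SCATTERED, SUSCEPTIBLE)

#: PA support of the resistant matrix / the susceptible habitat.
RESISTANT_PA_RANGE = (0, 1, 2, 3)
SUSCEPTIBLE_PA_RANGE = (6, 7, 8, 9)

PA_MIN, PA_MAX = 0, 9
PATCH_SIZE_M = 5.0

#: Default lattice side (patches).  448 x 448 patches of 5 m ~= 501.8 ha,
#: leaving > 1.1 km of headroom from the central source to every edge.
DEFAULT_GRID_SIDE = 448

#: Attack threshold endpoints: the least susceptible attackable host
#: (PA = 1) resists up to 199 simultaneous attackers, the most
#: susceptible one (PA = 9) only up to 29.
THRESHOLD_AT_PA1 = 200.0
THRESHOLD_AT_PA9 = 30.0
_THRESHOLD_SLOPE = (THRESHOLD_AT_PA1 - THRESHOLD_AT_PA9) / 8.0  # 21.25

# Tree / patch status codes (shared with the engine).
UNATTACKED, UNDER_ATTACK, INFESTED, RESISTED = 0, 1, 2, 3
STATUS_NAMES = ("unattacked", "under_attack", "infested", "resisted")


@dataclass(frozen=True)
class HabitatConfig:
    """Static description of the forest lattice.

    ``scattered_fraction`` is a percentage in (0, 100]; it is only used
    when ``habitat_type == "scattered"``.
    """

    habitat_type: str = RESISTANT
    grid_side: int = DEFAULT_GRID_SIDE
    patch_size: float = PATCH_SIZE_M
    scattered_fraction: float = 1.0
    scattered_pa: int = 8

    def __post_init__(self) -> None:
        if self.habitat_type not in HABITAT_TYPES:
            raise ValueError(f"unknown habitat_type {self.habitat_type!r}")
        if self.grid_side < 1:
            raise ValueError("grid_side must be positive")
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if self.habitat_type == SCATTERED:
            if not (0.0 < self.scattered_fraction <= 100.0):
                raise ValueError("scattered_fraction must be in (0, 100]")
            if not (PA_MIN < self.scattered_pa <= PA_MAX):
                raise ValueError("scattered_pa must be in 1..9")

    @property
    def source(self) -> tuple[int, int]:
        """(col, row) of the central source patch."""
        return (self.grid_side // 2, self.grid_side // 2)

    @property
    def area_ha(self) -> float:
        return (self.grid_side * self.patch_size) ** 2 / 1e4


@dataclass(frozen=True)
class Tree:
    """One tree patch, as a record (the lattice itself is array-backed)."""

    col: int
    row: int
    pa: int
    n_attackers: int = 0
    status: str = "unattacked"
    distance_to_source: float = 0.0

    def __post_init__(self) -> None:
        if not (PA_MIN <= self.pa <= PA_MAX):
            raise ValueError("PA out of range 0..9")
        if self.n_attackers < 0:
            raise ValueError("attacker count must be non-negative")


def resistance_threshold(pa: int, scale: float = 1.0) -> int:
    """Minimum simultaneous attacker count that overcomes a host's defense.

    Linear in PA with R(1) = 200 and R(9) = 30, rounded to the nearest
    integer (half up).  PA = 0 is a non-host and has no threshold.
    ``scale`` shrinks the threshold proportionally for population-scaled
    runs (never below 1).
    """
    if not (PA_MIN < pa <= PA_MAX):
        raise ValueError(f"resistance threshold undefined for PA={pa}")
    value = THRESHOLD_AT_PA1 - _THRESHOLD_SLOPE * (pa - 1)
    return max(1, math.floor(value * scale + 0.5))


def resistance_thresholds(pa: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Vectorized :func:`resistance_threshold`; PA = 0 maps to +inf."""
    pa = np.asarray(pa)
    value = THRESHOLD_AT_PA1 - _THRESHOLD_SLOPE * (pa.astype(float) - 1.0)
    thr = np.maximum(1.0, np.floor(value * scale + 0.5))
    return np.where(pa <= 0, np.inf, thr)


def perception_offsets(
    radius: float, patch_size: float = PATCH_SIZE_M
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lattice offsets within ``radius`` meters of a patch center.

    Returns ``(dx, dy, d2)`` with ``d2`` the squared offset in patch
    units, sorted by (d2, dx, dy) so that scans are deterministic and
    distance-ordered.  Includes (0, 0).
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    rmax = int(radius // patch_size)
    out = []
    for dx in range(-rmax, rmax + 1):
        for dy in range(-rmax, rmax + 1):
            d2 = dx * dx + dy * dy
            if d2 * patch_size * patch_size <= radius * radius:
                out.append((d2, dx, dy))
    out.sort()
    d2 = np.array([o[0] for o in out], dtype=np.int64)
    dx = np.array([o[1] for o in out], dtype=np.int64)
    dy = np.array([o[2] for o in out], dtype=np.int64)
    return dx, dy, d2


class Habitat:
    """The static forest: PA lattice plus source geometry."""

    def __init__(self, config: HabitatConfig, pa: np.ndarray, seed=None):
        pa = np.asarray(pa, dtype=np.int64)
        if pa.shape != (config.grid_side, config.grid_side):
            raise ValueError("PA grid shape does not match config")
        if pa.min() < PA_MIN or pa.max() > PA_MAX:
            raise ValueError("PA values out of range 0..9")
        self.config = config
        self.pa = pa
        self.seed = seed
        self._distances: np.ndarray | None = None

    @property
    def grid_side(self) -> int:
        return self.config.grid_side

    @property
    def source(self) -> tuple[int, int]:
        return self.config.source

    def distance_m(self, col: int, row: int) -> float:
        sc, sr = self.source
        return self.config.patch_size * math.hypot(col - sc, row - sr)

    def distances(self) -> np.ndarray:
        """Patch-center distance to the source for every patch (meters)."""
        if self._distances is None:
            side = self.grid_side
            sc, sr = self.source
            cols = np.arange(side)[:, None] - sc
            rows = np.arange(side)[None, :] - sr
            self._distances = self.config.patch_size * np.hypot(cols, rows)
        return self._distances

    def on_grid(self, col: int, row: int) -> bool:
        return 0 <= col < self.grid_side and 0 <= row < self.grid_side

    def tree(self, col: int, row: int, n_attackers: int = 0,
             status: int = UNATTACKED) -> Tree:
        if not self.on_grid(col, row):
            raise ValueError(f"position ({col}, {row}) off grid")
        return Tree(
            col=col,
            row=row,
            pa=int(self.pa[col, row]),
            n_attackers=n_attackers,
            status=STATUS_NAMES[status],
            distance_to_source=self.distance_m(col, row),
        )

    def to_frame(self) -> pd.DataFrame:
        side = self.grid_side
        cols, rows = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        return pd.DataFrame(
            {"col": cols.ravel(), "row": rows.ravel(), "pa": self.pa.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: HabitatConfig | None = None) -> "Habitat":
        df = pd.read_csv(path)
        side = int(df["col"].max()) + 1
        if config is None:
            config = HabitatConfig(habitat_type=RESISTANT, grid_side=side)
        pa = np.zeros((side, side), dtype=np.int64)
        pa[df["col"].to_numpy(), df["row"].to_numpy()] = df["pa"].to_numpy()
        return cls(config, pa)


def generate_habitat(config: HabitatConfig, rng_seed) -> Habitat:
    """Draw a forest lattice for one simulation run.

    Deterministic for a given ``(config, rng_seed)``.  Draw order:
    the base PA field first, then (scattered only) the replacement mask.
    """
    rng = np.random.default_rng(rng_seed)
    side = config.grid_side
    if config.habitat_type == SUSCEPTIBLE:
        pa = rng.integers(6, 10, size=(side, side))
    else:
        pa = rng.integers(0, 4, size=(side, side))
        if config.habitat_type == SCATTERED:
            mask = rng.random((side, side)) < config.scattered_fraction / 100.0
            pa = np.where(mask, config.scattered_pa, pa)
    return Habitat(config, pa, seed=rng_seed)


def trees_in_radius(
    habitat: Habitat, position: tuple[int, int], radius: float,
    n_attackers: np.ndarray | None = None,
    status: np.ndarray | None = None,
) -> list[Tree]:
    """All trees whose patch center lies within ``radius`` meters.

    At ``radius == 0`` only the occupied patch's tree is returned.
    Clipped at the lattice edges.  Optional ``n_attackers`` / ``status``
    arrays attach dynamic state to the returned records.
    """
    col, row = position
    if not habitat.on_grid(col, row):
        raise ValueError(f"position {position} off grid")
    dx, dy, _ = perception_offsets(radius, habitat.config.patch_size)
    out = []
    for ddx, ddy in zip(dx, dy):
        c, r = col + int(ddx), row + int(ddy)
        if not habitat.on_grid(c, r):
            continue
        n = int(n_attackers[c, r]) if n_attackers is not None else 0
        s = int(status[c, r]) if status is not None else UNATTACKED
        out.append(habitat.tree(c, r, n_attackers=n, status=s))
    return out
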