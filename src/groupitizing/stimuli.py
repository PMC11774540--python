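"""Generation of grouped and ungrouped numerosity stimulus arrays.

Stimuli are arrays of small square items briefly flashed around a central
fixation point. Two spatial arrangements are supported:

* **ungrouped** — item positions drawn without replacement from the centers
  of a regular grid tiling a square stimulus area, with a rectangular
  exclusion zone around fixation;
* **grouped** — the numerosity is split into 2–4 subgroups (each of 1–5
  items), every subgroup is placed in its own peripheral quadrant, and item
  positions are drawn without replacement from a fixed set of slots inside
  that quadrant.

All coordinates are in degrees of visual angle, fixation at the origin,
x rightward, y upward; positions are item centers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "GridSpec",
    "QuadrantSpec",
    "GroupConfiguration",
    "StimulusArray",
    "build_ungrouped_grid",
    "configuration_table",
    "sample_ungrouped",
    "sample_grouped",
]


class StimulusSpecError(ValueError):
    """Invalid geometry or configuration for stimulus generation."""


class CapacityError(StimulusSpecError):
    """Requested more items than available positions."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the ungrouped-stimulus position grid.

    The stimulus area is tiled with as many whole ``cell_size`` cells as fit
    per axis, centered on fixation; cells whose centers fall strictly inside
    the central exclusion rectangle are removed. With the defaults this
    yields an 11 x 11 tiling minus a 5 x 3 central block = 106 positions.
    """

    area_width: float = 6.0
    area_height: float = 6.0
    cell_size: float = 0.54
    exclusion_width: float = 2.73
    exclusion_height: float = 1.64
    item_size: float = 0.4

    def __post_init__(self) -> None:
        for name in ("area_width", "area_height", "cell_size", "item_size"):
            if getattr(self, name) <= 0:
                raise StimulusSpecError(f"{name} must be > 0")
        if self.exclusion_width < 0 or self.exclusion_height < 0:
            raise StimulusSpecError("exclusion dimensions must be >= 0")
        if (self.exclusion_width > self.area_width
                or self.exclusion_height > self.area_height):
            raise StimulusSpecError("exclusion zone must fit inside the stimulus area")


@dataclass(frozen=True)
class QuadrantSpec:
    """Geometry of the four peripheral quadrants used for grouped stimuli.

    Quadrant centers sit on the diagonals at ``eccentricity`` degrees from
    fixation, i.e. at (+-e/sqrt(2), +-e/sqrt(2)). Each quadrant holds a
    ``slot_columns`` x ``slot_rows`` grid of item slots (12 by default).
    """

    quadrant_width: float = 1.64
    quadrant_height: float = 2.2
    eccentricity: float = 3.0
    slot_columns: int = 3
    slot_rows: int = 4

    def __post_init__(self) -> None:
        if min(self.quadrant_width, self.quadrant_height, self.eccentricity) <= 0:
            raise StimulusSpecError("quadrant dimensions and eccentricity must be > 0")
        if self.slot_columns < 1 or self.slot_rows < 1:
            raise StimulusSpecError("slot layout must have >= 1 row and column")

    @property
    def slots_per_quadrant(self) -> int:
        return self.slot_columns * self.slot_rows

    def quadrant_centers(self) -> np.ndarray:
        """Centers of the four quadrants, ordered I..IV (counterclockwise
        from upper-right)."""
        e = self.eccentricity / math.sqrt(2.0)
        return np.array([[e, e], [-e, e], [-e, -e], [e, -e]])

    def slot_positions(self, quadrant: int) -> np.ndarray:
        """Slot centers (n_slots, 2) of one quadrant (0-based index)."""
        cx, cy = self.quadrant_centers()[quadrant]
        w, h = self.quadrant_width, self.quadrant_height
        xs = (np.arange(self.slot_columns) - (self.slot_columns - 1) / 2) * (w / self.slot_columns)
        ys = (np.arange(self.slot_rows) - (self.slot_rows - 1) / 2) * (h / self.slot_rows)
        gx, gy = np.meshgrid(xs, ys, indexing="xy")
        return np.column_stack([gx.ravel() + cx, gy.ravel() + cy])


@dataclass(frozen=True)
class GroupConfiguration:
    """A partition of a numerosity into subitizable subgroups."""

    numerosity: int
    subgroup_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if sum(self.subgroup_sizes) != self.numerosity:
            raise StimulusSpecError(
                f"subgroup sizes {self.subgroup_sizes} do not sum to {self.numerosity}")
        if not all(1 <= s <= 5 for s in self.subgroup_sizes):
            raise StimulusSpecError("each subgroup must contain 1-5 items")
        if not 2 <= len(self.subgroup_sizes) <= 4:
            raise StimulusSpecError("numerosity must be split into 2-4 subgroups")

    @property
    def label(self) -> str:
        return ",".join(str(s) for s in self.subgroup_sizes)


@dataclass(frozen=True)
class StimulusArray:
    """One sampled stimulus: item positions plus arrangement metadata."""

    arrangement: str  # "grouped" | "ungrouped"
    numerosity: int
    positions: tuple[tuple[float, float], ...]
    seed: int
    configuration: GroupConfiguration | None = None
    group_assignment: tuple[int, ...] | None = field(default=None)

    def to_dict(self) -> dict:
        d = {
            "arrangement": self.arrangement,
            "numerosity": self.numerosity,
            "seed": self.seed,
            "positions": [list(p) for p in self.positions],
            "configuration": self.configuration.label if self.configuration else None,
            "group_assignment": list(self.group_assignment) if self.group_assignment else None,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def build_ungrouped_grid(spec: GridSpec = GridSpec()) -> np.ndarray:
    """Centers of the grid cells available to ungrouped stimuli.

    Returns an (n, 2) array. Cells whose centers lie strictly inside the
    central exclusion rectangle are dropped; with default geometry n == 106.
    """
    nx = int(spec.area_width / spec.cell_size + 1e-9)
    ny = int(spec.area_height / spec.cell_size + 1e-9)
    xs = (np.arange(nx) - (nx - 1) / 2) * spec.cell_size
    ys = (np.arange(ny) - (ny - 1) / 2) * spec.cell_size
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    pos = np.column_stack([gx.ravel(), gy.ravel()])
    inside = (np.abs(pos[:, 0]) < spec.exclusion_width / 2) & (
        np.abs(pos[:, 1]) < spec.exclusion_height / 2)
    return pos[~inside]


# Partitions presented for each numerosity, three per numerosity in fixed
# presentation order; one block shows each entry once (36 trials).
_CONFIGURATIONS: tuple[tuple[int, tuple[int, ...]], ...] = (
    (5, (2, 2, 1)), (5, (3, 2)), (5, (1, 1, 1, 2)),
    (6, (3, 3)), (6, (2, 2, 2)), (6, (3, 2, 1)),
    (7, (3, 3, 1)), (7, (2, 2, 2, 1)), (7, (3, 2, 1, 1)),
    (8, (3, 3, 2)), (8, (2, 2, 2, 2)), (8, (4, 4)),
    (9, (4, 3, 2)), (9, (4, 4, 1)), (9, (3, 3, 3)),
    (10, (3, 3, 3, 1)), (10, (4, 4, 2)), (10, (2, 2, 2, 4)),
    (11, (4, 4, 2, 1)), (11, (3, 3, 3, 2)), (11, (3, 4, 3, 1)),
    (12, (3, 3, 3, 3)), (12, (4, 4, 4)), (12, (4, 2, 3, 3)),
    (13, (5, 5, 3)), (13, (4, 4, 4, 1)), (13, (4, 3, 4, 2)),
    (14, (4, 4, 3, 3)), (14, (4, 4, 4, 2)), (14, (3, 3, 3, 5)),
    (15, (4, 4, 4, 3)), (15, (5, 4, 4, 2)), (15, (5, 5, 4, 1)),
    (16, (4, 4, 4, 4)), (16, (4, 4, 3, 5)), (16, (5, 5, 4, 2)),
)


def configuration_table() -> list[GroupConfiguration]:
    """The 36 grouped configurations (numerosities 5-16, three each)."""
    return [GroupConfiguration(n, sizes) for n, sizes in _CONFIGURATIONS]


def sample_ungrouped(n: int, spec: GridSpec = GridSpec(), seed: int = 0) -> StimulusArray:
    """Sample ``n`` distinct grid positions uniformly without replacement."""
    grid = build_ungrouped_grid(spec)
    if not 1 <= n <= len(grid):
        raise CapacityError(
            f"numerosity {n} outside grid capacity 1..{len(grid)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(grid), size=n, replace=False)
    positions = tuple(map(tuple, grid[idx]))
    return StimulusArray("ungrouped", n, positions, seed)


def sample_grouped(config: GroupConfiguration,
                   spec: QuadrantSpec = QuadrantSpec(),
                   seed: int = 0) -> StimulusArray:
    """Place each subgroup of ``config`` in its own random quadrant.

    The subgroup-to-quadrant assignment is drawn first (without replacement
    over the four quadrants, in the order the sizes are listed), then item
    slots are drawn without replacement within each quadrant.
    """
    sizes = config.subgroup_sizes
    if len(sizes) > 4:
        raise StimulusSpecError("at most 4 subgroups (one per quadrant)")
    if max(sizes) > spec.slots_per_quadrant:
        raise CapacityError(
            f"subgroup of {max(sizes)} items exceeds {spec.slots_per_quadrant} slots")
    rng = np.random.default_rng(seed)
    quadrants = rng.choice(4, size=len(sizes), replace=False)
    positions: list[tuple[float, float]] = []
    assignment: list[int] = []
    for gi, (size, quad) in enumerate(zip(sizes, quadrants)):
        slots = spec.slot_positions(int(quad))
        idx = rng.choice(len(slots), size=size, replace=False)
        positions.extend(map(tuple, slots[idx]))
        assignment.extend([gi] * size)
    return StimulusArray("grouped", config.numerosity, tuple(positions), seed,
                         configuration=config, group_assignment=tuple(assignment))
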