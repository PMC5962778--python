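"""Discrete 2-D grid world: geometry, entity placement and motion.

The simulated infant's workspace is a square grid of ``area_width`` x
``area_height`` squares (default 15 x 15 squares of 4 cm, i.e. a 60 x 60 cm
reachable area, the span of the outstretched arms).  The area partitions into
3 x 3 proprioceptive blocks of ``block_size`` squares (20 x 20 cm); the
central block doubles as the center of the visual field, the target region of
hand regard.  The field of view covers every column but excludes the row
nearest the body.

Coordinate conventions
----------------------
Positions are ``(col, row)`` pairs of 0-based square indices with the origin
at the top-left; ``x`` increases to the right and "up" means a *decreasing*
row index (away from the body, which sits at the bottom edge).  Metric
coordinates used by the motor-error equations are the centers of squares:
``x_cm = (col + 0.5) * square_size`` and ``y_cm`` measured upward from the
body edge, ``y_cm = (area_height - row - 0.5) * square_size``, so that the
centering servo's positive "upward" error corresponds to an upward move.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Coord = tuple[int, int]

#: Unit moves for the 4-neighborhood used by the distractor's random walk.
_NEIGHBOR_STEPS: tuple[Coord, ...] = ((1, 0), (0, -1), (-1, 0), (0, 1))


class ConfigurationError(ValueError):
    """Raised when a geometry or placement request is unsatisfiable."""


@dataclass(frozen=True)
class GridGeometry:
    """Layout of the movable area, its proprioceptive blocks and the FOV.

    Parameters
    ----------
    area_width, area_height
        Size of the movable area in squares.  Must equal ``3 * block_size``
        on both axes so the area partitions exactly into 3 x 3 blocks.
    square_size
        Side of one square in cm (default 4 cm; 15 squares span 60 cm).
    block_size
        Side of one proprioceptive block in squares (default 5, i.e. 20 cm).
    fov_rows, fov_cols
        Half-open ``(start, stop)`` ranges of rows/columns inside the field
        of view.  Default: all columns, rows ``0..area_height-2`` (the row
        nearest the body is not visible), giving 15 x 14 = 210 FOV squares.
    """

    area_width: int = 15
    area_height: int = 15
    square_size: float = 4.0
    block_size: int = 5
    fov_cols: tuple[int, int] = field(default=None)  # type: ignore[assignment]
    fov_rows: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fov_cols is None:
            object.__setattr__(self, "fov_cols", (0, self.area_width))
        if self.fov_rows is None:
            object.__setattr__(self, "fov_rows", (0, self.area_height - 1))
        if self.area_width != 3 * self.block_size:
            raise ConfigurationError(
                f"area_width={self.area_width} must equal 3*block_size="
                f"{3 * self.block_size} (3x3 block partition)"
            )
        if self.area_height != 3 * self.block_size:
            raise ConfigurationError(
                f"area_height={self.area_height} must equal 3*block_size="
                f"{3 * self.block_size} (3x3 block partition)"
            )
        c0, c1 = self.fov_cols
        r0, r1 = self.fov_rows
        if not (0 <= c0 < c1 <= self.area_width and 0 <= r0 < r1 <= self.area_height):
            raise ConfigurationError("fov rectangle must lie inside the movable area")
        # The center block must be visible.
        bs = self.block_size
        if not (c0 <= bs and 2 * bs <= c1 and r0 <= bs and 2 * bs <= r1):
            raise ConfigurationError("center block must lie inside the field of view")

    # -- metric frame -----------------------------------------------------

    @property
    def d(self) -> float:
        """Block pitch in cm (side of one proprioceptive block)."""
        return self.block_size * self.square_size

    @property
    def x0(self) -> float:
        """x (cm) of the centers of the leftmost column of blocks."""
        return (self.block_size // 2 + 0.5) * self.square_size

    @property
    def y0(self) -> float:
        """y (cm) of the centers of the bottom row of blocks (nearest body)."""
        row_c = 2 * self.block_size + self.block_size // 2
        return (self.area_height - row_c - 0.5) * self.square_size

    def square_center_cm(self, pos: Coord) -> tuple[float, float]:
        col, row = pos
        return (
            (col + 0.5) * self.square_size,
            (self.area_height - row - 0.5) * self.square_size,
        )

    # -- membership -------------------------------------------------------

    def contains(self, pos: Coord) -> bool:
        col, row = pos
        return 0 <= col < self.area_width and 0 <= row < self.area_height

    def in_fov(self, pos: Coord) -> bool:
        col, row = pos
        return (
            self.fov_cols[0] <= col < self.fov_cols[1]
            and self.fov_rows[0] <= row < self.fov_rows[1]
        )

    @property
    def n_fov_squares(self) -> int:
        return (self.fov_cols[1] - self.fov_cols[0]) * (
            self.fov_rows[1] - self.fov_rows[0]
        )

    # -- proprioceptive blocks -------------------------------------------

    def block_index(self, pos: Coord) -> tuple[int, int]:
        """``(bcol, brow)`` of the block containing ``pos`` (each in 0..2)."""
        col, row = pos
        return col // self.block_size, row // self.block_size

    def block_center_square(self, bcol: int, brow: int) -> Coord:
        half = self.block_size // 2
        return bcol * self.block_size + half, brow * self.block_size + half

    def block_center_cm(self, bcol: int, brow: int) -> tuple[float, float]:
        return self.square_center_cm(self.block_center_square(bcol, brow))


def in_center(pos: Coord, geometry: GridGeometry) -> bool:
    """True iff ``pos`` lies in the central block (center of the FOV)."""
    return geometry.block_index(pos) == (1, 1)


def perceived_block(pos: Coord, geometry: GridGeometry) -> tuple[float, float]:
    """Proprioceptively perceived hand position in cm.

    The position is quantized to the center of the containing 20 x 20 cm
    block, modelling a +/-10 cm proprioceptive error: the perceived
    coordinates take one of the nine block-center values ``x0 + i*d``,
    ``y0 + j*d`` with ``i, j`` in 0..2.
    """
    bcol, brow = geometry.block_index(pos)
    return geometry.block_center_cm(bcol, brow)


@dataclass(frozen=True)
class MoveCommand:
    """One-step hand displacements in square units.

    ``dx`` is the column delta (+1 = rightward), ``dy`` the row delta
    (-1 = upward, away from the body).  Magnitudes never exceed 1: hands
    move at most one square per time step.
    """

    dx_left: int = 0
    dy_left: int = 0
    dx_right: int = 0
    dy_right: int = 0

    def __post_init__(self) -> None:
        for v in (self.dx_left, self.dy_left, self.dx_right, self.dy_right):
            if abs(v) > 1:
                raise ValueError("hand moves are limited to one square per axis")


ZERO_COMMAND = MoveCommand()


@dataclass
class WorldState:
    """Positions of both hands and the distractor objects at time ``t``."""

    left_hand: Coord
    right_hand: Coord
    others: list[Coord]
    t: int = 0


def _sample_square(
    geometry: GridGeometry, rng: np.random.Generator, fov_only: bool
) -> Coord:
    if fov_only:
        (c0, c1), (r0, r1) = geometry.fov_cols, geometry.fov_rows
    else:
        c0, c1, r0, r1 = 0, geometry.area_width, 0, geometry.area_height
    return int(rng.integers(c0, c1)), int(rng.integers(r0, r1))


def _others_in_fov(case) -> bool:
    # Distractors are confined to the field of view during the test phase.
    return getattr(case, "phase", "training") == "test"


def _place_entities(
    world: WorldState, geometry: GridGeometry, case, rng: np.random.Generator
) -> None:
    fov_only = _others_in_fov(case)
    n_others = case.n_others
    region = geometry.n_fov_squares if fov_only else geometry.area_width * geometry.area_height
    if n_others > region:
        raise ConfigurationError(
            f"{n_others} distractors do not fit in a {region}-square region"
        )
    # Fixed sampling order (left, right, others) keeps seeded runs replayable.
    world.left_hand = _sample_square(geometry, rng, fov_only=False)
    world.right_hand = _sample_square(geometry, rng, fov_only=False)
    world.others = [_sample_square(geometry, rng, fov_only) for _ in range(n_others)]


def init_world(geometry: GridGeometry, case, rng: np.random.Generator) -> WorldState:
    """Place hands and distractors uniformly at random; ``t = 0``.

    Hands are placed anywhere in the movable area.  Distractors are placed in
    the whole area during training and inside the FOV during the test phase.
    """
    world = WorldState(left_hand=(0, 0), right_hand=(0, 0), others=[], t=0)
    _place_entities(world, geometry, case, rng)
    return world


def schedule_due(t: int, period: int) -> bool:
    """True when a periodic event (reposition / distractor move) fires at ``t``."""
    return t > 0 and t % period == 0


def reposition(
    world: WorldState, geometry: GridGeometry, case, rng: np.random.Generator
) -> WorldState:
    """Re-place all entities at random (every 1,000 steps); ``t`` preserved."""
    _place_entities(world, geometry, case, rng)
    return world


def step_other(
    world: WorldState, geometry: GridGeometry, case, rng: np.random.Generator
) -> WorldState:
    """Each distractor takes one uniformly random 4-neighborhood step.

    A proposal that would leave the allowed region (whole area in training,
    FOV in the test phase, where the distractor is kept in view) is rejected
    and the distractor stays in place.
    """
    fov_only = _others_in_fov(case)
    allowed = geometry.in_fov if fov_only else geometry.contains
    for i, (col, row) in enumerate(world.others):
        dx, dy = _NEIGHBOR_STEPS[int(rng.integers(4))]
        cand = (col + dx, row + dy)
        if allowed(cand):
            world.others[i] = cand
    return world


def _clamp(v: int, lo: int, hi: int) -> int:
    return lo if v < lo else hi if v > hi else v


def apply_moves(world: WorldState, cmd: MoveCommand, geometry: GridGeometry) -> WorldState:
    """Translate both hands by the command, clamped to the area; ``t += 1``."""
    w, h = geometry.area_width - 1, geometry.area_height - 1
    lx, ly = world.left_hand
    rx, ry = world.right_hand
    world.left_hand = (_clamp(lx + cmd.dx_left, 0, w), _clamp(ly + cmd.dy_left, 0, h))
    world.right_hand = (_clamp(rx + cmd.dx_right, 0, w), _clamp(ry + cmd.dy_right, 0, h))
    world.t += 1
    return world
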