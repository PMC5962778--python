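"""Input encoding: visual field, proprioceptive blocks, corollary discharge.

Every time step the network sees one flat input vector (default 238 units):

* **visual** — one unit per FOV square (default 15 x 14 = 210).  A square
  containing a hand contributes the hand visual value (0.5 in training), a
  square containing a distractor the distractor value (0.2 in training);
  empty squares are 0.  A hand occluding a distractor wins.
* **proprioceptive** — per hand, a one-hot code over the nine 20 x 20 cm
  blocks (2 x 9 = 18 units): the perceived hand position quantized to a
  block center.
* **corollary discharge** — per hand, four direction units
  (right/up/left/down) plus one no-move unit (2 x 5 = 10 units), signalling
  the direction of the movement occurring at this step (the simplified
  forward model's prediction from the efference copy; distances ignored).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .world import GridGeometry, MoveCommand, WorldState

# Direction unit order inside each hand's corollary-discharge group.
CD_RIGHT, CD_UP, CD_LEFT, CD_DOWN, CD_NOMOVE = range(5)


@dataclass(frozen=True)
class CaseConfig:
    """A stimulus condition: visual values, distractor count, CD gating.

    The training condition is ``(hand 0.5, other 0.2, 1 other, CD on)``.
    Test cases 1-6 vary the distractor value (0.2 or 0.5) and count
    (1, 5 or 20); case 7 equals case 1 with invisible hands and the
    corollary discharge silenced, probing purely proprioceptive control.
    """

    name: str = "training"
    hand_visual_value: float = 0.5
    other_visual_value: float = 0.2
    n_others: int = 1
    cd_enabled: bool = True
    phase: str = "training"  # "training" | "test"

    def __post_init__(self) -> None:
        if self.phase not in ("training", "test"):
            raise ValueError(f"unknown phase {self.phase!r}")


TRAINING_CASE = CaseConfig()

#: Test-phase conditions 1-7.  Cases 1-6 combine distractor visual values
#: (0.2, 0.5) with distractor counts (1, 5, 20); case 7 is case 1 with the
#: hands' visual value and the corollary discharge set to zero.
TEST_CASES: dict[int, CaseConfig] = {
    1: CaseConfig("case1", 0.5, 0.2, 1, True, "test"),
    2: CaseConfig("case2", 0.5, 0.2, 5, True, "test"),
    3: CaseConfig("case3", 0.5, 0.2, 20, True, "test"),
    4: CaseConfig("case4", 0.5, 0.5, 1, True, "test"),
    5: CaseConfig("case5", 0.5, 0.5, 5, True, "test"),
    6: CaseConfig("case6", 0.5, 0.5, 20, True, "test"),
    7: CaseConfig("case7", 0.0, 0.2, 1, False, "test"),
}


@dataclass(frozen=True)
class InputLayout:
    """Index layout of the input vector, derived from the geometry.

    Segment order is fixed: visual, proprio (left then right hand), CD
    (left then right hand).  ``proprio_value`` and ``cd_value`` are the
    magnitudes of active non-visual units (1.0 by default; the visual
    magnitudes live in :class:`CaseConfig`).
    """

    n_visual: int
    fov_cols: tuple[int, int]
    fov_rows: tuple[int, int]
    proprio_value: float = 1.0
    cd_value: float = 1.0

    N_BLOCKS: int = 9
    N_CD: int = 5

    @classmethod
    def from_geometry(
        cls, geometry: GridGeometry, proprio_value: float = 1.0, cd_value: float = 1.0
    ) -> "InputLayout":
        return cls(
            n_visual=geometry.n_fov_squares,
            fov_cols=geometry.fov_cols,
            fov_rows=geometry.fov_rows,
            proprio_value=proprio_value,
            cd_value=cd_value,
        )

    # -- segment slices ---------------------------------------------------

    @property
    def visual(self) -> slice:
        return slice(0, self.n_visual)

    @property
    def proprio_left(self) -> slice:
        return slice(self.n_visual, self.n_visual + self.N_BLOCKS)

    @property
    def proprio_right(self) -> slice:
        return slice(self.n_visual + self.N_BLOCKS, self.n_visual + 2 * self.N_BLOCKS)

    @property
    def cd_left(self) -> slice:
        start = self.n_visual + 2 * self.N_BLOCKS
        return slice(start, start + self.N_CD)

    @property
    def cd_right(self) -> slice:
        start = self.n_visual + 2 * self.N_BLOCKS + self.N_CD
        return slice(start, start + self.N_CD)

    @property
    def cd(self) -> slice:
        """The whole corollary-discharge segment (both hands)."""
        start = self.n_visual + 2 * self.N_BLOCKS
        return slice(start, start + 2 * self.N_CD)

    @property
    def total(self) -> int:
        return self.n_visual + 2 * self.N_BLOCKS + 2 * self.N_CD

    def visual_unit(self, pos: tuple[int, int]) -> int:
        """Index of the visual unit for a FOV square (bijective on the FOV)."""
        col, row = pos
        (c0, c1), (r0, _) = self.fov_cols, self.fov_rows
        return (row - r0) * (c1 - c0) + (col - c0)

    def table(self) -> list[dict]:
        """Human/machine-readable segment table (exported for reproducibility)."""
        segs = [
            ("visual", self.visual, "one unit per FOV square, row-major"),
            ("proprio_left", self.proprio_left, "one-hot block of left hand (brow*3+bcol)"),
            ("proprio_right", self.proprio_right, "one-hot block of right hand"),
            ("cd_left", self.cd_left, "left-hand move direction: right,up,left,down,no-move"),
            ("cd_right", self.cd_right, "right-hand move direction: right,up,left,down,no-move"),
        ]
        return [
            {"segment": name, "start": s.start, "stop": s.stop, "meaning": meaning}
            for name, s, meaning in segs
        ]


def encode_visual(
    world: WorldState,
    geometry: GridGeometry,
    case: CaseConfig,
    layout: InputLayout,
    out: np.ndarray,
) -> np.ndarray:
    """Fill the visual segment of ``out``; entities outside the FOV are dark."""
    seg = out[layout.visual]
    seg[:] = 0.0
    for pos in world.others:
        if geometry.in_fov(pos):
            seg[layout.visual_unit(pos)] = case.other_visual_value
    # Hands written last: a hand occludes a distractor on a shared square.
    for pos in (world.left_hand, world.right_hand):
        if geometry.in_fov(pos):
            seg[layout.visual_unit(pos)] = case.hand_visual_value
    return out


def block_unit(pos: tuple[int, int], geometry: GridGeometry) -> int:
    """Index (0..8) of the one-hot proprioceptive unit for a hand position."""
    bcol, brow = geometry.block_index(pos)
    return brow * 3 + bcol


def encode_proprio(
    world: WorldState, geometry: GridGeometry, layout: InputLayout, out: np.ndarray
) -> np.ndarray:
    """One-hot perceived block per hand (always exactly one active unit)."""
    for sl, pos in (
        (layout.proprio_left, world.left_hand),
        (layout.proprio_right, world.right_hand),
    ):
        seg = out[sl]
        seg[:] = 0.0
        seg[block_unit(pos, geometry)] = layout.proprio_value
    return out


def encode_cd(
    prev_cmd: MoveCommand, case: CaseConfig, layout: InputLayout, out: np.ndarray
) -> np.ndarray:
    """Direction-of-movement units for the command applied this step.

    The active units mirror the nonzero axes of the command (up = row
    decrease); the no-move unit fires when both axes are zero.  With the
    corollary discharge disabled (case 7) the whole segment stays silent.
    """
    out[layout.cd] = 0.0
    if not case.cd_enabled:
        return out
    for sl, dx, dy in (
        (layout.cd_left, prev_cmd.dx_left, prev_cmd.dy_left),
        (layout.cd_right, prev_cmd.dx_right, prev_cmd.dy_right),
    ):
        seg = out[sl]
        if dx == 0 and dy == 0:
            seg[CD_NOMOVE] = layout.cd_value
            continue
        if dx > 0:
            seg[CD_RIGHT] = layout.cd_value
        elif dx < 0:
            seg[CD_LEFT] = layout.cd_value
        if dy < 0:
            seg[CD_UP] = layout.cd_value
        elif dy > 0:
            seg[CD_DOWN] = layout.cd_value
    return out


def build_input(
    world: WorldState,
    prev_cmd: MoveCommand,
    geometry: GridGeometry,
    case: CaseConfig,
    layout: InputLayout,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble the full input vector (visual | proprio | CD)."""
    if out is None:
        out = np.zeros(layout.total)
    elif out.shape[0] < layout.total:
        raise ValueError(
            f"input buffer of length {out.shape[0]} < layout total {layout.total}"
        )
    encode_visual(world, geometry, case, layout, out)
    encode_proprio(world, geometry, layout, out)
    encode_cd(prev_cmd, case, layout, out)
    return out
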