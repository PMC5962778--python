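"""Simplified population-vector decoding of the 8 output units.

Each hand is driven by four output units with preferred directions right,
up, left, down (indices 0-3 for the left hand, 4-7 for the right), each
assumed silent for movements off its preferred direction.  Per axis the
decoder takes the difference of the opposing activities; a difference of at
least the threshold (default 0.8) moves the hand one square in that
direction, otherwise the hand stays.  The two axes are evaluated
independently, so simultaneous triggering yields a diagonal step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .world import MoveCommand

# Output-unit order per hand, matching the motor-error equations:
# preferred directions right, up, left, down.
OUT_RIGHT, OUT_UP, OUT_LEFT, OUT_DOWN = range(4)


@dataclass(frozen=True)
class DecoderConfig:
    """Activity-difference threshold for a one-square move (default 0.8)."""

    threshold: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")


def _axis(pos_act: float, neg_act: float, threshold: float) -> int:
    diff = pos_act - neg_act
    if diff >= threshold:
        return 1
    if diff <= -threshold:
        return -1
    return 0


# All 81 possible commands, keyed by per-axis steps (avoids re-validating a
# frozen dataclass in the hot loop).
_COMMANDS: dict[tuple[int, int, int, int], MoveCommand] = {
    (a, b, c, d): MoveCommand(a, b, c, d)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    for d in (-1, 0, 1)
}


def decode(output: np.ndarray, config: DecoderConfig = DecoderConfig()) -> MoveCommand:
    """Convert 8 output activations into a hand move command.

    "Up" decreases the row index (movement away from the body).  The decoder
    is stateless and deterministic; swapping a direction pair's activities
    flips the sign of that axis.
    """
    if output.shape[0] != 8:
        raise ValueError("decoder expects 8 output activations")
    th = config.threshold
    y0, y1, y2, y3, y4, y5, y6, y7 = output.tolist()
    return _COMMANDS[
        _axis(y0, y2, th),
        -_axis(y1, y3, th),
        _axis(y4, y6, th),
        -_axis(y5, y7, th),
    ]
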