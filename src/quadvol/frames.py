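"""Quadrat sampling frame geometry.

The field protocol measures vegetation inside a fixed 0.4 m x 0.5 m
(0.2 m^2) aluminium sampling frame.  All gridding and clipping in the
package uses the half-open convention [min, max) so that a point can
never be counted in two cells or on both sides of a frame edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FRAME_WIDTH_X = 0.4
FRAME_WIDTH_Y = 0.5


@dataclass(frozen=True)
class QuadratFrame:
    """Plot-local sampling frame: [x0, x0+width_x) x [y0, y0+width_y)."""

    x0: float = 0.0
    y0: float = 0.0
    width_x: float = FRAME_WIDTH_X
    width_y: float = FRAME_WIDTH_Y

    def __post_init__(self) -> None:
        if self.width_x <= 0 or self.width_y <= 0:
            raise ValueError("frame widths must be positive")

    @property
    def area(self) -> float:
        """Horizontal area in m^2 (0.2 m^2 for the standard frame)."""
        return self.width_x * self.width_y

    @property
    def origin(self) -> tuple[float, float]:
        return (self.x0, self.y0)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean half-open membership test for an (N, 2+) array of coordinates."""
        xy = np.asarray(xy, dtype=float)
        x, y = xy[:, 0], xy[:, 1]
        return (
            (x >= self.x0)
            & (x < self.x0 + self.width_x)
            & (y >= self.y0)
            & (y < self.y0 + self.width_y)
        )
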