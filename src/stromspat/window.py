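"""Physical observation window and pixel calibration.

A confocal cross-section is a square raster with a fixed physical pixel
size.  The default calibration is the one used throughout the analysis:
a 512 x 512 pixel image spans 682.67 x 682.67 um, i.e. 1.33333 um/pixel.
All geometry is carried in micrometres; rasterisation happens only at
the final step of scene rendering or mask construction.

Coordinate convention: origin at the top-left corner, x rightward,
y downward, so the mat surface sits near y = 0 and depth increases
with y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError

#: Map calibration of a 512-px confocal frame spanning 682.67 um.
DEFAULT_PIXEL_SIZE_UM: float = 682.67 / 512.0

#: Default frame edge length in micrometres.
DEFAULT_FRAME_UM: float = 682.67


@dataclass(frozen=True)
class Window:
    """Rectangular observation window with square pixels.

    Parameters
    ----------
    width_um, height_um:
        Physical extent of the window in micrometres.
    pixel_size_um:
        Side length of a (square) pixel in micrometres.
    """

    width_um: float = DEFAULT_FRAME_UM
    height_um: float = DEFAULT_FRAME_UM
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        if self.width_um <= 0 or self.height_um <= 0:
            raise ParameterError("window extent must be > 0")

    @property
    def n_cols(self) -> int:
        return int(round(self.width_um / self.pixel_size_um))

    @property
    def n_rows(self) -> int:
        return int(round(self.height_um / self.pixel_size_um))

    @property
    def shape(self) -> tuple[int, int]:
        """Raster shape as (rows, cols)."""
        return (self.n_rows, self.n_cols)

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um

    def contains(self, points_um: np.ndarray) -> np.ndarray:
        """Boolean mask of points (n, 2) = (x, y) lying inside the window."""
        pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
        return (
            (pts[:, 0] >= 0.0)
            & (pts[:, 0] < self.width_um)
            & (pts[:, 1] >= 0.0)
            & (pts[:, 1] < self.height_um)
        )

    def um_to_px(self, coords_um: np.ndarray) -> np.ndarray:
        """Convert (x_um, y_um) coordinates to float (row, col) pixel coordinates."""
        pts = np.asarray(coords_um, dtype=float).reshape(-1, 2)
        return np.column_stack([pts[:, 1], pts[:, 0]]) / self.pixel_size_um


#: Window matching the default confocal frame.
DEFAULT_WINDOW = Window()

#: Finer-pixel window used for the microsphere calibration fields, where the
#: 1.0-um spheres must be resolved by several pixels (a higher-magnification
#: field: 512 px spanning 136.53 um, 0.2667 um/pixel).
MICROSPHERE_WINDOW = Window(
    width_um=DEFAULT_FRAME_UM / 5.0,
    height_um=DEFAULT_FRAME_UM / 5.0,
    pixel_size_um=DEFAULT_PIXEL_SIZE_UM / 5.0,
)
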