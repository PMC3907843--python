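"""Microsphere ground-truthing: area-derived vs direct vs known abundance.

A dilution series of 1.0-um fluorescent microspheres calibrates the
area-based abundance estimate that the mat analysis relies on: each field
is classified into foreground/background, the total fluorescent area and a
direct object count are measured, and the three product-moment correlations
(area vs known, direct vs known, area vs direct) quantify how faithfully
"fluorescence area" tracks cell numbers.  Because cells are neither
perfectly spherical nor uniformly sized, area-derived counts support
*relative*, not absolute, abundance inference — the outputs are labelled
accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import classify_twoclass, segment_and_count
from .exceptions import DegenerateInputError, ParameterError
from .image import CalibratedImage

__all__ = [
    "UNIT_MICROSPHERE_AREA_UM2",
    "area_count_estimate",
    "CalibrationResult",
    "calibrate_series",
]

#: Cross-sectional area of a 1.0-um-diameter microsphere (the unit object).
UNIT_MICROSPHERE_AREA_UM2 = float(np.pi * 0.5**2)


def area_count_estimate(
    mask: np.ndarray, unit_object_area_um2: float, pixel_size_um: float
) -> float:
    """Relative object-count estimate: foreground area over unit object area.

    Real-valued (not rounded); additive over disjoint image regions.  This
    is a *relative* abundance estimate — absolute counts from complex
    matrices are not claimed.
    """
    if unit_object_area_um2 <= 0:
        raise ParameterError("unit_object_area_um2 must be > 0")
    area = float(np.asarray(mask, bool).sum()) * pixel_size_um**2
    return area / unit_object_area_um2


def _pearson_or_nan(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """(r, defined).  Zero variance in either series flags degeneracy."""
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, False
    return float(sps.pearsonr(x, y).statistic), True


@dataclass
class CalibrationResult:
    """Per-image calibration records plus the three correlations.

    ``table`` columns: dilution, known_count, direct_count, area_um2,
    area_count (a relative estimate).  Correlations are NaN with the
    matching flag False when a series is constant.
    """

    table: pd.DataFrame
    r_area_known: float
    r_direct_known: float
    r_area_direct: float
    area_known_defined: bool = True
    direct_known_defined: bool = True
    area_direct_defined: bool = True

    def summary(self) -> str:
        lines = [
            "Microsphere calibration (area-derived counts are RELATIVE estimates)",
            f"  images analysed:              {len(self.table)}",
            f"  r(area, known concentration): {self.r_area_known:.4f}"
            + ("" if self.area_known_defined else "  [degenerate]"),
            f"  r(direct, known concentration): {self.r_direct_known:.4f}"
            + ("" if self.direct_known_defined else "  [degenerate]"),
            f"  r(area, direct counts):       {self.r_area_direct:.4f}"
            + ("" if self.area_direct_defined else "  [degenerate]"),
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.4f")


def calibrate_series(
    images: Sequence[CalibratedImage],
    known_counts: Sequence[float],
    unit_object_area_um2: float = UNIT_MICROSPHERE_AREA_UM2,
    dilutions: Optional[Sequence[float]] = None,
    channel: str = "probe",
) -> CalibrationResult:
    """Run the calibration pipeline over a dilution series of fields.

    Each image is segmented by two-class classification of the probe
    channel; direct counts come from connected components under the fragment
    counting rule, area-derived counts from total foreground area divided by
    the unit object area.  Pearson correlations are computed across all
    images for the three pairings.
    """
    if len(images) != len(known_counts):
        raise ParameterError("images and known_counts must align")
    if len(images) < 3:
        raise ParameterError("need at least 3 images")
    known = np.asarray(known_counts, dtype=float)
    if dilutions is not None and len(dilutions) != len(images):
        raise ParameterError("dilutions must align with images")

    records = []
    for i, img in enumerate(images):
        mask = classify_twoclass(img.channels[channel])
        _, direct = segment_and_count(mask, unit_object_area_um2, img.pixel_size_um)
        area = float(mask.sum()) * img.pixel_size_um**2
        records.append(
            (
                dilutions[i] if dilutions is not None else np.nan,
                known[i],
                direct,
                area,
                area / unit_object_area_um2,
            )
        )
    table = pd.DataFrame(
        records, columns=["dilution", "known_count", "direct_count", "area_um2", "area_count"]
    )
    areas = table["area_um2"].to_numpy()
    direct = table["direct_count"].to_numpy(dtype=float)

    r_ak, ok_ak = _pearson_or_nan(areas, known)
    r_dk, ok_dk = _pearson_or_nan(direct, known)
    r_ad, ok_ad = _pearson_or_nan(areas, direct)
    return CalibrationResult(
        table=table,
        r_area_known=r_ak,
        r_direct_known=r_dk,
        r_area_direct=r_ad,
        area_known_defined=ok_ak,
        direct_known_defined=ok_dk,
        area_direct_defined=ok_ad,
    )
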