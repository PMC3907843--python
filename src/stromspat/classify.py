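"""Pixel classification, filament subtraction, co-localization, and counting.

The stages mirror the image-quantification workflow for FISH-probed mat
sections:

1. supervised minimum-distance classification from representative training
   pixels per feature (SRM, bacteria, precipitate, background);
2. unsupervised two-class (foreground/background) classification by
   iterative 2-means, used for the microsphere calibration fields;
3. identification and subtraction of filamentous shapes (cyanobacteria),
   which share the general stain's spectral signature with other bacteria
   and can only be separated morphologically — including when filaments
   are discontinuous;
4. co-localization gating: probe-positive objects count as SRM cells only
   where the general DNA stain is also present;
5. connected-component counting with a fragment "counting rule": border or
   sub-size fragments are summed by area into approximate integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import disk, skeletonize

from .exceptions import DegenerateInputError, ParameterError
from .image import CalibratedImage

__all__ = [
    "ClassMasks",
    "LabeledObjects",
    "classify_supervised",
    "classify_twoclass",
    "subtract_filaments",
    "colocalize",
    "segment_and_count",
    "training_from_image",
]

#: 8-connectivity structuring element used for all component labelling.
EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class ClassMasks:
    """Per-class binary masks sharing one image shape.

    ``filaments`` and ``other_bacteria`` partition the combined
    bacteria/cyanobacteria stain mask after filament subtraction.
    """

    srm: np.ndarray
    other_bacteria: np.ndarray
    filaments: np.ndarray
    precipitates: np.ndarray
    background: np.ndarray
    pixel_size_um: float = 682.67 / 512.0

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.as_dict().values()}
        if len(shapes) != 1:
            raise ParameterError("class masks must share one shape")
        if (self.srm & self.background).any():
            raise ParameterError("SRM and background masks overlap")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "srm": self.srm,
            "other_bacteria": self.other_bacteria,
            "filaments": self.filaments,
            "precipitates": self.precipitates,
            "background": self.background,
        }

    @property
    def total_cells(self) -> np.ndarray:
        """Union of all cell classes (SRM, other bacteria, filaments)."""
        return self.srm | self.other_bacteria | self.filaments

    @property
    def shape(self) -> tuple[int, int]:
        return self.srm.shape


@dataclass
class LabeledObjects:
    """Connected components of a mask with per-object measurements."""

    labels: np.ndarray
    table: pd.DataFrame  # columns: label, area_um2, x_um, y_um, border

    @property
    def n_objects(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# supervised minimum-distance classification
# ---------------------------------------------------------------------------

def training_from_image(
    image: CalibratedImage, coords: dict[str, list[tuple[int, int]]]
) -> dict[str, np.ndarray]:
    """Extract per-class training feature vectors from (row, col) samples."""
    stack = image.stack()
    out = {}
    for cls, pix in coords.items():
        pix = np.asarray(pix, dtype=int).reshape(-1, 2)
        out[cls] = stack[:, pix[:, 0], pix[:, 1]].T.copy()
    return out


def classify_supervised(
    image: CalibratedImage,
    training_pixels: dict[str, np.ndarray],
    min_intensity: Optional[float] = None,
) -> dict[str, np.ndarray]:
    """Minimum-distance-to-class-mean pixel classification.

    ``training_pixels`` maps class names (must include ``'background'``) to
    (n_samples, n_channels) arrays of representative channel intensities; each
    image pixel is assigned to the class whose mean training vector is
    nearest in channel space.  Pixels whose every channel falls below
    ``min_intensity`` go to background regardless.  Returns one boolean mask
    per class.  The rule is invariant to a uniform intensity rescaling of
    image and training pixels together.
    """
    if "background" not in training_pixels:
        raise ParameterError("training_pixels must include a 'background' class")
    for cls, samples in training_pixels.items():
        if np.asarray(samples).size == 0:
            raise ParameterError(f"class {cls!r} has no training pixels")

    stack = image.stack()  # (k, r, c)
    k = stack.shape[0]
    names = list(training_pixels)
    centroids = np.stack(
        [np.asarray(training_pixels[n], dtype=float).reshape(-1, k).mean(axis=0) for n in names]
    )  # (n_classes, k)
    feats = stack.reshape(k, -1).T  # (n_pixels, k)
    # squared Euclidean distance to each centroid
    d2 = ((feats[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1)
    if min_intensity is not None:
        sub = (feats < min_intensity).all(axis=1)
        assign[sub] = names.index("background")
    assign = assign.reshape(stack.shape[1:])
    return {name: assign == i for i, name in enumerate(names)}


# ---------------------------------------------------------------------------
# unsupervised two-class classification (microspheres vs background)
# ---------------------------------------------------------------------------

def classify_twoclass(
    channel: np.ndarray,
    max_iterations: int = 20,
    convergence_threshold: float = 0.95,
) -> np.ndarray:
    """Iterative two-means intensity clustering into foreground/background.

    Pixels are assigned to the nearer of two intensity cluster centres
    (initialised at the channel minimum and maximum), centres are recomputed,
    and iteration stops when the fraction of pixels whose assignment did not
    change reaches ``convergence_threshold`` or after ``max_iterations``
    global reassignment passes.  The brighter cluster is foreground.
    """
    arr = np.asarray(channel, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        raise DegenerateInputError("constant channel: two-class split undefined")
    if not (0.0 < convergence_threshold <= 1.0):
        raise ParameterError("convergence_threshold must be in (0, 1]")
    c_lo, c_hi = lo, hi
    prev = None
    for _ in range(max_iterations):
        fg = np.abs(arr - c_hi) < np.abs(arr - c_lo)
        if prev is not None:
            unchanged = float(np.mean(fg == prev))
            if unchanged >= convergence_threshold:
                prev = fg
                break
        prev = fg
        if fg.any():
            c_hi = float(arr[fg].mean())
        if (~fg).any():
            c_lo = float(arr[~fg].mean())
        if c_hi < c_lo:  # keep the bright cluster on top
            c_lo, c_hi = c_hi, c_lo
    return prev


# ---------------------------------------------------------------------------
# filament identification and subtraction
# ---------------------------------------------------------------------------

def subtract_filaments(
    combined_mask: np.ndarray,
    pixel_size_um: float,
    min_length_um: float = 10.0,
    max_gap_um: float = 3.0,
    min_elongation: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a combined stain mask into filaments and residual bacteria.

    Components of the gap-closed mask whose skeleton length reaches
    ``min_length_um`` and whose elongation (major/minor axis ratio) reaches
    ``min_elongation`` are filamentous; gap closure (morphological closing)
    bridges breaks up to ``max_gap_um`` so that discontinuous filaments are
    identified as single linear features.  Returns ``(filament_mask,
    residual_mask)``; the two partition the input exactly.
    """
    mask = np.asarray(combined_mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask), np.zeros_like(mask)
    # gap closure by dilation-based grouping: pieces up to max_gap apart fall
    # into one dilated component (plain morphological closing fails to bridge
    # thin dashes, whose connecting lens the erosion step removes)
    radius = max(int(np.ceil(max_gap_um / pixel_size_um / 2.0)), 1)
    grouped = ndimage.binary_dilation(mask, structure=disk(radius))
    labels = sk_label(grouped, connectivity=2)
    filament = np.zeros_like(mask)
    for region in regionprops(labels):
        rmin, cmin, rmax, cmax = region.bbox
        comp = labels[rmin:rmax, cmin:cmax] == region.label
        # length from the skeleton of the gap-bridged component; elongation
        # from the moments of the original pixels (halo-free minor axis)
        skel_px = int(skeletonize(comp).sum())
        length_um = skel_px * pixel_size_um
        orig = comp & mask[rmin:rmax, cmin:cmax]
        props = regionprops(orig.astype(np.uint8))[0]
        minor = max(props.axis_minor_length, 1.0)
        elongation = props.axis_major_length / minor
        if length_um >= min_length_um and elongation >= min_elongation:
            filament[rmin:rmax, cmin:cmax] |= comp
    filament &= mask
    residual = mask & ~filament
    return filament, residual


# ---------------------------------------------------------------------------
# co-localization gating
# ---------------------------------------------------------------------------

def colocalize(
    probe_mask: np.ndarray,
    counterstain_mask: np.ndarray,
    min_overlap_fraction: float = 0.5,
) -> np.ndarray:
    """Retain probe objects whose counterstain overlap reaches the threshold.

    A probe-positive object counts as an SRM cell only if the fraction of its
    area that also carries the general DNA stain is at least
    ``min_overlap_fraction``; retained objects are output whole.
    """
    probe = np.asarray(probe_mask, dtype=bool)
    counter = np.asarray(counterstain_mask, dtype=bool)
    if probe.shape != counter.shape:
        raise ParameterError("masks must share one shape")
    labels, n = ndimage.label(probe, structure=EIGHT)
    if n == 0:
        return np.zeros_like(probe)
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(probe, labels, idx)
    overlaps = ndimage.sum_labels(counter, labels, idx)
    keep = (overlaps / areas) >= min_overlap_fraction
    lut = np.zeros(n + 1, dtype=bool)
    lut[idx[keep]] = True
    return lut[labels]


# ---------------------------------------------------------------------------
# segmentation and the counting rule
# ---------------------------------------------------------------------------

def segment_and_count(
    mask: np.ndarray,
    typical_object_area_um2: float,
    pixel_size_um: float,
    full_size_fraction: float = 0.5,
) -> tuple[LabeledObjects, int]:
    """Label objects and count them under the fragment counting rule.

    Components at least ``full_size_fraction`` of the typical object area
    that do not touch the image border each count as one object; the
    remaining fragments (sub-size residue and border-truncated pieces) are
    pooled and their total area divided by the typical object area, rounded
    to an integer.  Two half-cells truncated at opposite borders therefore
    sum to one cell, and the rule never exceeds the naive component count
    for fragment areas below the typical area.
    """
    if typical_object_area_um2 <= 0:
        raise ParameterError("typical_object_area_um2 must be > 0")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=EIGHT)
    px_area = pixel_size_um**2
    if n == 0:
        table = pd.DataFrame(columns=["label", "area_um2", "x_um", "y_um", "border"])
        return LabeledObjects(labels=labels, table=table), 0
    idx = np.arange(1, n + 1)
    areas_px = ndimage.sum_labels(mask, labels, idx)
    areas = areas_px * px_area
    centroids = np.asarray(ndimage.center_of_mass(mask, labels, idx), dtype=float)
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border = np.isin(idx, border_labels[border_labels > 0])
    table = pd.DataFrame(
        {
            "label": idx,
            "area_um2": areas,
            "x_um": (centroids[:, 1] + 0.5) * pixel_size_um,
            "y_um": (centroids[:, 0] + 0.5) * pixel_size_um,
            "border": border,
        }
    )
    full = (areas >= full_size_fraction * typical_object_area_um2) & ~border
    fragment_area = float(areas[~full].sum())
    count = int(full.sum()) + int(round(fragment_area / typical_object_area_um2))
    return LabeledObjects(labels=labels, table=table), count
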