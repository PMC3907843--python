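"""End-to-end analysis of a rendered mat image.

Bundles the standard stage sequence — supervised classification,
co-localization gating, filament subtraction, surface delineation, then the
microspatial statistics — so tests, scripts and the CLI run one code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .classify import ClassMasks, classify_supervised, colocalize, subtract_filaments
from .image import CalibratedImage, SurfaceLine, detect_surface
from .scenes import FULL_INTENSITY
from .spatial import (
    DEFAULT_BUFFER_DEPTH_UM,
    BufferZone,
    ClusterSet,
    PairCorrelationCurve,
    ProximityResult,
    area_fraction_srm,
    buffer_zone,
    detect_clusters,
    pair_correlation,
    proximity_fractions,
)
from .window import Window

__all__ = ["canonical_training", "classify_mat_image", "MatAnalysis", "analyze_mat_image"]


def canonical_training(background: float = 10.0) -> dict[str, np.ndarray]:
    """Representative channel-intensity samples for each feature class.

    One idealised sample per class in (probe, counterstain, reflectance)
    space: SRM fluoresce in probe and counterstain, other bacteria and
    cyanobacteria in the counterstain only, minerals in the reflectance
    channel, background near the camera offset in all three.
    """
    F = FULL_INTENSITY
    b = background
    return {
        "srm": np.array([[F, F, b]]),
        "bacteria": np.array([[b, F, b]]),
        "precipitate": np.array([[b, b, F]]),
        "background": np.array([[b, b, b]]),
    }


def classify_mat_image(
    image: CalibratedImage,
    training: Optional[dict[str, np.ndarray]] = None,
    min_overlap_fraction: float = 0.5,
    min_filament_length_um: float = 10.0,
    max_filament_gap_um: float = 3.0,
    min_elongation: float = 5.0,
) -> ClassMasks:
    """Supervised classification + co-localization + filament subtraction.

    The supervised step separates SRM, stained bacteria (which includes the
    spectrally identical cyanobacteria) and precipitates; probe objects are
    then gated on counterstain co-localization, and filamentous shapes are
    subtracted morphologically from the stain mask.
    """
    if training is None:
        training = canonical_training()
    raw = classify_supervised(image, training)
    counterstain_positive = raw["srm"] | raw["bacteria"]
    srm = colocalize(raw["srm"], counterstain_positive, min_overlap_fraction)
    filaments, other = subtract_filaments(
        raw["bacteria"],
        image.pixel_size_um,
        min_length_um=min_filament_length_um,
        max_gap_um=max_filament_gap_um,
        min_elongation=min_elongation,
    )
    background = raw["background"] & ~srm
    return ClassMasks(
        srm=srm,
        other_bacteria=other,
        filaments=filaments,
        precipitates=raw["precipitate"],
        background=background,
        pixel_size_um=image.pixel_size_um,
    )


@dataclass
class MatAnalysis:
    """Bundle of the microspatial measurements on one mat image."""

    masks: ClassMasks
    surface: SurfaceLine
    zone: BufferZone
    srm_area_percent: float
    clusters: ClusterSet
    curve: Optional[PairCorrelationCurve]
    proximity: ProximityResult


def analyze_mat_image(
    image: CalibratedImage,
    srm_points_um: Optional[np.ndarray] = None,
    surface: Optional[SurfaceLine] = None,
    training: Optional[dict[str, np.ndarray]] = None,
    buffer_depth_um: float = DEFAULT_BUFFER_DEPTH_UM,
    envelope_sims: int = 39,
    seed: Optional[int] = None,
) -> MatAnalysis:
    """Classify one image and compute the full microspatial read-out.

    ``srm_points_um`` supplies the SRM cell centroids for the point-pattern
    statistics (e.g. ground-truth centroids of a synthetic scene); when
    omitted they are taken from the centroids of classified SRM objects.
    ``surface`` likewise defaults to the line detected from the union of all
    classified foreground.
    """
    masks = classify_mat_image(image, training=training)
    if surface is None:
        foreground = masks.total_cells | masks.precipitates
        surface = detect_surface(foreground, pixel_size_um=image.pixel_size_um)
    zone = buffer_zone(surface, buffer_depth_um, n_rows=image.shape[0])
    srm_pct = area_fraction_srm(masks, zone)

    if srm_points_um is None:
        from .classify import segment_and_count

        objects, _ = segment_and_count(masks.srm, np.pi * 0.25, image.pixel_size_um)
        srm_points_um = objects.table[["x_um", "y_um"]].to_numpy(dtype=float)

    pts = np.asarray(srm_points_um, dtype=float).reshape(-1, 2)
    depths = pts[:, 1] - surface.at_x_um(pts[:, 0])
    in_zone = (depths >= 0) & (depths <= buffer_depth_um)
    zone_pts = pts[in_zone].copy()
    zone_pts[:, 1] = depths[in_zone]  # depth coordinates within the band

    clusters = detect_clusters(zone_pts)
    curve = None
    if len(zone_pts) >= 2:
        band = Window(
            width_um=image.shape[1] * image.pixel_size_um,
            height_um=buffer_depth_um,
            pixel_size_um=image.pixel_size_um,
        )
        curve = pair_correlation(
            zone_pts, window=band, envelope_sims=envelope_sims, seed=seed
        )
    proximity = proximity_fractions(
        masks.srm, masks.other_bacteria | masks.filaments, masks.precipitates,
        image.pixel_size_um,
    )
    return MatAnalysis(
        masks=masks,
        surface=surface,
        zone=zone,
        srm_area_percent=srm_pct,
        clusters=clusters,
        curve=curve,
        proximity=proximity,
    )
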