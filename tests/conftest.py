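"""Shared fixtures: small windows and hand-built scenes for exact oracles."""

import numpy as np
import pandas as pd
import pytest

from stromspat import NoiseModel, SceneSpec, Window
from stromspat.scenes import ALL_CLASSES, GroundTruthScene


@pytest.fixture
def default_window() -> Window:
    return Window()


@pytest.fixture
def fine_window() -> Window:
    """Small high-resolution window for exact rasterisation arithmetic."""
    return Window(width_um=51.2, height_um=51.2, pixel_size_um=0.2)


def manual_scene(
    window: Window,
    objects: list[tuple[str, float, float, float]],
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> GroundTruthScene:
    """Build a GroundTruthScene from explicit (class, x, y, radius) disks."""
    from stromspat.scenes import _disk_pixels

    spec = SceneSpec(
        mat_type="type1",
        seed=seed,
        window=window,
        noise=NoiseModel.noiseless() if noise is None else noise,
        srm_area_fraction_target=0.0,
        n_other_bacteria=0,
        n_filaments=0,
        n_precipitate_patches=0,
        n_ooids=0,
    )
    masks = {name: np.zeros(window.shape, dtype=bool) for name in ALL_CLASSES}
    class_of = {
        "srm": "srm",
        "other-bacterium": "other_bacteria",
        "microsphere": "microspheres",
        "precipitate": "precipitates",
        "ooid": "ooids",
    }
    for cls, x, y, r in objects:
        rr, cc = _disk_pixels(x, y, r, window)
        masks[class_of[cls]][rr, cc] = True
    frame = pd.DataFrame(objects, columns=["class", "x_um", "y_um", "radius_um"])
    surface = np.zeros(window.n_cols)
    return GroundTruthScene(spec=spec, objects=frame, masks=masks, surface_px=surface)
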