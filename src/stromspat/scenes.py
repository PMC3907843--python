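"""Ground-truthed synthetic confocal scenes of stromatolite surface mats.

The generator emulates the two surface-mat states whose discrimination the
analysis is built for:

* **Type-1** (non-lithifying, binding/trapping stage): sparse sulfate-reducing
  microorganisms (SRM) placed completely spatially at random among other
  bacteria and cyanobacterial filaments, with small CaCO3 microprecipitates
  dispersed in the upper EPS, and SRM making up ~21% of total cell area in
  the surface buffer zone.
* **Type-2** (lithifying, biofilm stage): SRM concentrated in a dense layer in
  the top ~130 um, organised into Thomas-process clusters, beneath/within a
  near-continuous 30-50 um CaCO3 crust, with SRM making up ~88% of the cell
  area in the buffer zone.

A third scene kind renders fields of 1.0-um fluorescent microspheres for the
area-vs-count calibration experiment (dilution series c, c/2, c/4, c/8, c/16).

Every scene carries its exact ground truth: per-object records, noiseless
per-class rasterised masks, and the true surface line, so each downstream
stage can be verified against planted values.  All geometry is generated in
micrometres; rasterisation happens once, at mask/rendering resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter

from .exceptions import ParameterError
from .image import CalibratedImage
from .window import DEFAULT_FRAME_UM, MICROSPHERE_WINDOW, Window

__all__ = [
    "FULL_INTENSITY",
    "NoiseModel",
    "SceneSpec",
    "GroundTruthScene",
    "type1_spec",
    "type2_spec",
    "microsphere_spec",
    "build_scene",
    "render_scene",
    "make_microsphere_series",
    "DILUTION_FACTORS",
]

#: Peak rendered intensity of an in-focus object (arbitrary fluorescence units).
FULL_INTENSITY = 100.0

#: Depth of the surface buffer zone the abundance targets refer to
#: (100 map pixels at the default calibration).
BUFFER_DEPTH_UM = 100 * (682.67 / 512.0)

#: Serial dilution factors of the microsphere calibration series.
DILUTION_FACTORS = (1.0, 0.5, 0.25, 0.125, 0.0625)

CELL_CLASSES = ("srm", "other_bacteria", "filaments")
ALL_CLASSES = CELL_CLASSES + ("precipitates", "ooids", "microspheres")


@dataclass(frozen=True)
class NoiseModel:
    """Additive imaging noise plus out-of-focus dimming.

    ``snr`` is peak-signal over noise standard deviation; ``None`` disables
    additive noise.  A fraction ``dim_fraction`` of cell-like objects is
    rendered at ``dim_factor`` of full intensity, mimicking items below the
    focal plane that fluoresce at lower intensity.
    """

    background: float = 10.0
    snr: Optional[float] = 10.0
    dim_fraction: float = 0.2
    dim_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.snr is not None and self.snr <= 0:
            raise ParameterError("snr must be > 0 or None")
        if not (0.0 <= self.dim_fraction <= 1.0):
            raise ParameterError("dim_fraction must be in [0, 1]")
        if not (0.0 < self.dim_factor <= 1.0):
            raise ParameterError("dim_factor must be in (0, 1]")
        if self.background < 0:
            raise ParameterError("background must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(background=0.0, snr=None, dim_fraction=0.0, dim_factor=1.0)


@dataclass(frozen=True)
class SceneSpec:
    """Full parameterisation of one synthetic mat or microsphere scene."""

    mat_type: str  # 'type1' | 'type2' | 'microsphere'
    seed: int = 0
    window: Window = field(default_factory=Window)
    noise: NoiseModel = field(default_factory=NoiseModel)

    # -- SRM placement ----------------------------------------------------
    #: target SRM share of total cell area inside the surface buffer zone (%)
    srm_area_fraction_target: float = 20.7
    #: depth of the SRM-rich layer (type2) below the surface
    srm_layer_depth_um: float = 130.0
    #: fraction of SRM placed inside the layer (type2); remainder deeper
    srm_layer_fraction: float = 0.9
    #: Thomas-cluster offspring dispersion and mean cluster size (type2)
    cluster_sigma_um: float = 2.0
    cluster_mean_offspring: float = 30.0
    #: fraction of SRM re-seated to within ~4.4 um of precipitate pixels
    srm_near_precipitate_fraction: float = 0.4
    #: maximum depth of any bacterial cell below the surface
    cell_depth_um: float = 500.0

    # -- community around the SRM -----------------------------------------
    n_other_bacteria: int = 150
    cell_radius_mean_um: float = 0.5
    cell_radius_sd_um: float = 0.1
    n_filaments: int = 1
    filament_length_um: float = 40.0
    filament_width_px: int = 2
    filament_gap_um: float = 2.0
    filament_dash_um: float = 12.0

    # -- minerals ----------------------------------------------------------
    crust_depth_range_um: tuple[float, float] = (30.0, 50.0)
    n_crust_gaps: int = 3
    crust_gap_um: float = 8.0
    n_precipitate_patches: int = 0
    patch_radius_range_um: tuple[float, float] = (1.0, 2.5)
    patch_depth_um: float = 200.0
    n_ooids: int = 2
    ooid_radius_range_um: tuple[float, float] = (40.0, 70.0)

    # -- surface profile ---------------------------------------------------
    surface_profile: str = "sinusoid"  # 'flat' | 'sinusoid'
    surface_offset_um: float = 20.0
    surface_amplitude_um: float = 8.0
    surface_period_um: float = 170.0

    # -- microsphere fields ------------------------------------------------
    n_microspheres: int = 0
    microsphere_radius_um: float = 0.5

    def __post_init__(self) -> None:
        if self.mat_type not in ("type1", "type2", "microsphere"):
            raise ParameterError(f"unknown mat_type {self.mat_type!r}")
        if not (0.0 <= self.srm_area_fraction_target <= 100.0):
            raise ParameterError("srm_area_fraction_target must be in [0, 100] %")
        if self.n_other_bacteria < 0 or self.n_filaments < 0 or self.n_microspheres < 0:
            raise ParameterError("object counts must be >= 0")
        if self.n_precipitate_patches < 0 or self.n_ooids < 0:
            raise ParameterError("densities must be >= 0")
        if not (0.0 <= self.srm_near_precipitate_fraction <= 1.0):
            raise ParameterError("srm_near_precipitate_fraction must be in [0, 1]")
        if not (0.0 <= self.srm_layer_fraction <= 1.0):
            raise ParameterError("srm_layer_fraction must be in [0, 1]")
        lo, hi = self.crust_depth_range_um
        if lo < 0 or hi < lo:
            raise ParameterError("crust_depth_range_um must be ordered and >= 0")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = asdict(self.window)
        d["noise"] = asdict(self.noise)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        d["window"] = Window(**d["window"])
        d["noise"] = NoiseModel(**d["noise"])
        for key in ("crust_depth_range_um", "patch_radius_range_um", "ooid_radius_range_um"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def type1_spec(seed: int = 0, **overrides) -> SceneSpec:
    """Defaults for a non-lithifying Type-1 mat: sparse, random SRM (~21% of
    cell area), dispersed microprecipitates, no crust."""
    params = dict(
        mat_type="type1",
        seed=seed,
        srm_area_fraction_target=20.7,
        n_other_bacteria=150,
        n_filaments=1,
        filament_length_um=40.0,
        n_precipitate_patches=60,
        srm_near_precipitate_fraction=0.4,
    )
    params.update(overrides)
    return SceneSpec(**params)


def type2_spec(seed: int = 0, **overrides) -> SceneSpec:
    """Defaults for a lithifying Type-2 mat: clustered SRM at ~88% of cell
    area in the top ~130 um, under a near-continuous 30-50 um crust."""
    params = dict(
        mat_type="type2",
        seed=seed,
        srm_area_fraction_target=88.0,
        n_other_bacteria=400,
        n_filaments=2,
        filament_length_um=60.0,
        n_precipitate_patches=0,
        srm_near_precipitate_fraction=0.5,
    )
    params.update(overrides)
    return SceneSpec(**params)


def microsphere_spec(
    n_microspheres: int,
    seed: int = 0,
    window: Optional[Window] = None,
    noise: Optional[NoiseModel] = None,
    **overrides,
) -> SceneSpec:
    """Defaults for a microsphere calibration field.

    Calibration slides are thin aqueous mounts, so fewer objects sit out of
    focus than in a thick mat section; the default dimming is correspondingly
    milder than for mat scenes.
    """
    params = dict(
        mat_type="microsphere",
        seed=seed,
        window=MICROSPHERE_WINDOW if window is None else window,
        noise=NoiseModel(dim_fraction=0.1, dim_factor=0.6) if noise is None else noise,
        n_microspheres=n_microspheres,
        n_other_bacteria=0,
        n_filaments=0,
        n_precipitate_patches=0,
        n_ooids=0,
    )
    params.update(overrides)
    return SceneSpec(**params)


@dataclass
class GroundTruthScene:
    """A planted scene: object records, noiseless truth masks, true surface.

    ``objects`` has columns (class, x_um, y_um, radius_um); filaments appear
    once with their centroid and NaN radius, with vertex chains kept in
    ``filament_vertices``.  ``masks`` maps every class name to a boolean
    raster that exactly rasterises the planted footprints.  ``surface_px``
    gives the true surface row (float) per column (None for microsphere
    fields, which have no mat surface).
    """

    spec: SceneSpec
    objects: pd.DataFrame
    masks: dict[str, np.ndarray]
    surface_px: Optional[np.ndarray]
    filament_vertices: list[np.ndarray] = field(default_factory=list)

    @property
    def window(self) -> Window:
        return self.spec.window

    def points(self, cls: str) -> np.ndarray:
        """(n, 2) array of (x_um, y_um) centroids of one object class."""
        sub = self.objects[self.objects["class"] == cls]
        return sub[["x_um", "y_um"]].to_numpy(dtype=float)

    def srm_points(self) -> np.ndarray:
        return self.points("srm")


# ---------------------------------------------------------------------------
# rasterisation helpers
# ---------------------------------------------------------------------------

def _disk_pixels(
    x_um: float, y_um: float, radius_um: float, window: Window
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices (rows, cols) covered by a disk footprint.

    A pixel is covered when its centre lies within the disk radius.  Objects
    smaller than a pixel (e.g. 1-um cells at the 1.33-um map calibration)
    rasterise to the single nearest pixel so that no planted object vanishes.
    """
    px = window.pixel_size_um
    n_rows, n_cols = window.shape
    r_px = radius_um / px
    rc = y_um / px - 0.5  # row coordinate of the centre in pixel-centre units
    cc = x_um / px - 0.5
    r_lo = max(int(math.floor(rc - r_px)), 0)
    r_hi = min(int(math.ceil(rc + r_px)), n_rows - 1)
    c_lo = max(int(math.floor(cc - r_px)), 0)
    c_hi = min(int(math.ceil(cc + r_px)), n_cols - 1)
    if r_hi < r_lo or c_hi < c_lo:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rows = np.arange(r_lo, r_hi + 1)
    cols = np.arange(c_lo, c_hi + 1)
    rr, cc2 = np.meshgrid(rows, cols, indexing="ij")
    d2 = (rr - rc) ** 2 + (cc2 - cc) ** 2
    inside = d2 <= r_px**2
    if not inside.any():
        # sub-pixel object: claim the nearest pixel centre
        k = np.argmin(d2)
        return rr.ravel()[k : k + 1], cc2.ravel()[k : k + 1]
    return rr[inside], cc2[inside]


def _rasterize_polyline(
    vertices_um: np.ndarray,
    window: Window,
    width_px: int,
    gap_um: float,
    dash_um: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rasterise a polyline at the given pixel width, optionally dashed.

    With ``gap_um > 0`` the line is broken into dashes of ``dash_um`` length
    separated by gaps, exercising discontinuous-filament detection.
    """
    from skimage.draw import line as draw_line

    px = window.pixel_size_um
    mask = np.zeros(window.shape, dtype=bool)
    # resample the polyline at sub-pixel spacing, then drop gap segments
    verts = np.asarray(vertices_um, dtype=float)
    seg_len = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    total = seg_len.sum()
    n_samples = max(int(total / (0.25 * px)), 2)
    t = np.linspace(0.0, total, n_samples)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    xs = np.interp(t, cum, verts[:, 0])
    ys = np.interp(t, cum, verts[:, 1])
    if gap_um > 0:
        period = dash_um + gap_um
        phase = rng.uniform(0, period)
        keep = ((t + phase) % period) < dash_um
    else:
        keep = np.ones_like(t, dtype=bool)
    rows = np.clip((ys / px - 0.5).round().astype(int), 0, window.n_rows - 1)
    cols = np.clip((xs / px - 0.5).round().astype(int), 0, window.n_cols - 1)
    for i in range(len(t) - 1):
        if keep[i] and keep[i + 1]:
            rr, cc = draw_line(rows[i], cols[i], rows[i + 1], cols[i + 1])
            mask[rr, cc] = True
    if width_px > 1:
        mask = binary_dilation(mask, structure=np.ones((width_px, width_px), bool))
    return mask


def _surface_um(spec: SceneSpec, x_um: np.ndarray) -> np.ndarray:
    """True surface depth (um from the image top) at horizontal positions."""
    x = np.asarray(x_um, dtype=float)
    if spec.surface_profile == "flat":
        return np.full_like(x, spec.surface_offset_um)
    if spec.surface_profile == "sinusoid":
        phase = 2.0 * np.pi * x / spec.surface_period_um
        return spec.surface_offset_um + 0.5 * spec.surface_amplitude_um * (1.0 + np.sin(phase))
    raise ParameterError(f"unknown surface_profile {spec.surface_profile!r}")


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

def _draw_cell_radius(spec: SceneSpec, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Truncated-normal cell radii (um), bacteria-sized around 0.5 um."""
    r = rng.normal(spec.cell_radius_mean_um, spec.cell_radius_sd_um, size=n)
    lo = max(0.2, spec.cell_radius_mean_um - 3 * spec.cell_radius_sd_um)
    hi = spec.cell_radius_mean_um + 3 * spec.cell_radius_sd_um
    return np.clip(r, lo, hi)


def _build_microsphere_scene(spec: SceneSpec, rng: np.random.Generator) -> GroundTruthScene:
    window = spec.window
    masks = {name: np.zeros(window.shape, dtype=bool) for name in ALL_CLASSES}
    records = []
    for _ in range(spec.n_microspheres):
        # centres uniform over the full frame: spheres may straddle borders
        x = rng.uniform(0, window.width_um)
        y = rng.uniform(0, window.height_um)
        rr, cc = _disk_pixels(x, y, spec.microsphere_radius_um, window)
        masks["microspheres"][rr, cc] = True
        records.append(("microsphere", x, y, spec.microsphere_radius_um))
    objects = pd.DataFrame(records, columns=["class", "x_um", "y_um", "radius_um"])
    return GroundTruthScene(spec=spec, objects=objects, masks=masks, surface_px=None)


def _near_precipitate_position(
    precip_px: np.ndarray,
    window: Window,
    rng: np.random.Generator,
    max_dist_um: float = 4.0,
) -> tuple[float, float]:
    """A position within ``max_dist_um`` of a random precipitate pixel."""
    row, col = precip_px[rng.integers(len(precip_px))]
    px = window.pixel_size_um
    x0 = (col + 0.5) * px
    y0 = (row + 0.5) * px
    d = rng.uniform(0.0, max_dist_um)
    theta = rng.uniform(0, 2 * np.pi)
    x = np.clip(x0 + d * np.cos(theta), 0, np.nextafter(window.width_um, 0))
    y = np.clip(y0 + d * np.sin(theta), 0, np.nextafter(window.height_um, 0))
    return float(x), float(y)


def _srm_candidates(
    spec: SceneSpec, rng: np.random.Generator, batch: int = 256
) -> "np.ndarray":
    """One batch of SRM candidate positions (x_um, y_um) *in depth terms*.

    Returned y holds the depth below the local surface; conversion to image
    coordinates happens in the caller.  Type-1 candidates are CSR over the
    full cell depth; Type-2 candidates come from a Thomas process confined to
    the surface layer, with a ``1 - srm_layer_fraction`` share placed deeper.
    """
    if spec.mat_type == "type1":
        x = rng.uniform(0, spec.window.width_um, size=batch)
        depth = rng.uniform(0, spec.cell_depth_um, size=batch)
        return np.column_stack([x, depth])
    # type2: emit whole clusters to preserve the planted correlation structure
    out = []
    count = 0
    while count < batch:
        if rng.uniform() < spec.srm_layer_fraction:
            px_ = rng.uniform(0, spec.window.width_um)
            pd_ = rng.uniform(0, spec.srm_layer_depth_um)
            n_off = rng.poisson(spec.cluster_mean_offspring)
            if n_off == 0:
                continue
            off = rng.normal(scale=spec.cluster_sigma_um, size=(n_off, 2))
            pts = off + (px_, pd_)
            ok = (
                (pts[:, 0] >= 0)
                & (pts[:, 0] < spec.window.width_um)
                & (pts[:, 1] >= 0)
                & (pts[:, 1] < spec.srm_layer_depth_um)
            )
            pts = pts[ok]
        else:
            pts = np.array(
                [[rng.uniform(0, spec.window.width_um),
                  rng.uniform(spec.srm_layer_depth_um, spec.cell_depth_um)]]
            )
        out.append(pts)
        count += len(pts)
    return np.concatenate(out, axis=0)


def build_scene(spec: SceneSpec) -> GroundTruthScene:
    """Construct the ground truth of one scene from its specification.

    Mineral and community components are placed first; SRM cells are then
    added one at a time — from a CSR stream (Type-1) or a layered Thomas
    cluster stream (Type-2) — until the rasterised SRM share of total cell
    area inside the surface buffer zone reaches the planted target, so the
    planted abundance is exact at mask level by construction.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.mat_type == "microsphere":
        return _build_microsphere_scene(spec, rng)

    window = spec.window
    px = window.pixel_size_um
    n_rows, n_cols = window.shape
    masks = {name: np.zeros(window.shape, dtype=bool) for name in ALL_CLASSES}
    records: list[tuple] = []
    filament_vertices: list[np.ndarray] = []

    # --- true surface line ------------------------------------------------
    col_x = (np.arange(n_cols) + 0.5) * px
    surface_um = _surface_um(spec, col_x)
    surface_px = surface_um / px

    # --- minerals ----------------------------------------------------------
    if spec.mat_type == "type2":
        thickness_um = rng.uniform(*spec.crust_depth_range_um)
        t_px = thickness_um / px
        rows = np.arange(n_rows)[:, None]
        crust = (rows >= surface_px[None, :]) & (rows < surface_px[None, :] + t_px)
        # carve a few narrow gaps: the crust is near-continuous, not perfect
        gap_px = max(int(round(spec.crust_gap_um / px)), 1)
        for _ in range(spec.n_crust_gaps):
            c0 = rng.integers(0, max(n_cols - gap_px, 1))
            crust[:, c0 : c0 + gap_px] = False
        masks["precipitates"] |= crust
        records.append(("precipitate", window.width_um / 2.0, float(np.mean(surface_um) + thickness_um / 2), np.nan))
    for _ in range(spec.n_precipitate_patches):
        x = rng.uniform(0, window.width_um)
        depth = rng.uniform(0, spec.patch_depth_um)
        y = float(_surface_um(spec, np.array([x]))[0] + depth)
        r = rng.uniform(*spec.patch_radius_range_um)
        rr, cc = _disk_pixels(x, y, r, window)
        masks["precipitates"][rr, cc] = True
        records.append(("precipitate", x, y, r))
    for _ in range(spec.n_ooids):
        x = rng.uniform(0, window.width_um)
        depth = rng.uniform(200.0, max(spec.cell_depth_um - 50.0, 250.0))
        y = float(_surface_um(spec, np.array([x]))[0] + depth)
        r = rng.uniform(*spec.ooid_radius_range_um)
        rr, cc = _disk_pixels(x, y, r, window)
        masks["ooids"][rr, cc] = True
        records.append(("ooid", x, y, r))

    # --- cyanobacterial filaments ------------------------------------------
    for _ in range(spec.n_filaments):
        x0 = rng.uniform(0, window.width_um - min(spec.filament_length_um, window.width_um * 0.5))
        depth = rng.uniform(5.0, 60.0)
        n_seg = max(int(spec.filament_length_um / 10.0), 1)
        xs = x0 + np.linspace(0, spec.filament_length_um, n_seg + 1)
        wobble = np.cumsum(rng.normal(0, 2.0, size=n_seg + 1))
        ys = _surface_um(spec, xs) + depth + wobble - wobble[0]
        ys = np.clip(ys, 0, np.nextafter(window.height_um, 0))
        xs = np.clip(xs, 0, np.nextafter(window.width_um, 0))
        verts = np.column_stack([xs, ys])
        fmask = _rasterize_polyline(
            verts, window, spec.filament_width_px, spec.filament_gap_um,
            spec.filament_dash_um, rng,
        )
        masks["filaments"] |= fmask
        filament_vertices.append(verts)
        records.append(("cyanobacterium-filament", float(xs.mean()), float(ys.mean()), np.nan))

    # --- other bacteria -----------------------------------------------------
    radii = _draw_cell_radius(spec, rng, spec.n_other_bacteria)
    for i in range(spec.n_other_bacteria):
        x = rng.uniform(0, window.width_um)
        depth = rng.uniform(0, spec.cell_depth_um)
        y = float(_surface_um(spec, np.array([x]))[0] + depth)
        if y >= window.height_um:
            y = np.nextafter(window.height_um, 0)
        rr, cc = _disk_pixels(x, y, float(radii[i]), window)
        masks["other_bacteria"][rr, cc] = True
        records.append(("other-bacterium", x, y, float(radii[i])))

    # --- SRM: add until the planted buffer-zone area fraction is reached ----
    rows_grid = np.arange(n_rows)[:, None]
    depth_px = int(round(BUFFER_DEPTH_UM / px))
    zone = (rows_grid >= surface_px[None, :]) & (rows_grid < surface_px[None, :] + depth_px)
    other_union = masks["other_bacteria"] | masks["filaments"]
    base_union = int((other_union & zone).sum())
    srm_mask = masks["srm"]
    precip_px = np.argwhere(masks["precipitates"])
    target = spec.srm_area_fraction_target / 100.0
    # microprecipitate patches are cell-scale: at most one near-precipitate
    # SRM per patch, so the association does not plant spurious clustering
    # in an otherwise random pattern (the crust band has no such limit)
    free_patches = [
        (rec[1], rec[2], rec[3])
        for rec in records
        if rec[0] == "precipitate" and np.isfinite(rec[3])
    ]
    rng.shuffle(free_patches)

    srm_zone = 0
    union_extra = 0
    n_added = 0
    max_candidates = 60000
    seen = 0
    # with no other cell area in the zone the fraction is undefined: plant none
    placing = target > 0 and base_union > 0

    def _ratio() -> float:
        denom = base_union + union_extra
        return srm_zone / denom if denom else 0.0

    while placing and _ratio() < target:
        cand = _srm_candidates(spec, rng)
        for x, depth in cand:
            if _ratio() >= target:
                break
            seen += 1
            if seen > max_candidates:
                raise ParameterError(
                    "srm_area_fraction_target unreachable with these densities"
                )
            y = float(_surface_um(spec, np.array([x]))[0] + depth)
            if spec.srm_near_precipitate_fraction > 0 and len(precip_px) and (
                rng.uniform() < spec.srm_near_precipitate_fraction
            ):
                if free_patches:
                    px_x, px_y, px_r = free_patches.pop()
                    d = rng.uniform(0.0, px_r + 4.0)
                    theta = rng.uniform(0, 2 * np.pi)
                    x = float(np.clip(px_x + d * np.cos(theta), 0,
                                      np.nextafter(window.width_um, 0)))
                    y = float(np.clip(px_y + d * np.sin(theta), 0,
                                      np.nextafter(window.height_um, 0)))
                elif spec.mat_type == "type2":
                    x, y = _near_precipitate_position(precip_px, window, rng)
            if not (0 <= x < window.width_um and 0 <= y < window.height_um):
                continue
            r = float(_draw_cell_radius(spec, rng, 1)[0])
            rr, cc = _disk_pixels(x, y, r, window)
            new = ~srm_mask[rr, cc]
            rr_n, cc_n = rr[new], cc[new]
            srm_mask[rr_n, cc_n] = True
            in_zone = zone[rr_n, cc_n]
            srm_zone += int(in_zone.sum())
            union_extra += int((in_zone & ~other_union[rr_n, cc_n]).sum())
            records.append(("srm", float(x), float(y), r))
            n_added += 1

    objects = pd.DataFrame(records, columns=["class", "x_um", "y_um", "radius_um"])
    return GroundTruthScene(
        spec=spec,
        objects=objects,
        masks=masks,
        surface_px=surface_px,
        filament_vertices=filament_vertices,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

#: Optical blur of the emulated confocal system (um, Gaussian sigma);
#: the lateral PSF of a high-NA confocal at ~500 nm.
RENDER_BLUR_SIGMA_UM = 0.1

_CHANNEL_OF_CLASS = {
    "srm": ("probe", "counterstain"),
    "microsphere": ("probe",),
    "other-bacterium": ("counterstain",),
    "cyanobacterium-filament": ("counterstain",),
    "precipitate": ("reflectance",),
    "ooid": ("reflectance",),
}


def render_scene(scene: GroundTruthScene, window: Optional[Window] = None) -> CalibratedImage:
    """Render a ground-truth scene to a noisy three-channel image.

    Channel semantics: ``probe`` carries the FISH signal (SRM and, in
    calibration fields, microspheres), ``counterstain`` the general DNA stain
    (all bacteria and cyanobacteria), ``reflectance`` the mineral signal
    (precipitates and ooids).  Objects are drawn at full intensity except for
    a planted fraction rendered dimmed (below the focal plane), then blurred
    and overlaid with background plus Gaussian noise.  A fixed scene seed
    yields a bit-identical image.
    """
    spec = scene.spec
    if window is not None and window != spec.window:
        raise ParameterError("render window must match the scene window")
    window = spec.window
    rng = np.random.default_rng([spec.seed, 202])
    noise = spec.noise

    channels = {
        name: np.zeros(window.shape, dtype=float)
        for name in ("probe", "counterstain", "reflectance")
    }

    # cell-like objects individually (so each can be dimmed independently)
    classes = scene.objects["class"].to_numpy()
    xs = scene.objects["x_um"].to_numpy(dtype=float)
    ys = scene.objects["y_um"].to_numpy(dtype=float)
    rads = scene.objects["radius_um"].to_numpy(dtype=float)
    dim_flags = rng.uniform(size=len(classes)) < noise.dim_fraction
    for idx in range(len(classes)):
        cls = classes[idx]
        if cls not in ("srm", "other-bacterium", "microsphere"):
            continue
        amp = FULL_INTENSITY * (noise.dim_factor if dim_flags[idx] else 1.0)
        rr, cc = _disk_pixels(xs[idx], ys[idx], rads[idx], window)
        for ch in _CHANNEL_OF_CLASS[cls]:
            np.maximum.at(channels[ch], (rr, cc), amp)

    # extended structures from their truth masks, at full intensity
    channels["counterstain"] = np.maximum(
        channels["counterstain"], FULL_INTENSITY * scene.masks["filaments"]
    )
    channels["reflectance"] = np.maximum(
        channels["reflectance"],
        FULL_INTENSITY * (scene.masks["precipitates"] | scene.masks["ooids"]),
    )

    sigma_px = RENDER_BLUR_SIGMA_UM / window.pixel_size_um
    for name in channels:
        img = gaussian_filter(channels[name], sigma=sigma_px)
        img += noise.background
        if noise.snr is not None:
            img += rng.normal(0.0, FULL_INTENSITY / noise.snr, size=img.shape)
        channels[name] = np.clip(img, 0.0, None)

    return CalibratedImage(channels=channels, pixel_size_um=window.pixel_size_um)


# ---------------------------------------------------------------------------
# microsphere dilution series
# ---------------------------------------------------------------------------

def make_microsphere_series(
    base_count: int,
    window: Optional[Window] = None,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    n_replicates: int = 5,
) -> list[tuple[GroundTruthScene, int]]:
    """Five-step serial dilution of 1.0-um microsphere fields.

    Dilution means follow ``c, c/2, c/4, c/8, c/16`` with ``n_replicates``
    fields per dilution and Poisson-distributed per-field counts around each
    dilution mean.  Returns ``(scene, true_count)`` pairs in dilution-major
    order.
    """
    if base_count < 0:
        raise ParameterError("base_count must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for factor in DILUTION_FACTORS:
        mean = base_count * factor
        for _ in range(n_replicates):
            n = int(rng.poisson(mean))
            child_seed = int(rng.integers(0, 2**31 - 1))
            spec = microsphere_spec(n, seed=child_seed, window=window, noise=noise)
            out.append((build_scene(spec), n))
    return out
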