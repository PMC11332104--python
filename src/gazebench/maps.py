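"""Spatial salience grids: fixation maps, central bias, meaning maps, fixture model.

A :class:`SalienceGrid` is a dense real-valued grid with one cell per
screen pixel. Downstream NSS scoring z-standardises grids, so only the
relative spatial pattern matters; builders here make no attempt to
normalise to densities.

Conventions (shared with the rest of the pipeline):

* grids are (height_px, width_px) arrays indexed ``[y, x]``;
* continuous fields are sampled at pixel centres ``i + 0.5``;
* fixation coordinates are binned to pixels by truncation (floor);
* the 1 dva smoothing kernel uses per-axis px/deg (the study screen is
  anisotropic: 38.4 px/deg horizontally, 45.0 px/deg vertically).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.fft import fft2, ifft2

from .geometry import ScreenGeometry, STUDY_GEOMETRY

__all__ = [
    "SalienceGrid",
    "MapParams",
    "make_fixation_map",
    "central_bias_map",
    "aggregate_meaning_map",
    "fixture_saliency",
    "save_grid",
    "load_grid",
]

GRID_KINDS = ("fixation_map", "central_bias", "model_prediction", "meaning_map", "fixture")


@dataclass
class SalienceGrid:
    """Dense 2-D salience values tied to a screen geometry."""

    values: np.ndarray
    geometry: ScreenGeometry
    kind: str = "model_prediction"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"grid shape {self.values.shape} does not match geometry {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("salience grid contains non-finite values")
        if self.kind not in GRID_KINDS:
            raise ValueError(f"unknown grid kind {self.kind!r}")


@dataclass
class MapParams:
    """Tunable map-construction parameters.

    blur_sd_dva: SD of the Gaussian that turns discrete fixation locations
        into a continuous map (1 dva, acting as regularisation for small
        measurement error).
    central_bias_sd_px: per-axis SD of the central-bias Gaussian; defaults
        to the screen half-dimensions (aspect-ratio skewed).
    meaning_patch_diameters_dva: patch scales of the meaning-map rating
        procedure.
    """

    blur_sd_dva: float = 1.0
    central_bias_sd_px: tuple[float, float] | None = None
    meaning_patch_diameters_dva: tuple[float, ...] = (1.5, 3.0, 7.0)
    truncate_sd: float = 4.0
    fixture_blur_sd_dva: float = 0.5

    def __post_init__(self) -> None:
        if self.blur_sd_dva <= 0 or self.truncate_sd <= 0:
            raise ValueError("map parameters must be positive")
        if any(d <= 0 for d in self.meaning_patch_diameters_dva):
            raise ValueError("patch diameters must be positive")


def fixation_pixels(fixations: pd.DataFrame, geometry: ScreenGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Fixation centroid pixel indices (col, row) by truncation."""
    x = np.floor(np.asarray(fixations["x_px"], dtype=float)).astype(int)
    y = np.floor(np.asarray(fixations["y_px"], dtype=float)).astype(int)
    if np.any((x < 0) | (x >= geometry.width_px) | (y < 0) | (y >= geometry.height_px)):
        raise ValueError("fixations outside the screen bounds")
    return x, y


def fixation_count_grid(fixations: pd.DataFrame, geometry: ScreenGeometry) -> np.ndarray:
    """Binary-ish count grid: number of fixations landing in each pixel."""
    if len(fixations) == 0:
        raise ValueError("cannot build a fixation map from an empty fixation set")
    x, y = fixation_pixels(fixations, geometry)
    counts = np.zeros(geometry.shape)
    np.add.at(counts, (y, x), 1.0)
    return counts


def blur_sigma_px(geometry: ScreenGeometry, sd_dva: float) -> tuple[float, float]:
    """(sigma_y, sigma_x) in pixels for a dva-specified isotropic kernel."""
    sx, sy = geometry.dva_to_px(sd_dva)
    return sy, sx


def make_fixation_map(
    fixations: pd.DataFrame,
    geometry: ScreenGeometry = STUDY_GEOMETRY,
    params: MapParams | None = None,
) -> SalienceGrid:
    """Continuous fixation map: count grid blurred with a 1 dva Gaussian.

    Reflective boundary handling keeps total mass for fixations near the
    screen edge; the kernel is truncated at ``params.truncate_sd`` SDs.
    """
    params = params or MapParams()
    counts = fixation_count_grid(fixations, geometry)
    values = ndimage.gaussian_filter(
        counts,
        sigma=blur_sigma_px(geometry, params.blur_sd_dva),
        mode="reflect",
        truncate=params.truncate_sd,
    )
    return SalienceGrid(values, geometry, kind="fixation_map")


def central_bias_map(
    geometry: ScreenGeometry = STUDY_GEOMETRY, params: MapParams | None = None
) -> SalienceGrid:
    """Anisotropic Gaussian central bias, SD = screen half-dimensions.

    Centred on the screen centre and evaluated at pixel centres, hence
    exactly symmetric under left-right and up-down flips.
    """
    params = params or MapParams()
    sx, sy = params.central_bias_sd_px or (geometry.width_px / 2.0, geometry.height_px / 2.0)
    if sx <= 0 or sy <= 0:
        raise ValueError("central bias SDs must be positive")
    cx, cy = geometry.center_px
    xc = np.arange(geometry.width_px) + 0.5
    yc = np.arange(geometry.height_px) + 0.5
    gx = np.exp(-0.5 * ((xc - cx) / sx) ** 2)
    gy = np.exp(-0.5 * ((yc - cy) / sy) ** 2)
    return SalienceGrid(np.outer(gy, gx), geometry, kind="central_bias")


def aggregate_meaning_map(
    ratings: pd.DataFrame, geometry: ScreenGeometry = STUDY_GEOMETRY
) -> SalienceGrid:
    """Aggregate patch meaningfulness ratings into a dense map.

    ``ratings`` columns: x_px, y_px (patch centre), diameter_dva, rating.
    Per pixel, ratings of all covering patches are averaged within each
    scale, then scale maps are averaged (unweighted) across scales for
    which the pixel is covered. Pixels covered by no patch at any scale
    are assigned the grid minimum.
    """
    required = {"x_px", "y_px", "diameter_dva", "rating"}
    if len(ratings) == 0:
        raise ValueError("empty ratings table")
    if not required.issubset(ratings.columns):
        raise ValueError(f"ratings table requires columns {sorted(required)}")

    h, w = geometry.shape
    scale_maps = []
    for diameter, group in ratings.groupby("diameter_dva"):
        total = np.zeros((h, w))
        count = np.zeros((h, w))
        rx = diameter / 2.0 * geometry.px_per_deg_x
        ry = diameter / 2.0 * geometry.px_per_deg_y
        for row in group.itertuples():
            x0 = max(int(np.floor(row.x_px - rx)), 0)
            x1 = min(int(np.ceil(row.x_px + rx)) + 1, w)
            y0 = max(int(np.floor(row.y_px - ry)), 0)
            y1 = min(int(np.ceil(row.y_px + ry)) + 1, h)
            if x0 >= x1 or y0 >= y1:
                continue
            xs = np.arange(x0, x1) + 0.5
            ys = np.arange(y0, y1) + 0.5
            mask = ((xs - row.x_px) / rx) ** 2 + (((ys - row.y_px) / ry) ** 2)[:, None] <= 1.0
            total[y0:y1, x0:x1][mask] += row.rating
            count[y0:y1, x0:x1][mask] += 1.0
        scale_maps.append((total, count))

    acc = np.zeros((h, w))
    n_scales = np.zeros((h, w))
    for total, count in scale_maps:
        covered = count > 0
        acc[covered] += total[covered] / count[covered]
        n_scales += covered
    covered_any = n_scales > 0
    if not covered_any.any():
        raise ValueError("no pixel is covered by any patch")
    values = np.zeros((h, w))
    values[covered_any] = acc[covered_any] / n_scales[covered_any]
    values[~covered_any] = values[covered_any].min()
    return SalienceGrid(values, geometry, kind="meaning_map")


def fixture_saliency(
    image: np.ndarray,
    geometry: ScreenGeometry | None = None,
    params: MapParams | None = None,
) -> SalienceGrid:
    """Spectral-residual salience of a luminance image (in-repo fixture model).

    Subtracts the image mean (making the output invariant to adding a
    constant), smooths the log-amplitude spectrum with a 3x3 mean filter,
    back-transforms the residual spectrum with the original phase, squares
    the magnitude and blurs lightly. A deterministic stand-in "model
    prediction" so end-to-end runs need no external saliency model output.
    """
    params = params or MapParams()
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if geometry is None:
        geometry = ScreenGeometry(
            width_px=img.shape[1], height_px=img.shape[0], width_dva=50.0, height_dva=24.0
        )
    img = img - img.mean()
    if np.allclose(img, 0.0):
        return SalienceGrid(np.zeros(img.shape), geometry, kind="fixture")
    spectrum = fft2(img)
    spectrum[0, 0] = 0.0  # exact DC removal; mean subtraction leaves fp residue
    amplitude = np.abs(spectrum)
    phase = np.angle(spectrum)
    log_amp = np.log(amplitude + 1e-12)
    residual = log_amp - ndimage.uniform_filter(log_amp, size=3, mode="wrap")
    residual_spectrum = np.exp(residual + 1j * phase)
    residual_spectrum[0, 0] = 0.0
    sal = np.abs(ifft2(residual_spectrum)) ** 2
    sal = ndimage.gaussian_filter(
        sal, sigma=blur_sigma_px(geometry, params.fixture_blur_sd_dva), mode="reflect"
    )
    return SalienceGrid(sal, geometry, kind="fixture")


# ---------------------------------------------------------------------------
# grid I/O: lossless text/NPY grids, or 16-bit PNG (min-max scaled, lossy)
# with a JSON sidecar carrying geometry, kind and the scaling.


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_grid(grid: SalienceGrid, path) -> None:
    path = Path(path)
    meta = {
        "kind": grid.kind,
        "geometry": {
            "width_px": grid.geometry.width_px,
            "height_px": grid.geometry.height_px,
            "width_dva": grid.geometry.width_dva,
            "height_dva": grid.geometry.height_dva,
            "viewing_distance_cm": grid.geometry.viewing_distance_cm,
        },
    }
    if path.suffix == ".png":
        vmin, vmax = float(grid.values.min()), float(grid.values.max())
        scale = (vmax - vmin) or 1.0
        img = np.round((grid.values - vmin) / scale * 65535).astype(np.uint16)
        iio.imwrite(path, img)
        meta["scaling"] = {"vmin": vmin, "vmax": vmax}
    elif path.suffix == ".npy":
        np.save(path, grid.values)
    else:
        np.savetxt(path, grid.values)
    _sidecar(path).write_text(json.dumps(meta))


def load_grid(path) -> SalienceGrid:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    geometry = ScreenGeometry(**meta["geometry"])
    if path.suffix == ".png":
        img = np.asarray(iio.imread(path), dtype=float)
        s = meta["scaling"]
        values = img / 65535.0 * (s["vmax"] - s["vmin"]) + s["vmin"]
    elif path.suffix == ".npy":
        values = np.load(path)
    else:
        values = np.loadtxt(path)
    return SalienceGrid(values, geometry, kind=meta["kind"])
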