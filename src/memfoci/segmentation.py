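"""Cell segmentation from bright-field images.

Cells are segmented by global (Otsu) thresholding followed by
8-connected component labelling; components smaller than a minimum area
are discarded and cells touching the image border are removed before any
per-cell statistic.  Cell area is ``|pixels| * pixel_size^2``.  The
major-axis angle from second central image moments normalises each rod to
a horizontal orientation for axial line scans.

Pixel coordinates are 0-based ``(row, col)``; physical coordinates are in
micrometres with x along columns (pixel centres at ``(i + 0.5) * pixel``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

from .config import ImagingConfig


@dataclass
class CellROI:
    """One segmented cell."""

    label: int
    coords: np.ndarray          # (n, 2) int array of (row, col)
    area_um2: float
    centroid_um: tuple[float, float]          # (x, y)
    major_axis_angle_deg: float               # in (-90, 90]
    touches_edge: bool
    bounding_box: tuple[int, int, int, int]   # (min_row, min_col, max_row, max_col) exclusive

    def mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(image_shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m

    def contains_um(self, x_um: np.ndarray, y_um: np.ndarray,
                    pixel_size_um: float, image_shape: tuple[int, int]) -> np.ndarray:
        """Whether physical points fall on (or adjacent to) this ROI.

        Membership is tested against the mask dilated by one pixel:
        localisation is sub-pixel while the mask is pixelated, so a point
        on the cell outline can round to a pixel just outside the binary
        mask; strict pixel membership would systematically drop
        membrane-edge foci.
        """
        from scipy.ndimage import binary_dilation
        col = np.clip((np.asarray(x_um) / pixel_size_um).astype(int),
                      0, image_shape[1] - 1)
        row = np.clip((np.asarray(y_um) / pixel_size_um).astype(int),
                      0, image_shape[0] - 1)
        m = binary_dilation(self.mask(image_shape), np.ones((3, 3), bool))
        return m[row, col]


def _moment_angle_deg(coords: np.ndarray) -> float:
    """Major-axis angle to the horizontal from second central moments.

    x = col, y = row; returns degrees in (-90, 90]; isotropic shapes
    (disc, square) get 0 by convention.
    """
    x = coords[:, 1].astype(float)
    y = coords[:, 0].astype(float)
    x -= x.mean()
    y -= y.mean()
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    if abs(mu20 - mu02) < 1e-12 and abs(mu11) < 1e-12:
        return 0.0
    ang = 0.5 * math.degrees(math.atan2(2.0 * mu11, mu20 - mu02))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return ang


def _build_rois(mask: np.ndarray, imaging: ImagingConfig,
                min_area_um2: float) -> list[CellROI]:
    lab = sk_label(mask, connectivity=2)  # 8-connectivity, raster-order labels
    px_area = imaging.pixel_size_um ** 2
    h, w = mask.shape
    rois: list[CellROI] = []
    for region in regionprops(lab):
        area = region.num_pixels * px_area
        if area < min_area_um2:
            continue
        coords = region.coords
        r0, c0, r1, c1 = region.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        cy, cx = region.centroid
        rois.append(CellROI(
            label=len(rois) + 1,
            coords=coords,
            area_um2=area,
            centroid_um=((cx + 0.5) * imaging.pixel_size_um,
                         (cy + 0.5) * imaging.pixel_size_um),
            major_axis_angle_deg=_moment_angle_deg(coords),
            touches_edge=touches,
            bounding_box=(r0, c0, r1, c1),
        ))
    return rois


def _rodlikeness(rois: list[CellROI]) -> int:
    """Score a candidate segmentation by its count of rod-shaped cells."""
    n = 0
    for roi in rois:
        if roi.area_um2 > 30.0:
            continue
        r0, c0, r1, c1 = roi.bounding_box
        long_side = max(r1 - r0, c1 - c0)
        short_side = max(min(r1 - r0, c1 - c0), 1)
        if long_side / short_side >= 1.5:
            n += 1
    return n


def segment_cells(bright_field: np.ndarray, imaging: ImagingConfig,
                  min_area_um2: float = 1.0) -> list[CellROI]:
    """Threshold a bright-field image into per-cell ROIs.

    Polarity (cells darker or brighter than the background) is chosen
    automatically: the polarity whose components look more rod-like wins,
    with darker-than-background as the tie-break (the usual bright-field
    appearance).  A uniform image yields no ROIs.
    """
    img = np.asarray(bright_field, dtype=float)
    if img.ndim != 2:
        raise ValueError("bright-field image must be 2D")
    if img.size == 0:
        raise ValueError("empty image")
    if np.ptp(img) == 0:
        return []
    thresh = threshold_otsu(img)
    dark = _build_rois(img < thresh, imaging, min_area_um2)
    bright = _build_rois(img > thresh, imaging, min_area_um2)
    return bright if _rodlikeness(bright) > _rodlikeness(dark) else dark


def remove_edge_cells(rois: list[CellROI],
                      image_shape: tuple[int, int]) -> list[CellROI]:
    """Drop ROIs with any pixel on the image border (incomplete cells)."""
    h, w = image_shape
    kept = []
    for roi in rois:
        rows, cols = roi.coords[:, 0], roi.coords[:, 1]
        on_edge = (rows.min() == 0 or cols.min() == 0
                   or rows.max() == h - 1 or cols.max() == w - 1)
        if not on_edge:
            kept.append(roi)
    return kept


def orient_cell(roi: CellROI) -> tuple[float, Callable[[np.ndarray], np.ndarray]]:
    """Angle of the major axis and a transform into the horizontal cell frame.

    The returned function maps (n, 2) image-frame points in micrometres to
    cell-frame coordinates: origin at the ROI centroid, major axis along +x.
    """
    if len(roi.coords) < 3:
        raise ValueError("ROI too small to orient")
    ang = roi.major_axis_angle_deg
    theta = math.radians(-ang)
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    center = np.asarray(roi.centroid_um)

    def transform(xy_um: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(np.asarray(xy_um, dtype=float)) - center
        return rel @ rot.T

    return ang, transform


def clip_cell_movie(movie: np.ndarray, roi: CellROI) -> np.ndarray:
    """Crop a movie to the ROI bounding box, NaN-masking outside pixels.

    The NaN sentinel marks pixels that do not belong to the cell; the
    detector treats them as background.
    """
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, rows, cols)")
    r0, c0, r1, c1 = roi.bounding_box
    h, w = movie.shape[1:]
    if r1 > h or c1 > w:
        raise ValueError("ROI does not fit the movie frame")
    sub = movie[:, r0:r1, c0:c1].astype(np.float32)
    local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    local[roi.coords[:, 0] - r0, roi.coords[:, 1] - c0] = True
    sub[:, ~local] = np.nan
    return sub
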