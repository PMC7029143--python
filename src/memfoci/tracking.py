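"""Laplacian-of-Gaussian focus detection and LAP frame-to-frame linking.

Detection: scale-normalised LoG response (sigma matched to the expected
blob diameter, TrackMate's ``sigma = diameter / (2 * sqrt(2))``), 3x3 local
maxima above a quality threshold, quadratic subpixel refinement, and focus
intensity as the mean raw counts in the 3x3 pixel window around the peak.

Linking: per consecutive frame pair, a one-to-one assignment minimising
total squared displacement among candidate pairs closer than the linking
radius (solved with the Jonker-Volgenant algorithm); unmatched detections
start new tracks, unmatched tracks end — no gap closing, matching a
Simple-LAP tracker with gaps disabled.

Detections and tracks are plain pandas DataFrames:

``detections``: frame, x_um, y_um, quality, intensity
``tracks``:     track_id + the detection columns (+ cell_label after
                assignment; -1 marks tracks outside every cell)
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .config import ImagingConfig, TrackingConfig
from .segmentation import CellROI

DETECTION_COLUMNS = ["frame", "x_um", "y_um", "quality", "intensity"]

_UNLINKABLE = 1e9  # cost sentinel: forbidden pairs; dominates any real cost


def _log_response(frame: np.ndarray, sigma_px: float) -> np.ndarray:
    """Scale-normalised negated LoG: bright blobs give positive peaks."""
    img = np.asarray(frame, dtype=float)
    if np.isnan(img).any():
        fill = np.nanmedian(img)
        img = np.where(np.isnan(img), fill, img)
    return -sigma_px ** 2 * ndimage.gaussian_laplace(img, sigma_px)


def _quadratic_offset(m: float, c: float, p: float) -> float:
    """Vertex offset of the parabola through (-1, m), (0, c), (+1, p)."""
    denom = m - 2.0 * c + p
    if denom >= 0:  # not a maximum; keep the integer position
        return 0.0
    return float(np.clip(0.5 * (m - p) / denom, -0.5, 0.5))


def window_mean(raw: np.ndarray, row: int, col: int) -> float:
    """Mean of the 3x3 pixel window centred at (row, col).

    Edge positions average the available pixels only; NaN pixels (the
    clipped-cell sentinel) are ignored.
    """
    h, w = raw.shape
    win = raw[max(0, row - 1):min(h, row + 2), max(0, col - 1):min(w, col + 2)]
    return float(np.nanmean(win))


def response_threshold(response: np.ndarray, k: float) -> float:
    """Per-movie quality calibration: k noise-SDs above the response centre.

    Uses the median and the MAD-derived robust SD so that the calibration
    measures the noise floor rather than the spots themselves; a naive
    mean + k*SD rule would rise with spot density and make detection
    sensitivity differ between sparse and crowded conditions.
    """
    med = float(np.median(response))
    mad = float(np.median(np.abs(response - med)))
    return med + k * 1.4826 * mad


def detect_foci(frame_image: np.ndarray, imaging: ImagingConfig,
                cfg: TrackingConfig, frame: int = 0,
                quality_threshold: float | None = None) -> pd.DataFrame:
    """Detect diffraction-limited spots in one frame.

    ``quality_threshold`` overrides the config (used by ``detect_movie``
    to apply one movie-wide calibrated threshold); otherwise the config
    value or, failing that, a per-frame ``mean + k*SD`` calibration is
    used.  NaN pixels (clipped-cell sentinel) are treated as background.
    """
    px = imaging.pixel_size_um
    sigma_px = cfg.log_sigma_um() / px
    if sigma_px < 1.0:
        raise ValueError("blob diameter below one pixel at this pixel size")
    raw = np.asarray(frame_image, dtype=float)
    if raw.ndim != 2:
        raise ValueError("frame must be 2D")
    resp = _log_response(raw, sigma_px)
    thr = quality_threshold
    if thr is None:
        thr = cfg.quality_threshold
    if thr is None:
        thr = response_threshold(resp, cfg.threshold_k)

    footprint = np.ones((3, 3), dtype=bool)
    is_max = (resp == ndimage.maximum_filter(resp, footprint=footprint)) \
        & (resp > thr)
    is_max[0, :] = is_max[-1, :] = False
    is_max[:, 0] = is_max[:, -1] = False
    # a spot centred on a pixel corner ties 2x2 neighbours at the same
    # response: keep one representative per connected plateau
    labels, n_peaks = ndimage.label(is_max, structure=footprint)
    peaks = np.asarray(ndimage.center_of_mass(
        is_max, labels, range(1, n_peaks + 1)), dtype=float)
    peaks = np.round(peaks).astype(int) if len(peaks) else \
        np.empty((0, 2), dtype=int)

    rows = []
    h, w = raw.shape
    for r, c in peaks:
        if np.isnan(raw[r, c]):
            continue
        dr = dc = 0.0
        if cfg.subpixel:
            dc = _quadratic_offset(resp[r, c - 1], resp[r, c], resp[r, c + 1])
            dr = _quadratic_offset(resp[r - 1, c], resp[r, c], resp[r + 1, c])
        intensity = window_mean(raw, r, c)
        rows.append((frame, (c + 0.5 + dc) * px, (r + 0.5 + dr) * px,
                     float(resp[r, c]), intensity))
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def detect_movie(movie: np.ndarray, imaging: ImagingConfig,
                 cfg: TrackingConfig) -> pd.DataFrame:
    """Detect spots in every frame with a single movie-wide threshold.

    The threshold is calibrated on the pooled response statistics of a
    subsample of frames so detection sensitivity is constant over time.
    """
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, rows, cols)")
    thr = cfg.quality_threshold
    if thr is None:
        sigma_px = cfg.log_sigma_um() / imaging.pixel_size_um
        sample = movie[:: max(1, len(movie) // 16)]
        resp = np.stack([_log_response(f, sigma_px) for f in sample])
        thr = response_threshold(resp, cfg.threshold_k)
    parts = [detect_foci(movie[f], imaging, cfg, frame=f, quality_threshold=thr)
             for f in range(len(movie))]
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(columns=DETECTION_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def _assign_pair(prev_xy: np.ndarray, next_xy: np.ndarray,
                 max_dist: float) -> list[tuple[int, int]]:
    """Min-cost one-to-one links (squared distance) within ``max_dist``.

    Maximises the number of allowed links first (forbidden pairs carry a
    dominating sentinel cost), then minimises total squared distance.
    """
    if len(prev_xy) == 0 or len(next_xy) == 0:
        return []
    d2 = ((prev_xy[:, None, :] - next_xy[None, :, :]) ** 2).sum(-1)
    cost = np.where(d2 <= max_dist ** 2, d2, _UNLINKABLE)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols)
            if cost[i, j] < _UNLINKABLE]


def link_frames(detections: pd.DataFrame, cfg: TrackingConfig) -> pd.DataFrame:
    """Link per-frame detections into gap-free trajectories.

    Returns the detection table with a ``track_id`` column; track ids are
    assigned in order of track creation (frame order, then detection
    order), which makes linking deterministic.
    """
    if len(detections) == 0:
        out = detections.copy()
        out["track_id"] = pd.Series(dtype=int)
        return out
    det = detections.sort_values(["frame", "y_um", "x_um"],
                                 kind="stable").reset_index(drop=True)
    track_of = np.full(len(det), -1, dtype=int)
    groups = {int(f): idx.to_numpy()
              for f, idx in det.groupby("frame").groups.items()}
    frames = sorted(groups)
    next_track = 0
    prev_idx = np.array([], dtype=int)
    prev_frame = None
    for f in frames:
        idx = groups[f]
        if prev_frame is not None and f == prev_frame + 1 and len(prev_idx):
            pxy = det.loc[prev_idx, ["x_um", "y_um"]].to_numpy()
            nxy = det.loc[idx, ["x_um", "y_um"]].to_numpy()
            for i, j in _assign_pair(pxy, nxy, cfg.link_max_dist_um):
                track_of[idx[j]] = track_of[prev_idx[i]]
        for k in idx:
            if track_of[k] < 0:
                track_of[k] = next_track
                next_track += 1
        prev_idx, prev_frame = idx, f
    det["track_id"] = track_of
    return det[["track_id"] + DETECTION_COLUMNS]


def filter_tracks(tracks: pd.DataFrame, cfg: TrackingConfig) -> pd.DataFrame:
    """Keep tracks spanning at least ``min_track_frames`` frames (inclusive)."""
    if len(tracks) == 0:
        return tracks.copy()
    sizes = tracks.groupby("track_id")["frame"].size()
    keep = sizes.index[sizes >= cfg.min_track_frames]
    return tracks[tracks["track_id"].isin(keep)].reset_index(drop=True)


def assign_tracks_to_cells(tracks: pd.DataFrame, rois: list[CellROI],
                           imaging: ImagingConfig) -> pd.DataFrame:
    """Attach each track to the cell containing most of its detections.

    Detections are mapped to the pixel they fall on; a track belongs to
    the ROI holding the (strict or tie-broken lowest-label) majority of
    its detections, or gets ``cell_label = -1`` when it lies outside all
    ROIs.
    """
    out = tracks.copy()
    if len(out) == 0:
        out["cell_label"] = pd.Series(dtype=int)
        return out
    shape = imaging.image_shape
    label_img = np.zeros(shape, dtype=int)
    for roi in sorted(rois, key=lambda r: -r.label):
        label_img[roi.coords[:, 0], roi.coords[:, 1]] = roi.label
    col = np.clip((out["x_um"].to_numpy() / imaging.pixel_size_um).astype(int),
                  0, shape[1] - 1)
    row = np.clip((out["y_um"].to_numpy() / imaging.pixel_size_um).astype(int),
                  0, shape[0] - 1)
    out["_pixel_label"] = label_img[row, col]

    def majority(s: pd.Series) -> int:
        counts = s[s > 0].value_counts()
        if counts.empty:
            return -1
        top = counts[counts == counts.max()]
        return int(min(top.index))

    lab = out.groupby("track_id")["_pixel_label"].apply(majority)
    out["cell_label"] = out["track_id"].map(lab)
    return out.drop(columns="_pixel_label")


def track_lengths(tracks: pd.DataFrame) -> pd.Series:
    return tracks.groupby("track_id")["frame"].size()
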