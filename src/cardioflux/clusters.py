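"""Cluster quantification in STED/confocal frames.

Immunolabel clusters (TOM20, RyR2, phalloidin) are segmented by global
thresholding plus connected components; touching spots are split by an
intensity-marker watershed, the standard workflow for dense punctate
super-resolution images.  Reported metrics follow the field's conventions:
per-cluster area (um^2), cluster density per 1 um^2 tile, fractional
labelled area (%), and centroid nearest-neighbour distances within or
between channels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage import filters, measure, restoration, segmentation
from skimage.draw import polygon2mask
from skimage.feature import peak_local_max

from .errors import AnalysisError, ValidationError
from .io import LabelImage


@dataclass(frozen=True)
class SegmentationConfig:
    """Segmentation knobs; every output records the values used.

    threshold_method
        "otsu" (default) or "fixed" with ``threshold_value``.
    min_size_px
        Clusters below this pixel count are discarded (4 px ~ 0.0009 um^2
        at 15 nm: single-pixel shot noise, two orders of magnitude below
        the smallest reported clusters).
    rolling_ball_radius_px
        Optional background subtraction radius; None = off.
    split_touching
        Split merged components by intensity-marker watershed; reduces to
        plain connected components when spots are well separated.
    peak_min_distance_px
        Minimum marker separation for the watershed (5 px = 75 nm at
        15 nm/px, just above the STED resolution limit).
    smooth_sigma_px
        Gaussian smoothing applied only for marker detection; rounds the
        plateau of a filled cluster into a single maximum.
    """

    threshold_method: str = "otsu"
    threshold_value: float | None = None
    min_size_px: int = 4
    rolling_ball_radius_px: float | None = None
    split_touching: bool = True
    peak_min_distance_px: int = 5
    smooth_sigma_px: float = 2.0

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValidationError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ValidationError("threshold_method='fixed' requires threshold_value")
        if self.min_size_px < 1:
            raise ValidationError("min_size_px must be >= 1")


@dataclass
class Cluster:
    id: int
    area_um2: float
    centroid_um: tuple[float, float]  # (x, y) = (col, row) * pixel size
    n_pixels: int
    edge: bool  # touches the frame border (area is frame-clipped)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    channel_label: str
    pixel_size_nm: float
    frame_um: tuple[float, float]
    threshold_used: float
    min_size_used: int
    source: str = ""

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([c.area_um2 for c in self.clusters], dtype=float)

    @property
    def centroids_um(self) -> np.ndarray:
        if not self.clusters:
            return np.empty((0, 2))
        return np.array([c.centroid_um for c in self.clusters], dtype=float)

    def interior(self) -> "ClusterSet":
        """Copy with edge-clipped clusters removed."""
        return ClusterSet(
            clusters=[c for c in self.clusters if not c.edge],
            channel_label=self.channel_label,
            pixel_size_nm=self.pixel_size_nm,
            frame_um=self.frame_um,
            threshold_used=self.threshold_used,
            min_size_used=self.min_size_used,
            source=self.source,
        )


@dataclass
class DensityMap:
    tile_um2: float
    counts: np.ndarray  # (rows, cols) of full tiles
    mean_per_tile: float
    n_assigned: int


def _threshold(pixels: np.ndarray, cfg: SegmentationConfig) -> float | None:
    if cfg.threshold_method == "fixed":
        return float(cfg.threshold_value)
    if np.ptp(pixels) == 0:
        return None  # constant image: nothing to segment
    return float(filters.threshold_otsu(pixels))


def _label_mask(pixels: np.ndarray, mask: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    lab = measure.label(mask, connectivity=2)  # 8-connectivity
    if not cfg.split_touching or lab.max() == 0:
        return lab
    smooth = filters.gaussian(pixels, sigma=cfg.smooth_sigma_px, preserve_range=True)
    coords = peak_local_max(
        smooth, min_distance=cfg.peak_min_distance_px, labels=lab, exclude_border=False
    )
    markers = np.zeros_like(lab)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    # any component without a detected peak keeps its brightest pixel as marker
    marked = set(np.unique(lab[markers > 0])) - {0}
    nxt = len(coords) + 1
    for region in measure.regionprops(lab, intensity_image=smooth):
        if region.label in marked:
            continue
        rr, cc = region.coords[np.argmax(smooth[tuple(region.coords.T)])]
        markers[rr, cc] = nxt
        nxt += 1
    return segmentation.watershed(-smooth, markers=markers, mask=mask, connectivity=2)


def segment_clusters(img: LabelImage, config: SegmentationConfig | None = None) -> ClusterSet:
    """Threshold, label and measure clusters in a single-channel frame."""
    cfg = config or SegmentationConfig()
    pixels = img.pixels
    if cfg.rolling_ball_radius_px:
        pixels = pixels - restoration.rolling_ball(pixels, radius=cfg.rolling_ball_radius_px)
    thr = _threshold(pixels, cfg)
    s_um = img.pixel_size_nm / 1000.0
    empty = ClusterSet(
        clusters=[],
        channel_label=img.channel_label,
        pixel_size_nm=img.pixel_size_nm,
        frame_um=img.frame_um,
        threshold_used=math.nan if thr is None else thr,
        min_size_used=cfg.min_size_px,
        source=str(img.meta.get("image_id", "")),
    )
    if thr is None:
        return empty
    mask = pixels > thr
    if not mask.any():
        warnings.warn("threshold at or above maximum intensity: no clusters", stacklevel=2)
        return empty
    lab = _label_mask(pixels, mask, cfg)
    h, w = lab.shape
    clusters = []
    for region in measure.regionprops(lab):
        if region.area < cfg.min_size_px:
            continue
        r0, c0, r1, c1 = region.bbox
        cy, cx = region.centroid
        clusters.append(
            Cluster(
                id=len(clusters),
                area_um2=float(region.area) * s_um * s_um,
                centroid_um=(cx * s_um, cy * s_um),
                n_pixels=int(region.area),
                edge=bool(r0 == 0 or c0 == 0 or r1 == h or c1 == w),
            )
        )
    empty.clusters = clusters
    return empty


def cluster_density(cs: ClusterSet, tile_um2: float = 1.0) -> DensityMap:
    """Clusters per tile, assigning each cluster to the tile holding its centroid.

    The frame is tiled from the origin with square tiles of ``tile_um2``;
    partial edge tiles are excluded from the map and the mean.
    """
    if tile_um2 <= 0:
        raise ValidationError("tile_um2 must be positive")
    side = math.sqrt(tile_um2)
    fw, fh = cs.frame_um
    if side > fw or side > fh:
        raise ValidationError("tile larger than frame")
    ncols, nrows = int(fw / side + 1e-9), int(fh / side + 1e-9)
    counts = np.zeros((nrows, ncols), dtype=int)
    n_assigned = 0
    for x, y in cs.centroids_um:
        col, row = int(x / side), int(y / side)
        if 0 <= col < ncols and 0 <= row < nrows:
            counts[row, col] += 1
            n_assigned += 1
    return DensityMap(
        tile_um2=tile_um2,
        counts=counts,
        mean_per_tile=float(counts.mean()),
        n_assigned=n_assigned,
    )


def fractional_area(
    img: LabelImage,
    roi_um: np.ndarray | None = None,
    config: SegmentationConfig | None = None,
) -> float:
    """Percent of ROI pixels above threshold (full frame when no ROI given).

    ``roi_um`` is a polygon as (x, y) vertices in um, same thresholding
    config as `segment_clusters`.
    """
    cfg = config or SegmentationConfig()
    pixels = img.pixels
    if cfg.rolling_ball_radius_px:
        pixels = pixels - restoration.rolling_ball(pixels, radius=cfg.rolling_ball_radius_px)
    thr = _threshold(pixels, cfg)
    if roi_um is None:
        roi = np.ones(pixels.shape, dtype=bool)
    else:
        verts = np.asarray(roi_um, dtype=float)
        if verts.ndim != 2 or verts.shape[0] < 3:
            raise ValidationError("roi_um must be a polygon of >= 3 (x, y) vertices")
        s_um = img.pixel_size_nm / 1000.0
        roi = polygon2mask(pixels.shape, verts[:, ::-1] / s_um)  # (row, col) order
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValidationError("degenerate ROI: zero pixels")
    if thr is None:
        return 0.0
    return 100.0 * float((pixels[roi] > thr).sum()) / n_roi


def nearest_neighbour_distances(a: ClusterSet, b: ClusterSet) -> np.ndarray:
    """For each cluster in ``a``, distance (um) to the nearest centroid in ``b``.

    When ``a`` and ``b`` are the same set, each cluster's own centroid is
    excluded, so a single-cluster set has no neighbour and is an error.
    """
    if len(b) == 0:
        raise AnalysisError("empty reference cluster set: no neighbours")
    same = a is b
    if same and len(b) < 2:
        raise AnalysisError("nearest-neighbour within a set needs >= 2 clusters")
    if len(a) == 0:
        return np.empty(0)
    tree = cKDTree(b.centroids_um)
    if same:
        d, _ = tree.query(a.centroids_um, k=2)
        return d[:, 1]
    d, _ = tree.query(a.centroids_um, k=1)
    return np.asarray(d, dtype=float)
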