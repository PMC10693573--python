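"""Focus gating and pore/vessel segmentation on magnified surface images.

A deliberately classical (non-learned) pipeline, chosen for determinism:

* focus gating — threshold on the local variance of a Laplacian response in
  a sliding window, followed by morphological opening;
* pores — contrast normalisation, thresholding below the background level
  within the focus mask, morphological cleanup, contour extraction, then
  area/solidity/elongation filters.  Merged pore candidates are *not*
  split: coalescing outlets are treated as real biology;
* vessels — multiscale ridge (tubeness) enhancement, thresholding,
  skeletonisation, splitting at branch points, per-point width as twice the
  distance-transform value at the centreline.

Coordinates are pixel-based (origin top-left, x rightward, y downward);
physical quantities are derived via the image's pixel size.  All thresholds
live in :class:`vped.config.SegmentationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import SegmentationConfig
from .morphometry import max_feret_diameter, min_feret_diameter

__all__ = [
    "TissueImage",
    "Detection",
    "SpecimenEnsemble",
    "focus_mask",
    "detect_pores",
    "detect_vessels",
    "collate_specimen",
]


@dataclass
class TissueImage:
    """One acquired image with its physical calibration."""

    pixels: np.ndarray
    pixel_size: float                  # um / px
    magnification: str = "4X"
    specimen_id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.size == 0 or self.pixels.ndim != 2:
            raise ValueError("image must be a non-empty 2D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    def normalized(self) -> np.ndarray:
        """Intensities scaled to [0, 1] regardless of dtype."""
        img = self.pixels.astype(float)
        if np.issubdtype(self.pixels.dtype, np.integer):
            img = img / np.iinfo(self.pixels.dtype).max
        return img


@dataclass
class Detection:
    """One segmented tissue element in pixel coordinates."""

    kind: str                              # "pore" | "vessel"
    polygon: np.ndarray | None = None      # pores: closed boundary (x, y) px
    mask: np.ndarray | None = None         # pores: filled boolean mask
    centerline: np.ndarray | None = None   # vessels: (x, y) px polyline
    widths: np.ndarray | None = None       # vessels: per-point width, px
    quality: float = 1.0
    image_id: str = ""
    magnification: str = "4X"

    @property
    def centroid(self) -> np.ndarray:
        if self.kind == "pore":
            if self.mask is not None:
                r, c = ndimage.center_of_mass(self.mask)
                return np.array([c, r])
            from .morphometry import polygon_centroid
            return polygon_centroid(self.polygon)
        return self.centerline.mean(axis=0)


@dataclass
class SpecimenEnsemble:
    """All detections of one specimen, partitioned by magnification."""

    specimen_id: str
    detections: list = field(default_factory=list)
    analyzed_area_um2: dict = field(default_factory=dict)   # per magnification

    def partition(self, magnification: str) -> list:
        return [d for d in self.detections if d.magnification == magnification]

    @property
    def n_detections(self) -> int:
        return len(self.detections)


# ---------------------------------------------------------------------------
# focus gating
# ---------------------------------------------------------------------------

def focus_mask(image: TissueImage,
               config: SegmentationConfig | None = None) -> np.ndarray:
    """Boolean mask of in-focus pixels.

    Sharpness statistic: variance of the Laplacian response in a sliding
    window; pixels above the configured threshold survive, then a
    morphological opening removes speckle.  A fully blurred or constant
    image yields an empty mask (not an error).
    """
    config = config or SegmentationConfig()
    img = image.normalized()
    lap = ndimage.laplace(img)
    w = config.focus_window
    mean = ndimage.uniform_filter(lap, w)
    sq = ndimage.uniform_filter(lap * lap, w)
    local_var = np.clip(sq - mean * mean, 0.0, None)
    mask = local_var > config.focus_threshold
    if config.focus_opening > 1:
        k = config.focus_opening
        st = np.ones((k, k), bool)
        padded = np.pad(mask, k, mode="edge")   # keep morphology border-safe
        padded = ndimage.binary_opening(padded, structure=st)
        padded = ndimage.binary_closing(padded, structure=st)
        mask = padded[k:-k, k:-k]
    return mask


# ---------------------------------------------------------------------------
# pore detection
# ---------------------------------------------------------------------------

def _boundary_polygon(region_mask: np.ndarray, offset: tuple) -> np.ndarray | None:
    """Closed boundary (x, y) of the largest contour of a filled region."""
    from skimage import measure

    padded = np.pad(region_mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)                    # rows, cols
    contour = contour - 1.0                             # un-pad
    xy = np.column_stack([contour[:, 1] + offset[1], contour[:, 0] + offset[0]])
    return xy


def detect_pores(image: TissueImage, mask: np.ndarray,
                 config: SegmentationConfig | None = None) -> list:
    """Segment gland outlets (dark blobs) inside the focus mask."""
    from skimage import measure

    config = config or SegmentationConfig()
    img = image.normalized()
    if not mask.any():
        return []
    background = float(np.median(img[mask]))
    binary = (img < background - config.pore_threshold_offset) & mask
    binary = ndimage.binary_opening(binary, structure=np.ones((3, 3), bool))
    binary = ndimage.binary_fill_holes(binary)

    px2 = image.pixel_size ** 2
    detections = []
    labels = measure.label(binary, connectivity=2)
    shape = img.shape
    grad = ndimage.gaussian_gradient_magnitude(img, 1.0)
    for region in measure.regionprops(labels):
        # refine the boundary at half contrast: the initial threshold sits
        # high on the softened edge ramp and inflates areas
        r0, c0, r1, c1 = region.bbox
        pad = 4
        rr0, cc0 = max(r0 - pad, 0), max(c0 - pad, 0)
        rr1, cc1 = min(r1 + pad, shape[0]), min(c1 + pad, shape[1])
        window = img[rr0:rr1, cc0:cc1]
        core = float(np.percentile(window[labels[rr0:rr1, cc0:cc1] == region.label], 10))
        if core > background - config.pore_min_core_contrast:
            continue        # too shallow: vessel lumen, not a gland outlet
        half = 0.5 * (background + core)
        refined = ndimage.binary_fill_holes(window < half)
        lab2, _ = ndimage.label(refined, structure=np.ones((3, 3), int))
        overlap = lab2[labels[rr0:rr1, cc0:cc1] == region.label]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            continue
        region_mask = lab2 == np.bincount(overlap).argmax()
        area_um2 = float(region_mask.sum()) * px2
        if not (config.pore_min_area_um2 <= area_um2 <= config.pore_max_area_um2):
            continue
        solidity = _mask_solidity(region_mask)
        if solidity < config.pore_min_solidity:
            continue
        poly = _boundary_polygon(region_mask, (rr0, cc0))
        if poly is None or len(poly) < 8:
            continue
        feret_max = max_feret_diameter(poly)
        feret_min = min_feret_diameter(poly)
        if feret_min > 0 and feret_max / feret_min > config.pore_max_elongation:
            continue
        full_mask = np.zeros(shape, dtype=bool)
        full_mask[rr0:rr1, cc0:cc1] = region_mask
        quality = _boundary_contrast(grad, full_mask)
        if config.quality_filter and quality < config.min_quality:
            continue
        detections.append(Detection(kind="pore", polygon=poly, mask=full_mask,
                                    quality=quality, image_id=image.image_id,
                                    magnification=image.magnification))
    return detections


def _mask_solidity(region_mask: np.ndarray) -> float:
    from skimage.morphology import convex_hull_image

    filled = int(region_mask.sum())
    if filled == 0:
        return 0.0
    hull = int(convex_hull_image(region_mask).sum())
    return filled / hull if hull else 0.0


def _boundary_contrast(grad: np.ndarray, region_mask: np.ndarray) -> float:
    """Mean gradient magnitude on the region boundary, clipped to [0, 1]."""
    boundary = region_mask ^ ndimage.binary_erosion(region_mask)
    if not boundary.any():
        return 0.0
    return float(np.clip(grad[boundary].mean() * 5.0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# vessel detection
# ---------------------------------------------------------------------------

def _order_skeleton_path(coords: np.ndarray) -> np.ndarray:
    """Order the pixels of a branchless skeleton segment into a path."""
    if len(coords) <= 2:
        return coords
    pts = {tuple(c) for c in coords}
    nbrs = {}
    for r, c in pts:
        nbrs[(r, c)] = [(r + dr, c + dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                        if (dr or dc) and (r + dr, c + dc) in pts]
    ends = [p for p, nb in nbrs.items() if len(nb) == 1]
    start = ends[0] if ends else min(pts)
    path, seen = [start], {start}
    while True:
        nxt = [p for p in nbrs[path[-1]] if p not in seen]
        if not nxt:
            break
        nxt.sort(key=lambda p: (abs(p[0] - path[-1][0]) + abs(p[1] - path[-1][1])))
        path.append(nxt[0])
        seen.add(nxt[0])
    return np.asarray(path)


def _vessel_segments(image: TissueImage, mask: np.ndarray,
                     config: SegmentationConfig,
                     pore_detections: list | None = None) -> list:
    """Ridge-enhance, skeletonise, split at branch points, measure widths.

    Returns vessel Detections whose skeleton length is at least
    ``vessel_min_aspect`` times their mean width — blob-shaped skeleton
    fragments (pore interiors produce them) are discarded.
    """
    from skimage.filters import sato
    from skimage.morphology import skeletonize

    img = image.normalized()
    if not mask.any():
        return []
    work = img.copy()
    background = float(np.median(img[mask]))
    if pore_detections:
        for det in pore_detections:
            if det.mask is not None:
                grown = ndimage.binary_dilation(det.mask, iterations=3)
                work[grown] = background

    tube = sato(background - work, sigmas=config.vessel_scales, black_ridges=False)
    tmax = tube.max()
    if tmax <= 0:
        return []
    binary = (tube / tmax > config.vessel_threshold) & mask
    binary = ndimage.binary_closing(binary, structure=np.ones((3, 3), bool))
    if not binary.any():
        return []

    skel = skeletonize(binary)
    # widths from the intensity half-contrast mask: the tubeness support
    # depends on the ridge threshold, the dark band itself does not
    core = float(np.median(work[skel])) if skel.any() else background
    dark = work < 0.5 * (background + core)
    edt = ndimage.distance_transform_edt(dark)

    # split at branch points: remove pixels with >= 3 skeleton neighbours
    nb = ndimage.convolve(skel.astype(int), np.ones((3, 3), int),
                          mode="constant") - skel.astype(int)
    branch = skel & (nb >= 3)
    segments = skel & ~ndimage.binary_dilation(branch,
                                               structure=np.ones((3, 3), bool))
    labels, n_seg = ndimage.label(segments, structure=np.ones((3, 3), int))

    detections = []
    for lab in range(1, n_seg + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) < config.vessel_min_skeleton_px:
            continue
        path = _order_skeleton_path(coords)
        depth = background - float(np.median(work[path[:, 0], path[:, 1]]))
        if depth < config.vessel_min_contrast:
            continue        # ridge response without a dark band: noise
        widths = np.maximum(2.0 * edt[path[:, 0], path[:, 1]], 1.0)
        seg_len = np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1))
        mean_w = float(widths.mean())
        if seg_len / mean_w < config.vessel_min_aspect:
            continue
        centerline = np.column_stack([path[:, 1], path[:, 0]]).astype(float)
        detections.append(Detection(kind="vessel", centerline=centerline,
                                    widths=widths, image_id=image.image_id,
                                    magnification=image.magnification))
    return detections


def detect_vessels(image: TissueImage, mask: np.ndarray,
                   config: SegmentationConfig | None = None,
                   pore_detections: list | None = None) -> list:
    """Segment blood vessels (dark curvilinear bands) inside the focus mask.

    Already-detected pores are masked out before ridge enhancement so blob
    responses do not leak into the vessel channel.  The skeleton is split at
    branch points; each branchless segment becomes one Detection with
    per-point width = 2 x distance to background.
    """
    config = config or SegmentationConfig()
    return _vessel_segments(image, mask, config, pore_detections=pore_detections)


# ---------------------------------------------------------------------------
# specimen collation
# ---------------------------------------------------------------------------

def collate_specimen(per_image_detections: list, images: list,
                     focus_masks: list | None = None) -> SpecimenEnsemble:
    """Concatenate detections from all images of one specimen.

    2X and 4X sets are kept as separate partitions; the analyzed (in-focus)
    area is accumulated per magnification.  Mixed specimen identifiers are
    an error; across-image de-duplication is not attempted (images are
    treated as disjoint fields of view).
    """
    ids = {im.specimen_id for im in images}
    if len(ids) > 1:
        raise ValueError(f"mixed specimen identifiers: {sorted(ids)}")
    specimen_id = ids.pop() if ids else ""
    ensemble = SpecimenEnsemble(specimen_id=specimen_id)
    for i, (dets, im) in enumerate(zip(per_image_detections, images)):
        for d in dets:
            if not d.image_id:
                d.image_id = im.image_id
            d.magnification = im.magnification
            ensemble.detections.append(d)
        if focus_masks is not None and focus_masks[i] is not None:
            area = float(focus_masks[i].sum()) * im.pixel_size ** 2
        else:
            area = im.pixels.size * im.pixel_size ** 2
        ensemble.analyzed_area_um2[im.magnification] = \
            ensemble.analyzed_area_um2.get(im.magnification, 0.0) + area
    return ensemble


def ensemble_feature_table(ensemble: SpecimenEnsemble, pixel_size: float,
                           magnification: str | None = None) -> pd.DataFrame:
    """Morphometry over all detections of a specimen -> long feature table."""
    from .morphometry import pore_features, vessel_features

    rows = []
    for det in ensemble.detections:
        if magnification and det.magnification != magnification:
            continue
        try:
            if det.kind == "pore":
                f = pore_features(det.polygon, pixel_size, check_simple=False)
                rows.append({"kind": "pore", "image_id": det.image_id,
                             "pore_area": f.area, "pore_length": f.length,
                             "pore_curvature": f.curvature,
                             "pore_tortuosity": f.tortuosity})
            else:
                f = vessel_features(det.centerline, det.widths, pixel_size)
                rows.append({"kind": "vessel", "image_id": det.image_id,
                             "bv_diameter": f.diameter,
                             "bv_segment_length": f.segment_length})
        except ValueError:
            continue
    return pd.DataFrame(rows)
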