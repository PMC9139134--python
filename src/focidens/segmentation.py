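"""Nuclei segmentation from the DAPI channel.

The mask construction follows a fixed morphological sequence:

1. Otsu binarization (foreground = pixels >= threshold);
2. adaptive median filtering of the binary mask (impulse denoising);
3. hole filling (4-connected background);
4. opening by reconstruction — erosion by a disk of radius
   ``min_nucleus_radius_px`` followed by reconstruction by dilation under the
   hole-filled mask, which deletes every object too small to contain that disk
   while preserving the surviving objects' exact shapes;
5. closing — ``closing_iterations`` successive dilations by a radius-1 disk,
   hole filling, then the same number of erosions.

Connected components of the final mask (8-connected foreground, 4-connected
background for holes) are the objects of quantification: individual nuclei or
small unseparated groups. No watershed splitting and no border-object removal
are performed — touching nuclei deliberately stay merged, since the downstream
statistic is a per-area foci density rather than a per-cell count.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .errors import DegenerateImageError
from .filters import adaptive_median
from .imaging import Raster2D

logger = logging.getLogger(__name__)

_N8 = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element
_DISK1 = ndi.generate_binary_structure(2, 1)  # radius-1 disk (cross)


@dataclasses.dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the nuclei mask construction.

    ``min_nucleus_radius_px`` is the radius of the disk every kept object must
    contain (default 25 px at the ~1880x1880 tile-scan resolution);
    ``closing_iterations`` the number of radius-1 dilations/erosions in the
    closing step; ``median_max_window`` the largest adaptive-median window.
    """

    min_nucleus_radius_px: int = 25
    closing_iterations: int = 4
    median_max_window: int = 7

    def __post_init__(self) -> None:
        if self.min_nucleus_radius_px < 1:
            raise ValueError("min_nucleus_radius_px must be >= 1")
        if self.closing_iterations < 0:
            raise ValueError("closing_iterations must be >= 0")


@dataclasses.dataclass(frozen=True)
class LabeledObjects:
    """Integer label map (0 = background) with per-object pixel areas."""

    labels: np.ndarray
    object_areas: dict[int, int]

    @property
    def n_objects(self) -> int:
        return len(self.object_areas)

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "LabeledObjects":
        labels = np.asarray(labels)
        counts = np.bincount(labels.ravel())
        areas = {lab: int(counts[lab]) for lab in range(1, len(counts)) if counts[lab]}
        return cls(labels=labels, object_areas=areas)


def _values(raster) -> np.ndarray:
    return raster.values if isinstance(raster, Raster2D) else np.asarray(raster)


def otsu_threshold(raster) -> float:
    """Between-class-variance-maximizing threshold on a 256-bin histogram.

    Foreground is defined as pixels ``>= threshold``. Candidate thresholds are
    the 255 interior bin edges; on ties the lowest is returned.

    Raises
    ------
    DegenerateImageError
        If the raster is constant (fewer than 2 distinct values).
    """
    values = _values(raster).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise DegenerateImageError("constant raster: Otsu threshold undefined")
    counts, edges = np.histogram(values, bins=256, range=(vmin, vmax))
    centers = (edges[:-1] + edges[1:]) / 2.0
    n = counts.sum()
    w0 = np.cumsum(counts)[:-1]  # background counts for thresholds edges[1..255]
    w1 = n - w0
    csum = np.cumsum(counts * centers)[:-1]
    total = csum[-1] + counts[-1] * centers[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum / w0
        mu1 = (total - csum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf
    best = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximum
    return float(edges[best + 1])


def segment_nuclei(
    nuclei_raster, params: SegmentationParams | None = None
) -> LabeledObjects:
    """Build the labeled object mask from the nuclei channel.

    The pipeline is deterministic; a degenerate (constant) raster yields an
    empty labeling with a warning rather than an error, so a blank field in a
    batch does not abort the run.
    """
    params = params or SegmentationParams()
    values = _values(nuclei_raster)

    try:
        threshold = otsu_threshold(values)
    except DegenerateImageError:
        warnings.warn("degenerate nuclei raster: returning empty labeling")
        return LabeledObjects.from_labels(np.zeros(values.shape, dtype=np.int32))

    binary = values >= threshold
    binary = adaptive_median(binary, max_window=params.median_max_window)
    filled = ndi.binary_fill_holes(binary, structure=_DISK1)

    # opening by reconstruction: erosion by disk(r) == EDT > r (outside the
    # frame counts as foreground), then geodesic dilation under the
    # hole-filled mask; an all-foreground mask is its own erosion
    if filled.all():
        seed = filled
    else:
        seed = ndi.distance_transform_edt(filled) > params.min_nucleus_radius_px
    if not seed.any():
        return LabeledObjects.from_labels(np.zeros(values.shape, dtype=np.int32))
    opened = morphology.reconstruction(
        seed.astype(np.uint8), filled.astype(np.uint8), method="dilation", footprint=_N8
    ).astype(bool)

    mask = opened
    if params.closing_iterations > 0:
        mask = ndi.binary_dilation(
            mask, structure=_DISK1, iterations=params.closing_iterations
        )
    mask = ndi.binary_fill_holes(mask, structure=_DISK1)
    if params.closing_iterations > 0:
        mask = ndi.binary_erosion(
            mask,
            structure=_DISK1,
            iterations=params.closing_iterations,
            border_value=1,
        )

    labels, n = ndi.label(mask, structure=_N8)
    logger.debug("segmented %d objects (threshold %.4g)", n, threshold)
    return LabeledObjects.from_labels(labels.astype(np.int32))


def export_labels(labeled: LabeledObjects, tiff_path=None, csv_path=None) -> None:
    """Export the label map as a 16-bit TIFF and/or a per-object CSV.

    The CSV has one row per object: label, area_px, centroid_row,
    centroid_col (0-based pixel coordinates).
    """
    if tiff_path is not None:
        import tifffile

        tifffile.imwrite(str(tiff_path), labeled.labels.astype(np.uint16))
    if csv_path is not None:
        import pandas as pd

        labs = sorted(labeled.object_areas)
        centroids = ndi.center_of_mass(
            labeled.labels > 0, labeled.labels, labs
        )
        pd.DataFrame(
            {
                "label": labs,
                "area_px": [labeled.object_areas[lab] for lab in labs],
                "centroid_row": [c[0] for c in centroids],
                "centroid_col": [c[1] for c in centroids],
            }
        ).to_csv(csv_path, index=False)
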