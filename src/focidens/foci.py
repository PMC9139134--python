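"""Foci detection and density quantification in the gamma-H2AX channel.

For each labeled object the number of punctate foci is counted and divided by
the object's pixel area, giving a per-object foci density (foci per pixel).
Detection is controlled by two user parameters:

``r_f``
    Maximal focus radius in pixels — the disk radius of the white top-hat
    filter, which suppresses background structures wider than a focus.
``T_e``
    Intensity gate in [0, 1] applied to the *original* (unfiltered,
    normalized) pixel values at candidate maxima.

The per-image detection sequence is:

1. adaptive median filtering of the normalized foci channel;
2. white top-hat with a disk of radius ``r_f``;
3. ``h`` = Otsu threshold of the top-hat values restricted to object pixels
   (the transform operates on the filtered image, so ``h`` is measured there);
4. H-maxima transform with height ``h`` (reconstruction by dilation of
   ``tophat - h`` under ``tophat``) and extraction of 8-connected
   regional-maximum components — a plateau counts once;
5. each maximum component intersecting an object counts as one focus of that
   object iff the maximum of the original foci raster over the component
   strictly exceeds ``T_e``; the component is attributed to the object
   containing its brightest in-object pixel (ties -> lowest label).

Filtering is computed once over the full frame and counts are then restricted
to objects; inside objects away from the frame border this is equivalent to
per-object filtering.

``r_f`` and ``T_e`` can be tuned per treatment group (nanoparticle incubation
changes the culture condition, hence potentially the foci morphology) by
exhaustive evaluation over a parameter grid, scored by default with the
coefficient of determination of the linear dose-response fit of mean density
vs dose.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology

from .errors import ContractError, DegenerateImageError, InsufficientDataError
from .filters import adaptive_median
from .imaging import ChannelPair, Raster2D, normalize
from .segmentation import LabeledObjects, SegmentationParams, otsu_threshold, segment_nuclei

logger = logging.getLogger(__name__)

_N8 = np.ones((3, 3), dtype=bool)

DEFAULT_R_F_GRID = (9, 11, 13, 15, 17, 19, 21, 23, 25, 27)
DEFAULT_T_E_GRID = (0.3, 0.35, 0.40, 0.45, 0.5, 0.55, 0.6, 0.65, 0.7)


@dataclasses.dataclass(frozen=True)
class FociParams:
    """Detection parameters; defaults follow the reference tuning for
    nanoparticle-treated datasets (``r_f`` 13; controls used 23), ``T_e`` 0.55."""

    r_f: int = 13
    t_e: float = 0.55

    def __post_init__(self) -> None:
        if self.r_f < 1:
            raise ValueError("r_f must be >= 1")
        if not 0.0 < self.t_e < 1.0:
            raise ValueError("t_e must lie strictly inside (0, 1)")


@dataclasses.dataclass(frozen=True)
class FociResult:
    """Per-object focus count and density (foci per pixel)."""

    image_id: str
    object_label: int
    area_px: int
    foci_count: int
    density: float


@dataclasses.dataclass(frozen=True)
class OptimizationGrid:
    r_f_values: tuple[int, ...] = DEFAULT_R_F_GRID
    t_e_values: tuple[float, ...] = DEFAULT_T_E_GRID
    criterion: str = "linear_dose_response_r2"

    def __post_init__(self) -> None:
        if not self.r_f_values or not self.t_e_values:
            raise ValueError("parameter grids must be nonempty")
        for r in self.r_f_values:
            if r < 1:
                raise ValueError("r_f grid values must be >= 1")
        for t in self.t_e_values:
            if not 0.0 < t < 1.0:
                raise ValueError("t_e grid values must lie in (0, 1)")


def _normalized_values(foci_raster) -> np.ndarray:
    if isinstance(foci_raster, Raster2D):
        if not foci_raster.normalized:
            raise ContractError("foci raster must be normalized to [0, 1]")
        return foci_raster.values
    arr = np.asarray(foci_raster, dtype=np.float64)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ContractError("foci array must be normalized to [0, 1]")
    return arr


def _candidate_components(
    foci_values: np.ndarray,
    labels: np.ndarray,
    r_f: int,
    median_max_window: int = 7,
) -> list[tuple[float, int]]:
    """Detect candidate maxima; return (gate intensity, object label) pairs.

    The gate intensity is the maximum of the original raster over the whole
    component; the label is that of the object containing the component's
    brightest in-object pixel (0 if the component misses every object).
    """
    filtered = adaptive_median(foci_values, max_window=median_max_window)
    tophat = morphology.white_tophat(filtered, footprint=morphology.disk(r_f))

    in_object = labels > 0
    try:
        h = otsu_threshold(tophat[in_object])
    except DegenerateImageError:
        return []
    if h <= 0.0:
        return []

    hmax = morphology.reconstruction(
        tophat - h, tophat, method="dilation", footprint=_N8
    )
    maxima = morphology.local_maxima(hmax, connectivity=2)
    comp_labels, n_comp = ndi.label(maxima, structure=_N8)
    if n_comp == 0:
        return []

    candidates: list[tuple[float, int]] = []
    for sl, comp in zip(ndi.find_objects(comp_labels), range(1, n_comp + 1)):
        member = comp_labels[sl] == comp
        orig = foci_values[sl]
        gate_intensity = float(orig[member].max())
        obj = labels[sl]
        inside = member & (obj > 0)
        if not inside.any():
            candidates.append((gate_intensity, 0))
            continue
        vals_in = orig[inside]
        best = vals_in.max()
        label = int(obj[inside][vals_in == best].min())
        candidates.append((gate_intensity, label))
    return candidates


def detect_foci(
    foci_raster,
    labeled_objects: LabeledObjects,
    params: FociParams | None = None,
    image_id: str = "",
    median_max_window: int = 7,
) -> list[FociResult]:
    """Count foci per labeled object and compute densities.

    Returns one :class:`FociResult` per object (sorted by label); an empty
    labeling yields an empty list. Each detected maximum component is counted
    for exactly one object, so the per-object counts sum to the count over the
    union mask.
    """
    params = params or FociParams()
    values = _normalized_values(foci_raster)
    labels = labeled_objects.labels
    if values.shape != labels.shape:
        raise ContractError("foci raster and label map shapes differ")
    if labeled_objects.n_objects == 0:
        return []

    candidates = _candidate_components(values, labels, params.r_f, median_max_window)
    counts: dict[int, int] = {lab: 0 for lab in labeled_objects.object_areas}
    for gate_intensity, label in candidates:
        if label > 0 and gate_intensity > params.t_e:
            counts[label] += 1

    return [
        FociResult(
            image_id=image_id,
            object_label=lab,
            area_px=area,
            foci_count=counts[lab],
            density=counts[lab] / area,
        )
        for lab, area in sorted(labeled_objects.object_areas.items())
    ]


def _r2_of_mean_density_vs_dose(
    per_image: list[tuple[float, list[FociResult]]]
) -> float:
    """Default optimization criterion: R^2 of mean density vs dose."""
    from .stats import exclude_outliers

    pooled: dict[float, list[float]] = {}
    for dose, results in per_image:
        kept, _ = exclude_outliers([r.density for r in results])
        pooled.setdefault(dose, []).extend(kept)
    doses = sorted(pooled)
    means = [float(np.mean(pooled[d])) for d in doses if pooled[d]]
    doses = [d for d in doses if pooled[d]]
    if len(doses) < 3:
        return float("-inf")
    x = np.asarray(doses)
    y = np.asarray(means)
    if np.allclose(y, y[0]):
        return float("-inf")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def optimize_parameters(
    calibration_images: Sequence[ChannelPair],
    grid: OptimizationGrid | None = None,
    segmentation_params: SegmentationParams | None = None,
    criterion: Callable[[list[tuple[float, list[FociResult]]]], float] | None = None,
    median_max_window: int = 7,
) -> tuple[FociParams, pd.DataFrame]:
    """Exhaustively score every (r_f, T_e) pair on a calibration series.

    All images are assumed to come from ONE treatment group; run the
    optimization separately per group. Requires at least 3 distinct dose
    levels. Returns the arg-max pair (ties -> lowest ``r_f``, then lowest
    ``T_e``) and the full score table with columns ``r_f``, ``t_e``,
    ``score``.

    Candidate maxima are detected once per (image, r_f) and re-gated for each
    ``T_e``, which is equivalent to rerunning the full detection.
    """
    grid = grid or OptimizationGrid()
    doses = {p.dose_gy for p in calibration_images}
    if len(doses) < 3:
        raise InsufficientDataError(
            f"parameter optimization needs >= 3 distinct dose levels, got {len(doses)}"
        )
    score_fn = criterion or _r2_of_mean_density_vs_dose

    segmented: list[tuple[ChannelPair, LabeledObjects, np.ndarray]] = []
    for pair in calibration_images:
        labeled = segment_nuclei(pair.nuclei, segmentation_params)
        foci = pair.foci if pair.foci.normalized else normalize(pair.foci)
        segmented.append((pair, labeled, foci.values))

    rows = []
    for r_f in grid.r_f_values:
        cached = []
        for pair, labeled, values in segmented:
            if labeled.n_objects == 0:
                cached.append((pair, labeled, []))
                continue
            cands = _candidate_components(values, labeled.labels, r_f, median_max_window)
            cached.append((pair, labeled, cands))
        for t_e in grid.t_e_values:
            per_image = []
            for pair, labeled, cands in cached:
                counts = {lab: 0 for lab in labeled.object_areas}
                for gate_intensity, label in cands:
                    if label > 0 and gate_intensity > t_e:
                        counts[label] += 1
                results = [
                    FociResult(pair.image_id, lab, area, counts[lab], counts[lab] / area)
                    for lab, area in sorted(labeled.object_areas.items())
                ]
                per_image.append((pair.dose_gy, results))
            rows.append(
                {"r_f": r_f, "t_e": t_e, "score": score_fn(per_image)}
            )
    table = pd.DataFrame(rows)
    best_row = table.sort_values(
        ["score", "r_f", "t_e"], ascending=[False, True, True], kind="stable"
    ).iloc[0]
    best = FociParams(r_f=int(best_row["r_f"]), t_e=float(best_row["t_e"]))
    logger.info("optimization best: r_f=%d t_e=%.2f score=%.4f", best.r_f, best.t_e, best_row["score"])
    return best, table
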