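"""Adaptive median filtering.

Classic adaptive median scheme: for each pixel the window grows from 3x3 in
odd steps up to ``max_window`` until the window median is not an impulse
(strictly between the window min and max); the pixel is then kept if it is
itself non-impulse, otherwise replaced by the median.  If the largest window
is reached without a non-impulse median, the median of that window is used.

On binary masks the median always coincides with an extreme, so the scheme
specializes to a majority vote over the largest window — this is the variant
applied to the thresholded nuclei mask.

Borders are handled by symmetric reflection (scipy's default ``reflect``).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


def adaptive_median(image: np.ndarray, max_window: int = 7) -> np.ndarray:
    """Apply the adaptive median filter.

    Parameters
    ----------
    image
        2-D array; boolean masks and float/integer images are both accepted.
        The output has the dtype of the input.
    max_window
        Largest window side length, odd and >= 3.
    """
    if max_window < 3 or max_window % 2 == 0:
        raise ValueError(f"max_window must be odd and >= 3, got {max_window}")
    arr = np.asarray(image)
    was_bool = arr.dtype == bool
    work = arr.astype(np.uint8) if was_bool else arr

    out = np.empty_like(work)
    decided = np.zeros(arr.shape, dtype=bool)
    zmed = work
    for w in range(3, max_window + 1, 2):
        zmin = ndi.minimum_filter(work, size=w)
        zmed = ndi.median_filter(work, size=w)
        zmax = ndi.maximum_filter(work, size=w)
        stage_a = (zmin < zmed) & (zmed < zmax) & ~decided
        # stage B: keep the pixel unless it is itself an impulse
        keep = (zmin < work) & (work < zmax)
        out[stage_a] = np.where(keep, work, zmed)[stage_a]
        decided |= stage_a
    out[~decided] = zmed[~decided]
    return out.astype(bool) if was_bool else out
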