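"""Brute-force reference implementations used as independent oracles.

Everything here is written from the mathematical definitions (shift-and-min
Minkowski morphology, iterative geodesic reconstruction, plateau flood fill,
exhaustive threshold scans) and deliberately avoids the code paths of the
package under test. Intended for tiny images only.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


def disk_offsets(r: int) -> list[tuple[int, int]]:
    return [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= r * r
    ]


def _shift_reduce(image: np.ndarray, offsets, reduce_fn, init) -> np.ndarray:
    r = max(max(abs(dy), abs(dx)) for dy, dx in offsets)
    p = np.pad(image, r, mode="symmetric")
    h, w = image.shape
    out = np.full_like(image, init, dtype=np.float64)
    for dy, dx in offsets:
        out = reduce_fn(out, p[r + dy : r + dy + h, r + dx : r + dx + w])
    return out


def erode_disk(image: np.ndarray, r: int) -> np.ndarray:
    return _shift_reduce(image, disk_offsets(r), np.minimum, np.inf)


def dilate_disk(image: np.ndarray, r: int) -> np.ndarray:
    return _shift_reduce(image, disk_offsets(r), np.maximum, -np.inf)


def white_tophat(image: np.ndarray, r: int) -> np.ndarray:
    return image - dilate_disk(erode_disk(image, r), r)


def adaptive_median(image: np.ndarray, max_window: int = 7) -> np.ndarray:
    """Per-pixel adaptive median with growing windows, symmetric borders."""
    h, w = image.shape
    out = np.empty_like(image)
    pmax = max_window // 2
    p = np.pad(image, pmax, mode="symmetric")
    for i in range(h):
        for j in range(w):
            for win_size in range(3, max_window + 1, 2):
                k = win_size // 2
                win = p[i + pmax - k : i + pmax + k + 1, j + pmax - k : j + pmax + k + 1]
                zmin, zmed, zmax = win.min(), np.median(win), win.max()
                if zmin < zmed < zmax:
                    out[i, j] = image[i, j] if zmin < image[i, j] < zmax else zmed
                    break
            else:
                out[i, j] = zmed
    return out


def _dilate8_unpadded(image: np.ndarray) -> np.ndarray:
    p = np.pad(image, 1, mode="constant", constant_values=-np.inf)
    h, w = image.shape
    out = image.copy()
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            out = np.maximum(out, p[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w])
    return out


def reconstruct_by_dilation(seed: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Geodesic reconstruction: iterate 8-connected dilation clipped by mask."""
    rec = np.minimum(seed, mask)
    while True:
        new = np.minimum(_dilate8_unpadded(rec), mask)
        if np.array_equal(new, rec):
            return rec
        rec = new


def regional_maxima(image: np.ndarray) -> np.ndarray:
    """Plateau-aware 8-connected regional maxima by explicit flood fill."""
    h, w = image.shape
    visited = np.zeros((h, w), dtype=bool)
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            if visited[i, j]:
                continue
            val = image[i, j]
            stack = [(i, j)]
            plateau = []
            visited[i, j] = True
            is_max = True
            while stack:
                y, x = stack.pop()
                plateau.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w:
                            if image[yy, xx] == val:
                                if not visited[yy, xx]:
                                    visited[yy, xx] = True
                                    stack.append((yy, xx))
                            elif image[yy, xx] > val:
                                is_max = False
            if is_max:
                for y, x in plateau:
                    out[y, x] = True
    return out


def otsu_scan_from_data(values: np.ndarray) -> float:
    """Exhaustive threshold scan, class statistics from the raw data values."""
    values = np.asarray(values, dtype=np.float64).ravel()
    vmin, vmax = values.min(), values.max()
    assert vmin < vmax
    _, edges = np.histogram(values, bins=256, range=(vmin, vmax))
    best_t, best_v = None, -np.inf
    for t in edges[1:]:
        fg = values >= t
        n1 = fg.sum()
        n0 = values.size - n1
        if n0 == 0 or n1 == 0:
            continue
        mu0, mu1 = values[~fg].mean(), values[fg].mean()
        v = (n0 / values.size) * (n1 / values.size) * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return float(best_t)


def otsu_scan_from_histogram(values: np.ndarray) -> float:
    """Exhaustive scan over 256-bin edges, moments from counts and centers."""
    values = np.asarray(values, dtype=np.float64).ravel()
    vmin, vmax = values.min(), values.max()
    assert vmin < vmax
    counts, edges = np.histogram(values, bins=256, range=(vmin, vmax))
    centers = (edges[:-1] + edges[1:]) / 2.0
    n = counts.sum()
    best_t, best_v = None, -np.inf
    for k in range(1, 256):
        w0 = counts[:k].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = float((counts[:k] * centers[:k]).sum()) / w0
        mu1 = float((counts[k:] * centers[k:]).sum()) / w1
        v = float(w0) * float(w1) * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, edges[k]
    return float(best_t)


def count_foci(
    foci_values: np.ndarray,
    labels: np.ndarray,
    r_f: int,
    t_e: float,
    max_window: int = 7,
) -> dict[int, int]:
    """Full brute-force foci count per labeled object.

    Adaptive median -> top-hat(disk r_f) -> h = Otsu of top-hat over object
    pixels -> H-maxima candidates -> gate on max original intensity > t_e,
    attribution to the object holding the brightest in-object pixel
    (ties -> lowest label).
    """
    counts = {int(lab): 0 for lab in np.unique(labels) if lab > 0}
    filtered = adaptive_median(foci_values, max_window)
    tophat = white_tophat(filtered, r_f)
    inside = tophat[labels > 0]
    if inside.min() == inside.max():
        return counts
    h = otsu_scan_from_histogram(inside)
    if h <= 0:
        return counts
    hmax = reconstruct_by_dilation(tophat - h, tophat)
    maxima = regional_maxima(hmax)
    comp, n_comp = ndi.label(maxima, structure=np.ones((3, 3)))
    for c in range(1, n_comp + 1):
        member = comp == c
        if foci_values[member].max() <= t_e:
            continue
        in_obj = member & (labels > 0)
        if not in_obj.any():
            continue
        vals = foci_values[in_obj]
        winner = int(labels[in_obj][vals == vals.max()].min())
        counts[winner] += 1
    return counts
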