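"""Synthetic two-channel fixtures with known ground truth.

The generator emulates the acquisition geometry of 8-bit two-channel confocal
tile scans: a nuclei channel of anti-aliased filled ellipses on a dark
background, and a foci channel of isotropic Gaussian spots planted inside the
nuclei, both with additive Gaussian noise clipped to [0, 1] and quantized to
the declared bit depth AFTER noise.  Nuclei are placed without overlap (and
with a gap wide enough that the closing step cannot bridge them), foci with a
minimum pairwise separation so every planted spot is a resolvable regional
maximum.

Dose series plant a per-nucleus mean density that is linear in dose,
``intercept + slope * dose``, with Gaussian object-level noise; the realized
count of each nucleus is the rounded product of its drawn density and its
rendered pixel area, so the recorded truth is exact to rounding.

Toy voxel dose grids pair a reference dose distribution with a copy scaled by
a known enhancement factor inside a spherical target, with controllable
out-of-target spill for conformity tests.

Default frames are 512x512 (full-size 1880x1880 generation just means passing
that ``image_size``); all randomness flows from the mandatory integer seed.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Callable, Sequence

import numpy as np
from skimage import draw

from .dosemetrics import DoseGrid, StructureMask
from .errors import PlacementError, SceneSpecError
from .imaging import ChannelPair, Raster2D

FociCountSpec = int | Sequence[int] | Callable[[int, np.random.Generator], int]


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field.

    ``nucleus_radius_range`` bounds both ellipse semi-axes (px); keep the
    lower bound above the segmentation minimum radius (25 px) for fixtures
    whose nuclei should all be detectable. ``foci_per_nucleus`` is an int, a
    per-nucleus sequence, or a callable ``(area_px, rng) -> count``.
    """

    seed: int
    image_size: tuple[int, int] = (512, 512)
    n_nuclei: int = 12
    nucleus_radius_range: tuple[float, float] = (30.0, 60.0)
    nucleus_intensity: float = 0.7
    focus_sigma_px: float = 3.0
    focus_peak_range: tuple[float, float] = (0.6, 0.9)
    background_noise_sd: float = 0.02
    foci_per_nucleus: FociCountSpec = 5
    min_focus_separation_px: float | None = None  # default 5 * sigma
    nucleus_gap_px: float = 12.0
    bit_depth: int = 8
    dose_gy: float = 0.0
    group: str = "control"
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise SceneSpecError("n_nuclei must be >= 0")
        lo, hi = self.nucleus_radius_range
        if not 1.0 <= lo <= hi:
            raise SceneSpecError("invalid nucleus_radius_range")
        plo, phi = self.focus_peak_range
        if not 0.0 < plo <= phi <= 1.0:
            raise SceneSpecError("focus_peak_range must lie in (0, 1]")
        if not 0.0 < self.nucleus_intensity <= 1.0:
            raise SceneSpecError("nucleus_intensity must lie in (0, 1]")


@dataclasses.dataclass(frozen=True)
class NucleusTruth:
    center: tuple[float, float]  # (row, col)
    radii: tuple[float, float]
    orientation: float
    area_px: int


@dataclasses.dataclass(frozen=True)
class FocusTruth:
    nucleus_index: int
    position: tuple[float, float]
    peak: float


@dataclasses.dataclass(frozen=True)
class SceneTruth:
    nuclei: list[NucleusTruth]
    foci: list[FocusTruth]
    per_nucleus_density: list[float]


def _quantize(img: np.ndarray, bit_depth: int) -> np.ndarray:
    full = 2**bit_depth - 1
    q = np.round(np.clip(img, 0.0, 1.0) * full)
    return q.astype(np.uint8 if bit_depth <= 8 else np.uint16)


def _place_nuclei(spec: SceneSpec, rng: np.random.Generator):
    h, w = spec.image_size
    lo, hi = spec.nucleus_radius_range
    placed: list[tuple[float, float, float, float, float]] = []  # cy, cx, a, b, theta
    for i in range(spec.n_nuclei):
        for _ in range(500):
            a, b = rng.uniform(lo, hi, size=2)
            rmax = max(a, b)
            if 2 * rmax + 4 >= min(h, w):
                continue
            cy = rng.uniform(rmax + 2, h - rmax - 2)
            cx = rng.uniform(rmax + 2, w - rmax - 2)
            ok = all(
                math.hypot(cy - py, cx - px)
                >= rmax + max(pa, pb) + spec.nucleus_gap_px
                for py, px, pa, pb, _ in placed
            )
            if ok:
                placed.append((cy, cx, a, b, rng.uniform(0.0, math.pi)))
                break
        else:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{spec.n_nuclei} in "
                f"{spec.image_size} after 500 attempts"
            )
    return placed


def _sample_foci_positions(
    nucleus, n: int, margin: float, min_sep: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    cy, cx, a, b, theta = nucleus
    ia, ib = a - margin, b - margin
    if min(ia, ib) <= 0:
        raise SceneSpecError("nucleus too small for the focus margin")
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    positions: list[tuple[float, float]] = []
    sep = min_sep
    floor = 2.0  # never relax below 2 px
    tries = 0
    while len(positions) < n:
        r = math.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * math.pi)
        u, v = r * math.cos(phi) * ia, r * math.sin(phi) * ib
        py = cy + u * cos_t - v * sin_t
        px = cx + u * sin_t + v * cos_t
        if all(math.hypot(py - qy, px - qx) >= sep for qy, qx in positions):
            positions.append((py, px))
            tries = 0
        else:
            tries += 1
            if tries > 200:  # relax separation rather than fail a large batch
                sep = max(floor, sep * 0.8)
                tries = 0
    return positions


def _resolve_counts(
    spec: SceneSpec, areas: list[int], rng: np.random.Generator
) -> list[int]:
    f = spec.foci_per_nucleus
    if callable(f):
        return [max(0, int(f(area, rng))) for area in areas]
    if isinstance(f, int):
        return [f] * len(areas)
    counts = [int(c) for c in f]
    if len(counts) != len(areas):
        raise SceneSpecError("foci_per_nucleus sequence length != n_nuclei")
    return counts


def generate_scene(spec: SceneSpec) -> tuple[ChannelPair, SceneTruth]:
    """Render one two-channel field and its exact ground truth.

    Bit-identical for identical specs (the seed drives all randomness).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    sigma = spec.focus_sigma_px
    min_sep = (
        spec.min_focus_separation_px
        if spec.min_focus_separation_px is not None
        else 5.0 * sigma
    )

    placed = _place_nuclei(spec, rng)

    # anti-aliased nuclei rendering: 2x supersampled fill, box-downsampled
    ss = np.zeros((2 * h, 2 * w), dtype=np.float64)
    areas: list[int] = []
    nuclei_truth: list[NucleusTruth] = []
    for cy, cx, a, b, theta in placed:
        rr, cc = draw.ellipse(
            2 * cy, 2 * cx, 2 * a, 2 * b, shape=ss.shape, rotation=theta
        )
        ss[rr, cc] = 1.0
        rr1, cc1 = draw.ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
        areas.append(len(rr1))
        nuclei_truth.append(
            NucleusTruth(center=(cy, cx), radii=(a, b), orientation=theta,
                         area_px=len(rr1))
        )
    coverage = ss.reshape(h, 2, w, 2).mean(axis=(1, 3))
    nuclei_img = coverage * spec.nucleus_intensity

    counts = _resolve_counts(spec, areas, rng)
    foci_img = np.zeros((h, w), dtype=np.float64)
    foci_truth: list[FocusTruth] = []
    patch = int(math.ceil(4 * sigma))
    for idx, (nucleus, n_foci) in enumerate(zip(placed, counts)):
        if n_foci == 0:
            continue
        positions = _sample_foci_positions(nucleus, n_foci, 2 * sigma + 1, min_sep, rng)
        for py, px in positions:
            peak = rng.uniform(*spec.focus_peak_range)
            y0, y1 = max(0, int(py) - patch), min(h, int(py) + patch + 1)
            x0, x1 = max(0, int(px) - patch), min(w, int(px) + patch + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            foci_img[y0:y1, x0:x1] += peak * np.exp(
                -((yy - py) ** 2 + (xx - px) ** 2) / (2.0 * sigma**2)
            )
            foci_truth.append(FocusTruth(idx, (py, px), peak))

    if spec.background_noise_sd > 0:
        nuclei_img = nuclei_img + rng.normal(0.0, spec.background_noise_sd, (h, w))
        foci_img = foci_img + rng.normal(0.0, spec.background_noise_sd, (h, w))

    pair = ChannelPair(
        nuclei=Raster2D(_quantize(nuclei_img, spec.bit_depth), spec.bit_depth),
        foci=Raster2D(_quantize(foci_img, spec.bit_depth), spec.bit_depth),
        image_id=spec.image_id or f"scene-{spec.seed}",
        dose_gy=spec.dose_gy,
        group=spec.group,
    )
    densities = [c / a for c, a in zip(counts, areas)]
    return pair, SceneTruth(nuclei=nuclei_truth, foci=foci_truth,
                            per_nucleus_density=densities)


@dataclasses.dataclass(frozen=True)
class SeriesTruth:
    """Planted linear dose response and the per-scene realized truths."""

    slope_per_gy: float
    intercept: float
    noise_sd: float
    doses: tuple[float, ...]
    scene_truths: dict[float, list[SceneTruth]]

    def realized_mean_density(self, dose: float) -> float:
        ds = [d for t in self.scene_truths[dose] for d in t.per_nucleus_density]
        return float(np.mean(ds))


def generate_dose_series(
    slope_per_gy: float,
    intercept: float,
    doses: Sequence[float] = (0.0, 0.25, 0.5, 1.0, 2.0),
    objects_per_dose: int = 200,
    noise_sd: float = 1e-4,
    seed: int = 0,
    group: str = "control",
    image_size: tuple[int, int] = (512, 512),
    n_nuclei_per_scene: int = 16,
    nucleus_radius_range: tuple[float, float] = (28.0, 40.0),
    **scene_overrides,
) -> tuple[list[ChannelPair], SeriesTruth]:
    """Generate scenes realizing a linear dose response in planted density.

    Mirrors the in-vitro design: doses {0, 0.25, 0.5, 1, 2} Gy with at least
    ``objects_per_dose`` nuclei per condition. Each nucleus draws a target
    density from ``Normal(intercept + slope * dose, noise_sd)`` (clipped at 0)
    realized as ``round(density * area)`` planted foci.
    """
    if slope_per_gy < 0:
        raise SceneSpecError("slope_per_gy must be >= 0")
    for d in doses:
        if intercept + slope_per_gy * d < 0:
            raise SceneSpecError(f"negative planted density at {d} Gy")

    master = np.random.default_rng(seed)
    pairs: list[ChannelPair] = []
    truths: dict[float, list[SceneTruth]] = {}
    n_scenes = max(1, math.ceil(objects_per_dose / n_nuclei_per_scene))
    for dose in doses:
        mu = intercept + slope_per_gy * dose
        truths[dose] = []
        for k in range(n_scenes):
            def planted_count(area: int, rng: np.random.Generator, _mu=mu) -> int:
                return max(0, int(round(rng.normal(_mu, noise_sd) * area)))

            spec = SceneSpec(
                seed=int(master.integers(0, 2**31 - 1)),
                image_size=image_size,
                n_nuclei=n_nuclei_per_scene,
                nucleus_radius_range=nucleus_radius_range,
                foci_per_nucleus=planted_count,
                dose_gy=float(dose),
                group=group,
                image_id=f"{group}-{dose:g}Gy-{k:02d}",
                **scene_overrides,
            )
            pair, truth = generate_scene(spec)
            pairs.append(pair)
            truths[dose].append(truth)
    return pairs, SeriesTruth(
        slope_per_gy=slope_per_gy,
        intercept=intercept,
        noise_sd=noise_sd,
        doses=tuple(float(d) for d in doses),
        scene_truths=truths,
    )


def generate_dose_grids(
    shape: tuple[int, int, int] = (32, 32, 32),
    btv_center: tuple[float, float, float] | None = None,
    btv_radius: float = 8.0,
    enhancement: float = 1.159,
    spill_fraction: float = 0.0,
    seed: int = 0,
    prescription_gy: float = 70.0,
    background_fraction: float = 0.3,
    noise_sd: float = 0.0,
) -> tuple[DoseGrid, DoseGrid, StructureMask]:
    """Paired with/without dose grids and a spherical target mask.

    The without-grid delivers the prescription inside the target plus
    ``round(spill_fraction * V)`` spill voxels in the shell just outside it,
    over a uniform low-dose background; the with-grid is the without-grid
    scaled by ``enhancement`` inside the target, optionally jittered.
    """
    if enhancement <= 0:
        raise SceneSpecError("enhancement must be > 0")
    rng = np.random.default_rng(seed)
    center = (
        np.asarray(btv_center, dtype=np.float64)
        if btv_center is not None
        else (np.asarray(shape, dtype=np.float64) - 1) / 2.0
    )
    if np.any(center - btv_radius < -0.5) or np.any(
        center + btv_radius > np.asarray(shape) - 0.5
    ):
        raise SceneSpecError("BTV sphere does not fit inside the grid")

    zz, yy, xx = np.indices(shape)
    dist = np.sqrt(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )
    btv = dist <= btv_radius
    if not btv.any():
        raise SceneSpecError("BTV mask is empty")

    without = np.full(shape, background_fraction * prescription_gy)
    without[btv] = prescription_gy
    n_spill = int(round(spill_fraction * btv.sum()))
    if n_spill:
        outside = np.flatnonzero(~btv.ravel())
        order = np.argsort(dist.ravel()[outside], kind="stable")
        if n_spill > outside.size:
            raise SceneSpecError("spill_fraction too large for the grid")
        flat = without.ravel()
        flat[outside[order[:n_spill]]] = prescription_gy
        without = flat.reshape(shape)

    with_np = without.copy()
    factors = enhancement + (
        rng.normal(0.0, noise_sd, int(btv.sum())) if noise_sd > 0 else 0.0
    )
    with_np[btv] = without[btv] * factors
    return (
        DoseGrid(with_np),
        DoseGrid(without),
        StructureMask(btv, name="BTV"),
    )
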