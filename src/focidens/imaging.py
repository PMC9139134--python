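"""Image containers and I/O.

Two-channel fluorescence micrographs are carried as a :class:`ChannelPair`
(nuclei stain + foci channel) together with the per-image experimental
metadata (dose in Gy, treatment group).  Pixel coordinates are 0-based,
row-major ``(row, column)`` throughout the package.

Rasters are either *raw* (integer counts at a declared bit depth, 8 expected)
or *normalized* (real values in [0, 1] obtained by dividing by the full-scale
value ``2**bit_depth - 1``).  The foci intensity threshold ``T_e`` operates on
the normalized scale, so the foci channel must be normalized exactly once
before detection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, ContractError, FormatError

logger = logging.getLogger(__name__)

GROUPS = ("control", "treated")

_BIT_DEPTHS = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


@dataclasses.dataclass(frozen=True)
class Raster2D:
    """A single-channel 2-D image.

    Parameters
    ----------
    values
        2-D array. Integer counts when ``normalized`` is False, floats in
        [0, 1] when True.
    bit_depth
        Bits per pixel of the acquisition (8 expected; 16 accepted).
    normalized
        Whether ``values`` are on the [0, 1] scale.
    """

    values: np.ndarray
    bit_depth: int = 8
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise FormatError(f"Raster2D requires a 2-D array, got shape {v.shape}")
        object.__setattr__(self, "values", v)
        if self.normalized:
            if v.min() < 0.0 or v.max() > 1.0:
                raise FormatError("normalized raster has values outside [0, 1]")
        else:
            full_scale = 2**self.bit_depth - 1
            if v.min() < 0 or v.max() > full_scale:
                raise FormatError(
                    f"raw raster has values outside [0, {full_scale}] "
                    f"for bit depth {self.bit_depth}"
                )

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclasses.dataclass(frozen=True)
class ChannelPair:
    """Aligned nuclei/foci rasters of one field with its metadata."""

    nuclei: Raster2D
    foci: Raster2D
    image_id: str
    dose_gy: float
    group: str

    def __post_init__(self) -> None:
        if self.nuclei.shape != self.foci.shape:
            raise FormatError(
                f"channel shapes differ: nuclei {self.nuclei.shape} "
                f"vs foci {self.foci.shape}"
            )
        if self.dose_gy < 0:
            raise FormatError(f"dose_gy must be >= 0, got {self.dose_gy}")
        if self.group not in GROUPS:
            raise FormatError(f"group must be one of {GROUPS}, got {self.group!r}")


def normalize(raster: Raster2D) -> Raster2D:
    """Map a raw-integer raster onto [0, 1] by dividing by ``2**bit_depth - 1``.

    Normalization is monotone and exact at the endpoints (0 -> 0.0,
    full scale -> 1.0). Applying it to an already-normalized raster is an
    error: double normalization would silently rescale ``T_e``.
    """
    if raster.normalized:
        raise ContractError("raster is already normalized; refusing to renormalize")
    full_scale = 2**raster.bit_depth - 1
    return Raster2D(
        values=np.asarray(raster.values, dtype=np.float64) / full_scale,
        bit_depth=raster.bit_depth,
        normalized=True,
    )


def _extract_channel(arr: np.ndarray, index: int) -> np.ndarray:
    """Select one channel plane from a 2-D or 3-D TIFF array.

    Channel order is never assumed; the caller supplies the index and, for 3-D
    stacks, the channel axis is taken to be the shortest axis (ties -> axis 0),
    which covers both planar (C, H, W) and interleaved (H, W, C) layouts.
    """
    if arr.ndim == 2:
        if index != 0:
            raise ConfigurationError(
                f"channel index {index} out of range for single-channel image"
            )
        return arr
    if arr.ndim == 3:
        axis = int(np.argmin(arr.shape))
        n_channels = arr.shape[axis]
        if not 0 <= index < n_channels:
            raise ConfigurationError(
                f"channel index {index} out of range for {n_channels} channels"
            )
        return np.take(arr, index, axis=axis)
    raise FormatError(f"unsupported TIFF dimensionality: {arr.ndim}")


def read_image(
    path: str | Path,
    nuclei_channel_index: int,
    foci_channel_index: int,
    dose_gy: float,
    group: str,
    image_id: str | None = None,
) -> ChannelPair:
    """Read a single- or multi-channel TIFF into an aligned :class:`ChannelPair`.

    Raw intensities are preserved bit-exactly; the bit depth is taken from the
    file's dtype (uint8 -> 8, uint16 -> 16).
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise OSError(f"could not read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.dtype not in _BIT_DEPTHS:
        raise FormatError(f"{path}: unsupported pixel dtype {arr.dtype}")
    depth = _BIT_DEPTHS[arr.dtype]
    nuclei = _extract_channel(arr, nuclei_channel_index)
    foci = _extract_channel(arr, foci_channel_index)
    if nuclei.shape != foci.shape:
        raise FormatError(f"{path}: channel shapes differ")
    return ChannelPair(
        nuclei=Raster2D(nuclei, bit_depth=depth),
        foci=Raster2D(foci, bit_depth=depth),
        image_id=image_id if image_id is not None else path.stem,
        dose_gy=float(dose_gy),
        group=group,
    )


def write_channel_pair(pair: ChannelPair, path: str | Path) -> None:
    """Write a raw ChannelPair as a planar (2, H, W) TIFF (nuclei first)."""
    if pair.nuclei.normalized or pair.foci.normalized:
        raise ContractError("only raw-integer channel pairs are written to TIFF")
    dtype = np.uint8 if pair.nuclei.bit_depth == 8 else np.uint16
    stack = np.stack(
        [pair.nuclei.values.astype(dtype), pair.foci.values.astype(dtype)]
    )
    tifffile.imwrite(Path(path), stack)


def write_results(records, path: str | Path, params: dict | None = None) -> None:
    """Write a homogeneous collection of result dataclasses to CSV.

    One row per record; run parameters are echoed to a ``<path>.params.json``
    sidecar. An empty collection produces a header-only CSV (with a warning)
    using the per-object foci-result columns.
    """
    path = Path(path)
    records = list(records)
    if records:
        rows = [dataclasses.asdict(r) for r in records]
        frame = pd.DataFrame(rows)
    else:
        warnings.warn("writing header-only CSV: empty record collection")
        from .foci import FociResult

        frame = pd.DataFrame(columns=[f.name for f in dataclasses.fields(FociResult)])
    frame.to_csv(path, index=False)
    sidecar = path.with_name(path.name + ".params.json")
    with open(sidecar, "w") as fh:
        json.dump(params or {}, fh, indent=2, default=str)
    logger.info("wrote %d rows to %s", len(records), path)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_results`."""
    return pd.read_csv(Path(path))
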