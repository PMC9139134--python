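"""Treatment-plan evaluation metrics on voxel dose grids.

Dose enhancement factor (DEF): voxelwise ratio of the absorbed dose with vs
without nanoparticles over a target mask, reported as mean +/- sample SD of
the per-voxel ratios.

Conformity number (CN) at a percentage ``p`` of the prescription dose, with
``V`` the target (BTV) voxel count, ``Vp`` the target voxels receiving at
least ``p%`` of the prescription and ``Tp`` all voxels receiving at least
that dose:

    CN_p = (Vp / V) * (Vp / Tp)

i.e. coverage times selectivity; CN = 1 iff the at-dose region coincides with
the target exactly, and CN = 0 by convention when no voxel reaches the
threshold.  "Receiving" uses the inclusive >= comparison, the standard DVH
convention.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .errors import ContractError

DEFAULT_CN_PERCENTS = (100.0, 90.0)


@dataclasses.dataclass(frozen=True)
class DoseGrid:
    """3-D absorbed-dose grid in Gy with voxel spacing in mm."""

    doses: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=np.float64)
        if d.ndim != 3:
            raise ContractError(f"dose grid must be 3-D, got shape {d.shape}")
        if d.min() < 0:
            raise ContractError("doses must be nonnegative")
        object.__setattr__(self, "doses", d)

    @property
    def d_max(self) -> float:
        return float(self.doses.max())


@dataclasses.dataclass(frozen=True)
class StructureMask:
    """Binary structure (target or organ-at-risk) congruent with a DoseGrid."""

    mask: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3:
            raise ContractError(f"structure mask must be 3-D, got shape {m.shape}")
        object.__setattr__(self, "mask", m)


@dataclasses.dataclass(frozen=True)
class DEFReport:
    mean: float
    sd: float
    per_voxel: np.ndarray
    n_excluded_zero_denominator: int = 0


def _doses(grid) -> np.ndarray:
    return grid.doses if isinstance(grid, DoseGrid) else np.asarray(grid, dtype=np.float64)


def _mask(structure) -> np.ndarray:
    return structure.mask if isinstance(structure, StructureMask) else np.asarray(structure, dtype=bool)


def dose_enhancement_factor(dose_with, dose_without, target_mask) -> DEFReport:
    """Per-voxel dose ratio with/without nanoparticles over the target.

    Voxels whose without-nanoparticle dose is zero are excluded from the
    distribution (with a warning) and counted in the report. ``sd`` is the
    sample standard deviation (0 for a single voxel).
    """
    dw = _doses(dose_with)
    dwo = _doses(dose_without)
    mask = _mask(target_mask)
    if dw.shape != dwo.shape or dw.shape != mask.shape:
        raise ContractError(
            f"incongruent grids/mask: {dw.shape}, {dwo.shape}, {mask.shape}"
        )
    if not mask.any():
        raise ContractError("target mask is empty")
    num = dw[mask]
    den = dwo[mask]
    ok = den > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} target voxels with zero reference dose excluded",
            stacklevel=2,
        )
    ratios = num[ok] / den[ok]
    if ratios.size == 0:
        raise ContractError("no target voxel has a positive reference dose")
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    return DEFReport(
        mean=float(ratios.mean()),
        sd=sd,
        per_voxel=ratios,
        n_excluded_zero_denominator=n_excluded,
    )


def conformity_number(dose, btv_mask, prescription_gy: float, percent: float = 100.0) -> float:
    """Conformity number at ``percent`` of the prescription dose; in [0, 1]."""
    if prescription_gy <= 0:
        raise ContractError("prescription_gy must be > 0")
    if not 0.0 < percent <= 200.0:
        raise ContractError("percent must lie in (0, 200]")
    d = _doses(dose)
    btv = _mask(btv_mask)
    if d.shape != btv.shape:
        raise ContractError(f"dose {d.shape} and BTV mask {btv.shape} incongruent")
    v = int(btv.sum())
    if v == 0:
        raise ContractError("BTV mask is empty")
    threshold = percent / 100.0 * prescription_gy
    at_dose = d >= threshold
    tp = int(at_dose.sum())
    if tp == 0:
        return 0.0
    vp = int((at_dose & btv).sum())
    return (vp / v) * (vp / tp)
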