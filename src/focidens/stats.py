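"""Dose-response statistics on per-object foci densities.

Per image, object densities are screened with Tukey fences
``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` (linear-interpolation quartiles, one pass);
kept densities are pooled per (group, dose) condition into mean +/- SEM, the
condition means are regressed on dose by ordinary least squares, and the
radiosensitization factor is the ratio of the treated to the control
gradient.  Pearson-correlation and Shapiro-Wilk residual-normality p-values
are reported as diagnostics only; they never gate the fit.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from collections.abc import Sequence

import numpy as np
from scipy import stats as sps

from .errors import EmptyConditionError, InsufficientDataError, UndefinedFactorError

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ConditionSummary:
    """Mean +/- SEM of kept per-object densities at one (group, dose)."""

    group: str
    dose_gy: float
    n_objects_raw: int
    n_outliers_removed: int
    mean_density: float
    sem_density: float


@dataclasses.dataclass(frozen=True)
class DoseResponseFit:
    """OLS fit of condition mean density on dose for one group.

    ``slope`` is the gradient in density units per Gy; ``r_squared`` the
    squared Pearson correlation of the fitted points; ``pearson_p`` the
    p-value of the Pearson correlation test; ``shapiro_p`` the Shapiro-Wilk
    p-value on the fit residuals (NaN when the residuals are numerically
    degenerate, e.g. a perfect fit).
    """

    group: str
    slope: float
    intercept: float
    r_squared: float
    pearson_p: float
    shapiro_p: float


def exclude_outliers(densities) -> tuple[np.ndarray, np.ndarray]:
    """One-pass Tukey-fence screening of the densities of ONE image.

    Quartiles use linear interpolation between order statistics; values
    strictly outside ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` are removed. Fewer than
    4 values: nothing is excluded (a warning is emitted), since quartiles of
    so few points are not meaningful.
    """
    d = np.asarray(list(densities), dtype=np.float64)
    if d.size < 4:
        if d.size:
            warnings.warn(
                f"only {d.size} densities: outlier exclusion skipped", stacklevel=2
            )
        return d, np.empty(0, dtype=np.float64)
    q1, q3 = np.percentile(d, [25.0, 75.0])  # method='linear' default
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (d >= lo) & (d <= hi)
    return d[keep], d[~keep]


def summarize_condition(
    kept_densities,
    *,
    group: str,
    dose_gy: float,
    n_objects_raw: int | None = None,
    n_outliers_removed: int = 0,
) -> ConditionSummary:
    """Mean and SEM (sample SD / sqrt(n)) over kept object densities.

    A single-object condition gets SEM 0 by convention (flagged with a
    warning); zero kept objects is an error.
    """
    d = np.asarray(list(kept_densities), dtype=np.float64)
    if d.size == 0:
        raise EmptyConditionError(f"no kept objects for {group} at {dose_gy} Gy")
    if d.size == 1:
        warnings.warn(
            f"single object for {group} at {dose_gy} Gy: SEM set to 0", stacklevel=2
        )
        sem = 0.0
    else:
        sem = float(np.std(d, ddof=1) / np.sqrt(d.size))
    return ConditionSummary(
        group=group,
        dose_gy=float(dose_gy),
        n_objects_raw=int(n_objects_raw if n_objects_raw is not None else d.size),
        n_outliers_removed=int(n_outliers_removed),
        mean_density=float(np.mean(d)),
        sem_density=sem,
    )


def fit_dose_response(summaries: Sequence[ConditionSummary]) -> DoseResponseFit:
    """OLS of condition mean density on dose for one group's summaries.

    Needs at least 3 distinct dose levels; the design is expected to include
    an unirradiated 0 Gy control (warned about if missing, not enforced).
    """
    if not summaries:
        raise InsufficientDataError("no condition summaries")
    groups = {s.group for s in summaries}
    if len(groups) != 1:
        raise InsufficientDataError(f"summaries mix groups: {sorted(groups)}")
    ordered = sorted(summaries, key=lambda s: s.dose_gy)
    doses = np.asarray([s.dose_gy for s in ordered])
    means = np.asarray([s.mean_density for s in ordered])
    if len(np.unique(doses)) < 3:
        raise InsufficientDataError(
            f"dose-response fit needs >= 3 dose levels, got {len(np.unique(doses))}"
        )
    if 0.0 not in doses:
        warnings.warn("no 0 Gy control among the dose levels", stacklevel=2)

    res = sps.linregress(doses, means)
    residuals = means - (res.intercept + res.slope * doses)
    if residuals.size >= 3 and np.ptp(residuals) > 1e-12 * max(np.ptp(means), 1e-300):
        shapiro_p = float(sps.shapiro(residuals).pvalue)
    else:
        shapiro_p = float("nan")
    return DoseResponseFit(
        group=ordered[0].group,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pearson_p=float(res.pvalue),
        shapiro_p=shapiro_p,
    )


def relative_summaries(summaries: Sequence[ConditionSummary]) -> list[ConditionSummary]:
    """Rescale one group's summaries by its 0 Gy mean (relative foci density)."""
    baseline = [s for s in summaries if s.dose_gy == 0.0]
    if not baseline or baseline[0].mean_density <= 0:
        raise InsufficientDataError("relative mode needs a positive 0 Gy mean")
    b = baseline[0].mean_density
    return [
        dataclasses.replace(s, mean_density=s.mean_density / b, sem_density=s.sem_density / b)
        for s in summaries
    ]


def radiosensitization_factor(fit_treated, fit_control) -> float:
    """Ratio of the treated to the control dose-response gradient.

    Accepts :class:`DoseResponseFit` objects or bare slopes. A nonpositive
    control gradient leaves the factor undefined.
    """
    slope_t = getattr(fit_treated, "slope", fit_treated)
    slope_c = getattr(fit_control, "slope", fit_control)
    if slope_c <= 0:
        raise UndefinedFactorError(
            f"control gradient must be > 0, got {slope_c}"
        )
    if slope_t <= 0:
        warnings.warn("treated gradient is nonpositive", stacklevel=2)
    return float(slope_t) / float(slope_c)
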