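"""End-to-end orchestration: images -> densities -> fits -> factor.

This is the glue the CLI and the analysis scripts use: segment each field's
nuclei channel, detect foci with the group's parameters, screen outliers per
image, pool kept densities per (group, dose), fit each group's linear dose
response and — when both groups are present — form the radiosensitization
factor.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

from .errors import InsufficientDataError
from .foci import FociParams, FociResult, detect_foci
from .imaging import ChannelPair, normalize
from .segmentation import LabeledObjects, SegmentationParams, segment_nuclei
from .stats import (
    ConditionSummary,
    DoseResponseFit,
    exclude_outliers,
    fit_dose_response,
    radiosensitization_factor,
    relative_summaries,
    summarize_condition,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AnalysisResult:
    per_object: list[FociResult]
    summaries: list[ConditionSummary]
    fits: dict[str, DoseResponseFit]
    factor: float | None
    relative: dict[str, list[ConditionSummary]]


def quantify_images(
    pairs: Sequence[ChannelPair],
    segmentation_params: SegmentationParams | None = None,
    foci_params_by_group: dict[str, FociParams] | None = None,
) -> list[tuple[ChannelPair, LabeledObjects, list[FociResult]]]:
    """Segment and count each field with its group's detection parameters."""
    out = []
    for pair in pairs:
        params = (foci_params_by_group or {}).get(pair.group, FociParams())
        labeled = segment_nuclei(pair.nuclei, segmentation_params)
        foci_raster = pair.foci if pair.foci.normalized else normalize(pair.foci)
        results = detect_foci(foci_raster, labeled, params, image_id=pair.image_id)
        logger.debug(
            "%s: %d objects, %d foci",
            pair.image_id, labeled.n_objects, sum(r.foci_count for r in results),
        )
        out.append((pair, labeled, results))
    return out


def analyze_dose_response(
    pairs: Sequence[ChannelPair],
    segmentation_params: SegmentationParams | None = None,
    foci_params_by_group: dict[str, FociParams] | None = None,
) -> AnalysisResult:
    """Run the full quantification and dose-response analysis."""
    quantified = quantify_images(pairs, segmentation_params, foci_params_by_group)

    per_object: list[FociResult] = []
    pooled: dict[tuple[str, float], dict[str, list]] = {}
    for pair, _labeled, results in quantified:
        per_object.extend(results)
        kept, removed = exclude_outliers([r.density for r in results])
        cond = pooled.setdefault(
            (pair.group, pair.dose_gy), {"kept": [], "n_raw": 0, "n_removed": 0}
        )
        cond["kept"].extend(kept.tolist())
        cond["n_raw"] += len(results)
        cond["n_removed"] += len(removed)

    summaries = [
        summarize_condition(
            cond["kept"],
            group=group,
            dose_gy=dose,
            n_objects_raw=cond["n_raw"],
            n_outliers_removed=cond["n_removed"],
        )
        for (group, dose), cond in sorted(pooled.items())
        if cond["kept"]
    ]

    fits: dict[str, DoseResponseFit] = {}
    relative: dict[str, list[ConditionSummary]] = {}
    for group in sorted({s.group for s in summaries}):
        group_summaries = [s for s in summaries if s.group == group]
        try:
            fits[group] = fit_dose_response(group_summaries)
        except InsufficientDataError:
            logger.warning("group %r: too few dose levels for a fit", group)
        try:
            relative[group] = relative_summaries(group_summaries)
        except InsufficientDataError:
            pass

    factor = None
    if "treated" in fits and "control" in fits and fits["control"].slope > 0:
        factor = radiosensitization_factor(fits["treated"], fits["control"])
    return AnalysisResult(
        per_object=per_object,
        summaries=summaries,
        fits=fits,
        factor=factor,
        relative=relative,
    )


def plot_dose_response(result: AnalysisResult, path) -> None:
    """Mean density vs dose with SEM error bars, fitted lines and R^2."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(5, 4))
    for group, color in (("control", "tab:blue"), ("treated", "tab:green")):
        ss = [s for s in result.summaries if s.group == group]
        if not ss:
            continue
        doses = np.array([s.dose_gy for s in ss])
        means = np.array([s.mean_density for s in ss])
        sems = np.array([s.sem_density for s in ss])
        ax.errorbar(doses, means, yerr=sems, fmt="o", color=color, capsize=3,
                    label=group)
        fit = result.fits.get(group)
        if fit is not None:
            xs = np.linspace(doses.min(), doses.max(), 50)
            ax.plot(xs, fit.intercept + fit.slope * xs, "-", color=color,
                    label=f"{group}: $R^2$={fit.r_squared:.4f}")
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("foci density (foci px$^{-1}$)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
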