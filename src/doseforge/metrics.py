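"""DVH comparison metrics and significance tests.

Degradation is quantified against the original plan with relative changes in
mean/maximum structure dose (ΔDmean, ΔDmax), relative changes in target
coverage at the 99%/95% prescription levels (ΔV99%, ΔV95%), and the absolute
change (cm³) in target volume above 107% of prescription (ΔV107%). Across a
cohort, one-sided location tests against zero establish whether a technique
moved a metric in the intended direction; normality is reported via
Shapiro–Wilk but never assumed, so the working test is the non-parametric
Wilcoxon signed-rank (a two-sample rank-sum mode is available as well).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import DoseGrid, StructureSet, logger

__all__ = [
    "dose_metrics",
    "coverage",
    "volume_above",
    "DeltaReport",
    "delta_metrics",
    "StatResult",
    "test_deltas",
    "ranksum_compare",
]


def _masked(dose: DoseGrid, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.shape:
        raise ValueError("mask is not congruent with the dose grid")
    if not mask.any():
        raise ValueError("mask is empty")
    return dose.values[mask]


def dose_metrics(dose: DoseGrid, mask: np.ndarray) -> tuple[float, float]:
    """(Dmean, Dmax) in cGy over the mask; Dmax is the single-voxel maximum."""
    vals = _masked(dose, mask)
    return float(vals.mean()), float(vals.max())


def coverage(dose: DoseGrid, mask: np.ndarray, rx: float, level: float) -> float:
    """Fraction of mask voxels receiving at least ``level``·Rx (voxel-count DVH)."""
    if rx <= 0:
        raise ValueError("prescription must be positive")
    vals = _masked(dose, mask)
    return float(np.mean(vals >= level * rx))


def volume_above(dose: DoseGrid, mask: np.ndarray, threshold: float) -> float:
    """Absolute volume (cm³) of mask voxels with dose strictly above ``threshold`` cGy."""
    vals = _masked(dose, mask)
    return float(np.sum(vals > threshold)) * dose.voxel_volume_cm3


@dataclass
class DeltaReport:
    """Per-structure DVH deltas between an original and a degraded dose.

    Relative quantities are unitless ((new − old)/old); ``delta_v107`` is the
    absolute change in cm³. Metrics whose baseline is zero are recorded in
    ``undefined`` and reported as NaN rather than silently zero.
    """

    delta_dmean: dict[str, float] = field(default_factory=dict)
    delta_dmax: dict[str, float] = field(default_factory=dict)
    delta_v99: dict[str, float] = field(default_factory=dict)
    delta_v95: dict[str, float] = field(default_factory=dict)
    delta_v107: dict[str, float] = field(default_factory=dict)
    undefined: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def _relative(new: float, old: float, label: str, undefined: list[str]) -> float:
    if old == 0:
        undefined.append(label)
        logger.warning("zero baseline for %s; relative delta undefined", label)
        return math.nan
    return (new - old) / old


def delta_metrics(
    original: DoseGrid,
    degraded: DoseGrid,
    structures: StructureSet,
    rx: float | None = None,
    metadata: dict | None = None,
) -> DeltaReport:
    """DVH deltas for every structure; coverage/V107 use each target's own Rx.

    ``rx`` overrides the per-target prescription for the volumetric metrics
    when given (e.g. to evaluate everything against a single level).
    """
    if original.shape != degraded.shape:
        raise ValueError("original and degraded grids are not congruent")
    report = DeltaReport(metadata=dict(metadata or {}))
    for name, mask in structures.iter_structures():
        mean0, max0 = dose_metrics(original, mask)
        mean1, max1 = dose_metrics(degraded, mask)
        report.delta_dmean[name] = _relative(mean1, mean0, f"{name}.dmean", report.undefined)
        report.delta_dmax[name] = _relative(max1, max0, f"{name}.dmax", report.undefined)
    for name, mask in structures.targets.items():
        level = rx if rx is not None else original.prescriptions.get(name)
        if level is None:
            raise ValueError(f"no prescription available for target {name!r}")
        v99_0 = coverage(original, mask, level, 0.99)
        v99_1 = coverage(degraded, mask, level, 0.99)
        v95_0 = coverage(original, mask, level, 0.95)
        v95_1 = coverage(degraded, mask, level, 0.95)
        report.delta_v99[name] = _relative(v99_1, v99_0, f"{name}.v99", report.undefined)
        report.delta_v95[name] = _relative(v95_1, v95_0, f"{name}.v95", report.undefined)
        report.delta_v107[name] = volume_above(degraded, mask, 1.07 * level) - volume_above(
            original, mask, 1.07 * level
        )
    return report


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    p_value: float
    alternative: str
    n: int
    shapiro_p: float | None = None
    degenerate: bool = False


def test_deltas(samples, alternative: str) -> StatResult:
    """One-sided Wilcoxon signed-rank test of the deltas' location against zero.

    Shapiro–Wilk normality is computed and reported alongside but does not
    gate the test. Exact p-values are used where the sample size permits.
    All-zero samples are degenerate: no evidence of a shift, p = 1.
    """
    x = np.asarray(list(samples), dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 samples")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    shapiro_p = float(stats.shapiro(x).pvalue) if np.ptp(x) > 0 else None
    if np.all(x == 0):
        logger.warning("all deltas are exactly zero; signed-rank test degenerate")
        return StatResult("wilcoxon_signed_rank", math.nan, 1.0, alternative, int(x.size),
                          shapiro_p, degenerate=True)
    res = stats.wilcoxon(x, alternative=alternative)
    return StatResult(
        "wilcoxon_signed_rank",
        float(res.statistic),
        float(res.pvalue),
        alternative,
        int(x.size),
        shapiro_p,
    )


def ranksum_compare(original_metrics, degraded_metrics, alternative: str) -> StatResult:
    """Two-sample Wilcoxon rank-sum mode: degraded metric population vs original.

    ``alternative`` states the hypothesis about the degraded population
    ('greater': degraded values are larger than original).
    """
    x = np.asarray(list(degraded_metrics), dtype=float)
    y = np.asarray(list(original_metrics), dtype=float)
    if x.size < 5 or y.size < 5:
        raise ValueError("need at least 5 samples per group")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    res = stats.ranksums(x, y, alternative=alternative)
    return StatResult(
        "wilcoxon_rank_sum", float(res.statistic), float(res.pvalue), alternative, int(x.size)
    )
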