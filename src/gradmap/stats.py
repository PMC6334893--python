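"""Nonparametric comparison of clusters along gradient axes.

Two clusters' gradient-value distributions (one sample per in-cluster voxel)
are compared per axis with the Mann-Whitney U test, the rank-based
nonparametric analogue of the t-test.  The exact null distribution is used
for small tie-free samples; otherwise the normal approximation with
tie-corrected variance and continuity correction.

Caveat: voxels are treated as independent observations, ignoring spatial
autocorrelation — p-values are therefore descriptive rather than strictly
calibrated for smooth imaging data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import GradientAtlas, GradientCoordinates

__all__ = ["AxisSample", "TestResult", "axis_sample", "mann_whitney", "compare_clusters"]

EXACT_MAX_N = 8

_ALTERNATIVES = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


@dataclass
class AxisSample:
    """Gradient coordinates of one cluster's voxels along one axis."""

    values: np.ndarray
    axis: int
    cluster_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("axis sample is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("axis sample contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class TestResult:
    statistic: float  # U for the first sample
    p_value: float
    method: str  # "exact" or "normal_approx"
    n1: int
    n2: int
    tie_correction_applied: bool


def axis_sample(coords: GradientCoordinates, axis: int) -> AxisSample:
    """Extract the chosen axis' coordinates for all in-cluster voxels.

    ``axis`` is the 1-indexed gradient component and must be one of the two
    axes the coordinate table was built on.
    """
    if axis not in coords.axes:
        raise ValueError(
            f"axis {axis} not in coordinate table (axes {coords.axes})"
        )
    col = "g_x" if axis == coords.axes[0] else "g_y"
    rows = coords.nonzero()
    if rows.empty:
        raise ValueError("cluster is empty; no gradient values to sample")
    return AxisSample(
        values=rows[col].to_numpy(), axis=axis, cluster_id=coords.cluster_id
    )


def mann_whitney(
    a: AxisSample,
    b: AxisSample,
    alternative: str = "two_sided",
    use_continuity: bool = True,
) -> TestResult:
    """Mann-Whitney U test between two axis samples.

    U is computed from rank sums with midrank tie handling.  The p-value is
    exact (full enumeration of the null distribution) when both samples have
    at most 8 observations and the pooled sample is tie-free; otherwise the
    normal approximation with tie-corrected variance and (optionally)
    continuity correction is used.  A pooled sample with zero variance yields
    p = 1 with a warning.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    x, y = a.values, b.values
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])

    if np.all(pooled == pooled[0]):
        warnings.warn(
            "all pooled values identical; the test is degenerate (p = 1)",
            stacklevel=2,
        )
        return TestResult(
            statistic=n1 * n2 / 2.0,
            p_value=1.0,
            method="normal_approx",
            n1=n1,
            n2=n2,
            tie_correction_applied=True,
        )

    has_ties = np.unique(pooled).size < pooled.size
    exact = n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N and not has_ties
    res = sps.mannwhitneyu(
        x,
        y,
        alternative=_ALTERNATIVES[alternative],
        method="exact" if exact else "asymptotic",
        use_continuity=use_continuity,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "normal_approx",
        n1=n1,
        n2=n2,
        tie_correction_applied=(not exact) and has_ties,
    )


def compare_clusters(
    atlas: GradientAtlas,
    coords_a: GradientCoordinates,
    coords_b: GradientCoordinates,
    axes: tuple | None = None,
    alternative: str = "two_sided",
    bonferroni: bool = False,
) -> tuple[list, dict]:
    """Per-axis Mann-Whitney tests plus distribution summaries.

    Returns ``(results, summary)`` where ``results`` has one
    :class:`TestResult` per axis (Bonferroni-adjusted across axes only if
    requested; off by default, matching per-axis reporting) and ``summary``
    carries per-cluster medians, IQRs and the raw per-axis samples for
    violin-style display.
    """
    if coords_a.axes != coords_b.axes:
        raise ValueError("coordinate tables use different gradient axes")
    axes = tuple(axes) if axes is not None else coords_a.axes
    results = []
    summary = {"axes": axes, "clusters": {}, "samples": {}}
    for axis in axes:
        sa = axis_sample(coords_a, axis)
        sb = axis_sample(coords_b, axis)
        res = mann_whitney(sa, sb, alternative=alternative)
        if bonferroni:
            res = TestResult(
                statistic=res.statistic,
                p_value=min(1.0, res.p_value * len(axes)),
                method=res.method,
                n1=res.n1,
                n2=res.n2,
                tie_correction_applied=res.tie_correction_applied,
            )
        results.append(res)
        summary["samples"][axis] = {"a": sa.values, "b": sb.values}
        for name, s in (("a", sa), ("b", sb)):
            q1, med, q3 = np.percentile(s.values, [25, 50, 75])
            summary["clusters"].setdefault(name, {})[axis] = {
                "median": float(med),
                "iqr": float(q3 - q1),
                "n": s.n,
            }
    return results, summary


def results_to_frame(results: list, axes: tuple) -> pd.DataFrame:
    """Tabulate per-axis test results (axis, U, p, method, n1, n2)."""
    return pd.DataFrame(
        {
            "axis": list(axes),
            "U": [r.statistic for r in results],
            "p": [r.p_value for r in results],
            "method": [r.method for r in results],
            "n1": [r.n1 for r in results],
            "n2": [r.n2 for r in results],
        }
    )
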