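"""Association of between-sex expression ratio with monoallelic frequency.

If partial silencing in the homogametic sex counteracts over-expression,
loci with a higher homogametic:heterogametic expression ratio should show a
higher fraction of 1-active nuclei.  This module fits that relationship by
ordinary least squares (percentage of 1-active nuclei regressed on the
expression ratio) and reports R² and the slope's p-value.

Expression ratios are user-supplied (e.g. from RNA-seq); none are bundled.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["RatioPoint", "RegressionFit", "fit_ratio_regression", "average_replicates",
           "build_points"]


@dataclass(frozen=True)
class RatioPoint:
    """One locus: expression ratio (homogametic:heterogametic) and the
    percentage of homogametic nuclei with one active allele."""

    probe_id: str
    expression_ratio: float
    pct_1_active: float

    def __post_init__(self) -> None:
        if self.expression_ratio <= 0:
            raise ValueError(f"{self.probe_id}: expression_ratio must be > 0")


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def fit_ratio_regression(points: Sequence[RatioPoint]) -> RegressionFit:
    """OLS of pct_1_active on expression_ratio; p from the slope's t/F test
    (1 and n − 2 df)."""
    if len(points) < 3:
        raise ValueError(f"need at least 3 points, got {len(points)}")
    x = np.array([pt.expression_ratio for pt in points])
    y = np.array([pt.pct_1_active for pt in points])
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: all expression ratios identical")
    res = stats.linregress(x, y)
    # constant response: no variance to explain, r is undefined -> R² = 0
    r_squared = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r_squared,
        p_value=float(res.pvalue) if np.isfinite(res.pvalue) else 1.0,
        n=len(points),
    )


def average_replicates(replicates: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Unweighted per-probe mean of replicate 1-active percentages."""
    out = {}
    for probe_id, values in replicates.items():
        if not values:
            raise ValueError(f"{probe_id}: no replicates")
        out[probe_id] = float(np.mean(values))
    return out


def build_points(
    ratios: Mapping[str, float],
    pct_1_active: Mapping[str, float],
    exclude: Iterable[str] = (),
) -> list[RatioPoint]:
    """Join expression ratios with per-probe 1-active percentages.

    Probes missing from either table are dropped; ``exclude`` lists probes to
    omit (e.g. sex-determination loci whose ratios are confounded).
    """
    excluded = set(exclude)
    points = []
    for probe_id, ratio in ratios.items():
        if probe_id in excluded or probe_id not in pct_1_active:
            continue
        points.append(RatioPoint(probe_id, ratio, pct_1_active[probe_id]))
    return points
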