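"""Two-color neighbouring-gene-pair analysis.

Two questions, answered per pair of closely linked loci on the inactivatable
chromosome:

1. Is there a single active chromosome?  Among nuclei in which *both* loci
   show exactly one signal, co-location of the two signals means both derive
   from the same chromosome.  A co-location fraction near 1 supports one
   always-active homologue and one inactivatable one.

2. Is silencing of neighbours coordinated?  Under independent silencing the
   expected fraction of nuclei biallelic at *both* loci is the product of the
   marginal biallelic fractions (taken from single-probe experiments).  A
   significant excess of joint-biallelic nuclei indicates regional
   coordination of transcription on the inactivatable chromosome.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data import PairExperimentRecord
from .inference import ALPHA, bonferroni

__all__ = [
    "Regime",
    "PairResult",
    "colocation_fraction",
    "expected_joint_biallelic",
    "test_coordination",
    "classify_regime",
    "score_pair",
]


class Regime(str, enum.Enum):
    """Silencing regime of a neighbouring-gene pair."""

    INDEPENDENT_ESCAPE = "independent_escape"
    COORDINATED_ESCAPE = "coordinated_escape"


@dataclass(frozen=True)
class PairResult:
    pair: str
    n_both_monoallelic: int
    colocation_fraction: float | None
    n_scored_joint: int
    expected_joint_pct: float
    observed_joint_pct: float
    chi2: float
    df: int
    p: float
    p_adj: float
    coordinated: bool
    regime: Regime
    anti_coordinated: bool = False


def colocation_fraction(
    records: Sequence[PairExperimentRecord],
) -> tuple[float | None, int]:
    """Fraction of both-monoallelic nuclei whose two signals co-locate.

    Eligible nuclei are those with exactly one signal at each locus (the only
    configuration in which chromosome-of-origin is informative).  Returns
    ``(None, 0)`` when no nucleus is eligible.
    """
    eligible = [r for r in records if r.signals_a == 1 and r.signals_b == 1]
    if not eligible:
        return None, 0
    n_coloc = sum(1 for r in eligible if r.colocated)
    return n_coloc / len(eligible), len(eligible)


def expected_joint_biallelic(f2_a: float, f2_b: float) -> float:
    """Expected joint-biallelic fraction under independence: f2_a × f2_b."""
    for name, f in (("f2_a", f2_a), ("f2_b", f2_b)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {f}")
    return f2_a * f2_b


def test_coordination(
    observed_joint: float,
    n: int,
    expected_fraction: float,
    family_size: int = 1,
) -> tuple[float, int, float, float]:
    """χ² (1 df) of the joint-biallelic count against the independence
    expectation.

    ``observed_joint`` may be fractional (tallies back-computed from
    published percentages).  Returns ``(chi2, df, p, p_bonferroni)``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= observed_joint <= n:
        raise ValueError(f"observed_joint must be in [0, n], got {observed_joint}")
    if not 0.0 < expected_fraction < 1.0:
        raise ValueError(
            f"expected_fraction must be strictly inside (0, 1), got {expected_fraction}"
        )
    obs = np.array([observed_joint, n - observed_joint], dtype=float)
    exp = np.array([expected_fraction, 1.0 - expected_fraction]) * n
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    p = float(stats.chi2.sf(chi2, 1))
    p_adj = bonferroni([p], family_size)[0]
    return chi2, 1, p, p_adj


def classify_regime(
    observed_fraction: float,
    expected_fraction: float,
    p_adj: float,
    alpha: float = ALPHA,
) -> tuple[Regime, bool]:
    """Classify a pair as coordinated or independent escape.

    ``coordinated_escape`` requires a significant *excess* of joint-biallelic
    nuclei.  A significant deficit is still classified independent but
    flagged anti-coordinated (returned boolean), since the one-sided rule
    does not cover it.
    """
    excess = observed_fraction > expected_fraction
    if p_adj < alpha and excess:
        return Regime.COORDINATED_ESCAPE, False
    anti = p_adj < alpha and not excess
    return Regime.INDEPENDENT_ESCAPE, anti


def score_pair(
    records: Sequence[PairExperimentRecord],
    pair_label: str,
    f2_a: float,
    f2_b: float,
    family_size: int = 1,
    alpha: float = ALPHA,
) -> PairResult:
    """Full pair analysis from per-nucleus records.

    Marginal biallelic fractions ``f2_a``/``f2_b`` come from the single-probe
    experiments; the joint-biallelic count is tallied from the pair
    experiment itself.
    """
    coloc, n_mono = colocation_fraction(records)
    n = len(records)
    if n == 0:
        raise ValueError("no pair records")
    joint = sum(1 for r in records if r.signals_a == 2 and r.signals_b == 2)
    e = expected_joint_biallelic(f2_a, f2_b)
    chi2, df, p, p_adj = test_coordination(joint, n, e, family_size)
    obs_frac = joint / n
    regime, anti = classify_regime(obs_frac, e, p_adj, alpha)
    return PairResult(
        pair=pair_label,
        n_both_monoallelic=n_mono,
        colocation_fraction=coloc,
        n_scored_joint=n,
        expected_joint_pct=100.0 * e,
        observed_joint_pct=100.0 * obs_frac,
        chi2=chi2,
        df=df,
        p=p,
        p_adj=p_adj,
        coordinated=regime is Regime.COORDINATED_ESCAPE,
        regime=regime,
        anti_coordinated=anti,
    )
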