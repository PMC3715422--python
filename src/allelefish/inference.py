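"""Detection-efficiency null model and inactivation testing.

The model: in the homogametic sex every diploid nucleus carries two copies of
a sex-specific locus.  If both alleles transcribe and a transcribing allele
is detected with probe-specific efficiency p, the nucleus shows two signals
with probability p², one with 2pq and none with q² (q = 1 − p).  Departure
from this null — an excess of one-signal nuclei — is evidence that one
allele is transcriptionally silenced in a fraction of cells.

Efficiency p is estimated from the heterogametic sex, where every nucleus
carries exactly one transcribing allele of the locus, so the one-signal
frequency directly measures p.

Experimental error (signals missed for reasons other than silencing) is
bounded from autosomal controls: every diploid nucleus should show two
signals, so zero- and one-signal control nuclei count missed hybridization
events.  An exact (Garwood) Poisson confidence interval on the missed count
gives a conservative upper error bound used to shift observed values toward
expectation before re-testing.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .data import SignalCountSummary, Sex

__all__ = [
    "EfficiencyEstimate",
    "NullDistribution",
    "ErrorEstimate",
    "InactivationResult",
    "SmallExpectedCountWarning",
    "estimate_efficiency",
    "pooled_efficiency",
    "null_distribution",
    "test_inactivation",
    "bonferroni",
    "poisson_exact_ci",
    "estimate_error",
    "adjust_and_retest",
    "robustness_sweep",
    "estimate_silencing",
    "score_locus",
]

ALPHA = 0.01  #: significance threshold after Bonferroni correction


class SmallExpectedCountWarning(UserWarning):
    """An expected category count < 1 entered a chi-square test."""


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Probe hybridization efficiency p̂ (q̂ = 1 − p̂) from heterogametic nuclei."""

    probe_id: str
    p_hat: float
    n_het: int

    @property
    def q_hat(self) -> float:
        return 1.0 - self.p_hat


@dataclass(frozen=True)
class NullDistribution:
    """Expected fractions of 2-, 1-, 0-signal nuclei under biallelic transcription."""

    f2: float
    f1: float
    f0: float


@dataclass(frozen=True)
class ErrorEstimate:
    """Experimental-error bound from autosomal (obligate biallelic) controls."""

    species: str
    n_experiments: int
    n_nuclei: int
    missed: int
    ci_low: float
    ci_high: float

    @property
    def expected_signals(self) -> int:
        return 2 * self.n_nuclei

    @property
    def raw_rate(self) -> float:
        return self.missed / self.expected_signals

    @property
    def max_error_rate(self) -> float:
        """Upper 95% bound on the per-signal miss rate; the rate used for
        observed-value adjustment."""
        return self.ci_high / self.expected_signals


@dataclass(frozen=True)
class InactivationResult:
    """Full per-locus inference record for the homogametic sex."""

    probe_id: str
    sex: Sex
    efficiency: EfficiencyEstimate
    observed: SignalCountSummary
    expected: NullDistribution
    chi2_raw: float
    df_raw: int
    p_raw: float
    chi2_adjusted: float
    df_adjusted: int
    p_adjusted: float
    p_adj_bonferroni: float
    error_rate: float
    significant: bool

    @property
    def pct_2_active(self) -> float:
        return 100.0 * self.observed.fractions[0]

    @property
    def pct_1_active(self) -> float:
        return 100.0 * self.observed.fractions[1]

    @property
    def pct_0(self) -> float:
        return 100.0 * self.observed.fractions[2]


# ---------------------------------------------------------------------------
# Efficiency and the null
# ---------------------------------------------------------------------------


def estimate_efficiency(summary: SignalCountSummary) -> EfficiencyEstimate:
    """Estimate hybridization efficiency from heterogametic-sex nuclei.

    A single-copy locus gives one signal when detected, zero when missed, so
    p̂ = n1 / (n1 + n0).  Two-signal nuclei should not occur for a
    sex-specific locus in this sex; they are excluded from the estimate and
    flagged with a warning.
    """
    if summary.sex is not Sex.HETEROGAMETIC:
        raise ValueError("efficiency must be estimated from the heterogametic sex")
    if summary.n2 > 0:
        warnings.warn(
            f"{summary.probe_id}: {summary.n2} heterogametic nuclei with two signals "
            "at a single-copy locus; excluded from the efficiency estimate",
            UserWarning,
            stacklevel=2,
        )
    n = summary.n1 + summary.n0
    if n == 0:
        raise ValueError(f"{summary.probe_id}: no usable heterogametic nuclei (n1 + n0 = 0)")
    return EfficiencyEstimate(probe_id=summary.probe_id, p_hat=summary.n1 / n, n_het=n)


def pooled_efficiency(summaries: Sequence[SignalCountSummary]) -> EfficiencyEstimate:
    """Pool heterogametic tallies across probes into one efficiency estimate.

    Off by default in the pipeline; provided for sparse heterogametic data.
    """
    n1 = sum(s.n1 for s in summaries)
    n0 = sum(s.n0 for s in summaries)
    if n1 + n0 == 0:
        raise ValueError("no usable heterogametic nuclei in pool")
    return EfficiencyEstimate(probe_id="<pooled>", p_hat=n1 / (n1 + n0), n_het=n1 + n0)


def null_distribution(p: float) -> NullDistribution:
    """Expected (f2, f1, f0) = (p², 2pq, q²) for a biallelically transcribed locus."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"efficiency p must be in [0, 1], got {p}")
    q = 1.0 - p
    return NullDistribution(f2=p * p, f1=2.0 * p * q, f0=q * q)


# ---------------------------------------------------------------------------
# Chi-square machinery
# ---------------------------------------------------------------------------


def _pearson_chi2(observed: np.ndarray, expected: np.ndarray, df: int) -> tuple[float, float]:
    """Pearson χ² with explicit df; expected counts of 0 with nonzero observed
    give (inf, 0.0)."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any((expected == 0) & (observed > 0)):
        return math.inf, 0.0
    mask = expected > 0
    chi2 = float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))
    return chi2, float(stats.chi2.sf(chi2, df))


def test_inactivation(
    observed: SignalCountSummary, eff: EfficiencyEstimate
) -> tuple[float, int, float]:
    """Three-category χ² (2 df) of observed signal counts against the
    detection null.

    Warns when any expected count falls below 1 (typical for the zero-signal
    class when p ≈ 1); the two-category error-adjusted test is the primary
    inference in that regime.
    """
    n = observed.n_scored
    if n == 0:
        raise ValueError("empty summary")
    null = null_distribution(eff.p_hat)
    exp = np.array([null.f2, null.f1, null.f0]) * n
    if np.any((exp < 1.0) & (exp > 0.0)):
        warnings.warn(
            f"{observed.probe_id}: expected count < 1 in the 3-category test "
            f"(E = {np.round(exp, 3).tolist()})",
            SmallExpectedCountWarning,
            stacklevel=2,
        )
    obs = np.array([observed.n2, observed.n1, observed.n0], dtype=float)
    chi2, p = _pearson_chi2(obs, exp, df=2)
    return chi2, 2, p


def bonferroni(p_values: Sequence[float], family_size: int) -> list[float]:
    """Multiply each p-value by the family size, capping at 1."""
    if family_size < 1:
        raise ValueError(f"family_size must be ≥ 1, got {family_size}")
    if family_size < len(p_values):
        raise ValueError("family_size smaller than the number of p-values")
    return [min(1.0, p * family_size) for p in p_values]


def poisson_exact_ci(k: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence limits for a Poisson count.

    low = ½·χ²_{α/2}(2k) (0 when k = 0); high = ½·χ²_{1−α/2}(2k + 2).
    """
    if k < 0:
        raise ValueError("count must be non-negative")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else 0.5 * stats.chi2.ppf(alpha / 2.0, 2 * k)
    high = 0.5 * stats.chi2.ppf(1.0 - alpha / 2.0, 2 * k + 2)
    return float(low), float(high)


def estimate_error(
    autosomal_summaries: Sequence[SignalCountSummary],
    species: str = "",
    locus_classes: dict[str, str] | None = None,
) -> ErrorEstimate:
    """Bound experimental error from autosomal control experiments.

    Every diploid nucleus should show two signals; each zero-signal nucleus
    counts two missed hybridizations and each one-signal nucleus one.  The
    upper Garwood 95% limit on the total missed count, divided by the number
    of expected signals, is the maximum error rate.

    ``locus_classes`` optionally maps probe_id → locus class string; any
    non-autosomal probe present raises, guarding against silenced loci
    contaminating the error estimate.
    """
    if not autosomal_summaries:
        raise ValueError("no autosomal control summaries supplied")
    if locus_classes is not None:
        bad = [s.probe_id for s in autosomal_summaries
               if locus_classes.get(s.probe_id) not in (None, "autosomal")]
        if bad:
            raise ValueError(f"non-autosomal loci in error estimate: {bad}")
    missed = sum(2 * s.n0 + s.n1 for s in autosomal_summaries)
    n_nuclei = sum(s.n_scored for s in autosomal_summaries)
    lo, hi = poisson_exact_ci(missed)
    return ErrorEstimate(
        species=species,
        n_experiments=len(autosomal_summaries),
        n_nuclei=n_nuclei,
        missed=missed,
        ci_low=lo,
        ci_high=hi,
    )


AdjustMode = Literal["percentage_point", "proportional"]


def adjust_and_retest(
    observed: SignalCountSummary,
    eff: EfficiencyEstimate,
    error_rate: float,
    mode: AdjustMode = "percentage_point",
) -> tuple[tuple[float, float], float, int, float]:
    """Error-adjusted two-category re-test.

    Zero-signal nuclei are removed and the (2-signal, 1-signal) table is
    renormalized; observed category fractions are then shifted toward the
    renormalized expected fractions to discount hybridization misses, and a
    Pearson χ² with 1 df is computed.

    ``mode`` selects the shift arithmetic: ``"percentage_point"`` (default)
    moves each fraction ``error_rate`` percentage points toward expectation,
    clamped so it never overshoots; ``"proportional"`` moves it a fraction
    ``error_rate`` of the gap.

    Returns ``((adj_n2, adj_n1), chi2, df, p)`` with adjusted counts on the
    renormalized n' = n2 + n1 scale.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError(f"error_rate must be in [0, 0.5), got {error_rate}")
    n_prime = observed.n2 + observed.n1
    if n_prime == 0:
        raise ValueError(f"{observed.probe_id}: no 1- or 2-signal nuclei to test")
    null = null_distribution(eff.p_hat)
    denom = null.f2 + null.f1
    if denom == 0:
        raise ValueError("degenerate null: p = 0 leaves no 1- or 2-signal class")
    e2 = null.f2 / denom
    o2 = observed.n2 / n_prime
    if mode == "percentage_point":
        gap = e2 - o2
        shift = math.copysign(min(abs(gap), error_rate), gap)
        o2_adj = o2 + shift
    elif mode == "proportional":
        o2_adj = o2 + error_rate * (e2 - o2)
    else:
        raise ValueError(f"unknown adjustment mode: {mode!r}")
    adj = np.array([o2_adj, 1.0 - o2_adj]) * n_prime
    exp = np.array([e2, 1.0 - e2]) * n_prime
    chi2, p = _pearson_chi2(adj, exp, df=1)
    return (float(adj[0]), float(adj[1])), chi2, 1, p


def robustness_sweep(
    observed: SignalCountSummary,
    eff: EfficiencyEstimate,
    error_rates: Sequence[float],
    family_size: int = 1,
    alpha: float = ALPHA,
    mode: AdjustMode = "percentage_point",
) -> list[dict]:
    """Re-run the adjusted test across a grid of error rates.

    Used to show that a significance call survives even deliberately
    conservative error assumptions (e.g. a 5-percentage-point shift toward
    expectation).  Returns one dict per rate with keys ``error_rate``,
    ``chi2``, ``p``, ``p_bonferroni``, ``significant``.
    """
    out = []
    for rate in error_rates:
        _, chi2, _, p = adjust_and_retest(observed, eff, rate, mode=mode)
        p_corr = bonferroni([p], family_size)[0]
        out.append(
            {
                "error_rate": rate,
                "chi2": chi2,
                "p": p,
                "p_bonferroni": p_corr,
                "significant": p_corr < alpha,
            }
        )
    return out


def estimate_silencing(observed: SignalCountSummary, eff: EfficiencyEstimate) -> float:
    """Point estimate of the per-locus silencing probability s.

    With efficiency p and silencing s, the one-signal fraction in the
    homogametic sex is 2pq + s·p·(2p − 1): the detection null plus the
    silencing excess.  Inverting gives ŝ = (f1_obs − 2pq) / (p(2p − 1)),
    clamped to [0, 1].  Requires p > 0.5 (identifiability: below that an
    extra 1-signal nucleus is better explained by missed detection).
    """
    p = eff.p_hat
    if p <= 0.5:
        raise ValueError(f"silencing not identifiable from f1 at efficiency p = {p} ≤ 0.5")
    f1_obs = observed.fractions[1]
    excess = f1_obs - null_distribution(p).f1
    return float(min(1.0, max(0.0, excess / (p * (2.0 * p - 1.0)))))


def score_locus(
    homogametic: SignalCountSummary,
    eff: EfficiencyEstimate,
    error_rate: float,
    family_size: int,
    alpha: float = ALPHA,
    mode: AdjustMode = "percentage_point",
) -> InactivationResult:
    """Run the full per-locus inference: raw 3-category test, error-adjusted
    2-category re-test (the primary inference), Bonferroni correction and
    the significance call at ``alpha``."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallExpectedCountWarning)
        chi2_raw, df_raw, p_raw = test_inactivation(homogametic, eff)
    _, chi2_adj, df_adj, p_adj = adjust_and_retest(homogametic, eff, error_rate, mode=mode)
    p_corr = bonferroni([p_adj], family_size)[0]
    return InactivationResult(
        probe_id=homogametic.probe_id,
        sex=homogametic.sex,
        efficiency=eff,
        observed=homogametic,
        expected=null_distribution(eff.p_hat),
        chi2_raw=chi2_raw,
        df_raw=df_raw,
        p_raw=p_raw,
        chi2_adjusted=chi2_adj,
        df_adjusted=df_adj,
        p_adjusted=p_adj,
        p_adj_bonferroni=p_corr,
        error_rate=error_rate,
        significant=p_corr < alpha,
    )
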