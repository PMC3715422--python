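"""End-to-end per-locus scoring: records → diploid filter → tallies →
efficiency → error bound → inactivation calls.

This is the programmatic equivalent of the ``allelefish score`` command.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .data import (
    LocusClass,
    LocusProbe,
    NucleusRecord,
    Sex,
    SignalCountSummary,
    filter_diploid,
    summarize_counts,
)
from .inference import (
    ALPHA,
    AdjustMode,
    EfficiencyEstimate,
    ErrorEstimate,
    InactivationResult,
    estimate_efficiency,
    estimate_error,
    pooled_efficiency,
    score_locus,
)

__all__ = ["PanelScores", "score_panel", "results_table"]


@dataclass
class PanelScores:
    """Outcome of a full panel run."""

    results: list[InactivationResult]
    error: ErrorEstimate | None
    family_size: int
    n_excluded_nondiploid: int


def _summaries_by_key(
    records: Sequence[NucleusRecord],
) -> dict[tuple[str, Sex], SignalCountSummary]:
    keys = sorted({(r.probe_id, r.sex) for r in records}, key=lambda k: (k[0], k[1].value))
    return {key: summarize_counts(records, *key) for key in keys}


def score_panel(
    records: Sequence[NucleusRecord],
    panel: Sequence[LocusProbe],
    alpha: float = ALPHA,
    family_size: int | None = None,
    error_rate: float | None = None,
    mode: AdjustMode = "percentage_point",
    species: str = "",
) -> PanelScores:
    """Score every testable locus of a panel from per-nucleus records.

    Sex-specific loci are tested in the homogametic sex against a probe
    efficiency estimated from heterogametic nuclei of the same probe.
    Pseudoautosomal loci are tested in both sexes (both carry two alleles)
    against the efficiency pooled across the panel's sex-specific probes,
    since a two-allele locus gives no direct single-copy efficiency readout.
    Autosomal loci provide the experimental-error bound and are not tested.

    ``error_rate``: ``None`` estimates the upper-bound rate from autosomal
    controls; pass a number to fix it (0 disables the adjustment shift).
    ``family_size`` defaults to the number of tests performed.
    """
    classes = {p.probe_id: p.locus_class for p in panel}
    unknown = sorted({r.probe_id for r in records} - set(classes))
    if unknown:
        raise KeyError(f"records reference probes missing from panel: {unknown}")
    kept, excluded = filter_diploid(records)
    summaries = _summaries_by_key(kept)

    err: ErrorEstimate | None = None
    if error_rate is None:
        autosomal = [
            s for (pid, _), s in summaries.items()
            if classes[pid] is LocusClass.AUTOSOMAL
        ]
        if not autosomal:
            raise ValueError(
                "no autosomal control summaries to estimate error from; "
                "pass error_rate explicitly"
            )
        err = estimate_error(autosomal, species=species)
        error_rate = err.max_error_rate

    # efficiency per sex-specific probe, pooled fallback for PAR loci
    eff_by_probe: dict[str, EfficiencyEstimate] = {}
    het_sex_specific = []
    for (pid, sex), summ in summaries.items():
        if sex is Sex.HETEROGAMETIC and classes[pid] is LocusClass.SEX_SPECIFIC:
            eff_by_probe[pid] = estimate_efficiency(summ)
            het_sex_specific.append(summ)

    tests: list[tuple[SignalCountSummary, EfficiencyEstimate]] = []
    for (pid, sex), summ in summaries.items():
        cls = classes[pid]
        if cls is LocusClass.SEX_SPECIFIC and sex is Sex.HOMOGAMETIC:
            if pid not in eff_by_probe:
                raise ValueError(
                    f"{pid}: sex-specific locus has no heterogametic summary "
                    "to estimate efficiency from"
                )
            tests.append((summ, eff_by_probe[pid]))
        elif cls is LocusClass.PSEUDOAUTOSOMAL:
            if not het_sex_specific:
                raise ValueError(
                    "pseudoautosomal testing needs sex-specific heterogametic "
                    "summaries for the pooled efficiency"
                )
            tests.append((summ, pooled_efficiency(het_sex_specific)))

    if family_size is None:
        family_size = max(1, len(tests))
    results = [
        score_locus(summ, eff, error_rate, family_size, alpha=alpha, mode=mode)
        for summ, eff in tests
    ]
    return PanelScores(
        results=results,
        error=err,
        family_size=family_size,
        n_excluded_nondiploid=len(excluded),
    )


def results_table(scores: PanelScores) -> pd.DataFrame:
    """Flatten panel scores into the per-locus results table."""
    rows = []
    for r in scores.results:
        rows.append(
            {
                "probe_id": r.probe_id,
                "sex": r.sex.value,
                "n": r.observed.n_scored,
                "pct_2_active": round(r.pct_2_active, 2),
                "pct_1_active": round(r.pct_1_active, 2),
                "pct_0": round(r.pct_0, 2),
                "efficiency": round(r.efficiency.p_hat, 4),
                "chi2_raw": round(r.chi2_raw, 4),
                "chi2_adj": round(r.chi2_adjusted, 4),
                "p_adj": r.p_adj_bonferroni,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
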