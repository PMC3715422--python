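"""Generative model of nucleus-level allelic states in a fibroblast population.

The model mirrors the biology the inference modules assume.  In the
homogametic sex one sex chromosome is always active (every sex-specific
locus on it transcribes) while its homologue is "inactivatable": each locus
on it is silenced independently per nucleus with a locus-specific probability
s.  Silencing is drawn fresh per nucleus — activity status is not clonally
inherited, so no lineage structure is modelled.  Heterogametic cells carry a
single transcribing allele per sex-specific locus.  Pseudoautosomal loci
carry two alleles in both sexes, with the inactivatable-/Y-side allele
silenced with the same probability s in either sex; autosomal alleles are
never silenced.

Each transcribing allele is then detected with probe efficiency p, and the
co-hybridized autosomal control with ``control_efficiency``.  A small
fraction of cells is tetraploid: these carry twice the diploid allele count
before detection, so the two-control-signal filter removes them whenever the
control efficiency is near 1.

Neighbouring-locus coordination is a single coupling parameter ρ per pair:
the second locus copies the first locus's silencing state with probability
ρ, and draws independently otherwise — ρ = 0 gives independent silencing,
ρ = 1 identical states.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .data import (
    LocusClass,
    MAX_SIGNALS,
    NucleusRecord,
    PairExperimentRecord,
    Sex,
    SignalCountSummary,
)

__all__ = [
    "SimLocus",
    "SimPair",
    "SimConfig",
    "simulate_population",
    "simulate_summaries",
    "simulate_pair_population",
    "study_panel_config",
    "recovery_study",
]


@dataclass(frozen=True)
class SimLocus:
    """One simulated locus.

    ``silencing_prob`` is the per-nucleus probability that the
    inactivatable-chromosome allele is silenced; ``efficiency`` the per-allele
    detection probability.  Efficiency is constrained to [0.5, 1]: below 0.5
    the silencing excess is not identifiable from signal counts.
    """

    probe_id: str
    locus_class: LocusClass
    silencing_prob: float
    efficiency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.silencing_prob <= 1.0:
            raise ValueError(f"{self.probe_id}: silencing_prob outside [0, 1]")
        if not 0.5 <= self.efficiency <= 1.0:
            raise ValueError(f"{self.probe_id}: efficiency outside [0.5, 1]")


@dataclass(frozen=True)
class SimPair:
    """A neighbouring-locus pair with silencing coupling ρ ∈ [0, 1]."""

    locus_a: str
    locus_b: str
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho outside [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a simulated two-color scoring experiment."""

    loci: tuple[SimLocus, ...]
    n_homogametic: int = 200
    n_heterogametic: int = 200
    seed: int = 0
    tetraploid_fraction: float = 0.05
    control_efficiency: float = 0.985
    colocation_fidelity: float = 1.0
    pairs: tuple[SimPair, ...] = ()
    species: str = "synthetic"

    def __post_init__(self) -> None:
        for name in ("tetraploid_fraction", "control_efficiency", "colocation_fidelity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")
        ids = [l.probe_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate probe_id in loci")
        known = set(ids)
        for p in self.pairs:
            if p.locus_a not in known or p.locus_b not in known:
                raise ValueError(f"pair references unknown locus: {p}")

    def locus(self, probe_id: str) -> SimLocus:
        for l in self.loci:
            if l.probe_id == probe_id:
                return l
        raise KeyError(probe_id)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["loci"] = [
            {**asdict(l), "locus_class": l.locus_class.value} for l in self.loci
        ]
        doc["pairs"] = [asdict(p) for p in self.pairs]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        doc = yaml.safe_load(Path(path).read_text())
        loci = tuple(
            SimLocus(
                probe_id=l["probe_id"],
                locus_class=LocusClass(l["locus_class"]),
                silencing_prob=l["silencing_prob"],
                efficiency=l["efficiency"],
            )
            for l in doc.pop("loci")
        )
        pairs = tuple(SimPair(**p) for p in doc.pop("pairs", []))
        return cls(loci=loci, pairs=pairs, **doc)


# ---------------------------------------------------------------------------
# Core draws (vectorized; shared by the record- and summary-level views)
# ---------------------------------------------------------------------------


def _allele_counts(locus: SimLocus, sex: Sex) -> tuple[int, int]:
    """(always-transcribing alleles, inactivatable alleles) for a diploid cell."""
    if locus.locus_class is LocusClass.AUTOSOMAL:
        return 2, 0
    if locus.locus_class is LocusClass.PSEUDOAUTOSOMAL:
        return 1, 1  # inactivatable-/Y-side allele silenced in both sexes
    # sex-specific
    if sex is Sex.HOMOGAMETIC:
        return 1, 1
    return 1, 0


def _draw_silencing(
    config: SimConfig, sex: Sex, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-nucleus silencing states, shape (n, n_loci), with pair coupling."""
    idx = {l.probe_id: j for j, l in enumerate(config.loci)}
    s = np.array([l.silencing_prob for l in config.loci])
    silenced = rng.random((n, len(config.loci))) < s
    for pair in config.pairs:
        a, b = idx[pair.locus_a], idx[pair.locus_b]
        copy = rng.random(n) < pair.rho
        silenced[copy, b] = silenced[copy, a]
    # silencing only acts where an inactivatable allele exists; masking is
    # handled by _allele_counts, so the matrix itself need not be masked
    return silenced


def _draw_cells(
    config: SimConfig, sex: Sex, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Draw one population: returns (tetraploid mask, control counts per
    locus, test counts per locus)."""
    tetra = rng.random(n) < config.tetraploid_fraction
    ploidy_mult = np.where(tetra, 2, 1)
    silenced = _draw_silencing(config, sex, n, rng)
    controls: dict[str, np.ndarray] = {}
    tests: dict[str, np.ndarray] = {}
    for j, locus in enumerate(config.loci):
        n_active, n_inact = _allele_counts(locus, sex)
        transcribing = (n_active + n_inact * (~silenced[:, j])) * ploidy_mult
        test = rng.binomial(transcribing, locus.efficiency)
        ctrl = rng.binomial(2 * ploidy_mult, config.control_efficiency)
        tests[locus.probe_id] = np.minimum(test, MAX_SIGNALS)
        controls[locus.probe_id] = np.minimum(ctrl, MAX_SIGNALS)
    return tetra, controls, tests


def simulate_population(config: SimConfig) -> list[NucleusRecord]:
    """Simulate per-nucleus records for every locus in both sexes.

    Each locus is its own hybridization experiment (experiment_id
    ``sim-<probe>-<sex>``) with its own independently drawn control counts,
    as in a real two-color experiment where each probe is scored on a
    separate coverslip.  Output is deterministic for a given config
    (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    records: list[NucleusRecord] = []
    for sex, n in ((Sex.HOMOGAMETIC, config.n_homogametic),
                   (Sex.HETEROGAMETIC, config.n_heterogametic)):
        if n == 0:
            continue
        _, controls, tests = _draw_cells(config, sex, n, rng)
        for locus in config.loci:
            exp_id = f"sim-{locus.probe_id}-{sex.value}"
            ctrl = controls[locus.probe_id]
            test = tests[locus.probe_id]
            for i in range(n):
                records.append(
                    NucleusRecord(
                        experiment_id=exp_id,
                        individual_id="sim-1",
                        sex=sex,
                        probe_id=locus.probe_id,
                        control_signals=int(ctrl[i]),
                        test_signals=int(test[i]),
                    )
                )
    return records


def simulate_summaries(
    config: SimConfig, rng: np.random.Generator | None = None
) -> dict[tuple[str, Sex], SignalCountSummary]:
    """Fast path: diploid-filtered per-(locus, sex) tallies without building
    per-nucleus records.  Uses the same draw core as
    :func:`simulate_population`; pass an explicit ``rng`` to chain replicate
    draws in Monte-Carlo studies."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out: dict[tuple[str, Sex], SignalCountSummary] = {}
    for sex, n in ((Sex.HOMOGAMETIC, config.n_homogametic),
                   (Sex.HETEROGAMETIC, config.n_heterogametic)):
        if n == 0:
            continue
        _, controls, tests = _draw_cells(config, sex, n, rng)
        for locus in config.loci:
            keep = controls[locus.probe_id] == 2
            t = tests[locus.probe_id][keep]
            out[(locus.probe_id, sex)] = SignalCountSummary(
                probe_id=locus.probe_id,
                sex=sex,
                n2=int(np.sum(t == 2)),
                n1=int(np.sum(t == 1)),
                n0=int(np.sum(t == 0)),
                n_anomalous=int(np.sum(t > 2)),
            )
    return out


def simulate_pair_population(
    config: SimConfig, pair: SimPair | tuple[str, str], n: int | None = None
) -> list[PairExperimentRecord]:
    """Simulate a two-color neighbouring-pair experiment on homogametic
    diploid nuclei.

    Tracks the chromosome of origin of each detected signal: when both loci
    show a single signal, the two signals co-locate with probability
    ``colocation_fidelity`` if they derive from the same chromosome, and
    never co-locate if from opposite chromosomes.
    """
    if not isinstance(pair, SimPair):
        a, b = pair
        matches = [p for p in config.pairs if (p.locus_a, p.locus_b) == (a, b)]
        if not matches:
            raise KeyError(f"pair ({a}, {b}) not declared in config")
        pair = matches[0]
    if not any((p.locus_a, p.locus_b) == (pair.locus_a, pair.locus_b) for p in config.pairs):
        raise KeyError(f"pair {pair} not declared in config")
    la, lb = config.locus(pair.locus_a), config.locus(pair.locus_b)
    n = config.n_homogametic if n is None else n
    rng = np.random.default_rng(config.seed)

    sil_a = rng.random(n) < la.silencing_prob
    copy = rng.random(n) < pair.rho
    sil_b_ind = rng.random(n) < lb.silencing_prob
    sil_b = np.where(copy, sil_a, sil_b_ind)

    # allele detection; index 0 = active chromosome, 1 = inactivatable
    det_a = rng.random((n, 2)) < la.efficiency
    det_b = rng.random((n, 2)) < lb.efficiency
    det_a[:, 1] &= ~sil_a
    det_b[:, 1] &= ~sil_b
    sig_a = det_a.sum(axis=1)
    sig_b = det_b.sum(axis=1)

    coloc_roll = rng.random(n) < config.colocation_fidelity
    exp_id = f"sim-pair-{pair.locus_a}-{pair.locus_b}"
    records = []
    for i in range(n):
        colocated: bool | None = None
        if sig_a[i] == 1 and sig_b[i] == 1:
            chrom_a = 0 if det_a[i, 0] else 1
            chrom_b = 0 if det_b[i, 0] else 1
            colocated = bool(coloc_roll[i]) if chrom_a == chrom_b else False
        records.append(
            PairExperimentRecord(
                experiment_id=exp_id,
                probe_a=pair.locus_a,
                probe_b=pair.locus_b,
                signals_a=int(sig_a[i]),
                signals_b=int(sig_b[i]),
                colocated=colocated,
            )
        )
    return records


def panel_from_config(config: SimConfig) -> list["LocusProbe"]:
    """Build a locus panel with synthetic coordinates for a simulated config.

    Sex-specific loci are laid out on "chrZ", pseudoautosomal on "chrPAR"
    and autosomal controls on "chrA", at 1-Mb spacing with BAC-sized
    (200 kb) extents; purely positional bookkeeping for the activity map.
    """
    from .data import LocusProbe

    chrom_for = {
        LocusClass.SEX_SPECIFIC: "chrZ",
        LocusClass.PSEUDOAUTOSOMAL: "chrPAR",
        LocusClass.AUTOSOMAL: "chrA",
    }
    counters = {c: 0 for c in chrom_for.values()}
    panel = []
    for locus in config.loci:
        chrom = chrom_for[locus.locus_class]
        i = counters[chrom]
        counters[chrom] += 1
        start = 1_000_000 * (i + 1)
        panel.append(
            LocusProbe(
                probe_id=locus.probe_id,
                species=config.species,
                chromosome=chrom,
                locus_class=locus.locus_class,
                start_bp=start,
                end_bp=start + 200_000,
                genes=(f"GENE_{locus.probe_id.upper()}",),
            )
        )
    return panel


# ---------------------------------------------------------------------------
# Reference fixture panels
# ---------------------------------------------------------------------------


def study_panel_config(species: str = "chicken", seed: int = 0) -> SimConfig:
    """Deterministic fixture panel emulating the study populations.

    ``"chicken"``: 11 Z-like sex-specific loci with per-locus silencing
    probabilities evenly spanning 0.15–0.51 and efficiencies 0.95–1.0, plus
    10 autosomal controls (s = 0).  ``"platypus"``: 19 X-specific loci with
    s spanning 0.25–0.62 and efficiencies 0.94–1.0, 9 pseudoautosomal loci
    with s spanning 0.16–0.47, plus 12 autosomal controls.  Neighbouring
    pairs are declared with ρ = 0 (chicken, independent silencing) and
    ρ = 1 (platypus, regionally coordinated escape).
    """
    if species == "chicken":
        n_z = 11
        s_vals = np.linspace(0.15, 0.51, n_z)
        p_vals = np.linspace(0.95, 1.0, n_z)
        loci = [
            SimLocus(f"cz{i + 1:02d}", LocusClass.SEX_SPECIFIC,
                     round(float(s), 4), round(float(p), 4))
            for i, (s, p) in enumerate(zip(s_vals, p_vals))
        ]
        loci += [
            SimLocus(f"ca{i + 1:02d}", LocusClass.AUTOSOMAL, 0.0, 0.99)
            for i in range(10)
        ]
        pairs = (SimPair("cz01", "cz02", 0.0), SimPair("cz03", "cz04", 0.0))
        return SimConfig(
            loci=tuple(loci), pairs=pairs, seed=seed, species="chicken-like",
            control_efficiency=0.985, colocation_fidelity=0.96,
        )
    if species == "platypus":
        n_x = 19
        s_vals = np.linspace(0.25, 0.62, n_x)
        p_vals = np.linspace(0.94, 1.0, n_x)
        loci = [
            SimLocus(f"px{i + 1:02d}", LocusClass.SEX_SPECIFIC,
                     round(float(s), 4), round(float(p), 4))
            for i, (s, p) in enumerate(zip(s_vals, p_vals))
        ]
        s_par = np.linspace(0.16, 0.47, 9)
        loci += [
            SimLocus(f"pp{i + 1:02d}", LocusClass.PSEUDOAUTOSOMAL,
                     round(float(s), 4), 0.97)
            for i, s in enumerate(s_par)
        ]
        loci += [
            SimLocus(f"pa{i + 1:02d}", LocusClass.AUTOSOMAL, 0.0, 0.99)
            for i in range(12)
        ]
        pairs = (
            SimPair("px01", "px02", 1.0),
            SimPair("px03", "px04", 1.0),
            SimPair("px05", "px06", 1.0),
        )
        return SimConfig(
            loci=tuple(loci), pairs=pairs, seed=seed, species="platypus-like",
            control_efficiency=0.975, colocation_fidelity=1.0,
        )
    raise ValueError(f"unknown species fixture: {species!r}")


def recovery_study(
    config: SimConfig, n_replicates: int, seed: int
) -> "pd.DataFrame":
    """Simulate → infer repeatedly and report silencing-probability recovery.

    For each replicate the population is simulated, diploid-filtered, and the
    per-locus silencing probability estimated from the homogametic one-signal
    excess using the probe efficiency estimated from heterogametic nuclei.
    Only sex-specific loci are scored (the inference target; pseudoautosomal
    efficiency is not identifiable from heterogametic counts because both
    alleles are present in that sex too).

    Returns a DataFrame with columns probe_id, true_s, mean_s_hat, bias, rmse.
    """
    import pandas as pd

    from .inference import estimate_efficiency, estimate_silencing

    rng = np.random.default_rng(seed)
    loci = [l for l in config.loci if l.locus_class is LocusClass.SEX_SPECIFIC]
    estimates: dict[str, list[float]] = {l.probe_id: [] for l in loci}
    for _ in range(n_replicates):
        summaries = simulate_summaries(config, rng=rng)
        for locus in loci:
            het = summaries[(locus.probe_id, Sex.HETEROGAMETIC)]
            hom = summaries[(locus.probe_id, Sex.HOMOGAMETIC)]
            if het.n1 + het.n0 == 0 or hom.n_scored == 0:
                continue
            eff = estimate_efficiency(het)
            if eff.p_hat <= 0.5:
                continue
            estimates[locus.probe_id].append(estimate_silencing(hom, eff))
    rows = []
    for locus in loci:
        est = np.array(estimates[locus.probe_id])
        rows.append(
            {
                "probe_id": locus.probe_id,
                "true_s": locus.silencing_prob,
                "n_replicates": len(est),
                "mean_s_hat": float(est.mean()) if est.size else float("nan"),
                "bias": float(est.mean() - locus.silencing_prob) if est.size else float("nan"),
                "rmse": float(np.sqrt(np.mean((est - locus.silencing_prob) ** 2)))
                if est.size
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
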