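"""Domain types, tabular I/O, diploid-control filtering and activity-map export.

The unit of observation is one scored interphase nucleus hybridized with two
probes: an autosomal control (expected biallelic in every diploid nucleus) and
a test probe.  Signal counts are small non-negative integers; a diploid
nucleus showing other than two control signals is excluded from inference
(polyploidy, or poor probe accessibility).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "LocusClass",
    "Sex",
    "LocusProbe",
    "NucleusRecord",
    "SignalCountSummary",
    "PairExperimentRecord",
    "RowError",
    "SchemaError",
    "read_nucleus_table",
    "write_nucleus_table",
    "read_panel",
    "write_panel",
    "read_pair_table",
    "write_pair_table",
    "read_summary_table",
    "filter_diploid",
    "summarize_counts",
    "write_activity_map",
]

NUCLEUS_COLUMNS = [
    "experiment_id",
    "individual_id",
    "sex",
    "probe_id",
    "control_signals",
    "test_signals",
]
PANEL_COLUMNS = ["probe_id", "species", "chromosome", "locus_class", "start", "end", "genes"]
PAIR_COLUMNS = ["experiment_id", "probe_a", "probe_b", "signals_a", "signals_b", "colocated"]
SUMMARY_COLUMNS = ["probe_id", "sex", "n2", "n1", "n0"]

#: Signal counts above this flag an unmodelled anomaly in a diploid nucleus.
MAX_SIGNALS = 4


class LocusClass(str, enum.Enum):
    """Chromosomal class of a probe target."""

    AUTOSOMAL = "autosomal"
    SEX_SPECIFIC = "sex_specific"
    PSEUDOAUTOSOMAL = "pseudoautosomal"


class Sex(str, enum.Enum):
    """Abstract sex encoding.

    ``HOMOGAMETIC`` is the sex with two like sex chromosomes (ZZ male bird,
    XX female mammal); ``HETEROGAMETIC`` the other.  One code path then
    serves both a ZW bird and an XY/multiple-sex-chromosome mammal.
    """

    HOMOGAMETIC = "homogametic"
    HETEROGAMETIC = "heterogametic"


class SchemaError(ValueError):
    """A required column is missing or a file header does not match."""


@dataclass(frozen=True)
class RowError:
    """A malformed row, reported with its 1-based line number."""

    line: int
    message: str


@dataclass(frozen=True)
class LocusProbe:
    """One probe/locus: the unit of inference.

    Coordinates are 0-based half-open.  ``genes`` lists gene symbols covered
    by the probe; strand is ignored (nascent-RNA scoring is strandless here).
    """

    probe_id: str
    species: str
    chromosome: str
    locus_class: LocusClass
    start_bp: int
    end_bp: int
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.start_bp < self.end_bp:
            raise ValueError(
                f"{self.probe_id}: start_bp ({self.start_bp}) must be < end_bp ({self.end_bp})"
            )


@dataclass(frozen=True)
class NucleusRecord:
    """One scored nucleus: control-probe and test-probe signal counts."""

    experiment_id: str
    individual_id: str
    sex: Sex
    probe_id: str
    control_signals: int
    test_signals: int

    def __post_init__(self) -> None:
        for name in ("control_signals", "test_signals"):
            v = getattr(self, name)
            if not (0 <= v <= MAX_SIGNALS):
                raise ValueError(f"{name}={v} outside accepted range 0–{MAX_SIGNALS}")


@dataclass(frozen=True)
class SignalCountSummary:
    """Per (probe, sex) tally of nuclei by test-signal count.

    ``n_anomalous`` counts diploid nuclei with >2 test signals; these are
    reported but never folded into ``n2``.
    """

    probe_id: str
    sex: Sex
    n2: int
    n1: int
    n0: int
    n_anomalous: int = 0

    @property
    def n_scored(self) -> int:
        return self.n2 + self.n1 + self.n0

    @property
    def fractions(self) -> tuple[float, float, float]:
        """(f2, f1, f0) among scored nuclei; requires n_scored > 0."""
        n = self.n_scored
        if n == 0:
            raise ValueError(f"{self.probe_id}/{self.sex.value}: empty summary")
        return self.n2 / n, self.n1 / n, self.n0 / n


@dataclass(frozen=True)
class PairExperimentRecord:
    """One nucleus scored in a two-color neighbouring-gene-pair experiment.

    ``colocated`` says whether the two single signals sit in close proximity
    (same-chromosome origin); it is defined only when both loci show exactly
    one signal, and must be ``None`` otherwise.
    """

    experiment_id: str
    probe_a: str
    probe_b: str
    signals_a: int
    signals_b: int
    colocated: bool | None = None

    def __post_init__(self) -> None:
        both_mono = self.signals_a == 1 and self.signals_b == 1
        if both_mono and self.colocated is None:
            raise ValueError("colocated must be set when both loci show one signal")
        if not both_mono and self.colocated is not None:
            raise ValueError("colocated is defined only when both loci show one signal")


# ---------------------------------------------------------------------------
# Tabular I/O.  All on-disk formats are headed TSV; lines starting with '#'
# are treated as comments (the simulator writes provenance there).
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_nucleus_table(
    path: str | Path,
) -> tuple[list[NucleusRecord], list[RowError]]:
    """Read a per-nucleus TSV; malformed rows are collected, not fatal.

    Returns ``(records, errors)`` where each error carries the 1-based line
    number of the offending data row.
    """
    df = _read_tsv(path, NUCLEUS_COLUMNS)
    records: list[NucleusRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        try:
            records.append(
                NucleusRecord(
                    experiment_id=row.experiment_id,
                    individual_id=row.individual_id,
                    sex=Sex(row.sex),
                    probe_id=row.probe_id,
                    control_signals=_parse_count(row.control_signals, "control_signals"),
                    test_signals=_parse_count(row.test_signals, "test_signals"),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(RowError(line=line, message=str(exc)))
    return records, errors


def _parse_count(raw: str, name: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise ValueError(f"non-integer {name}: {raw!r}") from None


def write_nucleus_table(
    records: Iterable[NucleusRecord], path: str | Path, header_comments: Sequence[str] = ()
) -> None:
    path = Path(path)
    rows = [
        (r.experiment_id, r.individual_id, r.sex.value, r.probe_id, r.control_signals, r.test_signals)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=NUCLEUS_COLUMNS)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_panel(path: str | Path) -> list[LocusProbe]:
    """Read a locus panel TSV (probe_id, species, chromosome, locus_class,
    start, end, genes comma-joined).  probe_id must be unique."""
    df = _read_tsv(path, PANEL_COLUMNS)
    probes = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.probe_id in seen:
            raise ValueError(f"duplicate probe_id in panel: {row.probe_id}")
        seen.add(row.probe_id)
        probes.append(
            LocusProbe(
                probe_id=row.probe_id,
                species=row.species,
                chromosome=row.chromosome,
                locus_class=LocusClass(row.locus_class),
                start_bp=int(row.start),
                end_bp=int(row.end),
                genes=tuple(g for g in row.genes.split(",") if g),
            )
        )
    return probes


def write_panel(panel: Iterable[LocusProbe], path: str | Path) -> None:
    rows = [
        (p.probe_id, p.species, p.chromosome, p.locus_class.value, p.start_bp, p.end_bp,
         ",".join(p.genes))
        for p in panel
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pair_table(path: str | Path) -> list[PairExperimentRecord]:
    """Read a two-color pair experiment TSV (colocated in {0,1,NA})."""
    df = _read_tsv(path, PAIR_COLUMNS)
    records = []
    for row in df.itertuples(index=False):
        coloc_raw = row.colocated.strip()
        colocated = None if coloc_raw in ("", "NA", "na", ".") else bool(int(coloc_raw))
        records.append(
            PairExperimentRecord(
                experiment_id=row.experiment_id,
                probe_a=row.probe_a,
                probe_b=row.probe_b,
                signals_a=int(row.signals_a),
                signals_b=int(row.signals_b),
                colocated=colocated,
            )
        )
    return records


def write_pair_table(
    records: Iterable[PairExperimentRecord], path: str | Path, header_comments: Sequence[str] = ()
) -> None:
    rows = [
        (r.experiment_id, r.probe_a, r.probe_b, r.signals_a, r.signals_b,
         "NA" if r.colocated is None else int(r.colocated))
        for r in records
    ]
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_summary_table(path: str | Path) -> list[SignalCountSummary]:
    """Read pre-aggregated per-(probe, sex) tallies.

    Accepts data published only as aggregates; columns probe_id, sex, n2,
    n1, n0 (and optionally n_anomalous).
    """
    df = _read_tsv(path, SUMMARY_COLUMNS)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SignalCountSummary(
                probe_id=row.probe_id,
                sex=Sex(row.sex),
                n2=int(row.n2),
                n1=int(row.n1),
                n0=int(row.n0),
                n_anomalous=int(getattr(row, "n_anomalous", 0) or 0),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Filtering and aggregation
# ---------------------------------------------------------------------------


def filter_diploid(
    records: Sequence[NucleusRecord],
) -> tuple[list[NucleusRecord], list[NucleusRecord]]:
    """Partition nuclei by the diploid-control rule.

    Only nuclei with exactly two control-probe signals are scored for the
    test probe; all others (polyploid, or control hybridization failure) are
    excluded.  ``kept + excluded`` is always a partition of the input.
    """
    kept = [r for r in records if r.control_signals == 2]
    excluded = [r for r in records if r.control_signals != 2]
    return kept, excluded


def summarize_counts(
    records: Iterable[NucleusRecord], probe_id: str, sex: Sex
) -> SignalCountSummary:
    """Tally diploid-filtered nuclei of one probe and sex by test-signal count.

    Nuclei with >2 test signals in a diploid nucleus are an anomaly class,
    counted in ``n_anomalous`` and never folded into ``n2``.  Raises
    ``ValueError`` when no record matches.
    """
    n2 = n1 = n0 = n_anom = 0
    for r in records:
        if r.probe_id != probe_id or r.sex != sex:
            continue
        if r.test_signals > 2:
            n_anom += 1
        elif r.test_signals == 2:
            n2 += 1
        elif r.test_signals == 1:
            n1 += 1
        else:
            n0 += 1
    if n2 + n1 + n0 + n_anom == 0:
        raise ValueError(f"no records for probe {probe_id!r}, sex {sex.value!r}")
    return SignalCountSummary(probe_id=probe_id, sex=sex, n2=n2, n1=n1, n0=n0, n_anomalous=n_anom)


def write_activity_map(results, panel: Sequence[LocusProbe], path: str | Path) -> None:
    """Write a BED-like per-locus activity map.

    One row per locus, sorted by chromosome then start.  Columns: chrom,
    start, end, probe_id, score (= pct 1-active rounded to integer), strand
    ".", then pct_2_active, pct_1_active, pct_0, adjusted p-value.

    ``results`` is a sequence of :class:`~allelefish.inference.InactivationResult`.
    """
    by_id = {p.probe_id: p for p in panel}
    rows = []
    for res in results:
        probe = by_id.get(res.probe_id)
        if probe is None:
            raise KeyError(f"probe_id {res.probe_id!r} not found in panel")
        rows.append(
            (
                probe.chromosome,
                probe.start_bp,
                probe.end_bp,
                probe.probe_id,
                int(round(res.pct_1_active)),
                ".",
                round(res.pct_2_active, 4),
                round(res.pct_1_active, 4),
                round(res.pct_0, 4),
                res.p_adj_bonferroni,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "probe_id", "score", "strand",
                 "pct_2_active", "pct_1_active", "pct_0_active", "p_adj"],
    )
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
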