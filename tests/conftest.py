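import pytest

from allelefish.data import NucleusRecord, Sex, SignalCountSummary


def make_records(counts, probe_id="z1", sex=Sex.HOMOGAMETIC, control=2):
    """Build NucleusRecords with the given test-signal counts."""
    return [
        NucleusRecord(
            experiment_id="e1",
            individual_id="i1",
            sex=sex,
            probe_id=probe_id,
            control_signals=control,
            test_signals=c,
        )
        for c in counts
    ]


@pytest.fixture
def nucleus_tsv(tmp_path):
    """A well-formed 3-row per-nucleus table on disk."""
    path = tmp_path / "nuclei.tsv"
    path.write_text(
        "experiment_id\tindividual_id\tsex\tprobe_id\tcontrol_signals\ttest_signals\n"
        "e1\ti1\thomogametic\tz1\t2\t2\n"
        "e1\ti1\thomogametic\tz1\t2\t1\n"
        "e1\ti2\theterogametic\tz1\t2\t1\n"
    )
    return path


@pytest.fixture
def strong_summary():
    """Homogametic tally with a strong one-signal excess (40% 1-active)."""
    return SignalCountSummary("z1", Sex.HOMOGAMETIC, n2=118, n1=80, n0=2)
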