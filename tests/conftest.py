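import pytest

from ssrkit.model import GenotypeCall, GenotypeTable, SampleRecord


def make_sample(sid, calls, cultivar="CV", locality="loc", sex="female"):
    return SampleRecord(
        sample_id=sid,
        cultivar=cultivar,
        locality=locality,
        sex=sex,
        calls={locus: GenotypeCall(*pair) if pair else GenotypeCall() for locus, pair in calls.items()},
    )


def make_table(rows, locus_names=None):
    """rows: list of (sid, cultivar, {locus: (a, b) or None})."""
    samples = [make_sample(sid, calls, cultivar=cv) for sid, cv, calls in rows]
    return GenotypeTable.from_samples(samples, locus_names)


@pytest.fixture
def toy_table():
    return make_table(
        [
            ("s1", "alpha", {"L1": (140, 150), "L2": (200, 200)}),
            ("s2", "alpha", {"L1": (140, 140), "L2": (200, 202)}),
            ("s3", "beta", {"L1": (150, 150), "L2": (202, 202)}),
            ("s4", "beta", {"L1": (140, 150), "L2": None}),
        ]
    )
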