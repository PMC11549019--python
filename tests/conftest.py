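import numpy as np
import pysam
import pytest

from atacqc.io_formats import AlignedRead
from atacqc.synthetic import generate_fixture, preset_fixtures


def make_read(**kw) -> AlignedRead:
    """In-memory AlignedRead with sensible defaults for unit tests."""
    defaults = dict(
        query_name="r1",
        reference_name="Chr1",
        start=100,
        end=200,
        strand="+",
        mapq=60,
        paired=True,
        proper_pair=True,
        mate_unmapped=False,
        reverse=False,
        secondary=False,
        supplementary=False,
        duplicate=False,
        qc_fail=False,
        unmapped=False,
        first_in_pair=True,
        template_length=180,
        aligned_length=100,
        gc_count=50,
        query_length=100,
        segment=None,
    )
    defaults.update(kw)
    if "aligned_length" not in kw and not defaults["unmapped"]:
        defaults["aligned_length"] = defaults["end"] - defaults["start"]
    return AlignedRead(**defaults)


def write_bam(path, header, rows):
    """Write a coordinate-sorted BAM from (name, ref, start, span, flag,
    mapq, tlen) tuples; rows must already be position-sorted per reference."""
    ref_ids = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for name, ref, start, span, flag, mapq, tlen in rows:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.flag = flag
            a.mapping_quality = mapq
            a.template_length = tlen
            if ref is None:
                a.reference_id = -1
            else:
                a.reference_id = ref_ids[ref]
                a.reference_start = start
                a.cigarstring = f"{span}M"
            a.query_sequence = "A" * span
            a.query_qualities = pysam.qualitystring_to_array("I" * span)
            out.write(a)
    pysam.index(str(path))
    return path


SIMPLE_HEADER = {
    "HD": {"VN": "1.6", "SO": "coordinate"},
    "SQ": [
        {"SN": "Chr1", "LN": 100_000},
        {"SN": "ChrM", "LN": 10_000},
    ],
}


@pytest.fixture(scope="session")
def presets():
    return preset_fixtures()


@pytest.fixture(scope="session")
def fixtures(tmp_path_factory, presets):
    """All named preset fixtures, generated once per session."""
    root = tmp_path_factory.mktemp("fixtures")
    out = {}
    for name, spec in presets.items():
        out[name] = generate_fixture(spec, root / name, prefix=name)
    return out


@pytest.fixture(scope="session")
def clean_fixture(fixtures):
    return fixtures["clean"]


@pytest.fixture(scope="session")
def grid_fixture(fixtures):
    return fixtures["grid"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
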