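"""Shared fixtures: tiny in-memory SAM files and simulated datasets."""

import numpy as np
import pysam
import pytest

from clipcall import synthetic


HEADER = pysam.AlignmentHeader.from_dict(
    {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": "chr1", "LN": 100000}, {"SN": "chr2", "LN": 100000}],
    }
)


def make_read(
    name,
    chrom="chr1",
    start=100,
    cigar="30M",
    strand="+",
    seq=None,
    md=None,
    flag_extra=0,
):
    read = pysam.AlignedSegment(HEADER)
    read.query_name = name
    read.flag = (16 if strand == "-" else 0) | flag_extra
    read.reference_id = 0 if chrom == "chr1" else 1
    read.reference_start = start
    read.mapping_quality = 60
    read.cigarstring = cigar
    if seq is None:
        seq = "A" * read.infer_query_length()
    read.query_sequence = seq
    read.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    if md is not None:
        read.set_tag("MD", md)
    return read


def write_sam(path, reads):
    with pysam.AlignmentFile(str(path), "wh", header=HEADER) as fh:
        for read in reads:
            fh.write(read)
    return str(path)


@pytest.fixture
def sam_factory(tmp_path):
    def _factory(reads, name="test.sam"):
        return write_sam(tmp_path / name, reads)

    return _factory


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small default-scenario simulation shared across fast tests."""
    out = tmp_path_factory.mktemp("smallsim")
    config = synthetic.SimulationConfig(seed=202, n_clusters=60)
    return synthetic.simulate_dataset(config, str(out))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
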