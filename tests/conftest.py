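from array import array
from types import SimpleNamespace

import pysam
import pytest

from mitoscreen.synth import SimulationConfig, simulate_reads, simulate_reference

DEFAULT_HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6", "SO": "coordinate"},
     "SQ": [{"SN": "synthetic_chrM", "LN": 100_000}]}
)


def make_record(seq, mm=None, ml=None, name="r1", flag=0, ref_start=0, cigar=None,
                header=DEFAULT_HEADER):
    """Build an in-memory aligned record; ``seq`` is the stored (aligned
    orientation) sequence, MM/ML refer to the as-sequenced read."""
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.query_sequence = seq
    rec.flag = flag
    if not rec.is_unmapped:
        rec.reference_id = 0
        rec.reference_start = ref_start
        rec.mapping_quality = 60
        rec.cigarstring = cigar or f"{len(seq)}M"
    if mm is not None:
        rec.set_tag("MM", mm, value_type="Z")
    if ml is not None:
        rec.set_tag("ML", array("B", ml))
    return rec


def _simulate(tmp_path_factory, name, config):
    d = tmp_path_factory.mktemp(name)
    reference = simulate_reference(config)
    truth = simulate_reads(reference, config, d / "reads.bam", d / "truth.tsv")
    return SimpleNamespace(
        dir=d,
        config=config,
        reference=reference,
        truth=truth,
        truth_by_id={t.read_id: t for t in truth},
        bam=d / "reads.bam",
        truth_tsv=d / "truth.tsv",
    )


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """500-read default-world simulation for unit tests."""
    return _simulate(tmp_path_factory, "sim_small", SimulationConfig(n_reads=500, seed=5))


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """The stated default world at n = 10,000 (seed fixed a priori)."""
    return _simulate(
        tmp_path_factory, "sim_default", SimulationConfig(n_reads=10_000, seed=20)
    )
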