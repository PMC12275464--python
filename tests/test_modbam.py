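"""MM/ML codec: decoding, lossless re-encoding, and 5hmC stripping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitoscreen.modbam import (
    DeltaOverrunError,
    MLLengthError,
    MMGrammarError,
    ModCall,
    ModRun,
    decode_mod_tags,
    decode_record,
    encode_mod_tags,
    ml_byte_to_probability,
    probability_to_ml_byte,
    strip_modification,
)

from conftest import make_record
from oracles import oracle_decode, oracle_strip, random_mod_tags

DNA = st.text(alphabet="ACGT", min_size=0, max_size=50)


def _as_tuples(calls):
    return [
        (c.position, c.canonical_base, c.mod_strand, c.mod_code,
         probability_to_ml_byte(c.probability))
        for c in calls
    ]


@pytest.mark.parametrize(
    "seq, mm, ml, expected",
    [
        # skips: C occurrences {2,4,5}; skip 1 then 0 -> positions 4, 5
        ("AGCTCCG", "C+m,1,0;", [230, 10],
         [(4, "C", "+", "m", 230), (5, "C", "+", "m", 10)]),
        # header-only run on a C-free read
        ("AAAA", "C+m;", [], []),
        # multi-code run: per-position bytes interleaved h then m
        ("CGCG", "C+hm,0,0;", [10, 200, 30, 100],
         [(0, "C", "+", "h", 10), (0, "C", "+", "m", 200),
          (2, "C", "+", "h", 30), (2, "C", "+", "m", 100)]),
        # explicit-mode flag and reverse-strand run are accepted
        ("ACGCG", "G-m?,0,0;", [7, 9],
         [(2, "G", "-", "m", 7), (4, "G", "-", "m", 9)]),
        # ChEBI numeric code passes through as one code
        ("CCC", "C+76792,2;", [128], [(2, "C", "+", "76792", 128)]),
    ],
)
def test_decode_examples(seq, mm, ml, expected):
    calls, _ = decode_mod_tags(seq, mm, ml)
    assert _as_tuples(calls) == expected


def test_decode_probability_is_bin_midpoint():
    calls, _ = decode_mod_tags("AGCTCCG", "C+m,1,0;", [230, 10])
    assert calls[0].probability == pytest.approx((2 * 230 + 1) / 512)
    assert calls[1].probability == pytest.approx((2 * 10 + 1) / 512)
    assert ml_byte_to_probability(0) == pytest.approx(1 / 512)
    assert ml_byte_to_probability(255) == pytest.approx(511 / 512)


@pytest.mark.parametrize(
    "seq, mm, ml, exc",
    [
        ("ACGT", "C+m,x;", [1], MMGrammarError),
        ("ACGT", "Zm,0;", [1], MMGrammarError),
        ("ACGT", "C+m,0", [1], MMGrammarError),          # missing terminator
        ("ACGT", "C+m,5;", [1], DeltaOverrunError),      # only one C
        ("ACGT", "C+m,0;", [1, 2], MLLengthError),
        ("CGCG", "C+hm,0;", [1], MLLengthError),         # 2 codes need 2 bytes
    ],
)
def test_decode_errors(seq, mm, ml, exc):
    with pytest.raises(exc):
        decode_mod_tags(seq, mm, ml)


def test_missing_ml_assumes_probability_one():
    with pytest.warns(UserWarning, match="probability 1.0"):
        calls, _ = decode_mod_tags("ACGT", "C+m,0;", None)
    assert calls[0].probability == 1.0


def test_skip_mode_semantics():
    _, runs = decode_mod_tags("CGCG", "C+m?,0;C-h.;", [5])
    assert runs[0].skip_mode == "explicit"
    assert runs[1].skip_mode == "implicit"
    _, runs = decode_mod_tags("CGCG", "C+m,0;", [5])
    assert runs[0].skip_mode == "implicit"  # absent flag == implicit


def test_encode_round_trip_example():
    calls, runs = decode_mod_tags("AGCTCCG", "C+m,1,0;", [230, 10])
    assert encode_mod_tags(calls, runs, "AGCTCCG") == ("C+m,1,0;", [230, 10])


def test_encode_header_only_run():
    mm, ml = encode_mod_tags([], [ModRun("C", "+", ("m",), "?")], "AAAA")
    assert (mm, ml) == ("C+m?;", [])


def test_encode_rejects_call_off_base():
    calls = [ModCall(0, "C", "+", "m", 0.5)]
    runs = [ModRun("C", "+", ("m",), "?")]
    with pytest.raises(Exception, match="not a C"):
        encode_mod_tags(calls, runs, "AGCT")


@settings(max_examples=300, derandomize=True)
@given(seq=DNA, seed=st.integers(0, 2**31 - 1))
def test_fuzzed_decode_matches_oracle_and_round_trips(seq, seed):
    """Decoder agrees with brute-force occurrence enumeration, and
    decode -> encode reproduces the original MM/ML byte for byte."""
    rng = np.random.default_rng(seed)
    mm, ml = random_mod_tags(rng, seq)
    calls, runs = decode_mod_tags(seq, mm, ml)
    assert _as_tuples(calls) == oracle_decode(seq, mm, ml)
    assert sum(len(r.deltas) * len(r.mod_codes) for r in runs) == len(ml)
    mm2, ml2 = encode_mod_tags(calls, runs, seq)
    assert (mm2, ml2) == (mm, ml)


def test_decode_record_uses_as_sequenced_orientation():
    """A reverse-aligned record's MM coordinates refer to the
    reverse-complement of the stored SEQ."""
    stored = "AACGTT"            # as-sequenced read is also AACGTT revcomp'd
    rec = make_record(stored, mm="C+m,0;", ml=[200], flag=16)
    fwd, calls, _ = decode_record(rec)
    assert fwd == "AACGTT"[::-1].translate(str.maketrans("ACGT", "TGCA"))
    assert fwd[calls[0].position] == "C"


def test_decode_record_cross_checked_against_pysam():
    """pysam's modified_bases_forward is an independent decoder."""
    revcomp = str.maketrans("ACGT", "TGCA")
    rng = np.random.default_rng(42)
    for i in range(50):
        as_sequenced = "".join(rng.choice(list("ACGT"), size=60))
        occurrences = [j for j, b in enumerate(as_sequenced) if b == "C"]
        if not occurrences:
            continue
        n = int(rng.integers(1, len(occurrences) + 1))
        chosen = sorted(rng.choice(len(occurrences), size=n, replace=False))
        deltas, prev = [], -1
        for idx in chosen:
            deltas.append(int(idx) - prev - 1)
            prev = int(idx)
        ml = [int(b) for b in rng.integers(0, 256, size=n)]
        mm = "C+m?" + "".join(f",{d}" for d in deltas) + ";"
        flag = 16 if i % 2 else 0
        stored = as_sequenced if flag == 0 else as_sequenced.translate(revcomp)[::-1]
        rec = make_record(stored, mm=mm, ml=ml, flag=flag)
        _, calls, _ = decode_record(rec)
        expected = rec.modified_bases_forward.get(("C", 0, "m"), [])
        # pysam lists calls in stored-coordinate order on reverse records
        assert sorted((c.position, probability_to_ml_byte(c.probability)) for c in calls) \
            == sorted((p, q) for p, q in expected)


# --- strip_modification ----------------------------------------------------

def test_strip_drop_removes_interleaved_h_bytes():
    rec = make_record("CGAT", mm="C+hm,0;", ml=[40, 200])
    strip_modification(rec, {"h"}, "drop")
    assert rec.get_tag("MM") == "C+m,0;"
    assert list(rec.get_tag("ML")) == [200]


def test_strip_is_noop_without_target_code():
    rec = make_record("CGAT", mm="C+m,0;", ml=[200])
    strip_modification(rec, {"h"}, "drop")
    assert rec.get_tag("MM") == "C+m,0;"
    assert list(rec.get_tag("ML")) == [200]


def test_strip_passes_through_untagged_records():
    rec = make_record("CGAT")
    assert strip_modification(rec, {"h"}) is rec
    assert not rec.has_tag("MM")


def test_strip_merge_sums_bin_midpoints():
    rec = make_record("CGAT", mm="C+hm,0;", ml=[100, 100])
    strip_modification(rec, {"h"}, "merge_into_m")
    # 0.3926 + 0.3926 = 0.7852 re-bins to byte 200
    assert rec.get_tag("MM") == "C+m,0;"
    assert list(rec.get_tag("ML")) == [200]


def test_strip_merge_caps_at_max_probability():
    rec = make_record("CGAT", mm="C+hm,0;", ml=[255, 255])
    strip_modification(rec, {"h"}, "merge_into_m")
    assert list(rec.get_tag("ML")) == [255]


@settings(max_examples=200, derandomize=True)
@given(seq=DNA, seed=st.integers(0, 2**31 - 1))
def test_strip_drop_matches_interleaving_oracle(seq, seed):
    """After dropping 'h', no 'h' calls remain and retained calls keep
    position and byte, per an independent interleaving oracle."""
    if not seq:
        return
    rng = np.random.default_rng(seed)
    mm, ml = random_mod_tags(rng, seq)
    rec = make_record(seq, mm=mm, ml=ml)
    strip_modification(rec, {"h"}, "drop")
    _, calls, _ = decode_record(rec)
    assert _as_tuples(calls) == oracle_strip(seq, mm, ml, {"h"})
    assert all(c.mod_code != "h" for c in calls)
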