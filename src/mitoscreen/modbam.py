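"""MM/ML modified-base tag codec.

Decodes the delta-encoded MM tag and paired ML probability bytes of a
modBAM record into explicit per-position modification calls, re-encodes
them losslessly, and supports stripping selected modification codes
(e.g. removing 5hmC so that only 5mC calls remain).

Coordinate convention: MM positions refer to the read in its
AS-SEQUENCED orientation.  For reverse-strand alignments the stored SEQ
must be reverse-complemented before decoding (``get_forward_sequence``
on a pysam record); decoded positions are reported in as-sequenced
coordinates.

Probability convention: ML byte ``b`` encodes the interval
``[b/256, (b+1)/256)``; calls carry the bin midpoint ``(2b+1)/512``.
"""

from __future__ import annotations

import re
import warnings
from array import array
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ModCall",
    "ModRun",
    "ModTagError",
    "MMGrammarError",
    "DeltaOverrunError",
    "MLLengthError",
    "EncodingError",
    "decode_mod_tags",
    "encode_mod_tags",
    "decode_record",
    "strip_modification",
    "probability_to_ml_byte",
    "ml_byte_to_probability",
]


class ModTagError(ValueError):
    """Base class for MM/ML codec failures."""


class MMGrammarError(ModTagError):
    """MM string does not match the tag grammar."""


class DeltaOverrunError(ModTagError):
    """A delta list skips past the available base occurrences."""


class MLLengthError(ModTagError):
    """ML byte count disagrees with the calls implied by MM."""


class EncodingError(ModTagError):
    """A call is inconsistent with the read sequence."""


def ml_byte_to_probability(byte: int) -> float:
    """Midpoint of the probability bin encoded by an ML byte."""
    if not 0 <= byte <= 255:
        raise ModTagError(f"ML byte {byte} outside 0..255")
    return (2 * byte + 1) / 512.0


def probability_to_ml_byte(probability: float) -> int:
    """Inverse of :func:`ml_byte_to_probability`; exact on bin midpoints."""
    if not 0.0 <= probability <= 1.0:
        raise ModTagError(f"probability {probability} outside [0, 1]")
    return min(255, max(0, int(round(probability * 256.0 - 0.5))))


@dataclass(frozen=True, order=True)
class ModCall:
    """One decoded base-modification call on a read.

    ``position`` is a 0-based offset into the read in its as-sequenced
    orientation.  ``mod_strand`` is the strand of the sequenced molecule
    the modification is reported on ('+' means the read base at
    ``position`` equals ``canonical_base``).  ``probability`` is the
    midpoint of the ML probability bin.
    """

    position: int
    canonical_base: str
    mod_strand: str
    mod_code: str
    probability: float


@dataclass
class ModRun:
    """Structured form of one semicolon-delimited MM item.

    ``mod_codes`` is the ordered tuple of codes sharing one delta list
    (a ChEBI numeric code occupies a single entry).  ``flag`` is the
    literal skip-mode character from the tag: '?' for explicit mode,
    '.' or '' for implicit mode.
    """

    canonical_base: str
    mod_strand: str
    mod_codes: tuple[str, ...]
    flag: str = "?"
    deltas: list[int] = field(default_factory=list)

    @property
    def skip_mode(self) -> str:
        """'implicit': uncalled canonical bases asserted unmodified;
        'explicit': uncalled bases carry no information."""
        return "explicit" if self.flag == "?" else "implicit"


_RUN_RE = re.compile(r"([ACGTUN])([-+])((?:[a-z]+)|(?:\d+))([.?]?)((?:,\d+)*);")


def _occurrences(base: str, sequence: str) -> list[int]:
    if base == "N":
        return list(range(len(sequence)))
    return [i for i, b in enumerate(sequence) if b == base]


def decode_mod_tags(
    read_sequence_as_sequenced: str,
    mm_value: str,
    ml_values: Sequence[int] | None,
    read_id: str = "?",
) -> tuple[list[ModCall], list[ModRun]]:
    """Decode MM/ML tags into explicit calls plus their run structure.

    Parameters
    ----------
    read_sequence_as_sequenced
        Read bases in sequencing orientation (reverse-complement of the
        stored SEQ for reverse-aligned records).
    mm_value
        The MM tag payload: zero or more semicolon-terminated runs.
    ml_values
        The ML byte list, or ``None`` for a missing ML tag, in which
        case every call is assigned probability 1.0 (with a warning).

    Returns
    -------
    (calls, runs)
        Calls in tag order with resolved read coordinates, and one
        :class:`ModRun` per MM item.
    """
    seq = read_sequence_as_sequenced
    calls: list[ModCall] = []
    runs: list[ModRun] = []

    pos = 0
    while pos < len(mm_value):
        m = _RUN_RE.match(mm_value, pos)
        if m is None:
            raise MMGrammarError(
                f"read {read_id}: malformed MM run at {mm_value[pos:pos + 30]!r}"
            )
        base, strand, codes_str, flag, delta_str = m.groups()
        codes = (codes_str,) if codes_str.isdigit() else tuple(codes_str)
        deltas = [int(d) for d in delta_str.split(",")[1:]] if delta_str else []
        runs.append(ModRun(base, strand, codes, flag, deltas))
        pos = m.end()

    n_expected = sum(len(r.deltas) * len(r.mod_codes) for r in runs)
    if ml_values is None:
        if n_expected:
            warnings.warn(
                f"read {read_id}: MM without ML; assuming probability 1.0",
                stacklevel=2,
            )
        ml: list[int] | None = None
    else:
        ml = list(ml_values)
        if len(ml) != n_expected:
            raise MLLengthError(
                f"read {read_id}: MM implies {n_expected} ML bytes, got {len(ml)}"
            )

    k = 0
    for run in runs:
        occ = _occurrences(run.canonical_base, seq)
        idx = -1
        for delta in run.deltas:
            idx += delta + 1
            if idx >= len(occ):
                raise DeltaOverrunError(
                    f"read {read_id}: run {run.canonical_base}{run.mod_strand}"
                    f"{''.join(run.mod_codes)} skips past the last "
                    f"{run.canonical_base} occurrence ({len(occ)} available)"
                )
            for code in run.mod_codes:
                prob = 1.0 if ml is None else ml_byte_to_probability(ml[k])
                k += 1 if ml is not None else 0
                calls.append(
                    ModCall(occ[idx], run.canonical_base, run.mod_strand, code, prob)
                )
    if ml is not None and k != len(ml):  # defensive; cannot trip after length check
        raise MLLengthError(f"read {read_id}: consumed {k} of {len(ml)} ML bytes")
    return calls, runs


def encode_mod_tags(
    calls: Iterable[ModCall],
    runs: Iterable[ModRun],
    read_sequence_as_sequenced: str,
) -> tuple[str, list[int]]:
    """Re-encode calls into MM/ML values; inverse of :func:`decode_mod_tags`.

    Runs supply the grouping (base, strand, code order, skip flag);
    deltas are recomputed from call positions, and each probability is
    re-binned to its ML byte (the original byte when the probability
    came from decoding).  Header-only runs (no calls) are preserved.
    """
    seq = read_sequence_as_sequenced
    remaining = list(calls)
    mm_items: list[str] = []
    ml: list[int] = []
    for run in runs:
        mine = [
            c
            for c in remaining
            if c.canonical_base == run.canonical_base
            and c.mod_strand == run.mod_strand
            and c.mod_code in run.mod_codes
        ]
        for c in mine:
            remaining.remove(c)
        by_pos: dict[int, dict[str, float]] = defaultdict(dict)
        for c in mine:
            by_pos[c.position][c.mod_code] = c.probability

        occ = _occurrences(run.canonical_base, seq)
        occ_index = {p: i for i, p in enumerate(occ)}
        deltas: list[int] = []
        prev = -1
        for p in sorted(by_pos):
            if p not in occ_index:
                raise EncodingError(
                    f"call at position {p} is not a {run.canonical_base} in the read"
                )
            deltas.append(occ_index[p] - prev - 1)
            prev = occ_index[p]
            for code in run.mod_codes:
                if code not in by_pos[p]:
                    raise EncodingError(
                        f"multi-code run {''.join(run.mod_codes)} lacks a "
                        f"'{code}' call at position {p}"
                    )
                ml.append(probability_to_ml_byte(by_pos[p][code]))
        mm_items.append(
            f"{run.canonical_base}{run.mod_strand}{''.join(run.mod_codes)}{run.flag}"
            + "".join(f",{d}" for d in deltas)
            + ";"
        )
    if remaining:
        c = remaining[0]
        raise EncodingError(
            f"call ({c.position}, {c.mod_code}) matches no run in the run list"
        )
    return "".join(mm_items), ml


# ---------------------------------------------------------------------------
# pysam record helpers

def _get_mm_ml(record) -> tuple[str | None, list[int] | None]:
    mm = None
    for tag in ("MM", "Mm"):
        if record.has_tag(tag):
            mm = record.get_tag(tag)
            break
    ml = None
    for tag in ("ML", "Ml"):
        if record.has_tag(tag):
            ml = list(record.get_tag(tag))
            break
    return mm, ml


def decode_record(record) -> tuple[str, list[ModCall], list[ModRun]]:
    """Decode a pysam record's MM/ML tags in as-sequenced orientation.

    Returns ``(forward_sequence, calls, runs)``.  A record without an MM
    tag decodes to empty calls and runs.
    """
    seq = record.get_forward_sequence()
    if seq is None:
        raise ModTagError(f"read {record.query_name}: record has no sequence")
    mm, ml = _get_mm_ml(record)
    if mm is None:
        return seq, [], []
    calls, runs = decode_mod_tags(seq, mm, ml, read_id=record.query_name)
    return seq, calls, runs


_MAX_PROB = 511 / 512.0


def strip_modification(record, codes_to_remove: set[str], policy: str = "drop"):
    """Remove modification codes from a record's MM/ML tags, in place.

    Under ``'drop'`` the removed codes' probability mass is discarded
    (implicitly reassigned to the canonical base); retained calls keep
    their positions and bytes.  Under ``'merge_into_m'`` the removed
    mass is folded into the 5mC call at the same position, capped at
    511/512 (a bare removed call becomes an 'm' call).  Records without
    MM/ML pass through unchanged.
    """
    if policy not in ("drop", "merge_into_m"):
        raise ValueError(f"unknown strip policy {policy!r}")
    mm, _ = _get_mm_ml(record)
    if mm is None:
        return record
    seq, calls, runs = decode_record(record)

    if policy == "drop":
        new_calls = [c for c in calls if c.mod_code not in codes_to_remove]
        new_runs = []
        for run in runs:
            kept = tuple(c for c in run.mod_codes if c not in codes_to_remove)
            if kept:
                new_runs.append(
                    ModRun(run.canonical_base, run.mod_strand, kept, run.flag)
                )
    else:
        merged: dict[tuple[str, str, int], float] = defaultdict(float)
        new_calls = []
        for c in calls:
            if c.mod_code == "m" or c.mod_code in codes_to_remove:
                merged[(c.canonical_base, c.mod_strand, c.position)] += c.probability
            else:
                new_calls.append(c)
        for (base, strand, pos), prob in merged.items():
            new_calls.append(ModCall(pos, base, strand, "m", min(prob, _MAX_PROB)))
        # runs rebuilt one code per run: 'h' and 'm' positions may differ
        # in explicit mode, so a shared delta list is not reconstructible
        flags = {(r.canonical_base, r.mod_strand): r.flag for r in runs}
        seen: dict[tuple[str, str, str], str] = {}
        for c in new_calls:
            key = (c.canonical_base, c.mod_strand, c.mod_code)
            seen.setdefault(key, flags.get((c.canonical_base, c.mod_strand), "?"))
        new_runs = [
            ModRun(base, strand, (code,), flag)
            for (base, strand, code), flag in seen.items()
        ]

    new_mm, new_ml = encode_mod_tags(new_calls, new_runs, seq)
    for tag in ("Mm", "Ml"):  # normalize legacy lowercase tags away
        if record.has_tag(tag):
            record.set_tag(tag, None)
    record.set_tag("MM", new_mm, value_type="Z")
    record.set_tag("ML", array("B", new_ml))
    return record
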