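"""Read-set overlap between two partitions or alignments.

Used to check the methylation-based split against an orthogonal,
alignment-based assignment: reads that realign to nuclear NuMT loci
should overlap the methylated (+m) partition almost completely.  The
realignment itself is external; this module only computes the set
overlap given two BAMs or read-id lists.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import pysam

__all__ = ["OverlapReport", "overlap_report", "read_ids"]

_SUFFIX_RE = re.compile(r"/[12]$")


def _normalize(read_id: str) -> str:
    return _SUFFIX_RE.sub("", read_id.split()[0])


@dataclass
class OverlapReport:
    """Overlap of two read-id sets; the fraction is relative to the
    reference set (by convention the externally realigned set)."""

    n_reference_set: int
    n_query_set: int
    n_overlap: int
    overlap_fraction: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def read_ids(source) -> set[str]:
    """Unique, suffix-normalized read ids from a BAM/SAM path, a text
    file of ids (one per line), or any iterable of id strings."""
    if isinstance(source, (set, frozenset, list, tuple)) or (
        not isinstance(source, (str, Path)) and isinstance(source, Iterable)
    ):
        return {_normalize(r) for r in source}
    path = Path(source)
    if path.suffix.lower() in (".bam", ".sam", ".cram"):
        ids = set()
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh.fetch(until_eof=True):
                if not rec.is_unmapped:
                    ids.add(_normalize(rec.query_name))
        return ids
    with open(path) as fh:
        return {_normalize(line) for line in (l.strip() for l in fh) if line}


def overlap_report(reference_reads, query_reads) -> OverlapReport:
    """Compute the unique-id overlap between two read sets.

    Either argument may be a BAM/SAM path, an id-list file path, or an
    iterable of ids.  The denominator is the reference set; an empty
    reference set is an error (the fraction would be undefined).
    """
    ref = read_ids(reference_reads)
    query = read_ids(query_reads)
    if not ref:
        raise ValueError("reference read set is empty; overlap fraction undefined")
    n_overlap = len(ref & query)
    return OverlapReport(
        n_reference_set=len(ref),
        n_query_set=len(query),
        n_overlap=n_overlap,
        overlap_fraction=n_overlap / len(ref),
    )
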