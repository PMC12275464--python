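"""Per-read CpG methylation screening and BAM partitioning.

Each read's CpG methylation level is the fraction of its assessed
CpG-context 5mC calls whose probability reaches the call threshold
(default 0.5).  Reads below the split threshold (default 0.15, i.e.
15%) are routed to the unmethylated output (``minus_m``, the putative
mtDNA class); reads at or above it go to the methylated output
(``plus_m``, the putative NuMT class).  A fraction of exactly 0.15 is
methylated: the boundary belongs to the plus partition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import pysam

from .modbam import decode_record

__all__ = [
    "ReadMethylProfile",
    "PartitionResult",
    "ConfigurationError",
    "cpg_sites",
    "read_methylation_fraction",
    "classify_read",
    "split_bam",
    "write_profiles_tsv",
]

PROFILE_COLUMNS = ("read_id", "n_cpg_assessed", "n_methylated", "fraction", "label")


class ConfigurationError(ValueError):
    """Invalid threshold or policy configuration."""


@dataclass
class ReadMethylProfile:
    """Per-read CpG methylation accounting.

    ``n_cpg_assessed`` counts CpG-context cytosines with a 5mC call
    (plus, under implicit skip mode, uncalled CpG cytosines asserted
    unmodified); ``n_methylated`` counts assessed sites at or above the
    call threshold.  ``n_off_target`` diagnoses 'm' calls at non-CpG
    positions, which are excluded from the fraction.
    """

    read_id: str
    n_cpg_assessed: int
    n_methylated: int
    methylation_fraction: float | None
    label: str
    n_off_target: int = 0


@dataclass
class PartitionResult:
    """Accounting of one BAM split; counts are unique reads."""

    n_input: int = 0
    n_minus: int = 0
    n_plus: int = 0
    n_no_cpg: int = 0
    n_unmapped_excluded: int = 0
    n_secondary_dropped: int = 0
    split_threshold: float = 0.15
    call_threshold: float = 0.5

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def cpg_sites(read_sequence_as_sequenced: str) -> list[int]:
    """0-based positions of the C of each CG dinucleotide in the read."""
    seq = read_sequence_as_sequenced
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def classify_read(fraction: float | None, split_threshold: float = 0.15) -> str:
    """Label a methylation fraction: below the threshold is 'minus_m',
    at or above it 'plus_m', undefined (no assessable CpGs) 'no_cpg'."""
    if not 0.0 <= split_threshold <= 1.0:
        raise ConfigurationError(f"split threshold {split_threshold} outside [0, 1]")
    if fraction is None or (isinstance(fraction, float) and math.isnan(fraction)):
        return "no_cpg"
    return "minus_m" if fraction < split_threshold else "plus_m"


def read_methylation_fraction(
    record,
    call_threshold: float = 0.5,
    split_threshold: float = 0.15,
    confidence_band: tuple[float, float] | None = None,
) -> ReadMethylProfile:
    """Quantify a record's CpG methylation from its MM/ML tags.

    Only top-strand 'm' calls whose position is a CpG cytosine of the
    read's as-sequenced sequence are assessed.  Under implicit ('.')
    skip mode, CpG cytosines without a call are asserted unmodified and
    enter the denominator.  ``confidence_band``, if given, excludes
    calls with probability strictly inside the band (low-confidence
    sites) from both counts.
    """
    if not 0.0 <= call_threshold <= 1.0:
        raise ConfigurationError(f"call threshold {call_threshold} outside [0, 1]")
    seq, calls, runs = decode_record(record)
    sites = set(cpg_sites(seq))

    assessed = 0
    methylated = 0
    off_target = 0
    called_positions: set[int] = set()
    for c in calls:
        if c.mod_code != "m" or c.mod_strand != "+":
            continue
        if c.position not in sites:
            off_target += 1
            continue
        called_positions.add(c.position)
        if confidence_band is not None and confidence_band[0] < c.probability < confidence_band[1]:
            continue
        assessed += 1
        if c.probability >= call_threshold:
            methylated += 1

    # implicit mode: every uncalled C occurrence is an assessed unmodified call
    if any(
        r.skip_mode == "implicit"
        and r.canonical_base == "C"
        and r.mod_strand == "+"
        and "m" in r.mod_codes
        for r in runs
    ):
        assessed += len(sites - called_positions)

    fraction = methylated / assessed if assessed else None
    return ReadMethylProfile(
        read_id=record.query_name,
        n_cpg_assessed=assessed,
        n_methylated=methylated,
        methylation_fraction=fraction,
        label=classify_read(fraction, split_threshold),
        n_off_target=off_target,
    )


def write_profiles_tsv(profiles, path: str | Path) -> None:
    """Write per-read profiles as a TSV (the low-methylation read list
    and its complement in one table)."""
    with open(path, "w") as fh:
        fh.write("\t".join(PROFILE_COLUMNS) + "\n")
        for p in profiles:
            frac = "" if p.methylation_fraction is None else f"{p.methylation_fraction:.6g}"
            fh.write(
                f"{p.read_id}\t{p.n_cpg_assessed}\t{p.n_methylated}\t{frac}\t{p.label}\n"
            )


def screen_bam(
    in_bam: str | Path,
    call_threshold: float = 0.5,
    split_threshold: float = 0.15,
    confidence_band: tuple[float, float] | None = None,
):
    """Profile every mapped primary record of a BAM.

    Returns ``(profiles, n_unmapped, n_secondary)`` where profiles are
    keyed by read id in input order.
    """
    profiles: dict[str, ReadMethylProfile] = {}
    n_unmapped = 0
    n_secondary = 0
    with pysam.AlignmentFile(str(in_bam), "rb", check_sq=False) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if rec.is_secondary:
                n_secondary += 1
                continue
            if rec.is_supplementary:
                continue
            profiles[rec.query_name] = read_methylation_fraction(
                rec, call_threshold, split_threshold, confidence_band
            )
    return profiles, n_unmapped, n_secondary


def split_bam(
    in_bam: str | Path,
    out_minus_path: str | Path,
    out_plus_path: str | Path,
    split_threshold: float = 0.15,
    call_threshold: float = 0.5,
    no_cpg_policy: str = "to_minus",
    out_no_cpg_path: str | Path | None = None,
    report_tsv: str | Path | None = None,
    confidence_band: tuple[float, float] | None = None,
) -> PartitionResult:
    """Split a modBAM into unmethylated (−m) and methylated (+m) outputs.

    Unmapped records are excluded and secondary alignments dropped;
    supplementary alignments follow their primary's label, so all
    records of a split read land in the same output.  Reads with no
    assessable CpGs are routed per ``no_cpg_policy``: 'to_minus'
    (default — absence of methylation evidence matches the unmethylated
    mtDNA class), 'to_plus', 'separate_file', or 'drop'.  Outputs
    preserve input (coordinate) order and are indexable.
    """
    out_minus_path, out_plus_path = Path(out_minus_path), Path(out_plus_path)
    if out_minus_path.resolve() == out_plus_path.resolve():
        raise ConfigurationError("minus and plus outputs are the same path")
    if no_cpg_policy not in ("to_minus", "to_plus", "separate_file", "drop"):
        raise ConfigurationError(f"unknown no_cpg policy {no_cpg_policy!r}")
    if no_cpg_policy == "separate_file" and out_no_cpg_path is None:
        raise ConfigurationError("no_cpg policy 'separate_file' requires a path")

    profiles, n_unmapped, n_secondary = screen_bam(
        in_bam, call_threshold, split_threshold, confidence_band
    )
    labels = {rid: p.label for rid, p in profiles.items()}

    result = PartitionResult(
        split_threshold=split_threshold, call_threshold=call_threshold
    )
    result.n_unmapped_excluded = n_unmapped
    result.n_secondary_dropped = n_secondary
    for p in profiles.values():
        if p.label == "minus_m":
            result.n_minus += 1
        elif p.label == "plus_m":
            result.n_plus += 1
        else:
            result.n_no_cpg += 1
    result.n_input = result.n_minus + result.n_plus + result.n_no_cpg + n_unmapped

    route = {"minus_m": "minus", "plus_m": "plus"}
    no_cpg_dest = {
        "to_minus": "minus",
        "to_plus": "plus",
        "separate_file": "no_cpg",
        "drop": None,
    }[no_cpg_policy]

    with pysam.AlignmentFile(str(in_bam), "rb", check_sq=False) as bam:
        outs = {
            "minus": pysam.AlignmentFile(str(out_minus_path), "wb", template=bam),
            "plus": pysam.AlignmentFile(str(out_plus_path), "wb", template=bam),
        }
        if no_cpg_policy == "separate_file":
            outs["no_cpg"] = pysam.AlignmentFile(
                str(out_no_cpg_path), "wb", template=bam
            )
        try:
            for rec in bam.fetch(until_eof=True):
                if rec.is_unmapped or rec.is_secondary:
                    continue
                label = labels.get(rec.query_name)
                if label is None:  # supplementary without a primary in file
                    label = read_methylation_fraction(
                        rec, call_threshold, split_threshold, confidence_band
                    ).label
                dest = route.get(label, no_cpg_dest)
                if dest is not None:
                    outs[dest].write(rec)
        finally:
            for out in outs.values():
                out.close()

    if report_tsv is not None:
        write_profiles_tsv(profiles.values(), report_tsv)
    return result
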