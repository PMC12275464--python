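"""Per-BAM summary statistics and the read-methylation histogram.

The summary mirrors the standard per-partition block for
mitochondrial-aligned nanopore data: unique read count, mean depth of
coverage, base composition (GC%), strand-composition skews, read
length, and aggregate 5mC call counts.  GC and AT skew are computed per
read on the aligned-orientation sequence (the stored SEQ) and averaged
unweighted across reads; averaging as-sequenced orientations would
cancel the strand signature toward zero.
"""

from __future__ import annotations

import json
import math
import statistics
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .modbam import decode_record
from .screen import ReadMethylProfile, cpg_sites

__all__ = [
    "SummaryStats",
    "MethylationHistogram",
    "gc_skew",
    "at_skew",
    "gc_percent",
    "summarize",
    "methylation_histogram",
]


def _skew(sequence: str, plus: str, minus: str) -> float:
    p = sequence.count(plus)
    m = sequence.count(minus)
    if p + m == 0:
        return math.nan
    return (p - m) / (p + m)


def gc_skew(sequence: str) -> float:
    """(G − C) / (G + C); NaN when the sequence has no G or C.

    N bases are ignored.  Antisymmetric under reverse complement.
    """
    return _skew(sequence, "G", "C")


def at_skew(sequence: str) -> float:
    """(A − T) / (A + T); NaN when the sequence has no A or T."""
    return _skew(sequence, "A", "T")


def gc_percent(sequence: str) -> float:
    """G+C share of non-N bases, in percent; NaN for empty input."""
    n = sum(sequence.count(b) for b in "ACGT")
    if n == 0:
        return math.nan
    return 100.0 * (sequence.count("G") + sequence.count("C")) / n


@dataclass
class SummaryStats:
    """Aggregate statistics of one (partitioned) modBAM.

    ``unmodified_c`` and ``n_5mc`` count assessed 5mC calls below /
    at-or-above the call threshold; ``fraction_5mc`` is
    n_5mc / (unmodified_c + n_5mc), None when no calls were assessed.
    ``mean_coverage`` is mean depth: aligned reference bases divided by
    reference length.
    """

    unique_reads: int
    mean_coverage: float
    gc_pct: float
    mean_gc_skew: float
    mean_at_skew: float
    mean_read_length: float
    median_read_length: float
    unmodified_c: int
    n_5mc: int
    fraction_5mc: float | None
    call_threshold: float = 0.5

    def to_json(self, path: str | Path | None = None) -> str:
        d = {k: (None if isinstance(v, float) and math.isnan(v) else v)
             for k, v in asdict(self).items()}
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    _ROW_NAMES = {
        "unique_reads": "UNIQUE READS",
        "mean_coverage": "Coverage",
        "gc_pct": "GC%",
        "mean_gc_skew": "GC skew",
        "mean_at_skew": "AT skew",
        "mean_read_length": "Read length (mean)",
        "median_read_length": "Read length (median)",
        "unmodified_c": "Unmodified C",
        "n_5mc": "5mC",
        "fraction_5mc": "Fraction 5mC (5mC/C + 5mC)",
    }

    def to_tsv(self, path: str | Path | None = None) -> str:
        rows = []
        for field_name, row in self._ROW_NAMES.items():
            v = getattr(self, field_name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                s = "NA"
            elif isinstance(v, float):
                s = f"{v:.4g}"
            else:
                s = str(v)
            rows.append(f"{row}\t{s}")
        text = "\n".join(rows) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize(
    bam: str | Path,
    call_threshold: float = 0.5,
    reference_name: str | None = None,
    cpg_only: bool = True,
) -> SummaryStats:
    """Compute :class:`SummaryStats` over the mapped reads of a BAM.

    Skews, GC% and read length are taken per mapped primary record on
    the stored (aligned-orientation) SEQ and averaged unweighted; reads
    with an undefined skew are excluded from that mean only.  Coverage
    sums aligned reference bases over primary and supplementary records
    against the header length of ``reference_name`` (the sole SQ entry
    when omitted).  5mC calls are pooled across primary records; with
    ``cpg_only`` (default) only CpG-context calls are counted.
    """
    read_ids: set[str] = set()
    gc_skews: list[float] = []
    at_skews: list[float] = []
    gc_pcts: list[float] = []
    lengths: list[int] = []
    aligned_bases = 0
    unmodified_c = 0
    n_5mc = 0

    with pysam.AlignmentFile(str(bam), "rb", check_sq=False) as fh:
        sqs = list(zip(fh.references, fh.lengths))
        if reference_name is None:
            if len(sqs) != 1:
                raise ValueError(
                    "header has {} references; pass reference_name".format(len(sqs))
                )
            ref_len = sqs[0][1]
        else:
            by_name = dict(sqs)
            if reference_name not in by_name:
                raise ValueError(f"reference {reference_name!r} not in BAM header")
            ref_len = by_name[reference_name]

        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rec.reference_length:
                aligned_bases += rec.reference_length
            if rec.is_supplementary:
                continue
            seq = rec.query_sequence
            if seq is None:
                continue
            read_ids.add(rec.query_name)
            lengths.append(len(seq))
            g = gc_skew(seq)
            if not math.isnan(g):
                gc_skews.append(g)
            a = at_skew(seq)
            if not math.isnan(a):
                at_skews.append(a)
            p = gc_percent(seq)
            if not math.isnan(p):
                gc_pcts.append(p)

            fwd, calls, _ = decode_record(rec)
            sites = set(cpg_sites(fwd)) if cpg_only else None
            for c in calls:
                if c.mod_code != "m" or c.mod_strand != "+":
                    continue
                if sites is not None and c.position not in sites:
                    continue
                if c.probability >= call_threshold:
                    n_5mc += 1
                else:
                    unmodified_c += 1

    n_calls = unmodified_c + n_5mc
    return SummaryStats(
        unique_reads=len(read_ids),
        mean_coverage=aligned_bases / ref_len,
        gc_pct=statistics.fmean(gc_pcts) if gc_pcts else math.nan,
        mean_gc_skew=statistics.fmean(gc_skews) if gc_skews else math.nan,
        mean_at_skew=statistics.fmean(at_skews) if at_skews else math.nan,
        mean_read_length=statistics.fmean(lengths) if lengths else math.nan,
        median_read_length=statistics.median(lengths) if lengths else math.nan,
        unmodified_c=unmodified_c,
        n_5mc=n_5mc,
        fraction_5mc=n_5mc / n_calls if n_calls else None,
        call_threshold=call_threshold,
    )


@dataclass
class MethylationHistogram:
    """Histogram of per-read methylation percentages.

    Bins are half-open ``[k·w, (k+1)·w)`` except the last, which is
    closed at 100%.  The 5% default binning is what makes the
    mtDNA/NuMT bimodality visible: unmethylated mitochondrial reads
    pile into the lowest bin while NuMT reads form a high-methylation
    mode.
    """

    bin_width: float
    counts: list[int]

    @property
    def n_reads(self) -> int:
        return int(sum(self.counts))

    @property
    def shares(self) -> list[float]:
        n = self.n_reads
        return [c / n if n else math.nan for c in self.counts]

    @property
    def bin_edges(self) -> list[float]:
        return [i * self.bin_width for i in range(len(self.counts) + 1)]

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["bin_start\tbin_end\tcount\tshare"]
        for i, c in enumerate(self.counts):
            share = self.shares[i]
            lines.append(
                f"{i * self.bin_width:g}\t{(i + 1) * self.bin_width:g}\t{c}\t"
                + ("NA" if math.isnan(share) else f"{share:.6g}")
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def plot(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.bar(self.bin_edges[:-1], self.counts, width=self.bin_width,
               align="edge", edgecolor="black", linewidth=0.4)
        ax.set_xlabel("per-read CpG methylation (%)")
        ax.set_ylabel("reads")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def methylation_histogram(
    profiles: Iterable[ReadMethylProfile] | Sequence[float],
    bin_width: float = 5.0,
) -> MethylationHistogram:
    """Bin per-read methylation fractions into percent bins.

    Accepts :class:`ReadMethylProfile` objects (reads without
    assessable CpGs are excluded) or bare fractions in [0, 1].
    """
    if 100.0 % bin_width != 0:
        raise ValueError(f"bin width {bin_width} does not divide 100")
    values = []
    for p in profiles:
        f = p.methylation_fraction if isinstance(p, ReadMethylProfile) else p
        if f is None or math.isnan(f):
            continue
        values.append(100.0 * f)
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return MethylationHistogram(bin_width=bin_width, counts=[int(c) for c in counts])
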