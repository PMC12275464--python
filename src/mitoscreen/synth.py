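"""Synthetic modBAM fixtures: a toy circular mitochondrial reference
plus aligned reads with valid MM/ML tags.

The generator states a simple world: a circular reference whose base
frequencies realize a target GC%, GC skew and AT skew (the human chrM
forward strand is strongly C-rich, skew ≈ −0.35); reads of two origins
sampled from that same reference — 'mito' reads essentially
unmethylated, 'numt' reads highly methylated — so that per-read CpG
methylation is bimodal.  NuMT-class reads deliberately reuse
mitochondrial-like sequence: sequence similarity is the confound, and
the discriminator uses methylation only.

Per-read site methylation is drawn from a Beta per class; each CpG
cytosine gets an 'm' call whose ML byte comes from a high band when the
site is methylated and a low band otherwise.  Wrap-around reads are
split into a primary plus a supplementary record sharing one read id.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pysam
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .modbam import ModCall, ModRun, encode_mod_tags
from .screen import cpg_sites

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "base_frequencies",
    "simulate_reference",
    "simulate_reads",
    "write_truth_tsv",
    "read_truth_tsv",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Parameters of the stated synthetic world.

    Composition defaults match the human mitochondrial forward strand
    (GC 44%, GC skew −0.35, AT skew 0.10).  ``numt_weight`` is the NuMT
    class share (0.30, giving ~70% of reads below the 15% split).  The
    low (mtDNA) methylation mode is Beta(1, 500), mean ≈ 0.002 —
    mitochondrial CpG methylation is background-level, a few permille —
    and the high (NuMT) mode Beta(6, 4), mean 0.6, like bulk nuclear
    chromatin.  Read lengths are log-normal (median 4 kb) truncated to
    [500, reference_length].  ML noise bands: methylated sites draw
    bytes from ``high_band``, unmethylated from ``low_band``; both
    bands sit on one side of the 0.5 call threshold (byte 128).
    """

    reference_length: int = 16_569
    reference_name: str = "synthetic_chrM"
    target_gc_percent: float = 44.0
    target_gc_skew: float = -0.35
    target_at_skew: float = 0.10
    n_reads: int = 1000
    numt_weight: float = 0.30
    low_mode: tuple[float, float] = (1.0, 500.0)
    high_mode: tuple[float, float] = (6.0, 4.0)
    read_length_log_mu: float = math.log(4000.0)
    read_length_log_sigma: float = 0.6
    min_read_length: int = 500
    high_band: tuple[int, int] = (200, 255)
    low_band: tuple[int, int] = (0, 55)
    hmc_probability: float = 0.0
    reverse_fraction: float = 0.5
    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class TruthRecord:
    """Ground truth for one simulated read."""

    read_id: str
    true_class: str  # 'mito' | 'numt'
    true_site_methylation: float
    n_cpg: int


def base_frequencies(config: SimulationConfig) -> dict[str, float]:
    """Solve G/C/A/T frequencies from GC%, GC skew and AT skew.

    gc_skew = (g−c)/(g+c) with g+c fixed by GC% gives
    g = GC·(1+skew)/2 and c = GC·(1−skew)/2; A/T likewise.
    """
    gc = config.target_gc_percent / 100.0
    if not 0.0 < gc < 1.0:
        raise ValueError(f"target GC% {config.target_gc_percent} outside (0, 100)")
    for name, s in (("GC skew", config.target_gc_skew),
                    ("AT skew", config.target_at_skew)):
        if not -1.0 < s < 1.0:
            raise ValueError(f"target {name} {s} outside (-1, 1)")
    at = 1.0 - gc
    freqs = {
        "G": gc * (1.0 + config.target_gc_skew) / 2.0,
        "C": gc * (1.0 - config.target_gc_skew) / 2.0,
        "A": at * (1.0 + config.target_at_skew) / 2.0,
        "T": at * (1.0 - config.target_at_skew) / 2.0,
    }
    for b, f in freqs.items():
        if f <= 0.0:  # cannot happen with the bounds above; keep the guard
            raise ValueError(f"infeasible composition: frequency of {b} = {f}")
    return freqs


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SeqRecord:
    """Sample a circular reference realizing the composition targets."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    freqs = base_frequencies(config)
    bases = np.array(list(freqs))
    seq = "".join(rng.choice(bases, size=config.reference_length, p=list(freqs.values())))
    return SeqRecord(
        Seq(seq),
        id=config.reference_name,
        description=f"synthetic circular mitochondrial-like reference "
        f"len={config.reference_length} gc={config.target_gc_percent} "
        f"gc_skew={config.target_gc_skew} at_skew={config.target_at_skew}",
    )


def _make_records(
    header: pysam.AlignmentHeader,
    read_id: str,
    stored_seq: str,
    start: int,
    first_len: int,
    reverse: bool,
    mm: str,
    ml: list[int],
) -> list[pysam.AlignedSegment]:
    """Build the primary (and, for wrap-around reads, supplementary)
    alignment records for one read; both carry the full SEQ and tags."""
    total = len(stored_seq)
    second_len = total - first_len
    parts = [(start, f"{first_len}M{second_len}S" if second_len else f"{total}M", False)]
    if second_len:
        parts.append((0, f"{first_len}S{second_len}M", True))
    records = []
    for pos, cigar, supplementary in parts:
        rec = pysam.AlignedSegment(header)
        rec.query_name = read_id
        rec.query_sequence = stored_seq
        rec.reference_id = 0
        rec.reference_start = pos
        rec.mapping_quality = 60
        rec.cigarstring = cigar
        rec.flag = (16 if reverse else 0) | (2048 if supplementary else 0)
        rec.set_tag("MM", mm, value_type="Z")
        if ml:
            from array import array

            rec.set_tag("ML", array("B", ml))
        records.append(rec)
    return records


def simulate_reads(
    reference: SeqRecord | str,
    config: SimulationConfig,
    bam_path: str | Path,
    truth_path: str | Path | None = None,
) -> list[TruthRecord]:
    """Simulate aligned modBAM reads and their ground-truth table.

    Reads wrap the circular reference; wrap-around reads are emitted as
    a primary plus a supplementary record sharing the read id (this
    exercises the supplementary-alignment labeling rule downstream).
    Deterministic for a fixed ``config.seed``.  The output BAM is
    coordinate-sorted and indexed.
    """
    ref_seq = str(reference.seq) if isinstance(reference, SeqRecord) else str(reference)
    ref_name = (
        reference.id if isinstance(reference, SeqRecord) else config.reference_name
    )
    ref_len = len(ref_seq)
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from the reference

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": ref_name, "LN": ref_len}],
            "PG": [{"ID": "mitoscreen-simulate", "PN": "mitoscreen"}],
        }
    )

    doubled = ref_seq + ref_seq  # circular substring extraction
    records: list[pysam.AlignedSegment] = []
    truth: list[TruthRecord] = []
    width = max(6, len(str(max(config.n_reads - 1, 0))))
    for i in range(config.n_reads):
        read_id = f"read{i:0{width}d}"
        is_numt = bool(rng.random() < config.numt_weight)
        alpha, beta = config.high_mode if is_numt else config.low_mode
        p_meth = float(rng.beta(alpha, beta))

        length = int(rng.lognormal(config.read_length_log_mu, config.read_length_log_sigma))
        length = min(max(length, config.min_read_length), ref_len)
        start = int(rng.integers(0, ref_len))
        stored_seq = doubled[start : start + length]  # aligned orientation
        reverse = bool(rng.random() < config.reverse_fraction)
        as_sequenced = _revcomp(stored_seq) if reverse else stored_seq

        sites = cpg_sites(as_sequenced)
        calls: list[ModCall] = []
        runs: list[ModRun] = [ModRun("C", "+", ("m",), "?")]
        lo, hi = config.low_band
        hlo, hhi = config.high_band
        for pos in sites:
            methylated = rng.random() < p_meth
            byte = int(rng.integers(hlo, hhi + 1)) if methylated else int(rng.integers(lo, hi + 1))
            calls.append(ModCall(pos, "C", "+", "m", (2 * byte + 1) / 512.0))
            if config.hmc_probability and rng.random() < config.hmc_probability:
                h_byte = int(rng.integers(lo, hi + 1))
                calls.append(ModCall(pos, "C", "+", "h", (2 * h_byte + 1) / 512.0))
        if config.hmc_probability:
            runs.append(ModRun("C", "+", ("h",), "?"))
        mm, ml = encode_mod_tags(calls, runs, as_sequenced)

        first_len = min(length, ref_len - start)
        records.extend(
            _make_records(header, read_id, stored_seq, start, first_len, reverse, mm, ml)
        )
        truth.append(TruthRecord(read_id, "numt" if is_numt else "mito", p_meth, len(sites)))

    records.sort(key=lambda r: (r.reference_start, r.query_name))
    bam_path = str(bam_path)
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.index(bam_path)

    if truth_path is not None:
        write_truth_tsv(truth, truth_path)
    return truth


def write_truth_tsv(truth: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttrue_class\ttrue_site_methylation\tn_cpg\n")
        for t in truth:
            fh.write(
                f"{t.read_id}\t{t.true_class}\t{t.true_site_methylation:.8g}\t{t.n_cpg}\n"
            )


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    truth = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            rid, cls, p, n = line.rstrip("\n").split("\t")
            truth.append(TruthRecord(rid, cls, float(p), int(n)))
    return truth
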