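# mitoscreen

Sort mitochondrial-aligned Oxford Nanopore reads into true mtDNA and
nuclear-mitochondrial-segment (NuMT) classes by per-read CpG methylation.

## The problem

Human mtDNA is a 16,569 bp circular genome that is essentially free of CpG
methylation, while NuMTs — mtDNA-derived sequences integrated into the
nuclear genome — are methylated like the rest of nuclear chromatin. Because
NuMTs are nearly identical in sequence to mtDNA, NuMT-derived reads
cross-map onto the mitochondrial reference and corrupt heteroplasmy
estimates and variant calls. Nanopore sequencing of native DNA calls 5mC
per molecule during basecalling, so methylation can separate the two read
origins where sequence identity cannot.

`mitoscreen` is for anyone analysing mitochondrial variants or methylation
from ONT whole-genome data: it takes an aligned, modified-base BAM
("modBAM", MM/ML tags from a 5mCG-aware basecaller) and partitions it into
an unmethylated, mtDNA-like BAM (`−m`) and a methylated, NuMT-like BAM
(`+m`).

## Method

For each read the MM tag's delta-encoded positions and the ML tag's
probability bytes are decoded into explicit 5mC calls (ML byte *b* maps to
the bin midpoint *(2b+1)/512*). The read's CpG methylation level is

```
fraction = n(CpG sites with P(5mC) ≥ 0.5) / n(assessed CpG sites)
```

where CpG context is the read's own CG dinucleotides. Reads with
`fraction < 0.15` go to `−m`; reads with `fraction ≥ 0.15` (the boundary
included) go to `+m`. The 15% threshold sits in the trough of the strongly
bimodal distribution of per-read methylation levels. Supporting modules
compute per-partition summaries (coverage, GC%, per-read GC skew
(G−C)/(G+C) and AT skew (A−T)/(A+T) — the mitochondrial forward strand has
a distinctive skew signature near −0.35 / +0.10), 5hmC stripping, read-set
overlap validation, and a fully synthetic modBAM generator so the whole
pipeline is testable without any sequencing data.

## Worked example

Simulate a 2,000-read mixture (70% unmethylated mtDNA-class, 30%
methylated NuMT-class) and split it:

```sh
mitoscreen simulate --out-dir demo --n-reads 2000 --seed 7
mitoscreen split demo/reads.bam --out-minus demo/minus.bam \
    --out-plus demo/plus.bam --report demo/profiles.tsv
```

prints the partition accounting:

```json
{
  "n_input": 2000,
  "n_minus": 1400,
  "n_plus": 600,
  "n_no_cpg": 0,
  "n_unmapped_excluded": 0,
  "n_secondary_dropped": 0,
  "split_threshold": 0.15,
  "call_threshold": 0.5
}
```

1,400 of 2,000 reads (70%) fall below 15% methylation, matching the
simulated class weights. `mitoscreen summary demo/minus.bam` then shows the
two partitions are cleanly separated:

```json
{
  "unique_reads": 1400,
  "mean_gc_skew": -0.35653961704026466,
  "mean_at_skew": 0.08093920841405416,
  "unmodified_c": 268058,
  "n_5mc": 550,
  "fraction_5mc": 0.002047593519180367
}
```

versus `fraction_5mc = 0.6055` for `demo/plus.bam` (full output has more
fields): the unmethylated partition's aggregate 5mC fraction is ~0.002 —
background level, two orders of magnitude below the methylated partition —
and its mean per-read GC skew (−0.357) matches the mitochondrial forward
strand. `mitoscreen overlap` and `mitoscreen screen` expose the validation
and per-read views; `--help` on any subcommand lists the knobs
(thresholds accept `0.15` or `15%`).

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch on the
default synthetic world: it simulates 10,000 reads, splits them at 15%,
summarizes both partitions, bins the per-read methylation histogram, and
measures the overlap between the methylated partition and the ground-truth
NuMT read set, logging the headline quantities to stderr.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
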