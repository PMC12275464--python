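# Methods

## Model

A read aligned to the mitochondrial reference is of one of two origins:
true mtDNA, which in humans carries essentially no CpG methylation, or a
nuclear mitochondrial segment (NuMT), which is methylated like bulk
nuclear chromatin. The per-read CpG methylation level is therefore a
near-separable discriminator: its distribution across a mitochondrial
alignment is bimodal, with an unmethylated mode at ~0–0.5% and a
methylated mode around 60%. The classifier is a single threshold on that
level; everything else in the package is decoding, accounting and
validation around it.

### Per-read methylation level

The modified-base calls live in the MM/ML tags (SAM modification-tag
encoding). MM positions are delta counts over occurrences of the stated
canonical base in the read **as sequenced**; for reverse-strand
alignments the stored SEQ is reverse-complemented before decoding and
positions are reported in as-sequenced coordinates. ML byte *b* encodes
the probability interval [b/256, (b+1)/256); calls carry the midpoint
(2b+1)/512, so byte → probability → byte round-trips exactly. A missing
ML tag is treated as probability 1.0 for every MM call, with a warning
(permitted by the tag specification). Both skip-mode dialects are
decoded: under explicit mode ('?') uncalled cytosines carry no
information; under implicit mode ('.' or no flag) uncalled CpG cytosines
are asserted unmodified and enter the denominator.

A site is called methylated when P(5mC) ≥ `call_threshold` (default
0.5). No per-site probability rule is forced by the data model, so the
threshold is configurable, and an optional two-sided confidence band
(ignore sites with, say, 0.33 < p < 0.67) is available but off by
default: with modern basecallers the probability mass is strongly
bimodal and the band changes little. CpG context is taken from the
read's own sequence, not the reference — the basecaller models call CG
context on the molecule, and no reference FASTA is then required.

The read's methylation level is `n_methylated / n_assessed` over
CpG-context 5mC calls. Calls at non-CpG cytosines (possible after
realignment or with non-CG models) are excluded and surfaced in a
diagnostics counter.

### Partitioning

Reads with level < `split_threshold` (default 0.15) go to the
unmethylated output, reads at or above it to the methylated output; the
boundary belongs to the methylated side ("equal to or exceeding").
Unmapped reads are excluded first; secondary alignments are dropped;
supplementary alignments inherit their primary's label so a split read
never straddles the partition. Reads with zero assessable CpGs default
to the unmethylated output (absence of methylation evidence matches the
unmethylated mtDNA class) with a separate count; routing is
configurable (`to_plus`, `separate_file`, `drop`).

### 5hmC stripping

5mCG/5hmCG basecall models emit both codes; only 5mC separates the
origins, so 'h' calls are removed first. Default policy `drop` discards
the 5hmC probability mass (implicitly reassigning it to canonical C);
`merge_into_m` instead folds it into the 5mC call at the same position,
capped at 511/512. The original pipeline's behaviour between these two
is not documented; both are provided and `drop` is the default. Under
`merge_into_m`, runs are re-emitted one code per run because 'h' and 'm'
call positions may differ in explicit mode, making a shared multi-code
delta list unreconstructible in general.

### Summary statistics and skews

Per-partition summaries report unique mapped reads, mean depth of
coverage (aligned reference bases ÷ reference length — matching the
magnitude conventions of standard per-partition tables, not breadth),
GC%, mean per-read GC skew (G−C)/(G+C) and AT skew (A−T)/(A+T), mean
and median read length (published tables are ambiguous about which;
both are reported), and pooled 5mC call counts: `unmodified_c` counts
assessed calls below the call threshold, `n_5mc` those at or above it,
`fraction_5mc = n_5mc / (unmodified_c + n_5mc)`. Skews are computed on
the aligned-orientation (stored) SEQ and averaged unweighted across
reads: forward- and reverse-aligned reads of the same strand origin
then agree, whereas averaging as-sequenced orientations would cancel
the strand signature toward zero; the mitochondrial forward strand's
mean read skew of ≈ −0.35 supports this orientation choice. Reads with
an undefined skew (no G+C, or no A+T) are excluded from that mean only.

The per-read methylation histogram uses 5-percentage-point bins,
half-open except the last ([95, 100]); the unmethylated pile-up in the
[0, 5) bin against the high-methylation mode is what justifies the 15%
threshold visually.

## Synthetic data generator

The generator states a small, explicit world:

- **Reference** — one circular contig, default 16,569 bp, with base
  frequencies solved from GC% = 44, GC skew = −0.35, AT skew = +0.10
  (`g = GC·(1+s)/2`, etc.), i.e. the composition of the human
  mitochondrial forward strand. Feasibility (|skew| < 1, 0 < GC% < 100)
  is checked and the violated bound reported.
- **Reads** — class `numt` with probability 0.30, else `mito`; start
  uniform on the circle; length log-normal (median 4 kb, σ = 0.6)
  truncated to [500, reference length]. Both classes draw sequence from
  the same reference: sequence similarity is precisely the confound,
  and the discriminator must use methylation only. Reads that wrap the
  origin are emitted as a primary plus a supplementary record sharing
  one read id, exercising the supplementary-labeling rule. Orientation
  is 50:50; reverse records store the reverse-complement with MM
  referring to the as-sequenced read.
- **Methylation** — each read draws a site-methylation probability p
  from Beta(1, 500) (mito, mean ≈ 0.002) or Beta(6, 4) (numt, mean
  0.6). Mitochondrial CpG methylation is background-level — published
  estimates run ~0.2–0.7% and unmethylated-partition aggregate 5mC
  fractions ~0.002 — which is why the low mode is permille-scale, not
  percent-scale; a percent-scale low mode could not reproduce an
  aggregate −m 5mC fraction below 0.01. Every CpG cytosine receives an
  'm' call; methylated sites draw ML bytes uniformly from [200, 255],
  unmethylated from [0, 55]. Both bands sit strictly on one side of the
  0.5 call threshold, so the per-site call equals the simulated state
  and a binomial oracle over (p, n_CpG) predicts read-level quantities
  exactly. Optional 'h' calls (off by default) exercise stripping.
- **Determinism** — one `numpy` generator seeded from the config; a
  fixed seed reproduces the BAM and truth table byte for byte.

What the generator does **not** emulate: sequencing errors (no
substitutions/indels), nuclear flanking sequence on NuMT reads,
alignment ambiguity, basecaller-dependent probability calibration, or
signal-level artefacts. A green end-to-end test therefore establishes
that decoding, accounting, thresholding and partition plumbing are
correct under the stated world — not that the 15% threshold is optimal
for any particular flow cell or basecaller.

## Numerical choices

- ML byte → probability uses bin midpoints; the inverse
  `round(256·p − 0.5)` recovers the original byte and re-bins merged
  probabilities (e.g. midpoint sums under `merge_into_m`).
- Thresholds compare with `<` / `≥` so the split boundary is stable and
  exactly representable comparisons (k/20 sweeps) behave predictably.
- Undefined quantities are explicit: methylation fraction is `None`
  with zero assessed sites, skews are NaN for degenerate composition,
  `fraction_5mc` is `None` with no calls; none silently become 0.
- Histogram bin width must divide 100; the last bin is closed so a
  fully methylated read is counted.

## Limitations

- Per-read decoding is pure Python; throughput is roughly 1–2k typical
  long reads per second per core — ample for mitochondrial alignments,
  not intended for whole-genome modBAMs.
- The overlap validator compares read-id sets only; it does not run the
  nuclear realignment that produces the orthogonal assignment.
- Multi-code runs are re-encoded faithfully only when every position in
  the run carries a byte for every code (the tag grammar's own
  requirement).
- No pileup (per-site across reads) methylation output; the unit of
  analysis is the read.
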