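# Methods

## Tumor model

A simulated patient consists of a diploid **control genome** — a maternal
and a paternal haplotype, each built by implanting that lineage's germline
variants into the reference — and a pool of **haploid cancer genomes**:
`n_per_lineage` copies per lineage (default 5, i.e. ten cancer genomes),
each carrying its lineage's full germline complement plus an independent
random subset of the somatic SNVs (each variant enters each cancer genome
with `inclusion_prob`, default 0.5; a variant drawn into no genome is
re-drawn, so membership counts follow a zero-truncated binomial).

This is deliberately not a phylogenetic clone tree. The maternal and
paternal pools are mixed independently: a sequenced fragment picks a
lineage with probability ½ and then a genome within the lineage according
to that lineage's mixture weights, one flat Dirichlet(1) simplex per
lineage. Dirichlet(1) is the uninformative choice for "randomized
proportions"; any simplex law could be substituted. Under this model every
variant has a closed-form expected allele frequency in the pure tumor,

    AF_tumor = 1/2 * sum_{i in maternal carriers} w^M_i
             + 1/2 * sum_{j in paternal carriers} w^P_j,

and germline variants (carried by every cancer genome of their control
lineage) have AF_tumor equal to their control AF (0.5 het, 1.0 hom).

**Admixture** dilutes the tumor with a fraction `a` of control material,
strictly linearly:

    AF(a) = (1 - a) * AF_tumor + a * AF_control.

Somatic variants (AF_control = 0) therefore decay linearly to zero —
a clonal 30% variant reads at 3% when a = 0.9 — while germline AFs are
invariant under admixture. The default study design is ten tumor samples at
a = 0.0, 0.1, …, 0.9 plus one pure control. `a` is capped at 0.95 to keep
somatic alleles observable. A separate two-genome mixer supports the
reference-material design in which two diploid genotype sets are combined
at a fixed ratio r, giving discrete AFs at multiples of r/2 and (1−r)/2.

## Genome forging and coordinates

Variants use VCF-style 1-based positions; intervals are BED-style 0-based
half-open, with conversions localized in the I/O layer. Insertions anchor
AFTER their position; deletions start AT it. Overlapping edits are rejected
outright (rejection keeps the truth unambiguous), reference-allele
mismatches are fatal with contig/position detail, and no variant may sit on
an `N`. Each haplotype carries a coordinate map (sorted insertion anchors
and deletion spans with cumulative offsets) providing O(log k) lifts of
positions and intervals into haplotype space; interval lifts include
sequence inserted strictly inside the interval, and a fully deleted
interval lifts to an empty one. A per-base source array (haplotype index →
reference index or −1 for inserted bases) supports read simulation and
truth-CIGAR construction.

## Synthetic fixtures

The fixture generator emulates the real inputs at desk scale: uniform
random contigs at configurable GC (default 0.45), capture targets placed in
evenly spaced slots with random offsets, germline SNVs and 1–6 bp indels
placed uniformly in targets padded by 200 bp (near-target confounders),
and somatic SNVs strictly inside targets so the somatic truth is fully
evaluable. Variants keep a 12 bp minimum spacing, which guarantees
non-overlap for the largest indel. Germline zygosity uses a het:hom ratio
(default 2:1, the typical ratio in human exomes); heterozygous variants are
assigned to one lineage by a fair coin, since real phasing information has
no bearing on the framework's statistics. A hypermutation multiplier
scales the in-target somatic count for small panel designs, where an
unmodified somatic load would leave false-negative rates statistically
unreliable.

What the generator does *not* emulate: real genomic sequence composition
(repeats, segmental duplications, homopolymers), mutation signatures, GC
coverage bias, mapping ambiguity, copy-number variation. Passing tests
therefore demonstrate the correctness of the simulation/evaluation
machinery and the statistical behavior of callers under dilution — not
caller performance on real, alignable human data.

## Read simulation

Fragments are drawn directly from target intervals; probe hybridization is
not modeled — this preserves the coverage and AF structure the analyses
depend on while avoiding an alignment-based capture step. Per fragment:
source genome (control with probability `a`, else lineage ½/½ then mixture
weight), target interval with probability proportional to its length,
length ~ Normal(insert_mean, insert_sd) truncated to ≥ read_length, start
uniform among placements overlapping the (coordinate-lifted) target by at
least one base. Both ends are read inward `read_length` bases; the
reverse-strand mate is reverse-complemented in FASTQ.

Presets: exome — 100 bp reads, 300 ± 100 bp inserts, 70× median target
coverage; panel — 200 ± 50 bp inserts, 520×. The planned fragment count is
`N = coverage × target_bases / (2 × read_length)`; realized median
on-target coverage is within ±10% of the configured value when targets are
long relative to the insert (fragment ends spill past target edges, so very
short targets run below nominal — the test fixtures use 8–10 kb targets).

Sequencing errors are injected during a per-base template walk: one
uniform draw per template step selects deletion (`del_rate`), insertion
(`ins_rate`), substituted copy (`sub_rate`) or clean copy. Defaults are
sub 1e−3, ins 1e−4, del 1e−4 — the error classes are standard for
Illumina-like data, the specific rates are configurable placeholders.
Base qualities follow a linear decay from Q37 at cycle 0 to Q30 at the last
cycle and are cosmetic: the baseline caller uses counts only. Read names
encode `<run_id>:<fragment>` with `:1`/`:2` mate suffixes.

Because every haplotype maps back to the reference, the simulator emits
**truth alignments**: each read at its known reference coordinate with a
CIGAR composed from the implanted indels it spans plus its injected read
errors (unaligned read bases become I in the interior, soft-clips at the
edges; reference gaps become D). Mate flags, PNEXT and TLEN are consistent
and the SAM is coordinate-sorted; the rare pair with a read entirely inside
inserted sequence is dropped from the SAM (counted) but kept in FASTQ.
All randomness comes from one generator seeded by the run configuration,
so identical seeds give byte-identical FASTQ/SAM.

## Baseline caller

A minimal pileup caller closes the loop without external tools: per-site
A/C/G/T counts from the alignments (M-ops only), then thresholds on depth,
alt count and alt fraction, and a one-sided binomial tail test
P(X ≥ alt | depth, max_error_rate) < p_cutoff. One ALT per site — the
highest-count non-reference allele, ties broken alphabetically. Defaults:
min_depth 10, min_alt_count 3, min_alt_fraction 0.05, error rate 1e−3,
p_cutoff 1e−4. It is a generic member of the count-test family and
intentionally not a re-implementation of any published caller; base
qualities are ignored by design.

## Evaluation

Evaluation is restricted to SNV truth records and to the capture targets.
The default match criterion is position **and** allele; position-only
matching is available (the looser, historical criterion). Multi-allelic
call records are split per ALT before matching; duplicate calls match a
truth record once; TP + FN always equals the evaluated truth size. When
scoring somatic-only callsets, calls that match a germline truth SNV are
ignored rather than counted as false positives — otherwise abundant
germline calls would mask somatic precision.

Percentages are formatted with round-half-up at one decimal by default.
Precision with zero calls is reported `NA`, not 0, to avoid rewarding
silent callers. Parameter selection maximizes the harmonic mean
2sp/(s+p) per tool × admixture group; ties break toward higher
sensitivity, then lexicographically smaller parameter label, so selection
is deterministic. Concordance tables count, for every position in the
union of two or more callsets, how many callers support it, split by
truth-matched vs unmatched.

## Reproducibility and numerics

Every stochastic stage derives its seed from one master seed through a
named substream (`sha256(master/label)` truncated to 31 bits), so stages
can be re-run independently and whole runs reproduce byte-identically; the
manifest records the config hash and every derived seed. Mixture weight
sums are validated to 1e−9 and a variant carried by all genomes has its
summed AF clamped at 1.0 against float round-up. Truth AF histogram bins
are left-open right-closed on (0, 1] so AF = 1 falls in the last bin. Truth
VCF `TAF` values are stored as VCF floats (32-bit), exact to ~1e−7.

## Problem sizes in the test suite

The test and acceptance suites run the full machinery at reduced scale as
the package's own design point: 20–70 kb references, 16–50 kb capture
footprints, 60–150 germline and 20–80 somatic variants, coverages of
40–520×, and six master seeds for the admixture-decline experiment. These
sizes keep every statistical check (binomial standard-error bands,
±10% coverage calibration, monotone sensitivity decline) well-powered
while completing in minutes on one CPU.

## Known limitations

- No copy-number events, structural variants, or multi-nucleotide
  substitutions; no phylogenetic clone structure; no tumor-in-normal
  contamination of the control.
- No probe-hybridization, GC or strand bias in read simulation; no
  duplicate fragments; quality strings carry no information.
- The baseline caller is single-sample and SNV-only; paired tumor–normal
  joint modeling and indel calling are out of scope (the evaluator scores
  any external caller's VCF, but does not run external callers).
- Germline evaluation treats phasing as irrelevant; het variants are
  assigned to a lineage at random.
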