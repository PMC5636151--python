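"""Targeted paired-end read simulation from admixed tumor samples.

Fragments are drawn directly from capture target intervals (probe
hybridization is not modeled): a fragment picks its source genome (control
with probability equal to the sample's admixture fraction, otherwise a
cancer genome via lineage and mixture weights), a target interval with
probability proportional to its length, a length from a truncated normal
insert-size law, and a uniform placement overlapping the target in lifted
haplotype coordinates.  Both ends are read inward ``read_length`` bases with
substitution/insertion/deletion sequencing errors at configured rates.

Because every haplotype carries a coordinate map back to the reference, the
simulator can also emit truth alignments: each read placed at its known
reference coordinate with a CIGAR composed from the implanted indels it
spans and the injected read errors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .mixing import AdmixedSample, LINEAGES
from .variants import HaplotypeGenome, reverse_complement

__all__ = [
    "TargetRegions",
    "ReadSimConfig",
    "GenomeSet",
    "SimRun",
    "exome_config",
    "panel_config",
    "plan_fragment_count",
    "simulate_reads",
]


@dataclass(frozen=True)
class TargetRegions:
    """Merged, contig-sorted capture intervals (0-based half-open)."""

    intervals: tuple[tuple[str, int, int], ...]

    @classmethod
    def from_intervals(cls, intervals: Sequence[tuple[str, int, int]]) -> "TargetRegions":
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in intervals:
            if start < 0 or end <= start:
                raise ValueError(f"invalid interval {contig}:{start}-{end}")
            by_contig.setdefault(contig, []).append((start, end))
        merged: list[tuple[str, int, int]] = []
        for contig in sorted(by_contig):
            spans = sorted(by_contig[contig])
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((contig, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((contig, cur_s, cur_e))
        return cls(intervals=tuple(merged))

    @classmethod
    def from_bed(cls, path: str | Path) -> "TargetRegions":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls.from_intervals(intervals)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig, start, end in self.intervals:
                fh.write(f"{contig}\t{start}\t{end}\n")

    @property
    def total_bases(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def contains(self, contig: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        i = pos - 1
        for c, s, e in self.intervals:  # interval counts stay small in practice
            if c == contig and s <= i < e:
                return True
        return False

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass(frozen=True)
class ReadSimConfig:
    """Sequencing-run parameters.

    The exome preset reads 100 bp ends off ~300 bp (s.d. 100) fragments at
    70x median target coverage; the panel preset uses 200 bp (s.d. 50)
    fragments at 520x.  Error rates are per-base probabilities; base
    qualities follow a linear decay from ``qual_start`` at read position 0
    to ``qual_end`` at the last cycle and carry no information beyond that.
    """

    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 100.0
    target_median_coverage: float = 70.0
    sub_rate: float = 1e-3
    ins_rate: float = 1e-4
    del_rate: float = 1e-4
    qual_start: int = 37
    qual_end: int = 30
    seed: int = 0
    run_id: str = "sim"
    write_truth_sam: bool = True

    def __post_init__(self) -> None:
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must be >= read_length")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.1:
                raise ValueError(f"{name} must lie in [0, 0.1], got {rate}")
        if self.target_median_coverage <= 0:
            raise ValueError("target_median_coverage must be positive")

    def quality_string(self) -> str:
        n = self.read_length
        if n == 1:
            quals = [self.qual_start]
        else:
            quals = [
                int(round(self.qual_start + (self.qual_end - self.qual_start) * i / (n - 1)))
                for i in range(n)
            ]
        return "".join(chr(q + 33) for q in quals)


def exome_config(**overrides) -> ReadSimConfig:
    return replace(ReadSimConfig(), **overrides)


def panel_config(**overrides) -> ReadSimConfig:
    base = ReadSimConfig(
        insert_mean=200.0, insert_sd=50.0, target_median_coverage=520.0
    )
    return replace(base, **overrides)


@dataclass
class GenomeSet:
    """All source genomes of one simulated patient.

    ``control`` maps lineage -> control haplotype; ``tumor`` maps
    ``(lineage, index)`` -> cancer genome.  All genomes must share the
    reference contig set.
    """

    control: dict[str, HaplotypeGenome]
    tumor: dict[tuple[str, int], HaplotypeGenome]

    def __post_init__(self) -> None:
        contig_sets = {frozenset(g.coord_map.ref_lengths) for g in self.all_genomes().values()}
        if len(contig_sets) > 1:
            raise ValueError("all genomes must share the same reference contig set")

    def all_genomes(self) -> dict[tuple, HaplotypeGenome]:
        out: dict[tuple, HaplotypeGenome] = {}
        for lin in LINEAGES:
            if lin in self.control:
                out[("control", lin)] = self.control[lin]
        for key in sorted(self.tumor):
            out[("tumor",) + key] = self.tumor[key]
        return out

    @property
    def n_per_lineage(self) -> int:
        return max((i + 1 for _, i in self.tumor), default=0)


@dataclass
class SimRun:
    """Paths and bookkeeping for one simulated sample."""

    sample_label: str
    fastq1: Path
    fastq2: Path
    truth_sam: Path | None
    n_fragments: int
    n_skipped: int
    n_unmapped_pairs: int


def plan_fragment_count(cfg: ReadSimConfig, targets: TargetRegions) -> int:
    """Fragments needed for the configured median on-target coverage.

    ``N = coverage * target_bases / (2 * read_length)``; each fragment
    contributes two reads, almost entirely on target when targets are long
    relative to the insert size.
    """
    total = targets.total_bases
    if total <= 0:
        raise ValueError("target regions are empty")
    return int(round(cfg.target_median_coverage * total / (2 * cfg.read_length)))


_OTHER_BASES = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
_ALPHABET = "ACGT"


def _walk_read(
    seq: str,
    refpos: np.ndarray,
    start: int,
    read_length: int,
    rng: np.random.Generator,
    del_rate: float,
    ins_rate: float,
    sub_rate: float,
    u: np.ndarray,
) -> tuple[str, list[int]]:
    """Read ``read_length`` bases forward from ``start`` with error injection.

    One uniform draw decides each template step (deletion / insertion /
    substituted copy / clean copy); ``u`` supplies the first draws so the
    error-free fast path in the caller consumes the identical stream.
    Returns the forward-strand read sequence and its per-base reference
    source (0-based position, or -1 for inserted or padded bases).
    """
    d, di, dis = del_rate, del_rate + ins_rate, del_rate + ins_rate + sub_rate
    n = len(seq)
    bases: list[str] = []
    rp: list[int] = []
    t = start
    k = 0
    while len(bases) < read_length:
        if t >= n:
            bases.append(_ALPHABET[rng.integers(4)])
            rp.append(-1)
            continue
        uu = u[k] if k < len(u) else rng.random()
        k += 1
        if uu < d:
            t += 1
            continue
        if uu < di:
            bases.append(_ALPHABET[rng.integers(4)])
            rp.append(-1)
            continue
        b = seq[t]
        if uu < dis:
            b = _OTHER_BASES.get(b, _ALPHABET)[rng.integers(3)]
        bases.append(b)
        rp.append(int(refpos[t]))
        t += 1
    return "".join(bases), rp


def _cigar_from_refpos(rp: Sequence[int]) -> tuple[int, str, int] | None:
    """Build (1-based ref pos, CIGAR, ref span) from per-base sources.

    Unaligned read bases become I in the interior and S at the edges; gaps
    between consecutive reference sources become D.  Returns ``None`` when
    no read base maps to the reference.
    """
    items: list[list] = []  # [op, length]
    prev_q: int | None = None
    first_q: int | None = None
    for q in rp:
        if q < 0:
            op = "I"
        else:
            if prev_q is not None and q > prev_q + 1:
                items.append(["D", q - prev_q - 1])
            op = "M"
            prev_q = q
            if first_q is None:
                first_q = q
        if items and items[-1][0] == op:
            items[-1][1] += 1
        else:
            items.append([op, 1])
    if first_q is None:
        return None
    if items[0][0] == "I":
        items[0][0] = "S"
    if items[-1][0] == "I":
        items[-1][0] = "S"
    cigar = "".join(f"{ln}{op}" for op, ln in items)
    ref_span = prev_q - first_q + 1
    return first_q + 1, cigar, ref_span


def simulate_reads(
    genomes: GenomeSet,
    targets: TargetRegions,
    cfg: ReadSimConfig,
    sample: AdmixedSample | None,
    out_prefix: str | Path,
) -> SimRun:
    """Simulate one sample's paired reads (and truth alignments).

    ``sample=None`` simulates the pure control data set (every fragment
    drawn from the two control haplotypes).  Output is deterministic for a
    fixed configuration: identical seeds yield byte-identical FASTQ.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    rl = cfg.read_length

    # --- source-genome categorical over (control haplotypes + cancer genomes)
    keys = list(genomes.all_genomes().keys())
    genome_list = list(genomes.all_genomes().values())
    probs = np.zeros(len(keys))
    a = 1.0 if sample is None else sample.admixture
    for idx, key in enumerate(keys):
        if key[0] == "control":
            probs[idx] = a / 2.0
        else:
            if sample is None:
                continue
            _, lineage, gi = key
            probs[idx] = (1.0 - a) / 2.0 * sample.mixture.weight(lineage, gi)
    if probs.sum() <= 0:
        raise ValueError("no genome has positive sampling probability")
    probs /= probs.sum()

    # --- per-genome caches: sequence, source arrays, lifted targets
    contigs = sorted(genome_list[0].coord_map.ref_lengths)
    contig_index = {c: i for i, c in enumerate(contigs)}
    seqs: list[dict[str, str]] = []
    refpos_arrays: list[dict[str, np.ndarray]] = []
    lifted: list[list[tuple[str, int, int]]] = []
    for g in genome_list:
        seqs.append(g.sequences)
        refpos_arrays.append({c: g.coord_map.ref_position_array(c) for c in contigs})
        lifts = []
        for contig, s, e in targets:
            hs, he = g.coord_map.lift_interval(contig, s, e)
            if he <= hs:  # target erased in this genome; keep a 1-base anchor
                he = hs + 1
            lifts.append((contig, hs, he))
        lifted.append(lifts)

    n_fragments = plan_fragment_count(cfg, targets)
    target_lengths = np.array([e - s for _, s, e in targets], dtype=float)
    target_probs = target_lengths / target_lengths.sum()

    genome_draw = rng.choice(len(keys), size=n_fragments, p=probs)
    target_draw = rng.choice(len(targets), size=n_fragments, p=target_probs)
    frag_lengths = np.maximum(
        rl, np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_fragments)).astype(np.int64)
    )
    placement_u = rng.random(n_fragments)
    orientation = rng.integers(0, 2, size=n_fragments)

    qual_fwd = cfg.quality_string()
    qual_rev = qual_fwd[::-1]
    p_event = cfg.sub_rate + cfg.ins_rate + cfg.del_rate

    sam_records: list[tuple[int, int, str]] = []
    n_skipped = 0
    n_unmapped_pairs = 0

    fq1 = open(out_prefix.with_name(out_prefix.name + "_R1.fastq"), "w")
    fq2 = open(out_prefix.with_name(out_prefix.name + "_R2.fastq"), "w")
    try:
        for f in range(n_fragments):
            gi = int(genome_draw[f])
            ti = int(target_draw[f])
            flen = int(frag_lengths[f])
            contig, hs, he = lifted[gi][ti]
            seq = seqs[gi][contig]
            hap_len = len(seq)
            if hap_len < flen:
                n_skipped += 1
                continue
            low = hs - flen + 1
            high = he - 1
            start = low + int(placement_u[f] * (high - low + 1))
            start = max(0, min(start, hap_len - flen))
            end = start + flen
            refpos = refpos_arrays[gi][contig]

            reads = []  # (seq, rp) for left (forward) and right (reverse) read
            for rstart in (start, end - rl):
                u = rng.random(rl)
                if p_event == 0.0 or not (u < p_event).any():
                    rseq = seq[rstart : rstart + rl]
                    rp = refpos[rstart : rstart + rl].tolist()
                else:
                    rseq, rp = _walk_read(
                        seq, refpos, rstart, rl, rng,
                        cfg.del_rate, cfg.ins_rate, cfg.sub_rate, u,
                    )
                reads.append((rseq, rp))

            (left_seq, left_rp), (right_seq, right_rp) = reads
            qname = f"{cfg.run_id}:{f}"
            # read1/read2 assignment alternates with fragment orientation
            if orientation[f] == 0:
                r1_seq, r2_seq = left_seq, reverse_complement(right_seq)
            else:
                r1_seq, r2_seq = reverse_complement(right_seq), left_seq
            fq1.write(f"@{qname}:1\n{r1_seq}\n+\n{qual_fwd}\n")
            fq2.write(f"@{qname}:2\n{r2_seq}\n+\n{qual_fwd}\n")

            if cfg.write_truth_sam:
                left_aln = _cigar_from_refpos(left_rp)
                right_aln = _cigar_from_refpos(right_rp)
                if left_aln is None or right_aln is None:
                    n_unmapped_pairs += 1
                    continue
                lpos, lcigar, lspan = left_aln
                rpos, rcigar, rspan = right_aln
                tlen = (rpos + rspan - 1) - lpos + 1
                first_is_left = orientation[f] == 0
                # forward (left) read: mate-reverse set; reverse (right) read: reverse set
                lflag = 0x1 | 0x2 | 0x20 | (0x40 if first_is_left else 0x80)
                rflag = 0x1 | 0x2 | 0x10 | (0x80 if first_is_left else 0x40)
                sam_records.append(
                    (
                        contig_index[contig],
                        lpos,
                        f"{qname}\t{lflag}\t{contig}\t{lpos}\t60\t{lcigar}\t=\t{rpos}\t{tlen}\t{left_seq}\t{qual_fwd}",
                    )
                )
                sam_records.append(
                    (
                        contig_index[contig],
                        rpos,
                        f"{qname}\t{rflag}\t{contig}\t{rpos}\t60\t{rcigar}\t=\t{lpos}\t{-tlen}\t{right_seq}\t{qual_rev}",
                    )
                )
    finally:
        fq1.close()
        fq2.close()

    truth_sam: Path | None = None
    if cfg.write_truth_sam:
        truth_sam = out_prefix.with_name(out_prefix.name + "_truth.sam")
        ref_lengths = genome_list[0].coord_map.ref_lengths
        sam_records.sort(key=lambda r: (r[0], r[1]))
        with open(truth_sam, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            for c in contigs:
                fh.write(f"@SQ\tSN:{c}\tLN:{ref_lengths[c]}\n")
            fh.write("@PG\tID:tumorbench\tPN:tumorbench\n")
            for _, _, line in sam_records:
                fh.write(line + "\n")

    label = sample.label if sample is not None else "control"
    return SimRun(
        sample_label=label,
        fastq1=out_prefix.with_name(out_prefix.name + "_R1.fastq"),
        fastq2=out_prefix.with_name(out_prefix.name + "_R2.fastq"),
        truth_sam=truth_sam,
        n_fragments=n_fragments,
        n_skipped=n_skipped,
        n_unmapped_pairs=n_unmapped_pairs,
    )
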