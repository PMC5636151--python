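"""Minimal pileup-based SNV caller over truth alignments.

A deliberately simple caller so the simulation -> calling -> evaluation loop
runs end-to-end with no external tools: it counts aligned bases per site,
applies depth / alt-count / alt-fraction thresholds and a one-sided binomial
test of the alt count against a background per-base error rate.  It is a
generic member of the count-test caller family, not a re-implementation of
any published tool, and it ignores base qualities (counts only).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam
from scipy import stats

from .variants import read_fasta

__all__ = [
    "CallerParams",
    "Call",
    "PileupColumn",
    "pileup_counts",
    "call_snvs",
    "sweep_params",
    "write_callset_vcf",
    "read_callset_vcf",
]

_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_CODE_BASE = "ACGT"


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the baseline caller.

    ``max_error_rate`` is the assumed per-base background error rate for the
    binomial alt-count test; ``None`` disables the test.  The binomial tail
    ``P(X >= alt_count | depth, max_error_rate)`` must fall below
    ``p_cutoff`` for a site to be emitted.
    """

    min_depth: int = 10
    min_alt_count: int = 3
    min_alt_fraction: float = 0.05
    max_error_rate: float | None = 1e-3
    p_cutoff: float = 1e-4
    label: str = "default"

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_alt_count < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.min_alt_fraction <= 1.0:
            raise ValueError("min_alt_fraction must lie in [0, 1]")
        if self.max_error_rate is not None and not 0.0 <= self.max_error_rate <= 1.0:
            raise ValueError("max_error_rate must lie in [0, 1]")

    @classmethod
    def permissive(cls) -> "CallerParams":
        return cls(
            min_depth=1, min_alt_count=1, min_alt_fraction=0.0,
            max_error_rate=None, p_cutoff=1.0, label="permissive",
        )


@dataclass(frozen=True)
class Call:
    """One emitted SNV call."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    af: float
    depth: int
    p_value: float | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PileupColumn:
    contig: str
    pos: int  # 1-based
    depth: int
    counts: tuple[int, int, int, int]  # A, C, G, T

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts) or sum(self.counts) > self.depth:
            raise ValueError("allele counts must be non-negative and sum to at most depth")


def pileup_counts(alignments: str | Path) -> dict[str, np.ndarray]:
    """Count aligned A/C/G/T per reference position from a SAM/BAM file.

    Returns contig -> (4, contig_length) matrix of base counts at aligned
    (M) positions; insertions, deletions and clipped bases do not count.
    """
    counts: dict[str, np.ndarray] = {}
    with pysam.AlignmentFile(str(alignments), "r", check_sq=True) as sam:
        for contig, length in zip(sam.references, sam.lengths):
            counts[contig] = np.zeros((4, length), dtype=np.int32)
        for read in sam:
            if read.is_unmapped or read.cigartuples is None:
                continue
            mat = counts[read.reference_name]
            seq = read.query_sequence
            codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            read_i = 0
            ref_i = read.reference_start  # 0-based
            for op, ln in read.cigartuples:
                if op in (0, 7, 8):  # M, =, X
                    block = codes[read_i : read_i + ln]
                    valid = block < 4
                    np.add.at(
                        mat,
                        (block[valid], np.arange(ref_i, ref_i + ln)[valid]),
                        1,
                    )
                    read_i += ln
                    ref_i += ln
                elif op in (1, 4):  # I, S consume the read
                    read_i += ln
                elif op in (2, 3):  # D, N consume the reference
                    ref_i += ln
    return counts


def call_snvs(
    alignments: str | Path,
    reference: Mapping[str, str] | str | Path,
    params: CallerParams = CallerParams(),
) -> list[Call]:
    """Call SNVs from coordinate-sorted alignments.

    At each site with depth >= ``min_depth`` the non-reference allele with
    the highest count (ties broken alphabetically) is tested against the
    alt-count, alt-fraction and binomial-tail thresholds; one ALT per site.
    """
    if not isinstance(reference, Mapping):
        reference = read_fasta(reference)
    counts = pileup_counts(alignments)
    return _call_from_counts(counts, reference, params)


def _call_from_counts(
    counts: dict[str, np.ndarray],
    reference: Mapping[str, str],
    params: CallerParams,
) -> list[Call]:
    for contig in counts:
        if contig not in reference:
            raise ValueError(f"alignment contig {contig!r} absent from the reference")
        if counts[contig].shape[1] != len(reference[contig]):
            raise ValueError(
                f"contig {contig!r} length mismatch between alignments and reference"
            )

    calls: list[Call] = []
    for contig in sorted(counts):
        mat = counts[contig]
        depth = mat.sum(axis=0)
        candidate = np.nonzero(depth >= max(params.min_depth, 1))[0]
        if candidate.size == 0:
            continue
        ref_codes = _BASE_CODE[
            np.frombuffer(reference[contig].encode(), dtype=np.uint8)
        ][candidate]
        sub = mat[:, candidate].astype(np.int64)
        # mask the reference allele; argmax over A<C<G<T gives alphabetic ties
        sub_masked = sub.copy()
        valid_ref = ref_codes < 4
        sub_masked[ref_codes[valid_ref], np.nonzero(valid_ref)[0]] = -1
        alt_codes = sub_masked.argmax(axis=0)
        alt_counts = sub_masked.max(axis=0)
        site_depth = depth[candidate]
        keep = valid_ref & (alt_counts >= max(params.min_alt_count, 1))
        frac = np.zeros_like(alt_counts, dtype=float)
        nz = site_depth > 0
        frac[nz] = alt_counts[nz] / site_depth[nz]
        keep &= frac >= params.min_alt_fraction
        if params.max_error_rate is not None:
            pvals = stats.binom.sf(alt_counts - 1, site_depth, params.max_error_rate)
            keep &= pvals < params.p_cutoff
        else:
            pvals = np.full(alt_counts.shape, np.nan)
        for j in np.nonzero(keep)[0]:
            i = int(candidate[j])
            calls.append(
                Call(
                    contig=contig,
                    pos=i + 1,
                    ref=_CODE_BASE[int(ref_codes[j])],
                    alt=_CODE_BASE[int(alt_codes[j])],
                    af=float(frac[j]),
                    depth=int(site_depth[j]),
                    p_value=None if np.isnan(pvals[j]) else float(pvals[j]),
                )
            )
    return calls


def sweep_params(
    alignments: str | Path,
    reference: Mapping[str, str] | str | Path,
    grid: Sequence[CallerParams],
) -> list[tuple[CallerParams, list[Call]]]:
    """Run the caller once per parameter set; the pileup is computed once."""
    if not grid:
        raise ValueError("parameter grid is empty")
    if not isinstance(reference, Mapping):
        reference = read_fasta(reference)
    counts = pileup_counts(alignments)
    return [(params, _call_from_counts(counts, reference, params)) for params in grid]


def write_callset_vcf(
    calls: Sequence[Call],
    path: str | Path,
    contig_lengths: Mapping[str, int],
) -> None:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Observed alt allele fraction">')
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##INFO=<ID=P,Number=1,Type=Float,Description="Binomial tail p-value">')
    for contig, length in contig_lengths.items():
        header.add_line(f"##contig=<ID={contig},length={length}>")
    ordered = sorted(calls, key=lambda c: (c.contig, c.pos, c.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in ordered:
            rec = out.new_record(
                contig=c.contig, start=c.pos - 1, stop=c.pos,
                alleles=(c.ref, c.alt),
            )
            rec.info["AF"] = (c.af,)
            rec.info["DP"] = c.depth
            if c.p_value is not None:
                rec.info["P"] = c.p_value
            out.write(rec)


def read_callset_vcf(path: str | Path) -> list[Call]:
    """Read any SNV callset VCF; multi-allelic records are split per ALT."""
    calls: list[Call] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            raw_af = rec.info.get("AF", 0.0)
            if isinstance(raw_af, tuple):
                raw_af = raw_af[0] if raw_af else 0.0
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                    continue  # SNV evaluation only
                calls.append(
                    Call(
                        contig=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        af=float(raw_af or 0.0),
                        depth=int(rec.info.get("DP", 0) or 0),
                        p_value=float(rec.info["P"]) if "P" in rec.info else None,
                    )
                )
    return calls
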