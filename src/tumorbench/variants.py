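"""Personal-genome construction: implanting variants into a reference.

A haploid "personal" genome is built by applying a sorted, non-overlapping
list of SNVs, insertions and deletions to a reference sequence.  Because
indels shift coordinates, every haplotype carries a :class:`CoordinateMap`
that lifts reference positions (and intervals) into haplotype space; the
read simulator and the truth-alignment writer both depend on it.

Coordinate conventions
----------------------
Variants use VCF-style 1-based positions; intervals are BED-style 0-based
half-open.  Insertions are anchored AFTER ``pos`` (to the right of the
anchor base); a deletion removes ``ref_allele`` starting AT ``pos``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

__all__ = [
    "VariantClass",
    "Origin",
    "Variant",
    "CoordinateMap",
    "HaplotypeGenome",
    "implant_variants",
    "lift_to_haplotype",
    "lift_interval_to_haplotype",
    "read_fasta",
    "write_fasta",
    "read_variants_vcf",
    "read_variants_tsv",
    "write_variants_tsv",
]

_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class VariantClass(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"


class Origin(str, Enum):
    GERMLINE = "germline"
    SOMATIC = "somatic"


class ImplantError(ValueError):
    """Raised for reference mismatches, overlapping edits or malformed variants."""


@dataclass(frozen=True)
class Variant:
    """One reference-anchored edit.

    ``pos`` is the 1-based reference position of the affected base; for an
    insertion it is the base after which ``alt_allele`` is inserted.  An SNV
    has single, distinct ref/alt bases; an insertion has an empty
    ``ref_allele``; a deletion has an empty ``alt_allele``.
    """

    id: str
    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    vclass: VariantClass
    origin: Origin

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ImplantError(f"{self.id}: position must be >= 1, got {self.pos}")
        for allele, name in ((self.ref_allele, "ref"), (self.alt_allele, "alt")):
            if not set(allele) <= _BASES:
                raise ImplantError(f"{self.id}: {name} allele {allele!r} has non-ACGT characters")
        if self.vclass is VariantClass.SNV:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ImplantError(f"{self.id}: SNV alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ImplantError(f"{self.id}: SNV ref and alt alleles are identical")
        elif self.vclass is VariantClass.INS:
            if self.ref_allele != "" or not self.alt_allele:
                raise ImplantError(f"{self.id}: INS needs empty ref and non-empty alt")
        elif self.vclass is VariantClass.DEL:
            if self.alt_allele != "" or not self.ref_allele:
                raise ImplantError(f"{self.id}: DEL needs non-empty ref and empty alt")

    @property
    def is_indel(self) -> bool:
        return self.vclass is not VariantClass.SNV

    def sort_key(self) -> tuple:
        # At equal pos an SNV edits the anchor base before an INS extends
        # to its right; the builder relies on this ordering.
        order = 0 if self.vclass is not VariantClass.INS else 1
        return (self.contig, self.pos, order, self.id)


@dataclass
class CoordinateMap:
    """Reference -> haplotype position map for one set of implanted indels.

    Per contig the map stores insertion anchors (0-based boundary index,
    inserted length) and deletion spans (0-based half-open), both sorted.
    Lifting is O(log k) in the number of indels.
    """

    ref_lengths: dict[str, int] = field(default_factory=dict)
    _ins_bounds: dict[str, list[int]] = field(default_factory=dict)
    _ins_cum: dict[str, list[int]] = field(default_factory=dict)
    _del_starts: dict[str, list[int]] = field(default_factory=dict)
    _del_ends: dict[str, list[int]] = field(default_factory=dict)
    _del_cum: dict[str, list[int]] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        ref_lengths: Mapping[str, int],
        insertions: Mapping[str, Sequence[tuple[int, int]]],
        deletions: Mapping[str, Sequence[tuple[int, int]]],
    ) -> "CoordinateMap":
        """``insertions``: contig -> [(boundary, length)]; ``deletions``: contig -> [(start, end)), 0-based."""
        m = cls(ref_lengths=dict(ref_lengths))
        for contig in ref_lengths:
            ins = sorted(insertions.get(contig, ()))
            dels = sorted(deletions.get(contig, ()))
            m._ins_bounds[contig] = [b for b, _ in ins]
            cum = [0]
            for _, ln in ins:
                cum.append(cum[-1] + ln)
            m._ins_cum[contig] = cum
            m._del_starts[contig] = [s for s, _ in dels]
            m._del_ends[contig] = [e for _, e in dels]
            dcum = [0]
            for s, e in dels:
                dcum.append(dcum[-1] + (e - s))
            m._del_cum[contig] = dcum
        return m

    def _check_contig(self, contig: str) -> None:
        if contig not in self.ref_lengths:
            raise KeyError(f"unknown contig {contig!r}")

    def _deleted_before(self, contig: str, x: int) -> int:
        """Total deleted reference bases in [0, x)."""
        starts, ends, cum = self._del_starts[contig], self._del_ends[contig], self._del_cum[contig]
        j = bisect.bisect_right(ends, x)
        total = cum[j]
        if j < len(starts) and starts[j] < x:
            total += x - starts[j]
        return total

    def _inserted_at_or_before(self, contig: str, boundary: int) -> int:
        j = bisect.bisect_right(self._ins_bounds[contig], boundary)
        return self._ins_cum[contig][j]

    def _inserted_before(self, contig: str, boundary: int) -> int:
        j = bisect.bisect_left(self._ins_bounds[contig], boundary)
        return self._ins_cum[contig][j]

    def is_deleted(self, contig: str, pos: int) -> bool:
        """Whether 1-based reference position ``pos`` falls inside a deletion."""
        self._check_contig(contig)
        i = pos - 1
        starts, ends = self._del_starts[contig], self._del_ends[contig]
        j = bisect.bisect_right(starts, i) - 1
        return j >= 0 and i < ends[j]

    def lift_position(self, contig: str, pos: int) -> int | None:
        """Lift a 1-based reference position; ``None`` when it was deleted."""
        self._check_contig(contig)
        if not 1 <= pos <= self.ref_lengths[contig]:
            raise ValueError(f"position {pos} outside contig {contig!r} (length {self.ref_lengths[contig]})")
        if self.is_deleted(contig, pos):
            return None
        i = pos - 1
        return i - self._deleted_before(contig, i) + self._inserted_at_or_before(contig, i) + 1

    def lift_interval(self, contig: str, start: int, end: int) -> tuple[int, int]:
        """Lift a 0-based half-open reference interval to haplotype coordinates.

        The result covers the surviving images of the input bases plus any
        sequence inserted strictly inside the interval; a fully deleted
        interval lifts to an empty one.
        """
        self._check_contig(contig)
        if not 0 <= start <= end <= self.ref_lengths[contig]:
            raise ValueError(f"invalid interval [{start},{end}) on {contig!r}")
        h_start = start - self._deleted_before(contig, start) + self._inserted_at_or_before(contig, start)
        h_end = end - self._deleted_before(contig, end) + self._inserted_before(contig, end)
        return h_start, max(h_start, h_end)

    def haplotype_length(self, contig: str) -> int:
        self._check_contig(contig)
        n = self.ref_lengths[contig]
        return n - self._del_cum[contig][-1] + self._ins_cum[contig][-1]

    def ref_position_array(self, contig: str) -> np.ndarray:
        """Per-haplotype-base source array: 0-based reference index, or -1 for inserted bases."""
        self._check_contig(contig)
        events: list[tuple[int, int, str, int]] = []
        for b, ln in zip(
            self._ins_bounds[contig],
            np.diff(self._ins_cum[contig]).tolist() if len(self._ins_bounds[contig]) else [],
        ):
            events.append((b, 0, "I", ln))
        for s, e in zip(self._del_starts[contig], self._del_ends[contig]):
            events.append((s, 1, "D", e - s))
        events.sort()
        pieces: list[np.ndarray] = []
        cursor = 0
        for anchor, _, kind, ln in events:
            if anchor > cursor:
                pieces.append(np.arange(cursor, anchor, dtype=np.int64))
                cursor = anchor
            if kind == "I":
                pieces.append(np.full(ln, -1, dtype=np.int64))
            else:
                cursor += ln
        n = self.ref_lengths[contig]
        if cursor < n:
            pieces.append(np.arange(cursor, n, dtype=np.int64))
        if not pieces:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(pieces)


@dataclass
class HaplotypeGenome:
    """One edited haploid genome plus its reference<->haplotype coordinate map."""

    label: str
    sequences: dict[str, str]
    variants_applied: tuple[str, ...]
    coord_map: CoordinateMap


def implant_variants(
    reference: Mapping[str, str],
    variants: Sequence[Variant],
    label: str = "haplotype",
) -> HaplotypeGenome:
    """Apply ``variants`` to ``reference`` and return the edited haplotype.

    Variants must not overlap any shared reference base; SNV/DEL ref alleles
    must match the (case-insensitive) reference and no variant may sit on an
    ``N``.  Violations raise :class:`ImplantError` with contig/position detail.
    """
    by_contig: dict[str, list[Variant]] = {}
    for v in sorted(variants, key=Variant.sort_key):
        if v.contig not in reference:
            raise ImplantError(f"{v.id}: contig {v.contig!r} not in reference")
        by_contig.setdefault(v.contig, []).append(v)

    sequences: dict[str, str] = {}
    insertions: dict[str, list[tuple[int, int]]] = {}
    deletions: dict[str, list[tuple[int, int]]] = {}
    applied: list[str] = []

    for contig, ref_seq in reference.items():
        ref = ref_seq.upper()
        parts: list[str] = []
        cursor = 0  # 0-based index of the next unconsumed reference base
        prev: Variant | None = None
        for v in by_contig.get(contig, ()):
            start = v.pos if v.vclass is VariantClass.INS else v.pos - 1
            if start < cursor:
                raise ImplantError(
                    f"overlapping variants on {contig}: {prev.id if prev else '?'} and {v.id} (pos {v.pos})"
                )
            span = v.ref_allele if v.vclass is not VariantClass.INS else ""
            if v.pos - 1 + max(len(span), 1) > len(ref):
                raise ImplantError(f"{v.id}: position {v.pos} outside contig {contig} (length {len(ref)})")
            anchor = ref[v.pos - 1]
            if anchor == "N":
                raise ImplantError(f"{v.id}: cannot implant on an N base at {contig}:{v.pos}")
            if span:
                observed = ref[v.pos - 1 : v.pos - 1 + len(span)]
                if observed != span:
                    raise ImplantError(
                        f"{v.id}: ref allele mismatch at {contig}:{v.pos} (expected {span!r}, reference has {observed!r})"
                    )
                if "N" in observed:
                    raise ImplantError(f"{v.id}: cannot implant on an N base at {contig}:{v.pos}")
            parts.append(ref[cursor:start])
            if v.vclass is VariantClass.SNV:
                parts.append(v.alt_allele)
                cursor = v.pos
            elif v.vclass is VariantClass.INS:
                parts.append(v.alt_allele)
                cursor = v.pos
                insertions.setdefault(contig, []).append((v.pos, len(v.alt_allele)))
            else:  # DEL
                cursor = v.pos - 1 + len(v.ref_allele)
                deletions.setdefault(contig, []).append((v.pos - 1, cursor))
            applied.append(v.id)
            prev = v
        parts.append(ref[cursor:])
        sequences[contig] = "".join(parts)

    coord_map = CoordinateMap.build(
        {c: len(s) for c, s in reference.items()}, insertions, deletions
    )
    return HaplotypeGenome(
        label=label,
        sequences=sequences,
        variants_applied=tuple(applied),
        coord_map=coord_map,
    )


def lift_to_haplotype(coord_map: CoordinateMap, contig: str, pos: int) -> int | None:
    """Functional wrapper for :meth:`CoordinateMap.lift_position`."""
    return coord_map.lift_position(contig, pos)


def lift_interval_to_haplotype(
    coord_map: CoordinateMap, contig: str, start: int, end: int
) -> tuple[int, int]:
    """Functional wrapper for :meth:`CoordinateMap.lift_interval`."""
    return coord_map.lift_interval(contig, start, end)


# ---------------------------------------------------------------------------
# I/O: FASTA, VCF and TSV variant lists
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-contig) FASTA into contig -> uppercase sequence."""
    sequences: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks).upper()
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _variant_from_vcf_alleles(
    vid: str, contig: str, pos: int, ref: str, alt: str, origin: Origin
) -> Variant:
    """Convert a VCF (anchored) REF/ALT pair to the internal edit representation."""
    if any(ch not in _BASES for ch in ref + alt):
        raise ImplantError(f"{vid}: symbolic or non-ACGT alleles are not supported ({ref}>{alt})")
    if len(ref) == 1 and len(alt) == 1:
        return Variant(vid, contig, pos, ref, alt, VariantClass.SNV, origin)
    if len(ref) == 1 and len(alt) > 1 and alt[0] == ref:
        return Variant(vid, contig, pos, "", alt[1:], VariantClass.INS, origin)
    if len(alt) == 1 and len(ref) > 1 and ref[0] == alt:
        return Variant(vid, contig, pos + 1, ref[1:], "", VariantClass.DEL, origin)
    raise ImplantError(f"{vid}: unsupported complex allele pair {ref}>{alt} at {contig}:{pos}")


def read_variants_vcf(path: str | Path, default_origin: Origin = Origin.GERMLINE) -> list[Variant]:
    """Read variants from a VCF (one ALT per record; symbolic alleles rejected).

    The INFO field ``ORIGIN`` overrides ``default_origin`` when present.
    """
    variants: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        has_origin = "ORIGIN" in vcf.header.info
        for i, rec in enumerate(vcf):
            alts = rec.alts or ()
            if len(alts) != 1:
                raise ImplantError(
                    f"record {rec.chrom}:{rec.pos} must carry exactly one ALT, found {len(alts)}"
                )
            origin = default_origin
            if has_origin and "ORIGIN" in rec.info:
                origin = Origin(str(rec.info["ORIGIN"]))
            vid = rec.id or f"var{i + 1}"
            variants.append(
                _variant_from_vcf_alleles(vid, rec.chrom, rec.pos, rec.ref, alts[0], origin)
            )
    return variants


_TSV_HEADER = ["id", "contig", "pos", "ref_allele", "alt_allele", "vclass", "origin"]


def write_variants_tsv(variants: Iterable[Variant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for v in variants:
            fh.write(
                f"{v.id}\t{v.contig}\t{v.pos}\t{v.ref_allele or '.'}\t"
                f"{v.alt_allele or '.'}\t{v.vclass.value}\t{v.origin.value}\n"
            )


def read_variants_tsv(path: str | Path) -> list[Variant]:
    """Read the tabular variant format (columns mirroring :class:`Variant`).

    A leading ``id`` column is optional; rows without one get sequential ids.
    """
    variants: list[Variant] = []
    with open(path) as fh:
        header: list[str] | None = None
        for n, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None and fields[0] in ("id", "contig"):
                header = fields
                continue
            if len(fields) == len(_TSV_HEADER) - 1:
                fields = [f"var{n}"] + fields
            if len(fields) != len(_TSV_HEADER):
                raise ImplantError(f"{path}: line {n + 1} has {len(fields)} columns")
            vid, contig, pos, ref, alt, vclass, origin = fields
            variants.append(
                Variant(
                    vid,
                    contig,
                    int(pos),
                    "" if ref == "." else ref.upper(),
                    "" if alt == "." else alt.upper(),
                    VariantClass(vclass),
                    Origin(origin),
                )
            )
    return variants
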