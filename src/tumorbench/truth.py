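"""Gold-standard truth sets: VCF emission, AF histograms, density tracks.

The truth set is the list of implanted variants with their closed-form
expected allele frequencies for one sample; it is what callers are scored
against.  Indels are written to the truth VCF (they exist in the simulated
data as confounders) but flagged, since evaluation is SNV-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .readsim import TargetRegions
from .variants import Origin, Variant, VariantClass

__all__ = [
    "TruthRecord",
    "TruthSet",
    "write_truth_vcf",
    "read_truth_vcf",
    "af_histogram",
    "variant_density_track",
    "plot_af_histogram_series",
]


@dataclass(frozen=True)
class TruthRecord:
    variant: Variant
    expected_af: float

    def __post_init__(self) -> None:
        if not 0.0 < self.expected_af <= 1.0:
            raise ValueError(
                f"{self.variant.id}: expected AF must lie in (0, 1], got {self.expected_af}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        v = self.variant
        return (v.contig, v.pos, v.ref_allele, v.alt_allele)


@dataclass
class TruthSet:
    """All truth records of one sample, optionally restricted to target regions."""

    sample_label: str
    records: list[TruthRecord] = field(default_factory=list)
    targets: TargetRegions | None = None

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for rec in self.records:
            if rec.key in seen:
                raise ValueError(f"duplicate truth record at {rec.key}")
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def restrict_to_targets(self, targets: TargetRegions) -> "TruthSet":
        kept = [
            rec
            for rec in self.records
            if targets.contains(rec.variant.contig, rec.variant.pos)
        ]
        return TruthSet(sample_label=self.sample_label, records=kept, targets=targets)

    def snv_records(self, origin: Origin | None = None) -> list[TruthRecord]:
        return [
            rec
            for rec in self.records
            if rec.variant.vclass is VariantClass.SNV
            and (origin is None or rec.variant.origin is origin)
        ]


def _vcf_alleles(variant: Variant, reference: Mapping[str, str] | None) -> tuple[int, str, str]:
    """Internal edit -> anchored VCF (pos, REF, ALT)."""
    if variant.vclass is VariantClass.SNV:
        return variant.pos, variant.ref_allele, variant.alt_allele
    if reference is None:
        raise ValueError(
            f"{variant.id}: writing indels to VCF requires the reference for anchor bases"
        )
    seq = reference[variant.contig]
    if variant.vclass is VariantClass.INS:
        anchor = seq[variant.pos - 1]
        return variant.pos, anchor, anchor + variant.alt_allele
    # DEL at pos: anchored at pos-1 (VCF left-anchoring)
    if variant.pos < 2:
        raise ValueError(f"{variant.id}: deletion at contig start cannot be left-anchored")
    anchor = seq[variant.pos - 2]
    return variant.pos - 1, anchor + variant.ref_allele, anchor


def _truth_header(contig_lengths: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=ORIGIN,Number=1,Type=String,Description="Variant origin: germline or somatic">')
    header.add_line('##INFO=<ID=TAF,Number=1,Type=Float,Description="True (expected) allele frequency">')
    header.add_line('##INFO=<ID=VCLASS,Number=1,Type=String,Description="Variant class: SNV, INS or DEL">')
    for contig, length in contig_lengths.items():
        header.add_line(f"##contig=<ID={contig},length={length}>")
    return header


def write_truth_vcf(
    truth: TruthSet,
    path: str | Path,
    contig_lengths: Mapping[str, int],
    reference: Mapping[str, str] | None = None,
) -> None:
    """Write a sorted VCF 4.2 truth set with ORIGIN/TAF/VCLASS INFO fields.

    When ``truth.targets`` is set, records outside the target regions are
    excluded.  ``reference`` is only needed when the set contains indels
    (VCF anchoring).
    """
    records = truth.records
    if truth.targets is not None:
        records = [
            rec for rec in records if truth.targets.contains(rec.variant.contig, rec.variant.pos)
        ]
    rows = []
    for rec in records:
        pos, ref, alt = _vcf_alleles(rec.variant, reference)
        rows.append((rec.variant.contig, pos, ref, alt, rec))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))

    header = _truth_header(contig_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for contig, pos, ref, alt, rec in rows:
            vrec = out.new_record(
                contig=contig,
                start=pos - 1,
                stop=pos - 1 + len(ref),
                alleles=(ref, alt),
                id=rec.variant.id,
            )
            vrec.info["ORIGIN"] = rec.variant.origin.value
            vrec.info["TAF"] = float(rec.expected_af)
            vrec.info["VCLASS"] = rec.variant.vclass.value
            out.write(vrec)


def read_truth_vcf(path: str | Path, sample_label: str | None = None) -> TruthSet:
    """Read back a truth VCF written by :func:`write_truth_vcf`."""
    from .variants import _variant_from_vcf_alleles

    records: list[TruthRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf):
            origin = Origin(str(rec.info["ORIGIN"]))
            vid = rec.id or f"truth{i + 1}"
            variant = _variant_from_vcf_alleles(
                vid, rec.chrom, rec.pos, rec.ref, (rec.alts or ("",))[0], origin
            )
            records.append(TruthRecord(variant=variant, expected_af=float(rec.info["TAF"])))
    return TruthSet(sample_label=sample_label or Path(path).stem, records=records)


def af_histogram(truth: TruthSet, bins: int = 10) -> pd.DataFrame:
    """Histogram of true allele frequencies by origin.

    Bins are left-open right-closed on (0, 1], so AF=1 falls in the last
    bin; columns: bin_low, bin_high, somatic, germline.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts = {o: np.zeros(bins, dtype=int) for o in (Origin.SOMATIC, Origin.GERMLINE)}
    for rec in truth.records:
        # left-open right-closed: AF in (edges[k], edges[k+1]]
        k = min(bins - 1, max(0, int(np.ceil(rec.expected_af * bins)) - 1))
        counts[rec.variant.origin][k] += 1
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "somatic": counts[Origin.SOMATIC],
            "germline": counts[Origin.GERMLINE],
        }
    )


def variant_density_track(truth: TruthSet, bin_size: int) -> pd.DataFrame:
    """Per-contig binned variant counts by origin and class (SNV vs indel).

    Suitable for genome-wide density plots; columns: contig, bin (0-based
    index), start, end, then one count column per origin x class combination.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows: dict[tuple[str, int], dict[str, int]] = {}
    combos = [
        ("germline", "SNV"), ("germline", "indel"),
        ("somatic", "SNV"), ("somatic", "indel"),
    ]
    for rec in truth.records:
        v = rec.variant
        b = (v.pos - 1) // bin_size
        cell = rows.setdefault((v.contig, b), {f"{o}_{c}": 0 for o, c in combos})
        cls = "SNV" if v.vclass is VariantClass.SNV else "indel"
        cell[f"{v.origin.value}_{cls}"] += 1
    out = []
    for (contig, b), cell in sorted(rows.items()):
        out.append(
            {"contig": contig, "bin": b, "start": b * bin_size, "end": (b + 1) * bin_size, **cell}
        )
    columns = ["contig", "bin", "start", "end"] + [f"{o}_{c}" for o, c in combos]
    return pd.DataFrame(out, columns=columns)


def plot_af_histogram_series(
    truth_sets: Sequence[TruthSet],
    path: str | Path,
    bins: int = 20,
) -> None:
    """Panel of somatic-AF histograms across the admixture series.

    Visualizes how increasing normal admixture shifts somatic allele
    frequencies toward zero.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(truth_sets)
    ncols = min(5, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.5 * nrows), squeeze=False)
    for ax in axes.flat:
        ax.set_visible(False)
    for i, truth in enumerate(truth_sets):
        ax = axes[i // ncols][i % ncols]
        ax.set_visible(True)
        afs = [rec.expected_af for rec in truth.snv_records(Origin.SOMATIC)]
        ax.hist(afs, bins=np.linspace(0, 1, bins + 1), color="firebrick")
        ax.set_title(truth.sample_label, fontsize=9)
        ax.set_xlim(0, 1)
    fig.supxlabel("true allele frequency")
    fig.supylabel("somatic SNVs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
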