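"""Subclone structure, mixture weights and expected allele frequencies.

A heterogeneous tumor is modeled as two pools of haploid cancer genomes —
``n_per_lineage`` maternal and ``n_per_lineage`` paternal copies of the
control haplotypes, each carrying a random subset of the somatic variants.
A sequenced fragment picks a lineage with probability 1/2 and then a genome
within the lineage according to that lineage's mixture weights.  An admixed
sample further dilutes the tumor with a fraction ``a`` of normal (control)
material, so the expected allele frequency of a variant is

    AF(a) = (1 - a) * AF_tumor + a * AF_control

with ``AF_tumor = 1/2 * sum_i w^M_i [carried by maternal i]
               + 1/2 * sum_j w^P_j [carried by paternal j]``.

Germline variants are carried by every cancer genome of their control
lineage(s), which makes their AF invariant under admixture; somatic variants
have ``AF_control = 0`` and dilute linearly — a clonal 30% variant drops to
3% at 90% admixture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .variants import Origin, Variant

__all__ = [
    "MATERNAL",
    "PATERNAL",
    "LINEAGES",
    "SubcloneAssignment",
    "CloneMixture",
    "AdmixedSample",
    "assign_subclones",
    "draw_mixture",
    "dilute_af",
    "expected_af",
    "make_admixture_series",
    "mix_two_genomes",
    "DEFAULT_ADMIXTURE_LEVELS",
]

MATERNAL = "maternal"
PATERNAL = "paternal"
LINEAGES = (MATERNAL, PATERNAL)

#: The default admixture series: ten tumors from 0% to 90% normal contamination.
DEFAULT_ADMIXTURE_LEVELS: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(10))

MAX_ADMIXTURE = 0.95


@dataclass
class SubcloneAssignment:
    """Which cancer genomes carry which somatic variant.

    ``membership`` maps a variant id to the set of ``(lineage, index)``
    genomes carrying it; every somatic variant is carried by at least one
    genome.  ``redrawn`` records variants whose first Bernoulli draw left
    them in no genome and that were re-drawn.
    """

    n_per_lineage: int
    membership: dict[str, frozenset[tuple[str, int]]] = field(default_factory=dict)
    redrawn: tuple[str, ...] = ()

    def genomes(self) -> list[tuple[str, int]]:
        return [(lin, i) for lin in LINEAGES for i in range(self.n_per_lineage)]

    def members(self, variant_id: str) -> frozenset[tuple[str, int]]:
        try:
            return self.membership[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in subclone assignment") from None

    def to_json(self) -> dict:
        return {
            "n_per_lineage": self.n_per_lineage,
            "membership": {vid: sorted([list(g) for g in gs]) for vid, gs in self.membership.items()},
            "redrawn": list(self.redrawn),
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "SubcloneAssignment":
        return cls(
            n_per_lineage=int(obj["n_per_lineage"]),
            membership={
                vid: frozenset((lin, int(i)) for lin, i in gs)
                for vid, gs in obj["membership"].items()
            },
            redrawn=tuple(obj.get("redrawn", ())),
        )


@dataclass(frozen=True)
class CloneMixture:
    """Mixture weights over the cancer genomes, one simplex per lineage."""

    maternal_weights: tuple[float, ...]
    paternal_weights: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, w in ((MATERNAL, self.maternal_weights), (PATERNAL, self.paternal_weights)):
            arr = np.asarray(w, dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"{name} weights must be a non-empty vector")
            if (arr < 0).any():
                raise ValueError(f"{name} weights must be non-negative")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} weights must sum to 1, got {arr.sum()!r}")

    @property
    def n_per_lineage(self) -> int:
        return len(self.maternal_weights)

    def weight(self, lineage: str, index: int) -> float:
        if lineage == MATERNAL:
            return self.maternal_weights[index]
        if lineage == PATERNAL:
            return self.paternal_weights[index]
        raise ValueError(f"unknown lineage {lineage!r}")

    def to_json(self) -> dict:
        return {
            "maternal_weights": list(self.maternal_weights),
            "paternal_weights": list(self.paternal_weights),
        }


@dataclass(frozen=True)
class AdmixedSample:
    """One simulated tumor sample: a clone mixture plus a normal-admixture fraction."""

    mixture: CloneMixture
    admixture: float
    label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.admixture <= MAX_ADMIXTURE:
            raise ValueError(
                f"admixture must lie in [0, {MAX_ADMIXTURE}], got {self.admixture}"
            )


def assign_subclones(
    somatic_variants: Sequence[Variant],
    n_per_lineage: int = 5,
    inclusion_prob: float = 0.5,
    seed: int = 0,
) -> SubcloneAssignment:
    """Draw a random subset of somatic variants into each cancer genome.

    Each variant enters each of the ``2 * n_per_lineage`` genomes
    independently with ``inclusion_prob``; a variant drawn into no genome is
    re-drawn until it is carried by at least one (and recorded in
    ``redrawn``), so the membership-count law is a zero-truncated binomial.
    """
    if not 0 < inclusion_prob <= 1:
        raise ValueError(f"inclusion_prob must be in (0, 1], got {inclusion_prob}")
    if n_per_lineage < 1:
        raise ValueError("n_per_lineage must be >= 1")
    rng = np.random.default_rng(seed)
    genomes = [(lin, i) for lin in LINEAGES for i in range(n_per_lineage)]
    membership: dict[str, frozenset[tuple[str, int]]] = {}
    redrawn: list[str] = []
    for v in somatic_variants:
        if v.origin is not Origin.SOMATIC:
            raise ValueError(f"{v.id}: subclone assignment applies to somatic variants only")
        while True:
            mask = rng.random(len(genomes)) < inclusion_prob
            if mask.any():
                break
            if v.id not in redrawn:
                redrawn.append(v.id)
        membership[v.id] = frozenset(g for g, keep in zip(genomes, mask) if keep)
    return SubcloneAssignment(
        n_per_lineage=n_per_lineage, membership=membership, redrawn=tuple(redrawn)
    )


def draw_mixture(n_per_lineage: int = 5, seed: int = 0) -> CloneMixture:
    """Draw randomized mixture proportions: one flat Dirichlet per lineage."""
    if n_per_lineage < 1:
        raise ValueError("n_per_lineage must be >= 1")
    rng = np.random.default_rng(seed)
    alpha = np.ones(n_per_lineage)
    wm = rng.dirichlet(alpha)
    wp = rng.dirichlet(alpha)
    return CloneMixture(
        maternal_weights=tuple((wm / wm.sum()).tolist()),
        paternal_weights=tuple((wp / wp.sum()).tolist()),
    )


def dilute_af(af_tumor: float, admixture: float, control_af: float = 0.0) -> float:
    """Linear dilution of a tumor allele frequency by normal admixture."""
    if not 0.0 <= af_tumor <= 1.0:
        raise ValueError(f"tumor AF must lie in [0, 1], got {af_tumor}")
    if not 0.0 <= admixture <= 1.0:
        raise ValueError(f"admixture must lie in [0, 1], got {admixture}")
    return (1.0 - admixture) * af_tumor + admixture * control_af


def tumor_af(
    variant: Variant, assignment: SubcloneAssignment, mixture: CloneMixture
) -> float:
    """Allele frequency of a variant in the pure (undiluted) tumor.

    Somatic variants sum the mixture weights of their carrier genomes;
    germline membership (every genome of the carrier lineage) must already
    be present in the assignment for germline variants.
    """
    members = assignment.members(variant.id)
    af = 0.0
    for lineage, idx in members:
        af += 0.5 * mixture.weight(lineage, idx)
    return min(af, 1.0)  # guard against float round-up when carried by all genomes


def expected_af(
    variant: Variant,
    assignment: SubcloneAssignment,
    sample: AdmixedSample,
    control_af: float = 0.0,
) -> float:
    """Expected allele frequency of ``variant`` in an admixed sample.

    ``control_af`` is the variant's frequency in the diploid control genome:
    0 for somatic variants, 0.5 for heterozygous and 1.0 for homozygous
    germline variants.
    """
    if variant.id not in assignment.membership:
        if control_af == 0.0:
            raise KeyError(f"variant {variant.id!r} unknown: not in assignment and control AF is 0")
        af_t = control_af  # germline not listed explicitly: carried clonally
    else:
        af_t = tumor_af(variant, assignment, sample.mixture)
    return dilute_af(af_t, sample.admixture, control_af)


def make_admixture_series(
    mixture: CloneMixture,
    levels: Sequence[float] = DEFAULT_ADMIXTURE_LEVELS,
    label_prefix: str = "tumor",
) -> list[AdmixedSample]:
    """One admixed sample per level; the default grid is 0%, 10%, ..., 90%."""
    previous = -1.0
    for a in levels:
        if a <= previous:
            raise ValueError(f"admixture levels must be strictly increasing, got {list(levels)}")
        previous = a
    return [
        AdmixedSample(mixture=mixture, admixture=a, label=f"{label_prefix}_a{int(round(a * 100)):02d}")
        for a in levels
    ]


def mix_two_genomes(
    sample_a: Mapping[tuple[str, int, str, str], float],
    sample_b: Mapping[tuple[str, int, str, str], float],
    ratio: float,
):
    """Mix two diploid genotype sets at ``ratio`` (fraction of ``sample_b``).

    Each input maps ``(contig, pos, ref, alt)`` to the variant's allele
    frequency in that genome (0.5 heterozygous, 1.0 homozygous).  The result
    is the union truth set with ``AF = (1 - r) * AF_a + r * AF_b``; the
    mixture AFs are therefore discrete multiples of ``r/2`` and ``(1-r)/2``.
    Emulates a two-sample reference-material dilution (e.g. two reference
    genomes mixed 1:7).
    """
    from .truth import TruthRecord, TruthSet
    from .variants import VariantClass

    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must lie in (0, 1), got {ratio}")
    by_site: dict[tuple[str, int], tuple[str, str]] = {}
    for source in (sample_a, sample_b):
        for (contig, pos, ref, alt), af in source.items():
            if not 0.0 < af <= 1.0:
                raise ValueError(f"genotype AF must lie in (0, 1], got {af} at {contig}:{pos}")
            site = (contig, pos)
            if site in by_site and by_site[site][0] != ref:
                raise ValueError(
                    f"conflicting ref alleles at {contig}:{pos}: {by_site[site][0]!r} vs {ref!r}"
                )
            by_site.setdefault(site, (ref, alt))
    records = []
    keys = sorted(set(sample_a) | set(sample_b))
    for n, key in enumerate(keys):
        contig, pos, ref, alt = key
        af = (1.0 - ratio) * sample_a.get(key, 0.0) + ratio * sample_b.get(key, 0.0)
        vclass = VariantClass.SNV if len(ref) == 1 and len(alt) == 1 else (
            VariantClass.INS if len(ref) == 0 else VariantClass.DEL
        )
        records.append(
            TruthRecord(
                variant=Variant(f"mix{n + 1}", contig, pos, ref, alt, vclass, Origin.GERMLINE),
                expected_af=af,
            )
        )
    return TruthSet(sample_label=f"mixture_r{ratio:g}", records=records)


def save_mixture_sidecar(
    path: str | Path,
    seed: int,
    mixture: CloneMixture,
    assignment: SubcloneAssignment,
    samples: Iterable[AdmixedSample] = (),
) -> None:
    """Serialize the full mixture design next to the truth VCF for reproducibility."""
    payload = {
        "seed": seed,
        "mixture": mixture.to_json(),
        "assignment": assignment.to_json(),
        "samples": [{"label": s.label, "admixture": s.admixture} for s in samples],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
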