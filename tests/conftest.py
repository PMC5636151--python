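"""Shared fixtures and independent oracles.

The string-surgery oracle rebuilds an edited haplotype by naive per-edit
cell manipulation, independently of the production coordinate-map code, and
is reused by both the unit tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from tumorbench.variants import Origin, Variant, VariantClass


def surgery_oracle(ref: str, variants: list[Variant]) -> tuple[str, dict[int, int | None]]:
    """Apply edits one at a time by string surgery.

    Returns the haplotype sequence and a map from every 1-based reference
    position to its 1-based haplotype position (``None`` if deleted).
    Assumes edits do not touch adjacent bases (the generators below keep a
    spacing margin).
    """
    cells = [b for b in ref.upper()]
    deleted = [False] * len(ref)
    for v in variants:
        i = v.pos - 1
        if v.vclass is VariantClass.SNV:
            cells[i] = v.alt_allele
        elif v.vclass is VariantClass.INS:
            cells[i] = cells[i] + v.alt_allele
        else:
            for k in range(i, i + len(v.ref_allele)):
                cells[k] = ""
                deleted[k] = True
    hap = "".join(cells)
    pos_map: dict[int, int | None] = {}
    offset = 0
    for i in range(len(ref)):
        if deleted[i]:
            pos_map[i + 1] = None
        else:
            pos_map[i + 1] = offset + 1
        offset += len(cells[i])
    return hap, pos_map


def random_reference(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))


def random_edit_set(
    rng: np.random.Generator,
    ref: str,
    n_edits: int,
    max_indel: int = 6,
    origin: Origin = Origin.GERMLINE,
) -> list[Variant]:
    """Non-adjacent random SNV/INS/DEL edits with a safety spacing."""
    spacing = max_indel + 2
    n_slots = (len(ref) - 2) // spacing
    n_edits = min(n_edits, n_slots)
    slots = rng.choice(n_slots, size=n_edits, replace=False)
    variants = []
    for k, slot in enumerate(sorted(slots.tolist())):
        pos = slot * spacing + 2  # 1-based, away from the contig ends
        kind = rng.integers(0, 3)
        if kind == 0:
            ref_base = ref[pos - 1]
            alt = "ACGT".replace(ref_base, "")[rng.integers(3)]
            variants.append(Variant(f"e{k}", "chr1", pos, ref_base, alt, VariantClass.SNV, origin))
        elif kind == 1:
            ln = int(rng.integers(1, max_indel + 1))
            alt = "".join("ACGT"[c] for c in rng.integers(0, 4, size=ln))
            variants.append(Variant(f"e{k}", "chr1", pos, "", alt, VariantClass.INS, origin))
        else:
            ln = int(rng.integers(1, max_indel + 1))
            variants.append(
                Variant(f"e{k}", "chr1", pos, ref[pos - 1 : pos - 1 + ln], "", VariantClass.DEL, origin)
            )
    return variants


def check_implant_against_surgery(
    rng: np.random.Generator, ref_length: int = 10_000, n_edits: int = 60
) -> None:
    """One randomized round-trip comparison; raises AssertionError on mismatch."""
    from tumorbench.variants import implant_variants

    ref = random_reference(rng, ref_length)
    edits = random_edit_set(rng, ref, n_edits)
    genome = implant_variants({"chr1": ref}, edits)
    expected_seq, pos_map = surgery_oracle(ref, edits)
    assert genome.sequences["chr1"] == expected_seq
    net = sum(len(v.alt_allele) - len(v.ref_allele) for v in edits)
    assert len(genome.sequences["chr1"]) == ref_length + net
    # spot-check position lifts against the oracle map
    probe = set(rng.integers(1, ref_length + 1, size=40).tolist())
    probe.update(v.pos for v in edits)
    for pos in probe:
        assert genome.coord_map.lift_position("chr1", int(pos)) == pos_map[pos]


def brute_force_match(calls, truth_records, mode):
    """Independent all-pairs TP/FP/FN matcher (quadratic scan, no hashing)."""

    def matches(c, rec):
        v = rec.variant
        if c.contig != v.contig or c.pos != v.pos:
            return False
        if mode == "position":
            return True
        return c.ref == v.ref_allele and c.alt == v.alt_allele

    tp = sum(1 for rec in truth_records if any(matches(c, rec) for c in calls))
    fp = sum(1 for c in calls if not any(matches(c, rec) for rec in truth_records))
    fn = len(truth_records) - tp
    return tp, fp, fn


@pytest.fixture(scope="session")
def small_run_config():
    """A compact but fully featured pipeline configuration."""
    from tumorbench.pipeline import RunConfig

    return RunConfig(
        seed=7,
        contig_length=30_000,
        n_targets=2,
        target_length=8_000,
        target_flank=2_500,
        n_germline_snvs=150,
        n_germline_indels=15,
        n_somatic_snvs=60,
        coverage=40,
    )


@pytest.fixture(scope="session")
def small_fixture(small_run_config):
    from tumorbench.pipeline import generate_fixture

    return generate_fixture(small_run_config)
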