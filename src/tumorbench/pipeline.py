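"""End-to-end orchestration: fixture generation -> genome forging -> mixing
-> read simulation -> calling -> evaluation, from one seeded configuration.

The fixture generator produces a synthetic stand-in for the real inputs
(reference genome, germline variant catalogue, cancer variant catalogue,
capture design): uniform-random contigs at a configurable GC content,
germline SNVs and small indels apportioned between the maternal and
paternal lineages by a het:hom ratio, and somatic SNVs placed inside the
capture targets.  Every stochastic stage draws its seed from one master
seed via a named substream, so any stage can be re-run independently and a
full run is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import readsim
from .caller import CallerParams, call_snvs, write_callset_vcf
from .evaluate import EvalResult, admixture_curve, compare_calls
from .mixing import (
    AdmixedSample,
    CloneMixture,
    DEFAULT_ADMIXTURE_LEVELS,
    LINEAGES,
    MATERNAL,
    PATERNAL,
    SubcloneAssignment,
    assign_subclones,
    draw_mixture,
    expected_af,
    make_admixture_series,
    save_mixture_sidecar,
)
from .readsim import GenomeSet, ReadSimConfig, TargetRegions, exome_config, panel_config
from .truth import TruthRecord, TruthSet, write_truth_vcf
from .variants import (
    HaplotypeGenome,
    Origin,
    Variant,
    VariantClass,
    implant_variants,
    write_fasta,
    write_variants_tsv,
)

__all__ = [
    "RunConfig",
    "GermlineVariant",
    "Fixture",
    "stage_seed",
    "generate_fixture",
    "forge_genomes",
    "truth_for_sample",
    "run_all",
]

_MIN_VARIANT_SPACING = 12  # bases; guarantees non-overlap incl. max indel length


def stage_seed(master_seed: int, label: str) -> int:
    """Derive a named substream seed (< 2^31) from the master seed."""
    digest = hashlib.sha256(f"{master_seed}/{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """One self-contained experiment configuration (round-trips via YAML)."""

    seed: int = 0
    # synthetic reference
    n_contigs: int = 1
    contig_length: int = 60_000
    gc_fraction: float = 0.45
    # capture design
    n_targets: int = 4
    target_length: int = 10_000
    target_flank: int = 2_500
    capture_preset: str = "exome"  # or "panel"
    # germline variant model
    n_germline_snvs: int = 300
    n_germline_indels: int = 30
    het_hom_ratio: float = 2.0
    max_indel_length: int = 6
    variant_pad: int = 200  # germline confounders may sit this far outside targets
    # somatic variant model
    n_somatic_snvs: int = 80
    hypermutation_multiplier: int = 1  # boosts in-target somatic count (panel runs)
    # tumor structure
    n_per_lineage: int = 5
    inclusion_prob: float = 0.5
    admixture_levels: tuple[float, ...] = DEFAULT_ADMIXTURE_LEVELS
    # sequencing overrides (None -> capture preset defaults)
    coverage: float | None = None
    read_length: int | None = None
    sub_rate: float | None = None
    ins_rate: float | None = None
    del_rate: float | None = None
    # calling
    caller_grid: tuple[CallerParams, ...] = (CallerParams(),)
    write_genome_fastas: bool = False

    def readsim_config(self, seed: int, run_id: str) -> ReadSimConfig:
        base = exome_config() if self.capture_preset == "exome" else panel_config()
        overrides: dict = {"seed": seed, "run_id": run_id}
        if self.coverage is not None:
            overrides["target_median_coverage"] = self.coverage
        if self.read_length is not None:
            overrides["read_length"] = self.read_length
        for name in ("sub_rate", "ins_rate", "del_rate"):
            value = getattr(self, name)
            if value is not None:
                overrides[name] = value
        return dataclasses.replace(base, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["admixture_levels"] = list(self.admixture_levels)
        d["caller_grid"] = [dataclasses.asdict(p) for p in self.caller_grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "admixture_levels" in d:
            d["admixture_levels"] = tuple(float(a) for a in d["admixture_levels"])
        if "caller_grid" in d:
            d["caller_grid"] = tuple(CallerParams(**p) for p in d["caller_grid"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass(frozen=True)
class GermlineVariant:
    """A germline variant plus the control lineage(s) carrying it."""

    variant: Variant
    lineages: frozenset[str]

    @property
    def control_af(self) -> float:
        return len(self.lineages) / 2.0


@dataclass
class Fixture:
    """Synthetic reference, variant catalogues and capture design."""

    reference: dict[str, str]
    germline: list[GermlineVariant]
    somatic: list[Variant]
    targets: TargetRegions

    def write(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.reference, outdir / "reference.fa")
        self.targets.to_bed(outdir / "targets.bed")
        write_variants_tsv([g.variant for g in self.germline], outdir / "germline.tsv")
        write_variants_tsv(self.somatic, outdir / "somatic.tsv")
        with open(outdir / "germline_lineages.tsv", "w") as fh:
            fh.write("id\tlineages\n")
            for g in self.germline:
                fh.write(f"{g.variant.id}\t{','.join(sorted(g.lineages))}\n")
        return {
            "reference": "reference.fa",
            "targets": "targets.bed",
            "germline": "germline.tsv",
            "somatic": "somatic.tsv",
        }


_GC_BASES = "ACGT"


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=probs)
    lut = np.frombuffer(_GC_BASES.encode(), dtype=np.uint8)
    return lut[codes].tobytes().decode()


def _place_targets(cfg: RunConfig, rng: np.random.Generator, contigs: Sequence[str]) -> TargetRegions:
    intervals = []
    per_contig = [cfg.n_targets // len(contigs)] * len(contigs)
    for i in range(cfg.n_targets % len(contigs)):
        per_contig[i] += 1
    for contig, n in zip(contigs, per_contig):
        if n == 0:
            continue
        usable_start, usable_end = cfg.target_flank, cfg.contig_length - cfg.target_flank
        slot = (usable_end - usable_start) // n
        if slot < cfg.target_length + 100:
            raise ValueError(
                f"contig length {cfg.contig_length} cannot hold {n} targets of "
                f"{cfg.target_length} bp with {cfg.target_flank} bp flanks"
            )
        for k in range(n):
            lo = usable_start + k * slot
            offset = int(rng.integers(0, slot - cfg.target_length))
            intervals.append((contig, lo + offset, lo + offset + cfg.target_length))
    return TargetRegions.from_intervals(intervals)


def _sample_positions(
    rng: np.random.Generator,
    windows: list[tuple[str, int, int]],
    count: int,
    occupied: dict[str, list[int]],
) -> list[tuple[str, int]]:
    """Sample ``count`` 1-based positions uniformly over windows, keeping a
    minimum spacing from every previously placed variant."""
    window_lengths = np.array([e - s for _, s, e in windows], dtype=float)
    probs = window_lengths / window_lengths.sum()
    placed: list[tuple[str, int]] = []
    attempts = 0
    max_attempts = 200 * count + 1000
    while len(placed) < count:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {count} variants (placed {len(placed)}); "
                "windows too small for the requested variant density"
            )
        w = int(rng.choice(len(windows), p=probs))
        contig, s, e = windows[w]
        pos = int(rng.integers(s, e)) + 1  # 1-based
        taken = occupied.setdefault(contig, [])
        if any(abs(pos - t) < _MIN_VARIANT_SPACING for t in taken):
            continue
        taken.append(pos)
        placed.append((contig, pos))
    return placed


def _random_snv(rng: np.random.Generator, vid: str, contig: str, pos: int, ref_base: str, origin: Origin) -> Variant:
    alt = "ACGT".replace(ref_base, "")[int(rng.integers(3))]
    return Variant(vid, contig, pos, ref_base, alt, VariantClass.SNV, origin)


def generate_fixture(cfg: RunConfig) -> Fixture:
    """Generate the synthetic reference, capture design and variant lists.

    Germline variants fall in targets padded by ``variant_pad`` (near-target
    confounders included); somatic SNVs fall strictly inside targets so the
    somatic truth is fully evaluable.  The in-target somatic count is
    multiplied by ``hypermutation_multiplier`` (used to emulate a
    hypermutated tumor for small panel designs).
    """
    rng_ref = np.random.default_rng(stage_seed(cfg.seed, "reference"))
    contigs = [f"chr{i + 1}" for i in range(cfg.n_contigs)]
    reference = {c: _random_sequence(rng_ref, cfg.contig_length, cfg.gc_fraction) for c in contigs}

    rng_targets = np.random.default_rng(stage_seed(cfg.seed, "targets"))
    targets = _place_targets(cfg, rng_targets, contigs)

    rng_var = np.random.default_rng(stage_seed(cfg.seed, "variants"))
    occupied: dict[str, list[int]] = {}
    pad = cfg.variant_pad
    germline_windows = [
        (c, max(0, s - pad), min(cfg.contig_length, e + pad)) for c, s, e in targets
    ]
    somatic_windows = [(c, s, e) for c, s, e in targets]

    germline: list[GermlineVariant] = []
    p_het = cfg.het_hom_ratio / (cfg.het_hom_ratio + 1.0)

    def draw_lineages() -> frozenset[str]:
        if rng_var.random() < p_het:
            return frozenset([MATERNAL if rng_var.random() < 0.5 else PATERNAL])
        return frozenset(LINEAGES)

    for i, (contig, pos) in enumerate(
        _sample_positions(rng_var, germline_windows, cfg.n_germline_snvs, occupied)
    ):
        v = _random_snv(rng_var, f"g_snv{i + 1}", contig, pos, reference[contig][pos - 1], Origin.GERMLINE)
        germline.append(GermlineVariant(v, draw_lineages()))

    for i, (contig, pos) in enumerate(
        _sample_positions(rng_var, germline_windows, cfg.n_germline_indels, occupied)
    ):
        length = int(rng_var.integers(1, cfg.max_indel_length + 1))
        if rng_var.random() < 0.5 or pos + length > cfg.contig_length:
            alt = "".join("ACGT"[int(b)] for b in rng_var.integers(0, 4, size=length))
            v = Variant(f"g_ins{i + 1}", contig, pos, "", alt, VariantClass.INS, Origin.GERMLINE)
        else:
            ref = reference[contig][pos - 1 : pos - 1 + length]
            v = Variant(f"g_del{i + 1}", contig, pos, ref, "", VariantClass.DEL, Origin.GERMLINE)
        germline.append(GermlineVariant(v, draw_lineages()))

    n_somatic = cfg.n_somatic_snvs * cfg.hypermutation_multiplier
    somatic = [
        _random_snv(rng_var, f"s_snv{i + 1}", contig, pos, reference[contig][pos - 1], Origin.SOMATIC)
        for i, (contig, pos) in enumerate(
            _sample_positions(rng_var, somatic_windows, n_somatic, occupied)
        )
    ]
    return Fixture(reference=reference, germline=germline, somatic=somatic, targets=targets)


def forge_genomes(fixture: Fixture, assignment: SubcloneAssignment) -> GenomeSet:
    """Implant variants to build the two control haplotypes and all cancer genomes."""
    control: dict[str, HaplotypeGenome] = {}
    for lineage in LINEAGES:
        germ = [g.variant for g in fixture.germline if lineage in g.lineages]
        control[lineage] = implant_variants(fixture.reference, germ, label=f"control_{lineage}")
    tumor: dict[tuple[str, int], HaplotypeGenome] = {}
    for lineage in LINEAGES:
        germ = [g.variant for g in fixture.germline if lineage in g.lineages]
        for i in range(assignment.n_per_lineage):
            som = [v for v in fixture.somatic if (lineage, i) in assignment.members(v.id)]
            tumor[(lineage, i)] = implant_variants(
                fixture.reference, germ + som, label=f"cancer_{lineage}_{i}"
            )
    return GenomeSet(control=control, tumor=tumor)


def truth_for_sample(
    fixture: Fixture,
    assignment: SubcloneAssignment,
    sample: AdmixedSample | None,
) -> TruthSet:
    """Truth records with closed-form expected AFs for one sample.

    ``sample=None`` builds the control truth (germline only, AF 0.5/1.0).
    """
    records: list[TruthRecord] = []
    for g in fixture.germline:
        records.append(TruthRecord(variant=g.variant, expected_af=g.control_af))
    if sample is not None:
        for v in fixture.somatic:
            af = expected_af(v, assignment, sample, control_af=0.0)
            if af > 0:
                records.append(TruthRecord(variant=v, expected_af=af))
    label = sample.label if sample is not None else "control"
    return TruthSet(sample_label=label, records=records, targets=fixture.targets)


@dataclass
class RunResult:
    """Outputs of one full pipeline run."""

    outdir: Path
    manifest: dict
    eval_table: "object"  # pandas DataFrame
    curve: "object"


def run_all(cfg: RunConfig, outdir: str | Path) -> RunResult:
    """Execute the whole pipeline under one master seed.

    Simulates one control data set plus one tumor data set per admixture
    level, writes truth VCFs with the mixture sidecar, runs the baseline
    caller grid on the truth alignments, and scores somatic calls against
    the somatic truth (germline calls on the control against the germline
    truth).  A manifest records every derived seed and the config hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    contig_lengths = {f"chr{i + 1}": cfg.contig_length for i in range(cfg.n_contigs)}

    fixture = generate_fixture(cfg)
    fixture.write(outdir / "fixture")

    assignment = assign_subclones(
        fixture.somatic, cfg.n_per_lineage, cfg.inclusion_prob,
        seed=stage_seed(cfg.seed, "subclones"),
    )
    mixture = draw_mixture(cfg.n_per_lineage, seed=stage_seed(cfg.seed, "mixture"))
    samples = make_admixture_series(mixture, cfg.admixture_levels)
    genomes = forge_genomes(fixture, assignment)
    if cfg.write_genome_fastas:
        gdir = outdir / "genomes"
        gdir.mkdir(exist_ok=True)
        for key, g in genomes.all_genomes().items():
            write_fasta(g.sequences, gdir / (g.label + ".fa"))

    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.seed,
        "stage_seeds": {
            "subclones": stage_seed(cfg.seed, "subclones"),
            "mixture": stage_seed(cfg.seed, "mixture"),
        },
        "samples": [],
    }
    results: list[EvalResult] = []
    rows = []

    # control data set: simulated once, germline calling evaluated against it
    control_seed = stage_seed(cfg.seed, "reads/control")
    control_cfg = cfg.readsim_config(control_seed, run_id="control")
    control_run = readsim.simulate_reads(
        genomes, fixture.targets, control_cfg, sample=None,
        out_prefix=outdir / "control" / "control",
    )
    control_truth = truth_for_sample(fixture, assignment, None)
    write_truth_vcf(
        control_truth, outdir / "control" / "control_truth.vcf",
        contig_lengths, reference=fixture.reference,
    )
    germline_result = None
    if control_run.truth_sam is not None:
        calls = call_snvs(control_run.truth_sam, fixture.reference, cfg.caller_grid[0])
        write_callset_vcf(calls, outdir / "control" / "control_calls.vcf", contig_lengths)
        germline_result = compare_calls(
            calls, control_truth, regions=fixture.targets, origin=Origin.GERMLINE
        ).with_labels(tool="baseline", params=cfg.caller_grid[0].label, sample="control")
    manifest["samples"].append(
        {"label": "control", "admixture": None, "seed": control_seed,
         "n_fragments": control_run.n_fragments}
    )

    for sample in samples:
        sdir = outdir / sample.label
        seed = stage_seed(cfg.seed, f"reads/{sample.label}")
        rs_cfg = cfg.readsim_config(seed, run_id=sample.label)
        run = readsim.simulate_reads(
            genomes, fixture.targets, rs_cfg, sample=sample, out_prefix=sdir / sample.label
        )
        truth = truth_for_sample(fixture, assignment, sample)
        write_truth_vcf(
            truth, sdir / f"{sample.label}_truth.vcf", contig_lengths,
            reference=fixture.reference,
        )
        save_mixture_sidecar(
            sdir / f"{sample.label}_mixture.json",
            seed=cfg.seed, mixture=mixture, assignment=assignment, samples=[sample],
        )
        best_for_sample: list[EvalResult] = []
        if run.truth_sam is not None:
            for params in cfg.caller_grid:
                calls = call_snvs(run.truth_sam, fixture.reference, params)
                result = compare_calls(
                    calls, truth, regions=fixture.targets, origin=Origin.SOMATIC
                ).with_labels(
                    tool="baseline", params=params.label,
                    admixture=f"{sample.admixture:g}", sample=sample.label,
                )
                best_for_sample.append(result)
                rows.append(
                    {
                        "sample": sample.label, "admixture": sample.admixture,
                        "params": params.label, "tp": result.tp, "fp": result.fp,
                        "fn": result.fn, "sensitivity": result.sensitivity,
                        "precision": result.precision,
                    }
                )
            best = max(
                best_for_sample,
                key=lambda r: (r.harmonic_mean or -1, r.sensitivity or -1),
            )
            write_callset_vcf(
                call_snvs(run.truth_sam, fixture.reference, cfg.caller_grid[0]),
                sdir / f"{sample.label}_calls.vcf", contig_lengths,
            )
            results.append(best)
        manifest["samples"].append(
            {"label": sample.label, "admixture": sample.admixture, "seed": seed,
             "n_fragments": run.n_fragments}
        )

    import pandas as pd

    eval_table = pd.DataFrame(rows)
    eval_table.to_csv(outdir / "eval_results.tsv", sep="\t", index=False)
    curve = admixture_curve(results) if results else None
    if curve is not None:
        curve.to_csv(outdir / "admixture_curve.tsv", sep="\t", index=False)
    if germline_result is not None:
        manifest["germline_eval"] = {
            "tp": germline_result.tp, "fp": germline_result.fp, "fn": germline_result.fn,
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return RunResult(outdir=outdir, manifest=manifest, eval_table=eval_table, curve=curve)
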