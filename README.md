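# tumorbench

Simulate admixed, heterogeneous tumor sequencing data with an **exactly
known variant truth**, and score any SNV caller's output against that truth.

Clinical tumor samples are rarely pure: biopsies routinely carry 60–90%
non-cancerous (germline) material, and the tumor itself is a mixture of
subclones carrying different somatic mutation subsets. Both effects push
somatic variant allele frequencies (VAFs) toward zero and degrade the
sensitivity and precision of SNV calling. Benchmarking callers under these
conditions requires data where every true variant and its expected VAF are
known — which real tumors cannot provide. `tumorbench` builds such data:

1. **Genome forging** — implant germline SNVs/indels into a reference to
   create maternal and paternal control haplotypes, then implant random
   subsets of somatic SNVs to create a pool of haploid cancer genomes per
   lineage, with exact reference↔haplotype coordinate maps.
2. **Clone mixing** — combine the cancer genomes in randomized (flat
   Dirichlet) proportions and dilute with a fraction *a* of control
   material. Every variant's expected allele frequency is closed-form:

   &nbsp;&nbsp; AF(*a*) = (1 − *a*) · AF<sub>tumor</sub> + *a* · AF<sub>control</sub>,
   &nbsp; AF<sub>tumor</sub> = ½ Σ<sub>i∈carriers</sub> w<sup>M</sup><sub>i</sub> + ½ Σ<sub>j∈carriers</sub> w<sup>P</sup><sub>j</sub>

   A clonal somatic variant at 30% tumor VAF reads at just 3% in a 90%
   admixed biopsy.
3. **Read simulation** — targeted paired-end reads (exome preset: 100 bp
   reads, 300 ± 100 bp inserts, 70× median coverage; panel preset:
   200 ± 50 bp inserts, 520×) with substitution/insertion/deletion errors,
   plus *truth alignments* (SAM with exact positions and CIGARs), so no
   external aligner is needed.
4. **Truth sets** — VCF 4.2 with `ORIGIN`, `TAF` (true AF) and `VCLASS`
   INFO fields, AF histograms and variant-density tracks.
5. **Baseline calling** — a minimal pileup caller (depth/alt-count/VAF
   thresholds + one-sided binomial test against a background error rate) so
   the loop runs end-to-end with zero external tools.
6. **Evaluation** — TP/FP/FN against the truth, sensitivity TP/(TP+FN),
   precision TP/(TP+FP), harmonic-mean (F-measure) parameter selection,
   sensitivity-vs-admixture curves, and multi-caller concordance tables.
   Any VCF can be scored, not just the built-in caller's.

## Worked example

```python
from tumorbench import RunConfig, run_all

cfg = RunConfig(seed=1, contig_length=30_000, n_targets=2, target_length=8_000,
                target_flank=2_500, n_germline_snvs=150, n_germline_indels=15,
                n_somatic_snvs=50, coverage=40)
result = run_all(cfg, "runs/demo")
print(result.curve.to_string(index=False))
```

prints the best-parameter somatic calling performance across the ten-tumor
admixture series (0% to 90% normal contamination) plus one control:

```
 admixture  tp  fp  fn  sensitivity  precision
       0.0  50   0   0         1.00        1.0
       0.1  50   0   0         1.00        1.0
       0.2  47   0   3         0.94        1.0
       0.3  47   0   3         0.94        1.0
       0.4  45   0   5         0.90        1.0
       0.5  49   0   1         0.98        1.0
       0.6  44   0   6         0.88        1.0
       0.7  40   0  10         0.80        1.0
       0.8  33   0  17         0.66        1.0
       0.9  13   0  37         0.26        1.0
```

Each row scores the baseline caller against the 50 implanted somatic SNVs
at one admixture level: sensitivity collapses as admixture dilutes somatic
VAFs below the caller's detection thresholds (0.26 at 90% contamination),
while precision stays at 1.0 because truth alignments carry no mapping
artifacts. The run directory holds FASTQs, truth SAM/VCFs, callsets, the
mixture sidecar JSON and a manifest with every derived seed.

Scoring printed counts from any benchmark directly:

```python
from tumorbench import EvalResult, summarize
summarize(EvalResult(tp=56_869, fp=24, fn=2_795))
# {'sensitivity': '95.3%', 'precision': '100.0%', 'harmonic_mean': '97.6%'}
```

The same operations are available from the shell:

```
tumorbench run-all --seed 1 --out runs/demo
tumorbench call --alignments runs/demo/tumor_a50/tumor_a50_truth.sam \
                --reference runs/demo/fixture/reference.fa --out calls.vcf
tumorbench eval --calls calls.vcf \
                --truth runs/demo/tumor_a50/tumor_a50_truth.vcf \
                --regions runs/demo/fixture/targets.bed --origin somatic
```

See `tumorbench --help` for the full list (`fixture`, `forge`, `mix`,
`simreads`, `call`, `sweep`, `eval`, `concordance`, `curve`, `run-all`).

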