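# diploidsim

A diploid-genome variant simulator and short-read generator, with a
truth-set rediscovery evaluator — for developers of variant-calling
pipelines who need reads with a *known* answer key.

`diploidsim` spikes the three common classes of germline variation into a
reference genome:

* **SNVs**, placed by a Gaussian random walk with mean spacing
  `D_avg = clamp(1/rate, 300, 1000)` bases, a 15 bp minimum-spacing
  filter, and N-region exclusion. The alternate base follows a
  transition/transversion model: a transition (A↔G, C↔T) is drawn with
  probability `R/(R+1)` so the expected Ti/Tv count ratio is exactly `R`
  (default `R = 2.1`, the genome-wide human value; `R = 0.5` is uniform
  random substitution). 20% of SNVs are heterozygous by default.
* **Indels** (1–100 bp) in four categories — 30% single-base, 20%
  tandem-motif repeat expansions, 49% mid-size (2–20 bp), 1% long
  (21–100 bp) — with 5% over-generation before duplicate removal,
  insertion:deletion and het:hom both 1:1, and two allele-specific truth
  logs.
* **Allele-specific CNVs** with user-defined count and size range, placed
  by rejection sampling against chromosome boundaries, other CNVs, and
  indel breakpoints; gains are tandem duplications (per-allele copy
  number 0, 1, or 2–4).

The two mutated allele sequences are then realized and sequenced in
silico: paired-end (or single-end) reads at a requested fold coverage,
with inner-distance `Normal(insert_mean, insert_sd)` fragment geometry,
base qualities drawn per cycle from an **empirical quality profile**
trained on real FASTQ, and substitution errors injected at the Phred rate
`10^(-q/10)`. Read names encode their true origin, so depth and error
properties can be checked without an aligner. Output bytes are invariant
to the worker count (1–4).

See `docs/methods.md` for the full model description and design choices.

## Worked example

Everything runs on synthetic fixtures — no downloads. Generate a 2 Mb
reference (2% N-runs) and a training FASTQ pair, train a quality profile,
and run the full pipeline from a YAML config:

```sh
diploidsim make-fixtures --outdir fixtures --chroms 1 \
    --chrom-length 2000000 --n-run-fraction 0.02 \
    --training-reads 20000 --seed 7
diploidsim build-profile --fastq-r1 fixtures/training_1.fastq \
    --fastq-r2 fixtures/training_2.fastq --out profile.txt

cat > sim.yaml <<'EOF'
reference: fixtures/reference.fasta
outdir: out
seed: 7
snv: {snv_rate: 0.001, titv_ratio: 2.1, het_fraction: 0.20}
indel: {n_indels: 2000}
cnv: {n_cnvs: 10, size_min: 5000, size_max: 20000}
reads: {coverage: 15, insert_mean: 200, insert_sd: 20, workers: 4}
profile_path: profile.txt
EOF
diploidsim simulate --config sim.yaml
```

which prints

```
snvs=1958 indels=2000 cnvs=10 pairs=300620 -> out
```

— 1958 SNVs (≈ 2 Mb / 1000 bases mean spacing, minus N-region losses),
exactly the 2000 requested indels and 10 CNVs, and 300,620 read pairs
(15× coverage of the ≈ 4.01 Mb diploid genome at 2 × 100 bp per pair).
`out/` now holds the truth logs (`snv_truth.tsv`, VCF renderings, two
allele-specific indel logs, a CNV table plus BED), the realized allele
FASTA, the paired FASTQ, and a provenance manifest. The truth logs look
like:

```
chrom  pos   ref  alt  zygosity  allele  ti_or_tv
chr1   825   A    G    hom       both    ti
chr1   1650  A    G    het       1       ti
```

To score a variant caller, feed its VCF to the evaluator (here scoring
the simulator's own truth VCF as a sanity check, which must be 100%):

```sh
diploidsim evaluate --snv-log out/snv_truth.tsv --vcf out/snv_truth.vcf
```

```
rediscovery report (indel position tolerance 10 bp)
  snv                  1958/1958     100.00%
  snv_het               397/397      100.00%
  snv_hom              1561/1561     100.00%
  ...
```

The same report against `out/indel_truth.vcf` with the indel logs shows
`indel 2000/2000 100.00%`, broken down into the 1–6, 7–10, 11–20 and
21–100 bp size bins. With a real caller's VCF these percentages become
the caller's rediscovery rates; `--tolerance` controls how far a called
indel may sit from the truth position (default 10 bp).

Every stage is also callable as a library (`diploidsim.simulate_snvs`,
`simulate_indels`, `simulate_cnvs`, `apply_variants`, `generate_reads`,
`match_variants`, ...), and each CLI subcommand runs independently.

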