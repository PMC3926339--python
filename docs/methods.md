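# Methods

`diploidsim` simulates the three common classes of germline variation —
single-nucleotide variants (SNVs), short insertions/deletions (indels,
1–100 bp) and copy-number variants (CNVs) — into a reference genome,
realizes the two resulting allele sequences of a diploid individual, and
generates Illumina-like short reads whose base qualities follow an
empirical per-cycle profile. A companion evaluator measures how much of
the simulated truth a variant caller rediscovers. This note records the
model, its assumptions, and the design choices made where the design was
genuinely open.

## Reference model and coordinates

A reference genome is a set of named chromosome sequences over
{A, C, G, T, N}. On input, lowercase letters are uppercased and every
non-ACGT code (including IUPAC ambiguity codes such as R/Y/S/W) collapses
to N, since an ambiguous base carries no usable identity for variant
placement. Maximal runs of N ("N-regions", e.g. assembly gaps or
centromeres) are precomputed as sorted disjoint intervals and excluded
from variant placement throughout.

Internally all coordinates are 0-based half-open. Emitted truth logs are
1-based inclusive (VCF-adjacent), except the BED rendering of CNVs, which
is 0-based half-open as BED requires. Insertions anchor AFTER their
stated reference base, matching VCF left-anchoring, so truth logs and
caller VCFs compare without ambiguity.

## SNV simulation

The SNV module treats substitutions as independent and random, placed by
a random walk along each chromosome:

* **Spacing.** The mean inter-SNV distance is `D_avg = 1/rate`, clamped
  to [300, 1000] bases — the empirical range of human SNV density (about
  one SNV per 300–1000 bases). Each successive gap is drawn from
  `Normal(D_avg, sd)`, rounded, and floored at the minimum spacing. The
  distribution's standard deviation is not dictated by the biology; the
  default is `D_avg/4`, which keeps gaps comfortably positive while
  spreading placements, and it is exposed as `spacing_sd`. Because the
  clamp binds at extreme rates, the realized rate can deviate from the
  requested one; this is documented behavior, not corrected.
* **Filters.** A positional filter drops any SNV closer than 15 bases
  (strictly less; exactly 15 is kept) to the last kept SNV, scanning left
  to right. SNVs landing in N-regions are discarded, not relocated.
* **Substitution model.** With transition/transversion ratio `R`
  (default 2.1, the genome-wide human value), the alternate base is the
  unique transition partner (A↔G, C↔T) with probability `R/(R+1)` and
  otherwise one of the two transversion partners uniformly, which makes
  the expected transition:transversion count ratio exactly `R`. Setting
  `R = 0.5` reproduces uniform random substitution (each of the three
  alternatives equally likely), the expected signature of systematic
  noise rather than biology.
* **Zygosity.** Each SNV is heterozygous with probability 0.20 by
  default; heterozygous SNVs go to allele 1 or 2 by a fair coin (the
  allele choice is not biologically constrained, so a fair coin is the
  natural default).

The SNV count is emergent from the spacing walk rather than precomputed:
an `L`-base chromosome yields about `L/D_avg` SNVs before filtering.

## Indel simulation

Indels are simulated in four categories totalling 100%: 30% single-base,
20% repeat expansions, 49% mid-size (2–20 bp), 1% long (21–100 bp).
Counts per category come from largest-remainder apportionment, so they
are exact at any n. Because duplicate and unplaceable positions are
removed later, 5% extra candidates are generated up front
(`ceil(n × 1.05)`), and after coordinate sorting, duplicate-position
removal and span-overlap removal, the list is trimmed from the tail to
the requested n. Trimming from the sorted tail (rather than randomly)
keeps the output deterministic and order-stable.

Placement is uniform: a length-weighted chromosome choice, then a uniform
position, redrawn while the anchor or (for deletions) the deleted span
touches an N-region; a bounded redraw budget turns an effectively all-N
chromosome into a clear error. Mid and long lengths are uniform on their
ranges. Insertion content is uniform random ACGT; deletion content is
read from the reference.

**Repeat expansions** are realized as tandem-motif insertions: the motif
of 1–5 bases immediately left of the anchor is inserted again as 2–4
copies (`motif × copies`). The motif and copy-count ranges are exposed as
configuration. A motif×copies product above 20 can make a long repeat
expansion, consistent with "long indels including repeat expansions".

**Insertion:deletion balance.** Repeat expansions are structurally
insertions. To keep the OVERALL insertion:deletion ratio at the
configured 1:1, the insertion coin for the other three categories is
compensated: `P(insertion | other category) = (0.5 − 0.20)/0.80 = 0.375`
at defaults. Without this compensation the overall ratio would be 1.5,
contradicting the 1:1 ratio the simulation is meant to maintain. (If the
user sets an overall insertion fraction below the repeat-expansion
fraction, the coin clips at 0 and the target is unreachable; the realized
ratio then floors at the repeat-expansion fraction.)

Heterozygous:homozygous is 1:1 by default, assigned after deduplication,
with fair-coin allele choice; the truth set is written as two
allele-specific logs reflecting the bi-allelic model (homozygous records
appear in both).

The 1–10/11–20/21–100 bp short/medium/large tripartition is a different
partition from the four simulation categories; the package simulates the
four-category split and reports the tripartition in summaries
(`IndelRecord.size_class`) and evaluation bins.

## CNV simulation

CNV size and location are generated dynamically by rejection sampling.
Each candidate draws a uniform size in the user's [size_min, size_max], a
uniform start on a length-weighted chromosome, gain vs loss with the
configured probability (default 0.5), a copy number uniform in
[2, max_copy_number] for gains, and the affected allele(s) — a fair coin
per allele with at least one affected, unless forced to one or both.
A candidate is accepted only if:

1. its span lies within the chromosome on BOTH alleles — on an allele
   whose indels shorten the chromosome, the usable span shrinks by the
   net length deficit;
2. it does not overlap any accepted CNV (disjointness only; no minimum
   gap is enforced);
3. neither boundary falls inside a simulated indel's span on either
   allele, which would make the breakpoint ill-defined.

A retry budget (default `1000 × n_cnvs` candidates) guarantees
termination; exhausting it raises an error stating how many CNVs were
placed. Copy numbers are stored per allele with 1 meaning unchanged, so
the tabular truth file fully determines both allele sequences.

**Gain realization is tandem duplication**: the (point-variant-mutated)
span appears as `copy_number` adjacent copies in the allele sequence;
losses remove the span entirely on affected alleles. Tandem realization
is the simplest mechanism that produces the correct read-depth signal for
depth-based CNV callers, which is the evaluation use case; dispersed
duplications, inversions and translocations are out of scope.

## Allele realization

`apply_variants` turns the reference plus the three truth sets into one
allele's sequence and a monotone reference→allele coordinate map
(positions inside deleted segments map to the deletion's left edge).
Homozygous variants apply to both alleles, heterozygous ones only to
their assigned allele. Because the three simulators place variants
independently, cross-class collisions are possible and are resolved
explicitly:

* a point variant strictly inside a CNV span is applied inside the copied
  segment, so every tandem copy carries it (exact for tandem gains; for
  losses the nested variant vanishes with the span);
* an SNV inside a deleted span is a no-op on that allele — substituting a
  base that the deletion removes is equivalent to the deletion alone.
  The SNV stays in the truth log; on that allele it is simply invisible,
  as it would be to any caller;
* same-class overlaps (which upstream simulation rules out) raise an
  error rather than being silently resolved.

## Quality profile and read generation

The error model is a per-mate, per-cycle empirical distribution over
Phred scores 0–41, trained by histogramming a Sanger-encoded (+33)
training FASTQ pair, typically 100 bp Illumina data. Scores above 41
after decoding indicate a non-Sanger encoding and abort training with the
offending record named. Reads longer than the profile length are
truncated; shorter ones are skipped and counted. Quality draws across
cycles are modeled as independent — real Illumina qualities are
autocorrelated along the read; this model reproduces the marginal
per-cycle distributions (the property the training/simulated comparison
checks) but not runs of low quality. Any other platform is supported by
training a profile from that platform's FASTQ.

Read generation draws fragments from the realized allele sequences,
sampled length-proportionally across chromosomes and alleles, so allele
fraction and CNV depth signals need no special handling. "Insert size"
is taken literally as the inner distance (gap between mates):
`fragment = 2 × read_length + round(Normal(insert_mean, insert_sd))`,
floored at zero inner distance, with bounded redraws for fragments that
do not fit. Mate 1 is the fragment's first `read_length` bases and mate 2
the reverse complement of its last `read_length` bases; a fair-coin
strand flip (default on) balances which mate sees which strand. Each mate
gets an independently sampled quality string, then substitution errors:
each cycle mutates to one of the other three bases with probability
`10^(-q/10)`. N bases pass through unmutated. Errors are
substitution-only — no sequencing-indel, adapter, optical-duplicate or
GC-bias artifacts.

Read names encode ground truth (`sim|chrom|allele|start|end|pair-index`,
allele coordinates, 1-based inclusive), so coverage, depth profiles and
error rates can be verified without an aligner.

The read count is `round(coverage × total_allele_length / (2 ×
read_length))` pairs (without the 2 for single-end), where
`total_allele_length` sums both alleles — coverage is measured against
the diploid genome. **Parallel contract:** the workload is always split
into four fixed chunks (matching the quad-core design target), each with
an independent stream spawned from the seed; chunk outputs are
concatenated in order, so output bytes are identical for any worker
count, and `workers` only sets how many chunks run concurrently.

## Rediscovery evaluation

The evaluator compares a caller's VCF against the truth logs. SNVs match
on exact chromosome, position and alternate base. Indels match on
chromosome, kind and exact length, with positions allowed to differ by a
tolerance (default 10 bases) to absorb left/right-alignment ambiguity;
some callers merge nearby indels over windows as wide as 40 bases, so the
tolerance is a flag, not a constant. Each truth record matches at most
one call, greedily by nearest position. Results are stratified by type,
SNV zygosity, and indel size bins 1–6, 7–10, 11–20 and 21–100 bp, and
reported as percentages of truth rediscovered. No specific matching rule
is standard in the field; this one is declared rather than inferred.

## Synthetic fixtures

All tests and the acceptance analysis run on synthetic inputs from
`diploidsim.fixtures`: a random ACGT genome with embedded N-runs
(default 5% of the genome in 500 bp runs), and a training FASTQ pair
drawn from a KNOWN per-cycle quality distribution — discretized clipped
Gaussians whose mean decays linearly from Q38 to Q30 along the read
(mate 2 two points lower), sd 3 — so profile training error is measurable
against an exact truth. These fixtures have uniform base composition, no
repeats beyond chance, and independent quality cycles; tests on them
establish the simulator's own contracts, not claims about real genomes
or instruments.

## Problem sizes and statistical tolerances

Statistical checks use three-standard-error bands (binomial or
multinomial; delta method for ratio statistics), at the sizes where the
checked fraction is informative: ≥100,000 SNVs (accumulated over repeat
runs on a 10 Mb fixture at the default rate), 10,000 indels for category
fractions, 100,000 indels (across seeds) for the 1:1 ratios, and 100,000
read pairs for quality/error distribution checks (per-cycle
total-variation distance < 0.02 against the profile). Determinism
contracts are asserted as byte-identity of output files under a fixed
seed. All randomness flows from `numpy.random.Generator` seeded
explicitly; a single pipeline seed derives per-module seeds via SHA-256
so stages are independently reproducible.

## Known limitations

* No mutation-signature or context-dependent substitution model; no
  population allele frequencies.
* Indel placement is uniform (no hotspots or microhomology).
* CNVs are tandem-only; no minimum inter-CNV gap beyond disjointness.
* Quality cycles independent; substitution-only sequencing errors.
* The evaluator does not run aligners or callers; absolute rediscovery
  percentages depend on the external tools used and are not reproduced
  here.
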