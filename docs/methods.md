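# Methods

This note documents the models, estimators, and numerical choices behind
`strainscope`, and what the synthetic benchmarks do and do not demonstrate.

## Overview

`strainscope` profiles bacterial communities from single-end shotgun reads in
three passes over progressively larger reference sets, then tracks strains
between hosts:

1. **Species abundance** — reads are recruited to a database of 15 universal
   single-copy gene (USCG) families, one sequence per species per family.
   Because these genes occur exactly once per genome, read depth on them
   estimates whole-genome fold coverage.
2. **Gene content** — for species with sufficient coverage (>1×), reads are
   mapped to the species pan-genome (gene clusters at 99% identity) to
   estimate per-gene coverage, copy number, and presence/absence.
3. **Core-genome SNPs** — for species with high coverage (>10×), reads are
   mapped end-to-end to a representative genome; quality-filtered pileups
   give per-site allele counts, a data-defined core genome, and cross-sample
   SNP matrices.
4. **Strain tracking** — rare alleles private to one host ("marker alleles")
   fingerprint strains; the percentage of a donor's markers recovered in a
   recipient classifies transmission.

The species database itself is built by average-linkage clustering of genomes
on marker-gene distances, validated against average nucleotide identity (ANI).

## Species delineation

For each pair of genomes and each of 30 universal marker-gene families we
compute percent identity over the best alignment, discarding alignments that
cover <70% of either sequence, and convert to a distance
`D = (100 − P) / 100`. Pairwise distances are averaged over families (masked
entries excluded from the mean; pairs with no defined family distance are
treated as distance 1.0, i.e. never mergeable on their own — a conservative
stand-in for the sparse-graph behaviour of out-of-memory UPGMA
implementations). Genomes are clustered by exact in-memory UPGMA
(`scipy.cluster.hierarchy`, average linkage) and the tree is cut at distance
**0.035** (96.5% marker identity), the cutoff at which marker clusters agree
best with the 95% genome-wide ANI species definition. Cluster ids are
assigned in order of each cluster's lexicographically smallest member, which
makes the labels invariant to input order. The species representative is the
member with maximal mean marker identity to the rest; all argmax/mode ties
break lexicographically.

Pairwise identity uses edlib infix alignment of the shorter sequence against
the longer (whole query vs. best substring). For near-full-length marker
homologs this is equivalent to the best local alignment while remaining
linear-time; the 70% mutual-coverage filter is applied to both sequences.

## Read mapping

The built-in mapper is seed-and-extend: exact 15-mers sampled every 10 bases
of the read (plus the final position) vote for (target, diagonal) candidates
on both strands; the best-voted diagonal per target is extended. Extension
prefers the **gapless** placement on the seeded diagonal and only accepts a
gapped (edlib) alignment when it saves at least two errors — the affine-gap
convention that point differences are substitutions, not spurious indel
pairs. This keeps pileup coordinates exact for substitution-only variation.

Scoring is +1 per match, −2 per error column. MAPQ is deliberately
two-valued: 60 when the best target beats the runner-up by at least one
mismatch (3 score units), else 3. The default MAPQ ≥ 20 filter therefore
implements "discard non-unique best hits" exactly, while the species
profiler, which runs before that filter, sees the tie list and redistributes
tied reads fractionally. Repeated placements *within* one target do not
lower MAPQ (the synthetic genomes have no internal repeats; a repeat-aware
MAPQ is out of scope).

Two modes mirror the two downstream uses: `local` (genes) soft-clips read
ends hanging off a target for free; `global` (genomes) only considers
placements covering the full read. Read-level filters — percent identity
≥ 94, aligned fraction ≥ 0.70, MAPQ ≥ 20, mean base quality ≥ 20 — are
applied at the gene-content and SNP stages. The marker stage applies only
the 70% read-coverage filter plus the per-family identity cutoff
(tuned cutoffs range 94.5–98%; 95% default for untuned families).

## Species abundance

Species coverage is pooled aligned base pairs on the species' markers
divided by total marker length, so partial (clipped) alignments contribute
proportionally; a per-family-median variant is available in configuration.
Reads whose best hits tie across species are split fractionally in
proportion to each tied species' uniquely-mapped read counts (uniform when
no tied species has unique reads) — a deterministic, expectation-equivalent
alternative to random assignment. Relative abundance is each species' share
of summed coverage; abundances over detected species always sum to 1.
Boundary clipping loses a little depth at gene edges, so coverage is
slightly underestimated while relative abundances are unaffected — the
benchmarks reproduce exactly this behaviour.

Total community coverage (the denominator of the database-coverage
statistic) uses one of two documented simplified estimators: re-mapping with
all family cutoffs relaxed to 75% identity and taking the median over
families of aligned bp / mean family gene length, or total read bp divided
by a supplied average genome size. Both are flagged as simplified in their
output notes.

## Gene content

Cluster coverage is aligned bp / centroid length over filtered alignments.
Copy number divides each coverage by the **median of the 15 USCG family
coverages** from the same mapping pass; families with no mapped reads count
as zero, so a species with fewer than 8 detected USCG families gets a zero
normalizer and is flagged unusable rather than producing unstable ratios.
Computing the normalizer from the same alignment pass (USCG clusters are
pan-genome members) means normalizer and gene coverages share mapping
biases, which is what keeps copy numbers calibrated. Presence is called at
copy number ≥ **0.35** (below 0.35 is absent; the bound is closed above).

A caveat quantified during development: when a USCG family fragments into
several 99% clusters (strains >1% apart), reads falling in locally identical
stretches of two split centroids tie and are discarded by the MAPQ rule,
deflating that family's summed coverage by up to tens of percent and, through
the lowered median, inflating unfragmented families. The median normalizer
absorbs typical losses and presence calls are robust to it (the benchmark's
balanced accuracy is ≥0.96 throughout), but per-family copy numbers should
not be over-interpreted near fragmented families. Against an unfragmented
(single-genome) pan-genome, USCG copy numbers are 1 ± 0.2 at 40× with 500-bp
genes; at lower depth, positional sampling noise alone exceeds that band.

Coverages can be aggregated onto coarser families (75–95% identity,
re-clustering centroids greedily) by summation, which conserves total
coverage; copy number and presence are then recomputed on aggregated values.

## Core-genome SNPs

Pileups count substitution columns only (indels and N bases are ignored;
the variation model is substitutions) from bases with quality ≥ 30, so all
depths are effective, post-filter depths. A site is core when depth is
strictly greater than 10 in at least 95% of samples; both parameters are
configurable and the core site set shrinks monotonically as either is
raised. Cross-sample matrices define the major/minor allele from pooled
counts; per-sample minor-allele frequencies are NaN (not 0) where a sample
has no coverage. Consensus SNP calls flag sites whose argmax allele differs
from the reference; ties produce no call (reference retained). Exported
site tables and VCFs are 1-based; everything internal is 0-based half-open.

With error-free reads and a representative of identical gene content,
consensus calls reproduce the true difference set exactly (FDR 0, misses
only coverage gaps). When strain and representative differ in gene content,
reads spanning a shared/absent gene junction can pass the identity filter
with a few overhanging bases and miscount 1–2 junction bases — the same
class of artifact a whole-genome-alignment truth would score as false
positives. The SNP benchmark (20×, 0.5% read error, ~1% true divergence)
bounds the consequence: TPR ≥ 0.9, FDR ≤ 0.05.

## Strain tracking

An allele is present in a sample when supported by ≥3 reads and ≥10% of the
site's (quality-filtered) depth — thresholds chosen to suppress sequencing
errors and unstable low-frequency variants. Only sites with exactly two
alleles present cohort-wide are considered; "biallelic" is evaluated on
post-threshold presence, not raw counts, so singleton errors cannot
disqualify a site. A marker allele for a unit (an individual, or a
mother–infant pair during discovery) is present in ≥1 of the unit's samples
and no sample outside it; privacy is monotone — growing the cohort can only
shrink marker sets. Sharing is the percentage of the donor unit's markers
found in the recipient sample; the denominator is all donor markers (the
>10× coverage gate on both samples makes uncovered marker sites rare; a
recipient-covered-only denominator is available as an option). Units with
<10 markers are excluded. Transmission is strictly >5% sharing, binary.

## The simulator

The generator emulates the validation design of the published benchmarks:
communities of 20 organisms with exponentially decreasing abundance
(a_i ∝ 2^(−i): 50%, 25%, 12.5%, 6.25%, …; the base-½ series is inferred
from the printed sequence), 100-bp single-end reads at 100× total genome
coverage, ~1% substitution error.

Synthetic genomes are concatenations of genes drawn from a per-species pool
of 60 × 500 bp (42 core + 18 accessory, i.e. a 30% accessory fraction).
Strains carry all core genes plus each accessory gene with probability 0.5,
and mutate from the species ancestor at a rate drawn uniformly from
[0, 1%], bounding pairwise within-species divergence at ≤2%. Species
ancestors mutate from a shared base pool at 5% per species (~10% pairwise
between-species divergence ≥ the 5% floor; marker identity ≥98% within,
<95% between species — verified on output). The first 30 core genes are the
clustering marker panel; the first 15 of those are the single-copy
abundance panel. Substitution-only mutation keeps strains colinear gene by
gene, making gene-content and SNP ground truth exact. Qualities are uniform
in [30, 40] for correct bases and [2, 35] for errored bases, so both the
mean-quality (20) and per-base (30) filters have bite. Read counts are
Poisson around coverage × length / read length; per-genome coverage is
total coverage × abundance. All randomness flows through numpy Generators
seeded from one integer; a fixed seed reproduces every byte.

What the simulator does **not** emulate: indels, GC/coverage bias,
duplicates, quality decay along the read, chimeras, contamination, and real
inter-gene synteny (genomes are gene concatenations with no intergenic
sequence). Passing benchmarks therefore demonstrate the correctness of the
estimators under the stated error model and coverage regimes, not
robustness to platform artifacts; the published validation used real
Illumina reads for that purpose.

## Benchmark problem sizes

The benchmarks run at desk scale, preserving the coverage regimes that
drive the published figures while completing in minutes on one core:

- **Abundance recovery** — 20 communities × 20 species (one strain each),
  exponential abundances from 50× down to ~10⁻⁴×, 1% error; pooled r²
  between true and estimated relative abundance (400 pairs).
- **Gene content** — 3 communities × 8 species × 3 strains, exponential
  abundances spanning ~50× to 0.4×; balanced accuracy of presence calls at
  0.35 for species >3× true coverage, plus a 0.05–0.95 cutoff sweep.
- **Species delineation** — 200 genomes in 25 species (8 strains each);
  pairwise F1 at cutoff 0.035 over all 19,900 genome pairs, with UPGMA
  checked against exhaustive agglomeration on ≤8-genome matrices.
- **Transmission controls** — one species, 30 units with distinct strains
  plus a held-out representative, two independent 20× read sets per unit;
  sensitivity over replicate pairs, specificity over all unrelated pairs.
- **SNP calling** — one strain at 20×, 0.5% error, ~1% divergence from its
  representative; consensus-call TPR and FDR against the exact truth set.

## Known limitations

- Single-end reads only; no paired-end rescue (the pipeline logic never
  requires pairing).
- No indel handling anywhere: the mapper penalizes gaps, the pileup ignores
  them, the simulator does not generate them.
- The MAPQ model is two-valued by contract and not calibrated for repeats
  within a target.
- The total-coverage estimators are simplified single-pass stand-ins for a
  full average-genome-size estimation and are flagged as such in output.
- Marker-allele discovery treats all samples of an individual as one unit;
  time-resolved within-host dynamics are out of scope.
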