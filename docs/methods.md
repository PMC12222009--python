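# Methods

## The Canina meiosis model

A karyotype is a multiset of chromosome copies tagged by linkage group
(1–7), subgenome and, on the duplicated subgenome, haplotype.  Male
meiosis returns one bivalent-subgenome haplotype per linkage group,
chosen independently and uniformly (seeded); female meiosis returns
the same plus every univalent.  Fertilization takes the union and
re-derives the offspring's bivalent subgenome as the unique
twice-present one, raising an error if that subgenome is not unique.
Seed tissues follow double fertilization: embryo = egg + sperm ploidy,
endosperm = 2·egg + sperm (two polar nuclei and one sperm); the ratio
is kept as an exact rational.

Deliberate simplifications: recombination within a bivalent is
represented only as the per-linkage-group haplotype choice — no
crossover breakpoints — because no quantity exposed by the model
depends on intra-chromosomal exchange.  Univalent
chromatid lagging and elimination are represented only by their
outcome (univalents never enter pollen).  Pollen viability (~20%
observed in nature) is available as an optional rejection filter
(`viable_pollen_filter`), a measured parameter rather than a derived
quantity.  Rare recombination between the two bivalent haplotypes is
not modelled.

## The synthetic genome generator

Each linkage group has a random ancestor sequence; every chromosome
copy is the ancestor plus i.i.d. substitutions (no indels by default).
The duplicated subgenome's haplotypes share a subgenome-level base
genome and then diverge by half the haplotype divergence each, giving
h1/h2 identity ≈ 1 − 0.005 = 99.5%; single-copy subgenomes diverge
independently (defaults S1 0.010, S2 0.015, R3 0.018, R4 0.022 vs the
ancestor), placing all pairwise identities in ~95.5–97.5%, inside the
observed 95–98% band.  Identity is measured over non-repeat space
(`pairwise_identity`), since tandem-array space is not meaningfully
column-alignable between subgenomes; at zero divergence the mutable
genome of all five copies is identical.

Centromeres are composed from per-subgenome recipes: CANR4 satellite
arrays (a ~160 bp synthetic monomer embedding the published 22-bp
probe — the real monomer/HOR structure is a stand-in), ATHILA
elements (LTR–internal–LTR, 400+800+400 bp), cenLTR tandem arrays (an
LTR-derived ~1.5 kb monomer, within the observed 1,425–2,596 bp
range) and random spacer.  Defaults mirror the bimodal pattern:
satellite-based centromeres on the univalent S2/R3 subgenomes,
retroelement-based on S1/R4, a cenLTR array on R4 of linkage group 1,
and minority ATHILA-interrupted CANR4 arrays on S1 linkage groups
2/4/5.  Each ATHILA's two LTRs independently accumulate
Poisson(r·T·L) substitutions for a planted age T (defaults: 0.7 Ma on
S1/S2/R3, 1.2 Ma on R4, r = 1.3×10⁻⁸/site/year), so paired-LTR
divergence carries the age signal the dating module recovers.  SCO
loci (500 bp) are placed on the ancestor frame away from the
centromere zone, so each exists exactly once per chromosome copy at
shared coordinates; the ancestor segment serves as the external
target/reference sequence.

Scale: chromosomes default to 1 Mb (real rose chromosomes are
~70 Mb) with 80 kb base centromeres, keeping the centromere at
~6–15% of the chromosome — deliberately close in proportion to the
real ~3–4% so that chromosome-wise statistics behave like the real
data; all sizes are configurable, and multi-seed tests use 100–400 kb
chromosomes with proportionally scaled centromeres as a problem-size
choice.  Two bundles generated with a shared `ancestor_seed` live on
one coordinate frame and differ only in substitutions and element
composition — the synthetic analogue of two related accessions, used
for parent/hybrid SNP analyses.

Reads are uniform-start, substitution-only (default error rate
0.002), drawn from the whole genome, from both bivalent haplotypes
(pollen pools many nuclei, so both haplotypes appear across reads),
or per a dosage vector; `regions` restricts sampling to intervals
(target-enrichment mode).  Read count per chromosome is deterministic
(coverage·length/read length), so realized coverage matches the
request closely.  Quality strings are constant; quality modelling is
out of scope.

ChIP tracks are emitted depth-normalized (baseline 1), mirroring
per-library read-count scaling, so log₂(CENH3/H3) is ~0 outside
centromeres and ~log₂(snr) inside; with composition scaling the
per-chromosome enrichment factor grows with the truth centromere's
CANR4 fraction and is boosted for cenLTR arrays, reproducing the
positive satellite–CENH3 association.  Window noise is multiplicative
log-normal, default σ = 0.15 per 10 kb window (appropriate for deep
coverage; the noiseless case with scaling off gives exactly
log₂ snr inside / 0 outside).  Methylation tables carry CpG/CHG/CHH
percentages per window, elevated at centromeres with a dip inside
CANR4 arrays that brings them below the chromosome-arm level.

What the generator does **not** emulate: indels and structural
variants, mapping biases from repeat families outside centromeres,
GC/coverage waves, chimeric or duplicate reads, Hi-C structure.
Passing tests therefore demonstrate the correctness of the inference
logic under the stated statistical structure, not robustness to every
real-data artefact.

## Pollen-SCO inference

Back-mapping assigns reads to targets by exact 21-mers (three anchor
positions, both strands); per-column base counts give a majority
consensus wherever depth ≥ 5, reference base otherwise
(substitution-only, length preserved) — a simplification of
genotype-caller-based consensus building that suffices because the
consensus is only used as a per-sample mapping query.  Consensus
sequences map to the genome through a seeded k-mer-anchor index
(k = 15, stride 4) with banded edit-distance scoring (edlib, infix
mode); placements within an edit-distance margin of the best
(default max(3, 1.2% of query length) — between haplotype-level and
subgenome-level divergence) are reported as XA-style alternatives.
The default retention rule keeps records with exactly one alternative
(the partner haplotype of a bivalent-derived locus); `<=1` and `any`
are selectable because the direction of the published filter is
ambiguous.  The bivalent call takes the subgenome with the maximal
aggregate count; it is confident iff its lead over the runner-up is
at least half the total (configurable), with lexicographic,
ambiguous-status tie-breaks.  As divergence between subgenomes
approaches zero the alternative-hit count rises from 1 toward the
copy number and retained records vanish — the call degrades to
ambiguous/no-call rather than to a wrong confident call (the
zero-divergence unit test pins this limit).

## Hybrid dosage

Window coverage is exact mean per-base depth per tiling window
(difference-array accumulation).  Copy number is the nearest integer
of the ratio of per-subgenome median window depth to the median over
baseline (one-copy) subgenomes; a call is flagged non-confident
beyond 0.25 from an integer.  Windows with > 50% repeat-annotation
overlap are excluded from medians.  No HMM or segmentation: medians
on a one-copy-per-subgenome reference are robust at the coverages of
interest (recovery is exact at ≥ 20×; at ~5× the ratio estimates
become unstable and the confidence flag starts to trip — reported
behaviour, not an assertion).  Parent-unique SNPs are the symmetric
difference of parental variant sets (position + allele identity);
hybrid contribution counts an allele as observed when ≥ 1 read
carries it at a site reaching the minimum depth.

## Centromere analysis

Enrichment is log₂((CENH3 + pc)/(H3 + pc)) over matched windows.
Because the generator emits depth-normalized tracks, no additional
mass rescaling is applied by default; equal-total-mass rescaling is
available (`normalize="mass"`) for raw-count inputs — it shifts the
log-ratio by a constant and leaves the mean + k·σ caller invariant.
The caller thresholds windows at the chromosome-wise mean + 2σ,
merges above-threshold runs separated by < 100 kb, and spans the
merged cluster containing the global maximum ("between the outermost
peaks"); flat tracks yield no call.  CENH3 abundance sums
positive-only log₂ values over the interval by default (raw summing
selectable, since the published definition is ambiguous).  Repeat
composition merges same-family features before clipping, making bp
fields invariant to annotation splitting; ATHILA_LTR features count
toward ATHILA.  Classification: CANR4-based if satellite ≥ 30% of
the interval, else cenLTR-based if the LTR-derived array ≥ 50 kb,
else ATHILA-based if ≥ 20%, else mixed — thresholds configurable and
echoed in run logs.  The regression is ordinary least squares of
abundance on CANR4 bp (scipy) with Spearman's rank correlation, on
unscaled abundances; [0,1] scaling is for plotting only.  Metaplots
scale each arm telomere→centromere (enrichment argmax) to [0, 1],
bin, average p/q arms within a chromosome and then across a
subgenome's chromosomes, and min–max scale all signals to [0, 1] by
global extremes except methylation (raw %); a constant positive
signal scales to 1.  Smoothing is a moving average over a
configurable bin bandwidth, applied last and never feeding
quantitative outputs (the published spline smoothing parameter is
implementation-specific).

## LTR dating

K = −¾·ln(1 − 4p/3) from ungapped mismatch fractions (gap columns are
excluded when an aligned pair contains them; the pair constructor
requires equal lengths for that reason); p ≥ 0.75 raises a saturation
error.  T = K/(2r), default r = 1.3×10⁻⁸/site/year.  Fossil
rescaling multiplies relative times by 2.96 Ma over the mean of an
explicitly supplied calibration contrast — the contrast set is an
input because the published averaging set is not enumerated.
Subgenome summaries report medians with seeded percentile-bootstrap
95% CIs (1,000 resamples).  Recovery bias shrinks with LTR length
(tested at 200/1,000/5,000 bp): the estimate is granular in units of
1/(2rL) years, which dominates at short lengths.

## Problem sizes in the test suite

Default-scale runs (1 Mb chromosomes, 35 centromeres) back the
centromere property suite (10 seeds) and the metaplot checks;
bivalent-subgenome recovery runs 20 seeds per duplication
configuration at 200 kb; dosage recovery uses 100–200 kb chromosomes
at 20–30×; LTR recovery uses 200 elements per age at 400 bp.  These
sizes are the package's chosen desk scale; every size is a spec
parameter.

## Known limitations

- Substitution-only sequence model; indel/SV modes are not
  implemented (the mapper's edit-distance scoring would tolerate
  small indels, but the truth bookkeeping assumes column alignment).
- The built-in mapper targets generator-style data (≤ a few percent
  divergence, few-hundred-bp to kb queries); it is not a general
  short-read aligner, and real datasets should come in as SAM from a
  production aligner.
- The consensus builder is a majority caller, not a genotyper; true
  heterozygous sites within a bivalent pair collapse to one allele.
- Centromere calling assumes one centromere per chromosome;
  holocentric or dicentric configurations are out of scope.
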