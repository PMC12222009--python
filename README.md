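# caninakit

Computational genetics of pentaploid dogrose (*Rosa* sect. *Caninae*)
reproduction: a model of the asymmetric *Canina* meiosis with its
quantitative predictions, plus the genomic analyses that test those
predictions — pollen single-copy-orthologue (SCO) mapping, hybrid
subgenome-dosage inference from read coverage, CENH3-based centromere
annotation and classification, and LTR retrotransposon insertion
dating.  A seeded synthetic pentaploid genome generator provides all
inputs and ground truth, so every analysis runs end to end with no
external data; the same entry points accept standard formats
(FASTA/FASTQ, SAM, GFF3, BED, bedGraph, VCF, TSV) for real data.

## The model

Pentaploid dogroses (2n = 5x = 35) carry four subgenomes: one
(e.g. S1 in *R. canina*) present as two near-identical haplotypes
(h1/h2), and three (S2, R3, R4) present once.  At meiosis the two S1
haplotypes form 7 bivalents and segregate normally; the remaining 21
chromosomes stay as univalents:

- **pollen**: 7 chromosomes (1x), one bivalent haplotype per linkage
  group, univalents excluded;
- **egg**: 28 chromosomes (4x), one bivalent haplotype per linkage
  group plus every univalent;
- **zygote**: 7 + 28 = 35 — pentaploidy restored, composition a fixed
  point under selfing.

Double fertilization predicts an endosperm/embryo ploidy ratio of
(2·4x + 1x)/(4x + 1x) = 9/5 = 1.8, against 3/2 = 1.5 in a diploid.  A
cross transmits the father's bivalent subgenome on top of one copy of
each maternal subgenome, so e.g. *R. canina* ♀ × *R. rubiginosa* ♂
(bivalent R4) gives the dosage vector {S1: 1, S2: 1, R3: 1, R4: 2} —
visible as doubled R4 read coverage in the hybrid.

Downstream, centromeres are annotated from CENH3 ChIP enrichment
(log₂[CENH3/H3], mean + k·σ peak runs merged across gaps), their
repeat composition (CANR4 satellite, ATHILA retroelements, cenLTR
tandem arrays) is quantified in bp and classified, and LTR insertions
are dated from paired-LTR divergence via JC69: K = −¾·ln(1 − 4p/3),
T = K/(2r) with r = 1.3×10⁻⁸ substitutions/site/year.

## Worked example

```
$ caninakit meiosis --mother canina --father rubiginosa
egg: 28 chromosomes (4x); sperm: 7 (1x)
embryo 5x, endosperm 9x, ratio 1.8
expected hybrid dosage: {'S1': 1, 'S2': 1, 'R3': 1, 'R4': 2}
```

The egg carries 28 chromosomes and the sperm 7, so the seedling is
pentaploid again; the seed's endosperm/embryo ratio of 1.8 is the
flow-cytometric signature of sexual reproduction in a pentaploid; and
the hybrid inherits a doubled R4 because that is the father's
bivalent-forming subgenome.

A full simulate→infer round trip on a synthetic genome:

```
$ caninakit run --analysis pollen-bivalent --seed 11 --out run1
analysis                     pollen-bivalent
bivalent_subgenome_truth                  S1
bivalent_subgenome_called                 S1
status                             confident
support                                  1.0
n_retained                                39
config_hash                     870caf4beab1
seed                                      11
```

Here the generator planted S1 as the duplicated subgenome, pollen
reads were drawn from it, per-locus consensus sequences were mapped
back to the 35 synthetic chromosomes, placements with exactly one
alternative hit (the partner haplotype) were retained, and all 39
retained loci landed on S1 — a confident call matching truth.  The
other analyses run the same way with
`--analysis hybrid-dosage` / `--analysis centromere-bimodality`, and
`caninakit simulate`, `sco-infer`, `hybrid-dosage`, `centromeres` and
`ltr-date` expose the individual stages for external data.

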