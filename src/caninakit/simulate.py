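"""Seeded synthetic pentaploid genome bundles with ground truth.

The generator emulates the statistical structure of a pentaploid
dogrose genome at desk scale: 7 linkage groups x 5 chromosome copies,
one subgenome present as two near-identical haplotypes (h1/h2,
~99.5% identity) and three divergent single-copy subgenomes (~95–98%
pairwise identity), centromeres built from CANR4 tandem arrays and/or
ATHILA retroelements (paired LTRs mutated according to a planted
insertion age) and/or cenLTR tandem arrays, and single-copy orthologue
(SCO) loci present exactly once per chromosome copy of a linkage
group.  Reads can be drawn from the whole genome, from the
bivalent-forming subgenome only (pollen), or according to a
per-subgenome dosage vector (hybrids).  All randomness flows from the
spec seed; identical spec + seed gives byte-identical output.

Divergence is modelled as i.i.d. substitutions from a per-linkage-group
common ancestor; no indels.  The CANR4 monomer is a synthetic stand-in
(~160 bp) embedding the published 22-bp probe, since the full monomer
is not available here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._seq import decode, encode, revcomp_codes
from .centromere import classify_composition
from .errors import CaninakitError, ConfigurationError
from .genome_map import ChromRecord, GenomeMap, chrom_name
from .ltr import DEFAULT_RATE, LTRPair

CANR4_PROBE = "ACCCTAGAAGCAAGAAGTTTGG"
# synthetic stand-in monomer (~160 bp) carrying the probe; the real
# monomer/HOR structure is not modelled
DEFAULT_CANR4_MONOMER = (
    CANR4_PROBE
    + "TTCGAACGGATCATCCGGTTAAGCTTGACCAGTACGATCGTTAGGCCATATCGGAACTTG"
    + "CGTTAAGGCTATCAGGATCCTTGAACGGTTACCAGATCGATTAGGCATCCGGTTAAGC"
    + "ACGATCGGTTAACCGGAT"
)

DEFAULT_SUBGENOME_DIVERGENCE = {"S1": 0.010, "S2": 0.015, "R3": 0.018, "R4": 0.022}
DEFAULT_LTR_AGE_YEARS = {"S1": 0.7e6, "S2": 0.7e6, "R3": 0.7e6, "R4": 1.2e6}


@dataclass(frozen=True)
class CentromerePlan:
    """Target composition fractions of a centromere (rest is spacer)."""

    canr4: float = 0.0
    athila: float = 0.0
    cenltr: float = 0.0

    def validate(self, key):
        tot = self.canr4 + self.athila + self.cenltr
        if not 0 <= tot <= 0.95:
            raise ConfigurationError(
                "centromere_plan", f"{key}: fractions sum to {tot:.2f}, must be <= 0.95")


def default_centromere_plan() -> dict:
    """Composition recipes mirroring the bimodal pattern: satellite-based
    centromeres on the univalent S2/R3 subgenomes, retroelement-based on
    S1/R4, a cenLTR array on R4 LG1, and minority CANR4 arrays
    (ATHILA-interrupted) on S1 LGs 2/4/5."""
    plan = {
        "S1": CentromerePlan(athila=0.70),
        "S2": CentromerePlan(canr4=0.60, athila=0.12),
        "R3": CentromerePlan(canr4=0.65, athila=0.08),
        "R4": CentromerePlan(athila=0.70),
        ("R4", 1): CentromerePlan(cenltr=0.62, athila=0.25),
    }
    for lg in (2, 4, 5):
        plan[("S1", lg)] = CentromerePlan(canr4=0.14, athila=0.60)
    return plan


@dataclass
class GenomeSpec:
    seed: int = 0
    linkage_groups: int = 7
    chromosome_length: int = 1_000_000
    subgenome_labels: tuple = ("S1", "S2", "R3", "R4")
    duplicated_subgenome: str = "S1"
    haplotype_divergence: float = 0.005
    subgenome_divergence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBGENOME_DIVERGENCE))
    n_sco_loci: int = 8
    sco_length: int = 500
    centromere_length: int = 80_000
    centromere_plan: Mapping = field(default_factory=default_centromere_plan)
    canr4_monomer: str = DEFAULT_CANR4_MONOMER
    athila_ltr_length: int = 400
    athila_internal_length: int = 800
    cenltr_monomer_length: int = 1500   # within the observed 1,425–2,596 bp
    ltr_age_years: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LTR_AGE_YEARS))
    mutation_rate: float = DEFAULT_RATE  # substitutions/site/year for LTR aging
    ancestor_seed: Optional[int] = None  # shared frame for multi-species bundles
    name_prefix: str = "Rca"

    def validate(self):
        if self.duplicated_subgenome not in self.subgenome_labels:
            raise ConfigurationError(
                "duplicated_subgenome",
                f"{self.duplicated_subgenome!r} not in subgenome_labels")
        if not 0 <= self.haplotype_divergence < 0.75:
            raise ConfigurationError("haplotype_divergence", "must be in [0, 0.75)")
        for sub in self.subgenome_labels:
            d = self.subgenome_divergence.get(sub)
            if d is None:
                raise ConfigurationError("subgenome_divergence", f"missing label {sub!r}")
            if not 0 <= d < 0.75:
                raise ConfigurationError("subgenome_divergence",
                                         f"{sub}: must be in [0, 0.75)")
        if not 1425 <= self.cenltr_monomer_length <= 2596:
            raise ConfigurationError("cenltr_monomer_length",
                                     "must lie in [1425, 2596] bp")
        if self.chromosome_length <= 2 * int(1.75 * self.centromere_length):
            raise ConfigurationError(
                "chromosome_length",
                "must exceed twice the (maximum realized) centromere length")
        if CANR4_PROBE not in self.canr4_monomer:
            warnings.warn("canr4_monomer does not contain the 22-bp probe; "
                          "FISH-probe detectability semantics are lost")
        for key, plan in self.centromere_plan.items():
            plan.validate(key)
        if self.linkage_groups < 1:
            raise ConfigurationError("linkage_groups", "must be >= 1")
        if self.n_sco_loci < 0:
            raise ConfigurationError("n_sco_loci", "must be >= 0")

    def plan_for(self, subgenome: str, lg: int) -> CentromerePlan:
        return self.centromere_plan.get((subgenome, lg),
                                        self.centromere_plan.get(subgenome,
                                                                 CentromerePlan()))


@dataclass
class TruthBundle:
    """Generator ground truth: the test oracle for the downstream analyses."""

    bivalent_subgenome: str
    centromeres: pd.DataFrame   # chrom, start0, end, length, class, *_bp
    sco: pd.DataFrame           # locus_id, linkage_group, chrom, subgenome, ...
    ltr: pd.DataFrame           # element_id, chrom, ltr coords, age, mismatches
    substitutions: dict         # chrom -> (pos array, ref codes, alt codes)

    def substitution_frame(self, chrom: str) -> pd.DataFrame:
        pos, ref, alt = self.substitutions[chrom]
        return pd.DataFrame({"chrom": chrom, "pos0": pos,
                             "ref": [decode(np.array([r])) for r in ref],
                             "alt": [decode(np.array([a])) for a in alt]})


@dataclass
class GenomeBundle:
    spec: GenomeSpec
    seqs: dict                  # chrom -> uint8 code array
    genome_map: GenomeMap
    features: pd.DataFrame      # chrom, type, start0, end, strand, family, id
    targets: dict               # locus_id -> ancestor-frame target sequence (str)
    truth: TruthBundle

    def sequence(self, chrom: str) -> str:
        return decode(self.seqs[chrom])

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.seqs.items()}

    def write(self, outdir, header_comment: str | None = None):
        from . import io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta({c: decode(a) for c, a in self.seqs.items()},
                       outdir / "genome.fa")
        io.write_fasta(self.targets, outdir / "sco_targets.fa")
        self.genome_map.to_tsv(outdir / "genome_map.tsv")
        gff = self.features.copy()
        gff["attributes"] = [
            {"ID": r.id, "family": r.family} for r in gff.itertuples()]
        gff["source"] = "caninakit"
        io.write_gff3(gff, outdir / "annotation.gff3", header_comment=header_comment)
        io.write_bed(self.truth.centromeres.assign(
            name=self.truth.centromeres["class"]), outdir / "centromere_truth.bed")
        io.write_tsv(self.truth.sco, outdir / "sco_truth.tsv")
        io.write_tsv(self.truth.ltr, outdir / "ltr_truth.tsv")
        io.write_json({"bivalent_subgenome": self.truth.bivalent_subgenome,
                       "seed": self.spec.seed}, outdir / "truth.json")
        subs = pd.concat([self.truth.substitution_frame(c)
                          for c in self.seqs], ignore_index=True)
        io.write_tsv(subs, outdir / "substitution_truth.tsv")


# ------------------------------------------------------------------ helpers
def _rng(seed_parts) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed_parts))


def _mutate(arr: np.ndarray, n_subs: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute ``n_subs`` distinct positions to a different base, in place."""
    if n_subs <= 0:
        return arr
    pos = rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False)
    arr[pos] = (arr[pos] + rng.integers(1, 4, size=len(pos))) % 4
    return arr


@dataclass
class _Templates:
    ltr: np.ndarray
    internal: np.ndarray
    cenltr_monomer: np.ndarray
    canr4_monomer: np.ndarray


def _make_templates(spec: GenomeSpec, rng: np.random.Generator) -> _Templates:
    ltr = rng.integers(0, 4, size=spec.athila_ltr_length).astype(np.uint8)
    internal = rng.integers(0, 4, size=spec.athila_internal_length).astype(np.uint8)
    # cenLTR monomer: an LTR-derived tandem-repeat unit (~85% identity to the LTR)
    reps = int(np.ceil(spec.cenltr_monomer_length / len(ltr)))
    cen = np.tile(ltr, reps)[:spec.cenltr_monomer_length].copy()
    _mutate(cen, int(0.15 * len(cen)), rng)
    return _Templates(ltr=ltr, internal=internal, cenltr_monomer=cen,
                      canr4_monomer=encode(spec.canr4_monomer))


def _athila_element(tpl: _Templates, age_years: float, rate: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, int, int, int]:
    """One ATHILA element (LTR-internal-LTR); each LTR accumulates
    Poisson(rate * age * L) substitutions since insertion."""
    lam = rate * age_years * len(tpl.ltr)
    ltr5 = _mutate(tpl.ltr.copy(), int(rng.poisson(lam)), rng)
    ltr3 = _mutate(tpl.ltr.copy(), int(rng.poisson(lam)), rng)
    seq = np.concatenate([ltr5, tpl.internal, ltr3])
    mism = int(np.count_nonzero(ltr5 != ltr3))
    return seq, len(tpl.ltr), len(tpl.internal), mism


def _compose_centromere(spec: GenomeSpec, plan: CentromerePlan, clen: int,
                        canr4_frac: float, age_years: float,
                        tpl: _Templates, rng: np.random.Generator):
    """Build the centromere sequence + relative features + LTR truth rows."""
    elem_len = 2 * spec.athila_ltr_length + spec.athila_internal_length
    canr4_total = int(canr4_frac * clen)
    athila_total = int(plan.athila * clen)
    cenltr_total = int(plan.cenltr * clen)
    n_elem = int(round(athila_total / elem_len)) if plan.athila > 0 else 0
    n_elem = max(n_elem, 1) if plan.athila > 0 else 0
    used = canr4_total + n_elem * elem_len + cenltr_total
    if used > clen:  # keep the element count, shrink the satellite array
        canr4_total = max(0, clen - n_elem * elem_len - cenltr_total)
        used = canr4_total + n_elem * elem_len + cenltr_total

    blocks: list[tuple[str, np.ndarray]] = []   # (family-or-spacer, seq)
    ltr_rows = []

    def _canr4_array(length):
        reps = int(np.ceil(length / len(tpl.canr4_monomer)))
        return np.tile(tpl.canr4_monomer, reps)[:length]

    elems = []
    for _ in range(n_elem):
        seq, lltr, lint, mism = _athila_element(tpl, age_years, spec.mutation_rate, rng)
        elems.append((seq, lltr, lint, mism))

    if canr4_total > 0:
        a_len = int(0.55 * canr4_total)
        blocks.append(("CANR4", _canr4_array(a_len)))
        for e in elems:
            blocks.append(("__ATHILA__", e))
        blocks.append(("CANR4", _canr4_array(canr4_total - a_len)))
    else:
        for e in elems:
            blocks.append(("__ATHILA__", e))
    if cenltr_total > 0:
        reps = int(np.ceil(cenltr_total / len(tpl.cenltr_monomer)))
        blocks.append(("cenLTR1", np.tile(tpl.cenltr_monomer, reps)[:cenltr_total]))
    spacer = clen - used
    if spacer > 0:
        blocks.append(("__spacer__", rng.integers(0, 4, size=spacer).astype(np.uint8)))

    seq = np.empty(clen, dtype=np.uint8)
    features = []   # (family, rel_start, rel_end)
    off = 0
    for fam, payload in blocks:
        if fam == "__ATHILA__":
            eseq, lltr, lint, mism = payload
            n = len(eseq)
            seq[off:off + n] = eseq
            features.append(("ATHILA", off, off + n))
            features.append(("ATHILA_LTR", off, off + lltr))
            features.append(("ATHILA_LTR", off + lltr + lint, off + n))
            ltr_rows.append({"ltr5_start0": off, "ltr5_end": off + lltr,
                             "ltr3_start0": off + lltr + lint, "ltr3_end": off + n,
                             "age_years": age_years, "planted_mismatches": mism})
            off += n
        else:
            n = len(payload)
            seq[off:off + n] = payload
            if fam != "__spacer__":
                features.append((fam, off, off + n))
            off += n
    assert off == clen
    return seq, features, ltr_rows


# --------------------------------------------------------------- generator
def generate_pentaploid(spec: GenomeSpec) -> GenomeBundle:
    """Generate a pentaploid bundle (sequences, annotation, truth).

    Layout (ancestor sequences, centromere positions/sizes, SCO
    placements, repeat templates) derives from ``ancestor_seed``
    (default: the main seed), so two bundles sharing an ancestor seed
    live in the same coordinate frame and differ only in their
    substitutions and element ages — the synthetic analogue of two
    related accessions.
    """
    spec.validate()
    anc_seed = spec.seed if spec.ancestor_seed is None else spec.ancestor_seed
    rng_anc = _rng([anc_seed, 11])
    rng_mut = _rng([spec.seed, 13])

    tpl = _make_templates(spec, rng_anc)
    L = spec.chromosome_length
    dup = spec.duplicated_subgenome

    seqs: dict[str, np.ndarray] = {}
    map_records: list[ChromRecord] = []
    feature_rows = []
    cen_rows, sco_rows, ltr_rows_all = [], [], []
    subs_truth: dict[str, tuple] = {}
    targets: dict[str, str] = {}

    max_cen = int(1.75 * spec.centromere_length)

    for lg in range(1, spec.linkage_groups + 1):
        ancestor = rng_anc.integers(0, 4, size=L).astype(np.uint8)
        cen_start = int(rng_anc.uniform(0.35, 0.55) * (L - max_cen))
        cen_start = max(cen_start, int(0.2 * L))

        # layout-level centromere geometry, one draw per copy in fixed order
        copies = []
        for sub in spec.subgenome_labels:
            haps = ("h1", "h2") if sub == dup else (None,)
            for hap in haps:
                plan = spec.plan_for(sub, lg)
                canr4_frac = plan.canr4 * rng_anc.uniform(0.75, 1.25)
                clen = int(spec.centromere_length
                           * (0.72 + 0.95 * canr4_frac + (0.35 if plan.cenltr else 0))
                           * rng_anc.uniform(0.97, 1.03))
                copies.append((sub, hap, plan, canr4_frac, clen))

        # SCO placement on the ancestor frame, clear of the centromere zone
        margin = 2_000
        zone_lo, zone_hi = cen_start - margin, cen_start + max_cen + margin
        step = spec.sco_length * 3
        grid = [p for p in range(5_000, L - spec.sco_length - 5_000, step)
                if p + spec.sco_length < zone_lo or p > zone_hi]
        if spec.n_sco_loci > len(grid):
            raise ConfigurationError("n_sco_loci", "too many loci for chromosome size")
        picks = sorted(rng_anc.choice(len(grid), size=spec.n_sco_loci, replace=False))
        locus_defs = []
        for i, gi in enumerate(picks):
            start = grid[gi]
            strand = "+" if rng_anc.random() < 0.8 else "-"
            locus_id = f"SCO_LG{lg}_{i:03d}"
            seg = ancestor[start:start + spec.sco_length]
            targets[locus_id] = decode(seg if strand == "+" else revcomp_codes(seg))
            locus_defs.append((locus_id, start, strand))

        # backbones: the duplicated subgenome's haplotypes share one
        # subgenome-level base so their pairwise divergence is only the
        # haplotype term (~99.5% identity); single-copy subgenomes
        # diverge independently from the ancestor
        backbones: dict[tuple, np.ndarray] = {}
        dup_base = _mutate(ancestor.copy(),
                           int(rng_mut.binomial(L, spec.subgenome_divergence[dup])),
                           rng_mut)
        for sub in spec.subgenome_labels:
            if sub == dup:
                for hap in ("h1", "h2"):
                    backbones[(sub, hap)] = _mutate(
                        dup_base.copy(),
                        int(rng_mut.binomial(L, spec.haplotype_divergence / 2)),
                        rng_mut)
            else:
                backbones[(sub, None)] = _mutate(
                    ancestor.copy(),
                    int(rng_mut.binomial(L, spec.subgenome_divergence[sub])),
                    rng_mut)

        for sub, hap, plan, canr4_frac, clen in copies:
            chrom = chrom_name(lg, sub, hap, prefix=spec.name_prefix)
            arr = backbones[(sub, hap)]

            age = float(spec.ltr_age_years.get(sub, 7e5))
            cseq, cfeats, crows = _compose_centromere(
                spec, plan, clen, canr4_frac, age, tpl, rng_mut)
            arr[cen_start:cen_start + clen] = cseq
            seqs[chrom] = arr
            map_records.append(ChromRecord(chrom, lg, sub, hap, L))

            canr4_bp = athila_bp = cenltr_bp = 0
            for fam, rs, re_ in cfeats:
                feature_rows.append({"chrom": chrom, "type": "repeat",
                                     "start0": cen_start + rs, "end": cen_start + re_,
                                     "strand": "+", "family": fam,
                                     "id": f"{chrom}_{fam}_{rs}"})
                if fam == "CANR4":
                    canr4_bp += re_ - rs
                elif fam == "ATHILA":
                    athila_bp += re_ - rs
                elif fam.startswith("cenLTR"):
                    cenltr_bp += re_ - rs
            for j, row in enumerate(crows):
                ltr_rows_all.append({
                    "element_id": f"{chrom}_ATHILA_{j:03d}", "chrom": chrom,
                    "subgenome": sub,
                    "ltr5_start0": cen_start + row["ltr5_start0"],
                    "ltr5_end": cen_start + row["ltr5_end"],
                    "ltr3_start0": cen_start + row["ltr3_start0"],
                    "ltr3_end": cen_start + row["ltr3_end"],
                    "age_years": row["age_years"],
                    "planted_mismatches": row["planted_mismatches"]})
            cen_rows.append({"chrom": chrom, "start0": cen_start,
                             "end": cen_start + clen, "length": clen,
                             "canr4_bp": canr4_bp, "athila_bp": athila_bp,
                             "cenltr_bp": cenltr_bp,
                             "class": classify_composition(
                                 canr4_bp, athila_bp, cenltr_bp, clen)})
            for locus_id, start, strand in locus_defs:
                sco_rows.append({"locus_id": locus_id, "linkage_group": lg,
                                 "chrom": chrom, "subgenome": sub,
                                 "haplotype": hap or ".", "start0": start,
                                 "end": start + spec.sco_length, "strand": strand})
                feature_rows.append({"chrom": chrom, "type": "sco_locus",
                                     "start0": start, "end": start + spec.sco_length,
                                     "strand": strand, "family": "SCO",
                                     "id": locus_id})
            # planted substitutions vs the ancestor, outside the centromere
            diff = np.flatnonzero(arr != ancestor)
            diff = diff[(diff < cen_start) | (diff >= cen_start + clen)]
            subs_truth[chrom] = (diff, ancestor[diff].copy(), arr[diff].copy())

    truth = TruthBundle(
        bivalent_subgenome=dup,
        centromeres=pd.DataFrame(cen_rows),
        sco=pd.DataFrame(sco_rows),
        ltr=pd.DataFrame(ltr_rows_all),
        substitutions=subs_truth,
    )
    features = pd.DataFrame(feature_rows)
    return GenomeBundle(spec=spec, seqs=seqs, genome_map=GenomeMap(map_records),
                        features=features, targets=targets, truth=truth)


def pairwise_identity(bundle: GenomeBundle, chrom_a: str, chrom_b: str,
                      exclude_repeats: bool = True) -> float:
    """Column identity between two chromosomes of one linkage group.

    With no indels the copies stay column-aligned to the ancestor, so
    identity is a direct position-wise comparison.  By default the
    planted repeat space (the centromere zones of either copy) is
    excluded, since tandem arrays are not meaningfully alignable
    between subgenomes.
    """
    a, b = bundle.seqs[chrom_a], bundle.seqs[chrom_b]
    mask = np.ones(len(a), dtype=bool)
    if exclude_repeats:
        cen = bundle.truth.centromeres
        for chrom in (chrom_a, chrom_b):
            row = cen[cen["chrom"] == chrom]
            for r in row.itertuples():
                mask[r.start0:r.end] = False
    n = mask.sum()
    return float(np.count_nonzero((a == b) & mask) / n)


# -------------------------------------------------------------------- reads
@dataclass
class ReadSet:
    truth: pd.DataFrame          # read_id, chrom, start0, end, strand
    seqs: Optional[list] = None  # sequences (None when skipped for speed)
    read_length: int = 100

    def write_fastq(self, path):
        from .io import write_fastq

        if self.seqs is None:
            raise CaninakitError("reads were generated without sequences")
        write_fastq(self.truth["read_id"].tolist(), self.seqs, path)

    def alignments(self, collapse: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Truth placements as an alignment table (chrom, start0, end).

        ``collapse`` optionally renames chromosomes (e.g. map both S1
        haplotypes onto the S1_h1 reference copy, the synthetic
        analogue of mapping to a one-copy-per-subgenome reference).
        """
        df = self.truth[["read_id", "chrom", "start0", "end"]].copy()
        if collapse:
            df["chrom"] = df["chrom"].map(lambda c: collapse.get(c, c))
        return df.sort_values(["chrom", "start0"], kind="stable").reset_index(drop=True)


def haplotype_collapse_map(genome_map: GenomeMap) -> dict[str, str]:
    """Map every haplotype copy onto the h1 representative of its subgenome."""
    out = {}
    for rec in genome_map:
        if rec.haplotype and rec.haplotype != "h1":
            out[rec.name] = rec.name[:-len(rec.haplotype)] + "h1"
    return out


def generate_reads(bundle: GenomeBundle,
                   source: Union[str, Mapping[str, int]] = "genome",
                   coverage: float = 20.0,
                   read_length: int = 100,
                   error_rate: float = 0.002,
                   seed: int = 0,
                   regions: pd.DataFrame | None = None,
                   with_sequences: bool = True) -> ReadSet:
    """Uniform substitution-only reads from a source selection.

    ``source`` is ``"genome"`` (every chromosome copy), ``"bivalent"``
    (both haplotypes of the bivalent subgenome — pollen pools many
    nuclei, so both haplotypes are represented), or a dosage vector
    mapping subgenome -> copy number (copies beyond the available
    haplotypes multiply coverage).  ``coverage`` is the fold coverage
    of each selected chromosome copy.  ``regions`` restricts read
    starts to intervals (target-enrichment mode).
    """
    if coverage <= 0:
        raise CaninakitError("coverage must be positive")
    if read_length >= bundle.spec.chromosome_length:
        raise CaninakitError("read_length must be below chromosome_length")
    rng = _rng([seed, 29])
    gm = bundle.genome_map
    dup = bundle.truth.bivalent_subgenome

    weights: dict[str, float] = {}
    if source == "genome":
        weights = {c: 1.0 for c in gm.names}
    elif source == "bivalent":
        weights = {r.name: 1.0 for r in gm.chroms(subgenome=dup)}
    elif isinstance(source, Mapping):
        if not source:
            raise CaninakitError("empty dosage selector")
        for sub, copies in source.items():
            chroms = gm.chroms(subgenome=sub)
            if not chroms:
                raise CaninakitError(f"dosage selector names unknown subgenome {sub!r}")
            haps = sorted({r.haplotype for r in chroms if r.haplotype})
            if haps:  # duplicated subgenome: fill haplotypes h1, h2, then stack
                for i in range(int(copies)):
                    hap = haps[i % len(haps)]
                    for r in chroms:
                        if r.haplotype == hap:
                            weights[r.name] = weights.get(r.name, 0.0) + 1.0
            else:
                for r in chroms:
                    weights[r.name] = weights.get(r.name, 0.0) + float(copies)
    else:
        raise CaninakitError(f"unknown read source {source!r}")
    if not weights:
        raise CaninakitError("empty read source selection")

    reg_by_chrom: dict[str, np.ndarray] = {}
    if regions is not None:
        for chrom, sub in regions.groupby("chrom"):
            reg_by_chrom[chrom] = sub[["start0", "end"]].to_numpy(dtype=np.int64)

    rows, seq_chunks = [], []
    rid = 0
    for chrom, w in weights.items():
        arr = bundle.seqs[chrom]
        if regions is not None:
            if chrom not in reg_by_chrom:
                continue
            iv = reg_by_chrom[chrom]
            spans = np.maximum(iv[:, 1] - iv[:, 0] - read_length, 1)
            n_reads = int(round(w * coverage * (iv[:, 1] - iv[:, 0]).sum()
                                / read_length))
            which = rng.choice(len(iv), size=n_reads, p=spans / spans.sum())
            starts = iv[which, 0] + (rng.random(n_reads) * spans[which]).astype(np.int64)
        else:
            n_reads = int(round(w * coverage * len(arr) / read_length))
            starts = rng.integers(0, len(arr) - read_length + 1, size=n_reads)
        starts = np.sort(starts)
        strands = rng.random(n_reads) < 0.5
        rows.append(pd.DataFrame({
            "read_id": [f"r{rid + i:08d}" for i in range(n_reads)],
            "chrom": chrom, "start0": starts, "end": starts + read_length,
            "strand": np.where(strands, "-", "+")}))
        rid += n_reads
        if with_sequences:
            mat = arr[starts[:, None] + np.arange(read_length)[None, :]].copy()
            if error_rate > 0:
                mask = rng.random(mat.shape) < error_rate
                mat[mask] = (mat[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
            minus = np.flatnonzero(strands)
            if len(minus):
                mat[minus] = 3 - mat[minus][:, ::-1]
            from ._seq import _DECODE

            flat = _DECODE[mat].tobytes().decode()
            seq_chunks.extend(flat[i * read_length:(i + 1) * read_length]
                              for i in range(n_reads))

    truth = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["read_id", "chrom", "start0", "end", "strand"])
    return ReadSet(truth=truth, seqs=seq_chunks if with_sequences else None,
                   read_length=read_length)


# ------------------------------------------------------------- ChIP tracks
def generate_chip_tracks(bundle: GenomeBundle,
                         window: int = 10_000,
                         snr: float = 8.0,
                         noise_sd: float = 0.15,
                         seed: int = 0,
                         composition_scaling: bool = True):
    """Windowed CENH3/H3 depth tracks plus a per-window methylation table.

    Tracks are emitted depth-normalized (baseline 1), so
    log2(CENH3/H3) is ~0 outside centromeres and ~log2(snr) inside.
    With ``composition_scaling`` the per-chromosome enrichment factor
    grows with the CANR4 fraction of the truth centromere (satellite
    centromeres bind more CENH3) and is boosted for cenLTR arrays;
    noiseless tracks with scaling off are exactly snr-fold enriched.
    Methylation is elevated at centromeres in all three contexts with
    a dip inside CANR4 arrays.
    """
    from .centromere import SignalTrack

    if snr <= 1:
        raise CaninakitError("snr must exceed 1")
    truth = bundle.truth.centromeres
    if truth.empty:
        raise CaninakitError("truth centromere intervals missing")
    rng = _rng([seed, 41])

    cen_by_chrom = {r.chrom: r for r in truth.itertuples()}
    canr4_windows = bundle.features[
        (bundle.features["family"] == "CANR4")] if len(bundle.features) else None

    meth_base = {"CpG": 60.0, "CHG": 40.0, "CHH": 10.0}
    meth_boost = {"CpG": 25.0, "CHG": 25.0, "CHH": 8.0}
    meth_dip = {"CpG": 32.0, "CHG": 30.0, "CHH": 10.0}

    rows_c, rows_h, rows_m = [], [], []
    for chrom, arr in bundle.seqs.items():
        L = len(arr)
        n_win = int(np.ceil(L / window))
        starts = np.arange(n_win) * window
        ends = np.minimum(starts + window, L)
        mids = 0.5 * (starts + ends)

        r = cen_by_chrom[chrom]
        frac = r.canr4_bp / r.length
        if composition_scaling:
            factor = snr * (0.5 + 1.5 * frac)
            if r.cenltr_bp >= 50_000:
                factor = snr * 1.1
            factor *= 2.0 ** rng.normal(0.0, noise_sd / 2)
        else:
            factor = snr
        inside = (mids >= r.start0) & (mids < r.end)

        h3 = np.ones(n_win)
        cenh3 = np.where(inside, factor, 1.0)
        if noise_sd > 0:
            h3 = h3 * 2.0 ** rng.normal(0.0, noise_sd, n_win)
            cenh3 = cenh3 * 2.0 ** rng.normal(0.0, noise_sd, n_win)
        rows_c.append(pd.DataFrame({"chrom": chrom, "start0": starts,
                                    "end": ends, "value": cenh3}))
        rows_h.append(pd.DataFrame({"chrom": chrom, "start0": starts,
                                    "end": ends, "value": h3}))

        in_canr4 = np.zeros(n_win, dtype=bool)
        if canr4_windows is not None:
            for f in canr4_windows[canr4_windows["chrom"] == chrom].itertuples():
                lo = np.searchsorted(starts, f.start0 - window, side="left")
                hi = np.searchsorted(starts, f.end, side="right")
                sel = slice(lo, hi)
                ov = (np.minimum(ends[sel], f.end)
                      - np.maximum(starts[sel], f.start0)).clip(min=0)
                in_canr4[sel] |= ov >= 0.5 * (ends[sel] - starts[sel])
        for ctx in ("CpG", "CHG", "CHH"):
            pct = np.full(n_win, meth_base[ctx])
            pct[inside] += meth_boost[ctx]
            pct[in_canr4 & inside] -= meth_dip[ctx]
            if noise_sd > 0:
                pct = pct + rng.normal(0.0, 6.0 * noise_sd, n_win)
            pct = np.clip(pct, 0.0, 100.0)
            rows_m.append(pd.DataFrame({"chrom": chrom, "start0": starts,
                                        "end": ends, "context": ctx, "pct": pct}))

    cenh3_track = SignalTrack(pd.concat(rows_c, ignore_index=True), "cenh3", window)
    h3_track = SignalTrack(pd.concat(rows_h, ignore_index=True), "h3", window)
    methylation = pd.concat(rows_m, ignore_index=True)
    return cenh3_track, h3_track, methylation


# ------------------------------------------------------------- LTR fixtures
def generate_ltr_pairs(n: int, ltr_length: int, age_years: float,
                       rate: float = DEFAULT_RATE, seed: int = 0,
                       subgenome: str | None = None,
                       element_prefix: str = "elem") -> list[LTRPair]:
    """Standalone paired-LTR fixture: n elements of one planted age.

    Each LTR independently accumulates Poisson(rate * age * L)
    substitutions from a shared per-element ancestral LTR.
    """
    rng = _rng([seed, 53])
    lam = rate * age_years * ltr_length
    pairs = []
    for i in range(n):
        anc = rng.integers(0, 4, size=ltr_length).astype(np.uint8)
        ltr5 = _mutate(anc.copy(), int(rng.poisson(lam)), rng)
        ltr3 = _mutate(anc.copy(), int(rng.poisson(lam)), rng)
        pairs.append(LTRPair(element_id=f"{element_prefix}{i:04d}",
                             ltr5_sequence=decode(ltr5), ltr3_sequence=decode(ltr3),
                             subgenome=subgenome))
    return pairs


def ltr_pairs_from_bundle(bundle: GenomeBundle) -> list[LTRPair]:
    """Extract every planted ATHILA element's LTR pair from the genome."""
    pairs = []
    for r in bundle.truth.ltr.itertuples():
        arr = bundle.seqs[r.chrom]
        pairs.append(LTRPair(
            element_id=r.element_id,
            ltr5_sequence=decode(arr[r.ltr5_start0:r.ltr5_end]),
            ltr3_sequence=decode(arr[r.ltr3_start0:r.ltr3_end]),
            subgenome=r.subgenome))
    return pairs
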