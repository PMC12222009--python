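"""The Canina meiosis inheritance model.

Pentaploid dogroses (2n = 5x = 35) reproduce sexually through an
asymmetric meiosis: within each of the 7 linkage groups, the two
near-identical haplotypes of one subgenome pair as a bivalent and
segregate normally, while the three remaining homoeologues stay
unpaired (univalents).  Pollen receives one bivalent haplotype per
linkage group and nothing else (7 chromosomes, 1x); the egg receives
one bivalent haplotype per linkage group *plus* every univalent
(28 chromosomes, 4x).  Fertilization restores pentaploidy, and the
subgenome composition is a fixed point under selfing.

The model deliberately represents recombination within a bivalent only
as an independent, uniform haplotype choice per linkage group — no
crossover breakpoints — which is sufficient for every quantitative
prediction exposed here (gamete sizes, seed-tissue ploidies, hybrid
dosage vectors, multi-generation stability).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional

import numpy as np

from .errors import ModelError

DEFAULT_SUBGENOMES = ("S1", "S2", "R3", "R4")
BASIC_NUMBER_X = 7

_copy_counter = itertools.count()


@dataclass(frozen=True)
class ChromosomeCopy:
    """One physical chromosome copy, tagged by its origin.

    ``copy_id`` is a stable identity token used to verify
    identity-by-descent of univalents across generations.
    """

    linkage_group: int
    subgenome: str
    haplotype: Optional[str] = None  # only the duplicated subgenome carries a tag
    copy_id: int = field(default_factory=lambda: next(_copy_counter))

    @property
    def label(self) -> str:
        h = f"_{self.haplotype}" if self.haplotype else ""
        return f"{self.subgenome}{h}.LG{self.linkage_group}"


@dataclass
class Karyotype:
    taxon: str
    copies: list[ChromosomeCopy]
    bivalent_subgenome: Optional[str]
    basic_number_x: int = BASIC_NUMBER_X

    def __post_init__(self):
        self._validate()

    def _validate(self):
        lgs = sorted({c.linkage_group for c in self.copies})
        per_lg = {lg: [c for c in self.copies if c.linkage_group == lg] for lg in lgs}
        sizes = {len(v) for v in per_lg.values()}
        if len(sizes) != 1:
            raise ModelError(f"{self.taxon}: unequal copy number across linkage groups")
        if self.bivalent_subgenome is not None:
            for lg, cps in per_lg.items():
                n_biv = sum(c.subgenome == self.bivalent_subgenome for c in cps)
                if n_biv != 2:
                    raise ModelError(
                        f"{self.taxon}: bivalent subgenome {self.bivalent_subgenome} "
                        f"present {n_biv} times on LG{lg}, expected 2"
                    )

    # ----------------------------------------------------------- summaries
    @property
    def ploidy_x(self) -> int:
        return len(self.copies) // len(self.linkage_groups)

    @property
    def linkage_groups(self) -> list[int]:
        return sorted({c.linkage_group for c in self.copies})

    def subgenome_counts(self) -> dict[str, int]:
        """Copy count per subgenome per linkage group (e.g. {S1: 2, S2: 1, ...})."""
        lg0 = self.linkage_groups[0]
        out: dict[str, int] = {}
        for c in self.copies:
            if c.linkage_group == lg0:
                out[c.subgenome] = out.get(c.subgenome, 0) + 1
        return out

    def n_bivalent_copies(self) -> int:
        """Chromosomes participating in bivalents (14 in a pentaploid)."""
        if self.bivalent_subgenome is None:
            return 0
        return sum(c.subgenome == self.bivalent_subgenome for c in self.copies)

    def n_univalents(self) -> int:
        """Chromosomes without a pairing partner (21 in a pentaploid)."""
        return len(self.copies) - self.n_bivalent_copies()

    def n_bivalents(self) -> int:
        """Bivalents formed at meiosis I (7 in a pentaploid)."""
        return self.n_bivalent_copies() // 2

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(c.linkage_group, c.subgenome, c.haplotype or ".", c.copy_id)
             for c in sorted(self.copies, key=lambda c: (c.linkage_group, c.subgenome,
                                                         c.haplotype or ""))],
            columns=["linkage_group", "subgenome", "haplotype", "copy_id"],
        )


@dataclass
class Gamete:
    sex: str  # "male" | "female"
    copies: list[ChromosomeCopy]
    ploidy_x: int

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ModelError(f"unknown gamete sex {self.sex!r}")

    def subgenome_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.copies:
            out[c.subgenome] = out.get(c.subgenome, 0) + 1
        return out


@dataclass(frozen=True)
class SeedTissues:
    embryo_ploidy_x: int
    endosperm_ploidy_x: int

    @property
    def ratio(self) -> Fraction:
        return Fraction(self.endosperm_ploidy_x, self.embryo_ploidy_x)


class DosageVector(dict):
    """Per-subgenome copy number of an individual; values sum to its ploidy."""

    def total(self) -> int:
        return sum(self.values())


# --------------------------------------------------------------- factories
def pentaploid_karyotype(taxon: str = "R. canina",
                         bivalent_subgenome: str = "S1",
                         subgenomes: Iterable[str] = DEFAULT_SUBGENOMES,
                         linkage_groups: int = BASIC_NUMBER_X) -> Karyotype:
    """Build a 35-copy pentaploid karyotype with one duplicated subgenome.

    ``bivalent_subgenome="S1"`` gives the R. canina configuration;
    ``"R4"`` gives the R. rubiginosa / R. agrestis one.
    """
    subgenomes = list(subgenomes)
    if bivalent_subgenome not in subgenomes:
        raise ModelError(f"bivalent subgenome {bivalent_subgenome!r} not among {subgenomes}")
    copies = []
    for lg in range(1, linkage_groups + 1):
        for sub in subgenomes:
            if sub == bivalent_subgenome:
                copies.append(ChromosomeCopy(lg, sub, "h1"))
                copies.append(ChromosomeCopy(lg, sub, "h2"))
            else:
                copies.append(ChromosomeCopy(lg, sub))
    return Karyotype(taxon, copies, bivalent_subgenome)


def diploid_karyotype(taxon: str = "diploid rose", subgenome: str = "D1",
                      linkage_groups: int = BASIC_NUMBER_X) -> Karyotype:
    copies = []
    for lg in range(1, linkage_groups + 1):
        copies.append(ChromosomeCopy(lg, subgenome, "h1"))
        copies.append(ChromosomeCopy(lg, subgenome, "h2"))
    return Karyotype(taxon, copies, subgenome)


# -------------------------------------------------------------- operations
def _bivalent_pairs(k: Karyotype) -> dict[int, list[ChromosomeCopy]]:
    if k.bivalent_subgenome is None:
        raise ModelError("no bivalent partner: karyotype has no twice-present subgenome")
    pairs = {}
    for lg in k.linkage_groups:
        pair = [c for c in k.copies
                if c.linkage_group == lg and c.subgenome == k.bivalent_subgenome]
        if len(pair) != 2:
            raise ModelError(f"no bivalent partner on LG{lg}")
        pairs[lg] = sorted(pair, key=lambda c: c.haplotype or "")
    return pairs


def male_meiosis(k: Karyotype, seed: int | np.random.Generator = 0) -> Gamete:
    """Pollen formation: one bivalent haplotype per linkage group, univalents excluded.

    Haplotype choice is independent and uniform per linkage group (seeded).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pairs = _bivalent_pairs(k)
    picks = rng.integers(0, 2, size=len(pairs))
    copies = [pairs[lg][int(p)] for lg, p in zip(sorted(pairs), picks)]
    return Gamete("male", copies, ploidy_x=1)


def female_meiosis(k: Karyotype, seed: int | np.random.Generator = 0) -> Gamete:
    """Egg formation: one bivalent haplotype per linkage group plus all univalents."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pairs = _bivalent_pairs(k)
    picks = rng.integers(0, 2, size=len(pairs))
    copies = [pairs[lg][int(p)] for lg, p in zip(sorted(pairs), picks)]
    univalents = [c for c in k.copies if c.subgenome != k.bivalent_subgenome]
    copies = copies + univalents
    ploidy = len(copies) // len(k.linkage_groups)
    return Gamete("female", copies, ploidy_x=ploidy)


def fertilize(egg: Gamete, sperm: Gamete, taxon: str = "offspring") -> Karyotype:
    """Fuse gametes; the offspring's bivalent subgenome is the one present twice per LG."""
    if egg.sex != "female" or sperm.sex != "male":
        raise ModelError("fertilize expects a female egg and a male sperm gamete")
    egg_lgs = {c.linkage_group for c in egg.copies}
    sperm_lgs = {c.linkage_group for c in sperm.copies}
    if egg_lgs != sperm_lgs:
        raise ModelError("incompatible gametes: linkage-group universes differ")
    copies = list(egg.copies) + list(sperm.copies)
    lg0 = sorted(egg_lgs)[0]
    counts: dict[str, int] = {}
    for c in copies:
        if c.linkage_group == lg0:
            counts[c.subgenome] = counts.get(c.subgenome, 0) + 1
    doubled = [s for s, n in counts.items() if n == 2]
    if len(doubled) != 1:
        raise ModelError(
            f"offspring has {len(doubled)} twice-present subgenomes "
            f"({counts}); cannot define a bivalent subgenome"
        )
    return Karyotype(taxon, copies, doubled[0])


def endosperm_ploidy(egg: Gamete, sperm: Gamete) -> SeedTissues:
    """Seed-tissue ploidies under double fertilization.

    Embryo = egg + sperm; endosperm = two polar nuclei (each of egg
    ploidy) + one sperm.  A 4x egg and 1x sperm give the pentaploid
    dogrose signature 9x endosperm / 5x embryo = 1.8; a diploid's 1x
    gametes give 3x/2x = 1.5.
    """
    if egg.ploidy_x <= 0 or sperm.ploidy_x <= 0:
        raise ModelError("degenerate gamete: ploidy must be positive")
    embryo = egg.ploidy_x + sperm.ploidy_x
    endosperm = 2 * egg.ploidy_x + sperm.ploidy_x
    return SeedTissues(embryo_ploidy_x=embryo, endosperm_ploidy_x=endosperm)


def predict_hybrid_dosage(mother: Karyotype, father: Karyotype) -> DosageVector:
    """Expected per-subgenome copy number of a mother x father seedling.

    The egg contributes one copy of every maternal subgenome; the sperm
    adds one extra copy of the paternal bivalent subgenome.  For
    R. canina (bivalent S1) x R. rubiginosa (bivalent R4) this is
    {S1: 1, S2: 1, R3: 1, R4: 2} — the doubled-R4-coverage pattern.
    """
    _bivalent_pairs(mother)  # raises if undefined
    _bivalent_pairs(father)
    dosage = DosageVector({s: 1 for s in mother.subgenome_counts()})
    pat = father.bivalent_subgenome
    dosage[pat] = dosage.get(pat, 0) + 1
    return dosage


def simulate_generations(founder: Karyotype, n_generations: int,
                         seed: int = 0) -> list[Karyotype]:
    """Self the founder for ``n_generations``; returns the trajectory.

    Univalent copies are transmitted maternally without recombination,
    so they remain identical-by-descent to the founder's (same
    ``copy_id``); the subgenome composition is a fixed point.
    """
    rng = np.random.default_rng(seed)
    trajectory = [founder]
    current = founder
    for g in range(n_generations):
        egg = female_meiosis(current, rng)
        sperm = male_meiosis(current, rng)
        current = fertilize(egg, sperm, taxon=f"{founder.taxon} F{g + 1}")
        trajectory.append(current)
    return trajectory


def viable_pollen_filter(gametes: Iterable[Gamete], viability: float = 0.20,
                         seed: int = 0) -> list[Gamete]:
    """Optional rejection step modelling observed pollen viability.

    Viability is an empirical parameter, not a model-derived quantity.
    """
    rng = np.random.default_rng(seed)
    gametes = list(gametes)
    keep = rng.random(len(gametes)) < viability
    return [g for g, k in zip(gametes, keep) if k]
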