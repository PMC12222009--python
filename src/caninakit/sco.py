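"""Pollen-SCO classification of the bivalent-forming subgenome.

Pollen of a pentaploid dogrose carries only the bivalent-forming
subgenome, so single-copy orthologue (SCO) loci sequenced from pollen
DNA map back to that subgenome's chromosomes.  The procedure:

1. keep loci that are genome-wide single copy — exactly one hit per
   chromosome copy of one linkage group (five hits in a pentaploid,
   one each on S1_h1/S1_h2/S2/R3/R4);
2. build a per-locus sample consensus from back-mapped reads;
3. map each consensus to the genome and retain placements by their
   alternative-hit count (default: exactly one XA-style alternative —
   a bivalent-derived locus hits both near-identical haplotypes);
4. count retained hits per chromosome (haplotype pairs also reported
   as means) and call the subgenome with the maximal aggregate count.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import decode, encode
from .alignment import AlignmentRecord, KmerIndex
from .errors import CaninakitError
from .genome_map import GenomeMap

ALT_RULES: dict[str, Callable[[int], bool]] = {
    "==1": lambda n: n == 1,
    "<=1": lambda n: n <= 1,
    "any": lambda n: True,
}


@dataclass(frozen=True)
class GenomicHit:
    locus_id: str
    chrom: str
    linkage_group: int
    subgenome: str
    haplotype: Optional[str]
    start0: int
    end: int
    strand: str = "+"
    identity: float = 1.0


@dataclass
class SCOHitTable:
    counts: pd.Series                   # per chromosome
    pair_means: pd.Series               # per haplotype pair (subgenome label)
    taxon: str = ""
    subsection: str = ""

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def subgenome_counts(self, genome_map: GenomeMap) -> pd.Series:
        """Aggregate counts per subgenome (haplotype counts summed)."""
        agg: dict[str, int] = {}
        for chrom, n in self.counts.items():
            sub = genome_map.chrom(chrom).subgenome
            agg[sub] = agg.get(sub, 0) + int(n)
        return pd.Series(agg).sort_index()

    def to_long_frame(self, genome_map: GenomeMap) -> pd.DataFrame:
        """Bubble-plot-ready long format (one row per chromosome)."""
        rows = []
        for chrom, n in self.counts.items():
            rec = genome_map.chrom(chrom)
            rows.append((self.taxon, self.subsection, chrom, rec.linkage_group,
                         rec.subgenome, rec.haplotype or ".", int(n)))
        return pd.DataFrame(rows, columns=["taxon", "subsection", "chrom",
                                           "linkage_group", "subgenome",
                                           "haplotype", "count"])


@dataclass
class BivalentCall:
    subgenome: str
    support: float          # winner count / total
    margin: float           # (winner - runner-up) / total
    status: str             # "confident" | "ambiguous"
    counts: dict = field(default_factory=dict)


# ----------------------------------------------------------------- filters
def filter_genomic_single_copy(hits: Sequence[GenomicHit],
                               genome_map: GenomeMap) -> list[str]:
    """Locus ids that are genome-wide single copy.

    Retained iff the locus has exactly one hit on every chromosome copy
    of a single linkage group (copies_per_lg hits total, one per
    subgenome/haplotype) and no hits elsewhere.  Idempotent and
    order-invariant.
    """
    n_copies = genome_map.copies_per_lg()
    for h in hits:
        if h.chrom not in genome_map:
            raise CaninakitError(f"hit on unknown chromosome {h.chrom!r}")
    by_locus: dict[str, list[GenomicHit]] = {}
    for h in hits:
        by_locus.setdefault(h.locus_id, []).append(h)
    retained = []
    for locus_id in sorted(by_locus):
        lhits = by_locus[locus_id]
        if len(lhits) != n_copies:
            continue
        lgs = {h.linkage_group for h in lhits}
        if len(lgs) != 1:
            continue
        copies = {(h.subgenome, h.haplotype) for h in lhits}
        expected = {(r.subgenome, r.haplotype)
                    for r in genome_map.chroms(linkage_group=next(iter(lgs)))}
        if copies == expected:
            retained.append(locus_id)
    return retained


def filter_alt_hits(records: Sequence[AlignmentRecord],
                    rule: str = "==1") -> list[AlignmentRecord]:
    """Retain records by their alternative-placement count.

    The default mirrors the XA:Z-based selection: keep records with
    exactly one alternative placement (the other haplotype of a
    bivalent pair); ``<=1`` and ``any`` are selectable.
    """
    try:
        pred = ALT_RULES[rule]
    except KeyError:
        raise CaninakitError(f"unknown alt-hits rule {rule!r}; "
                             f"choose from {sorted(ALT_RULES)}") from None
    return [r for r in records if pred(r.n_alt)]


# --------------------------------------------------------------- consensus
class TargetIndex:
    """Exact-k-mer index over SCO target sequences for read back-mapping."""

    def __init__(self, targets: Mapping[str, str], k: int = 21):
        self.k = k
        self.names = list(targets)
        self.seqs = {name: encode(s) for name, s in targets.items()}
        self.index: dict[int, tuple[int, int]] = {}
        ambiguous = set()
        for ti, name in enumerate(self.names):
            arr = self.seqs[name]
            n = len(arr) - k + 1
            code = 0
            mask = 4 ** k
            for i in range(len(arr)):
                code = (code * 4 + int(arr[i])) % mask
                if i >= k - 1:
                    key = code
                    pos = i - k + 1
                    if key in self.index and self.index[key][0] != ti:
                        ambiguous.add(key)
                    elif key not in self.index:
                        self.index[key] = (ti, pos)
        for key in ambiguous:
            self.index.pop(key, None)

    def assign(self, read: str) -> Optional[tuple[str, int]]:
        """(target, offset) of a read, or None; tries three anchors."""
        arr = encode(read)
        L = len(arr)
        for start in (0, max(0, (L - self.k) // 2), max(0, L - self.k)):
            code = 0
            for j in range(self.k):
                code = code * 4 + int(arr[start + j])
            hit = self.index.get(code)
            if hit is not None:
                ti, pos = hit
                return self.names[ti], pos - start
        return None


def build_consensus_reference(targets: Mapping[str, str],
                              reads: Sequence[tuple[str, str]] | Sequence[str],
                              min_depth: int = 5,
                              k: int = 21) -> dict[str, str]:
    """Per-locus sample consensus from back-mapped reads.

    Reads are anchored to targets by exact k-mers; per-column base
    counts are accumulated and the majority alternate base replaces
    the reference wherever depth >= ``min_depth`` (substitution-only;
    length preserved).  Loci without any assigned read are skipped
    with a warning.
    """
    if min_depth < 1:
        raise CaninakitError("min_depth must be >= 1")
    idx = TargetIndex(targets, k=k)
    counts = {name: np.zeros((4, len(seq)), dtype=np.int32)
              for name, seq in idx.seqs.items()}
    read_seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    for seq in read_seqs:
        hit = idx.assign(seq)
        if hit is None:
            # substitution errors may break all three anchors; also try revcomp
            from ._seq import revcomp

            hit = idx.assign(revcomp(seq))
            if hit is None:
                continue
            seq = revcomp(seq)
        name, off = hit
        arr = encode(seq)
        tlen = counts[name].shape[1]
        lo = max(0, -off)
        hi = min(len(arr), tlen - off)
        if hi <= lo:
            continue
        cols = np.arange(lo, hi) + off
        np.add.at(counts[name], (arr[lo:hi].astype(np.intp), cols), 1)

    out = {}
    for name, seq in targets.items():
        cnt = counts[name]
        depth = cnt.sum(axis=0)
        if depth.max(initial=0) == 0:
            warnings.warn(f"locus {name}: no reads assigned; skipped")
            continue
        cons = encode(seq).copy()
        ok = depth >= min_depth
        winners = cnt.argmax(axis=0).astype(np.uint8)
        cons[ok] = winners[ok]
        out[name] = decode(cons)
    return out


# ---------------------------------------------------------------- counting
def map_loci_to_genome(consensus: Mapping[str, str],
                       index: KmerIndex,
                       alt_margin: int | None = None) -> list[AlignmentRecord]:
    """Map locus consensus sequences to a genome k-mer index."""
    return index.map_queries(consensus, alt_margin=alt_margin)


def count_hits(records: Sequence[AlignmentRecord], genome_map: GenomeMap,
               taxon: str = "", subsection: str = "") -> SCOHitTable:
    """Per-chromosome counts of retained records, plus haplotype-pair means."""
    counts = {name: 0 for name in genome_map.names}
    for r in records:
        if r.chrom not in counts:
            raise CaninakitError(f"record on unannotated chromosome {r.chrom!r}")
        counts[r.chrom] += 1
    series = pd.Series(counts)
    pairs = {}
    for sub in genome_map.subgenomes:
        chroms = genome_map.chroms(subgenome=sub)
        haps = {r.haplotype for r in chroms}
        if None not in haps and len(haps) > 1:
            pairs[sub] = series[[r.name for r in chroms]].mean()
    return SCOHitTable(counts=series, pair_means=pd.Series(pairs, dtype=float),
                       taxon=taxon, subsection=subsection)


def assign_bivalent_subgenome(table: SCOHitTable, genome_map: GenomeMap,
                              margin_threshold: float = 0.5) -> BivalentCall:
    """Call the bivalent-forming subgenome from aggregate hit counts.

    Winner = subgenome with the maximal summed count; the call is
    confident iff the winner's lead over the runner-up is at least
    ``margin_threshold`` of the total.  Ties break lexicographically
    with status ambiguous.
    """
    agg = table.subgenome_counts(genome_map)
    total = int(agg.sum())
    if total == 0:
        raise CaninakitError("no informative hits: all counts are zero")
    ordered = agg.sort_values(ascending=False, kind="stable")
    # lexicographic tie-break on equal counts
    top_count = ordered.iloc[0]
    winners = sorted(ordered[ordered == top_count].index)
    winner = winners[0]
    runner_up = ordered[ordered.index != winner].max() if len(ordered) > 1 else 0
    support = float(agg[winner] / total)
    margin = float((agg[winner] - runner_up) / total)
    status = "confident" if margin >= margin_threshold and len(winners) == 1 \
        else "ambiguous"
    return BivalentCall(subgenome=winner, support=support, margin=margin,
                        status=status, counts=agg.to_dict())


# ---------------------------------------------------------------- pipeline
def records_to_genomic_hits(records: Sequence[AlignmentRecord],
                            genome_map: GenomeMap,
                            locus_length: Callable[[str], int] | None = None
                            ) -> list[GenomicHit]:
    hits = []
    for r in records:
        rec = genome_map.chrom(r.chrom)
        length = locus_length(r.query_id) if locus_length else (len(r.seq or "") or 0)
        hits.append(GenomicHit(locus_id=r.query_id, chrom=r.chrom,
                               linkage_group=rec.linkage_group,
                               subgenome=rec.subgenome, haplotype=rec.haplotype,
                               start0=r.pos0, end=r.pos0 + length,
                               strand=r.strand, identity=r.identity))
    return hits


def expand_placements(records: Sequence[AlignmentRecord], genome_map: GenomeMap,
                      locus_length: Callable[[str], int]) -> list[GenomicHit]:
    """Flatten primary + alternative placements into one GenomicHit each."""
    hits = []
    for r in records:
        placements = [(r.chrom, r.pos0, r.strand, r.identity)]
        placements += [(p.chrom, p.pos0, p.strand,
                        1.0 - p.distance / max(locus_length(r.query_id), 1))
                       for p in r.alt_placements]
        for chrom, pos0, strand, ident in placements:
            rec = genome_map.chrom(chrom)
            hits.append(GenomicHit(locus_id=r.query_id, chrom=chrom,
                                   linkage_group=rec.linkage_group,
                                   subgenome=rec.subgenome,
                                   haplotype=rec.haplotype, start0=pos0,
                                   end=pos0 + locus_length(r.query_id),
                                   strand=strand, identity=ident))
    return hits


def pollen_bivalent_pipeline(bundle, reads, alt_rule: str = "==1",
                             margin_threshold: float = 0.5,
                             min_depth: int = 5,
                             taxon: str = "",
                             k: int = 15,
                             index: KmerIndex | None = None):
    """simulate -> back-map -> consensus -> map -> filter -> count -> call.

    ``reads`` is a ReadSet of pollen (target-enrichment) reads; returns
    (BivalentCall, SCOHitTable, records).
    """
    if reads.seqs is None:
        raise CaninakitError("pollen pipeline needs read sequences")
    consensus = build_consensus_reference(bundle.targets, reads.seqs,
                                          min_depth=min_depth)
    if index is None:
        index = KmerIndex(bundle.seqs, k=k)
    records = map_loci_to_genome(consensus, index)
    retained = filter_alt_hits(records, rule=alt_rule)
    table = count_hits(retained, bundle.genome_map, taxon=taxon)
    call = assign_bivalent_subgenome(table, bundle.genome_map,
                                     margin_threshold=margin_threshold)
    return call, table, retained


# ------------------------------------------------------------------ export
def export_concatenated_loci(bundle, locus_order: Sequence[str] | None = None
                             ) -> dict[str, str]:
    """Per-subgenome concatenated SCO sequences in a fixed locus order.

    Minus-strand loci are reverse-complemented so every subgenome's
    concatenation is orientation-consistent; haplotype h1 represents
    the duplicated subgenome.  Intended for external tree building.
    """
    from ._seq import revcomp_codes

    sco = bundle.truth.sco
    if locus_order is None:
        locus_order = sorted(sco["locus_id"].unique())
    out = {}
    for sub in bundle.genome_map.subgenomes:
        parts = []
        for locus in locus_order:
            rows = sco[(sco["locus_id"] == locus) & (sco["subgenome"] == sub)]
            rows = rows[rows["haplotype"].isin(["h1", "."])]
            if not len(rows):
                continue
            r = rows.iloc[0]
            arr = bundle.seqs[r["chrom"]][r["start0"]:r["end"]]
            if r["strand"] == "-":
                arr = revcomp_codes(arr)
            parts.append(decode(arr))
        out[sub] = "".join(parts)
    return out
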