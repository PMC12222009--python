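"""Minimal seeded k-mer-anchor read/locus mapper.

Placement search anchors exact k-mers sampled along the query into a
sorted-array index of the reference, clusters anchor hits by alignment
diagonal, and scores each candidate region with a banded edit-distance
alignment (edlib, infix mode).  Placements whose edit distance lies
within ``alt_margin`` of the best are reported as alternatives — the
bwa ``XA:Z:`` semantics the pollen-SCO filtering relies on: a locus
consensus derived from bivalent reads lands on one haplotype with the
other near-identical haplotype as its single alternative, while
placements on diverged subgenomes fall outside the margin.

This mapper is adequate for the substitution-only reads and loci the
synthetic generator produces; real-data users can supply SAM
alignments from any external aligner instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import edlib
import numpy as np

from ._seq import decode, encode, revcomp_codes


@dataclass(frozen=True)
class Placement:
    chrom: str
    pos0: int
    strand: str
    distance: int
    cigar: Optional[str] = None


@dataclass
class AlignmentRecord:
    """A mapped query with its primary placement and XA-style alternatives."""

    query_id: str
    chrom: str
    pos0: int
    strand: str = "+"
    mapq: int = 60
    distance: int = 0
    identity: float = 1.0
    seq: Optional[str] = None
    alt_placements: list[Placement] = field(default_factory=list)

    @property
    def n_alt(self) -> int:
        return len(self.alt_placements)


def default_alt_margin(query_length: int) -> int:
    """Edit-distance slack separating haplotype-level from subgenome-level hits.

    Roughly one haplotype's worth of divergence (~1.2%) plus a floor for
    short queries; subgenome pairs diverge by >=2.5% at generator defaults.
    """
    return max(3, int(round(0.012 * query_length)))


class KmerIndex:
    """Sorted-code k-mer index over a set of reference sequences."""

    def __init__(self, seqs: Mapping[str, np.ndarray], k: int = 15, stride: int = 4):
        if k < 8 or k > 31:
            raise ValueError("k must be in [8, 31]")
        self.k = k
        self.stride = stride
        self.chrom_names = list(seqs)
        self.seqs = {name: np.ascontiguousarray(arr, dtype=np.uint8)
                     for name, arr in seqs.items()}
        lengths = np.array([len(self.seqs[n]) for n in self.chrom_names], dtype=np.int64)
        # global coordinate layout with k-sized gaps so no k-mer spans chromosomes
        self.offsets = np.concatenate([[0], np.cumsum(lengths + k)])[:-1]
        self.lengths = lengths

        codes_parts, pos_parts = [], []
        for name, off in zip(self.chrom_names, self.offsets):
            codes = self._codes(self.seqs[name])
            sel = np.arange(0, len(codes), stride)
            codes_parts.append(codes[sel])
            pos_parts.append(sel + off)
        all_codes = np.concatenate(codes_parts) if codes_parts else np.empty(0, np.int64)
        all_pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        order = np.argsort(all_codes, kind="stable")
        self._codes_sorted = all_codes[order]
        self._pos_sorted = all_pos[order]

    def _codes(self, arr: np.ndarray) -> np.ndarray:
        """Integer code of every k-mer (Horner scheme, k passes)."""
        n = len(arr) - self.k + 1
        if n <= 0:
            return np.empty(0, dtype=np.int64)
        out = np.zeros(n, dtype=np.int64)
        for j in range(self.k):
            out = out * 4 + arr[j:j + n]
        return out

    def _chrom_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, gpos, side="right") - 1

    def lookup(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (query_kmer_index, global_position) anchor pairs."""
        lo = np.searchsorted(self._codes_sorted, codes, side="left")
        hi = np.searchsorted(self._codes_sorted, codes, side="right")
        counts = hi - lo
        qidx = np.repeat(np.arange(len(codes)), counts)
        if len(qidx) == 0:
            return qidx, np.empty(0, dtype=np.int64)
        gpos = np.concatenate([self._pos_sorted[a:b] for a, b in zip(lo, hi) if b > a])
        return qidx, gpos

    def map_query(self, query, query_id: str = "q",
                  alt_margin: int | None = None,
                  max_candidates: int = 12,
                  min_anchor_votes: int = 1) -> Optional[AlignmentRecord]:
        """Map one query; returns None when no anchor cluster aligns."""
        qcodes_arr = encode(query) if isinstance(query, str) else np.asarray(query, np.uint8)
        qlen = len(qcodes_arr)
        if qlen < self.k:
            return None
        if alt_margin is None:
            alt_margin = default_alt_margin(qlen)
        max_dist = int(0.12 * qlen) + alt_margin  # saturation guard for the banded search

        placements: list[Placement] = []
        for strand, qarr in (("+", qcodes_arr), ("-", revcomp_codes(qcodes_arr))):
            step = max(1, self.stride // 2) if qlen < 200 else self.stride
            starts = np.arange(0, qlen - self.k + 1, step)
            codes = np.zeros(len(starts), dtype=np.int64)
            for j in range(self.k):
                codes = codes * 4 + qarr[starts + j]
            qidx, gpos = self.lookup(codes)
            if len(gpos) == 0:
                continue
            diag = gpos - starts[qidx]
            # cluster anchors on nearby diagonals
            band = 24
            keys, votes = np.unique(diag // band, return_counts=True)
            order = np.argsort(votes)[::-1]
            for rank in order[:max_candidates]:
                if votes[rank] < min_anchor_votes:
                    continue
                d0 = int(keys[rank]) * band
                ci = int(np.searchsorted(self.offsets, d0, side="right") - 1)
                ci = max(0, min(ci, len(self.chrom_names) - 1))
                chrom = self.chrom_names[ci]
                local = d0 - int(self.offsets[ci])
                lo = max(0, local - band - 8)
                hi = min(int(self.lengths[ci]), local + qlen + 2 * band + 8)
                if hi - lo < qlen // 2:
                    continue
                region = decode(self.seqs[chrom][lo:hi])
                res = edlib.align(decode(qarr), region, mode="HW", task="locate",
                                  k=max_dist)
                if res["editDistance"] < 0:
                    continue
                s0, e0 = res["locations"][0]
                if s0 is None:
                    s0 = max(0, (e0 or qlen - 1) - qlen + 1)
                placements.append(Placement(chrom, int(lo + s0), strand,
                                            int(res["editDistance"])))

        if not placements:
            return None
        # dedupe near-identical placements, keep best distance
        best_at: dict[tuple, Placement] = {}
        for p in placements:
            key = (p.chrom, p.strand, p.pos0 // 50)
            if key not in best_at or p.distance < best_at[key].distance:
                best_at[key] = p
        uniq = sorted(best_at.values(), key=lambda p: (p.distance, p.chrom, p.pos0))
        primary = uniq[0]
        alts = [p for p in uniq[1:] if p.distance <= primary.distance + alt_margin]
        return AlignmentRecord(
            query_id=query_id,
            chrom=primary.chrom,
            pos0=primary.pos0,
            strand=primary.strand,
            mapq=0 if alts and alts[0].distance == primary.distance else 60,
            distance=primary.distance,
            identity=1.0 - primary.distance / max(qlen, 1),
            alt_placements=alts,
        )

    def map_queries(self, queries: Mapping[str, str] | Sequence[tuple[str, str]],
                    **kwargs) -> list[AlignmentRecord]:
        items = queries.items() if isinstance(queries, Mapping) else queries
        out = []
        for qid, seq in items:
            rec = self.map_query(seq, query_id=qid, **kwargs)
            if rec is not None:
                out.append(rec)
        return out


def exhaustive_placements(query: str, seqs: Mapping[str, np.ndarray],
                          max_distance: int) -> list[Placement]:
    """Brute-force oracle: scan every chromosome (both strands) with edlib.

    Independent of the anchor index; used to validate the mapper on
    small references.
    """
    out = []
    qarr = encode(query)
    for strand, q in (("+", qarr), ("-", revcomp_codes(qarr))):
        qs = decode(q)
        for chrom, arr in seqs.items():
            res = edlib.align(qs, decode(arr), mode="HW", task="locate", k=max_distance)
            if res["editDistance"] < 0:
                continue
            seen = set()
            for s0, e0 in res["locations"]:
                if s0 is None:
                    s0 = max(0, (e0 if e0 is not None else len(qs) - 1) - len(qs) + 1)
                if s0 // 50 in seen:
                    continue
                seen.add(s0 // 50)
                out.append(Placement(chrom, int(s0), strand, int(res["editDistance"])))
    return sorted(out, key=lambda p: (p.distance, p.chrom, p.pos0))
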