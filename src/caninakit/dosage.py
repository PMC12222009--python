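"""Hybrid subgenome dosage from windowed coverage and parent-unique SNPs.

A hybrid seedling's per-subgenome copy number shows up as relative
read depth on a one-copy-per-subgenome reference: the doubled
subgenome (the paternal bivalent contribution) runs at twice the
baseline.  Copy number is read off the ratio of per-subgenome median
window depth to a baseline median — deliberately no HMM or
segmentation, since medians are robust to repeat-rich windows (which
are additionally excluded when an annotation is supplied).  Parental
contributions are verified independently from SNPs unique to one
parent: the fraction of each parent's private alleles observed in the
hybrid pileup.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CaninakitError
from .genome_map import GenomeMap


@dataclass
class CoverageTrack:
    df: pd.DataFrame       # chrom, start0, end, depth
    window_size: int

    def to_bedgraph(self, path, header_comment=None):
        from .io import write_bedgraph

        out = self.df.rename(columns={"depth": "value"})
        write_bedgraph(out, path, header_comment=header_comment)


@dataclass
class DosageCall:
    copy_number: dict                  # subgenome -> int
    modal_depth: dict                  # subgenome -> median window depth
    ratio: dict                        # subgenome -> depth / baseline
    confident: dict                    # subgenome -> bool
    baseline_depth: float

    def as_dict(self):
        return {"copy_number": self.copy_number, "modal_depth": self.modal_depth,
                "ratio": self.ratio, "confident": self.confident,
                "baseline_depth": self.baseline_depth}


@dataclass
class ContributionReport:
    fractions: dict                    # parent -> observed fraction
    observed: dict                     # parent -> count observed
    total: dict                        # parent -> count total

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p, self.observed[p], self.total[p], self.fractions[p])
             for p in sorted(self.fractions)],
            columns=["parent", "observed", "total", "fraction"])


# ---------------------------------------------------------------- coverage
def window_coverage(alignments: pd.DataFrame,
                    chrom_lengths: Mapping[str, int],
                    window_size: int = 100_000) -> CoverageTrack:
    """Mean per-base depth in tiling windows from an alignment table.

    ``alignments`` columns: chrom, start0, end (sorted by chrom,
    start0).  Windows are half-open; the last window of a chromosome
    may be short.  Chromosomes with no alignments get all-zero windows.
    """
    if window_size <= 0:
        raise CaninakitError("window_size must be positive")
    rows = []
    aln_by_chrom = dict(tuple(alignments.groupby("chrom", sort=False))) \
        if len(alignments) else {}
    for chrom, length in chrom_lengths.items():
        n_win = int(np.ceil(length / window_size))
        starts = np.arange(n_win, dtype=np.int64) * window_size
        ends = np.minimum(starts + window_size, length)
        bp = np.zeros(n_win)
        sub = aln_by_chrom.get(chrom)
        if sub is not None and len(sub):
            s = sub["start0"].to_numpy(dtype=np.int64)
            e = sub["end"].to_numpy(dtype=np.int64)
            if np.any(np.diff(s) < 0):
                raise CaninakitError(f"unsorted alignments on {chrom}")
            if s.min() < 0 or e.max() > length:
                raise CaninakitError(f"alignment outside {chrom} bounds")
            # per-base depth via a difference array, then window sums
            diff = np.zeros(length + 1)
            np.add.at(diff, s, 1.0)
            np.add.at(diff, e, -1.0)
            depth = np.cumsum(diff[:-1])
            edges = np.append(starts, length)
            bp = np.add.reduceat(depth, edges[:-1])
        rows.append(pd.DataFrame({"chrom": chrom, "start0": starts, "end": ends,
                                  "depth": bp / (ends - starts)}))
    return CoverageTrack(df=pd.concat(rows, ignore_index=True),
                         window_size=window_size)


def call_dosage(track: CoverageTrack, genome_map: GenomeMap,
                baseline: Sequence[str],
                repeat_annotation: pd.DataFrame | None = None,
                repeat_overlap: float = 0.5,
                tolerance: float = 0.25) -> DosageCall:
    """Integer copy number per subgenome from median window-depth ratios.

    ``baseline`` names the subgenomes assumed present at one copy; the
    baseline depth is the median window depth over them.  A call is
    flagged non-confident when its ratio sits farther than
    ``tolerance`` from the nearest integer.  Windows overlapping
    repeat annotation by more than ``repeat_overlap`` are excluded
    from the medians.
    """
    df = track.df.copy()
    if repeat_annotation is not None and len(repeat_annotation):
        keep = np.ones(len(df), dtype=bool)
        for i, row in enumerate(df.itertuples()):
            sub = repeat_annotation[(repeat_annotation["chrom"] == row.chrom)
                                    & (repeat_annotation["end"] > row.start0)
                                    & (repeat_annotation["start0"] < row.end)]
            if len(sub):
                ov = (np.minimum(sub["end"], row.end)
                      - np.maximum(sub["start0"], row.start0)).clip(lower=0).sum()
                if ov > repeat_overlap * (row.end - row.start0):
                    keep[i] = False
        df = df[keep]

    sub_of = {}
    for chrom in df["chrom"].unique():
        if chrom not in genome_map:
            raise CaninakitError(f"track chromosome {chrom!r} not in genome map")
        sub_of[chrom] = genome_map.chrom(chrom).subgenome
    df = df.assign(subgenome=df["chrom"].map(sub_of))

    for b in baseline:
        if not any(s == b for s in sub_of.values()):
            raise CaninakitError(f"baseline subgenome {b!r} absent from track")
    base_depth = float(df[df["subgenome"].isin(list(baseline))]["depth"].median())
    if base_depth <= 0:
        raise CaninakitError("zero baseline depth")

    medians, ratios, copies, conf = {}, {}, {}, {}
    for sub, grp in df.groupby("subgenome", sort=True):
        m = float(grp["depth"].median())
        r = m / base_depth
        cn = int(round(r))
        medians[sub], ratios[sub], copies[sub] = m, r, max(cn, 0)
        conf[sub] = abs(r - round(r)) <= tolerance
    return DosageCall(copy_number=copies, modal_depth=medians, ratio=ratios,
                      confident=conf, baseline_depth=base_depth)


# -------------------------------------------------------------------- SNPs
@dataclass
class SnpSet:
    df: pd.DataFrame  # chrom, pos0, ref, alt, parent, multiallelic

    def __len__(self):
        return len(self.df)

    def for_parent(self, parent: str) -> pd.DataFrame:
        return self.df[self.df["parent"] == parent]


def _dedupe_variants(df: pd.DataFrame, label: str) -> pd.DataFrame:
    df = df.copy()
    df["multiallelic"] = False
    dup = df.duplicated(subset=["chrom", "pos0"], keep=False)
    conflict = dup & df.duplicated(subset=["chrom", "pos0", "alt"], keep=False).eq(False)
    if conflict.any():
        warnings.warn(f"{label}: {int(conflict.sum())} records at multi-allelic "
                      "positions kept with a flag")
        df.loc[dup, "multiallelic"] = True
    return df.drop_duplicates(subset=["chrom", "pos0", "ref", "alt"])


def parent_unique_snps(parent1: pd.DataFrame, parent2: pd.DataFrame,
                       labels: tuple[str, str] = ("parent1", "parent2")) -> SnpSet:
    """Variants private to exactly one parent (symmetric difference).

    Inputs share one reference coordinate system with columns chrom,
    pos0, ref, alt.  Identity is position + allele.
    """
    p1 = _dedupe_variants(parent1, labels[0])
    p2 = _dedupe_variants(parent2, labels[1])
    key = ["chrom", "pos0", "ref", "alt"]
    k1 = set(map(tuple, p1[key].itertuples(index=False)))
    k2 = set(map(tuple, p2[key].itertuples(index=False)))
    u1 = p1[[tuple(r) in (k1 - k2) for r in p1[key].itertuples(index=False)]]
    u2 = p2[[tuple(r) in (k2 - k1) for r in p2[key].itertuples(index=False)]]
    out = pd.concat([u1.assign(parent=labels[0]), u2.assign(parent=labels[1])],
                    ignore_index=True)
    return SnpSet(df=out[key + ["parent", "multiallelic"]])


def pileup_at_sites(reads_truth: pd.DataFrame, read_seqs: Sequence[str],
                    sites: pd.DataFrame, read_length: int,
                    collapse: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Base counts at given sites from a ReadSet (plus-strand base space).

    Returns rows (chrom, pos0, base, count).  Read sequences are
    reported on the sequencing strand; minus-strand reads are
    complement-corrected back to reference space.
    """
    from ._seq import revcomp

    chrom_col = reads_truth["chrom"]
    if collapse:
        chrom_col = chrom_col.map(lambda c: collapse.get(c, c))
    rows: dict[tuple, int] = {}
    for chrom, site_grp in sites.groupby("chrom"):
        mask = (chrom_col == chrom).to_numpy()
        if not mask.any():
            continue
        starts = reads_truth["start0"].to_numpy()[mask]
        strands = reads_truth["strand"].to_numpy()[mask]
        idxs = np.flatnonzero(mask)
        order = np.argsort(starts, kind="stable")
        starts, strands, idxs = starts[order], strands[order], idxs[order]
        for pos in np.sort(site_grp["pos0"].unique()):
            lo = np.searchsorted(starts, pos - read_length + 1, side="left")
            hi = np.searchsorted(starts, pos, side="right")
            for j in range(lo, hi):
                s = starts[j]
                seq = read_seqs[idxs[j]]
                if strands[j] == "-":
                    seq = revcomp(seq)
                base = seq[pos - s]
                rows[(chrom, int(pos), base)] = rows.get((chrom, int(pos), base), 0) + 1
    return pd.DataFrame([(c, p, b, n) for (c, p, b), n in rows.items()],
                        columns=["chrom", "pos0", "base", "count"])


def snp_contribution(pileup: pd.DataFrame, snps: SnpSet,
                     min_depth: int = 1) -> ContributionReport:
    """Fraction of each parent's unique alleles observed in the hybrid.

    An allele counts as observed when at least one hybrid read carries
    it at a site with total depth >= ``min_depth``.
    """
    if min_depth < 1:
        raise CaninakitError("min_depth must be >= 1")
    if not len(snps.df):
        raise CaninakitError("empty SnpSet")
    depth = pileup.groupby(["chrom", "pos0"])["count"].sum()
    alleles = pileup.set_index(["chrom", "pos0", "base"])["count"]
    if len(depth) == 0 or (depth >= min_depth).sum() == 0:
        raise CaninakitError("no site reaches the minimum depth")
    fractions, observed, totals = {}, {}, {}
    for parent, grp in snps.df.groupby("parent"):
        n_obs = 0
        for r in grp.itertuples():
            key = (r.chrom, r.pos0)
            if key in depth.index and depth[key] >= min_depth:
                if alleles.get((r.chrom, r.pos0, r.alt), 0) >= 1:
                    n_obs += 1
        observed[parent] = n_obs
        totals[parent] = len(grp)
        fractions[parent] = n_obs / len(grp) if len(grp) else 0.0
    return ContributionReport(fractions=fractions, observed=observed, total=totals)


# ------------------------------------------------- generator-truth helpers
def variants_vs_reference(bundle, chrom: str, ref_chrom: str,
                          ref_bundle=None) -> pd.DataFrame:
    """Variant set of one chromosome copy against a reference copy.

    Both copies live on the shared ancestor coordinate frame (no
    indels), so variants are the positionwise sequence differences —
    reported on reference coordinates, excluding the planted repeat
    space of either copy (tandem arrays are not alignable).  Used to
    derive parent VCFs from generator truth.
    """
    ref_bundle = ref_bundle or bundle
    a = bundle.seqs[chrom]
    r = ref_bundle.seqs[ref_chrom]
    mask = np.ones(len(a), dtype=bool)
    for bnd, c in ((bundle, chrom), (ref_bundle, ref_chrom)):
        cen = bnd.truth.centromeres
        for row in cen[cen["chrom"] == c].itertuples():
            mask[row.start0:row.end] = False
    pos = np.flatnonzero((a != r) & mask)
    from ._seq import _DECODE

    return pd.DataFrame({
        "chrom": ref_chrom, "pos0": pos,
        "ref": [chr(_DECODE[b]) for b in r[pos]],
        "alt": [chr(_DECODE[b]) for b in a[pos]]})
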