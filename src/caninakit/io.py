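"""Format readers and writers.

Internal coordinates are 0-based half-open everywhere; SAM/GFF3/VCF
(1-based inclusive) are converted at this boundary.  Writers accept an
optional header comment (the run pipeline passes its config hash).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

# --------------------------------------------------------------- config hash
def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


# -------------------------------------------------------------------- FASTA
def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -------------------------------------------------------------------- FASTQ
def write_fastq(names: Sequence[str], seqs: Sequence[str], path,
                quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in zip(names, seqs):
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path) -> tuple[list[str], list[str]]:
    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return names, seqs


# ------------------------------------------------------------------ tabular
def write_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_json(obj, path, header: Mapping | None = None) -> None:
    payload = dict(header or {})
    payload.update(obj if isinstance(obj, Mapping) else {"data": obj})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------- BED
BED_COLUMNS = ["chrom", "start0", "end", "name", "score", "strand"]


def write_bed(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df[cols].to_csv(fh, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(path, i, "BED line has fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(path, i, "non-integer BED coordinates") from None
            if not 0 <= start < end:
                raise FormatError(path, i, f"invalid interval [{start}, {end})")
            row = {"chrom": parts[0], "start0": start, "end": end}
            for j, col in enumerate(("name", "score", "strand"), start=3):
                if len(parts) > j:
                    row[col] = parts[j]
            rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- bedGraph
def write_bedgraph(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """df columns: chrom, start0, end, value."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df[["chrom", "start0", "end", "value"]].to_csv(
            fh, sep="\t", index=False, header=False, float_format="%.6g")


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(path, i, "bedGraph line must have 4 fields")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError:
                raise FormatError(path, i, "malformed bedGraph values") from None
    return pd.DataFrame(rows, columns=["chrom", "start0", "end", "value"])


# --------------------------------------------------------------------- GFF3
GFF_COLUMNS = ["chrom", "source", "type", "start0", "end", "score", "strand",
               "phase", "attributes"]


def write_gff3(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """df uses internal 0-based half-open ``start0``/``end``; attributes is a
    dict column or a pre-formatted string column."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for row in df.itertuples():
            attrs = row.attributes
            if isinstance(attrs, Mapping):
                attrs = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write("\t".join([
                str(row.chrom),
                str(getattr(row, "source", "caninakit")),
                str(getattr(row, "type", "region")),
                str(int(row.start0) + 1),           # 1-based inclusive
                str(int(row.end)),
                str(getattr(row, "score", ".")),
                str(getattr(row, "strand", "+")),
                str(getattr(row, "phase", ".")),
                attrs or ".",
            ]) + "\n")


def read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(path, i, "GFF3 line must have 9 fields")
            try:
                start1, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise FormatError(path, i, "non-integer GFF3 coordinates") from None
            attrs = {}
            for item in parts[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = v
            rows.append({
                "chrom": parts[0], "source": parts[1], "type": parts[2],
                "start0": start1 - 1, "end": end, "score": parts[5],
                "strand": parts[6], "phase": parts[7], "attributes": attrs,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- VCF
def write_vcf(df: pd.DataFrame, path, sample: str = "sample",
              header_comment: str | None = None) -> None:
    """Minimal VCF: CHROM POS REF ALT from internal (chrom, pos0, ref, alt)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if header_comment:
            fh.write(f"##caninakit={header_comment}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in df.itertuples():
            fh.write(f"{row.chrom}\t{int(row.pos0) + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\n")


def read_vcf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(path, i, "VCF line has fewer than 5 fields")
            try:
                pos1 = int(parts[1])
            except ValueError:
                raise FormatError(path, i, "non-integer VCF POS") from None
            rows.append({"chrom": parts[0], "pos0": pos1 - 1,
                         "ref": parts[3], "alt": parts[4]})
    return pd.DataFrame(rows, columns=["chrom", "pos0", "ref", "alt"])


# ---------------------------------------------------------------------- SAM
def write_sam(records, chrom_lengths: Mapping[str, int], path) -> None:
    """Write AlignmentRecords (see caninakit.alignment) as a minimal SAM.

    Alternative placements are encoded in a bwa-style ``XA:Z:`` tag.
    """
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": name, "LN": int(length)}
                     for name, length in chrom_lengths.items()]}
    name_to_tid = {name: i for i, name in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.query_id
            a.reference_id = name_to_tid[rec.chrom]
            a.reference_start = rec.pos0
            a.mapping_quality = rec.mapq
            a.flag = 16 if rec.strand == "-" else 0
            seq = getattr(rec, "seq", None)
            if seq:
                a.query_sequence = seq
                a.cigarstring = f"{len(seq)}M"
            if rec.alt_placements:
                xa = "".join(
                    f"{p.chrom},{'+' if p.strand == '+' else '-'}{p.pos0 + 1},"
                    f"{p.cigar or '*'},{p.distance};"
                    for p in rec.alt_placements)
                a.set_tag("XA", xa)
            a.set_tag("NM", int(rec.distance))
            out.write(a)


def read_sam(path):
    """Parse a SAM file into AlignmentRecords, decoding XA alt placements."""
    import pysam

    from .alignment import AlignmentRecord, Placement

    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            alts = []
            if a.has_tag("XA"):
                for item in str(a.get_tag("XA")).rstrip(";").split(";"):
                    chrom, pos, cigar, nm = item.split(",")
                    strand, pos1 = pos[0], int(pos[1:])
                    alts.append(Placement(chrom, pos1 - 1, strand, int(nm), cigar))
            records.append(AlignmentRecord(
                query_id=a.query_name,
                chrom=a.reference_name,
                pos0=a.reference_start,
                strand="-" if a.is_reverse else "+",
                mapq=a.mapping_quality,
                distance=int(a.get_tag("NM")) if a.has_tag("NM") else 0,
                seq=a.query_sequence or None,
                alt_placements=alts,
            ))
    return records
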