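"""Chromosome metadata: name, linkage group, subgenome, haplotype, length.

Chromosome names follow the ``Rca<LG>_<subgenome>[_<hap>]`` convention,
e.g. ``Rca3_S1_h1`` or ``Rca3_R4``.  The duplicated (bivalent-forming)
subgenome carries a haplotype tag (``h1``/``h2``); single-copy
subgenomes do not.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import ConfigurationError


@dataclass(frozen=True)
class ChromRecord:
    name: str
    linkage_group: int
    subgenome: str
    haplotype: Optional[str]  # "h1"/"h2" on the duplicated subgenome, else None
    length: int


def chrom_name(linkage_group: int, subgenome: str, haplotype: str | None = None,
               prefix: str = "Rca") -> str:
    base = f"{prefix}{linkage_group}_{subgenome}"
    return f"{base}_{haplotype}" if haplotype else base


class GenomeMap:
    """Lookup table from chromosome name to its linkage group / subgenome."""

    def __init__(self, records: Iterable[ChromRecord]):
        records = list(records)
        self._records = {r.name: r for r in records}
        if len(self._records) < len(records):
            raise ConfigurationError("genome_map", "duplicate chromosome names")

    def __len__(self):
        return len(self._records)

    def __contains__(self, name):
        return name in self._records

    def __iter__(self):
        return iter(self._records.values())

    def chrom(self, name: str) -> ChromRecord:
        try:
            return self._records[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in genome map") from None

    @property
    def names(self) -> list[str]:
        return list(self._records)

    @property
    def subgenomes(self) -> list[str]:
        seen = []
        for r in self._records.values():
            if r.subgenome not in seen:
                seen.append(r.subgenome)
        return seen

    @property
    def linkage_groups(self) -> list[int]:
        return sorted({r.linkage_group for r in self._records.values()})

    def chroms(self, subgenome: str | None = None,
               linkage_group: int | None = None) -> list[ChromRecord]:
        out = []
        for r in self._records.values():
            if subgenome is not None and r.subgenome != subgenome:
                continue
            if linkage_group is not None and r.linkage_group != linkage_group:
                continue
            out.append(r)
        return out

    def copies_per_lg(self) -> int:
        lgs = self.linkage_groups
        counts = {lg: len(self.chroms(linkage_group=lg)) for lg in lgs}
        if len(set(counts.values())) != 1:
            raise ConfigurationError("genome_map", "unequal copy number across linkage groups")
        return next(iter(counts.values()))

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.name, r.linkage_group, r.subgenome, r.haplotype or ".", r.length)
             for r in self._records.values()],
            columns=["chrom", "linkage_group", "subgenome", "haplotype", "length"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeMap":
        recs = [
            ChromRecord(str(row.chrom), int(row.linkage_group), str(row.subgenome),
                        None if row.haplotype in (".", "", None) else str(row.haplotype),
                        int(row.length))
            for row in df.itertuples()
        ]
        return cls(recs)

    @classmethod
    def from_tsv(cls, path) -> "GenomeMap":
        return cls.from_frame(pd.read_csv(Path(path), sep="\t", comment="#"))
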