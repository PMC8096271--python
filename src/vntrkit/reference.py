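"""Reference tandem-repeat loci: the curated set genotypes are called against.

Each locus records its genomic interval (0-based half-open), repeat pattern,
reference copy number and the flanking sequence used for read-to-locus
matching, plus a flag marking members of *indistinguishable* families —
dispersed loci sharing near-identical pattern and flanks, which are excluded
from genotyping because reads cannot be attributed to one of them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator


@dataclass
class ReferenceTRLocus:
    locus_id: int
    chrom: str
    start: int  # 0-based, array start
    end: int  # half-open, array end
    pattern: str
    ref_copies: float
    left_flank: str = ""
    right_flank: str = ""
    indistinguishable: bool = False

    @property
    def pattern_length(self) -> int:
        return len(self.pattern)

    @property
    def array_length(self) -> int:
        return self.end - self.start

    def allele_array_length(self, cgl: int) -> int:
        """Array length in bp of the allele with ``cgl`` copies gained/lost."""
        return round(self.pattern_length * (self.ref_copies + cgl))


class ReferenceTRSet:
    """An ordered collection of reference TR loci with id lookup."""

    def __init__(self, loci: list[ReferenceTRLocus]):
        self.loci = list(loci)
        self._by_id = {loc.locus_id: loc for loc in self.loci}
        if len(self._by_id) != len(self.loci):
            raise ValueError("duplicate locus ids")

    def __iter__(self) -> Iterator[ReferenceTRLocus]:
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def __getitem__(self, locus_id: int) -> ReferenceTRLocus:
        return self._by_id[locus_id]

    def __contains__(self, locus_id: int) -> bool:
        return locus_id in self._by_id

    @property
    def singletons(self) -> list[ReferenceTRLocus]:
        return [loc for loc in self.loci if not loc.indistinguishable]

    def to_bed(self, path: str | Path) -> None:
        """Write locus intervals as BED (0-based half-open, name = locus id)."""
        with open(path, "w") as fh:
            for loc in self.loci:
                fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.locus_id}\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                [
                    "locus_id",
                    "chrom",
                    "start",
                    "end",
                    "pattern",
                    "ref_copies",
                    "left_flank",
                    "right_flank",
                    "indistinguishable",
                ]
            )
            for loc in self.loci:
                w.writerow(
                    [
                        loc.locus_id,
                        loc.chrom,
                        loc.start,
                        loc.end,
                        loc.pattern,
                        loc.ref_copies,
                        loc.left_flank,
                        loc.right_flank,
                        int(loc.indistinguishable),
                    ]
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceTRSet":
        loci = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                loci.append(
                    ReferenceTRLocus(
                        locus_id=int(row["locus_id"]),
                        chrom=row["chrom"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        pattern=row["pattern"],
                        ref_copies=float(row["ref_copies"]),
                        left_flank=row["left_flank"],
                        right_flank=row["right_flank"],
                        indistinguishable=bool(int(row["indistinguishable"])),
                    )
                )
        return cls(loci)
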