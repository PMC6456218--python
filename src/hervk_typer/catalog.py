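"""Catalog of HERV-K loci and their allele sequences.

A *locus* is a genomic site known to carry (or to have carried) a HERV-K
provirus. Each locus is represented by one or more *alleles* -- full
provirus sequences observed at that site -- with LTR intervals annotated in
allele coordinates. One allele per locus is designated *primary*; positions
on other alleles are projected onto it through a per-allele coordinate
offset. Coordinates are 0-based half-open internally; display labels use
the conventional 1-based "chrom:start-end" style.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")

__all__ = [
    "Allele",
    "Locus",
    "LocusCatalog",
    "CatalogError",
    "read_catalog",
    "write_catalog",
    "read_bed",
    "write_bed",
]


class CatalogError(ValueError):
    """Raised when a catalog violates its structural invariants."""


@dataclass
class Allele:
    """One observed sequence of a provirus at a locus.

    ``ltr_intervals`` are 0-based half-open [start, end) pairs in allele
    coordinates. ``offset`` shifts this allele's coordinates onto the
    locus's primary allele (0 for substitution-only alleles).
    """

    allele_id: str
    sequence: str
    ltr_intervals: list[tuple[int, int]] = field(default_factory=list)
    offset: int = 0
    primary: bool = False

    def validate(self) -> None:
        if not self.sequence:
            raise CatalogError(f"allele {self.allele_id}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise CatalogError(
                f"allele {self.allele_id}: non-ACGTN symbols {sorted(bad)}"
            )
        length = len(self.sequence)
        ivals = sorted(self.ltr_intervals)
        for start, end in ivals:
            if not (0 <= start < end <= length):
                raise CatalogError(
                    f"allele {self.allele_id}: LTR interval ({start},{end}) "
                    f"outside [0,{length})"
                )
        for (_, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise CatalogError(
                    f"allele {self.allele_id}: overlapping LTR intervals"
                )


@dataclass
class Locus:
    """A genomic HERV-K site with its catalogued alleles."""

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    alleles: list[Allele] = field(default_factory=list)
    reporting_group: str | None = None

    @property
    def primary_allele(self) -> Allele:
        for allele in self.alleles:
            if allele.primary:
                return allele
        return self.alleles[0]

    @property
    def label(self) -> str:
        """1-based display label in the field's chrom:start-end style."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def validate(self) -> None:
        if not self.alleles:
            raise CatalogError(f"locus {self.locus_id}: no alleles")
        if self.start < 0 or self.end <= self.start:
            raise CatalogError(f"locus {self.locus_id}: bad interval")
        n_primary = sum(a.primary for a in self.alleles)
        if n_primary > 1:
            raise CatalogError(f"locus {self.locus_id}: multiple primary alleles")
        for allele in self.alleles:
            allele.validate()


@dataclass
class LocusCatalog:
    """All loci under analysis. Locus ids must be distinct."""

    loci: list[Locus]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.loci:
            raise CatalogError("empty catalog")
        seen: set[str] = set()
        for locus in self.loci:
            if locus.locus_id in seen:
                raise CatalogError(f"duplicate locus_id {locus.locus_id}")
            seen.add(locus.locus_id)
            locus.validate()

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def get(self, locus_id: str) -> Locus:
        for locus in self.loci:
            if locus.locus_id == locus_id:
                return locus
        raise KeyError(locus_id)

    @property
    def locus_ids(self) -> list[str]:
        return [locus.locus_id for locus in self.loci]


def _format_ltrs(intervals: list[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in intervals) or "."


def _parse_ltrs(text: str) -> list[tuple[int, int]]:
    if text in ("", "."):
        return []
    out = []
    for part in text.split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return out


LOCUS_TABLE_COLUMNS = [
    "locus_id",
    "chrom",
    "start",
    "end",
    "strand",
    "allele_id",
    "primary_allele",
    "offset",
    "ltr_intervals",
    "reporting_group",
]


def write_catalog(catalog: LocusCatalog, fasta_path: str | Path, table_path: str | Path) -> None:
    """Write allele sequences to FASTA and locus structure to a TSV table."""
    records = []
    for locus in catalog:
        for allele in locus.alleles:
            records.append(
                SeqRecord(Seq(allele.sequence), id=allele.allele_id, description="")
            )
    SeqIO.write(records, str(fasta_path), "fasta")

    with open(table_path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(LOCUS_TABLE_COLUMNS)
        for locus in catalog:
            for allele in locus.alleles:
                writer.writerow(
                    [
                        locus.locus_id,
                        locus.chrom,
                        locus.start,
                        locus.end,
                        locus.strand,
                        allele.allele_id,
                        int(allele.primary),
                        allele.offset,
                        _format_ltrs(allele.ltr_intervals),
                        locus.reporting_group or ".",
                    ]
                )


def read_catalog(fasta_path: str | Path, table_path: str | Path) -> LocusCatalog:
    """Load a catalog from an allele FASTA plus a locus table TSV.

    FASTA headers carry allele ids; the table links alleles to loci and
    carries LTR intervals formatted "start-end;start-end".
    """
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    loci: dict[str, Locus] = {}
    with open(table_path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            locus_id = row["locus_id"]
            if locus_id not in loci:
                group = row.get("reporting_group") or "."
                loci[locus_id] = Locus(
                    locus_id=locus_id,
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row.get("strand", "+"),
                    reporting_group=None if group == "." else group,
                )
            allele_id = row["allele_id"]
            if allele_id not in sequences:
                raise CatalogError(f"allele {allele_id} missing from FASTA")
            loci[locus_id].alleles.append(
                Allele(
                    allele_id=allele_id,
                    sequence=sequences[allele_id],
                    ltr_intervals=_parse_ltrs(row.get("ltr_intervals", ".")),
                    offset=int(row.get("offset", 0) or 0),
                    primary=bool(int(row.get("primary_allele", 0) or 0)),
                )
            )
    return LocusCatalog(loci=list(loci.values()))


def write_bed(catalog: LocusCatalog, path: str | Path) -> None:
    """Write locus intervals as BED (0-based half-open)."""
    with open(path, "w") as handle:
        for locus in catalog:
            handle.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.locus_id}\t0\t{locus.strand}\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) intervals from a BED file."""
    intervals = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return intervals
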