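"""Shared coordinate model, sequence utilities and format readers/writers.

All internal coordinates are 0-based half-open, matching BED. External
tables in 1-based closed convention are converted at the boundary and
never leak inward.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import pandas as pd

ASSAYS = ("DNASE", "H3K4ME3")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input stream violates its declared format."""


@dataclass(frozen=True)
class GenomicRegion:
    """A named half-open interval on an assembly.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``gene_strand`` is the
    genomic strand of the host gene the region belongs to ("." when the
    region is intergenic), used downstream to order module labels in gene
    sense.
    """

    chrom: str
    start: int
    end: int
    name: str
    assembly: str = "hg19"
    gene_strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"region {self.name!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.gene_strand not in ("+", "-", "."):
            raise ValueError(f"region {self.name!r}: bad gene_strand {self.gene_strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) shares >= 1 bp with this region."""
        return chrom == self.chrom and start < self.end and end > self.start


@dataclass(frozen=True)
class HotspotRecord:
    """One called hotspot interval of one assay in one cell type."""

    chrom: str
    start: int
    end: int
    cell_type: str
    assay: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"hotspot: start {self.start} >= end {self.end}")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")


@dataclass(frozen=True)
class StrandedSequence:
    """Carrier for FASTA content (genome slices, ESTs, primers)."""

    id: str
    residues: str
    strand: str = "+"

    def __post_init__(self) -> None:
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ValueError(f"sequence {self.id!r}: residues outside ACGTN: {sorted(bad)}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"sequence {self.id!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (N maps to N)."""
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"residues outside ACGTN: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_bed(stream: Iterable[str] | TextIO, assay: str, cell_type: str) -> list[HotspotRecord]:
    """Read BED3+ hotspot intervals, tagging each with assay and cell type.

    Coordinates are taken verbatim (BED is already 0-based half-open).
    ``track`` and ``#`` comment lines and blank lines are skipped.
    Malformed lines raise :class:`FormatError` naming the 1-based line.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    records: list[HotspotRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"line {lineno}: expected >=3 tab-separated fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(f"line {lineno}: non-integer coordinates") from None
        if start >= end:
            raise FormatError(f"line {lineno}: start {start} >= end {end}")
        records.append(HotspotRecord(chrom, start, end, cell_type, assay))
    return records


def write_bed(records: Iterable[HotspotRecord], stream: TextIO) -> None:
    """Write hotspots as BED3 in input order (round-trips read_bed)."""
    for rec in records:
        stream.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\n")


_CONVENTIONS = ("0-half-open", "1-closed")


def read_region_table(stream: TextIO | str) -> list[GenomicRegion]:
    """Read a region coordinate table (TSV) into 0-based half-open regions.

    Required columns: ``name, chrom, start, end, coordinate_convention``
    where the convention is ``0-half-open`` or ``1-closed``; 1-closed rows
    are converted by ``start <- start - 1``. Optional columns ``assembly``
    and ``gene_strand`` are carried through. Duplicate names and unknown
    convention tags are rejected.
    """
    df = pd.read_csv(stream, sep="\t", comment="#", dtype=str)
    required = {"name", "chrom", "start", "end", "coordinate_convention"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"region table missing columns: {sorted(missing)}")
    if df["name"].duplicated().any():
        dups = df.loc[df["name"].duplicated(), "name"].tolist()
        raise FormatError(f"duplicate region names: {dups}")
    regions: list[GenomicRegion] = []
    for _, row in df.iterrows():
        conv = row["coordinate_convention"]
        if conv not in _CONVENTIONS:
            raise FormatError(
                f"region {row['name']!r}: unknown coordinate convention {conv!r}"
            )
        start, end = int(row["start"]), int(row["end"])
        if conv == "1-closed":
            start -= 1
        regions.append(
            GenomicRegion(
                chrom=row["chrom"],
                start=start,
                end=end,
                name=row["name"],
                assembly=row.get("assembly", "hg19") if "assembly" in df.columns else "hg19",
                gene_strand=row["gene_strand"] if "gene_strand" in df.columns else ".",
            )
        )
    return regions


def write_region_table(regions: Iterable[GenomicRegion], stream: TextIO) -> None:
    """Write regions in the 0-half-open convention of the internal model."""
    stream.write("name\tchrom\tstart\tend\tcoordinate_convention\tassembly\tgene_strand\n")
    for r in regions:
        stream.write(
            f"{r.name}\t{r.chrom}\t{r.start}\t{r.end}\t0-half-open\t{r.assembly}\t{r.gene_strand}\n"
        )


def read_fasta(stream: TextIO | str) -> list[StrandedSequence]:
    """Read FASTA records, uppercased, restricted to ACGTN."""
    from Bio import SeqIO

    handle = io.StringIO(stream) if isinstance(stream, str) and "\n" in stream else stream
    if isinstance(handle, str):
        with open(handle) as fh:
            return read_fasta(fh)
    return [
        StrandedSequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(handle, "fasta")
    ]


def write_fasta(seqs: Iterable[StrandedSequence], stream: TextIO, width: int = 70) -> None:
    for s in seqs:
        stream.write(f">{s.id}\n")
        for i in range(0, len(s.residues), width):
            stream.write(s.residues[i : i + width] + "\n")
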