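"""Stranded CAGE-derived TSS counting per module.

TSS predictions arrive as stranded BED6 intervals (one per cell type and
predicted start). Each interval is reduced to a single representative
base, its 5' end in transcription sense, and tallied into the module
containing it, split by genomic strand and summed over cell types — no
cross-cell-type deduplication, matching bar-chart totals over all cell
types. A ``dedupe`` switch collapses identical (position, strand) calls
across cell types when a per-site view is wanted instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .binning import ModuleBin
from .core import FormatError


@dataclass(frozen=True)
class TssPrediction:
    chrom: str
    position: int  # single 0-based base
    strand: str
    cell_type: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS prediction requires strand '+' or '-', got {self.strand!r}")


@dataclass
class StrandedTssCounts:
    """Per-module plus/minus totals plus an outside-all-modules tally."""

    region: str
    modules: list[ModuleBin]
    plus: dict[str, int]
    minus: dict[str, int]
    outside_plus: int = 0
    outside_minus: int = 0

    @property
    def total(self) -> int:
        return (
            sum(self.plus.values())
            + sum(self.minus.values())
            + self.outside_plus
            + self.outside_minus
        )

    def to_frame(self, gene_strand: str = ".") -> pd.DataFrame:
        """Long table of counts; ``sense_to_gene`` is derived when the host
        gene strand is known ('sense' = same strand as the gene)."""
        rows = []
        for mod in self.modules:
            for strand, table in (("+", self.plus), ("-", self.minus)):
                sense = "." if gene_strand == "." else (
                    "sense" if strand == gene_strand else "antisense"
                )
                rows.append(
                    {
                        "module_label": mod.label,
                        "strand": strand,
                        "count": table[mod.label],
                        "sense_to_gene": sense,
                    }
                )
        return pd.DataFrame(rows)


def load_tss(stream: Iterable[str] | TextIO, cell_type: str = "") -> list[TssPrediction]:
    """Read BED6 TSS predictions, reducing intervals to their 5' base.

    The representative base is the interval start for '+' records and
    ``end - 1`` for '-' records (a 1-bp interval maps to that base either
    way). A record without a strand field is rejected with its line number.
    """
    preds: list[TssPrediction] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(f"line {lineno}: BED6 required (strand missing)")
        chrom, start, end, strand = fields[0], int(fields[1]), int(fields[2]), fields[5]
        if strand not in ("+", "-"):
            raise FormatError(f"line {lineno}: bad strand {strand!r}")
        position = start if strand == "+" else end - 1
        preds.append(TssPrediction(chrom, position, strand, cell_type))
    return preds


def count_tss(
    modules: Sequence[ModuleBin],
    predictions: Iterable[TssPrediction],
    region_chrom: str,
    dedupe: bool = False,
) -> StrandedTssCounts:
    """Tally predictions into the module containing their position.

    Modules are half-open, so a prediction exactly at a boundary base
    belongs to the downstream (genomically later) module. Predictions on
    the region chromosome but outside all modules go to the outside tally;
    other chromosomes are ignored entirely.
    """
    modules = list(modules)
    if not modules:
        raise ValueError("no modules supplied")
    preds = list(predictions)
    if dedupe:
        seen: dict[tuple[str, int, str], TssPrediction] = {}
        for p in preds:
            seen.setdefault((p.chrom, p.position, p.strand), p)
        preds = list(seen.values())
    region_start, region_end = modules[0].start, modules[-1].end
    width = modules[0].width
    plus = {m.label: 0 for m in modules}
    minus = {m.label: 0 for m in modules}
    out_plus = out_minus = 0
    for p in preds:
        if p.chrom != region_chrom:
            continue
        if region_start <= p.position < region_end:
            idx = min((p.position - region_start) // width, len(modules) - 1)
            label = modules[idx].label
            if p.strand == "+":
                plus[label] += 1
            else:
                minus[label] += 1
        else:
            if p.strand == "+":
                out_plus += 1
            else:
                out_minus += 1
    return StrandedTssCounts(
        region=modules[0].parent,
        modules=modules,
        plus=plus,
        minus=minus,
        outside_plus=out_plus,
        outside_minus=out_minus,
    )
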