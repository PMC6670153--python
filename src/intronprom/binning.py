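"""Fixed-width module binning and cross-cell-type hotspot prevalence.

A region is subdivided into contiguous modules of a configured width
(2,500 bp by default, the last module truncated to the region end), and
for each module and assay we count how many distinct cell types show at
least one hotspot overlapping the module by >= 1 bp. For a gene region on
the genomic minus strand, module labels I, II, ... run in gene sense, i.e.
in descending genomic coordinate.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .core import ASSAYS, GenomicRegion, HotspotRecord

DEFAULT_MODULE_WIDTH = 2500

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def to_roman(n: int) -> str:
    if n <= 0:
        raise ValueError("Roman numerals start at 1")
    out = []
    for value, glyph in _ROMAN:
        while n >= value:
            out.append(glyph)
            n -= value
    return "".join(out)


@dataclass(frozen=True)
class ModuleBin:
    """One fixed-width subdivision of a region (half-open, genomic coords)."""

    parent: str
    index: int  # 1-based ordinal in genomic (ascending) order
    label: str  # Roman numeral in the configured label orientation
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start


LabelOrientation = Literal["gene_sense", "genomic"]


def make_modules(
    region: GenomicRegion,
    module_width: int = DEFAULT_MODULE_WIDTH,
    label_orientation: LabelOrientation = "gene_sense",
) -> list[ModuleBin]:
    """Subdivide ``region`` into ceil(length/width) contiguous modules.

    Modules are anchored at the region's lower genomic coordinate and
    returned in ascending genomic order; only the last may be truncated.
    With ``label_orientation="gene_sense"`` and a minus-strand gene, Roman
    labels I, II, ... are assigned from the highest genomic coordinate
    downward so that label order follows the direction of transcription;
    otherwise labels follow genomic order.
    """
    if module_width <= 0:
        raise ValueError(f"module_width must be positive, got {module_width}")
    n = -(-region.length // module_width)  # ceil
    reverse = label_orientation == "gene_sense" and region.gene_strand == "-"
    modules = []
    for i in range(1, n + 1):
        start = region.start + (i - 1) * module_width
        end = min(region.start + i * module_width, region.end)
        label_index = n - i + 1 if reverse else i
        modules.append(ModuleBin(region.name, i, to_roman(label_index), start, end))
    return modules


@dataclass
class PrevalenceTable:
    """Per-(module label, assay) distinct-cell-type counts.

    ``counts[label][assay]`` is the number of distinct cell types with at
    least one hotspot overlapping the module; ``n_cell_types[assay]`` the
    total number of cell types supplied for that assay (the denominator of
    the published bar charts); ``n_skipped`` counts hotspots ignored for
    being on another chromosome.
    """

    region: str
    modules: list[ModuleBin]
    counts: dict[str, dict[str, int]]
    n_cell_types: dict[str, int]
    n_skipped: int = 0

    def count(self, label: str, assay: str) -> int:
        return self.counts[label][assay]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mod in self.modules:
            for assay in sorted(self.n_cell_types):
                rows.append(
                    {
                        "region": self.region,
                        "module_label": mod.label,
                        "start": mod.start,
                        "end": mod.end,
                        "assay": assay,
                        "count": self.counts[mod.label][assay],
                        "n_cell_types": self.n_cell_types[assay],
                    }
                )
        return pd.DataFrame(rows)


def _module_range(modules: Sequence[ModuleBin], start: int, end: int) -> range:
    """Indices (into ``modules``) overlapped by [start, end) by >= 1 bp.

    Relies on modules being contiguous, equal width except the last, and
    ascending — the layout make_modules guarantees.
    """
    region_start = modules[0].start
    region_end = modules[-1].end
    if end <= region_start or start >= region_end:
        return range(0)
    width = modules[0].width
    lo = max(0, (max(start, region_start) - region_start) // width)
    hi = min(len(modules) - 1, (min(end, region_end) - 1 - region_start) // width)
    return range(lo, hi + 1)


def count_prevalence(
    modules: Sequence[ModuleBin],
    hotspots: Iterable[HotspotRecord],
    region_chrom: str,
    n_cell_types: dict[str, int],
) -> PrevalenceTable:
    """Count, per module and assay, cell types with >= 1 overlapping hotspot.

    A hotspot spanning a module boundary contributes to every module it
    touches; several hotspots of one cell type in one module still count
    once. Hotspots on other chromosomes are skipped (tallied in
    ``n_skipped``). ``n_cell_types`` must cover every assay present.
    """
    modules = list(modules)
    if not modules:
        raise ValueError("no modules supplied")
    seen: dict[tuple[int, str], set[str]] = defaultdict(set)
    skipped = 0
    for h in hotspots:
        if h.assay not in n_cell_types:
            raise ValueError(f"assay {h.assay!r} missing from n_cell_types")
        if h.chrom != region_chrom:
            skipped += 1
            continue
        for idx in _module_range(modules, h.start, h.end):
            seen[(idx, h.assay)].add(h.cell_type)
    counts = {
        mod.label: {assay: len(seen.get((i, assay), ())) for assay in n_cell_types}
        for i, mod in enumerate(modules)
    }
    return PrevalenceTable(
        region=modules[0].parent,
        modules=modules,
        counts=counts,
        n_cell_types=dict(n_cell_types),
        n_skipped=skipped,
    )


def region_prevalence(
    region: GenomicRegion,
    hotspots: Iterable[HotspotRecord],
    assay: str,
) -> int:
    """Number of distinct cell types with >= 1 hotspot anywhere in ``region``.

    The whole-region variant used for control regions (a single bin equal
    to the region).
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}")
    cell_types = {
        h.cell_type
        for h in hotspots
        if h.assay == assay and region.overlaps(h.chrom, h.start, h.end)
    }
    return len(cell_types)
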