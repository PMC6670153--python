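"""Synthetic stand-in reference tables for the published worked examples.

The study's per-cell-type supplementary tables (region coordinates, the
124-cell-type DNase and 51-cell-type H3K4me3 presence matrices, and the
53-entry EST list) are distributed as spreadsheets and are not shipped
here. This module builds — and the package ships, under
``intronprom/data/synthetic_*`` — deterministic SYNTHETIC stand-ins that
carry the same published aggregate structure (region sizes, the >80/124
DNase prevalence of intron-5 modules VI and X, the 1/51 gene-free
H3K4me3 prevalence, the 53 = 28 sense + 25 antisense EST split including
the eight selected antisense accessions), so the downstream arithmetic
can be exercised end to end. Per-cell-type and per-base detail is
synthetic throughout; the coordinates are hg19-like but invented.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import ModuleBin, make_modules
from .core import GenomicRegion, HotspotRecord, read_region_table
from .est import ESTRecord, load_est_table

_BUILD_SEED = 20190731  # fixed: the tables are reference fixtures, not draws

#: the eight antisense ESTs selected for the consensus alignment
SELECTED_ACCESSIONS = (
    "BU689215",
    "BU684610",
    "AW204843",
    "BX111268",
    "AI863417",
    "AI798118",
    "AI810863",
    "AA984901",
)

INTRON5 = "RUNX1_intron5"
SNRPD3 = "SNRPD3_TSS_region"
GENE_FREE = "genefree_chr1"
MBCR = "BCR_gene_MBCR"

_I5_START = 36_200_000  # synthetic hg19-like anchor, 0-based

# region rows: name, chrom, start, end, convention, assembly, gene_strand
_REGION_ROWS = [
    # 1-closed on purpose: exercises the convention conversion
    (INTRON5, "chr21", _I5_START + 1, _I5_START + 24_800, "1-closed", "hg19", "-"),
    (SNRPD3, "chr22", 21_000_000, 21_010_000, "0-half-open", "hg19", "+"),
    (GENE_FREE, "chr1", 84_000_000, 84_025_000, "0-half-open", "hg19", "."),
    (MBCR, "chr22", 23_520_000, 23_527_500, "0-half-open", "hg19", "+"),
]

# breakpoint cluster subregions of intron 5 (0-half-open, published sizes
# 0.8 / 4.2 / 2.1 kb; placement synthetic but honouring the module
# colocalizations: BCR2 ~ module VI, BCR3 ~ module X of the minus-strand
# gene, i.e. the genomically first bins carry the highest labels)
BCR_SUBREGIONS = {
    "BCR1": (_I5_START + 5_600, _I5_START + 6_400),
    "BCR2": (_I5_START + 10_000, _I5_START + 14_200),
    "BCR3": (_I5_START + 200, _I5_START + 2_300),
}

# per-module distinct-cell-type counts the stand-in matrices realize,
# keyed by (region, Roman label in gene-sense order)
_DNASE_COUNTS = {
    INTRON5: {"I": 44, "II": 39, "III": 52, "IV": 47, "V": 63,
              "VI": 103, "VII": 58, "VIII": 50, "IX": 78, "X": 98},
    SNRPD3: {"I": 95, "II": 110, "III": 118, "IV": 102},
    GENE_FREE: {"I": 6, "II": 4, "III": 9, "IV": 3, "V": 5,
                "VI": 7, "VII": 2, "VIII": 8, "IX": 4, "X": 6},
    MBCR: {"I": 90, "II": 101, "III": 86},
}
_H3K4_COUNTS = {
    INTRON5: {"I": 4, "II": 3, "III": 5, "IV": 4, "V": 7,
              "VI": 38, "VII": 9, "VIII": 11, "IX": 30, "X": 41},
    SNRPD3: {"I": 44, "II": 49, "III": 51, "IV": 46},
    # exactly one cell type anywhere in the region
    GENE_FREE: {"I": 0, "II": 0, "III": 0, "IV": 1, "V": 0,
                "VI": 0, "VII": 0, "VIII": 0, "IX": 0, "X": 0},
    MBCR: {"I": 3, "II": 5, "III": 2},
}

N_DNASE_CELL_TYPES = 124
N_H3K4_CELL_TYPES = 51
N_ESTS = 53
N_EST_SENSE = 28  # genomic '-', same sense as the host mRNA
N_EST_ANTISENSE = 25  # genomic '+'


def _region_table_text() -> str:
    lines = ["name\tchrom\tstart\tend\tcoordinate_convention\tassembly\tgene_strand"]
    for row in _REGION_ROWS:
        lines.append("\t".join(str(x) for x in row))
    return "\n".join(lines) + "\n"


def _presence_text(counts_by_region: dict, n_cell_types: int, prefix: str, rng) -> str:
    """Wide 0/1 matrix: cell_type column then one column per region|label."""
    cols: list[tuple[str, np.ndarray]] = []
    for region, counts in counts_by_region.items():
        for label, count in counts.items():
            col = np.zeros(n_cell_types, dtype=int)
            if count:
                col[rng.choice(n_cell_types, size=count, replace=False)] = 1
            cols.append((f"{region}|{label}", col))
    header = "cell_type\t" + "\t".join(name for name, _ in cols)
    lines = [header]
    for i in range(n_cell_types):
        lines.append(f"{prefix}{i:03d}\t" + "\t".join(str(col[i]) for _, col in cols))
    return "\n".join(lines) + "\n"


def _random_seq(rng, n: int, gc: float = 0.45) -> str:
    return "".join(
        rng.choice(list("ACGT"), size=n, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    )


def _mutate(rng, seq: str, rate: float = 0.01) -> str:
    chars = list(seq)
    for i in np.flatnonzero(rng.random(len(chars)) < rate):
        chars[i] = [b for b in "ACGT" if b != chars[i]][int(rng.integers(0, 3))]
    return "".join(chars)


def _est_catalog_text(rng) -> tuple[str, str]:
    """EST table TSV + transcript-set FASTA.

    Sequences derive from one synthetic plus-strand backbone spanning the
    intron-5 stand-in, so the eight selected antisense ESTs (placed as an
    overlapping stagger inside the BCR2 stand-in) support a consensus, and
    the shipped synthetic transcript contains their span.
    """
    start0, end0 = _I5_START, _I5_START + 24_800
    backbone = _random_seq(rng, end0 - start0)

    rows = ["accession\tchrom\tstart\tend\tstrand\tsequence"]

    def emit(acc: str, s: int, e: int, strand: str) -> None:
        seq = _mutate(rng, backbone[s - start0 : e - start0])
        rows.append(f"{acc}\tchr21\t{s}\t{e}\t{strand}\t{seq}")

    # the eight selected antisense ESTs: staggered 450-mers inside BCR2
    sel_start = _I5_START + 10_300
    for k, acc in enumerate(SELECTED_ACCESSIONS):
        s = sel_start + k * 150
        emit(acc, s, s + 450, "+")
    # remaining antisense ESTs scattered over the region
    for k in range(N_EST_ANTISENSE - len(SELECTED_ACCESSIONS)):
        ln = int(rng.integers(250, 550))
        s = start0 + int(rng.integers(0, end0 - start0 - ln))
        emit(f"SYNAS{k:03d}", s, s + ln, "+")
    # sense (host-mRNA-sense, genomic minus) ESTs
    for k in range(N_EST_SENSE):
        ln = int(rng.integers(250, 550))
        s = start0 + int(rng.integers(0, end0 - start0 - ln))
        emit(f"SYNSE{k:03d}", s, s + ln, "-")

    # transcript set: one lncRNA-like transcript containing the selected
    # ESTs' span, plus an unrelated decoy
    t_start, t_end = _I5_START + 9_800, _I5_START + 12_400
    transcript = backbone[t_start - start0 : t_end - start0]
    decoy = _random_seq(rng, 1_000)
    fasta = (
        ">synthetic_lncRNA_standin chr21:%d-%d(+)\n%s\n>synthetic_decoy_transcript\n%s\n"
        % (t_start, t_end, transcript, decoy)
    )
    return "\n".join(rows) + "\n", fasta


def build_standin_tables(outdir: str | Path) -> None:
    """Write every stand-in table; fully deterministic (fixed build seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(_BUILD_SEED)
    (outdir / "synthetic_region_table.tsv").write_text(_region_table_text())
    (outdir / "synthetic_dnase_presence.tsv").write_text(
        _presence_text(_DNASE_COUNTS, N_DNASE_CELL_TYPES, "DNCT", rng)
    )
    (outdir / "synthetic_h3k4me3_presence.tsv").write_text(
        _presence_text(_H3K4_COUNTS, N_H3K4_CELL_TYPES, "HKCT", rng)
    )
    est_tsv, transcripts = _est_catalog_text(rng)
    (outdir / "synthetic_est_catalog.tsv").write_text(est_tsv)
    (outdir / "synthetic_transcript_set.fasta").write_text(transcripts)


# ---------------------------------------------------------------------------
# loaders for the shipped copies


def _data_text(name: str) -> str:
    return (resources.files("intronprom.data") / name).read_text()


def load_region_table() -> list[GenomicRegion]:
    return read_region_table(StringIO(_data_text("synthetic_region_table.tsv")))


def region(name: str) -> GenomicRegion:
    for r in load_region_table():
        if r.name == name:
            return r
    raise KeyError(name)


def load_presence(assay: str) -> pd.DataFrame:
    name = {"DNASE": "synthetic_dnase_presence.tsv", "H3K4ME3": "synthetic_h3k4me3_presence.tsv"}[
        assay
    ]
    return pd.read_csv(StringIO(_data_text(name)), sep="\t")


def presence_to_hotspots(
    presence: pd.DataFrame,
    regions: list[GenomicRegion],
    assay: str,
    module_width: int = 2500,
) -> list[HotspotRecord]:
    """Expand a presence matrix into one small hotspot interval per marked
    (cell type, module), centered in the module, so the real overlap
    machinery recomputes the matrix's column sums."""
    modules_by_region: dict[str, dict[str, ModuleBin]] = {}
    chrom_by_region: dict[str, str] = {}
    for r in regions:
        modules_by_region[r.name] = {m.label: m for m in make_modules(r, module_width)}
        chrom_by_region[r.name] = r.chrom
    records: list[HotspotRecord] = []
    for col in presence.columns:
        if col == "cell_type":
            continue
        region_name, label = col.split("|")
        mod = modules_by_region[region_name][label]
        mid = (mod.start + mod.end) // 2
        for ct in presence.loc[presence[col] == 1, "cell_type"]:
            records.append(HotspotRecord(chrom_by_region[region_name], mid - 50, mid + 50, ct, assay))
    return records


def load_est_catalog() -> list[ESTRecord]:
    return load_est_table(StringIO(_data_text("synthetic_est_catalog.tsv")))


def load_transcript_set() -> list[tuple[str, str]]:
    from .core import read_fasta

    seqs = read_fasta(StringIO(_data_text("synthetic_transcript_set.fasta")))
    return [(s.id, s.residues) for s in seqs]
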