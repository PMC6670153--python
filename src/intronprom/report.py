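"""Workflow orchestration: per-module profile report and transcript chain.

``run_profile`` chains module binning, hotspot prevalence, initiator
scanning and stranded TSS counting into one per-module table and flags
modules whose DNase and H3K4me3 prevalence both clear configurable
fractions of their cell-type totals ("promoter-like" — a heuristic
convenience flag, labelled as such in output headers, not a statistical
call). ``run_transcript`` chains EST selection, multiple alignment,
consensus calling, transcript matching and amplicon prediction.

Outputs are written atomically (temp file + rename); re-running with the
same inputs reproduces them byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .binning import ModuleBin, count_prevalence, make_modules
from .core import GenomicRegion, HotspotRecord
from .est import (
    ESTRecord,
    Scheme,
    build_msa,
    call_consensus,
    match_consensus,
    select_ests,
    to_transcript_orientation,
)
from .inr import InrPWM, default_inr_pwm, hits_in_regions, scan_inr
from .pcr import PrimerPair, predict_amplicons
from .tss import TssPrediction, count_tss

HEURISTIC_NOTE = "# promoter_like is a heuristic flag: DNase and H3K4me3 prevalence both >= configured fractions of their cell-type totals\n"


@dataclass
class ProfileReport:
    region: GenomicRegion
    table: pd.DataFrame  # one row per module
    provenance: dict

    def flagged_modules(self) -> list[str]:
        return self.table.loc[self.table["promoter_like"], "module_label"].tolist()


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def run_profile(
    region: GenomicRegion,
    hotspots: Iterable[HotspotRecord],
    n_cell_types: dict[str, int],
    sequence: str | None = None,
    tss_predictions: Iterable[TssPrediction] = (),
    module_width: int = 2500,
    pwm: InrPWM | None = None,
    cutoff: float = 0.99,
    f_dnase: float = 0.5,
    f_h3k4me3: float = 0.5,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> ProfileReport:
    """Per-module profile of one region.

    ``sequence`` is the region's genomic sequence (forward strand,
    ``region.length`` long); when omitted the initiator columns are zero.
    Writes ``profile.tsv``, ``inr_hits.bed``, ``tss_counts.tsv`` and
    ``report.json`` when ``outdir`` is given.
    """
    modules = make_modules(region, module_width)
    prevalence = count_prevalence(modules, hotspots, region.chrom, n_cell_types)

    hits = []
    if sequence is not None:
        if len(sequence) != region.length:
            raise ValueError("sequence length does not match region length")
        if pwm is None:
            pwm = default_inr_pwm()
        hits = scan_inr(sequence, pwm, cutoff)
    module_intervals = [(m.label, m.start - region.start, m.end - region.start) for m in modules]
    inr_counts = hits_in_regions(hits, module_intervals)

    tss = count_tss(modules, tss_predictions, region.chrom)

    n_d = n_cell_types.get("DNASE", 0)
    n_h = n_cell_types.get("H3K4ME3", 0)
    rows = []
    for m in modules:
        d = prevalence.count(m.label, "DNASE") if "DNASE" in n_cell_types else 0
        h = prevalence.count(m.label, "H3K4ME3") if "H3K4ME3" in n_cell_types else 0
        rows.append(
            {
                "region": region.name,
                "module_label": m.label,
                "start": m.start,
                "end": m.end,
                "dnase_count": d,
                "dnase_n": n_d,
                "h3k4me3_count": h,
                "h3k4me3_n": n_h,
                "inr_hits": inr_counts[m.label],
                "tss_plus": tss.plus[m.label],
                "tss_minus": tss.minus[m.label],
                "promoter_like": bool(
                    n_d and n_h and d >= f_dnase * n_d and h >= f_h3k4me3 * n_h
                ),
            }
        )
    table = pd.DataFrame(rows)
    provenance = {
        "region": region.name,
        "module_width": module_width,
        "cutoff": cutoff,
        "f_dnase": f_dnase,
        "f_h3k4me3": f_h3k4me3,
        "seed": seed,
        "n_cell_types": dict(n_cell_types),
        "config_hash": hashlib.sha256(
            json.dumps(
                [region.name, module_width, cutoff, f_dnase, f_h3k4me3, sorted(n_cell_types.items())]
            ).encode()
        ).hexdigest()[:16],
    }
    report = ProfileReport(region, table, provenance)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _atomic_write(outdir / "profile.tsv", HEURISTIC_NOTE + table.to_csv(sep="\t", index=False))
        bed = "".join(
            f"{region.chrom}\t{region.start + h.center}\t{region.start + h.center + 1}"
            f"\tINR\t{int(round(h.score * 1000))}\t{h.strand}\n"
            for h in hits
        )
        _atomic_write(outdir / "inr_hits.bed", bed)
        _atomic_write(
            outdir / "tss_counts.tsv",
            tss.to_frame(region.gene_strand).to_csv(sep="\t", index=False),
        )
        _atomic_write(
            outdir / "report.json",
            json.dumps(
                {"provenance": provenance, "modules": table.to_dict(orient="records")},
                indent=2,
                sort_keys=True,
            )
            + "\n",
        )
    return report


@dataclass
class TranscriptResult:
    selected: list[ESTRecord]
    msa_rows: list[str]
    consensus: str
    match: object | None
    amplicons: dict[str, list]
    consensus_support: list[float] = field(default_factory=list)


def run_transcript(
    ests: Sequence[ESTRecord],
    region: GenomicRegion | None = None,
    strand: str | None = None,
    accessions: Sequence[str] | None = None,
    transcripts: Sequence[tuple[str, str]] | None = None,
    primer_pairs: Sequence[PrimerPair] | None = None,
    min_depth: int = 2,
    min_support: float = 0.5,
    scheme: Scheme = Scheme(),
    max_amplicon_len: int = 5000,
    outdir: str | Path | None = None,
) -> TranscriptResult:
    """EST selection -> MSA -> consensus -> transcript match -> amplicons.

    Minus-strand ESTs are reverse-complemented into transcript orientation
    before alignment. Fewer than two selected ESTs is an error. The
    transcript match and the amplicon prediction each run only when their
    optional inputs are supplied.
    """
    selected = select_ests(ests, region=region, strand=strand, accessions=accessions)
    if len(selected) < 2:
        raise ValueError(
            f"need >= 2 ESTs to build an alignment, selected {len(selected)}"
        )
    seqs = [to_transcript_orientation(e) for e in selected]
    msa = build_msa(seqs, ids=[e.accession for e in selected], scheme=scheme)
    consensus = call_consensus(msa, min_depth=min_depth, min_support=min_support)

    match = None
    if transcripts:
        match = match_consensus(consensus.sequence, transcripts, scheme=scheme)

    amplicons: dict[str, list] = {}
    if primer_pairs and transcripts:
        for tid, tseq in transcripts:
            for pair in primer_pairs:
                amps = predict_amplicons(tseq, pair, template_id=tid, max_len=max_amplicon_len)
                amplicons.setdefault(pair.name, []).extend(amps)

    result = TranscriptResult(
        selected=selected,
        msa_rows=list(msa.rows),
        consensus=consensus.sequence,
        match=match,
        amplicons=amplicons,
        consensus_support=list(consensus.support),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _atomic_write(outdir / "consensus.fasta", f">consensus\n{consensus.sequence}\n")
        _atomic_write(
            outdir / "msa.fasta",
            "".join(f">{i}\n{r}\n" for i, r in zip(msa.ids, msa.rows)),
        )
        if match is not None:
            _atomic_write(
                outdir / "match.tsv",
                "transcript_id\tscore\tidentity\ttarget_start\ttarget_end\n"
                f"{match.transcript_id}\t{match.score}\t{match.identity:.4f}"
                f"\t{match.target_start}\t{match.target_end}\n",
            )
        if amplicons:
            lines = ["pair\ttemplate\tstart\tend\tlength"]
            for pair_name, amps in amplicons.items():
                for a in amps:
                    lines.append(f"{pair_name}\t{a.template_id}\t{a.start}\t{a.end}\t{a.length}")
            _atomic_write(outdir / "amplicons.tsv", "\n".join(lines) + "\n")
    return result
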