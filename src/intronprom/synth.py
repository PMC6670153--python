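"""Seeded synthetic-data generator emulating the ENCODE-style inputs.

Generates a genome segment with planted intragenic promoters (each an
array of consensus-maximal initiator motifs), per-cell-type DNase and
H3K4me3 hotspot tracks enriched at the planted promoters, stranded CAGE
TSS predictions clustered at promoters, and error-bearing ESTs sampled
from a hidden antisense lncRNA — together with a truth record sufficient
to score every downstream stage.

Each output draws from its own random stream derived from (seed, stream
index), so adding an output never perturbs the others under a fixed seed,
and identical config + seed gives bit-identical outputs.

The default configuration mirrors the study scale: a 25-kb region in ten
2.5-kb modules, a single antisense promoter inside a "BCR3-like"
subregion of the first (gene-sense last) module, 124 DNase / 51 H3K4me3 /
35 CAGE cell types, promoter presence probability 0.8 and a background of
1 hotspot per 10 kb per cell type.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .core import GenomicRegion, HotspotRecord, StrandedSequence, reverse_complement
from .est import ESTRecord
from .inr import InrPWM, default_inr_pwm
from .tss import TssPrediction

_BASES = np.array(list("ACGT"))

# stream indices: one per output file family
_S_GENOME, _S_DNASE, _S_H3K4, _S_CAGE, _S_EST = range(5)


@dataclass(frozen=True)
class PlantedPromoter:
    position: int  # +1 base of the promoter's first initiator
    strand: str
    n_inr_motifs: int = 5


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    chrom: str = "chrS"
    region_name: str = "synthetic_region"
    genome_length: int = 25_000
    gc_fraction: float = 0.41
    host_gene_strand: str = "-"
    planted_promoters: tuple[PlantedPromoter, ...] = (PlantedPromoter(1500, "+", 5),)
    # hotspot tracks
    n_cell_types_dnase: int = 124
    n_cell_types_h3k4me3: int = 51
    background_hotspot_rate: float = 1.0  # hotspots per 10 kb per cell type
    promoter_presence_prob: float = 0.8
    hotspot_length_mean: float = 200.0
    hotspot_length_sd: float = 60.0
    promoter_hotspot_jitter_sd: float = 100.0
    # CAGE
    cage_cell_types: int = 35
    cage_tss_per_promoter_mean: float = 0.6
    cage_jitter_sd: float = 25.0
    cage_false_rate: float = 0.15  # predictions per 10 kb per cell type
    # ESTs / hidden lncRNA
    lnc_length: int = 600
    n_ests: int = 8
    est_length_mean: float = 350.0
    est_length_sd: float = 80.0
    est_error_rate: float = 0.01
    est_decoy_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "gc_fraction",
            "promoter_presence_prob",
            "est_error_rate",
            "est_decoy_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "genome_length",
            "n_cell_types_dnase",
            "n_cell_types_h3k4me3",
            "cage_cell_types",
            "lnc_length",
            "n_ests",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.host_gene_strand not in ("+", "-"):
            raise ValueError("host_gene_strand must be '+' or '-'")

    @property
    def region(self) -> GenomicRegion:
        return GenomicRegion(
            chrom=self.chrom,
            start=0,
            end=self.genome_length,
            name=self.region_name,
            assembly="synthetic",
            gene_strand=self.host_gene_strand,
        )


def config_from_yaml(stream) -> SynthConfig:
    raw = yaml.safe_load(stream)
    promoters = tuple(
        PlantedPromoter(int(p["position"]), p["strand"], int(p.get("n_inr_motifs", 5)))
        for p in raw.pop("planted_promoters", [])
    ) or SynthConfig().planted_promoters
    return SynthConfig(planted_promoters=promoters, **raw)


def config_to_yaml(config: SynthConfig) -> str:
    d = asdict(config)
    d["planted_promoters"] = [
        {"position": p.position, "strand": p.strand, "n_inr_motifs": p.n_inr_motifs}
        for p in config.planted_promoters
    ]
    return yaml.safe_dump(d, sort_keys=False)


@dataclass
class Truth:
    """Ground truth written alongside the synthetic inputs."""

    promoters: list[PlantedPromoter]
    inr_centers: list[tuple[int, str]]  # (+1 position, strand) of every planted motif
    lnc_id: str = ""
    lnc_start: int = -1
    lnc_end: int = -1
    lnc_strand: str = "+"
    lnc_sequence: str = ""


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def generate_genome(
    config: SynthConfig, pwm: InrPWM | None = None
) -> tuple[str, Truth]:
    """Random genome at the configured GC with planted initiator arrays.

    At each planted promoter, ``n_inr_motifs`` consensus-maximal initiator
    instances are written on the promoter strand, spaced so they never
    overlap; every +1 position is recorded in the truth.
    """
    if pwm is None:
        pwm = default_inr_pwm()
    rng = _rng(config, _S_GENOME)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(_BASES, size=config.genome_length, p=probs)
    consensus = pwm.consensus
    w, off = pwm.width, pwm.plus_one_offset
    spacing = w + 3
    centers: list[tuple[int, str]] = []
    for prom in config.planted_promoters:
        for k in range(prom.n_inr_motifs):
            center = prom.position + k * spacing
            if prom.strand == "+":
                start = center - off
                motif = consensus
            else:
                start = center - (w - 1 - off)
                motif = reverse_complement(consensus)
            if start < 0 or start + w > config.genome_length:
                raise ValueError(
                    f"planted motif at {center} falls outside the genome"
                )
            seq[start : start + w] = list(motif)
            centers.append((center, prom.strand))
    return "".join(seq), Truth(promoters=list(config.planted_promoters), inr_centers=centers)


def _lengths(rng: np.random.Generator, n: int, mean: float, sd: float, minimum: int) -> np.ndarray:
    """Normal draws resampled until >= minimum (never silently clamped)."""
    out = np.rint(rng.normal(mean, sd, size=n))
    for _ in range(1000):
        bad = out < minimum
        if not bad.any():
            break
        out[bad] = np.rint(rng.normal(mean, sd, size=int(bad.sum())))
    out[out < minimum] = minimum
    return out.astype(int)


def _track(
    rng: np.random.Generator,
    config: SynthConfig,
    cell_type: str,
    assay: str,
    background_rate: float,
) -> list[HotspotRecord]:
    L = config.genome_length
    records: list[HotspotRecord] = []
    n_bg = rng.poisson(background_rate * L / 10_000)
    starts = rng.integers(0, L, size=n_bg)
    lengths = _lengths(rng, n_bg, config.hotspot_length_mean, config.hotspot_length_sd, 50)
    for s, ln in zip(starts, lengths):
        records.append(
            HotspotRecord(config.chrom, int(s), min(int(s) + int(ln), L), cell_type, assay)
        )
    for prom in config.planted_promoters:
        if rng.random() < config.promoter_presence_prob:
            center = prom.position + rng.normal(0, config.promoter_hotspot_jitter_sd)
            ln = int(_lengths(rng, 1, config.hotspot_length_mean, config.hotspot_length_sd, 50)[0])
            start = max(0, int(round(center)) - ln // 2)
            end = min(start + ln, L)
            if end > start:
                records.append(HotspotRecord(config.chrom, start, end, cell_type, assay))
    records.sort(key=lambda r: (r.start, r.end))
    return records


def simulate_hotspots(config: SynthConfig) -> dict[str, dict[str, list[HotspotRecord]]]:
    """Per-assay, per-cell-type hotspot tracks.

    DNase background follows the configured rate; H3K4me3 background runs
    at one tenth of it (the promoter mark is sparser away from promoters).
    Each planted promoter receives, per cell type and assay, one hotspot
    with probability ``promoter_presence_prob``, centered on the promoter
    with jitter.
    """
    tracks: dict[str, dict[str, list[HotspotRecord]]] = {"DNASE": {}, "H3K4ME3": {}}
    rng_d = _rng(config, _S_DNASE)
    for i in range(config.n_cell_types_dnase):
        ct = f"DN{i:03d}"
        tracks["DNASE"][ct] = _track(rng_d, config, ct, "DNASE", config.background_hotspot_rate)
    rng_h = _rng(config, _S_H3K4)
    for i in range(config.n_cell_types_h3k4me3):
        ct = f"HK{i:03d}"
        tracks["H3K4ME3"][ct] = _track(
            rng_h, config, ct, "H3K4ME3", config.background_hotspot_rate / 10.0
        )
    return tracks


def simulate_cage(config: SynthConfig) -> list[TssPrediction]:
    """Stranded TSS predictions per cell type.

    Per cell type and promoter: Poisson(cage_tss_per_promoter_mean) points
    at the promoter position plus normal jitter on the promoter strand;
    false predictions arrive uniformly at ``cage_false_rate`` per 10 kb
    with a random strand.
    """
    rng = _rng(config, _S_CAGE)
    L = config.genome_length
    preds: list[TssPrediction] = []
    for i in range(config.cage_cell_types):
        ct = f"CG{i:03d}"
        for prom in config.planted_promoters:
            n = rng.poisson(config.cage_tss_per_promoter_mean)
            for _ in range(n):
                pos = int(round(prom.position + rng.normal(0, config.cage_jitter_sd)))
                pos = min(max(pos, 0), L - 1)
                preds.append(TssPrediction(config.chrom, pos, prom.strand, ct))
        n_false = rng.poisson(config.cage_false_rate * L / 10_000)
        for _ in range(n_false):
            pos = int(rng.integers(0, L))
            strand = "+" if rng.random() < 0.5 else "-"
            preds.append(TssPrediction(config.chrom, pos, strand, ct))
    return preds


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0 or not seq:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def simulate_ests(
    config: SynthConfig, genome: str, truth: Truth
) -> tuple[list[ESTRecord], Truth]:
    """ESTs sampled from a hidden antisense lncRNA, plus updated truth.

    The lncRNA is the genome subsequence of ``lnc_length`` transcribed
    from the first planted promoter antisense to the host gene; each EST
    is a random subinterval with i.i.d. substitutions at
    ``est_error_rate``. A configurable fraction of decoy ESTs is drawn
    from random genome positions on the host-gene strand. EST sequences
    are stored in genomic plus-strand orientation.
    """
    rng = _rng(config, _S_EST)
    antisense = [p for p in config.planted_promoters if p.strand != config.host_gene_strand]
    if not antisense:
        raise ValueError("no antisense promoter to transcribe the lncRNA from")
    prom = antisense[0]
    L = config.genome_length
    if prom.strand == "+":
        g_start, g_end = prom.position, min(prom.position + config.lnc_length, L)
    else:
        g_start, g_end = max(prom.position + 1 - config.lnc_length, 0), prom.position + 1
    lnc_fwd = genome[g_start:g_end]
    lnc_seq = lnc_fwd if prom.strand == "+" else reverse_complement(lnc_fwd)
    truth.lnc_id = "synthetic_lncRNA"
    truth.lnc_start, truth.lnc_end = g_start, g_end
    truth.lnc_strand = prom.strand
    truth.lnc_sequence = lnc_seq

    n_decoy = int(round(config.n_ests * config.est_decoy_fraction))
    n_real = config.n_ests - n_decoy
    ests: list[ESTRecord] = []
    lnc_len = g_end - g_start
    lengths = _lengths(rng, n_real, config.est_length_mean, config.est_length_sd, 50)
    lengths = np.minimum(lengths, lnc_len)
    for k in range(n_real):
        ln = int(lengths[k])
        offset = int(rng.integers(0, lnc_len - ln + 1))
        sub_fwd = genome[g_start + offset : g_start + offset + ln]
        ests.append(
            ESTRecord(
                accession=f"SYN_EST{k:03d}",
                chrom=config.chrom,
                start=g_start + offset,
                end=g_start + offset + ln,
                strand=prom.strand,
                sequence=_mutate(rng, sub_fwd, config.est_error_rate),
            )
        )
    decoy_lengths = _lengths(rng, n_decoy, config.est_length_mean, config.est_length_sd, 50)
    for k in range(n_decoy):
        ln = min(int(decoy_lengths[k]), L)
        start = int(rng.integers(0, L - ln + 1))
        ests.append(
            ESTRecord(
                accession=f"SYN_DECOY{k:03d}",
                chrom=config.chrom,
                start=start,
                end=start + ln,
                strand=config.host_gene_strand,
                sequence=_mutate(rng, genome[start : start + ln], config.est_error_rate),
            )
        )
    return ests, truth


@dataclass
class SynthDataset:
    config: SynthConfig
    genome: str
    truth: Truth
    hotspots: dict[str, dict[str, list[HotspotRecord]]]
    cage: list[TssPrediction]
    ests: list[ESTRecord]


def generate_dataset(config: SynthConfig | None = None, seed: int | None = None) -> SynthDataset:
    """Generate the complete synthetic input set for one configuration."""
    if config is None:
        config = SynthConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    genome, truth = generate_genome(config)
    hotspots = simulate_hotspots(config)
    cage = simulate_cage(config)
    ests, truth = simulate_ests(config, genome, truth)
    return SynthDataset(config, genome, truth, hotspots, cage, ests)


def write_dataset(ds: SynthDataset, outdir: str | Path) -> None:
    """Persist a dataset as FASTA/BED/TSV, seed-stamped in headers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"# seed={ds.config.seed}\n"
    cfg = ds.config
    (outdir / "config.yaml").write_text(config_to_yaml(cfg))
    with open(outdir / "genome.fasta", "w") as fh:
        fh.write(f">{cfg.chrom} seed={cfg.seed}\n")
        for i in range(0, len(ds.genome), 70):
            fh.write(ds.genome[i : i + 70] + "\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write(stamp)
        fh.write("record\tposition\tstrand\tdetail\n")
        for p in ds.truth.promoters:
            fh.write(f"promoter\t{p.position}\t{p.strand}\tn_inr={p.n_inr_motifs}\n")
        for c, s in ds.truth.inr_centers:
            fh.write(f"inr_center\t{c}\t{s}\t.\n")
        fh.write(
            f"lncRNA\t{ds.truth.lnc_start}\t{ds.truth.lnc_strand}\t"
            f"end={ds.truth.lnc_end}\n"
        )
    with open(outdir / "lncRNA_truth.fasta", "w") as fh:
        fh.write(f">{ds.truth.lnc_id} seed={cfg.seed}\n")
        for i in range(0, len(ds.truth.lnc_sequence), 70):
            fh.write(ds.truth.lnc_sequence[i : i + 70] + "\n")
    hotdir = outdir / "hotspots"
    hotdir.mkdir(exist_ok=True)
    for assay, by_ct in ds.hotspots.items():
        for ct, records in by_ct.items():
            with open(hotdir / f"{ct}.{assay}.bed", "w") as fh:
                fh.write(stamp)
                for r in records:
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
    with open(outdir / "cage_tss.bed", "w") as fh:
        fh.write(stamp)
        for p in ds.cage:
            fh.write(
                f"{p.chrom}\t{p.position}\t{p.position + 1}\ttss_{p.cell_type}\t0\t{p.strand}\n"
            )
    with open(outdir / "ests.tsv", "w") as fh:
        fh.write(stamp)
        fh.write("accession\tchrom\tstart\tend\tstrand\tsequence\n")
        for e in ds.ests:
            fh.write(
                f"{e.accession}\t{e.chrom}\t{e.start}\t{e.end}\t{e.strand}\t{e.sequence}\n"
            )
    with open(outdir / "ests.fasta", "w") as fh:
        for e in ds.ests:
            fh.write(f">{e.accession} {e.chrom}:{e.start}-{e.end}({e.strand})\n")
            fh.write(e.sequence + "\n")
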