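"""EST selection, multiple alignment and consensus calling.

ESTs overlapping a target region on a given strand (or an explicit
accession list) are aligned with an end-gap-free global ("overlap")
pairwise aligner, assembled into a center-star multiple alignment, and a
majority consensus is called per column. The consensus can then be matched
against a transcript set by local alignment — the offline counterpart of
submitting it to a nucleotide BLAST service.

Scoring scheme (declared, since no standard exists for this step):
match +1, mismatch -1, gap -2 per base, terminal gaps free. Traceback
tie-break is diagonal > up > left, so all outputs are deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .core import GenomicRegion, reverse_complement

GAP = "-"

DEFAULT_MATCH = 1
DEFAULT_MISMATCH = -1
DEFAULT_GAP = -2

#: slack allowed between an EST's sequence length and its genomic span
#: (clipping / polyA trimming leaves them unequal)
DEFAULT_CLIP_ALLOWANCE = 100


@dataclass(frozen=True)
class ESTRecord:
    """One expressed-sequence tag with its genomic placement.

    ``sequence`` is stored in genomic plus-strand orientation; use
    :func:`to_transcript_orientation` to flip minus-strand ESTs into the
    orientation of the transcript they evidence.
    """

    accession: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"EST {self.accession}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"EST {self.accession}: bad strand {self.strand!r}")


def to_transcript_orientation(est: ESTRecord) -> str:
    return est.sequence if est.strand == "+" else reverse_complement(est.sequence)


def load_est_table(
    stream: TextIO | str,
    clip_allowance: int = DEFAULT_CLIP_ALLOWANCE,
) -> list[ESTRecord]:
    """Read a TSV with columns accession, chrom, start, end, strand, sequence.

    Rejects records whose sequence is longer than their genomic span plus
    ``clip_allowance`` (ESTs may be clipped, not padded).
    """
    df = pd.read_csv(stream, sep="\t", comment="#", dtype=str)
    records = []
    for _, row in df.iterrows():
        rec = ESTRecord(
            accession=row["accession"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            sequence=row["sequence"].upper(),
        )
        span = rec.end - rec.start
        if len(rec.sequence) > span + clip_allowance:
            raise ValueError(
                f"EST {rec.accession}: sequence length {len(rec.sequence)} exceeds "
                f"genomic span {span} + allowance {clip_allowance}"
            )
        records.append(rec)
    return records


def select_ests(
    ests: Sequence[ESTRecord],
    region: GenomicRegion | None = None,
    strand: str | None = None,
    accessions: Sequence[str] | None = None,
) -> list[ESTRecord]:
    """ESTs overlapping ``region`` by >= 1 bp on ``strand``, or an explicit
    accession list (returned in list order; missing accessions are an error)."""
    if accessions is not None:
        by_acc = {e.accession: e for e in ests}
        missing = [a for a in accessions if a not in by_acc]
        if missing:
            raise KeyError(f"accessions not found: {missing}")
        return [by_acc[a] for a in accessions]
    out = []
    for e in ests:
        if region is not None and not region.overlaps(e.chrom, e.start, e.end):
            continue
        if strand is not None and e.strand != strand:
            continue
        out.append(e)
    return out


# ---------------------------------------------------------------------------
# pairwise alignment


@dataclass(frozen=True)
class Scheme:
    match: int = DEFAULT_MATCH
    mismatch: int = DEFAULT_MISMATCH
    gap: int = DEFAULT_GAP

    def s(self, a: str, b: str) -> int:
        return self.match if a == b else self.mismatch


def pairwise_align(
    a: str,
    b: str,
    scheme: Scheme = Scheme(),
) -> tuple[str, str, int]:
    """Optimal end-gap-free global (overlap) alignment of two sequences.

    Leading and trailing gaps in either sequence are free; internal gaps
    cost ``scheme.gap`` per base. Returns the gapped rows and the score.
    Tie-breaks: interior traceback prefers diagonal, then up (gap in b),
    then left (gap in a); among end cells of equal score the one aligning
    the most of both sequences (largest i, then largest j) is chosen.
    """
    if not a or not b:
        raise ValueError("pairwise_align requires non-empty sequences")
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        ai = a[i - 1]
        row, prev = H[i], H[i - 1]
        for j in range(1, n + 1):
            row[j] = max(
                prev[j - 1] + scheme.s(ai, b[j - 1]),
                prev[j] + scheme.gap,
                row[j - 1] + scheme.gap,
            )
    # end cell: max over last row and last column, both end gaps free
    best_i, best_j, best = m, n, H[m][n]
    for i in range(m, -1, -1):
        if H[i][n] > best:
            best_i, best_j, best = i, n, H[i][n]
    for j in range(n - 1, -1, -1):
        if H[m][j] > best:
            best_i, best_j, best = m, j, H[m][j]
    rows_a: list[str] = []
    rows_b: list[str] = []
    # trailing free gaps
    if best_i < m:
        rows_a.append(a[best_i:][::-1])
        rows_b.append(GAP * (m - best_i))
    if best_j < n:
        rows_a.append(GAP * (n - best_j))
        rows_b.append(b[best_j:][::-1])
    i, j = best_i, best_j
    while i > 0 and j > 0:
        here = H[i][j]
        if here == H[i - 1][j - 1] + scheme.s(a[i - 1], b[j - 1]):
            rows_a.append(a[i - 1])
            rows_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif here == H[i - 1][j] + scheme.gap:
            rows_a.append(a[i - 1])
            rows_b.append(GAP)
            i -= 1
        else:
            rows_a.append(GAP)
            rows_b.append(b[j - 1])
            j -= 1
    # leading free gaps (chunks pre-reversed: the join below reverses once)
    if i > 0:
        rows_a.append(a[:i][::-1])
        rows_b.append(GAP * i)
    if j > 0:
        rows_a.append(GAP * j)
        rows_b.append(b[:j][::-1])
    aligned_a = "".join(rows_a)[::-1]
    aligned_b = "".join(rows_b)[::-1]
    return aligned_a, aligned_b, best


def score_aligned_pair(row_a: str, row_b: str, scheme: Scheme = Scheme()) -> int:
    """Score a gapped pair under the overlap scheme (end gaps free).

    Gap-gap columns (artifacts of projecting an MSA) are ignored.
    """
    cols = [(x, y) for x, y in zip(row_a, row_b) if not (x == GAP and y == GAP)]
    lo, hi = 0, len(cols)
    while lo < hi and GAP in cols[lo]:
        lo += 1
    while hi > lo and GAP in cols[hi - 1]:
        hi -= 1
    total = 0
    for x, y in cols[lo:hi]:
        total += scheme.gap if GAP in (x, y) else scheme.s(x, y)
    return total


# ---------------------------------------------------------------------------
# center-star MSA


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]
    center_index: int = 0

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


def _gap_run(row: str, i: int) -> int:
    j = i
    while j < len(row) and row[j] == GAP:
        j += 1
    return j - i


def build_msa(
    sequences: Sequence[str],
    ids: Sequence[str] | None = None,
    scheme: Scheme = Scheme(),
) -> MultipleAlignment:
    """Center-star multiple alignment.

    The center is the sequence maximizing the summed pairwise alignment
    score against all others (first in input order on ties). Every other
    sequence is aligned to the center and merged under "once a gap, always
    a gap": gaps inserted into the center propagate to all previously
    merged rows. Row order equals input order.
    """
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValueError("build_msa requires at least 2 sequences")
    if ids is None:
        ids = [f"seq{k}" for k in range(len(seqs))]
    ids = list(ids)
    npair = len(seqs)
    totals = [0] * npair
    for i in range(npair):
        for j in range(i + 1, npair):
            _, _, sc = pairwise_align(seqs[i], seqs[j], scheme)
            totals[i] += sc
            totals[j] += sc
    center = max(range(npair), key=lambda k: (totals[k], -k))

    master = seqs[center]  # gapped center as merged so far
    merged: dict[int, str] = {center: master}
    for k in range(npair):
        if k == center:
            continue
        a_center, a_other, _ = pairwise_align(seqs[center], seqs[k], scheme)
        # walk master and the new pairwise center row in parallel, emitting
        # a merged column list; a gap new to either side is propagated
        out_master: list[str] = []
        out_other: list[str] = []
        insertions: list[tuple[int, int]] = []  # (master column, gaps to insert)
        mi = pi = 0
        leading = True  # before the first center residue
        while mi < len(master) or pi < len(a_center):
            m_char = master[mi] if mi < len(master) else None
            p_char = a_center[pi] if pi < len(a_center) else None
            if m_char == GAP and p_char == GAP and leading:
                # leading gap runs are right-aligned (anchored at the
                # center start): the longer run's excess columns come first
                r_m = _gap_run(master, mi)
                r_p = _gap_run(a_center, pi)
                if r_m > r_p:
                    out_master.append(GAP)
                    out_other.append(GAP)
                    mi += 1
                    continue
                if r_p > r_m:
                    out_master.append(GAP)
                    out_other.append(a_other[pi])
                    insertions.append((len(out_master) - 1, 1))
                    pi += 1
                    continue
                # equal runs fall through to the joint-consumption case
            if m_char not in (GAP, None):
                leading = False
            if m_char == GAP and p_char != GAP:
                # existing master gap absent from the new pairwise row
                out_master.append(GAP)
                out_other.append(GAP)
                mi += 1
            elif p_char == GAP and (m_char != GAP or m_char is None):
                # new gap introduced by this sequence
                out_master.append(GAP)
                out_other.append(a_other[pi])
                insertions.append((len(out_master) - 1, 1))
                pi += 1
            elif m_char is None:
                out_master.append(GAP)
                out_other.append(a_other[pi] if pi < len(a_other) else GAP)
                insertions.append((len(out_master) - 1, 1))
                pi += 1
            elif p_char is None:
                out_master.append(m_char)
                out_other.append(GAP)
                mi += 1
            else:  # both gap or both residue: columns correspond
                out_master.append(m_char)
                out_other.append(a_other[pi])
                mi += 1
                pi += 1
        new_master = "".join(out_master)
        # propagate newly inserted gap columns into previously merged rows
        if insertions:
            cols = sorted(c for c, _ in insertions)
            for key, row in merged.items():
                chars = list(row)
                for c in cols:
                    chars.insert(c, GAP)
                merged[key] = "".join(chars)
        merged[k] = "".join(out_other)
        master = new_master
    rows = [merged[k] for k in range(npair)]
    msa = MultipleAlignment(ids=ids, rows=rows, center_index=center)
    for k in range(npair):
        assert msa.degapped(k) == seqs[k], "degapping must recover inputs"
    return msa


# ---------------------------------------------------------------------------
# consensus


@dataclass
class ConsensusResult:
    sequence: str
    support: list[float]  # per retained column, fraction of non-gap rows agreeing
    depth: list[int]  # per retained column, non-gap row count
    columns: list[int]  # alignment column index of each consensus position


def call_consensus(
    msa: MultipleAlignment,
    min_depth: int = 2,
    min_support: float = 0.5,
) -> ConsensusResult:
    """Majority consensus per column.

    Columns with non-gap depth below ``min_depth`` (and all-gap columns)
    are dropped. Otherwise the majority residue is called when its
    fraction of non-gap rows is >= ``min_support`` and unique; ties and
    weak majorities yield N.
    """
    seq, support, depth, cols = [], [], [], []
    for c in range(msa.length):
        residues = [row[c] for row in msa.rows if row[c] != GAP]
        d = len(residues)
        if d == 0 or d < min_depth:
            continue
        counts = Counter(residues)
        top_count = max(counts.values())
        leaders = [b for b, v in counts.items() if v == top_count]
        frac = top_count / d
        call = leaders[0] if len(leaders) == 1 and frac >= min_support else "N"
        seq.append(call)
        support.append(frac)
        depth.append(d)
        cols.append(c)
    return ConsensusResult("".join(seq), support, depth, cols)


# ---------------------------------------------------------------------------
# local alignment of the consensus against a transcript set


@dataclass(frozen=True)
class TranscriptMatch:
    transcript_id: str
    score: int
    identity: float  # matches / aligned columns
    query_aligned: str
    target_aligned: str
    target_start: int
    target_end: int


def local_align(a: str, b: str, scheme: Scheme = Scheme()) -> tuple[str, str, int, int, int]:
    """Smith–Waterman local alignment; returns (row_a, row_b, score,
    b_start, b_end). Tie-breaks as in pairwise_align; among equal-scoring
    end cells the first in row-major order wins."""
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    best, best_i, best_j = 0, 0, 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        row, prev = H[i], H[i - 1]
        for j in range(1, n + 1):
            v = max(
                0,
                prev[j - 1] + scheme.s(ai, b[j - 1]),
                prev[j] + scheme.gap,
                row[j - 1] + scheme.gap,
            )
            row[j] = v
            if v > best:
                best, best_i, best_j = v, i, j
    rows_a: list[str] = []
    rows_b: list[str] = []
    i, j = best_i, best_j
    while i > 0 and j > 0 and H[i][j] > 0:
        here = H[i][j]
        if here == H[i - 1][j - 1] + scheme.s(a[i - 1], b[j - 1]):
            rows_a.append(a[i - 1])
            rows_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif here == H[i - 1][j] + scheme.gap:
            rows_a.append(a[i - 1])
            rows_b.append(GAP)
            i -= 1
        else:
            rows_a.append(GAP)
            rows_b.append(b[j - 1])
            j -= 1
    return "".join(rows_a)[::-1], "".join(rows_b)[::-1], best, j, best_j


def match_consensus(
    consensus: str,
    transcripts: Sequence[tuple[str, str]],
    scheme: Scheme = Scheme(),
    min_identity: float = 0.5,
) -> TranscriptMatch:
    """Best local-alignment hit of the consensus in a transcript set.

    ``transcripts`` is (id, sequence) pairs; ties on score go to the first
    transcript in input order. ``identity`` counts matching columns over
    all aligned columns (gap columns included); callers flag hits whose
    identity falls below ``min_identity`` (see :attr:`TranscriptMatch`).
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    best: TranscriptMatch | None = None
    for tid, tseq in transcripts:
        ra, rb, score, b_start, b_end = local_align(consensus, tseq, scheme)
        ncols = len(ra)
        matches = sum(1 for x, y in zip(ra, rb) if x == y and x != GAP)
        identity = matches / ncols if ncols else 0.0
        cand = TranscriptMatch(tid, score, identity, ra, rb, b_start, b_end)
        if best is None or cand.score > best.score:
            best = cand
    return best
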