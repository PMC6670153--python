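"""Initiator-element (INR) scanning with a max-ratio normalized PWM score.

The score of a window is the product of per-position probabilities divided
by the product of per-position maxima, so the consensus-maximal window
scores exactly 1.0 and a printed cutoff like 0.99 has an absolute meaning
independent of motif width. Both strands are scanned by default; a hit's
``center`` is the genomic (forward-frame) offset of the motif's +1 base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence, TextIO

import numpy as np

from .core import GenomicRegion, reverse_complement

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class InrPWM:
    """Initiator position-weight matrix over A, C, G, T.

    ``frequencies`` has shape (width, 4); rows are renormalized with
    ``pseudocount`` smoothing at construction so each sums to 1.
    ``plus_one_offset`` is the 0-based offset of the +1 (TSS) base within
    the motif window; an N residue scores the minimum probability of its
    column.
    """

    frequencies: np.ndarray
    pseudocount: float = 0.01
    plus_one_offset: int = 2
    source: str = "unspecified"

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4:
            raise ValueError("frequencies must have shape (width, 4)")
        if freq.shape[0] < 4:
            raise ValueError("motif width must be >= 4")
        if not (0 <= self.plus_one_offset < freq.shape[0]):
            raise ValueError("plus_one_offset outside motif window")
        freq = (freq + self.pseudocount) / (freq + self.pseudocount).sum(axis=1, keepdims=True)
        object.__setattr__(self, "frequencies", freq)
        assert np.allclose(self.frequencies.sum(axis=1), 1.0, atol=1e-9)

    @property
    def width(self) -> int:
        return self.frequencies.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.frequencies.argmax(axis=1))

    def column_scores(self) -> np.ndarray:
        """(width, 5) matrix of probabilities with column 4 = N = row min."""
        n_col = self.frequencies.min(axis=1, keepdims=True)
        return np.hstack([self.frequencies, n_col])


@dataclass(frozen=True)
class InrHit:
    """One initiator-element hit: +1 position, strand, normalized score."""

    center: int
    strand: str
    score: float


def load_pwm(stream: TextIO | str) -> InrPWM:
    """Read a PWM file: tab-delimited A C G T rows, ``#`` header lines.

    Header lines may carry ``plus_one_offset=<int>`` and
    ``pseudocount=<float>`` key-value annotations.
    """
    if isinstance(stream, str):
        with open(stream) as fh:
            return load_pwm(fh)
    plus_one, pseudo, source_lines, rows = 2, 0.01, [], []
    header_done = False
    for line in stream:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            text = line.lstrip("#").strip()
            source_lines.append(text)
            if text.startswith("plus_one_offset="):
                plus_one = int(text.split("=", 1)[1])
            elif text.startswith("pseudocount="):
                pseudo = float(text.split("=", 1)[1])
            continue
        fields = line.split("\t")
        if not header_done and fields[:4] == ["A", "C", "G", "T"]:
            header_done = True
            continue
        rows.append([float(x) for x in fields[:4]])
    return InrPWM(
        frequencies=np.array(rows),
        pseudocount=pseudo,
        plus_one_offset=plus_one,
        source=" ".join(source_lines[:1]) or "unspecified",
    )


def default_inr_pwm() -> InrPWM:
    """The packaged canonical initiator (YYANWYY) matrix."""
    ref = resources.files("intronprom.data") / "inr_pwm.tsv"
    return load_pwm(ref.read_text().splitlines().__iter__())  # type: ignore[arg-type]


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)  # default N
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if bad.any():
        raise ValueError(f"residues outside ACGTN at position {int(np.argmax(bad))}")
    return out


def _window_scores(sequence: str, pwm: InrPWM) -> np.ndarray:
    """Normalized score of every window start on the forward frame."""
    w = pwm.width
    if len(sequence) < w:
        return np.empty(0)
    codes = _encode(sequence)
    logp = np.log(pwm.column_scores())
    log_max = np.log(pwm.frequencies.max(axis=1)).sum()
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    scores = logp[np.arange(w), windows].sum(axis=1) - log_max
    return np.exp(np.minimum(scores, 0.0))


def score_window(pwm: InrPWM, window: str) -> float:
    """Score one window of exactly pwm.width residues, in [0, 1]."""
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != motif width {pwm.width}")
    return float(_window_scores(window, pwm)[0])


def scan_inr(
    sequence: str,
    pwm: InrPWM | None = None,
    cutoff: float = 0.99,
    strands: Sequence[str] = ("+", "-"),
) -> list[InrHit]:
    """Report every window on the requested strands scoring >= cutoff.

    Minus-strand windows are scored on the reverse complement and their +1
    position mapped back to forward-frame coordinates. Hits are sorted by
    center (then strand); overlapping hits are all kept. An empty or
    too-short sequence yields no hits.
    """
    if pwm is None:
        pwm = default_inr_pwm()
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    bad = set(strands) - {"+", "-"}
    if bad:
        raise ValueError(f"unknown strands {sorted(bad)}")
    hits: list[InrHit] = []
    L, w = len(sequence), pwm.width
    if "+" in strands:
        scores = _window_scores(sequence, pwm)
        for start in np.flatnonzero(scores >= cutoff):
            hits.append(InrHit(int(start) + pwm.plus_one_offset, "+", float(scores[start])))
    if "-" in strands and L >= w:
        rc_scores = _window_scores(reverse_complement(sequence), pwm)
        for rc_start in np.flatnonzero(rc_scores >= cutoff):
            # window start on forward frame, then +1 position within it
            start = L - w - int(rc_start)
            hits.append(
                InrHit(start + w - 1 - pwm.plus_one_offset, "-", float(rc_scores[rc_start]))
            )
    hits.sort(key=lambda h: (h.center, h.strand))
    return hits


def hits_in_regions(
    hits: Iterable[InrHit],
    subregions: Sequence[tuple[str, int, int]],
) -> dict[str, int]:
    """Assign each hit to every subregion containing its center.

    ``subregions`` are (name, start, end) half-open intervals in the same
    coordinate frame as the hit centers. Returns counts per subregion name
    plus an ``"outside"`` tally of hits contained by no subregion.
    """
    counts = {name: 0 for name, _, _ in subregions}
    counts["outside"] = 0
    for hit in hits:
        inside = False
        for name, start, end in subregions:
            if start <= hit.center < end:
                counts[name] += 1
                inside = True
        if not inside:
            counts["outside"] += 1
    return counts
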