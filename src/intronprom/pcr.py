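"""In-silico PCR: primer-site finding and amplicon prediction.

Pure sequence matching — no melting-temperature model. A primer may carry
mismatches anywhere except its 3'-terminal base (which must pair for the
polymerase to extend); N in the template never matches. Amplicons are
every compatible (forward site, reverse site) pairing up to a maximum
product length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import reverse_complement

MIN_PRIMER_LENGTH = 10


@dataclass(frozen=True)
class PrimerPair:
    """A named primer pair, both given 5'->3' as ordered."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < MIN_PRIMER_LENGTH:
                raise ValueError(
                    f"primer pair {self.name!r}: {label} primer shorter than "
                    f"{MIN_PRIMER_LENGTH} nt"
                )


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int
    end: int  # half-open on the template
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _mismatches_ok(primer: str, window: str, max_mismatch: int) -> bool:
    """Primer vs template window, 3'-terminal base (last of ``primer``)
    must match exactly; N in the template matches nothing."""
    if window[-1] != primer[-1] or window[-1] == "N":
        return False
    mismatches = 0
    for p, t in zip(primer[:-1], window[:-1]):
        if t == "N" or p != t:
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def find_sites(template: str, primer: str, max_mismatch: int = 0) -> list[tuple[int, str]]:
    """All annealing sites of ``primer`` on both strands of ``template``.

    Returns (position, strand) with ``position`` the 0-based start of the
    matched window on the template's forward frame. A '+' site means the
    primer matches the forward strand (primes rightward synthesis); a '-'
    site means the primer's reverse complement matches the forward strand
    (the primer anneals to it and primes leftward). A primer longer than
    the template yields no sites.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    k = len(primer)
    sites: list[tuple[int, str]] = []
    if k > len(template):
        return sites
    primer_rc = reverse_complement(primer)
    for i in range(len(template) - k + 1):
        window = template[i : i + k]
        if _mismatches_ok(primer, window, max_mismatch):
            sites.append((i, "+"))
        # on the minus strand the primer's 3' end sits at forward position i
        if _rc_site_ok(primer_rc, window, max_mismatch):
            sites.append((i, "-"))
    return sites


def _rc_site_ok(primer_rc: str, window: str, max_mismatch: int) -> bool:
    """Match of revcomp(primer) to the forward window; the primer's
    3'-terminal base corresponds to the window's first character."""
    if window[0] != primer_rc[0] or window[0] == "N":
        return False
    mismatches = 0
    for p, t in zip(primer_rc[1:], window[1:]):
        if t == "N" or p != t:
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def predict_amplicons(
    template: str,
    pair: PrimerPair,
    template_id: str = "template",
    max_len: int = 5000,
    max_mismatch: int = 0,
) -> list[Amplicon]:
    """Every amplicon the pair would produce on the template.

    A product needs a forward-primer '+' site at f and a reverse-primer
    '-' site at r with the two footprints non-overlapping (r >= f +
    len(forward)); it spans [f, r + len(reverse)) and must be <= max_len.
    Results are sorted by length, then start.
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    fwd_sites = [p for p, s in find_sites(template, pair.forward, max_mismatch) if s == "+"]
    rev_sites = [p for p, s in find_sites(template, pair.reverse, max_mismatch) if s == "-"]
    out = []
    for f in fwd_sites:
        for r in rev_sites:
            if r < f + len(pair.forward):
                continue
            end = r + len(pair.reverse)
            if end - f > max_len:
                continue
            out.append(Amplicon(template_id, f, end, template[f:end]))
    out.sort(key=lambda a: (a.length, a.start))
    return out
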