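"""Independent brute-force oracles the unit/acceptance tests compare against.

Every oracle is written as a direct enumeration over bases, windows or
monotone matchings, deliberately sharing no code path with the package
implementations.
"""

from __future__ import annotations

from itertools import combinations


def prevalence_bruteforce(modules, hotspots, region_chrom):
    """Per-(module label, assay) distinct cell types, by marking every
    covered base of every track and testing module occupancy."""
    out: dict[tuple[str, str], set[str]] = {}
    for mod in modules:
        for h in hotspots:
            if h.chrom != region_chrom:
                continue
            covered = any(mod.start <= b < mod.end for b in range(h.start, h.end))
            if covered:
                out.setdefault((mod.label, h.assay), set()).add(h.cell_type)
    return {k: len(v) for k, v in out.items()}


def window_scores_bruteforce(pwm, sequence):
    """Normalized score of every window by explicit per-position products."""
    probs = pwm.column_scores()  # (width, 5): A C G T N
    order = "ACGTN"
    best = 1.0
    for i in range(pwm.width):
        best *= max(probs[i][:4])
    scores = []
    for start in range(len(sequence) - pwm.width + 1):
        p = 1.0
        for i in range(pwm.width):
            p *= probs[i][order.index(sequence[start + i])]
        scores.append(p / best)
    return scores


def tss_counts_bruteforce(modules, predictions, region_chrom):
    """Direct per-position membership enumeration, split by strand."""
    counts = {(m.label, s): 0 for m in modules for s in "+-"}
    outside = {"+": 0, "-": 0}
    for p in predictions:
        if p.chrom != region_chrom:
            continue
        placed = False
        for m in modules:
            if m.start <= p.position < m.end:
                counts[(m.label, p.strand)] += 1
                placed = True
                break
        if not placed:
            outside[p.strand] += 1
    return counts, outside


def hit_region_counts_bruteforce(hits, subregions):
    counts = {name: 0 for name, _, _ in subregions}
    counts["outside"] = 0
    for h in hits:
        anywhere = False
        for name, s, e in subregions:
            if s <= h.center < e:
                counts[name] += 1
                anywhere = True
        if not anywhere:
            counts["outside"] += 1
    return counts


def _complement(base):
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[base]


def primer_sites_bruteforce(template, primer, max_mismatch):
    """Sliding-window enumeration of both strands; the primer's 3' base
    (last of the given 5'->3' sequence) must pair exactly; template N
    never matches."""
    k = len(primer)
    sites = []
    for i in range(len(template) - k + 1):
        window = template[i : i + k]
        # forward: primer as given vs window, 3' base = last position
        body_mm = sum(1 for p, t in zip(primer[:-1], window[:-1]) if t == "N" or p != t)
        if window[-1] != "N" and window[-1] == primer[-1] and body_mm <= max_mismatch:
            sites.append((i, "+"))
        # reverse: primer anneals to forward strand read right-to-left;
        # its 3' base pairs with window[0]
        paired = [_complement(t) if t != "N" else "N" for t in window[::-1]]
        mm_body = sum(
            1 for p, t in zip(primer[:-1], paired[:-1]) if t == "N" or p != t
        )
        if paired[-1] != "N" and paired[-1] == primer[-1] and mm_body <= max_mismatch:
            sites.append((i, "-"))
    return sorted(sites)


def _matching_scores(a, b, match, mismatch, gap):
    """Yield (substitution+internal-gap score, tails) for every non-empty
    monotone matching between positions of a and b. ``tails`` is
    (left_a, left_b, right_a, right_b): unmatched run lengths outside the
    matched span of each sequence."""
    n, m = len(a), len(b)
    for k in range(1, min(n, m) + 1):
        for ia in combinations(range(n), k):
            for jb in combinations(range(m), k):
                s = sum(
                    match if a[i] == b[j] else mismatch for i, j in zip(ia, jb)
                )
                s += gap * ((ia[-1] - ia[0] + 1 - k) + (jb[-1] - jb[0] + 1 - k))
                yield s, (ia[0], jb[0], n - 1 - ia[-1], m - 1 - jb[-1])


def overlap_score_bruteforce(a, b, match=1, mismatch=-1, gap=-2):
    """Best end-gap-free global (overlap) alignment score by enumerating
    every monotone matching between positions of a and b.

    At each end only one sequence's unmatched tail rides free; the other
    tail pays ``gap`` per base (the alignment must reach the end of one
    sequence on each side), so each end contributes gap times the shorter
    tail. The empty alignment scores 0.
    """
    best = 0
    for s, (la, lb, ra, rb) in _matching_scores(a, b, match, mismatch, gap):
        s += gap * (min(la, lb) + min(ra, rb))
        if s > best:
            best = s
    return best


def local_score_bruteforce(a, b, match=1, mismatch=-1, gap=-2):
    """Best local alignment score: as above but every tail of both
    sequences is free on both ends; empty alignment scores 0."""
    best = 0
    for s, _ in _matching_scores(a, b, match, mismatch, gap):
        if s > best:
            best = s
    return best
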