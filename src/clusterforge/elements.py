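"""Terminal-inverted-repeat, MITE, and telomere-array detection.

The TIR scanner is seed-and-extend: exact k-mer matches between the
sequence and its own reverse complement seed candidate arm pairs, which are
then extended without gaps under an einverted-style scoring of +3 per
match and -4 per mismatch with an X-drop cutoff.  This recovers the
essentially ungapped TIRs of MITEs and DNA-transposon relics; long gapped
palindromic structures are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .seqs import revcomp, seq_to_codes

MATCH, MISMATCH = 3, -4
XDROP = 24


@dataclass
class TirHit:
    contig: str
    left: tuple[int, int]
    right: tuple[int, int]
    identity: float
    loop: int
    score: int

    def __post_init__(self) -> None:
        if self.left[1] > self.right[0]:
            raise ValueError("TIR arms overlap")


@dataclass
class MiteCall:
    contig: str
    start: int
    end: int
    family_id: str
    tir: TirHit
    length: int


@dataclass
class TelomereHit:
    contig: str
    end: str                    # "left" | "right"
    motif: str
    copies: int
    start: int
    stop: int
    offset: int                 # distance of the array from the contig terminus


# --------------------------------------------------------------------------
# inverted repeats
# --------------------------------------------------------------------------

def _extend(codes: np.ndarray, comp: np.ndarray, l1: int, l2: int,
            r1: int, r2: int, min_loop: int = 0):
    """Greedy ungapped extension of a paired-arm seed.

    Pairing invariant: codes[l1:l2] aligns to the complement of
    codes[r1:r2] reversed, i.e. codes[l1+i] pairs with codes[r2-1-i].
    Extends outward (l1-1 with r2) then inward (l2 with r1-1) under
    X-drop; returns the best-scoring arm pair.
    """
    n = codes.size

    def run(limit_checks):
        nonlocal l1, l2, r1, r2
        best = (l1, l2, r1, r2)
        score = MATCH * (l2 - l1)
        best_score = score
        # outward
        a, b = l1 - 1, r2
        while a >= 0 and b < n:
            score += MATCH if codes[a] == comp[b] else MISMATCH
            if score > best_score:
                best_score, best = score, (a, l2, r1, b + 1)
            if score < best_score - XDROP:
                break
            a -= 1
            b += 1
        l1, l2, r1, r2 = best
        score = best_score
        # inward (loop must stay >= min_loop)
        a, b = l2, r1 - 1
        while b - 1 - a >= min_loop and a < n and b >= 0:
            score += MATCH if codes[a] == comp[b] else MISMATCH
            if score > best_score:
                best_score, best = score, (l1, a + 1, b, r2)
            if score < best_score - XDROP:
                break
            a += 1
            b -= 1
        return best, best_score

    best, best_score = run(None)
    return best, best_score


def find_inverted_repeats(seq: str, min_arm: int = 15, max_loop: int = 2000,
                          min_identity: float = 0.85, contig: str = "seq",
                          seed_k: int = 8) -> list[TirHit]:
    """All non-redundant arm pairs where a subsequence matches the reverse
    complement of a downstream subsequence at or above the thresholds."""
    n = len(seq)
    if n < 2 * min_arm:
        return []
    codes = seq_to_codes(seq)
    comp = seq_to_codes(revcomp(seq))[::-1].copy()   # comp[i] = complement of codes[i]
    k = min(seed_k, min_arm)
    index: dict[bytes, list[int]] = {}
    raw = codes.tobytes()
    for i in range(n - k + 1):
        index.setdefault(raw[i:i + k], []).append(i)
    rc_raw = comp.tobytes()
    seen: set[tuple[int, int, int, int]] = set()
    hits: list[TirHit] = []
    for i in range(n - k + 1):
        # seed: codes[i:i+k] pairs with positions j where
        # codes[j:j+k] reversed-complemented equals it
        key = rc_raw[i:i + k][::-1]
        for j in index.get(key, ()):
            if j < i + k:                       # keep left arm before right arm
                continue
            if j - (i + k) > max_loop + 4 * XDROP // MATCH:
                continue
            (l1, l2, r1, r2), score = _extend(codes, comp, i, i + k, j, j + k)
            arm = l2 - l1
            loop = r1 - l2
            if arm < min_arm or loop < 0 or loop > max_loop:
                continue
            matches = int((codes[l1:l2] == comp[r1:r2][::-1]).sum())
            ident = matches / arm
            if ident < min_identity:
                continue
            sig = (l1, l2, r1, r2)
            if sig in seen:
                continue
            seen.add(sig)
            hits.append(TirHit(contig, (l1, l2), (r1, r2), ident, loop, score))
    # non-redundant: drop hits strictly contained in a better hit
    hits.sort(key=lambda h: (-h.score, -h.identity, h.left, h.right))
    kept: list[TirHit] = []
    for h in hits:
        contained = any(
            k2.left[0] <= h.left[0] and h.left[1] <= k2.left[1]
            and k2.right[0] <= h.right[0] and h.right[1] <= k2.right[1]
            and (k2.identity >= h.identity or k2.score >= h.score)
            for k2 in kept)
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: (h.left, h.right))
    return kept


# --------------------------------------------------------------------------
# MITE calling
# --------------------------------------------------------------------------

def call_mites(families: Sequence, genome,
               length_bounds: tuple[int, int] = (80, 800),
               min_arm: int = 10, min_identity: float = 0.8,
               terminal_slack: int = 50,
               min_copies: int = 2) -> list[MiteCall]:
    """Classify repeat families as MITEs by exemplar length and TIRs.

    A family qualifies when its exemplar length is within ``length_bounds``,
    it has at least ``min_copies`` genomic copies, and the exemplar carries
    an inverted-repeat arm pair whose arms sit within ``terminal_slack`` bp
    of the exemplar termini.  All copies of qualifying families are emitted.
    """
    lo, hi = length_bounds
    calls: list[MiteCall] = []
    for fam in families:
        ex = fam.exemplar
        if not (lo <= len(ex) <= hi) or len(fam.copies) < min_copies:
            continue
        tirs = [h for h in find_inverted_repeats(
                    ex, min_arm=min_arm, max_loop=len(ex),
                    min_identity=min_identity)
                if h.left[0] <= terminal_slack
                and h.right[1] >= len(ex) - terminal_slack]
        if not tirs:
            continue
        best = max(tirs, key=lambda h: h.score)
        for copy in fam.copies:
            calls.append(MiteCall(copy.contig, copy.start, copy.end,
                                  fam.family_id, best, copy.end - copy.start))
    return calls


# --------------------------------------------------------------------------
# telomeres
# --------------------------------------------------------------------------

def _count_array(seq: str, motif: str, anchor: int, direction: int,
                 per_copy_mm: int) -> int:
    """Count tandem motif copies from ``anchor`` going ``direction`` (+1/-1).

    A copy with 1..per_copy_mm mismatches is tolerated only in the interior
    (at most one mismatched copy per three counted), and trailing mismatched
    copies are trimmed so that a perfect planted array is counted exactly.
    """
    m = len(motif)
    copies = 0
    mismatched_flags: list[bool] = []
    pos = anchor
    while True:
        if direction > 0:
            seg = seq[pos:pos + m]
        else:
            seg = seq[pos - m:pos]
        if len(seg) < m:
            break
        mm = sum(1 for a, b in zip(seg, motif) if a != b)
        if mm == 0:
            mismatched_flags.append(False)
        elif mm <= per_copy_mm and sum(mismatched_flags) + 1 <= (copies + 1) // 3:
            mismatched_flags.append(True)
        else:
            break
        copies += 1
        pos += direction * m
    while mismatched_flags and mismatched_flags[-1]:
        mismatched_flags.pop()
        copies -= 1
    return copies


def detect_telomeres(genome, motif: str = "TTAGGG", min_copies: int = 3,
                     max_offset: int = 50, per_copy_mm: int = 2
                     ) -> list[TelomereHit]:
    """Tandem terminal motif arrays (reverse complement at the left end).

    The array must start within ``max_offset`` of a contig end; the copy
    count is maximal.  Set ``per_copy_mm=0`` for strict counting.
    """
    if len(motif) < 4:
        raise ValueError("motif length must be >= 4")
    m = len(motif)
    rc = revcomp(motif)
    hits: list[TelomereHit] = []
    for name, seq in genome.sequences.items():
        n = len(seq)
        # right end: forward motif, arrays end near the terminus
        best = None
        for off in range(0, min(max_offset, n - m) + 1):
            k = _count_array(seq, motif, n - off, -1, per_copy_mm)
            if k >= min_copies and (best is None or k > best[0]):
                best = (k, off)
        if best:
            k, off = best
            hits.append(TelomereHit(name, "right", motif, k,
                                    n - off - k * m, n - off, off))
        # left end: reverse-complement motif arrays begin near the terminus
        best = None
        for off in range(0, min(max_offset, n - m) + 1):
            k = _count_array(seq, rc, off, +1, per_copy_mm)
            if k >= min_copies and (best is None or k > best[0]):
                best = (k, off)
        if best:
            k, off = best
            hits.append(TelomereHit(name, "left", motif, k,
                                    off, off + k * m, off))
    return hits


def distance_to_telomere(contig: str, interval: tuple[int, int],
                         hits: Sequence[TelomereHit],
                         contig_length: Optional[int] = None
                         ) -> Optional[int]:
    """bp gap between a feature and the nearest same-contig telomere array."""
    lo, hi = interval
    if lo < 0 or (contig_length is not None and hi > contig_length) or lo >= hi:
        raise ValueError(f"feature interval {interval} invalid on {contig}")
    dists = []
    for h in hits:
        if h.contig != contig:
            continue
        if h.start >= hi:
            dists.append(h.start - hi)
        elif h.stop <= lo:
            dists.append(lo - h.stop)
        else:
            dists.append(0)
    return min(dists) if dists else None
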