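"""Sliding-window RIP-index and composition tracks, and RIP classification.

Repeat-induced point mutation (RIP) converts CpA-context cytosines to
thymines in duplicated sequence, which depletes ApT relative to TpA (both
palindromic dinucleotides, so the index is strand-symmetric).  The index is
computed in 200 bp windows stepped by 20 bp; a window must lie fully inside
the contig (partial windows are not counted), and dinucleotides containing
ambiguity codes are skipped rather than imputed.

Two orientations of the index are supported: ``apT_over_tpA`` (the printed
convention, values *fall* with RIP) and ``tpA_over_apT`` (values *rise*
with RIP); classification uses the latter internally so "higher = more
RIPped".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seqs import gc_fraction, seq_to_codes

_VALID_ORIENT = ("apT_over_tpA", "tpA_over_apT")


@dataclass(frozen=True)
class RipParams:
    window: int = 200
    step: int = 20
    orientation: str = "apT_over_tpA"

    def validate(self) -> None:
        if not (0 < self.step <= self.window):
            raise ValueError("require 0 < step <= window")
        if self.orientation not in _VALID_ORIENT:
            raise ValueError(f"orientation must be one of {_VALID_ORIENT}")


@dataclass
class RipWindow:
    contig: str
    start: int
    end: int
    apt: int
    tpa: int
    index: Optional[float]      # None when the denominator is zero


@dataclass
class RipTrack:
    windows: list[RipWindow]
    params: RipParams

    def values(self) -> np.ndarray:
        return np.array([w.index for w in self.windows if w.index is not None])


def expected_window_count(length: int, window: int, step: int) -> int:
    """floor((L - window)/step) + 1 for L >= window, else 0."""
    if length < window:
        return 0
    return (length - window) // step + 1


def _dinuc_starts(seq: str, a: str, b: str) -> np.ndarray:
    codes = seq_to_codes(seq)
    hits = (codes[:-1] == ord(a)) & (codes[1:] == ord(b))
    return hits.astype(np.int64)


def rip_index_track(seq: str, params: RipParams = RipParams(),
                    contig: str = "seq") -> RipTrack:
    """RIP index per window, windows laid left-to-right from position 0."""
    params.validate()
    n = expected_window_count(len(seq), params.window, params.step)
    windows: list[RipWindow] = []
    if n == 0:
        return RipTrack(windows, params)
    apt = _dinuc_starts(seq, "A", "T")
    tpa = _dinuc_starts(seq, "T", "A")
    capt = np.concatenate(([0], np.cumsum(apt)))
    ctpa = np.concatenate(([0], np.cumsum(tpa)))
    for i in range(n):
        lo = i * params.step
        hi = lo + params.window
        # dinucleotide start positions lo .. hi-2 lie fully in the window
        a = int(capt[hi - 1] - capt[lo])
        t = int(ctpa[hi - 1] - ctpa[lo])
        num, den = (a, t) if params.orientation == "apT_over_tpA" else (t, a)
        idx = (num / den) if den > 0 else None
        windows.append(RipWindow(contig, lo, hi, a, t, idx))
    return RipTrack(windows, params)


def composition_track(seq: str, window: int = 200, step: int = 20,
                      contig: str = "seq"
                      ) -> list[tuple[str, int, int, float, float, float]]:
    """Per-window (contig, start, end, AT, GC, N) fractions; they sum to 1."""
    if not (0 < step <= window):
        raise ValueError("require 0 < step <= window")
    n = expected_window_count(len(seq), window, step)
    codes = seq_to_codes(seq)
    is_gc = np.isin(codes, (ord("G"), ord("C"))).astype(np.int64)
    is_at = np.isin(codes, (ord("A"), ord("T"))).astype(np.int64)
    cgc = np.concatenate(([0], np.cumsum(is_gc)))
    cat = np.concatenate(([0], np.cumsum(is_at)))
    rows = []
    for i in range(n):
        lo = i * step
        hi = lo + window
        gc = (cgc[hi] - cgc[lo]) / window
        at = (cat[hi] - cat[lo]) / window
        rows.append((contig, lo, hi, at, gc, 1.0 - at - gc))
    return rows


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

@dataclass
class RipBackground:
    """Genome-wide index background from non-repeat intergenic windows."""

    index_quantile: float       # configured quantile of tpA/apT values
    median_gc: float
    quantile: float = 0.95


@dataclass
class RipVerdict:
    copy_id: str
    contig: str
    start: int
    end: int
    ripped: Optional[bool]      # None = indeterminate (copy shorter than window)
    median_index: Optional[float]
    gc: float
    index_exceeds: Optional[bool]
    gc_below: Optional[bool]


def _subtract(intervals: Sequence[tuple[int, int]], length: int
              ) -> list[tuple[int, int]]:
    """Complement of a set of intervals within [0, length)."""
    out = []
    pos = 0
    for lo, hi in sorted(intervals):
        lo, hi = max(lo, 0), min(hi, length)
        if lo > pos:
            out.append((pos, lo))
        pos = max(pos, hi)
    if pos < length:
        out.append((pos, length))
    return out


def background_distribution(genome, exclude: dict[str, list[tuple[int, int]]],
                            params: RipParams = RipParams(),
                            quantile: float = 0.95,
                            block: int = 1000) -> RipBackground:
    """Background quantile of block-median indices + median GC.

    ``exclude`` should contain repeat and genic intervals per contig so the
    background reflects non-repeat intergenic composition.  Because a copy
    verdict compares the copy's *median* window index against the
    background, the background distribution is likewise built from median
    indices of ``block``-sized tiles (a copy-scale statistic), not from
    single windows, whose much larger spread would mask moderate RIP.
    """
    tparams = RipParams(params.window, params.step, "tpA_over_apT")
    medians: list[float] = []
    gcs: list[float] = []
    for name, seq in genome.sequences.items():
        for lo, hi in _subtract(exclude.get(name, []), len(seq)):
            for blo in range(lo, hi, block):
                sub = seq[blo:min(blo + block, hi)]
                if len(sub) < tparams.window:
                    continue
                track = rip_index_track(sub, tparams, name)
                vals = track.values()
                if vals.size == 0:
                    continue
                medians.append(float(np.median(vals)))
                g = gc_fraction(sub)
                if g == g:
                    gcs.append(g)
    if not medians or not gcs:
        raise ValueError("no background windows available")
    return RipBackground(index_quantile=float(np.quantile(medians, quantile)),
                         median_gc=float(np.median(gcs)),
                         quantile=quantile)


def classify_copy(seq: str, copy_id: str, contig: str, start: int, end: int,
                  background: RipBackground,
                  params: RipParams = RipParams()) -> RipVerdict:
    sub = seq[start:end]
    gc = gc_fraction(sub)
    tparams = RipParams(params.window, params.step, "tpA_over_apT")
    track = rip_index_track(sub, tparams, contig)
    vals = track.values()
    if vals.size == 0:
        return RipVerdict(copy_id, contig, start, end, None, None, gc, None, None)
    med = float(np.median(vals))
    exceeds = med > background.index_quantile
    below = gc < background.median_gc
    return RipVerdict(copy_id, contig, start, end, bool(exceeds and below),
                      med, gc, exceeds, below)


def classify_ripped(family, genome, background: RipBackground,
                    params: RipParams = RipParams()) -> list[RipVerdict]:
    """Per-copy RIP verdicts for a repeat family.

    A copy is flagged when its median window index (TpA/ApT orientation)
    exceeds the background quantile *and* its GC is below the background
    median; both sub-criteria are reported.
    """
    verdicts = []
    for copy in family.copies:
        seq = genome.sequences[copy.contig]
        verdicts.append(classify_copy(
            seq, f"{family.family_id}:{copy.contig}:{copy.start}",
            copy.contig, copy.start, copy.end, background, params))
    return verdicts
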