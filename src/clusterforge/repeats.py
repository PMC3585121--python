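"""Repeat-family discovery, cross-genome correspondence, masking, and the
genome partition / GC accounting.

Families are discovered from a genome self-alignment (all significant local
alignments, the trivial full-length self-identity excluded), merged into
candidate multicopy segments, and single-linkage clustered into
non-redundant families whose exemplar is the longest member.  Exemplars
re-aligned to the genome give the masked copy set; reciprocal exemplar
alignment across genomes gives a correspondence matrix whose connected
components are "universal repeat numbers" shared across genomes.

Alignment is delegated to NCBI BLAST+ (``makeblastdb``/``blastn``), the
field-standard local aligner; the scoring scheme in force is recorded with
every hit set so the raw-score threshold (default 100) is reproducible.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import edlib
import networkx as nx
import numpy as np

from .seqs import seq_to_codes
from .synthetic import GeneModel, GenomeSet

#: -task blastn defaults; sensitive enough for heavily diverged (RIPped) copies
BLASTN_TASK = "blastn"
SCORING_SCHEME = "blastn defaults: match +2, mismatch -3, gap open 5, gap extend 2"

_OUTFMT = ("6 qseqid sseqid pident length mismatch gapopen qstart qend "
           "sstart send evalue bitscore score")


class BlastNotFoundError(RuntimeError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    query: str
    qstart: int                 # 0-based half-open
    qend: int
    subject: str
    sstart: int
    send: int
    pident: float
    length: int
    score: float
    strand: str                 # strand of subject: "+" | "-"
    scheme: str = SCORING_SCHEME

    @property
    def qinterval(self) -> tuple[int, int]:
        return (self.qstart, self.qend)

    @property
    def sinterval(self) -> tuple[int, int]:
        return (self.sstart, self.send)


@dataclass
class RepeatCopy:
    contig: str
    start: int
    end: int
    strand: str
    family_id: str
    identity: float

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class RepeatFamily:
    family_id: str
    exemplar: str
    exemplar_loc: tuple[str, int, int]
    copies: list[RepeatCopy] = field(default_factory=list)
    superfamily: Optional[str] = None


@dataclass(frozen=True)
class CorrespondenceParams:
    min_score: float = 100.0    # raw score in the recorded scheme

    def validate(self) -> None:
        if self.min_score <= 0:
            raise ValueError("min_score must be > 0")


@dataclass
class CorrespondenceMatrix:
    #: ((genomeA, familyA), (genomeB, familyB)) -> best reciprocal score
    pair_scores: dict[tuple[tuple[str, str], tuple[str, str]], float]
    #: (genome, family) -> universal repeat number
    universal: dict[tuple[str, str], int]
    params: CorrespondenceParams
    scheme: str = SCORING_SCHEME


@dataclass
class GenomePartitionStats:
    total_bp: int               # non-gap length
    cds_bp: int
    genic_noncds_bp: int
    repeat_bp: int
    nonrepeat_intergenic_bp: int
    gc_genome: float
    gc_cds: float
    gc_genic_noncds: float
    gc_nonrepeat_intergenic: float
    gc_repeat: float

    @property
    def pct_cds(self) -> float:
        return 100.0 * self.cds_bp / self.total_bp

    @property
    def pct_repeat(self) -> float:
        return 100.0 * self.repeat_bp / self.total_bp

    @property
    def pct_nonrepeat_intergenic(self) -> float:
        return 100.0 * self.nonrepeat_intergenic_bp / self.total_bp


# --------------------------------------------------------------------------
# BLAST plumbing
# --------------------------------------------------------------------------

def _require_blast() -> None:
    for exe in ("makeblastdb", "blastn"):
        if shutil.which(exe) is None:
            raise BlastNotFoundError(f"{exe} not found on PATH")


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, s in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(s), 80):
                fh.write(s[i:i + 80] + "\n")


def _parse_hits(text: str) -> list[AlignmentHit]:
    hits = []
    for line in text.splitlines():
        f = line.rstrip("\n").split("\t")
        if len(f) < 13:
            continue
        qstart, qend = int(f[6]), int(f[7])
        sstart, send = int(f[8]), int(f[9])
        strand = "+" if send >= sstart else "-"
        if strand == "-":
            sstart, send = send, sstart
        hits.append(AlignmentHit(
            query=f[0], qstart=qstart - 1, qend=qend,
            subject=f[1], sstart=sstart - 1, send=send,
            pident=float(f[2]), length=int(f[3]),
            score=float(f[12]), strand=strand))
    return hits


def blastn_pairwise(queries: dict[str, str], subjects: dict[str, str],
                    evalue: float = 1e-5,
                    word_size: int = 11) -> list[AlignmentHit]:
    """All local alignments of ``queries`` against ``subjects``."""
    _require_blast()
    with tempfile.TemporaryDirectory(prefix="clusterforge_blast_") as tmp:
        tmp = Path(tmp)
        qpath, spath = tmp / "q.fa", tmp / "s.fa"
        _write_fasta(queries, qpath)
        _write_fasta(subjects, spath)
        subprocess.run(["makeblastdb", "-in", str(spath), "-dbtype", "nucl"],
                       check=True, capture_output=True)
        res = subprocess.run(
            ["blastn", "-task", BLASTN_TASK, "-query", str(qpath),
             "-db", str(spath), "-evalue", str(evalue),
             "-word_size", str(word_size),
             "-dust", "no", "-soft_masking", "false",
             "-outfmt", _OUTFMT],
            check=True, capture_output=True, text=True)
    hits = _parse_hits(res.stdout)
    hits.sort(key=lambda h: (h.query, h.subject, h.qstart, h.qend,
                             h.sstart, h.send, -h.score))
    return hits


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def self_align(genome: GenomeSet, min_score: float = 100.0
               ) -> list[AlignmentHit]:
    """Genome self-alignment, trivial self-identity hits excluded.

    The hit list is sorted canonically, so it is stable under contig
    reordering of the input.
    """
    if not genome.sequences:
        return []
    hits = blastn_pairwise(genome.sequences, genome.sequences)
    out = []
    for h in hits:
        if (h.query == h.subject and h.qinterval == h.sinterval
                and h.strand == "+"):
            continue
        if h.score >= min_score:
            out.append(h)
    return out


def _merge(intervals: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(m) for m in merged]


def call_multicopy_segments(hits: Sequence[AlignmentHit], min_len: int = 400,
                            min_copies: int = 3, merge_gap: int = 100,
                            overlap_frac: float = 0.5
                            ) -> list[tuple[str, int, int]]:
    """Per-locus unions of hit footprints supported by >= min_copies-1 hits.

    Footprints at one locus (alignments of that copy to the family's other
    copies) are grouped when they reciprocally overlap by ``overlap_frac``
    of the shorter footprint.  Non-overlapping footprints are glued only
    when they chain: query gap <= ``merge_gap`` *and* the subject
    footprints continue on the same subject and strand within the same
    gap -- i.e. fragments of one interrupted alignment.  Plain positional
    adjacency never merges two unrelated elements into a chimeric
    candidate.
    """
    per_contig: dict[str, list[int]] = {}
    for i, h in enumerate(hits):
        per_contig.setdefault(h.query, []).append(i)

    parent = list(range(len(hits)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for contig, idx in per_contig.items():
        idx.sort(key=lambda i: (hits[i].qstart, hits[i].qend))
        active: list[int] = []
        for j in idx:
            hj = hits[j]
            active = [i for i in active
                      if hits[i].qend + merge_gap > hj.qstart]
            for i in active:
                hi_ = hits[i]
                ov = min(hi_.qend, hj.qend) - max(hi_.qstart, hj.qstart)
                shorter = min(hi_.qend - hi_.qstart, hj.qend - hj.qstart)
                if ov >= overlap_frac * shorter:
                    union(i, j)
                    continue
                gap = hj.qstart - hi_.qend
                if 0 <= gap <= merge_gap and hi_.subject == hj.subject \
                        and hi_.strand == hj.strand:
                    if hj.strand == "+":
                        sgap = hj.sstart - hi_.send
                    else:
                        sgap = hi_.sstart - hj.send
                    if -merge_gap <= sgap <= merge_gap:
                        union(i, j)
            active.append(j)

    comps: dict[int, list[int]] = {}
    for contig, idx in per_contig.items():
        for i in idx:
            comps.setdefault(find(i), []).append(i)
    candidates = []
    for members in comps.values():
        contig = hits[members[0]].query
        lo = min(hits[i].qstart for i in members)
        hi_ = max(hits[i].qend for i in members)
        if hi_ - lo >= min_len and len(members) >= min_copies - 1:
            candidates.append((contig, lo, hi_))
    candidates.sort()
    return candidates


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def cluster_into_families(candidates: Sequence[tuple[str, int, int]],
                          hits: Sequence[AlignmentHit],
                          genome: GenomeSet,
                          overlap_frac: float = 0.5) -> list[RepeatFamily]:
    """Single-linkage clustering of candidate segments using hits as edges.

    An edge joins the candidates best covered by a hit's query and subject
    footprints when each covers at least ``overlap_frac`` of the shorter of
    hit footprint and candidate.  Family ids are deterministic: numbered by
    (exemplar contig, start).
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(len(candidates)))
    by_contig: dict[str, list[int]] = {}
    for i, (contig, lo, hi) in enumerate(candidates):
        by_contig.setdefault(contig, []).append(i)

    def find(contig: str, ival: tuple[int, int]) -> Optional[int]:
        best, best_ov = None, 0
        for i in by_contig.get(contig, ()):
            _, lo, hi = candidates[i]
            ov = _overlap(ival, (lo, hi))
            if ov > best_ov:
                best, best_ov = i, ov
        if best is None:
            return None
        _, lo, hi = candidates[best]
        need = overlap_frac * min(ival[1] - ival[0], hi - lo)
        return best if best_ov >= need else None

    for h in hits:
        qi = find(h.query, h.qinterval)
        si = find(h.subject, h.sinterval)
        if qi is not None and si is not None and qi != si:
            graph.add_edge(qi, si)

    families: list[RepeatFamily] = []
    comps = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        if len(members) < 2:
            continue
        exemplar_i = max(members,
                         key=lambda i: (candidates[i][2] - candidates[i][1],
                                        -i))
        comps.append((candidates[exemplar_i], exemplar_i, members))
    comps.sort(key=lambda c: c[0])
    for n, ((contig, lo, hi), exemplar_i, members) in enumerate(comps, 1):
        exemplar = genome.sequences[contig][lo:hi]
        fam = RepeatFamily(family_id=f"RF{n:03d}", exemplar=exemplar,
                           exemplar_loc=(contig, lo, hi))
        for i in members:
            c, mlo, mhi = candidates[i]
            ident = (1.0 if i == exemplar_i
                     else _identity(genome.sequences[c][mlo:mhi], exemplar))
            fam.copies.append(RepeatCopy(c, mlo, mhi, "+", fam.family_id, ident))
        fam.copies.sort(key=lambda cp: (cp.contig, cp.start))
        families.append(fam)
    return families


def discover_repeats(genome: GenomeSet, min_score: float = 100.0,
                     min_len: int = 400, min_copies: int = 3,
                     merge_gap: int = 100,
                     overlap_frac: float = 0.5) -> list[RepeatFamily]:
    """self_align -> call_multicopy_segments -> cluster_into_families."""
    hits = self_align(genome, min_score=min_score)
    candidates = call_multicopy_segments(hits, min_len=min_len,
                                         min_copies=min_copies,
                                         merge_gap=merge_gap)
    return cluster_into_families(candidates, hits, genome,
                                 overlap_frac=overlap_frac)


def correspond_families(libraries: dict[str, Sequence[RepeatFamily]],
                        params: CorrespondenceParams = CorrespondenceParams()
                        ) -> CorrespondenceMatrix:
    """Reciprocal exemplar alignment across genomes; universal numbers are
    the connected components of the score-threshold graph, numbered by
    sorted (genome, family) so labels are input-order invariant."""
    params.validate()
    names = sorted(libraries)
    nodes = [(g, fam.family_id) for g in names for fam in libraries[g]]
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    pair_scores: dict = {}
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            qa = {f.family_id: f.exemplar for f in libraries[ga]}
            qb = {f.family_id: f.exemplar for f in libraries[gb]}
            if not qa or not qb:
                continue
            fwd = blastn_pairwise(qa, qb)
            rev = blastn_pairwise(qb, qa)
            best_fwd: dict[tuple[str, str], float] = {}
            for h in fwd:
                key = (h.query, h.subject)
                best_fwd[key] = max(best_fwd.get(key, 0.0), h.score)
            best_rev: dict[tuple[str, str], float] = {}
            for h in rev:
                key = (h.subject, h.query)      # keyed as (famA, famB)
                best_rev[key] = max(best_rev.get(key, 0.0), h.score)
            for key in set(best_fwd) & set(best_rev):
                s = min(best_fwd[key], best_rev[key])
                if s >= params.min_score:
                    fa, fb = key
                    pair_scores[((ga, fa), (gb, fb))] = s
                    graph.add_edge((ga, fa), (gb, fb))
    universal: dict[tuple[str, str], int] = {}
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for n, comp in enumerate(comps, 1):
        for node in comp:
            universal[node] = n
    return CorrespondenceMatrix(pair_scores, universal, params)


def mask_repeats(genome: GenomeSet, families: Sequence[RepeatFamily],
                 min_identity: float = 70.0, min_len: int = 80,
                 min_score: float = 100.0) -> list[RepeatCopy]:
    """Re-align family exemplars to the genome; emit all qualifying
    placements, resolving overlaps between families by higher score."""
    if not families:
        raise ValueError("mask_repeats requires a non-empty family library")
    lib = {f.family_id: f.exemplar for f in families}
    hits = blastn_pairwise(lib, genome.sequences)
    placements = []
    for h in hits:
        if h.score < min_score or h.pident < min_identity:
            continue
        if h.send - h.sstart < min_len:
            continue
        placements.append(h)
    placements.sort(key=lambda h: (-h.score, h.subject, h.sstart, h.query))
    kept: list[AlignmentHit] = []
    per_contig: dict[str, list[AlignmentHit]] = {}
    for h in placements:
        drop = False
        for k in per_contig.get(h.subject, ()):
            if k.query == h.query:
                continue
            ov = _overlap(h.sinterval, k.sinterval)
            if ov > 0.5 * (h.send - h.sstart):
                drop = True
                break
        if not drop:
            kept.append(h)
            per_contig.setdefault(h.subject, []).append(h)
    copies = [RepeatCopy(h.subject, h.sstart, h.send, h.strand,
                         h.query, h.pident / 100.0) for h in kept]
    copies.sort(key=lambda c: (c.contig, c.start, c.end, c.family_id))
    return copies


def merged_masked_intervals(copies: Sequence[RepeatCopy]
                            ) -> dict[str, list[tuple[int, int]]]:
    per: dict[str, list[tuple[int, int]]] = {}
    for c in copies:
        per.setdefault(c.contig, []).append(c.interval)
    return {k: _merge(v, 0) for k, v in per.items()}


# --------------------------------------------------------------------------
# partition statistics
# --------------------------------------------------------------------------

def partition_stats(genome: GenomeSet, genes: Sequence[GeneModel],
                    masked: Sequence[RepeatCopy] | dict
                    ) -> GenomePartitionStats:
    """Assign every non-gap base to exactly one of four categories.

    Precedence CDS > genic-non-CDS > intergenic-repeat >
    intergenic-non-repeat; N bases are excluded everywhere, and
    percentages are taken over the non-gap total, so the categories
    partition it exactly.
    """
    if isinstance(masked, dict):
        masked_by_contig = masked
    else:
        masked_by_contig = merged_masked_intervals(masked)
    tot = np.zeros(5, dtype=np.int64)      # cds, genic-noncds, rpt, nonrpt-ig
    gc = np.zeros(5, dtype=np.int64)
    G, C, N = ord("G"), ord("C"), ord("N")
    for name, seq in genome.sequences.items():
        L = len(seq)
        codes = seq_to_codes(seq)
        is_gap = codes == N
        cds = np.zeros(L, dtype=bool)
        genic = np.zeros(L, dtype=bool)
        for g in genes:
            if g.contig != name:
                continue
            if g.start < 0 or g.end > L:
                raise ValueError(
                    f"gene {g.gene_id} interval ({g.start},{g.end}) outside "
                    f"contig {name} (length {L})")
            genic[g.start:g.end] = True
            for lo, hi in g.cds:
                cds[lo:hi] = True
        rpt = np.zeros(L, dtype=bool)
        for lo, hi in masked_by_contig.get(name, ()):
            rpt[max(lo, 0):min(hi, L)] = True
        ok = ~is_gap
        cat_cds = cds & ok
        cat_gnc = genic & ~cds & ok
        cat_rpt = rpt & ~genic & ok
        cat_ig = ok & ~genic & ~rpt
        isgc = (codes == G) | (codes == C)
        for j, cat in enumerate((cat_cds, cat_gnc, cat_rpt, cat_ig)):
            tot[j] += int(cat.sum())
            gc[j] += int((isgc & cat).sum())
        tot[4] += int(ok.sum())
        gc[4] += int((isgc & ok).sum())

    def frac(j: int) -> float:
        return gc[j] / tot[j] if tot[j] else float("nan")

    return GenomePartitionStats(
        total_bp=int(tot[4]), cds_bp=int(tot[0]), genic_noncds_bp=int(tot[1]),
        repeat_bp=int(tot[2]), nonrepeat_intergenic_bp=int(tot[3]),
        gc_genome=frac(4), gc_cds=frac(0), gc_genic_noncds=frac(1),
        gc_nonrepeat_intergenic=frac(3), gc_repeat=frac(2))
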