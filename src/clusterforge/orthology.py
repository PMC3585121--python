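"""Ortholog-group refinement by recursive bipartition.

Precomputed ortholog groups (e.g. from a Markov-cluster analysis) may mix
paralogs with orthologs.  Each group is recursively divided in two: members
are multiply aligned, pairwise p-distances are average-linkage clustered,
and the deepest split proposes a bipartition.  A division is accepted when
its column-bootstrap support is >= 0.75 and its split score -- the number
of taxa common to both sub-groups divided by the number of taxa in the
smaller sub-group -- is >= 0.5; a high split score marks an ancient
duplication (many taxa represented on both sides).  A group that cannot be
partitioned into exactly two subclusters is left unpartitioned.

A reciprocal-best-hit grouping stand-in is provided to build input groups
from per-genome protein sets without an external clustering tool.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

BOOTSTRAP_MIN = 0.75
SPLIT_MIN = 0.5


@dataclass
class GroupMember:
    genome: str
    gene_id: str
    seq: str


@dataclass
class OrthologGroup:
    group_id: str
    members: list[GroupMember]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"{self.group_id}: groups need >= 2 members")

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(m.genome for m in self.members)


@dataclass
class SplitDecision:
    taxa_a: frozenset[str]
    taxa_b: frozenset[str]
    bootstrap: float
    split_score: float
    accepted: bool
    bootstrap_min: float = BOOTSTRAP_MIN
    split_min: float = SPLIT_MIN


@dataclass
class RefinementNode:
    members: list[GroupMember]
    decision: Optional[SplitDecision] = None
    children: list["RefinementNode"] = field(default_factory=list)

    def leaves(self) -> list["RefinementNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_partition(self) -> list[list[str]]:
        return [[m.gene_id for m in leaf.members] for leaf in self.leaves()]


def split_score(taxa_a: frozenset[str] | set[str],
                taxa_b: frozenset[str] | set[str]) -> float:
    """|A intersect B| / min(|A|, |B|)."""
    if not taxa_a or not taxa_b:
        raise ValueError("split_score requires non-empty taxa sets")
    return len(set(taxa_a) & set(taxa_b)) / min(len(taxa_a), len(taxa_b))


# --------------------------------------------------------------------------
# built-in progressive aligner (center-star, edlib pairwise)
# --------------------------------------------------------------------------

def _pairwise_aligned(a: str, b: str) -> tuple[str, str]:
    res = edlib.align(a, b, task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    return nice["query_aligned"], nice["target_aligned"]


def progressive_align(seqs: Sequence[str]) -> list[str]:
    """Center-star multiple alignment: equal-length rows, gaps as '-'.

    The center sequence minimizes the total edit distance to the others;
    each remaining sequence is pairwise-aligned to the center and the gap
    patterns are merged.  Adequate for the distance-based clustering here;
    not a substitute for a likelihood-grade aligner.
    """
    n = len(seqs)
    if n == 0:
        return []
    if n == 1:
        return [seqs[0]]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seqs[i], seqs[j], task="distance")["editDistance"]
            dist[i, j] = dist[j, i] = d
    center = int(np.argmin(dist.sum(axis=1)))
    master_center = seqs[center]
    rows: dict[int, str] = {center: seqs[center]}
    for i in range(n):
        if i == center:
            continue
        c_aln, s_aln = _pairwise_aligned(master_center.replace("-", ""), seqs[i])
        # re-expand pairwise center to the master gap pattern
        merged_center: list[str] = []
        merged_rows = {k: [] for k in rows}
        new_row: list[str] = []
        mi = ci = 0
        while mi < len(master_center) or ci < len(c_aln):
            m_ch = master_center[mi] if mi < len(master_center) else None
            c_ch = c_aln[ci] if ci < len(c_aln) else None
            if m_ch == "-":
                # column where an earlier merge inserted a gap in the center
                merged_center.append("-")
                for k in merged_rows:
                    merged_rows[k].append(rows[k][mi])
                new_row.append("-")
                mi += 1
            elif c_ch == "-":
                # this sequence inserts relative to the center
                merged_center.append("-")
                for k in merged_rows:
                    merged_rows[k].append("-")
                new_row.append(s_aln[ci])
                ci += 1
            else:
                merged_center.append(m_ch)
                for k in merged_rows:
                    merged_rows[k].append(rows[k][mi])
                new_row.append(s_aln[ci])
                mi += 1
                ci += 1
        master_center = "".join(merged_center)
        rows = {k: "".join(v) for k, v in merged_rows.items()}
        rows[i] = "".join(new_row)
    return [rows[i] for i in range(n)]


def _p_distance_matrix(rows: Sequence[str],
                       columns: Optional[np.ndarray] = None) -> np.ndarray:
    arr = np.array([list(r) for r in rows])
    if columns is not None:
        arr = arr[:, columns]
    n = arr.shape[0]
    gap = arr == "-"
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            m = int(ok.sum())
            d = float((arr[i, ok] != arr[j, ok]).mean()) if m else 1.0
            dist[i, j] = dist[j, i] = d
    return dist


def _deepest_split(dist: np.ndarray) -> Optional[np.ndarray]:
    """Average-linkage bipartition labels (bool mask), or None if the
    clustering cannot produce exactly two subclusters."""
    n = dist.shape[0]
    if n < 2:
        return None
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=2, criterion="maxclust")
    if len(set(labels)) != 2:
        return None
    return labels == labels[0]


def _node_seed(seed: int, members: Sequence[GroupMember]) -> int:
    key = "|".join(sorted(m.gene_id for m in members))
    return (seed * 1_000_003 + zlib.crc32(key.encode())) % (2**31 - 1)


def refine_group(group: OrthologGroup, bootstrap_replicates: int = 100,
                 seed: int = 0, bootstrap_min: float = BOOTSTRAP_MIN,
                 split_min: float = SPLIT_MIN) -> RefinementNode:
    """Recursive bipartition of an ortholog group under the acceptance rule.

    Deterministic given ``seed``: each node draws its bootstrap from a seed
    derived from the sorted member ids, so acceptance thresholds do not
    perturb the resampling stream.
    """
    members = list(group.members)
    node = RefinementNode(members=members)
    if len(members) < 3:
        return node
    rows = progressive_align([m.seq for m in members])
    ncol = len(rows[0])
    dist = _p_distance_matrix(rows)
    mask = _deepest_split(dist)
    if mask is None or mask.all() or not mask.any():
        return node
    side_a = frozenset(m.gene_id for m, f in zip(members, mask) if f)
    rng = np.random.default_rng(_node_seed(seed, members))
    support = 0
    for _ in range(bootstrap_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        bmask = _deepest_split(_p_distance_matrix(rows, cols))
        if bmask is None:
            continue
        bs = frozenset(m.gene_id for m, f in zip(members, bmask) if f)
        if bs == side_a or bs == frozenset(m.gene_id for m in members) - side_a:
            support += 1
    bootstrap = support / bootstrap_replicates
    taxa_a = frozenset(m.genome for m, f in zip(members, mask) if f)
    taxa_b = frozenset(m.genome for m, f in zip(members, mask) if not f)
    score = split_score(taxa_a, taxa_b)
    accepted = bootstrap >= bootstrap_min and score >= split_min
    node.decision = SplitDecision(taxa_a, taxa_b, bootstrap, score, accepted,
                                  bootstrap_min, split_min)
    if accepted:
        for flag in (True, False):
            sub = [m for m, f in zip(members, mask) if f == flag]
            if len(sub) >= 2:
                child = refine_group(
                    OrthologGroup(f"{group.group_id}.{int(flag)}", sub),
                    bootstrap_replicates, seed, bootstrap_min, split_min)
            else:
                child = RefinementNode(members=sub)
            node.children.append(child)
    return node


# --------------------------------------------------------------------------
# reciprocal-best-hit grouping stand-in
# --------------------------------------------------------------------------

def build_groups_rbh(proteomes: dict[str, dict[str, str]],
                     max_distance_frac: float = 0.7
                     ) -> list[OrthologGroup]:
    """Reciprocal-best-hit groups across >= 2 genomes.

    Best hit of a gene in another genome = the minimum-edit-distance
    protein (ties broken lexicographically by gene id); an edge requires
    reciprocity and a distance below ``max_distance_frac`` of the longer
    sequence.  Single-linkage components with >= 2 members become groups,
    numbered deterministically.
    """
    if len(proteomes) < 2:
        raise ValueError("need >= 2 genomes")
    names = sorted(proteomes)
    graph = nx.Graph()
    for g in names:
        for gid in proteomes[g]:
            graph.add_node((g, gid))
    best: dict[tuple[str, str, str], tuple[str, float]] = {}
    for ga in names:
        for gb in names:
            if ga == gb:
                continue
            for gid, seq in sorted(proteomes[ga].items()):
                best_hit, best_d = None, None
                for hid, hseq in sorted(proteomes[gb].items()):
                    d = edlib.align(seq, hseq, task="distance")["editDistance"]
                    frac = d / max(len(seq), len(hseq))
                    if frac > max_distance_frac:
                        continue
                    if best_d is None or d < best_d:
                        best_hit, best_d = hid, d
                if best_hit is not None:
                    best[(ga, gid, gb)] = (best_hit, best_d)
    for (ga, gid, gb), (hid, _) in best.items():
        back = best.get((gb, hid, ga))
        if back is not None and back[0] == gid:
            graph.add_edge((ga, gid), (gb, hid))
    groups = []
    comps = sorted((sorted(c) for c in nx.connected_components(graph)),
                   key=lambda c: c[0])
    n = 0
    for comp in comps:
        if len(comp) < 2:
            continue
        n += 1
        members = [GroupMember(g, gid, proteomes[g][gid]) for g, gid in comp]
        groups.append(OrthologGroup(f"OG{n:04d}", members))
    return groups
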