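"""Specialized-metabolism (SM) gene cluster identification and delimitation.

Signature genes (NRPS, PKS, DMATS-family prenyltransferase, terpene
synthase/cyclase) are found by their InterPro/Pfam domain annotations.
Cluster extent follows the primary-metabolism ortholog rule: genes whose
ortholog group spans every genome under study are treated as probable
primary metabolism, and extension from a signature gene stops after a run
of consecutive such "core" genes.  Genes without any ortholog group are
treated as accessory (cluster-extendable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .elements import TelomereHit, distance_to_telomere
from .synthetic import GeneModel

#: signature domain catalog: class -> InterPro/Pfam ids
SIGNATURE_CATALOG: dict[str, frozenset[str]] = {
    "NRPS": frozenset({"IPR010071", "IPR006163", "IPR001242"}),
    "PKS": frozenset({"IPR013968"}),
    "DMATS": frozenset({"IPR017795", "PF11991"}),
    "TS": frozenset({"IPR008949"}),
}


@dataclass
class CoreOrthologSet:
    """Ortholog-group ids whose taxa span all input genomes."""

    groups: frozenset[str]

    @classmethod
    def from_groups(cls, memberships: dict[str, set[str]],
                    n_genomes: int) -> "CoreOrthologSet":
        """``memberships``: group id -> set of genome ids containing it."""
        return cls(frozenset(g for g, taxa in memberships.items()
                             if len(taxa) >= n_genomes))


@dataclass
class ClusterModel:
    cluster_id: str
    contig: str
    members: list[GeneModel]
    signature_ids: list[str]
    start: int
    end: int
    flank_left: Optional[GeneModel] = None
    flank_right: Optional[GeneModel] = None
    one_sided: bool = False
    repeat_bp: Optional[int] = None
    cds_bp: Optional[int] = None
    log_ratio: Optional[float] = None
    telomere: Optional[TelomereHit] = None
    telomere_distance: Optional[int] = None
    status: Optional[str] = None        # "active" | "inactive"

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def member_ids(self) -> list[str]:
        return [g.gene_id for g in self.members]


def find_signature_genes(genes: Sequence[GeneModel],
                         catalog: dict[str, frozenset[str]] = SIGNATURE_CATALOG
                         ) -> list[tuple[GeneModel, list[str]]]:
    """Genes carrying any catalog domain, with all matching classes listed.

    Pseudogenes are matched but remain flagged on the gene model itself.
    """
    out = []
    for g in genes:
        dom = set(g.domains)
        classes = sorted(cls for cls, ids in catalog.items() if dom & ids)
        if classes:
            out.append((g, classes))
    return out


def _is_core(gene: GeneModel, core: CoreOrthologSet) -> bool:
    return gene.ortholog_group is not None and gene.ortholog_group in core.groups


def delimit_cluster(signature: GeneModel, contig_genes: Sequence[GeneModel],
                    core: CoreOrthologSet, stop_run: int = 2,
                    cluster_id: Optional[str] = None) -> ClusterModel:
    """Extend left/right from the signature gene over non-core genes.

    Extension in a direction stops upon meeting ``stop_run`` consecutive
    core genes (which are excluded); the first core gene on each side is
    recorded as the flank.  A signature gene whose extension reaches a
    contig end without meeting a core run yields a one-sided cluster,
    flagged as such.
    """
    if stop_run < 1:
        raise ValueError("stop_run must be >= 1")
    order = sorted(contig_genes, key=lambda g: g.start)
    try:
        pos = next(i for i, g in enumerate(order)
                   if g.gene_id == signature.gene_id)
    except StopIteration:
        raise ValueError(f"signature gene {signature.gene_id} not on contig")

    def extend(direction: int):
        members: list[GeneModel] = []
        flank: Optional[GeneModel] = None
        run: list[GeneModel] = []
        i = pos + direction
        hit_end = True
        while 0 <= i < len(order):
            g = order[i]
            if _is_core(g, core):
                run.append(g)
                if len(run) >= stop_run:
                    flank = run[0]
                    hit_end = False
                    break
            else:
                # a shorter core run is interrupted: those genes are
                # inside the cluster span but remain non-members
                run = []
                members.append(g)
            i += direction
        if hit_end and run:
            flank = run[0]
        return members, flank, hit_end

    left_members, flank_left, left_open = extend(-1)
    right_members, flank_right, right_open = extend(+1)
    members = list(reversed(left_members)) + [order[pos]] + right_members
    members.sort(key=lambda g: g.start)
    start = min(g.start for g in members)
    end = max(g.end for g in members)
    sig_ids = [g.gene_id for g in members
               if set(g.domains) & set().union(*SIGNATURE_CATALOG.values())]
    return ClusterModel(
        cluster_id=cluster_id or f"cluster_{signature.gene_id}",
        contig=signature.contig, members=members,
        signature_ids=sig_ids or [signature.gene_id],
        start=start, end=end,
        flank_left=flank_left, flank_right=flank_right,
        one_sided=left_open or right_open)


def _clip_total(intervals: Sequence[tuple[int, int]],
                window: tuple[int, int]) -> int:
    lo, hi = window
    merged: list[list[int]] = []
    for a, b in sorted(intervals):
        a, b = max(a, lo), min(b, hi)
        if a >= b:
            continue
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return sum(b - a for a, b in merged)


def cluster_repeat_cds_logratio(cluster: ClusterModel,
                                masked: Sequence,
                                genes: Sequence[GeneModel]) -> ClusterModel:
    """Repeat bp and CDS bp inside the boundary; log10 ratio when both > 0."""
    window = cluster.interval
    rpt = [(c.start, c.end) for c in masked if c.contig == cluster.contig]
    cds = [iv for g in genes if g.contig == cluster.contig for iv in g.cds]
    cluster.repeat_bp = _clip_total(rpt, window)
    cluster.cds_bp = _clip_total(cds, window)
    if cluster.repeat_bp > 0 and cluster.cds_bp > 0:
        cluster.log_ratio = math.log10(cluster.repeat_bp / cluster.cds_bp)
    else:
        cluster.log_ratio = None
    return cluster


def assess_functional_status(cluster: ClusterModel) -> str:
    """"inactive" iff every signature gene is a pseudogene (or none left)."""
    sigs = [g for g in cluster.members if g.gene_id in cluster.signature_ids]
    cluster.status = ("active" if any(not g.pseudogene for g in sigs)
                      else "inactive")
    return cluster.status


def link_telomere(cluster: ClusterModel, hits: Sequence[TelomereHit],
                  max_distance: int = 100_000) -> ClusterModel:
    d = distance_to_telomere(cluster.contig, cluster.interval, hits)
    if d is not None and d <= max_distance:
        same = [h for h in hits if h.contig == cluster.contig]
        cluster.telomere = min(
            same, key=lambda h: min(abs(h.start - cluster.end),
                                    abs(cluster.start - h.stop)))
        cluster.telomere_distance = d
    return cluster


# --------------------------------------------------------------------------
# core-periphery layout statistic
# --------------------------------------------------------------------------

def core_periphery_layout(roles: Sequence[str], n_perm: int = 999,
                          seed: int = 0) -> tuple[float, float]:
    """Peripherality of decoration vs skeleton genes within a cluster.

    ``roles`` is the role label per gene in coordinate order (labels other
    than skeleton/decoration are ignored for the statistic but keep their
    rank positions).  Each gene's peripherality is its normalized rank
    distance from the cluster midpoint (0 = centre, 1 = either end); the
    statistic is mean(decoration) - mean(skeleton), positive when
    decorations sit toward the edges.  The p-value is a one-sided
    permutation test over role labels, seeded.
    """
    n = len(roles)
    if n < 2:
        raise ValueError("need >= 2 genes")
    ranks = np.arange(n, dtype=float)
    mid = (n - 1) / 2.0
    periph = np.abs(ranks - mid) / mid if mid > 0 else np.zeros(n)
    labels = np.asarray(roles)
    dec = labels == "decoration"
    ske = labels == "skeleton"
    if dec.sum() < 1 or ske.sum() < 1:
        raise ValueError("both decoration and skeleton roles required")

    def stat(d: np.ndarray, s: np.ndarray) -> float:
        return float(periph[d].mean() - periph[s].mean())

    observed = stat(dec, ske)
    rng = np.random.default_rng(seed)
    idx = np.where(dec | ske)[0]
    sub = labels[idx]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(sub)
        d = np.zeros(n, dtype=bool)
        s = np.zeros(n, dtype=bool)
        d[idx[perm == "decoration"]] = True
        s[idx[perm == "skeleton"]] = True
        if stat(d, s) >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return observed, p
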