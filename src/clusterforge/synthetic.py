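"""Synthetic genomes with known ground truth.

Generates contigs that reproduce the structural features the downstream
analyses assume in repeat-blocked fungal genomes: multicopy transposon
relics (optionally nested), RIP-mutated AT-rich copies, MITEs with terminal
inverted repeats, terminal telomere-repeat arrays, and clustered specialized
metabolism (SM) genes with a conserved-core / variable-periphery layout.

Every planted feature is recorded in a :class:`TruthTable` so that recall
and precision of the discovery stages can be measured exactly.  A recipe's
``seed`` fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seqs import mutate, random_seq, revcomp, seq_to_codes


class PackingError(ValueError):
    """Planted features exceed the available contig length."""


# --------------------------------------------------------------------------
# recipe types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TeFamilySpec:
    """A transposon-relic repeat family to plant.

    ``rip_rate`` is the per-copy probability that a C in CpA context (either
    strand) is transitioned to T, emulating repeat-induced point mutation;
    ``sub_rate`` is ordinary uniform divergence.  ``nest_prob`` is the
    chance that a copy inserts inside a previously placed copy of any
    family instead of standing alone.
    """

    family_id: str
    length: int
    copies: int
    sub_rate: float = 0.03
    rip_rate: float = 0.0
    nest_prob: float = 0.0
    exemplar_seed: Optional[int] = None

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.family_id}: length must be > 0")
        if self.copies < 1:
            raise ValueError(f"{self.family_id}: copies must be >= 1")
        for name in ("sub_rate", "rip_rate", "nest_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.family_id}: {name} outside [0,1]")


@dataclass(frozen=True)
class MiteSpec:
    """A miniature inverted-repeat element family (short, TIR-flanked)."""

    mite_id: str
    length: int = 250
    tir_len: int = 30
    tir_identity: float = 1.0
    copies: int = 5
    sub_rate: float = 0.01
    exemplar_seed: Optional[int] = None

    def validate(self) -> None:
        if 2 * self.tir_len > self.length:
            raise ValueError(f"{self.mite_id}: 2*tir_len exceeds total length")
        if not 0.0 <= self.tir_identity <= 1.0:
            raise ValueError(f"{self.mite_id}: tir_identity outside [0,1]")
        if self.copies < 1:
            raise ValueError(f"{self.mite_id}: copies must be >= 1")


@dataclass(frozen=True)
class TelomereSpec:
    """Terminal telomere-repeat arrays: which contig ends get one."""

    motif: str = "TTAGGG"
    copy_range: tuple[int, int] = (8, 15)
    #: (contig name, "left" | "right")
    ends: tuple[tuple[str, str], ...] = ()

    def validate(self) -> None:
        if len(self.motif) < 4:
            raise ValueError("telomere motif must be >= 4 bp")
        lo, hi = self.copy_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid telomere copy range")
        for _, end in self.ends:
            if end not in ("left", "right"):
                raise ValueError(f"telomere end must be left/right, got {end}")


@dataclass(frozen=True)
class ClusterSpec:
    """An SM gene cluster: ordered gene roles plus optional repeat blocks.

    ``roles`` uses the vocabulary ``flanking-core`` (conserved primary
    metabolism flank), ``skeleton`` (early pathway, builds the core ring
    system), ``decoration`` (late tailoring), and ``signature`` (the
    cluster-defining NRPS/PKS/DMATS/terpene-cyclase gene; exactly one).
    """

    cluster_id: str
    contig: str
    roles: tuple[str, ...] = ("flanking-core", "flanking-core",
                              "decoration", "skeleton", "signature",
                              "skeleton", "decoration",
                              "flanking-core", "flanking-core")
    gene_length: int = 1500
    spacer: int = 400
    repeat_block: int = 0
    repeat_family: Optional[str] = None
    telomere_distance: Optional[int] = None
    signature_class: str = "PKS"
    signature_pseudogene: bool = False

    _ALLOWED = ("flanking-core", "skeleton", "decoration", "signature")

    def validate(self) -> None:
        if not self.roles:
            raise ValueError(f"{self.cluster_id}: empty role list")
        bad = [r for r in self.roles if r not in self._ALLOWED]
        if bad:
            raise ValueError(f"{self.cluster_id}: unknown roles {bad}")
        if sum(r == "signature" for r in self.roles) != 1:
            raise ValueError(f"{self.cluster_id}: exactly one signature gene required")


@dataclass(frozen=True)
class GenomeRecipe:
    seed: int
    contigs: tuple[tuple[str, int], ...]
    base_gc: float = 0.44
    gene_density: float = 0.35          # background genes per kb
    te_families: tuple[TeFamilySpec, ...] = ()
    mites: tuple[MiteSpec, ...] = ()
    telomeres: Optional[TelomereSpec] = None
    clusters: tuple[ClusterSpec, ...] = ()
    cds_gc_boost: float = 0.11          # CDS GC above background, cf. genic/repeat GC contrast

    def validate(self) -> None:
        if not self.contigs:
            raise ValueError("recipe needs at least one contig")
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig names")
        for _, length in self.contigs:
            if length <= 0:
                raise ValueError("contig lengths must be > 0")
        if not 0.0 <= self.base_gc <= 1.0:
            raise ValueError("base_gc outside [0,1]")
        for spec in self.te_families:
            spec.validate()
        for spec in self.mites:
            spec.validate()
        if self.telomeres is not None:
            self.telomeres.validate()
            for contig, _ in self.telomeres.ends:
                if contig not in names:
                    raise ValueError(f"telomere on unknown contig {contig}")
        for spec in self.clusters:
            spec.validate()
            if spec.contig not in names:
                raise ValueError(f"cluster on unknown contig {spec.contig}")


# --------------------------------------------------------------------------
# output types
# --------------------------------------------------------------------------

@dataclass
class GenomeSet:
    """Named contig sequences plus N-gap annotation."""

    sequences: dict[str, str]
    gaps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gaps:
            self.gaps = {name: _find_gaps(seq) for name, seq in self.sequences.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


def _find_gaps(seq: str) -> list[tuple[int, int]]:
    codes = seq_to_codes(seq)
    isn = codes == ord("N")
    if not isn.any():
        return []
    d = np.diff(np.concatenate(([0], isn.view(np.int8), [0])))
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    cds: tuple[tuple[int, int], ...]
    pseudogene: bool = False
    domains: tuple[str, ...] = ()
    ortholog_group: Optional[str] = None
    role: str = "background"

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class PlantedRepeat:
    family_id: str
    copy_id: str
    contig: str
    start: int
    end: int
    rip_rate: float
    kind: str = "te"                    # "te" | "mite"
    nested_in: Optional[str] = None


@dataclass
class PlantedTelomere:
    contig: str
    end: str                            # "left" | "right"
    motif: str
    copies: int
    start: int
    stop: int


@dataclass
class PlantedCluster:
    cluster_id: str
    contig: str
    start: int
    end: int
    member_gene_ids: tuple[str, ...]
    signature_gene_id: str
    telomere_distance: Optional[int]


@dataclass
class TruthTable:
    repeats: list[PlantedRepeat] = field(default_factory=list)
    telomeres: list[PlantedTelomere] = field(default_factory=list)
    clusters: list[PlantedCluster] = field(default_factory=list)

    def repeat_intervals(self, kind: Optional[str] = None
                         ) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for r in self.repeats:
            if kind is not None and r.kind != kind:
                continue
            out.setdefault(r.contig, []).append((r.start, r.end))
        return out


# --------------------------------------------------------------------------
# RIP mutation
# --------------------------------------------------------------------------

def apply_rip(seq: str, rate: float, rng: np.random.Generator) -> str:
    """One pass of repeat-induced point mutation in CpA/TpG context.

    Each C in a forward-strand CpA dinucleotide mutates to T with
    probability ``rate``; independently each reverse-strand CpA (seen on
    the forward strand as TpG) mutates its C, i.e. the forward-strand G
    becomes A.  Contexts are read from the input sequence, so a single
    pass never cascades.  Length is preserved; ambiguity codes pass
    through untouched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("RIP rate outside [0,1]")
    if rate == 0.0 or len(seq) < 2:
        return seq
    codes = seq_to_codes(seq)
    out = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    C, A, G, T = ord("C"), ord("A"), ord("G"), ord("T")
    fwd = (codes[:-1] == C) & (codes[1:] == A)
    rev = (codes[:-1] == T) & (codes[1:] == G)
    fwd_idx = np.where(fwd)[0]
    rev_idx = np.where(rev)[0] + 1      # the G position
    fwd_hit = fwd_idx[rng.random(fwd_idx.size) < rate]
    rev_hit = rev_idx[rng.random(rev_idx.size) < rate]
    # preserve the case of the input
    lower = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) != codes
    out[fwd_hit] = np.where(lower[fwd_hit], ord("t"), T)
    out[rev_hit] = np.where(lower[rev_hit], ord("a"), A)
    return out.tobytes().decode("ascii")


# --------------------------------------------------------------------------
# block machinery
# --------------------------------------------------------------------------

class _Block:
    """A contiguous planted sequence, possibly hosting nested insertions.

    ``parts`` is an ordered list of (sequence, owner) where owner carries
    the metadata of the planted element that the bases belong to.  When a
    later element inserts into this block the containing part is split, so
    the host's truth interval ends up as two sub-intervals.
    """

    def __init__(self, seq: str, owner: dict):
        self.parts: list[tuple[str, dict]] = [(seq, owner)]

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self.parts)

    def insert(self, pos: int, seq: str, owner: dict) -> None:
        acc = 0
        for i, (s, o) in enumerate(self.parts):
            if acc <= pos <= acc + len(s):
                k = pos - acc
                new = []
                if k > 0:
                    new.append((s[:k], o))
                new.append((seq, owner))
                if k < len(s):
                    new.append((s[k:], o))
                self.parts[i:i + 1] = new
                return
            acc += len(s)
        raise ValueError("insertion position outside block")

    def emit(self, contig: str, offset: int, truth: TruthTable) -> str:
        pos = offset
        per_owner: dict[int, tuple[dict, list[tuple[int, int]]]] = {}
        for s, o in self.parts:
            if o is not None:
                key = id(o)
                per_owner.setdefault(key, (o, []))[1].append((pos, pos + len(s)))
            pos += len(s)
        for o, ivals in per_owner.values():
            for lo, hi in ivals:
                truth.repeats.append(PlantedRepeat(
                    family_id=o["family_id"], copy_id=o["copy_id"],
                    contig=contig, start=lo, end=hi,
                    rip_rate=o["rip_rate"], kind=o["kind"],
                    nested_in=o.get("nested_in")))
        return "".join(s for s, _ in self.parts)


def _mite_exemplar(spec: MiteSpec, rng: np.random.Generator, gc: float) -> str:
    arm = random_seq(spec.tir_len, gc, rng)
    loop = random_seq(spec.length - 2 * spec.tir_len, gc, rng)
    right = revcomp(arm)
    if spec.tir_identity < 1.0:
        right = mutate(right, 1.0 - spec.tir_identity, rng)
    return arm + loop + right


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------

def generate_genome(recipe: GenomeRecipe
                    ) -> tuple[GenomeSet, list[GeneModel], TruthTable]:
    """Build the genome, its gene annotation, and the truth table."""
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    truth = TruthTable()
    contig_names = [n for n, _ in recipe.contigs]
    contig_len = dict(recipe.contigs)

    # --- exemplars -------------------------------------------------------
    te_exemplars: dict[str, str] = {}
    for spec in recipe.te_families:
        r = (np.random.default_rng(spec.exemplar_seed)
             if spec.exemplar_seed is not None else rng)
        te_exemplars[spec.family_id] = random_seq(spec.length, recipe.base_gc, r)
    mite_exemplars: dict[str, str] = {}
    for spec in recipe.mites:
        r = (np.random.default_rng(spec.exemplar_seed)
             if spec.exemplar_seed is not None else rng)
        mite_exemplars[spec.mite_id] = _mite_exemplar(spec, r, recipe.base_gc)

    # --- copy blocks per contig -----------------------------------------
    weights = np.array([contig_len[n] for n in contig_names], dtype=float)
    weights /= weights.sum()
    floating: dict[str, list[_Block]] = {n: [] for n in contig_names}

    def _place(owner: dict, seq: str, contig: str, nest_prob: float) -> None:
        hosts = floating[contig]
        if hosts and rng.random() < nest_prob:
            host = hosts[rng.integers(len(hosts))]
            pos = int(rng.integers(1, max(2, len(host) - 1)))
            first = host.parts[0][1] if host.parts[0][1] else None
            owner["nested_in"] = first["copy_id"] if first else None
            host.insert(pos, seq, owner)
        else:
            floating[contig].append(_Block(seq, owner))

    for spec in recipe.te_families:
        exemplar = te_exemplars[spec.family_id]
        for j in range(spec.copies):
            seq = mutate(exemplar, spec.sub_rate, rng)
            seq = apply_rip(seq, spec.rip_rate, rng)
            contig = contig_names[int(rng.choice(len(contig_names), p=weights))]
            owner = {"family_id": spec.family_id,
                     "copy_id": f"{spec.family_id}.{j}",
                     "rip_rate": spec.rip_rate, "kind": "te"}
            _place(owner, seq, contig, spec.nest_prob)

    for spec in recipe.mites:
        exemplar = mite_exemplars[spec.mite_id]
        for j in range(spec.copies):
            seq = mutate(exemplar, spec.sub_rate, rng)
            contig = contig_names[int(rng.choice(len(contig_names), p=weights))]
            owner = {"family_id": spec.mite_id,
                     "copy_id": f"{spec.mite_id}.{j}",
                     "rip_rate": 0.0, "kind": "mite"}
            _place(owner, seq, contig, 0.0)

    # --- telomere blocks -------------------------------------------------
    telo_at: dict[tuple[str, str], tuple[str, int]] = {}
    if recipe.telomeres is not None:
        lo, hi = recipe.telomeres.copy_range
        for contig, end in recipe.telomeres.ends:
            k = int(rng.integers(lo, hi + 1))
            telo_at[(contig, end)] = (recipe.telomeres.motif * k, k)

    # --- cluster blocks --------------------------------------------------
    genes: list[GeneModel] = []
    cluster_blocks: dict[str, list[tuple[ClusterSpec, list]]] = {n: [] for n in contig_names}
    sig_domains = {"PKS": ("IPR013968",),
                   "NRPS": ("IPR010071", "IPR006163", "IPR001242"),
                   "DMATS": ("IPR017795", "PF11991"),
                   "TS": ("IPR008949",)}
    core_counter = 0

    def _gene_seq(length: int) -> str:
        return random_seq(length, min(0.95, recipe.base_gc + recipe.cds_gc_boost), rng)

    for cs in recipe.clusters:
        parts: list = []       # (kind, payload); kinds: seq / gene / repeat
        member_idx: list[int] = []
        for i, role in enumerate(cs.roles):
            if i > 0:
                parts.append(("seq", random_seq(cs.spacer, recipe.base_gc, rng)))
                if cs.repeat_block > 0 and role != "flanking-core" \
                        and cs.roles[i - 1] != "flanking-core":
                    if cs.repeat_family is not None:
                        ex = te_exemplars[cs.repeat_family]
                        rep = (ex * (cs.repeat_block // len(ex) + 1))[:cs.repeat_block]
                        fam = next(f for f in recipe.te_families
                                   if f.family_id == cs.repeat_family)
                        rep = apply_rip(mutate(rep, fam.sub_rate, rng),
                                        fam.rip_rate, rng)
                        parts.append(("repeat", (rep, cs.repeat_family)))
                    else:
                        rip_block = apply_rip(
                            random_seq(cs.repeat_block, recipe.base_gc, rng), 0.7, rng)
                        parts.append(("seq", rip_block))
                    parts.append(("seq", random_seq(cs.spacer, recipe.base_gc, rng)))
            gid = f"{cs.cluster_id}_g{i}"
            if role == "flanking-core":
                group = f"CORE_FLANK{core_counter:04d}"
                core_counter += 1
                domains: tuple[str, ...] = ()
                pseudo = False
            elif role == "signature":
                group = f"ACC_{cs.cluster_id}_{i}"
                domains = sig_domains[cs.signature_class]
                pseudo = cs.signature_pseudogene
            else:
                group = f"ACC_{cs.cluster_id}_{i}"
                domains = ()
                pseudo = False
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(("gene", (gid, cs.gene_length, strand, domains,
                                   group, role, pseudo)))
            if role != "flanking-core":
                member_idx.append(len(parts) - 1)
        cluster_blocks[cs.contig].append((cs, parts))

    # --- assemble each contig -------------------------------------------
    sequences: dict[str, str] = {}
    for name in contig_names:
        L = contig_len[name]
        left = telo_at.get((name, "left"))
        right = telo_at.get((name, "right"))
        blocks: list = list(floating[name])
        pinned = [(cs, parts) for cs, parts in cluster_blocks[name]
                  if cs.telomere_distance is not None]
        unpinned = [(cs, parts) for cs, parts in cluster_blocks[name]
                    if cs.telomere_distance is None]
        if len(pinned) > 1:
            raise PackingError(f"{name}: more than one telomere-pinned cluster")
        blocks += [("cluster", cp) for cp in unpinned]
        order = rng.permutation(len(blocks)) if blocks else []
        blocks = [blocks[i] for i in order]

        def _blen(b) -> int:
            if isinstance(b, _Block):
                return len(b)
            _, (cs, parts) = b
            return sum(len(p[1]) if p[0] == "seq"
                       else (len(p[1][0]) if p[0] == "repeat" else p[1][1])
                       for p in parts)

        planted = sum(_blen(b) for b in blocks)
        fixed = (len(left[0]) if left else 0) + (len(right[0]) if right else 0)
        pinned_len = 0
        if pinned:
            cs0, parts0 = pinned[0]
            pinned_len = sum(len(p[1]) if p[0] == "seq"
                             else (len(p[1][0]) if p[0] == "repeat" else p[1][1])
                             for p in parts0) + cs0.telomere_distance
        background = L - planted - fixed - pinned_len
        if background < 0:
            raise PackingError(
                f"{name}: planted features ({planted + fixed + pinned_len} bp) "
                f"exceed contig length ({L} bp)")

        n_gaps = len(blocks) + 1
        w = rng.random(n_gaps)
        gap_sizes = np.floor(background * w / w.sum()).astype(int)
        gap_sizes[-1] += background - int(gap_sizes.sum())

        chunks: list[str] = []
        bg_segments: list[tuple[int, int]] = []
        pos = 0

        def _emit_bg(n: int) -> None:
            nonlocal pos
            if n > 0:
                chunks.append(random_seq(n, recipe.base_gc, rng))
                bg_segments.append((pos, pos + n))
                pos += n

        def _emit_cluster(cs: ClusterSpec, parts: list) -> None:
            nonlocal pos
            gene_ivals: dict[str, tuple[int, int]] = {}
            member_ids: list[str] = []
            sig_id = ""
            for kind, payload in parts:
                if kind == "seq":
                    chunks.append(payload)
                    pos += len(payload)
                elif kind == "repeat":
                    rep, fam = payload
                    chunks.append(rep)
                    truth.repeats.append(PlantedRepeat(
                        family_id=fam, copy_id=f"{fam}.cl{len(truth.repeats)}",
                        contig=name, start=pos, end=pos + len(rep),
                        rip_rate=0.0, kind="te"))
                    pos += len(rep)
                else:
                    gid, glen, strand, domains, group, role, pseudo = payload
                    gseq = _gene_seq(glen)
                    chunks.append(gseq)
                    intron = max(40, glen // 10)
                    e1 = int(glen * 0.45)
                    cds = ((pos, pos + e1), (pos + e1 + intron, pos + glen))
                    genes.append(GeneModel(
                        gene_id=gid, contig=name, start=pos, end=pos + glen,
                        strand=strand, cds=cds, pseudogene=pseudo,
                        domains=domains, ortholog_group=group, role=role))
                    gene_ivals[gid] = (pos, pos + glen)
                    if role != "flanking-core":
                        member_ids.append(gid)
                    if role == "signature":
                        sig_id = gid
                    pos += glen
            lo = min(gene_ivals[g][0] for g in member_ids)
            hi = max(gene_ivals[g][1] for g in member_ids)
            truth.clusters.append(PlantedCluster(
                cluster_id=cs.cluster_id, contig=name, start=lo, end=hi,
                member_gene_ids=tuple(member_ids), signature_gene_id=sig_id,
                telomere_distance=cs.telomere_distance))

        if left:
            motif_arr, k = left
            truth.telomeres.append(PlantedTelomere(
                contig=name, end="left", motif=recipe.telomeres.motif,
                copies=k, start=0, stop=len(motif_arr)))
            chunks.append(revcomp(motif_arr))
            pos += len(motif_arr)
        for b, gap in zip(blocks, gap_sizes[:-1]):
            _emit_bg(int(gap))
            if isinstance(b, _Block):
                chunks.append(b.emit(name, pos, truth))
                pos += len(b)
            else:
                _emit_cluster(*b[1])
        _emit_bg(int(gap_sizes[-1]))
        if pinned:
            cs0, parts0 = pinned[0]
            _emit_cluster(cs0, parts0)
            _emit_bg(cs0.telomere_distance)
        if right:
            motif_arr, k = right
            truth.telomeres.append(PlantedTelomere(
                contig=name, end="right", motif=recipe.telomeres.motif,
                copies=k, start=pos, stop=pos + len(motif_arr)))
            chunks.append(motif_arr)
            pos += len(motif_arr)

        seq = "".join(chunks)
        assert len(seq) == L, f"{name}: assembled {len(seq)} != {L}"

        # background genes written onto the background segments
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        footprint = max(1200, int(round(1000.0 / max(recipe.gene_density, 1e-9))))
        for lo, hi in bg_segments:
            cursor = lo + int(rng.integers(100, 400))
            while True:
                glen = int(rng.integers(900, 2200))
                if cursor + glen + 100 > hi:
                    break
                gid = f"{name}_bg{len(genes)}"
                gseq = _gene_seq(glen)
                arr[cursor:cursor + glen] = np.frombuffer(
                    gseq.encode("ascii"), dtype=np.uint8)
                intron = max(40, glen // 10)
                e1 = int(glen * 0.45)
                genes.append(GeneModel(
                    gene_id=gid, contig=name, start=cursor, end=cursor + glen,
                    strand="+" if rng.random() < 0.5 else "-",
                    cds=((cursor, cursor + e1),
                         (cursor + e1 + intron, cursor + glen)),
                    pseudogene=False, domains=(),
                    ortholog_group=f"CORE{core_counter:05d}", role="core"))
                core_counter += 1
                cursor += glen + max(200, footprint - glen
                                     + int(rng.integers(-200, 200)))
        sequences[name] = arr.tobytes().decode("ascii")

    genes.sort(key=lambda g: (g.contig, g.start))
    return GenomeSet(sequences), genes, truth
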