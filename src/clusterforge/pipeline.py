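"""End-to-end orchestration and paper-style outputs.

Stages run in dependency order per genome -- repeat discovery -> masking ->
partition/GC stats -> RIP profiling -> MITE/telomere detection -> SM
cluster delimitation -> chemotype prediction -- followed by cross-genome
repeat correspondence when more than one genome is supplied.  Reports are
JSON/TSV first (machine-checkable), figures second; a manifest echoes every
parameter so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import chemotype as ct
from . import clusters as cl
from . import elements, io, repeats, rip
from .synthetic import GeneModel, GenomeSet


@dataclass
class GenomeInputs:
    genome_id: str
    fasta: str
    gff3: str


@dataclass
class PipelineConfig:
    inputs: list[GenomeInputs]
    outdir: str
    seed: int = 0
    min_score: float = 100.0
    repeat_min_len: int = 80        # keep MITE-scale elements discoverable
    repeat_min_copies: int = 3
    mask_min_identity: float = 70.0
    mite_bounds: tuple[int, int] = (80, 800)
    telomere_motif: str = "TTAGGG"
    telomere_min_copies: int = 3
    stop_run: int = 2
    telomere_link_max: int = 100_000
    rip_quantile: float = 0.95

    def validate(self) -> None:
        if not self.inputs:
            raise ValueError("pipeline needs at least one genome")
        for gi in self.inputs:
            for path in (gi.fasta, gi.gff3):
                if not Path(path).exists():
                    raise FileNotFoundError(f"{gi.genome_id}: missing input {path}")


@dataclass
class GenomeReport:
    genome_id: str
    partition: repeats.GenomePartitionStats
    n_repeat_families: int
    repeat_copies: int
    rip_flagged_fraction: Optional[float]
    n_mites: int
    n_telomeres: int
    clusters: list[cl.ClusterModel]
    chemotype: Optional[ct.ChemotypePrediction]


def _core_set(all_genes: dict[str, list[GeneModel]]) -> cl.CoreOrthologSet:
    memberships: dict[str, set[str]] = {}
    for gid, genes in all_genes.items():
        for g in genes:
            if g.ortholog_group:
                memberships.setdefault(g.ortholog_group, set()).add(gid)
    n = len(all_genes)
    if n == 1:
        # single genome: fall back to the annotation's own core labelling
        genes = next(iter(all_genes.values()))
        return cl.CoreOrthologSet(frozenset(
            g.ortholog_group for g in genes
            if g.ortholog_group and g.role in ("core", "flanking-core")))
    return cl.CoreOrthologSet.from_groups(memberships, n)


def _genotype_from_annotation(genome_id: str, genes: Sequence[GeneModel],
                              rulesets) -> Optional[ct.GenotypeProfile]:
    catalog: set[str] = set()
    aliases: dict[str, str] = {}
    for rs in rulesets.values():
        catalog |= rs.catalog
        aliases.update(rs.aliases)
    status: dict[str, int] = {}
    copies: dict[str, int] = {}
    prof = ct.GenotypeProfile(genome_id, {})
    for g in genes:
        base = g.gene_id.split("_")[-1].split(".")[0]
        name = aliases.get(base, base)
        if name not in catalog:
            continue
        if name not in prof.status or not g.pseudogene:
            prof.status[name] = "pseudogene" if g.pseudogene else "functional"
        prof.copies[name] = prof.copies.get(name, 0) + 1
    return prof if prof.status else None


def run_pipeline(config: PipelineConfig) -> dict[str, GenomeReport]:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rulesets = ct.load_all_rulesets()

    genomes: dict[str, GenomeSet] = {}
    genes_by_genome: dict[str, list[GeneModel]] = {}
    for gi in config.inputs:
        try:
            genomes[gi.genome_id] = io.read_fasta(gi.fasta)
            genes_by_genome[gi.genome_id] = io.read_gff3(gi.gff3)
        except Exception as exc:
            raise RuntimeError(f"stage=load genome={gi.genome_id}: {exc}") from exc

    core = _core_set(genes_by_genome)
    reports: dict[str, GenomeReport] = {}
    libraries: dict[str, list[repeats.RepeatFamily]] = {}

    for gi in config.inputs:
        gid = gi.genome_id
        genome = genomes[gid]
        genes = genes_by_genome[gid]
        gdir = outdir / gid
        gdir.mkdir(exist_ok=True)

        fams = repeats.discover_repeats(
            genome, min_score=config.min_score,
            min_len=config.repeat_min_len,
            min_copies=config.repeat_min_copies)
        libraries[gid] = fams
        masked = (repeats.mask_repeats(genome, fams,
                                       min_identity=config.mask_min_identity)
                  if fams else [])
        stats = repeats.partition_stats(genome, genes, masked)

        flagged = None
        if fams:
            exclude: dict[str, list[tuple[int, int]]] = {}
            for c in masked:
                exclude.setdefault(c.contig, []).append(c.interval)
            for g in genes:
                exclude.setdefault(g.contig, []).append(g.interval)
            try:
                background = rip.background_distribution(
                    genome, exclude, quantile=config.rip_quantile)
                verdicts = [v for fam in fams
                            for v in rip.classify_ripped(fam, genome, background)]
                done = [v for v in verdicts if v.ripped is not None]
                flagged = (sum(v.ripped for v in done) / len(done)
                           if done else None)
            except ValueError:
                flagged = None

        telos = elements.detect_telomeres(
            genome, motif=config.telomere_motif,
            min_copies=config.telomere_min_copies)
        mites = elements.call_mites(fams, genome,
                                    length_bounds=config.mite_bounds)

        sigs = cl.find_signature_genes(genes)
        models: list[cl.ClusterModel] = []
        by_contig: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_contig.setdefault(g.contig, []).append(g)
        claimed: set[str] = set()
        for n, (sig, _classes) in enumerate(sigs, 1):
            if sig.gene_id in claimed:
                continue
            model = cl.delimit_cluster(sig, by_contig[sig.contig], core,
                                       stop_run=config.stop_run,
                                       cluster_id=f"{gid}_SM{n:02d}")
            claimed.update(model.member_ids)
            cl.cluster_repeat_cds_logratio(model, masked, genes)
            cl.assess_functional_status(model)
            cl.link_telomere(model, telos, max_distance=config.telomere_link_max)
            models.append(model)

        genotype = _genotype_from_annotation(gid, genes, rulesets)
        prediction = ct.predict(genotype, rulesets) if genotype else None

        reports[gid] = GenomeReport(
            genome_id=gid, partition=stats, n_repeat_families=len(fams),
            repeat_copies=len(masked), rip_flagged_fraction=flagged,
            n_mites=len(mites), n_telomeres=len(telos),
            clusters=models, chemotype=prediction)

        io.write_bed([(c.contig, c.start, c.end, c.family_id) for c in masked],
                     gdir / "repeats.bed")
        _write_cluster_tsv(models, gdir / "clusters.tsv")
        io.write_json(_report_dict(reports[gid]), gdir / "report.json")

    if len(libraries) > 1:
        matrix = repeats.correspond_families(libraries)
        io.write_json(
            {"universal": {f"{g}:{f}": n for (g, f), n in matrix.universal.items()},
             "scheme": matrix.scheme,
             "min_score": matrix.params.min_score},
            outdir / "correspondence.json")

    manifest = {"config": {**asdict(config)}, "genomes": sorted(genomes)}
    io.write_json(manifest, outdir / "manifest.json")
    return reports


def _report_dict(rep: GenomeReport) -> dict:
    return {
        "genome_id": rep.genome_id,
        "partition": asdict(rep.partition),
        "pct": {"cds": rep.partition.pct_cds,
                "repeat": rep.partition.pct_repeat,
                "nonrepeat_intergenic": rep.partition.pct_nonrepeat_intergenic},
        "n_repeat_families": rep.n_repeat_families,
        "repeat_copies": rep.repeat_copies,
        "rip_flagged_fraction": rep.rip_flagged_fraction,
        "n_mites": rep.n_mites,
        "n_telomeres": rep.n_telomeres,
        "clusters": [{
            "cluster_id": c.cluster_id, "contig": c.contig,
            "start": c.start, "end": c.end,
            "members": c.member_ids, "signatures": c.signature_ids,
            "repeat_bp": c.repeat_bp, "cds_bp": c.cds_bp,
            "log_ratio": c.log_ratio, "status": c.status,
            "telomere_distance": c.telomere_distance,
            "one_sided": c.one_sided,
        } for c in rep.clusters],
        "chemotype": (None if rep.chemotype is None else {
            pw: {"producible": p.producible, "end_products": p.end_products,
                 "accumulating": p.accumulating, "blocked_at": p.blocked_at}
            for pw, p in rep.chemotype.pathways.items()}),
    }


def _write_cluster_tsv(models: Sequence[cl.ClusterModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tcontig\tstart\tend\trepeat_bp\tcds_bp\t"
                 "log_ratio\tstatus\ttelomere_distance\n")
        for c in models:
            fh.write(f"{c.cluster_id}\t{c.contig}\t{c.start}\t{c.end}\t"
                     f"{c.repeat_bp}\t{c.cds_bp}\t"
                     f"{'' if c.log_ratio is None else f'{c.log_ratio:.4f}'}\t"
                     f"{c.status}\t"
                     f"{'' if c.telomere_distance is None else c.telomere_distance}"
                     "\n")


# --------------------------------------------------------------------------
# locus maps
# --------------------------------------------------------------------------

def render_locus_map(cluster: cl.ClusterModel, masked: Sequence,
                     mites: Sequence, telomeres: Sequence,
                     genome: GenomeSet, out_prefix: str | Path,
                     window: int = 200, step: int = 200,
                     margin: int = 5000) -> list[tuple]:
    """One locus map per cluster: gene, repeat, MITE and AT/GC tracks.

    Writes ``<prefix>.png`` and a machine-readable layered table
    ``<prefix>.tsv`` (track, name, start, end, value) so tests need not
    parse images.  Telomere linkage, when present, is annotated with the
    distance in kb.  Returns the table rows.
    """
    lo = max(0, cluster.start - margin)
    hi = min(len(genome.sequences[cluster.contig]), cluster.end + margin)
    rows: list[tuple] = []
    for g in cluster.members:
        rows.append(("gene", g.gene_id, g.start, g.end,
                     -1.0 if g.pseudogene else 1.0))
    for c in masked:
        if c.contig == cluster.contig and c.start < hi and c.end > lo:
            rows.append(("repeat", c.family_id, c.start, c.end, c.identity))
    for m in mites:
        if m.contig == cluster.contig and m.start < hi and m.end > lo:
            rows.append(("mite", m.family_id, m.start, m.end, m.tir.identity))
    comp = rip.composition_track(genome.sequences[cluster.contig][lo:hi],
                                 window, step, cluster.contig)
    for contig, wlo, whi, at, gc, nfrac in comp:
        rows.append(("at", contig, lo + wlo, lo + whi, at))
        rows.append(("gc", contig, lo + wlo, lo + whi, gc))

    out_prefix = Path(out_prefix)
    with open(out_prefix.with_suffix(".tsv"), "w") as fh:
        fh.write("track\tname\tstart\tend\tvalue\n")
        for track, name, s, e, v in rows:
            fh.write(f"{track}\t{name}\t{s}\t{e}\t{v:.4f}\n")

    fig, axes = plt.subplots(4, 1, sharex=True, figsize=(10, 6),
                             height_ratios=[1, 1, 1, 2])
    for g in cluster.members:
        color = "tab:gray" if g.pseudogene else "tab:blue"
        axes[0].barh(0, g.end - g.start, left=g.start, height=0.5, color=color)
    axes[0].set_ylabel("genes")
    for track, name, s, e, v in rows:
        if track == "repeat":
            axes[1].barh(0, e - s, left=s, height=0.5, color="cyan")
        elif track == "mite":
            axes[2].barh(0, e - s, left=s, height=0.5, color="black")
    axes[1].set_ylabel("repeats")
    axes[2].set_ylabel("MITEs")
    at_rows = [(s, v) for t, _, s, e, v in rows if t == "at"]
    gc_rows = [(s, v) for t, _, s, e, v in rows if t == "gc"]
    if at_rows:
        axes[3].plot(*zip(*at_rows), color="red", label="AT")
        axes[3].plot(*zip(*gc_rows), color="blue", label="GC")
        axes[3].legend(loc="upper right", fontsize=8)
    axes[3].set_ylabel("fraction")
    axes[3].set_xlabel(f"{cluster.contig} (bp)")
    title = cluster.cluster_id
    if cluster.telomere_distance is not None:
        title += f"  (telomere {cluster.telomere_distance / 1000.0:.1f} kb)"
    axes[0].set_title(title)
    for ax in axes[:3]:
        ax.set_yticks([])
    fig.savefig(out_prefix.with_suffix(".png"), dpi=100)
    plt.close(fig)
    return rows
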