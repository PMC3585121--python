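"""File-format boundaries: FASTA, GFF3, BED, tabular hits, truth tables.

Internally everything is 0-based half-open; GFF3 and the 12-column BLAST
tabular dialect are 1-based inclusive, BED/bedGraph are 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import GeneModel, GenomeSet, TruthTable


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSet:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeSet(seqs)


def write_fasta(genome: GenomeSet | dict[str, str], path: str | Path) -> None:
    seqs = genome.sequences if isinstance(genome, GenomeSet) else genome
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Emit gene + CDS features; 0-based half-open -> 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            attrs = [f"ID={g.gene_id}"]
            if g.ortholog_group:
                attrs.append(f"ortholog_group={g.ortholog_group}")
            if g.role:
                attrs.append(f"role={g.role}")
            if g.pseudogene:
                attrs.append("pseudogene=true")
            if g.domains:
                attrs.append("Dbxref=" + ",".join(
                    ("InterPro:" + d) if d.startswith("IPR") else ("Pfam:" + d)
                    for d in g.domains))
            fh.write("\t".join([g.contig, "clusterforge", "gene",
                                str(g.start + 1), str(g.end), ".", g.strand,
                                ".", ";".join(attrs)]) + "\n")
            for i, (lo, hi) in enumerate(g.cds):
                fh.write("\t".join([g.contig, "clusterforge", "CDS",
                                    str(lo + 1), str(hi), ".", g.strand, "0",
                                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}"])
                         + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique")
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        cds = tuple(sorted((c.start - 1, c.end)
                           for c in db.children(feat, featuretype="CDS")))
        if not cds:
            cds = ((feat.start - 1, feat.end),)
        domains: list[str] = []
        for ref in feat.attributes.get("Dbxref", []):
            for token in ref.split(","):
                domains.append(token.split(":", 1)[-1])
        genes.append(GeneModel(
            gene_id=feat.id,
            contig=feat.seqid,
            start=feat.start - 1,
            end=feat.end,
            strand=feat.strand or "+",
            cds=cds,
            pseudogene=feat.attributes.get("pseudogene", ["false"])[0].lower()
            == "true",
            domains=tuple(domains),
            ortholog_group=feat.attributes.get("ortholog_group", [None])[0],
            role=feat.attributes.get("role", ["background"])[0],
        ))
    genes.sort(key=lambda g: (g.contig, g.start))
    return genes


# --------------------------------------------------------------------------
# BED / bedGraph / TSV
# --------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple[str, int, int, str]],
              path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, start, end, name in intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\n")


def write_bedgraph(rows: Iterable[tuple[str, int, int, float]],
                   path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, start, end, value in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{value:.6g}\n")


def write_truth(truth: TruthTable, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "truth_repeats.tsv", "w") as fh:
        fh.write("family_id\tcopy_id\tcontig\tstart\tend\trip_rate\tkind\tnested_in\n")
        for r in truth.repeats:
            fh.write(f"{r.family_id}\t{r.copy_id}\t{r.contig}\t{r.start}\t"
                     f"{r.end}\t{r.rip_rate}\t{r.kind}\t{r.nested_in or ''}\n")
    with open(outdir / "truth_telomeres.tsv", "w") as fh:
        fh.write("contig\tend\tmotif\tcopies\tstart\tstop\n")
        for t in truth.telomeres:
            fh.write(f"{t.contig}\t{t.end}\t{t.motif}\t{t.copies}\t"
                     f"{t.start}\t{t.stop}\n")
    with open(outdir / "truth_clusters.tsv", "w") as fh:
        fh.write("cluster_id\tcontig\tstart\tend\tmembers\tsignature\t"
                 "telomere_distance\n")
        for c in truth.clusters:
            fh.write(f"{c.cluster_id}\t{c.contig}\t{c.start}\t{c.end}\t"
                     f"{','.join(c.member_gene_ids)}\t{c.signature_gene_id}\t"
                     f"{'' if c.telomere_distance is None else c.telomere_distance}\n")


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        try:
            return asdict(o)
        except TypeError:
            return str(o)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
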