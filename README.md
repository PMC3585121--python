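# clusterforge

Comparative genome-architecture analysis of fungal alkaloid biosynthesis
loci, built for the repeat-blocked genomes of plant-symbiotic
Clavicipitaceae (*Epichloë*, *Neotyphodium*, *Claviceps*, *Periglandula*
and relatives). These fungi keep their specialized-metabolism (SM) gene
clusters — ergot alkaloids (*EAS*), indole-diterpenes (*IDT/LTM*), lolines
(*LOL*) and peramine (*PER*) — embedded in large AT-rich blocks of
RIP-degraded transposon relics, often near telomeres, and the gene content
of each cluster predicts which alkaloids a strain can make.

The package provides, as a library and a `clusterforge` command line:

- **`synthetic`** — genomes with known ground truth that emulate the
  structural features above (multicopy transposon relics with nested
  insertions, RIP-mutated copies, MITEs with terminal inverted repeats,
  terminal telomere arrays, SM clusters with core/periphery layout), so
  every downstream stage is testable without downloads.
- **`repeats`** — repeat-family discovery from a genome self-alignment
  (BLAST+ under the hood), non-redundant family clustering, cross-genome
  correspondence ("universal repeat numbers" from reciprocal exemplar
  alignment, score > 100), masking, and the genome partition / GC
  accounting (CDS / genic-non-CDS / repeat / non-repeat-intergenic).
- **`rip`** — sliding-window RIP-index profiling. Repeat-induced point
  mutation converts CpA-context cytosines to thymines; the index
  ApT/TpA is computed in 200 bp windows stepped by 20 bp (partial windows
  are not counted; both dinucleotides are palindromic, so the index is
  strand-symmetric). A composite per-copy classifier flags repeats whose
  median TpA/ApT exceeds the intergenic background and whose GC sits
  below it.
- **`elements`** — MITE detection by terminal-inverted-repeat structure
  (seed-and-extend, einverted-style +3/−4 scoring) and telomere-repeat
  array detection at contig ends (default motif TTAGGG), with feature
  distances to the nearest array.
- **`clusters`** — SM signature genes from InterPro/Pfam domains
  (NRPS IPR010071/IPR006163/IPR001242, PKS IPR013968, DMATS
  IPR017795/PF11991, terpene synthase/cyclase IPR008949), cluster
  delimitation by the primary-metabolism ortholog rule (extension stops at
  a run of genes whose ortholog group spans all genomes), repeat:CDS
  log10 ratios, active/inactive status, telomere linkage, and a
  core–periphery layout statistic with a permutation test.
- **`orthology`** — recursive bipartition of ortholog groups; a division
  is accepted when column-bootstrap support ≥ 0.75 and the split score
  |taxa(A) ∩ taxa(B)| / min(|taxa(A)|, |taxa(B)|) is ≥ 0.5 (a high split
  score marks an ancient duplication). A reciprocal-best-hit grouping
  stand-in builds input groups from per-genome protein sets.
- **`chemotype`** — rule-based genotype → chemotype prediction. Each
  pathway is a dependency chain of product nodes (e.g. EAS:
  {dmaW,easF,easE,easC} → chanoclavine-I, … → ergonovine (EN) →
  lysergic acid α-hydroxyethylamide (LAH), and lysergic acid +
  {lpsA,lpsB,easH} → ergopeptines). Pseudogenes count as absent; the
  deepest reachable product is the predicted accumulating end product.
  Shipped genotype tables cover the sequenced isolates.
- **`pipeline`** — orchestrates everything per genome and writes JSON/TSV
  reports, correspondence matrices, and gene/repeat/MITE/AT-GC locus maps.

## Worked example

Generate a 250 kb synthetic genome with a shared repeat family, a MITE
family, a right-arm telomere, and one telomere-linked SM cluster, then run
the pipeline:

```bash
clusterforge run --fasta gA.fa --gff3 gA.gff3 --out out/ --seed 1
# gA: 2 repeat families, 1 SM clusters, 1 telomeres, 6 MITE copies
```

`out/gA/report.json` (abridged):

```json
{
  "pct": {"cds": 47.045, "nonrepeat_intergenic": 42.229, "repeat": 5.512},
  "n_repeat_families": 2,
  "n_mites": 6,
  "n_telomeres": 1,
  "clusters": [{
    "cluster_id": "gA_SM01",
    "members": ["gA_cl1_g2", "gA_cl1_g3", "gA_cl1_g4", "gA_cl1_g5", "gA_cl1_g6"],
    "status": "active",
    "telomere_distance": 23800
  }]
}
```

Reading: 5.5% of the genome masks as repeat DNA in 2 families (one
transposon relic, one MITE with 6 copies); one SM cluster of 5 genes
around its PKS signature gene is delimited between conserved flanks and
sits 23.8 kb from the single detected telomere array.

Chemotype prediction for a strain that lacks only `lpsA` and `easH`:

```bash
clusterforge chemotype predict --strain Ngi
```

reports EAS producible products `CC, agroclavine, EC, lysergic_acid, EN,
LAH` with `LAH` accumulating and no ergopeptine — the gene content
supports the simple lysergyl amides but not the lysergyl peptide
synthetase step.

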