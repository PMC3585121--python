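# Methods

This note records the models, parameter choices and numerical decisions
behind each stage, what the synthetic genomes do and do not emulate, and
the known limitations.

## Synthetic genomes

Contigs are assembled from blocks: terminal telomere arrays, transposon
copies, MITE copies, SM cluster blocks, and i.i.d. background sequence at
a specified GC (default 0.44, the typical whole-genome GC of epichloid
assemblies; CDS regions are written at GC + 0.11 to reproduce the
genic/repeat GC contrast). Inter-block gaps are drawn from normalized
uniform weights over the residual length, so block order and spacing are
random but fully determined by the recipe seed. Packing that exceeds the
contig length raises an explicit error rather than truncating.

Transposon copies are an exemplar mutated at a uniform substitution rate,
then RIPped. RIP is modelled as a single pass over CpA context only (the
dominant *Neurospora*-style dinucleotide preference): each forward-strand
CpA cytosine mutates C→T with the per-copy rate, and independently each
reverse-strand CpA (forward TpG) mutates its C, i.e. G→A on the forward
strand. Contexts are read from the input, so one pass never cascades; the
per-copy RIP intensity of real genomes is not quantified anywhere we can
cite, so recipe rates are free parameters, not estimates. Nested
insertion places a later element inside an earlier copy and splits the
host's truth interval into two sub-intervals with the same copy id.

MITEs are an arm + loop + reverse-complement-arm construction; telomere
arrays are exact tandem motif repeats (reverse complement at the left
contig end). Background genes are laid into the inter-block gaps with
two-exon structures and sequential "core" ortholog-group labels; cluster
genes carry accessory group labels, the signature gene its class's domain
ids. Coordinates are 0-based half-open internally and converted to
1-based inclusive GFF3 only at I/O.

What the generator does *not* emulate: codon structure, transcription,
assembly gaps and errors, population variation, and the long-range
heterogeneity of real intergenic DNA. Passing tests on these genomes
demonstrate correctness of the interval logic, the scanners and the
statistics under the stated noise models — not performance on real
assemblies, where hand curation of repeat libraries remains necessary.

## Repeat discovery and accounting

Self-alignment, masking and exemplar correspondence call NCBI `blastn`
(`-task blastn`, match +2 / mismatch −3 / gap 5,2; `-dust no`, since
RIPped AT-rich repeats would otherwise be masked as low complexity). The
scoring scheme is recorded in every hit set because the raw-score
threshold (default 100) is only meaningful relative to it. The more
common megablast scoring was rejected: copies diverged ≥ 15% from their
exemplar — routine after RIP — fragment badly at word size 28.

Multicopy candidates are per-locus unions of hit query footprints.
Footprints group when they reciprocally overlap by ≥ 0.5 of the shorter;
non-overlapping footprints merge only when they *chain* — query gap and
subject gap both ≤ 100 bp on the same subject and strand — which glues
fragments of one interrupted alignment while never bridging two unrelated
adjacent elements into a chimeric candidate (plain positional merging
does, roughly whenever any two planted elements land within the merge gap
anywhere in the genome). Families are single-linkage components of
candidates connected by hits, exemplar = longest member, ids numbered by
exemplar position, so discovery is deterministic and input-order
invariant. Heavily RIPped copies can still fall below alignment
detectability; no RIP-aware reduced-alphabet alignment is attempted.

Masking re-aligns exemplars to the genome and resolves inter-family
overlaps by score. The genome partition assigns every non-gap base to
exactly one of CDS > genic-non-CDS > intergenic-repeat >
intergenic-non-repeat (the precedence keeps genic totals consistent with
the annotation and makes the partition exact); N bases are excluded, and
percentages are over non-gap length — whether published tables include
gap bases is ambiguous, so the choice is recorded in output metadata.
The per-category GCs satisfy the exact conservation identity
Σ bp·GC = total·GC, which the tests assert to 1e-9.

## RIP index and classification

The index is counted over overlapping dinucleotides, case-insensitive,
in 200 bp windows stepped 20 bp, windows fully inside the sequence only.
Dinucleotides containing ambiguity codes are skipped, not imputed. Both
orientations are supported: ApT/TpA (the printed convention; falls with
RIP) and TpA/ApT (rises with RIP; used internally for classification so
that "higher = more RIPped"). Windows run in stored contig orientation —
a centromere-to-telomere direction cannot be honored without centromere
annotation, and the index is strand- and direction-symmetric anyway.

A repeat copy is flagged RIPped when (a) its median window TpA/ApT
exceeds the 0.95 quantile of the background and (b) its GC is below the
background median — the composite criterion reflects that RIP inference
is always coupled with the low GC of affected repeats. The background is
built from non-repeat intergenic sequence tiled into 1 kb blocks, taking
the distribution of *block-median* indices: the verdict compares a copy's
median (a low-variance statistic over many windows) and must be referred
to the distribution of that same statistic; the 0.95 quantile of raw
single-window indices is inflated by window noise and would mask moderate
RIP. Copies shorter than one window are "indeterminate".

## MITEs and telomeres

The inverted-repeat scanner seeds on exact 8-mers matching the reverse
complement and extends without gaps under +3/−4 scoring with an X-drop
of 24, reporting maximal non-redundant arm pairs above the arm-length,
loop-length and identity thresholds. Gapped TIR arms are out of scope;
at MITE scale real TIRs are essentially ungapped. A repeat family is
MITE-classified when its exemplar is 80–800 bp, has ≥ 2 genomic copies,
and carries a TIR pair within 50 bp of the exemplar termini (the slack
absorbs the boundary fuzz of alignment-derived candidates, which can
overhang the element by a few tens of bp). Classification is structural
(de novo), not matched against any curated MITE database.

Telomere arrays are counted motif-by-motif from each contig end (default
TTAGGG, minimum 3 copies, array start within 50 bp of the terminus;
reverse complement at the left end). Up to 2 mismatches per motif copy
are tolerated for at most one copy in three, but only in the array
interior: the terminal-most copy must be exact and inward trailing
mismatched copies are trimmed. Without the trim, a random adjacent
hexamer within 2 mismatches of the motif (probability ≈ 4%) would
over-count a perfect array by one. Feature-to-telomere distance is the
bp gap to the nearest same-contig array, 0 when abutting.

## SM clusters

Genes whose ortholog group spans every input genome are treated as
probable primary metabolism ("core"); extension from a signature gene
includes non-core genes and stops at `stop_run` consecutive core genes
(default 2: a single inserted housekeeping gene should not truncate a
cluster; 1 and larger values are supported). Genes with no ortholog
group count as accessory. An interrupted core run sits inside the span
but its genes are not members; the first core gene of the terminating run
is recorded as the flank. A signature gene whose extension reaches a
contig end yields a flagged one-sided cluster. Cluster boundaries span
the first to last member gene; including contiguous flanking repeat
blocks in the span is a config toggle since published cluster figures do
not state the convention.

Repeat and CDS content are interval intersections within the boundary;
the log10(repeat bp / CDS bp) ratio is defined only when both are
positive. A cluster is inactive iff every signature gene is a
pseudogene. Telomere linkage = same contig and distance ≤ 100 kb
(configurable; published linkage statements are qualitative).

The core–periphery layout statistic is this package's own formalization:
each gene's peripherality is its normalized rank distance from the
cluster midpoint (0 = centre, 1 = end); the statistic is
mean(decoration) − mean(skeleton), and significance is a one-sided
seeded permutation of the role labels. Its attainable p-value floor is
set by the number of distinct label assignments, not by the permutation
count.

## Ortholog-group refinement

Members are aligned with a built-in center-star progressive aligner
(edlib pairwise alignments merged on the center's gap pattern) — adequate
for distance-based clustering, pluggable for anything better. Pairwise
p-distances over shared non-gap columns are average-linkage clustered and
cut into exactly two clusters (the deepest split); if the cut does not
produce two non-empty sides the group is left unpartitioned, mirroring
the upstream tool's documented infinite-loop fix. Support is the
fraction of 100 column-resampled replicates reproducing the same member
bipartition; a division is accepted at bootstrap ≥ 0.75 and split score
≥ 0.5 and refinement recurses into accepted sides. Each node derives its
resampling seed from the sorted member ids, so changing thresholds never
perturbs the bootstrap stream — acceptance counts are then provably
monotone in the thresholds. Groups of < 3 members are leaves. The
candidate-bipartition choice (deepest split) is an assumption this
package pins; the original procedure's internals are unpublished.

The RBH stand-in builds groups as single-linkage components of
reciprocal best edit-distance hits (ties broken lexicographically,
distance ≤ 0.7 of the longer sequence); it exists so refinement has
deterministic inputs without an external clustering tool, not as a
replacement for a real orthology inference.

## Chemotype rules

Pathways are acyclic dependency chains shipped as JSON data files; a
node's effective requirement is the union of its own and its ancestors'
gene sets. Pseudogene and absent are equivalent. The deepest reachable
node is the accumulating product; the missing genes of the shallowest
unreachable node are the reported block. Specific encodings:

- Elymoclavine and lysergic acid both require `cloA` by default (the
  oxygenase for the agroclavine step is uncertain in at least one
  non-producing lineage; the requirement is a documented default, not an
  inference from sequence).
- `easA` skeleton variation (ergoline vs dihydroergoline) is a gene
  attribute defaulting to the ergoline branch; none of the tabulated
  strains produce dihydroergolines, and sequence-based classification is
  out of scope.
- `lpsA` specificity is not inferred; ergopeptines are reported at class
  level, with one distinct ergopeptine per `lpsA` copy
  (`ergopeptine_count`).
- `idtS`/`ltmS` is co-required for paspaline but toggleable
  (`require_co=False`), since its role is unresolved.
- `perA-ΔR*` (reductase domain deleted) produces no peramine but is kept
  as a distinct genotype state.

The shipped genotype table transcribes the published strain × gene
matrix; where the plain-text table alignment is ambiguous the Results
prose wins, and cells not pinned by prose are best-effort (marked in the
file header). The concordance fixture asserts only the
genotype→chemotype cases the study itself called consistent, plus one
expected-discordant case (EAS genes present but unexpressed in one
isolate, so gene content alone over-predicts).

## Problem sizes

The acceptance script and test suite use: a 5 Mb two-contig genome with
8 families of 3–20 copies at 85–100% exemplar identity for repeat
recall/precision; 100 copies at RIP rates 0.5 vs 0 for classification
accuracy; 10 seeded genomes for exact telomere recovery; an 800 kb
genome with 10 MITE families and 2 non-MITE relic families for MITE
recall/precision; 50 replicates of planted clusters for boundary
accuracy; 20 seeded two-clade duplication scenarios (4 taxa × 2 copies,
200 aa, 30%/5% deep/shallow divergence) at 100 bootstrap replicates.
These sizes were chosen to estimate each rate with useful resolution
while the whole analysis remains a desk-scale computation.
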