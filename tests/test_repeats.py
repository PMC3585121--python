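"""Self-alignment, family calling, correspondence, masking, partition stats."""

import numpy as np
import pytest

from clusterforge.repeats import (AlignmentHit, CorrespondenceParams,
                                  call_multicopy_segments,
                                  cluster_into_families, correspond_families,
                                  discover_repeats, mask_repeats,
                                  merged_masked_intervals, partition_stats,
                                  self_align)
from clusterforge.seqs import random_seq
from clusterforge.synthetic import (GeneModel, GenomeRecipe, GenomeSet,
                                    TeFamilySpec, generate_genome)


def _hit(q, qs, qe, s, ss, se, score=200.0, pident=95.0):
    return AlignmentHit(q, qs, qe, s, ss, se, pident, qe - qs, score, "+")


class TestSelfAlign:
    def test_random_contig_no_hits(self):
        rng = np.random.default_rng(0)
        genome = GenomeSet({"c1": random_seq(10_000, 0.5, rng)})
        assert self_align(genome, min_score=100) == []

    def test_exact_duplication_detected(self):
        rng = np.random.default_rng(1)
        dup = random_seq(2000, 0.5, rng)
        seq = (random_seq(3000, 0.5, rng) + dup + random_seq(3000, 0.5, rng)
               + dup + random_seq(2000, 0.5, rng))
        hits = self_align(GenomeSet({"c1": seq}), min_score=100)
        full = [h for h in hits if h.pident == 100.0
                and h.qend - h.qstart >= 1990]
        assert full

    def test_stable_under_contig_reordering(self):
        rng = np.random.default_rng(2)
        dup = random_seq(1000, 0.5, rng)
        seqs = {"a": random_seq(2000, 0.5, rng) + dup,
                "b": dup + random_seq(2000, 0.5, rng)}
        h1 = self_align(GenomeSet(dict(seqs)))
        h2 = self_align(GenomeSet(dict(reversed(list(seqs.items())))))
        assert h1 == h2

    def test_empty_genome(self):
        assert self_align(GenomeSet({}), 100) == []


class TestCallMulticopy:
    def test_empty_hits(self):
        assert call_multicopy_segments([], 400, 3) == []

    def test_adjacent_chained_footprints_merged(self):
        # fragments of one interrupted alignment chain on query and subject
        hits = [_hit("c", 1000, 1500, "c", 5000, 5500),
                _hit("c", 1540, 2000, "c", 5540, 6000),
                _hit("c", 1000, 2000, "c", 8000, 9000)]
        segs = call_multicopy_segments(hits, min_len=400, min_copies=3,
                                       merge_gap=100)
        assert segs == [("c", 1000, 2000)]

    def test_adjacent_unrelated_footprints_not_merged(self):
        # same query gap, but the subjects do not continue: two elements
        hits = [_hit("c", 1000, 1500, "c", 5000, 5500),
                _hit("c", 1540, 2000, "c", 9000, 9460)]
        segs = call_multicopy_segments(hits, min_len=400, min_copies=2,
                                       merge_gap=100)
        assert segs == [("c", 1000, 1500), ("c", 1540, 2000)]

    def test_min_copies_filter(self):
        hits = [_hit("c", 1000, 2000, "c", 5000, 6000)]
        assert call_multicopy_segments(hits, 400, min_copies=3) == []
        assert call_multicopy_segments(hits, 400, min_copies=2) \
            == [("c", 1000, 2000)]

    def test_planted_copies_recovered(self, small_genome):
        genome, _, truth = small_genome
        hits = self_align(genome)
        segs = call_multicopy_segments(hits, min_len=400, min_copies=3)
        tahi = [(r.start, r.end) for r in truth.repeats
                if r.family_id == "tahi"]
        for lo, hi in tahi:
            best = max((min(hi, e) - max(lo, s)
                        for _, s, e in segs), default=0)
            assert best >= 0.9 * (hi - lo)


class TestFamilies:
    def test_two_planted_families_separate(self):
        recipe = GenomeRecipe(
            seed=9, contigs=(("c1", 400_000),),
            te_families=(TeFamilySpec("a", 2000, 5, sub_rate=0.02),
                         TeFamilySpec("b", 1000, 4, sub_rate=0.08)))
        genome, _, truth = generate_genome(recipe)
        fams = discover_repeats(genome)
        assert len(fams) == 2
        assert sorted(len(f.copies) for f in fams) == [4, 5]

    def test_clustering_matches_union_find_oracle(self):
        candidates = [("c", i * 1000, i * 1000 + 500) for i in range(8)]
        hits = [_hit("c", 0, 500, "c", 1000, 1500),
                _hit("c", 1000, 1500, "c", 2000, 2500),
                _hit("c", 4000, 4500, "c", 5000, 5500),
                _hit("c", 6000, 6500, "c", 7000, 7500),
                _hit("c", 5000, 5500, "c", 6000, 6500)]
        rng = np.random.default_rng(3)
        genome = GenomeSet({"c": random_seq(10_000, 0.5, rng)})
        fams = cluster_into_families(candidates, hits, genome)
        # brute-force union-find over the same edges
        parent = list(range(8))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a, b in [(0, 1), (1, 2), (4, 5), (6, 7), (5, 6)]:
            parent[find(a)] = find(b)
        expected = {}
        for i in range(8):
            expected.setdefault(find(i), set()).add(i)
        expected_sets = sorted(
            sorted(s) for s in expected.values() if len(s) >= 2)
        got_sets = sorted(sorted(c.start // 1000 for c in f.copies)
                          for f in fams)
        assert got_sets == expected_sets

    def test_exemplar_is_longest_member(self, small_genome):
        genome, _, _ = small_genome
        fams = discover_repeats(genome, min_len=80)
        for f in fams:
            assert len(f.exemplar) == max(c.end - c.start for c in f.copies)
            assert len(f.copies) >= 2


class TestCorrespondence:
    def test_shared_family_gets_common_number(self):
        libs = {}
        for gid, seed in (("gA", 21), ("gB", 22)):
            recipe = GenomeRecipe(
                seed=seed, contigs=(("c1", 300_000),),
                te_families=(TeFamilySpec("shared", 2000, 5, sub_rate=0.03,
                                          exemplar_seed=777),
                             TeFamilySpec("own", 1200, 4, sub_rate=0.03),))
            genome, _, _ = generate_genome(recipe)
            libs[gid] = discover_repeats(genome)
        matrix = correspond_families(libs)
        shared_pairs = [((g, f.family_id)) for g, fams in libs.items()
                        for f in fams]
        numbers = {}
        for node, n in matrix.universal.items():
            numbers.setdefault(n, []).append(node)
        multi = [v for v in numbers.values() if len(v) > 1]
        assert len(multi) == 1 and len(multi[0]) == 2
        singles = [v for v in numbers.values() if len(v) == 1]
        assert len(singles) == 2

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(6)
        ex = random_seq(1500, 0.5, rng)
        from clusterforge.repeats import RepeatCopy, RepeatFamily
        fam = lambda g: [RepeatFamily("RF001", ex, ("c", 0, 1500),
                                      [RepeatCopy("c", 0, 1500, "+", "RF001", 1.0),
                                       RepeatCopy("c", 3000, 4500, "+", "RF001", 1.0)])]
        m1 = correspond_families({"x": fam("x"), "y": fam("y")})
        m2 = correspond_families({"y": fam("y"), "x": fam("x")})
        assert m1.universal == m2.universal

    def test_min_score_positive_required(self):
        with pytest.raises(ValueError):
            CorrespondenceParams(0).validate()


class TestMasking:
    def test_masking_recovers_planted_bp(self, small_genome):
        genome, _, truth = small_genome
        fams = discover_repeats(genome, min_len=80)
        masked = mask_repeats(genome, fams)
        mm = merged_masked_intervals(masked)
        truth_iv = truth.repeat_intervals()
        tp = 0
        tbp = 0
        for contig, ivals in truth_iv.items():
            for lo, hi in ivals:
                tbp += hi - lo
                tp += sum(max(0, min(hi, e) - max(lo, s))
                          for s, e in mm.get(contig, []))
        assert tp / tbp >= 0.95

    def test_random_genome_low_false_masking(self):
        rng = np.random.default_rng(7)
        target = GenomeSet({"r": random_seq(200_000, 0.5, rng)})
        donor_recipe = GenomeRecipe(
            seed=55, contigs=(("c1", 200_000),),
            te_families=(TeFamilySpec("f", 1500, 4),))
        donor, _, _ = generate_genome(donor_recipe)
        fams = discover_repeats(donor)
        masked = mask_repeats(target, fams)
        bp = sum(c.end - c.start for c in masked)
        assert bp / 200_000 < 0.005

    def test_masking_deterministic(self, small_genome):
        genome, _, _ = small_genome
        fams = discover_repeats(genome, min_len=80)
        assert mask_repeats(genome, fams) == mask_repeats(genome, fams)


class TestPartitionStats:
    def _toy(self):
        rng = np.random.default_rng(8)
        seq = random_seq(1000, 0.5, rng)
        genome = GenomeSet({"c": seq})
        genes = [GeneModel("g1", "c", 0, 400, "+", ((0, 400),))]
        masked = {"c": [(500, 800)]}
        return genome, genes, masked

    def test_toy_percentages(self):
        genome, genes, masked = self._toy()
        st = partition_stats(genome, genes, masked)
        assert st.pct_cds == 40.0
        assert st.pct_repeat == 30.0
        assert st.pct_nonrepeat_intergenic == 30.0

    def test_all_cds_contig(self):
        rng = np.random.default_rng(9)
        genome = GenomeSet({"c": random_seq(600, 0.5, rng)})
        genes = [GeneModel("g", "c", 0, 600, "+", ((0, 600),))]
        st = partition_stats(genome, genes, {})
        assert st.pct_cds == 100.0
        assert st.repeat_bp == st.nonrepeat_intergenic_bp == 0

    def test_categories_partition_total(self, small_genome):
        genome, genes, _ = small_genome
        fams = discover_repeats(genome, min_len=80)
        masked = mask_repeats(genome, fams)
        st = partition_stats(genome, genes, masked)
        assert (st.cds_bp + st.genic_noncds_bp + st.repeat_bp
                + st.nonrepeat_intergenic_bp) == st.total_bp

    def test_weighted_gc_identity(self, small_genome):
        genome, genes, _ = small_genome
        fams = discover_repeats(genome, min_len=80)
        masked = mask_repeats(genome, fams)
        st = partition_stats(genome, genes, masked)
        parts = [(st.cds_bp, st.gc_cds),
                 (st.genic_noncds_bp, st.gc_genic_noncds),
                 (st.repeat_bp, st.gc_repeat),
                 (st.nonrepeat_intergenic_bp, st.gc_nonrepeat_intergenic)]
        weighted = sum(bp * g for bp, g in parts if bp) / st.total_bp
        assert weighted == pytest.approx(st.gc_genome, abs=1e-9)

    def test_gene_outside_contig_rejected(self):
        genome, genes, masked = self._toy()
        bad = [GeneModel("gX", "c", 900, 1200, "+", ((900, 1200),))]
        with pytest.raises(ValueError, match="gX"):
            partition_stats(genome, bad, masked)

    def test_gaps_excluded(self):
        genome = GenomeSet({"c": "ACGT" * 100 + "N" * 100})
        st = partition_stats(genome, [], {})
        assert st.total_bp == 400
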