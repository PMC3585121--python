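"""Signature genes, cluster delimitation vs brute-force oracle, accounting."""

import itertools
import math

import numpy as np
import pytest

from clusterforge.clusters import (SIGNATURE_CATALOG, CoreOrthologSet,
                                   assess_functional_status,
                                   cluster_repeat_cds_logratio,
                                   core_periphery_layout, delimit_cluster,
                                   find_signature_genes)
from clusterforge.repeats import RepeatCopy
from clusterforge.synthetic import (ClusterSpec, GeneModel, GenomeRecipe,
                                    generate_genome)


def _gene(i, group, domains=(), contig="c", pseudo=False):
    start = i * 2000
    return GeneModel(f"g{i}", contig, start, start + 1500, "+",
                     ((start, start + 1500),), pseudogene=pseudo,
                     domains=tuple(domains), ortholog_group=group)


def _core(groups):
    return CoreOrthologSet(frozenset(groups))


class TestSignatureGenes:
    def test_pks_domain_matched(self):
        genes = [_gene(0, "x", domains=("IPR013968",)),
                 _gene(1, "y", domains=("IPR999999",))]
        found = find_signature_genes(genes)
        assert [(g.gene_id, cls) for g, cls in found] == [("g0", ["PKS"])]

    def test_multi_class_gene_returned_once(self):
        genes = [_gene(0, "x", domains=("IPR013968", "IPR010071"))]
        found = find_signature_genes(genes)
        assert len(found) == 1
        assert found[0][1] == ["NRPS", "PKS"]

    def test_dmats_pfam_id(self):
        genes = [_gene(0, "x", domains=("PF11991",))]
        assert find_signature_genes(genes)[0][1] == ["DMATS"]

    def test_catalog_contents(self):
        assert SIGNATURE_CATALOG["NRPS"] == {"IPR010071", "IPR006163",
                                             "IPR001242"}
        assert SIGNATURE_CATALOG["TS"] == {"IPR008949"}


def _brute_force_delimit(order, sig_idx, core, stop_run):
    """Literal left/right scan: collect non-core genes, stop at stop_run
    consecutive core genes; an interrupted core run is dropped."""
    members = {sig_idx}
    for direction in (-1, 1):
        run = 0
        i = sig_idx + direction
        while 0 <= i < len(order):
            if core(i):
                run += 1
                if run >= stop_run:
                    break
            else:
                run = 0
                members.add(i)
            i += direction
    return sorted(members)


class TestDelimitation:
    def test_accessory_cluster_with_core_flanks(self):
        #        0     1     2    3    4    5    6     7
        genes = [_gene(0, "K1"), _gene(1, "K2"), _gene(2, "a"),
                 _gene(3, "b"), _gene(4, "sig", domains=("IPR013968",)),
                 _gene(5, "c"), _gene(6, "K3"), _gene(7, "K4")]
        core = _core({"K1", "K2", "K3", "K4"})
        model = delimit_cluster(genes[4], genes, core, stop_run=2)
        assert model.member_ids == ["g2", "g3", "g4", "g5"]
        assert model.flank_left.gene_id == "g1"
        assert model.flank_right.gene_id == "g6"
        assert not model.one_sided

    def test_signature_surrounded_by_core(self):
        genes = [_gene(0, "K1"), _gene(1, "K2"),
                 _gene(2, "sig", domains=("IPR013968",)),
                 _gene(3, "K3"), _gene(4, "K4")]
        model = delimit_cluster(genes[2], genes,
                                _core({"K1", "K2", "K3", "K4"}), 2)
        assert model.member_ids == ["g2"]

    def test_stop_run_sensitivity(self):
        # [SIG acc core acc core core]
        genes = [_gene(0, "sig", domains=("IPR013968",)), _gene(1, "a"),
                 _gene(2, "K1"), _gene(3, "b"), _gene(4, "K2"),
                 _gene(5, "K3")]
        core = _core({"K1", "K2", "K3"})
        m1 = delimit_cluster(genes[0], genes, core, stop_run=1)
        m2 = delimit_cluster(genes[0], genes, core, stop_run=2)
        is_core = lambda i: genes[i].ortholog_group in core.groups
        for stop_run, model in ((1, m1), (2, m2)):
            expected = _brute_force_delimit(genes, 0, is_core, stop_run)
            assert [g.gene_id for g in model.members] \
                == [f"g{i}" for i in expected]
        assert m1.member_ids != m2.member_ids

    def test_no_ortholog_group_treated_as_accessory(self):
        genes = [_gene(0, "K1"), _gene(1, "K2"), _gene(2, None),
                 _gene(3, "sig", domains=("IPR013968",)),
                 _gene(4, "K3"), _gene(5, "K4")]
        model = delimit_cluster(genes[3], genes, _core({"K1", "K2", "K3", "K4"}), 2)
        assert "g2" in model.member_ids

    def test_contig_end_flags_one_sided(self):
        genes = [_gene(0, "sig", domains=("IPR013968",)), _gene(1, "a"),
                 _gene(2, "K1"), _gene(3, "K2")]
        model = delimit_cluster(genes[0], genes, _core({"K1", "K2"}), 2)
        assert model.one_sided

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_on_random_configurations(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 25))
        labels = ["core" if rng.random() < 0.5 else f"acc{i}"
                  for i in range(n)]
        sig = int(rng.integers(0, n))
        labels[sig] = "accS"
        genes = [_gene(i, f"K{i}" if lab == "core" else lab,
                       domains=("IPR013968",) if i == sig else ())
                 for i, lab in enumerate(labels)]
        core = _core({f"K{i}" for i, lab in enumerate(labels)
                      if lab == "core"})
        stop_run = int(rng.integers(1, 4))
        model = delimit_cluster(genes[sig], genes, core, stop_run=stop_run)
        is_core = lambda i: genes[i].ortholog_group in core.groups
        expected = _brute_force_delimit(genes, sig, is_core, stop_run)
        assert [g.gene_id for g in model.members] \
            == [f"g{i}" for i in expected]

    def test_boundary_accuracy_on_planted_clusters(self):
        """Boundaries land within one gene of truth in >=90% of replicates."""
        good = 0
        n_rep = 50
        for seed in range(n_rep):
            recipe = GenomeRecipe(
                seed=seed + 1000, contigs=(("c1", 120_000),),
                clusters=(ClusterSpec("cl", "c1"),))
            _, genes, truth = generate_genome(recipe)
            cluster = truth.clusters[0]
            sig = next(g for g in genes
                       if g.gene_id == cluster.signature_gene_id)
            core = CoreOrthologSet(frozenset(
                g.ortholog_group for g in genes
                if g.role in ("core", "flanking-core") and g.ortholog_group))
            model = delimit_cluster(sig, genes, core, stop_run=2)
            order = [g.gene_id for g in sorted(genes, key=lambda g: g.start)]
            t0, t1 = (order.index(cluster.member_gene_ids[0]),
                      order.index(cluster.member_gene_ids[-1]))
            m0, m1 = (order.index(model.member_ids[0]),
                      order.index(model.member_ids[-1]))
            if abs(m0 - t0) <= 1 and abs(m1 - t1) <= 1:
                good += 1
        assert good / n_rep >= 0.9


class TestAccounting:
    def _model(self, members=None):
        members = members or [_gene(0, "s", domains=("IPR013968",))]
        from clusterforge.clusters import ClusterModel
        return ClusterModel("cl", "c", members,
                            [members[0].gene_id],
                            min(g.start for g in members),
                            max(g.end for g in members))

    def test_equal_repeat_and_cds_gives_zero(self):
        g = GeneModel("g0", "c", 0, 10_000, "+", ((0, 5000),))
        model = self._model([g])
        masked = [RepeatCopy("c", 5000, 10_000, "+", "f", 1.0)]
        cluster_repeat_cds_logratio(model, masked, [g])
        assert model.log_ratio == 0.0

    def test_tenfold_repeat_gives_one(self):
        g = GeneModel("g0", "c", 0, 22_000, "+", ((0, 2000),))
        model = self._model([g])
        masked = [RepeatCopy("c", 2000, 22_000, "+", "f", 1.0)]
        cluster_repeat_cds_logratio(model, masked, [g])
        assert model.log_ratio == pytest.approx(1.0)

    def test_zero_cds_flagged_undefined(self):
        g = GeneModel("g0", "c", 0, 1000, "+", ())
        model = self._model([g])
        cluster_repeat_cds_logratio(model, [], [g])
        assert model.log_ratio is None

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_interval_intersection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = 50_000
        genes = []
        for i in range(8):
            s = int(rng.integers(0, L - 3000))
            genes.append(GeneModel(f"g{i}", "c", s, s + 2000, "+",
                                   ((s, s + 1000),)))
        masked = []
        for i in range(12):
            s = int(rng.integers(0, L - 2000))
            masked.append(RepeatCopy("c", s, s + int(rng.integers(200, 2000)),
                                     "+", "f", 1.0))
        model = self._model([genes[0]])
        model.start, model.end = 10_000, 40_000
        cluster_repeat_cds_logratio(model, masked, genes)

        def bp(intervals):
            grid = np.zeros(L, dtype=bool)
            for lo, hi in intervals:
                grid[lo:hi] = True
            return int(grid[10_000:40_000].sum())

        assert model.repeat_bp == bp([(c.start, c.end) for c in masked])
        assert model.cds_bp == bp([iv for g in genes for iv in g.cds])
        assert model.repeat_bp + model.cds_bp <= 2 * (model.end - model.start)

    def test_status_rules(self):
        sig_pseudo = _gene(0, "s", domains=("IPR013968",), pseudo=True)
        model = self._model([sig_pseudo])
        assert assess_functional_status(model) == "inactive"
        sig_ok = _gene(0, "s", domains=("IPR013968",))
        acc_pseudo = _gene(1, "a", pseudo=True)
        model = self._model([sig_ok, acc_pseudo])
        assert assess_functional_status(model) == "active"
        two_sigs = [_gene(0, "s", domains=("IPR013968",), pseudo=True),
                    _gene(1, "t", domains=("IPR013968",))]
        from clusterforge.clusters import ClusterModel
        model = ClusterModel("cl", "c", two_sigs, ["g0", "g1"], 0, 3500)
        assert assess_functional_status(model) == "active"


class TestLayout:
    def test_extreme_layout_max_statistic_and_p(self):
        # decorations at the four most peripheral ranks of an 8-gene cluster
        roles = ["decoration", "decoration", "skeleton", "skeleton",
                 "skeleton", "skeleton", "decoration", "decoration"]
        stat, p = core_periphery_layout(roles, n_perm=1999, seed=1)
        # exhaustive check that no label assignment beats the observed one
        n = len(roles)
        idx = list(range(n))
        periph = [abs(i - (n - 1) / 2) / ((n - 1) / 2) for i in idx]
        best = -math.inf
        n_best = 0
        for combo in itertools.combinations(idx, 4):
            d = np.mean([periph[i] for i in combo])
            s = np.mean([periph[i] for i in idx if i not in combo])
            if d - s > best + 1e-12:
                best, n_best = d - s, 1
            elif abs(d - s - best) <= 1e-12:
                n_best += 1
        assert stat == pytest.approx(best)
        assert n_best == 1
        # minimal attainable p is ~1/C(8,4); observed must sit near it
        assert p <= 3 / math.comb(8, 4)

    def test_alternating_roles_near_zero(self):
        roles = ["decoration", "skeleton"] * 3
        stat, _ = core_periphery_layout(roles, n_perm=99, seed=0)
        assert abs(stat) < 0.35

    def test_antisymmetric_under_role_swap(self):
        roles = ["decoration", "skeleton", "decoration", "skeleton",
                 "skeleton", "decoration"]
        swapped = ["skeleton" if r == "decoration" else "decoration"
                   for r in roles]
        s1, _ = core_periphery_layout(roles, n_perm=9, seed=0)
        s2, _ = core_periphery_layout(swapped, n_perm=9, seed=0)
        assert s1 == pytest.approx(-s2)

    def test_missing_role_rejected(self):
        with pytest.raises(ValueError):
            core_periphery_layout(["skeleton", "skeleton"], 9, 0)
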